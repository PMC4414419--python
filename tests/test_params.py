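"""Units, parameter validation, and the receptor encounter-time formula."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytograd.params import (ModelParams, concentration_convert,
                             berg_purcell_time, fast_diffusion_range_cells,
                             MOLEC_PER_UM3_PER_NM)


class TestConcentrationConvert:
    @pytest.mark.parametrize("value,frm,to,expected", [
        (1.0, "nM", "molecules/um3", 0.602214076),
        (0.0, "pM", "nM", 0.0),
        (1.0, "pM", "molecules/um3", 6.02214076e-4),
    ])
    def test_known_values(self, value, frm, to, expected):
        assert concentration_convert(value, frm, to) == pytest.approx(
            expected, rel=1e-12)

    def test_one_pM_is_one_molecule_per_1660_um3(self):
        # 1 pM corresponds to ~1 molecule in 1700 um^3 (exactly 1660.6)
        c = concentration_convert(1.0, "pM", "molecules/um3")
        assert 1.0 / c == pytest.approx(1660.54, rel=1e-3)

    @given(st.floats(min_value=0, max_value=1e6),
           st.sampled_from(["nM", "pM", "molecules/um3"]),
           st.sampled_from(["nM", "pM", "molecules/um3"]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity(self, value, a, b):
        back = concentration_convert(concentration_convert(value, a, b), b, a)
        assert back == pytest.approx(value, rel=1e-12, abs=1e-300)

    def test_unknown_unit_is_named_in_error(self):
        with pytest.raises(ValueError, match="furlong"):
            concentration_convert(1.0, "furlong", "nM")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            concentration_convert(-1.0, "nM", "pM")


class TestBergPurcell:
    def test_reference_evaluation_is_6_9_minutes(self):
        # c=10 pM, R=100, d_R=0.1 nm, D=10 um^2/s, rho=5 um
        tau = berg_purcell_time(10.0, 100.0)
        assert tau / 60.0 == pytest.approx(6.9, abs=0.1)

    def test_cell_encounter_term_is_subsecond(self):
        # receptor-rich limit: only the diffusion-to-cell term remains
        tau = berg_purcell_time(10.0, 1e12)
        assert tau == pytest.approx(0.264, abs=0.005)
        assert tau < 1.0

    @given(st.floats(min_value=0.1, max_value=1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_doubling_concentration_halves_tau(self, c):
        assert berg_purcell_time(2 * c, 100.0) == pytest.approx(
            berg_purcell_time(c, 100.0) / 2.0, rel=1e-12)

    def test_monotone_decreasing_in_every_argument(self):
        base = dict(c=10.0, R=100.0)
        tau0 = berg_purcell_time(**base)
        assert berg_purcell_time(c=20.0, R=100.0) < tau0
        assert berg_purcell_time(c=10.0, R=200.0) < tau0
        for field, hi in (("D", 20.0), ("rho", 10.0), ("d_R", 2e-4)):
            tau = berg_purcell_time(10.0, 100.0,
                                    ModelParams().replace(**{field: hi}))
            assert tau < tau0

    @pytest.mark.parametrize("c,R", [(0, 100), (-1, 100), (10, 0)])
    def test_degenerate_inputs_rejected(self, c, R):
        with pytest.raises(ValueError):
            berg_purcell_time(c, R)


class TestModelParams:
    def test_defaults_match_published_values(self):
        p = ModelParams()
        assert (p.D, p.rho, p.L_cell, p.q) == (10.0, 5.0, 5.0, 10.0)
        assert (p.k_on, p.k_d) == (111.6, 0.1)
        assert (p.a, p.l_syn) == (2.0, 0.02)
        assert (p.R_low, p.R_high) == (100.0, 4000.0)
        assert (p.v0_Th, p.v0_Treg, p.v1_Th, p.v1_Treg) == (150.0, 1000.0,
                                                            3000.0, 8000.0)
        assert (p.K, p.hill_n, p.frac_secreting) == (1000.0, 3.0, 0.25)

    def test_bundled_parameter_file_round_trips(self, tmp_path):
        import importlib.resources as res
        with res.as_file(res.files("cytograd") / "data" /
                         "table1.yaml") as f:
            p = ModelParams.load(f)
        assert p == ModelParams()
        out = tmp_path / "p.yaml"
        p.save(out)
        assert ModelParams.load(out) == p

    @pytest.mark.parametrize("bad", [dict(D=-1), dict(frac_secreting=1.2),
                                     dict(hill_n=0.5), dict(rho=0)])
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="viscosity"):
            ModelParams.from_dict({"viscosity": 1.0})

    def test_fast_diffusion_range_is_40_cell_distances(self):
        assert fast_diffusion_range_cells() == pytest.approx(40.0, rel=1e-12)

    def test_kon_unit_conversion(self):
        p = ModelParams()
        assert p.k_on_um3_per_h * MOLEC_PER_UM3_PER_NM == pytest.approx(111.6)

    def test_bundled_kinetic_presets_match_parameter_set(self):
        from cytograd.params import load_kinetics_preset
        p = ModelParams()
        assert load_kinetics_preset("responder_th") == \
            p.kinetics("responder_th")
        assert load_kinetics_preset("treg") == p.kinetics("treg")
        with pytest.raises(ValueError, match="nk_cell"):
            load_kinetics_preset("nk_cell")
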