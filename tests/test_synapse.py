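"""Immunological-synapse cylinder model: Bessel solution vs. FD oracle."""

import numpy as np
import pytest

from cytograd.params import ModelParams
from cytograd.synapse import (SynapseScenario, solve_synapse, flux_breakdown,
                              effective_secretion_rate, solve_synapse_fd)

P = ModelParams()


def scenario(**kw):
    return SynapseScenario.from_params(P, **kw)


def fractions(**kw):
    return flux_breakdown(solve_synapse(scenario(**kw))).fractions


class TestFluxPartition:
    def test_no_receptors_everything_escapes(self):
        for l in (0.02, 0.5, 2.0):
            f = fractions(R=0, R_resp=0, l=l)
            assert f["J_escape"] == pytest.approx(1.0, abs=1e-9)
            assert f["J_auto"] == 0.0 and f["J_synapse"] == 0.0

    def test_apc_partner_gives_no_synaptic_flux(self):
        f = fractions(R=4000, R_resp=0)
        assert f["J_synapse"] == 0.0
        assert f["J_auto"] > 0.5   # upregulated secretor recaptures most

    def test_tt_synapse_low_low_symmetric_fluxes(self):
        # two basal Th cells: autocrine and synaptic uptake nearly equal
        # (exactly equal only as l -> 0: the source sits on one face)
        f = fractions(R=100, R_resp=100)
        assert f["J_auto"] == pytest.approx(f["J_synapse"], rel=0.01)

    def test_face_asymmetry_vanishes_with_cleft_height(self):
        gaps = []
        for l in (0.04, 0.02, 0.01, 0.005):
            f = fractions(R=100, R_resp=100, l=l)
            gaps.append(f["J_auto"] - f["J_synapse"])
        assert all(g > 0 for g in gaps)          # secreting face wins
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_treg_partner_outcompetes_secretor(self):
        f = fractions(R=100, R_resp=1e4)
        assert f["J_synapse"] > f["J_auto"]
        assert f["J_synapse"] > 0.8

    def test_escape_monotone_in_cleft_height(self):
        esc = [fractions(R=100, R_resp=100, l=l)["J_escape"]
               for l in (0.01, 0.02, 0.1, 0.5, 2.0)]
        assert all(a < b for a, b in zip(esc, esc[1:]))

    def test_autocrine_fraction_monotone_in_R(self):
        auto = [fractions(R=R, R_resp=100)["J_auto"]
                for R in (100, 1000, 4000)]
        assert all(a < b for a, b in zip(auto, auto[1:]))

    def test_conservation_over_parameter_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            sc = scenario(R=10 ** rng.uniform(0, 4.3),
                          R_resp=10 ** rng.uniform(0, 4.3),
                          l=10 ** rng.uniform(-2, 0.5),
                          q=rng.uniform(1, 50))
            fb = flux_breakdown(solve_synapse(sc))  # raises beyond 1e-6
            total = fb.J_auto + fb.J_synapse + fb.J_escape
            assert total == pytest.approx(sc.q, rel=1e-6)


class TestConcentrationField:
    def test_rim_dirichlet_and_positivity(self):
        field = solve_synapse(scenario(R=100, R_resp=100))
        z = np.linspace(0, 0.02, 7)
        assert np.allclose(field(2.0, z), 0.0, atol=1e-10)
        r, zz = np.meshgrid(np.linspace(0, 1.99, 40),
                            np.linspace(0, 0.02, 7), indexing="ij")
        assert (field(r, zz) >= -1e-12).all()

    def test_tight_synapse_reaches_nanomolar(self):
        field = solve_synapse(scenario(R=100, R_resp=100))
        assert field.concentration_nM(0.0, 0.0) > 1.0

    def test_no_synapse_geometry_dilutes_strongly(self):
        # 2 um cleft: opposed-surface concentration far below the tight case
        tall = solve_synapse(scenario(R=100, R_resp=100, l=2.0))
        c_pM = tall.concentration_nM(0.0, 2.0) * 1e3
        assert c_pM < 50.0
        tight = solve_synapse(scenario(R=100, R_resp=100))
        assert tight.concentration_nM(0.0, 0.02) * 1e3 > 10 * c_pM

    def test_linearity_in_q(self):
        f1 = solve_synapse(scenario(R=300, R_resp=50, q=10.0))
        f2 = solve_synapse(scenario(R=300, R_resp=50, q=20.0))
        assert f2(0.7, 0.01) == pytest.approx(2 * f1(0.7, 0.01), rel=1e-9)


class TestEffectiveSecretionRate:
    def test_zero_secretion_gives_zero(self):
        assert effective_secretion_rate(scenario(R=4000, q=0.0)) == 0.0

    def test_doubling_q_doubles_qeff(self):
        q1 = effective_secretion_rate(scenario(R=4000, q=10.0))
        q2 = effective_secretion_rate(scenario(R=4000, q=20.0))
        assert q2 == pytest.approx(2 * q1, rel=1e-9)

    def test_units_are_molecules_per_hour(self):
        sc = scenario(R=4000, R_resp=0)
        fb = flux_breakdown(solve_synapse(sc))
        assert effective_secretion_rate(sc) == pytest.approx(
            fb.J_escape * 3600.0, rel=1e-6)


class TestFiniteDifferenceOracle:
    @pytest.mark.parametrize("kw", [
        dict(R=4000, R_resp=0),
        dict(R=4000, R_resp=1e4),
        dict(R=100, R_resp=100),
        dict(R=100, R_resp=100, l=2.0),
    ])
    def test_fluxes_match_axisymmetric_fd(self, kw):
        sc = scenario(**kw)
        bessel = flux_breakdown(solve_synapse(sc))
        nz = 200 if sc.l > 1 else 40
        fd = solve_synapse_fd(sc, nr=400, nz=nz)
        for name in ("J_auto", "J_synapse", "J_escape"):
            assert getattr(fd, name) == pytest.approx(
                getattr(bessel, name), abs=0.01 * sc.q)
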