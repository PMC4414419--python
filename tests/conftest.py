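"""Shared fixtures.

The multicellular simulations are the expensive part of the suite, so the
scenarios used by several tests run once per session and are reused.
"""

import numpy as np
import pytest

from cytograd import (ModelParams, SimConfig, build_geometry, run)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_culture(params):
    """4^3 culture, 25% secretors, 30 h: a scaled-down dense Th culture."""
    geom = build_geometry((4, 4, 4), 0.25, seed=1)
    cfg = SimConfig(voxel_size=2.5, t_end=30.0, store_fields=True,
                    output_every=2.0)
    return run(geom, params, cfg)


@pytest.fixture(scope="session")
def fig3_culture(params):
    """216-cell Th culture (54 secretors, q_eff=7200/h, 30 h)."""
    geom = build_geometry((6, 6, 6), 0.25, seed=1)
    return run(geom, params, SimConfig(voxel_size=2.5, t_end=30.0))


@pytest.fixture(scope="session")
def fig4_coculture(params):
    """216-cell Th-Treg coculture (54 secretors + 54 Tregs), same seed."""
    geom = build_geometry((6, 6, 6), 0.25, 0.25, seed=1)
    return run(geom, params, SimConfig(voxel_size=2.5, t_end=30.0))
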