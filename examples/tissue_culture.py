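"""A small in-silico T cell culture: who activates, and at what cost?

Runs the 3D reaction-diffusion simulation for a 64-cell culture with 25%
polarized secretors for 30 h, then repeats it with regulatory T cells
added.  Prints activation counts, the bulk concentration time course and
the mass ledger.  (A few minutes of compute; the 216-cell setup behaves
the same way.)
"""

import numpy as np

from cytograd import (ModelParams, SimConfig, activation_summary,
                      build_geometry, bulk_vs_local_report, run)

params = ModelParams()
cfg = SimConfig(voxel_size=2.5, t_end=30.0)

for frac_treg, label in ((0.0, "Th culture"), (0.25, "Th-Treg coculture")):
    geom = build_geometry((4, 4, 4), frac_secreting=0.25,
                          frac_treg=frac_treg, seed=1)
    traj = run(geom, params, cfg)
    summ = activation_summary(traj)
    rep = bulk_vs_local_report(traj)
    print(f"--- {label} ---")
    print("  roles:", {k: v["total"] for k, v in summ.items()})
    print("  activated responders:",
          f"{summ['responder_th']['activated']}/"
          f"{summ['responder_th']['total']}")
    print(f"  bulk concentration: peak "
          f"{1e3 * traj.bulk_nM.max():7.1f} pM at "
          f"{rep['peak_time_h']:.1f} h, final "
          f"{rep['bulk_final_pM']:5.1f} pM")
    print(f"  local maxima exceed bulk {rep['local_over_bulk_max']:.1f}-fold")
    print(f"  mass-ledger closure error: {traj.mass_balance_error:.1e}")

# Without Tregs the culture sees a strong transient (nM range) that
# ignites receptor upregulation; competition then splits the population
# into receptor-high activated and receptor-low silent cells at ~10 pM.
# Tregs soak up the transient entirely: no responder ever activates.
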