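# cytograd

Spatial models of paracrine cytokine signaling between T cells, built
around interleukin-2 (IL-2).

Measured bulk cytokine concentrations are picomolar — at 10 pM a naive
T cell with R = 100 high-affinity receptors is hit by a ligand only once
every ~7 minutes (Berg–Purcell estimate
τ = 1/(4πDρc) + 1/(4·D·d_R·R·c) ≈ 6.9 min).  How, then, do effective
paracrine IL-2 signals arise?  `cytograd` answers this quantitatively at
three nested scales, with one shared parameter set:

1. **Spherical shell** (`cytograd.shell`) — closed-form steady state of
   secretion and receptor uptake around a single cell, c(r) = A/r + B,
   giving the autocrine/paracrine partition
   J_auto = k_on·c(ρ)·R, J_para = q − J_auto.
2. **Immunological synapse** (`cytograd.synapse`) — Bessel-mode solution
   of diffusion in the cylindrical cleft (contact radius a = 2 μm,
   height 20 nm–2 μm) with Robin uptake on the two cell faces and an
   absorbing rim, partitioning secretion into J_auto, J_synapse and the
   escape flux J_escape (the *effective secretion rate* q_eff available
   for extrasynaptic signaling).
3. **Multicellular tissue** (`cytograd.tissue`) — 3D finite-volume
   reaction–diffusion simulation of hundreds to thousands of spherical
   cells with polarized point secretion, per-cell receptor trafficking
   ODEs with Hill-type IL-2-induced receptor expression
   (v = v0 + v1·C³/(K³+C³)), regulatory T cells as strong competitors,
   and a mass ledger that closes to solver precision.

The intended users are quantitative immunologists and modelers who want
a tested, desk-scale reimplementation of this class of cytokine
reaction–diffusion models to probe signaling range, receptor
competition, and synapse leakage.

## Worked example

Where does cytokine secreted into an immunological synapse end up?

```bash
$ python examples/synapse_fluxes.py
geometry      secretor R  opposed R   auto   synapse  escape
tight 20 nm        100        100   0.286   0.286    0.428
tight 20 nm        100      10000   0.010   0.920    0.070
tight 20 nm       4000          0   0.893   0.000    0.107
tight 20 nm       4000      10000   0.285   0.656    0.059
no synapse         100        100   0.026   0.004    0.970
...
peak concentration in the tight synapse: 1.48 nM
```

Reading: in a tight (20 nm) synapse between two naive Th cells the two
cells split ~57% of the secretion and 43% leaks out; a regulatory T cell
on the other side (10⁴ receptors) captures 92% of everything; a
preactivated secretor (R = 4000) recaptures ~90% autocrinally.  Without
a synapse (2 μm gap) essentially everything escapes into the bulk.  The
1.48 nM peak shows how the 100:1 aspect ratio concentrates a
10 molecules/s source a hundred-fold above bulk levels.

At tissue scale (`python examples/tissue_culture.py`), a 30 h culture
with 25% polarized secretors (q_eff = 7200 molecules/h) shows the full
spatio-temporal story: a nanomolar transient in the first hours ignites
receptor upregulation everywhere, competitive uptake then depletes IL-2
to ~10 pM, and the population splits bimodally into receptor-high
activated cells (>4000 surface receptors) and receptor-low silent ones —
roughly 60–70 of 162 responders in the 216-cell setup.  Adding 25%
regulatory T cells absorbs the transient completely: zero responders
activate.  `examples/pulse_travel_distance.py` releases a single
molecule-equivalent and shows it is typically captured 3–5 cell
diameters from its source.

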