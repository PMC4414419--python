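# Receptor expression/trafficking presets per cell type (see docs/methods.md
# for the provenance of the trafficking rates).  Units: molecules/cell/h for
# v0/v1, complexes/cell for K, 1/(nM h) for k_on, 1/h otherwise.
responder_th:
  v0: 150.0
  v1: 3000.0
  K: 1000.0
  hill_n: 3.0
  k_on: 111.6
  k_off: 0.83
  k_iR: 1.6
  k_iC: 2.9
  k_rec: 5.0
  k_deg: 1.0
treg:
  v0: 1000.0
  v1: 8000.0
  K: 1000.0
  hill_n: 3.0
  k_on: 111.6
  k_off: 0.83
  k_iR: 1.6
  k_iC: 2.9
  k_rec: 5.0
  k_deg: 1.0
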