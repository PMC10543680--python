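# Toroidal water pores (R_w = 20 A) in a DPPC bilayer, a = 150 A, g_a = 0.3.
system:
  host_lipid: dppc
  concentration_mM: 3.0
  island:
    type: pore
    r_w: 20.0
  lattice: {a: 150.0, g_a: 0.3}
  stack: {n_bilayers: 1}
probe: {kind: xray, x_d: 0.0}
instrument: {kappa: 1.0, background: 0.0}
qgrid: {qmin: 0.01, qmax: 0.5, n: 160}
seed: 1
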