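# Classic Lotka-Volterra predator-prey worked example: a neutrally stable
# orbit around the coexistence point (H*, P*) = (d/(e a), r/a) = (15, 5).
model: predator-prey
variant: lv
params:
  r: 0.5
  a: 0.1
  e: 0.2
  d: 0.3
init:
  H: 10.0
  P: 10.0
t_end: 100.0
dt_out: 1.0
rel_tol: 1.0e-10
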