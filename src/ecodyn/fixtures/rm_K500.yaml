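# Rosenzweig-MacArthur above the enrichment threshold (K_crit ~ 366.67):
# growing oscillations onto a stable limit cycle.
model: predator-prey
variant: rosenzweig_macarthur
params:
  r: 0.5
  a: 0.02
  T_h: 0.3
  e: 0.4
  d: 0.5
  K: 500.0
init:
  H: 10.0
  P: 10.0
t_end: 400.0
dt_out: 0.1
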