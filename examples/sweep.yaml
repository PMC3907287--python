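# Success-rate sweep in the matched-rate regime (d = a = 0.003).
chain:
  n_cells: 170
  n_stim: 150
  g: 0.997
  c: 0.006
  dt: 0.05
schedule:
  T: 60.0
  t_exec: 30.0
  f1: 34.0
eps: 0.1
sweep:
  t_s_grid: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55]
  sigma_grid: [0.03, 0.045]
  reps: 200
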