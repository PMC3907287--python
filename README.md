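# decayamp

Simulator and analysis toolkit for a **decay–amplify** working-memory
mechanism. A noisy, leaky rate network stores an analog stimulus variable
as the amplitude of a traveling activity pulse in a feed-forward chain
(or a symmetric-kernel field). Because the cell-to-cell coupling `g` is
not tuned to the line-attractor point, the stored activity decays slowly;
an externally timed *executive input* at time `t_s` un-gates a block of
late cells whose feedback (strength `c`) amplifies the activity back to
the stimulus-indicative level by the end of the delay period.

The package bundles:

- `decayamp.gain` — the four rectified piecewise-linear response-function
  configurations (loading / maintenance / comparison / quiescent), fixed-point
  classification, and the monotone stimulus→activity map;
- `decayamp.dynamics` — Euler–Maruyama simulation of the chain and of the
  symmetric-kernel field with its late-cell line, with seeded,
  counter-split noise streams;
- `decayamp.theory` — closed forms: the deep-cell envelope
  `x0·exp((g−1)t)`, the piecewise-exponential decay–amplify envelope, the
  line-attractor minimal coupling `1 + ln(1−ε)/T`, and the admissible
  executive-input window `[(aT − ln(1+ε))/(a+d), (aT − ln(1−ε))/(a+d)]`
  of length `≈ 2ε/(a+d)`;
- `decayamp.analysis` — encoding criterion, early/persistent/late cell
  classification, encoding-count curves, wavefront tracking, comparison
  readout and trial success;
- `decayamp.experiments` — seeded, scripted studies: success-rate sweeps
  over `(t_s, σ)`, noise-integration comparison against a line attractor,
  delay-length stretching, and the four-pattern activity catalogue.

## CLI

Every figure-level experiment is a subcommand; each takes `--config`
(YAML, all keys optional), `--seed`, and `--out` (CSV plus a
`.meta.json` sidecar):

```sh
decayamp simulate --model chain --seed 1 --out traj.csv
decayamp simulate --model kernel --out kernel.csv
decayamp sweep --config examples/sweep.yaml --seed 1 --out sweep.csv
decayamp theory --d 0.05 --a 0.05 --eps 0.1 --delay 3 --out intervals.csv
decayamp classify --out labels.csv
decayamp stretch --out stretch.csv
decayamp patterns --out patterns.csv
decayamp noise-compare --out noise.csv
```

Config schema (see `decayamp/config.py` for full key lists):

```yaml
chain:    {n_cells: 150, n_stim: 100, g: 0.997, c: 0.006, sigma: 0.01, dt: 0.01}
schedule: {T: 50.0, t_exec: 25.0, t_cmp_len: 3.0, f1: 22.0, f2: 28.0}
stimulus: {f_min: 10.0, f_max: 34.0, x_lo: 0.4, x_hi: 1.2}
eps: 0.1
sweep:    {t_s_grid: [5, 10, 15], sigma_grid: [0.02], reps: 200}
```

Time is measured in units of the membrane time constant (τ = 1), with
time 0 at stimulus offset; the leading/trailing wavefronts move about one
cell per time unit, so a delay period spanning ~50 chain cells is `T = 50`.

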