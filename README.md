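# irristoch

A stochastic birth–death model of an irrigated commons: a ±1 population
process whose entry/exit rates respond to the gap between the per-capita
payoff inside the system and an outside option, coupled to annually
redrawn stochastic water availability (lognormal) and taxation (beta).

The package provides:

- **`irristoch.payoff_model`** — the deterministic core: available water,
  tax-funded infrastructure performance, per-capita payoff, entry/exit
  rates, threshold finding (maintenance threshold Ñ, payoff maximiser
  N_M, break-even population N\*), and the calibration that pins the
  functional-form constants (x0, κ, π_o) to integer population anchors
  (defaults 727 / 3,333 / 7,015 at mean drivers W=1, T=0.2).
- **`irristoch.drivers`** — moment-matched annual drivers: lognormal
  water and beta tax specified by (mean, CV) with closed-form natural
  parameters; CV = 0 is an exact constant.
- **`irristoch.simulator`** — the discrete-time process (dt = 0.00005 yr,
  20,000 steps per year, drivers redrawn annually), with two transition
  schemes: `jump` (a forced ±1 move with probabilities b/(b+d), d/(b+d);
  the default) and `bernoulli` (rate-thinned moves b·dt, d·dt with a stay
  probability). The hot loop is numba-compiled.
- **`irristoch.analytics`** — exact product-form stationary distributions
  (the analytic oracle for both schemes), empirical distributions,
  total-variation comparison, collapse detection (first passage below Ñ),
  drift profiles and the drift-asymmetry scan, CV-sweep collapse
  fractions, and the three-phase calm/storm/calm collapse-trap protocol.
- **`irristoch.cli_io`** — YAML/JSON configuration, experiment presets
  (`fig1`–`fig4`), and the `irristoch` CLI. Every run writes a manifest
  (config snapshot, seeds, RNG identity, output inventory).

The model is bistable at baseline: the stationary distribution has a
minor mass component near 0 and a dominant mode at N\* = 7,015 separated
by a probability barrier hundreds of log-units deep. Strong driver
stochasticity can push the population below the viability basin, after
which drift is negative at every population size — a one-way collapse
trap.

## CLI

```sh
irristoch thresholds --out out/thr          # landmark populations as JSON
irristoch calibrate  --out out/cal          # calibrated (x0, kappa, pi_o)
irristoch stationary --out out/stat         # analytic stationary distribution
irristoch simulate   --config cfg.yaml --out out/run
irristoch fig2 --out out/fig2               # benchmark: empirical vs oracle
irristoch fig3 --out out/fig3               # CV sweep collapse fractions
irristoch trap --out out/fig4               # calm/storm/calm protocol
irristoch surface --out out/fig1            # payoff surface over (N, T)
```

Configuration files are YAML with optional `params`, `drivers` and
`simulation` blocks; every omitted field takes the model defaults (an
empty file is a complete configuration):

```yaml
params: {T_bar: 0.2, scheme: jump}
drivers:
  W: {kind: lognormal, mean: 1.0, cv: 0.1}
  T: {kind: beta, mean: 0.2, cv: 0.3}
simulation: {n_years: 30, seed: 7, record_stride: 100}
```

## Notes

- The exact published payoff equations are not available; the shipped
  saturating-performance family reproduces all printed landmarks and the
  qualitative claims, but curve shape near the attractor (and hence the
  benchmark CV of the stationary distribution, here ≈ 0.003 vs the
  printed 0.0062) is form-dependent.
- `tests/test_acceptance.py` contains one deliberately failing
  parametrization (`criterion_3 [bernoulli]`): a 100-year rate-thinned
  run makes only ~200 population moves and cannot reach stationarity at
  the stipulated step count. The same scheme passes the equivalent check
  at an adequate horizon on a down-scaled system
  (`tests/test_simulator.py::TestSchemeEquivalence`).
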