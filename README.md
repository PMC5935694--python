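# lvimm

Predator–prey (Lotka–Volterra) dynamics with small immigration or migration
terms. The package computes coexistence equilibria (closed-form for the
linear functional response, numeric root-finding with residual certification
for the hyperbolic and sigmoid responses), classifies their local stability
through the analytic Jacobian (trace/determinant rule plus eigenvalues),
evaluates closed-form amplitude-decay rates, integrates trajectories, and
runs ensembles under piecewise-constant random immigration.

The model is

```
dx/dt = r*x - a*g(x)*y + C(x)
dy/dt = b*g(x)*y - m*y + D(y),    g(x) = x^(1+alpha) / (1 + h*x^(1+alpha))
```

with `C`, `D` either a constant rate (`c`), a density-dependent rate
(`c/x`), their negated (outflow) variants, or a uniformly drawn rate
resampled at regular intervals.

## Python API

```python
import lvimm as lv

p = lv.LVParameters(r=0.1, a=0.1, b=0.3, m=0.2)          # linear response
model = lv.model_for_case(p, "A1", 0.01)                  # constant prey inflow c=0.01
eq = lv.equilibrium_closed_form(p, "A1", 0.01)            # (2/3, 1.15)
report = lv.classify(model, eq)                           # asymptotically_stable
report.gamma_analytic                                     # b*c/(2*m) = 0.0075

traj = lv.integrate(model, 5, 5, t_end=2000)
lv.estimate_decay_rate(traj, eq).gamma_hat                # ~0.0075
```

Case labels: `A1`/`B1` constant inflow to prey/predator, `C1`/`D1`
density-dependent inflow, `A2`–`D2` the sign-flipped outflow (migration)
variants, `classical` no immigration.

## CLI

```bash
lvimm simulate  --config model.yaml --t-end 2000 --out traj.csv
lvimm stability --config model.yaml --out report.csv
lvimm ensemble  --config ens.yaml --n-steps 1500 --n-runs 15 --seed 1 --out-prefix ens
lvimm suite     --out verdicts.csv        # exits nonzero on any disagreement
lvimm decay     --traj traj.csv --x-star 0.6667 --y-star 1.15
```

Config files are flat YAML (`r, a, b, m, h, alpha, prey_mode, prey_c,
prey_sign, pred_mode, pred_d, pred_sign, interval, low, high, x0, y0,
x_floor`); any CLI flag overrides the file.

`lvimm suite` reproduces the published stability grid — three response
types crossed with {no immigration, four inflow cases}, plus the four
outflow cases and the both-sides-constant case — and reports
expected-versus-observed verdicts per cell.

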