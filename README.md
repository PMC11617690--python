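# copot

**Conditional severity distributions for extrapolated near-collision events,
via copulas and peaks-over-threshold tail models.**

## The problem

Road-user interactions observed from roadside video carry two interdependent
indicators: a proximity measure — the minimum Euclidean distance (MD, metres)
between two vehicles over their shared frames — and a severity measure — the
delta-v (m/s) a collision at closest approach would impose, computed from both
speeds, the vehicle masses and the approach angle α:

```
Δv₁ = m₂/(m₁+m₂) · √(v₁² + v₂² − 2 v₁ v₂ cos α),   Δv₂ symmetric,  Δv = max(Δv₁, Δv₂)
```

Safety analysis wants the distribution of Δv *given a collision* — but
collisions (proximity ≤ 0) are absent from any realistic observation period,
and the proximity margin is multi-modal, so no single parametric family fits
it. `copot` implements a resolution that combines extreme value theory with
copulas:

1. **Tail model.** Negate proximity (X̃ = −X) so its lower tail becomes an
   upper tail, and model excesses over a threshold u = −d₀ with a Generalized
   Pareto distribution H(x̃) = 1 − (1 + γ(x̃−u)/σ)^(−1/γ). A negative shape γ
   bounds the support; when the endpoint u − σ/γ exceeds 0 on the negated
   scale, the unobserved collision event has positive probability under the
   fitted tail.
2. **Restricted measure.** All modelling lives on the near-interaction region
   Ω₀ = {X < d₀} under Q(·) = P(·|Ω₀); the exceedance fraction P(Ω₀) converts
   back to the full space: P(X ≤ x, Y > y) = Q(X ≤ x, Y > y)·P(Ω₀).
3. **Copula.** A one-parameter copula (Gumbel, Clayton or Gaussian) couples
   the GP proximity margin with the severity margin on Ω₀, fitted by
   Kendall-τ inversion (θ̂ = g⁻¹(τ̂)) on pseudo-observations
   (uᵢ, vᵢ) = (H(x̃ᵢ), rank(yᵢ)/(m+1)), and checked with a Cramér–von Mises
   goodness-of-fit statistic and parametric bootstrap. If τ̂ < 0, the severity
   margin is negated first (probabilities are invariant to this adjustment).
4. **Conditional law.** The severity CDF given an extrapolated event:
   F_{Y|X≤x₀}(y) = Q(X ≤ x₀, Y ≤ y) / Q(X ≤ x₀), valid for any x₀ with
   positive tail mass — including x₀ = 0, the collision. Injury probability
   follows as ∫ r(y) dF_{Y|X≤x₀}(y) for a user-supplied risk curve r.

Because no interaction dataset is publicly deposited, the package ships a
first-class synthetic generator (`ScenarioSpec`, `generate_interactions`,
`generate_trajectories`) whose defaults mirror the reference study
conditions: GP tail d₀ = 4.84 m, σ = 2.60, γ = −0.493; Gumbel θ = 1.169
(τ ≈ 0.145); a bimodal Gaussian-mixture proximity body; lognormal delta-v.

## Worked example

```python
import numpy as np, copot as cp

spec = cp.ScenarioSpec(n=5000, seed=123)          # synthetic study conditions
df = cp.generate_interactions(spec)
model, pobs = cp.fit_restricted_model(df["md"].to_numpy(), df["dv"].to_numpy(), d0=4.84)

print(model.p_omega0, model.copula.param)          # 0.0498, 1.091
ys = np.linspace(0.01, 30, 3000)
for x0 in (4.84, 1.0, cp.ACCIDENT_PROXIMITY):
    F = cp.conditional_cdf(model, ys, x0)
    print(x0, ys[np.searchsorted(F, 0.5)])         # conditional median delta-v
```

Running `python examples/03_conditional_severity.py` prints:

```
P(Omega0) = 0.0498  (share of near interactions)
gumbel theta = 1.091

median delta-v conditional on X <= x0:
  x0 = 4.84 m               :  3.10 m/s
  x0 = 2.00 m               :  3.63 m/s
  x0 = 1.00 m               :  3.87 m/s
  collision (extrapolated)  :  7.68 m/s

P(injury | collision) = 0.5878
```

The conditional median rises as the conditioning proximity tightens — the
positive-dependence signature — and the collision-conditioned law, an event
never present in the data, is obtained from the extrapolated tail. The other
scripts in `examples/` walk through tail fitting and diagnostics, copula
selection with the bootstrap goodness-of-fit table, and trajectory-level
indicator computation.

A thin CLI mirrors the same pipeline for shell use:

```sh
copot simulate --n 5000 --seed 1 --out interactions.csv
copot fit interactions.csv --d0 4.84 --n-boot 999 --seed 1 --out-dir fit/
copot conditional fit/model_selected.json --x0 0 --x0 2 --out curves.csv
```

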