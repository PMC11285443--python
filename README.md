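# ecoculture

A stochastic consumer-resource model of coupled population, culture and
carrying-capacity dynamics, with ensemble experiments and
phase-synchronization analysis against periodic climate forcing.

## The model

Three coupled variables evolve under Euler-forward integration with unit
time step:

```
dρ/dt = α ρ (1 − ρ / (K (1 + c)))     population density, logistic growth
dc/dt = −λ c + σ ξ(t) ρ               culture: loss vs. stochastic innovation
dK/dt = −η (K − K0(t)) − μ ρ          carrying capacity: recovery vs. depletion
```

Culture multiplies the effective carrying capacity by (1 + c). Innovations
ξ(t) are heavy-tailed Weibull draws (shape 0.1) scaled by the population
density itself, so bigger populations innovate more — a positive feedback.
Consumption depletes the resource base (−μρ), which relaxes back towards a
climate-driven baseline K0(t) at rate η.

The emergent behavior is boom-bust dynamics: rare huge innovations launch
population booms far above the no-culture equilibrium, booms deplete
resources, and the crash follows. Under a periodic climate baseline
K0(t) = 1 + 0.5·cos(2πt/10000) the boom-bust cycle phase-locks to the
forcing, detectable with Hilbert-transform phase analysis.

See [docs/methods.md](docs/methods.md) for the full methods note,
parameter table and numerical details.

## Worked example

```python
import numpy as np
from ecoculture import (
    simulate, standard_parameters, equilibrium_fixed_point,
    standard_climate_forcing, synchronization_report,
)

# 1. the cultural boost: a 20 000-step standard run vs the no-culture equilibrium
params = standard_parameters(n_steps=20_000, seed=0)
traj = simulate(params)
rho_star = equilibrium_fixed_point(params.with_(sigma=0.0))[0]
print(f"no-culture equilibrium density: {rho_star:.4f}")
print(f"peak density: {traj.rho.max():.2f}  "
      f"(boost {traj.rho.max() / rho_star:.1f}x)")
print(f"peak culture: {traj.c.max():.1f}")

# 2. phase locking to a periodic climate (400 forcing periods)
forcing = standard_climate_forcing()          # K0(t) = 1 + 0.5 cos(2*pi*t/10000)
params = standard_parameters(kappa=0.5, omega=forcing.omega,
                             n_steps=4_000_000, seed=0)
report = synchronization_report(simulate(params, forcing), forcing)
for name, r in report.items():
    print(f"{name}: histogram rel-std {r.rel_std_pct:.1f}%  "
          f"KS p = {r.ks_pvalue:.3g}")
```

Output:

```
no-culture equilibrium density: 0.9901
peak density: 21.00  (boost 21.2x)
peak culture: 217.2
density: histogram rel-std 60.4%  KS p = 0
culture: histogram rel-std 17.3%  KS p = 0
```

The density boom on this seed peaks 21× above the deterministic
equilibrium 1/(1 + μ/η) ≈ 0.9901. Under periodic forcing the wrapped
phase-difference histograms are far from uniform (a uniform histogram has
rel-std 0%; uncorrelated noise gives a few percent), and the KS test
rejects phase uniformity decisively for both density and culture.

## Command line

```bash
ecoculture simulate --n-steps 200000 --seed 3 --out run/        # one trajectory
ecoculture ensemble --n-members 16 --out ens/                   # pooled expectations
ecoculture sweep --lam-values 1e-4,1e-3,1e-2,1e-1 --out sweep/  # (λ, μ) grid
ecoculture sync --trajectory run/trajectory.csv --kappa 0.5 \
    --omega 0.000628318530717959 --out sync/                    # phase analysis
ecoculture validate                                             # integrator vs closed forms
```

Every output directory contains the result CSVs, a `metadata.json` with
the full round-trippable configuration, and a `manifest.json` with SHA-256
checksums. Parameters can also come from a TOML or YAML config file
(`--config run.toml`), with flags overriding individual values.

## Reproduction

The quantitative claims this package is built around are recomputed from
scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This runs the deterministic no-culture equilibrium check, the multi-seed
cultural-boost and depletion-suppression ratios, and the full
phase-synchronization study (10 seeds × 2 regimes × 4·10⁶ steps), writing
one JSON entry per result with its sample size. Runtime is a few minutes
on one CPU core. The same claims are asserted with tolerances in
`tests/test_acceptance.py`.
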