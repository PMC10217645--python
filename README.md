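# persistext

Stochastic extinction of two-phenotype bacterial populations in fluctuating
environments: exact Gillespie-type simulation, quasi-stationary observables,
a master-equation oracle, and WKB (instanton) theory with linear-response
and Kapitsa corrections.

## The problem

A well-mixed population contains *normals* (count *n*), which divide at the
logistic per-capita rate *B*(1 − *n*/*K*) and die at unit rate, and
*persisters* (count *m*), a dormant stress-tolerant phenotype that neither
divides nor dies. The phenotypes interconvert: N → M at rate α, M → N at
rate β (Γ = α/β). All rates are per hour (the death rate sets the clock).

For *B* > 1 the deterministic dynamics have a stable viable state at
*n*<sub>M</sub> = *K*(1 − 1/*B*), *m*<sub>M</sub> = Γ*n*<sub>M</sub>, but
demographic noise makes extinction (*n* = *m* = 0) certain; the question is
*when*. The mean time to extinction (MTE) is exponentially large in *K*:

        MTE ~ exp(K·S),     S ≈ δ²(1/2 + Γ)  near the bifurcation δ = B − 1 → 0,

so persisters (Γ > 0) multiply the exponent — dormancy is protective.

The environment modulates the birth rate *B*(*t*): dichotomous Markov
(telegraph) noise jumping between *B*₊ and *B*₋ with rates ν₊/ν₋ (duty cycle
γ = ν₋/(ν₊+ν₋)), periodic square/rectangular waves, or a sinusoid
*B*₀ + ε·sin(ωt). The central phenomenon is a **non-monotonic dependence of
the MTE on the switching rate**: slow switching averages the MTEs of the two
environments, fast switching averages the environments themselves, and at
intermediate rates — resolved by the population but too fast to recover
from — the MTE dips well below the unperturbed value. That dip is what an
antimicrobial dosing schedule would exploit, and what a bacterial population
tuning α and β would avoid.

## What the package computes

| module | contents |
| --- | --- |
| `model_core` | parameters, mean-field flow, fixed points, relaxation time, near-bifurcation closed-form MTE |
| `environment` | telegraph/rectangular/sinusoidal drives *B*(*t*) and their stationary statistics |
| `gillespie` | exact samplers: plain Gillespie, DMN (flip as a 5th reaction), modified Gillespie with closed-form hazard inversion for *B*(*t*), modified next-reaction method; ensemble driver |
| `observables` | MTE estimates with subsample dispersion, time-weighted quasi-stationary size histograms, escape-time histograms (exponential fits, forbidden intervals, peak counts), MTE-vs-frequency scans |
| `cme` | finite-truncation master-equation generator; mean absorption times by sparse linear solve, QSD eigenpairs, time-ordered propagation — the small-system oracle |
| `wkb` | real- and momentum-space eikonal Hamiltonians, the extinction instanton via an alternating-sweep relaxation, the action S |
| `perturbation` | linear-response action correction ΔS(ω) and logarithmic susceptibility χ_S = \|ΔS\|/ε; second-order Kapitsa averaged Hamiltonian for ω ≫ δ |
| `config` / `cli` | flat/YAML configs, provenance-stamped CSV/JSON output, `persistext` CLI |

## Worked example

```python
import numpy as np
from persistext import ModelParams, EnvironmentSpec, run_ensemble, estimate_mte
from persistext.wkb import solve_instanton

params = ModelParams(B_ref=1.1, K=500, alpha=0.02, beta=0.02)

# stochastic MTE under a sinusoidal drive at nu = omega/pi = 0.003
env = EnvironmentSpec.sinusoidal(B0=1.1, epsilon=0.05, omega=np.pi * 0.003)
ens = run_ensemble(params, env, n_traj=240, seed=11, init=(175, 75))
est = estimate_mte(ens.escape_times, subsample_size=20)
print(f"MTE = {est.mean:.0f} +- {est.sd:.0f} h")

# WKB action for the unperturbed system
path = solve_instanton(params, B=1.1)
print(f"S = {path.action:.6f}, K*S = {params.K * path.action:.2f}")
```

prints (seed 11):

```
MTE = 1524 +- 263 h
S = 0.010781, K*S = 5.39
```

The simulated MTE at this switching rate (≈1.5·10³ h) sits well below the
unperturbed value (≈2.5·10³ h at these parameters): the drive is slow enough
for the population to feel the adverse phases but too fast to let it
recover. The instanton exponent K·S = 5.39 gives the unperturbed MTE only up
to an undetermined pre-exponential factor, so exp(K·S) ≈ 219 is the correct
order-of-magnitude scale, not a calibrated prediction.

The same scan over ν ∈ {3·10⁻⁴ … 0.1} (six points, 240 trajectories each)
is the package's headline figure: maximum at ν → 0, a clear minimum at
intermediate ν, recovery to the unperturbed MTE at large ν.

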