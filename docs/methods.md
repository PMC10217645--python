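# Methods

## Model

Reactions and propensities for the state (n, m):

    N -> 2N   at  B(t) n (1 - n/K)     (logistic division of normals)
    N -> 0    at  n                     (death; rate 1/h sets the clock)
    N -> M    at  alpha n               (switch to dormancy)
    M -> N    at  beta m                (reversion)

Persisters neither divide nor die. Extinction is the joint absorbing state
n = m = 0; the state n = 0, m > 0 is not absorbing because reversion revives
normals. Because reversion can push n above K, the birth propensity is
clipped at zero there (the logistic factor would otherwise be negative).

Mean field: dn̄/dt = Bn̄(1−n̄/K) − n̄ − αn̄ + βm̄, dm̄/dt = αn̄ − βm̄, with the
extinct fixed point F0 and the viable FM = (K(1−1/B), ΓK(1−1/B)), exchanging
stability at the transcritical point B = 1. The relaxation time near FM is
computed from the principal Jacobian eigenvalue (not from a transcribed
closed form, which is ambiguous in print); it satisfies t_r → 1/δ, δ = B−1,
for α, β ≪ δ.

## Environments

* **Telegraph (DMN)**: B jumps between B± leaving the + state at rate ν₊
  and the − state at ν₋. Derived statistics: mean rate ν = (ν₊+ν₋)/2,
  asymmetry Δ = (ν₋−ν₊)/2ν (= stationary mean of ζ), duty cycle
  γ = ν₋/(ν₊+ν₋), autocovariance (1−Δ²)e^{−2ν|t−t'|}.
* **Rectangular wave**: period T = 1/ν₊ + 1/ν₋; each period starts (at zero
  phase) with ζ = +1 for 1/ν₊ then ζ = −1 for 1/ν₋. This phase convention is
  fixed by the requirement that the symmetric wave equal sign{sin(πνt)};
  interval-edge evaluations return 0 (measure-zero, irrelevant to
  simulation). Unless a phase is given, each trajectory draws a uniform
  phase offset, which realizes the stationary start P(ζ=+1) = γ.
* **Sinusoid**: B(t) = B0 + ε sin(ωt + φ); per-trajectory φ ~ U(0, 2π)
  unless fixed. The DMN-matching parameters are ω = πν, B0 = (B₊+B₋)/2,
  ε = (B₊−B₋)/2.

Negative instantaneous birth rates (only possible for ε > B0) are clipped
to zero with a warning in point evaluation; the exact time-dependent sampler
refuses such parameters outright because its closed-form hazard integral
assumes B(t) ≥ 0. No production parameter set comes near this regime.

## Exact stochastic simulation

Constant-B and DMN dynamics are time-homogeneous CTMCs (the environment
flip is a fifth reaction channel), sampled with the plain Gillespie
algorithm. For deterministic B(t) the next-event time solves
∫ₜ^{t+τ} a₀(s) ds = Exp(1), where only the birth propensity is
time-dependent; the cumulative hazard is available in closed form for both
the sinusoid and the piecewise-constant wave, and the equation is inverted
with safeguarded Newton iterations to 10⁻¹⁰ (the integrand is bounded below
by the death rate, so the bracket [0, E/r] always contains the root). The
reaction fired is chosen with probabilities proportional to the
propensities at the firing time. Rectangular waves are additionally served
by a modified next-reaction sampler (per-channel internal clocks, the birth
hazard integrated exactly across wave edges); the two samplers agree in law
and the constant-B special case reproduces the plain Gillespie draws
bitwise under a shared seed.

Ensembles use one `SeedSequence`-spawned stream per trajectory, so results
are reproducible and order-independent. The default horizon is 50× the
closed-form MTE scale; censored trajectories are excluded from MTE
estimation and reported. Default initial condition: (⌊0.7K/2⌋, ⌊0.3K/2⌋).

Quasi-stationary size histograms are accumulated inside the samplers as
time-weighted occupancy of N = n + m over a window — the unbiased CTMC
occupancy estimator — rather than by recording full paths (which would be
GB-scale at production size) or by counting events (biased toward
fast-firing states).

## Master-equation oracle

On the truncated lattice n ≤ n_max, m ≤ m_max (optionally × {ζ = ±1}) the
generator is assembled sparsely with columns summing to zero; transitions
that would leave the truncation are dropped and the induced QSD boundary
mass is audited (warning above 10⁻⁸; defaults n_max ≈ 1.5K, m_max ≈ 4ΓK
keep it far below). Mean absorption times solve Q_ttᵀτ = −1; the QSD and
decay rate come from the principal eigenpair (shift-invert Arnoldi; dense
eigendecomposition below 50 states). Time-dependent propagation freezes
B(t) at step midpoints between sparse matrix exponentials (exact for
piecewise-constant drives) and integrates the survival curve for the MTE,
with an exponential-tail correction from the terminal log-slope. The oracle
is a small-K instrument by design: production K would need ~10⁶ states.

The central correctness property of the package is that every sampler
reproduces the oracle MTE at K = 20–30 within Monte-Carlo error; this is
enforced in the test suite for the constant, DMN, and sinusoidal runners.

## WKB theory

The eikonal ansatz π_{n,m} ∝ exp[−K S(x, y)] turns the quasi-stationary
master equation into a zero-energy Hamilton–Jacobi problem. Both the
real-space Hamiltonian (exponential momenta) and the polynomial
momentum-space Hamiltonian obtained through the probability-generating
function are implemented, with the exact variable map between them
(p₁ = e^{p_x}−1, q₁ = x e^{−p_x}, …) verified pointwise in tests, and both
flows verified against finite-difference gradients of their Hamiltonians.
The momentum-space form is used numerically.

The extinction instanton — the zero-energy heteroclinic from FM (momenta 0)
to the fluctuational extinction point (0, 0, (1−B)/B, (1−B)/B) — is found
by an alternating-sweep relaxation: integrate the coordinate equations
forward in time (RK4) with momenta frozen from the previous iterate, then
the momentum equations backward with coordinates frozen, and mix with
under-relaxation (factor 0.3). Both sweep directions are linearly stable at
the end points they start from, which is what makes the iteration contract.
Numerical choices:

* window [−T, T] with T = max(40/δ, 10/β), 8001 nodes (step ≈ 2T/8000);
  doubling the resolution changes the action by < 0.1%;
* straight-line initialization between the saddles;
* convergence when the max nodal change drops below 10⁻⁸ — or, because the
  heteroclinic has a *neutral time-translation mode* along which the
  discrete path can creep for arbitrarily many iterations without changing
  any observable, when nodal changes are below 10⁻⁶ while the action is
  stationary to 10⁻⁷ (relative) over 200 iterations. The translation mode
  is additionally pinned by re-centering the path when it wanders more than
  5% of the window, and accelerated by Aitken extrapolation of the
  crossing-point drift. These measures matter for strongly asymmetric
  switching (small β or large α), where the position mode is slowest.

The action S = −∫(q₁dp₁ + q₂dp₂) − ∫H dt (boundary terms of the canonical
one-form vanish at both saddles; the energy term is a discretization
correction for the time-independent flow, and an O(ε⁴) endpoint-energy
reference for effective flows). The solver was validated against an
independent `scipy.integrate.solve_bvp` solution of the same boundary-value
problem (agreement to ~10⁻⁶ relative) and against the exact 1-D reduction
at α = 0, S = ∫₀^{1−1/B} ln[B(1−x)]dx = lnB − 1 + 1/B.

The near-bifurcation closed form S ≈ δ²(1/2 + Γ) is an asymptote requiring
*both* δ ≪ 1 and slow switching (β ≪ δ). The package's instanton reproduces
it in that regime and quantifies the departure outside it (at δ = 0.05,
β/δ = 0.4 the true action is ~28% below the asymptote; even at α = 0 the
exact action is 1 − 4δ/3 + O(δ²) times δ²/2). MTE estimates from the action
are exponent-only: no pre-exponential factor is computed, so exp(K·S) is an
order-of-magnitude scale and absolute agreement with simulation is not
expected.

## Linear response and the logarithmic susceptibility

For B(t) = B0 + ε sin(ωt), the momentum-space Hamiltonian splits as
H0 + εHp·sin(ωt) with Hp = ∂H0/∂B. Assuming the path is unperturbed, the
action correction minimized over the escape phase t0 is
ΔS = min_{t0}{−ε∫Hp dt}. Because a single harmonic enters, the t0
dependence is a·sin(ωt0) + b·cos(ωt0) with (a, b) the Fourier coefficients
of the drive amplitude along the path, so ΔS = −ε√(a²+b²) exactly (a grid
search over t0 is retained as a cross-check). Hence ΔS ≤ 0 always, ΔS → 0
for ω ≫ δ (the Fourier coefficients of a smooth, exponentially localized
profile decay rapidly), and χ_S = |ΔS|/ε is ε-independent — the linear
response of log MTE to the drive. The (−∞, ∞) integral is truncated to the
instanton window; the neglected tail is bounded by (|h(−T)|+|h(T)|)/ω and
reported. χ_S scanned over β (α) shows a single interior peak that moves
right (left) with increasing ω: there is a most-susceptible switching rate.

## Kapitsa averaging

For ω ≫ δ a near-identity canonical transformation with generating function
F2 = q·Y + (cos ωt/ω)V(q, Y), V = εHp, removes the fast oscillation;
averaging over one period leaves the time-independent effective Hamiltonian

    H_eff = H0 + (ε²/4ω²)·{{H0, Hp}, Hp} + O((ε/ω)³).

The gauge freedom in F2 changes H_eff by (1/4ω²){H0, G} with G = V_q·V_p;
along the instanton this integrates to boundary terms that vanish at both
saddles (V_q = 0 at FM, V_p = 0 at the extinction point), so the action is
gauge-invariant at this order. The double Poisson bracket and the effective
flow's gradients are derived symbolically (sympy) once per process and
compiled with numba; the instanton of the effective flow is solved with the
same sweep iteration between the ε²-shifted fixed points (located by
root-finding from the unperturbed saddles and accepted by residual). A
cheap alternative evaluates the first-order action shift
−(ε²/4ω²)∫{{H0,Hp},Hp}dt along the unperturbed path; the two agree to a few
percent and the correction is quadratic in ε by construction. The method is
meaningless for ω ≲ δ (warned below 5δ).

## Observables and estimators

* MTE: mean over uncensored escape times; dispersion is the standard
  deviation of disjoint-block means (default 12 blocks), matching the
  subsample convention of frequency-scan figures.
* Escape-time histograms carry a one-parameter exponential MLE (rate
  1/mean) and a two-parameter (delayed) exponential fit: escape from the
  metastable state is Poissonian only after the state has formed, so the
  law is exponential above a positive onset time (for a K = 500 telegraph
  drive the delay is a few relaxation times, ~20% of the MTE). KS tests are
  reported for both fits.
* Forbidden intervals (fixed-phase periodic drives) are runs of empty bins
  strictly inside the support; histogram peaks are local maxima above a
  5%-of-maximum prominence (scipy `find_peaks`) — the paper-style counting
  rule, declared here because no printed rule exists. Peak-count
  comparisons between frequencies use a common time window with bins of a
  quarter period.
* Frequency scans annotate the grid argmin and both scan-end values; the
  ν → 0 limit equals the average of the two static MTEs and the ν → ∞
  limit the MTE of the duty-cycle-averaged birth rate, both verified
  against the oracle at small K.

## What the synthetic ensembles do and do not show

The simulator *is* the study's data generator: all conditions (rates,
amplitudes, sample sizes) are the production ones — K = 500, B0 = 1.1,
ε = 0.05, α = β = 0.02, 2400-trajectory ensembles subdivided into blocks of
200 for dispersion, initial state (175, 75) — except where a desk-scale
test says otherwise (oracle comparisons at K = 20–30; scan points at 240
trajectories with blocks of 20, which widens the error bars ~3× but moves
no systematic quantity). Passing tests therefore demonstrate correctness of
the sampling and of the asymptotic theory *for this model*: a well-mixed
population, one resource-free logistic interaction, no persister mortality
or division, and an environment acting only through the normals' birth
rate. Real persister biology (dose-dependent kill rates, resource dynamics,
age structure, resistance mutations) is outside what any of these tests can
certify.

## Known limitations

* The WKB MTE is exponent-only; simulation and theory MTEs agree in
  structure (location of dips, trends in α, β, ε, ω), not in absolute value.
* The instanton sweep handles the explored range B ∈ (1, 1.5], α, β ∈
  [0.002, 0.5]; far outside it (very stiff Γ) the fixed window/step may need
  retuning, and the energy-conservation diagnostic degrades for α ≳ 0.25.
* The sinusoidal frequency scan at production scale puts the grid minimum
  of the MTE at ν = 0.001 (ω ≈ 0.003), one log-grid point below the
  headline grid value of 0.003 quoted with the ν = ω/π convention; the
  non-monotonic dip itself is unambiguous and robust.
* The master-equation oracle is limited to K ≲ 50 on one CPU.
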