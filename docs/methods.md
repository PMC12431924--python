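# Methods

## Model and conventions

The package works with the mass-free generalized Langevin equation (GLE):
every term has units of acceleration, the thermal scale is the velocity
variance B = ⟨ẋ²⟩ (k_BT/m in the equipartition convention), and the
friction kernel Γ(t) = Σᵢ (γᵢ/τᵢ) e^{−t/τᵢ} carries 1/time².  The
amplitudes γᵢ (1/time) are the *integrated* friction of each component:
G(∞) = Σγᵢ, τ_m = 1/Σγᵢ, D = Bτ_m.  At equilibrium the random force obeys
⟨F_R(0)F_R(t)⟩ = BΓ(t); this relation is exact for harmonic potentials and
approximate otherwise, which is the standard caveat for GLE modelling of
anharmonic landscapes.

Memory kernels allow duplicate memory times (amplitudes of equal-τ
components simply add); components with identical τ are coalesced before
any characteristic-polynomial work so that degenerate ratios (c = 1 in the
geometric family) never manufacture spurious multiple poles.

## Exact MSD by partial fractions

For U = Kx²/2 the Laplace transform of the position autocorrelation is
C̃_xx(s) = (B/K)(s + Γ̃(s))/(s² + sΓ̃(s) + K) with
Γ̃(s) = Σγᵢ/(1 + τᵢs), and C_MSD(t) = 2B/K − 2C_xx(t).  For K = 0,
C̃_MSD(s) = 2B/(s²(s + Γ̃(s))).  Multiplying by Π(1 + τᵢs) yields rational
functions with denominator polynomials

    Q(s) = s·Π(1 + τᵢs) + Σᵢ γᵢ Π_{j≠i}(1 + τⱼs)        (degree n+1)
    P(s) = s·Q(s) + K·Π(1 + τᵢs)                        (degree n+2)

The K = 0 case is a separate code path: its double pole at s = 0 produces
the constant and linear (2Bτ_m·t) terms analytically and is never
approximated by small K.

**Precision.**  Geometric kernels of interest span τₙ/τ₁ up to 10¹⁶, which
makes these polynomials hopelessly ill-conditioned in double precision.
All coefficients, roots, residues and curve evaluations therefore run in
mpmath arbitrary precision; the working precision scales with the kernel's
dynamic range (50 digits plus ~2.5 digits per decade of τ- and γ-spread).
Roots come from `mpmath.polyroots` and are polished with Newton steps;
residues at simple poles are num(sₖ)/den′(sₖ).  Evaluation also stays in
extended precision because near t = 0 the offset, linear and exponential
parts cancel to O(Bt²) — a relative cancellation of 10¹⁰ and more at the
smallest times probed.

**Degenerate poles.**  Roots whose relative separation stays below 1e−9
after polishing are merged and their residue polynomial extracted from a
local Taylor expansion, giving (c₀ + c₁t + …)e^{st} terms.  In practice
float-precision inputs cannot place a system exactly at critical damping:
the closest representable parameters leave root gaps of ~1e−8, which the
high-precision simple-pole path resolves correctly (verified against the
numerical inverse Laplace oracle at a near-critically-damped point), so
the merged branch is a safety net rather than a hot path.

**Validation.**  Every decomposition asserts stability (Re s < 0),
conjugate-pair realness (imaginary residue below 1e−12 relative) and
C(0) = 0 to 1e−10 of the curve scale.  The assembled curves are checked in
the tests against `mpmath.invertlaplace` (Talbot), closed-form Markovian
limits, the 2B/K plateau and the ballistic Bt² onset.

## Simulation

Markovian embedding: each kernel component becomes an
Ornstein–Uhlenbeck bath variable,

    dyᵢ = −(yᵢ − x)/τᵢ dt + √(2B/γᵢ) dWᵢ,

coupled to v̇ through Σᵢ(γᵢ/τᵢ)(yᵢ − x).  Eliminating yᵢ reproduces the
multi-exponential friction integral and the BΓ(t) noise correlation
exactly; the extended system has the Gibbs stationary density
exp(−[U + v²/2 + Σᵢ(γᵢ/2τᵢ)(yᵢ−x)²]/B), which supplies the equilibrium
initial conditions (x Boltzmann-distributed, v ~ N(0,B),
yᵢ − x ~ N(0, Bτᵢ/γᵢ)).

The integrator splits each step into an exact OU half-step for every bath
variable (at frozen x), a velocity-Verlet step for (x, v) under the
combined potential + coupling force, and a second OU half-step.  Because
the stiff bath parts are integrated exactly, the scheme remains stable
across the many-decade τ-spreads where Euler–Maruyama fails.  The default
stability bound dt ≤ min(τ₁, τ_m, K_loc^{−1/2})/50 is enforced (override
flag available); default dt when unspecified is half that bound.
Correctness is established statistically: dt-halving moves the MSD by less
than the Monte-Carlo error, equipartition holds in confining potentials,
and the simulated MSD matches the exact harmonic-confinement curve within
3 standard errors at every lag (the package's central cross-validation).

The memoryless limit is integrated with BAOAB at noise intensity 2B/τ_m.

Randomness: one root seed per run; noise is drawn from a single seeded
generator vectorized across the trajectory ensemble, so a fixed
(config, seed) pair is bit-reproducible.  Changing the trajectory count
changes the stream; reports carry a config hash for provenance.

## MSD estimation and time scales

The MSD estimator averages (x(t₀+τ) − x(t₀))² over all overlapping origins
within each trajectory and then across trajectories; standard errors come
from the across-trajectory spread only, since sliding origins within one
trajectory are strongly correlated.  α(t) = d ln C/d ln t uses a 3-point
centered stencil on the log-lag grid (one-sided and flagged at the ends),
with optional moving-average smoothing that is flagged on the curve.  The
log-time average of α uses exponentially spaced points, which is what
makes the oscillating exponent of geometric kernels average to
ln(c/d)/ln(c).

τ_p, τ*_loc and τ*_glob solve monotone self-consistent equations
(τG(τ) = 1 and τK = G(τ)); both sides are monotone with a single crossing,
so the package uses guaranteed bracketing (Brent, relative tolerance
1e−12) with geometric bracket expansion rather than fixed-point iteration,
which can cycle for steep G.  When Γ(0) ≤ K the balance τK = G(τ) has no
positive root — the restoring force wins at all times and no overdamped
relaxation scale exists; the report returns NaN with a warning.  All
strongly damped parameter regimes of interest satisfy Γ(0) ≫ K.

Regime classification partitions the lag axis at {τ_p, τ*_loc, τ*_glob}
into ballistic / memory-dominated / barrier+memory / confined segments,
each annotated with its mean α; boundaries that coincide within 0.1% (for
instance τ*_loc = τ*_glob in a purely harmonic well) collapse with a
warning.  The 10% relative-deviation threshold used to locate where a
simulated double-well MSD departs from its local-harmonic surrogate is
this package's operational choice.

## Parameter choices that matter

* **Geometric-family normalization.**  For the closed-form exponent
  ln(c/d)/ln(c) to describe the *whole* window [τ₁, τₙ], the dynamics must
  already be overdamped at τ₁, i.e. γ₁τ₁ ≳ 1.  The package's exponent
  tests and examples therefore use γ₁ = 1/τ₁.  If instead the total
  friction is normalized (Σγᵢ = 1/τ₁) with d > 1, the early components
  carry almost no friction, the persistence time moves decades past τ₁,
  and the window is largely ballistic — the ballistic-prolongation effect,
  which the figure-style `fig2` sweep reproduces deliberately.
* **Boltzmann statistics.**  Quadrature runs on the interval where
  U − U_min ≤ 50B (excluded mass < e⁻⁵⁰) at relative tolerance 1e−12;
  the reported variance is the central second moment, which coincides with
  ⟨x²⟩ for the symmetric potentials used throughout but stays correct for
  asymmetric tabulated profiles.  Position sampling inverts the grid CDF
  on 2¹⁴ points — deterministic given the seed, exact to grid resolution.
* **Double well.**  U = U₀((x/L)²−1)² with K_loc = 8U₀/L² at the minima
  and diffusion time τ_D = L²/(Bτ_m).  U₀ = 0 degenerates to the free
  potential and is treated as non-confining.
* **Tabulated landscapes** use natural cubic splines, so U, U′ and U″ come
  from one consistent interpolant; queries outside the table raise.
* **Power-law kernel fits** default to the window [τ₁, τₙ] with 50
  exponentially spaced points, least squares on ln Γ vs ln t; window and
  point count are explicit arguments since no canonical protocol exists.
  Multi-exponential fits measure residuals on ln Γ (all decades weigh
  equally), initialize memory times log-uniformly with amplitudes from a
  non-negative linear solve, and take the best of 10 seeded restarts.

## Scale of the shipped computations

The figure-style sweeps default to reduced problem sizes that run at desk
scale: the double-well sweeps use τ_m = 10⁻⁴τ_D (reduced) or 10⁻⁶τ_D
(full) rather than the 10⁻⁸τ_D of a production study, whose 11+ decade
span calls for long dedicated runs; ensembles default to 50 (reduced) or
1000 (full) trajectories.  One consequence of weaker damping is physical,
not numerical: with τ₁ = 10³τ_m and larger τ_m, Γ(0) falls below K_loc,
so the memory-aware local relaxation time τ*_loc does not exist at reduced
scale and the regime reports show fewer segments than a production run
would; the full four-segment sequence (ballistic / memory / barrier+memory
/ confined) requires the strongly damped regime τ_m ≲ 10⁻⁷τ_D.  The simulation-vs-analytic cross-check runs 200
trajectories of 10⁵ steps.  These sizes are the package's defaults, not
limits — all counts are plain config fields.

## What the synthetic conditions do and do not show

The generator-driven tests establish internal consistency: the simulator
reproduces the exact MSDs where those exist, the fluctuation–dissipation
relation holds, and the self-consistent time scales land where the curves
actually bend.  They do not validate kernel *extraction* from real
trajectories (Volterra inversion is out of scope), non-equilibrium
generalizations of the GLE, or error bars on α estimated from single
finite experimental trajectories.  For anharmonic potentials the BΓ(t)
noise relation — and hence the Boltzmann initialization of the bath
variables — is itself an approximation of the projected many-body
dynamics, exactly as in the modelling practice this package supports.
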