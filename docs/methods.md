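# Methods

`neurotherm` implements a stochastic-thermodynamics toolbox for neural
systems: a discrete master-equation engine with complete entropy and
information accounting, a 1-D Langevin/Fokker–Planck layer, the falling
Brownian particle as a fully closed-form reference system, bipartite
information flows, a linear recurrent network inferring a stochastic
stimulus velocity, stochastic BCM plasticity with a bistable collective
weight, and a pair-approximation solver for chains of interacting synapses.
This note records the models, the conventions, and the numerical and design
choices, in that order of importance.

## Discrete Markov systems (`core_markov`)

State dynamics follow the master equation dp(z)/dt = Σ_z' [w_zz' p(z') −
w_z'z p(z)], with `w[i, j]` the rate j→i. Entropies are in nats throughout
(`nats_to_bits` converts). The entropy balance is computed pairwise:

* production  S_pr = Σ_{pairs} (a − b) ln(a/b), a = w_zz' p_z', b = w_z'z p_z,
* flow        S_fl = Σ_{pairs} (a − b) ln(w_zz'/w_z'z),
* dS/dt = S_pr − S_fl.

Degenerate terms follow the standard conventions: a = b = 0 contributes
nothing; a unidirectional link with nonzero flux has divergent production
and `+inf` is *returned* rather than raised — callers must see the
irreversibility.

**Quadratic lower bound.** The often-quoted bound with per-term denominator
w_zz' p_z' is not correct as a general statement: for a two-state system
with flows a = 2, b = 1 the production is ln 2 ≈ 0.693 while that expression
gives 0.75. `entropy_production_lower_bound` therefore uses the symmetrized
denominator (a + b)/2,

S_pr ≥ ½ Σ_{z,z'} (a − b)² / ((a + b)/2),

which follows from the logarithmic mean never exceeding the arithmetic mean
and coincides with the naive form to leading order near equilibrium.

Integration uses LSODA with rtol 1e-10 / atol 1e-12; rate matrices produced
by barrier-crossing reductions can mix scales by many orders of magnitude,
so a stiff-capable integrator is the default and the matrix exponential is
reserved for test oracles.

## Langevin / Fokker–Planck layer (`langevin_fp`)

The SDE contract is (1/μ) ż = F(z, t) + σsay η with ⟨η(t)η(t')⟩ = δ(t−t'),
integrated by fixed-step Euler–Maruyama. Weak order 1 is sufficient because
every quantity checked against it is distributional; the scheme also keeps
the noise convention transparent. Each trajectory draws from its own
counter-based Philox stream spawned from the user seed, so an ensemble is
bit-reproducible and trajectory i's path does not depend on n_traj.

On a uniform grid, the probability current is J = μF P − ½(μσ)² ∂P/∂z with
second-order central differences (`np.gradient`, edge_order=2) and trapezoid
integrals, matching the O(Δz²) error budget of the tests. Entropy rates are

S_pr = 2/(μσ)² ∫ J²/P dz,  S_fl = 2/(μσ²) ∫ J F dz,

with cells below a 1e-300 density floor contributing zero; σ = 0 is an
error because both expressions are undefined without noise.

`discretize_to_rate_matrix` builds the nearest-neighbour birth–death chain
with exponential (detailed-balance-preserving) splitting w(i→i±1) =
D/Δz² · exp(±μF Δz/2D); its discrete entropy rates converge to the
continuous ones as the grid refines, which is tested.

## Brownian particle in gravity (`brownian_particle`)

m v̇ = −k v + (m g + F0(t)) + √(2 m k) σ_v η, with σ_v² = kB T/m fixed by
fluctuation–dissipation. Bath temperature defaults to 300 K; the two
benchmark magnitudes (σ_v ≈ 2 μm/s at m = 1 μg, 0.002 μm/s at m = 1 g) are
insensitive to T within physiological ranges, and the masses are taken at
their stated round values rather than recomputed from a particle size and
density (a 0.1 mm sphere at 1 g/cm³ would weigh ≈ 0.52 μg; the benchmarks
follow from the round masses). In the overdamped limit the height performs
drifting Brownian motion with Var[x] = 2σ_x²γt (σ_x = σ_v/γ, γ = k/m), and
the position entropy ledger is closed-form:

S_x = ½ ln(4πe σ_x²γt),  dS_x/dt = 1/2t,
S_pr,x = 1/2t + (mg + F0)²/(γk²σ_x²),  S_fl,x = (mg + F0)²/(γk²σ_x²).

The grouping of the drive term was verified symbolically: it is the unique
grouping whose F0 = 0 asymptote equals m³g²/(k³σ_x²) and which satisfies
S_fl,x = k⟨v⟩²/(kB T) exactly through fluctuation–dissipation. The ledger
dS_x/dt = S_pr,x − S_fl,x then holds identically for any F0(t); tests check
it at relative machine precision (the two sides can differ by ~1e-16·S_fl
in absolute terms when the drive dwarfs 1/2t). General F0 callables are
handled by adaptive quadrature; constant F0 uses closed forms.

## Bipartite information flows (`bipartite_infoflow`)

Two subsystems that never jump simultaneously admit the decomposition
dI/dt = İ_x + İ_y with

İ_x = Σ_{x>x', y} (w^y_xx' p_x'y − w^y_x'x p_xy) ln[p(y|x)/p(y|x')],

and local productions/flows defined per jump direction. Sums run over
unordered pairs, equivalent to the ordered form by antisymmetry.

**A bookkeeping subtlety that matters.** The X-jump part of the *joint*
entropy rate (`s_dot_x`, which sums with its Y analogue to dS_xy/dt) and
the rate of the *marginal* entropy S_x (`ds_x_dt`) differ by exactly İ_x.
The local second law

S_pr,x = dS_x/dt + S_fl,x − İ_x ≥ 0

holds with the marginal rate, not the joint-partial one; using a single
symbol for both breaks the identity by İ_x. The ledger (`demon_ledger`)
reports both quantities, the residuals of both identities, and a flag for
the Maxwell-demon regime dS_x/dt + S_fl,x < 0, which is possible only when
information flows out of the subsystem (İ_x < 0). Conditional-probability
logarithms inherit the 0·ln 0 and flux-weighted conventions of the core
module.

## Neural inference (`neural_inference`)

N linear rate neurons with Gaussian tuning curves c_i(v) =
r_m exp(−(v−u_i)²/2ε²) and mean recurrent weight w̄ reduce to one
population SDE with enhancement factor κ = 1/(1 − w̄τ_n0), τ_n = κτ_n0,
σ_r = κσ_r0; stability requires w̄τ_n0 < 1 (validated). Preferred
velocities are taken as u_i ~ Normal(0, α²), for which the population
tuning curve is (r_m ε/α)·exp(−v²/2α²) in the α ≫ ε limit — the
Monte-Carlo average over 4·10⁶ sampled preferred velocities is the
normative oracle for this convention. All closed forms drop O(α⁻⁴)
remainders; an `order` switch exposes exact-vs-series evaluation.

The stationary mutual information between the collective rate and the
stimulus for an exponential v² covariance C0 e^{−|Δt|/τ_c} is

I∞ = N(εκr_m)²/(8α⁶σ_r²) · C0 τ_n²τ_c/(τ_n + τ_c),

a grouping confirmed by brute-force quadrature of the defining double
integral (to ~1e-6 relative, tested on a (τ_n, τ_c) grid). It vanishes for
fast stimuli and saturates for τ_c ≫ τ_n: time-scale separation is what
makes inference possible.

The stimulus generator (`OUSquaredStimulus`) uses a stationary zero-mean
Ornstein–Uhlenbeck velocity with relaxation time 2τ_c and variance
√(C0/2): for a Gaussian process cov(v²) decays at twice the OU rate, so
this is the simplest process with exactly the assumed covariance. Other
models can be supplied through the same sample/covariance interface.

The conditional entropy production of the tracking dynamics is derived by
inserting the Gaussian conditional law into the continuous-state
entropy-production integral (this route has no transcription ambiguity):

S(t) = e^{−2t/τ_n}/(τ_n(e^{2t/τ_n} − 1)) + N(⟨r̄(v,t)⟩ − κc̄(v))²/(τ_n σ_r²).

Its long-time form is the squared deviation of v²(t) from its exponentially
filtered history, with prefactor N(εκr_m)²/(4α⁶σ_r²τ_n) — exactly 2σ_r²(t)/
(σ_r²τ_n) times the mutual-information prefactor, so better tracking costs
proportionally more energy, and a frozen stimulus costs asymptotically
nothing. Simulated rates are not clipped at zero: negativity is a transient
artifact of the linear model and clipping would break the exact Gaussian
law; the negative-sample fraction is logged.

## BCM plasticity and memory (`bcm_plasticity`)

With a quasi-static sliding threshold (τ_θ ≪ τ_w; note the real requirement
is τ_θ faster than the *local* weight relaxation rate, which can be much
faster than 1/τ_w — a test demonstrates this) and an adiabatic neural rate
r ≈ c(v) + τ_n0 f̄ w̄, the population weight moves in the quartic potential

V0(w̄) = w̄²/2τ_w − (λf̄³τ_n0²/3)w̄³ + (λβf̄⁴τ_n0³/4)w̄⁴,

bistable iff λτ_wτ_n0f̄² > 4β. With the nominal parameter set (λ = 1.3,
β = 1.2, f̄ = 0.9 Hz, τ_n0 = 0.3 s, τ_w = 200 s, σ_w = 5.0, N_s = 1000) the
condition reads 63.18 > 4.8 and the fixed points are w̄_d = 0, w̄_m ≈
0.0598, w̄_u ≈ 3.027 s⁻¹. The figure caption labels the 0.3 s constant
"τ_n"; all §-level formulas use the single-neuron constant, so it is
identified with τ_n0 here (the alternative would shift fixed points through
κ; both readings are exposed via the parameters). A stimulus c > 0 tilts
the potential by a cubic ΔV whose normative definition is
−∫(F_w(x,c) − F_w(x,0))dx; the closed form was verified symbolically against
that integral. Kramers times use analytic curvatures,

T_d = 2π/√(V″_d|V″_m|) · exp[(N_sτ_w/σ_w²)ΔV_barrier],

computed in log space: at N_s = 1000 the up-state barrier is ≈ 1486
diffusion units and T_u overflows to `inf` (the up state is effectively
absorbing — this *is* the long-lived memory); the two-state reduction then
raises with guidance rather than fabricating rates. Validity is flagged when
a barrier is under ~3 diffusion units.

The two-state memory relaxes as p_u(t) = Δe^{−ω₀t} + p_u,∞ with lifetime
T_m = 1/ω₀. During forgetting the entropy production rate equals the decay
rate of the KL divergence from the steady state, S_w = −Ḋ_KL ≥ 0, and its
time integral equals D_KL at t = 0 — independent of ω₀, which the tests
verify across two decades: retaining information longer costs nothing extra
in total.

**Noise scale of the down state (a documented conflict).** The collective
diffusion D = σ_w²/(N_sτ_w) = 1.25·10⁻⁴ gives a stationary spread
√(Dτ_w) ≈ 0.158 around w̄_d — larger than both w̄_m ≈ 0.06 and the barrier
height (0.024·D). The down state is therefore *not* metastable at the
nominal noise: the analytic mean first-passage time from w̄_d to the up
basin is ≈ 410 s, and simulations show every seeded run converting
spontaneously well within 2000 s, stimulus or not. Slow-ramp learning runs
consequently all end up (as expected), but a steep ramp does **not**
suppress the transition at these parameters — noise alone drives it. The
acceptance suite keeps the steep-ramp assertion at its stated threshold and
it fails honestly; the package reports the measured fractions. No reflecting
boundary is imposed at w̄ = 0 by default (w̄_d = 0 is already a fixed point
and reflection would only accelerate escapes); an optional floor flag exists
for display runs.

First-passage ensembles for the Kramers comparison use a reduced-barrier
configuration (barrier ≈ 4 diffusion units, λτ_wτ_n0f̄² tuned to β_f = 0.9
so both wells are well-formed); 200 simulated escapes agree with the
Kramers prediction to ~20% (factor-2 log-scale tolerance), about as well as
the formula can do at such shallow barriers.

## Synapse chains and the pair approximation (`pair_approx`)

N_s synapses with K morphological states flip with neighbour-dependent
rates; boundary synapses condition on their single neighbour directly (no
ghost state) — the minimal consistent closure, isolated behind the rate
callable's `left`/`right` = None convention. The exact joint equation is
integrated only up to K^Ns = 65536 states; beyond that the solver refuses
and names the alternative. The pair approximation evolves N_s·K singles and
(N_s−1)·K² pair tables (linear in N_s), closing three-site terms as
P(l,m)P(m,r)/P(m) with a 1e-300 floor and zero-numerator short-circuit.
After each output segment, tables are renormalized; if pair/single marginal
mismatch exceeds 1e-6 the state is projected back by iterative proportional
fitting toward averaged marginals (the closed ODE system does not conserve
consistency exactly at finite step size; in practice the drift stays below
1e-6 over ten relaxation times and the projection is dormant).

Information gain during learning is the rate of KL divergence between the
current and reference steady-state pair laws (two boundary terms plus
interior closure terms); its normative check is the finite-difference
derivative of the joint KL along the exact dynamics on small chains (the
printed interior logarithm is transcribed ambiguously in sources, so the
oracle decides — agreement to ~1e-5 relative). Per-synapse entropy
productions are sums of (flux)·ln(flux ratio) over closure fluxes, each
non-negative by construction; the energy cost rate is E0·S_pr with
E0 = 10⁵ kBT per synapse by default. For weakly coupled chains
(neighbour boost ≤ 0.4) the pair totals track the exact joint production to
well under 10%, and closure error decreases monotonically as coupling → 0.

One equation-count remark in the source literature ("10100 equations" for
K = 2, N_s = 1000) conflicts with K^Ns = 2^1000 ≈ 10^301; it is a
typesetting artifact and nothing in the implementation depends on it.

## Interfaces, sizes, reproducibility

The CLI (`neurotherm {particle,infoflow,inference,bcm,chain}`) is a thin
layer over the library: YAML/JSON config in, tidy CSV (17 significant
digits) and a JSON summary (seed + library versions) out; identical configs
give byte-identical CSVs. Figure presets regenerate the learning-trajectory
and potential-landscape panels.

Default problem sizes were chosen so the full test suite runs in a few
minutes on one core: 10⁴-trajectory ensembles for moment checks, 200-escape
first-passage ensembles, 10-seed learning runs at dt = 10 ms over 2000 s,
6-synapse chains for exact-vs-pair comparisons. The synthetic generators
emulate the study conditions (parameter sets, ramps, noise scales) but not
features of real recordings — no spiking discreteness, no heterogeneous
synaptic weights beyond the mean field, no measurement noise — so passing
tests certify the mathematics and the simulators, not fit to biological
data.

## Known limitations

* 1-D state spaces only; no Kramers (position+velocity) joint solver.
* The linear rate model admits transiently negative rates by design.
* Kramers times at barriers ≲ 3 diffusion units are indicative only.
* The pair closure has no error bound; accuracy is established empirically
  against exact small chains.
* The two-state memory reduction requires representable dwell times; deep
  wells (e.g. the nominal N_s = 1000 up state) are reported as effectively
  absorbing rather than reduced.
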