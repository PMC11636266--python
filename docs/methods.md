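# Methods

## Channel model

The link is a point transmitter and a fully absorbing spherical receiver
(radius `r`, centre distance `d`) in an unbounded, flow-free fluid.  Molecule
motion is isotropic Brownian diffusion with coefficient `D`; per time step
`Δt` each coordinate moves by an independent draw from `N(0, σ²)` with
`σ = √(2DΔt)`.  The capture-time CDF of a single molecule,

    F(t) = (r/d) · erfc((d − r) / √(4Dt)),

is the standard first-passage result for this topology; `F(∞) = r/d`.
Default geometry and transport constants: `d = 200 µm`, `r = 1 µm`
(receiver diameter 2 µm), `D = 600 µm²/s` for the data carrier (IPTG) and
`870 µm²/s` for the antagonist (aTc).  Releases are impulses at the emission
instant; spreading a release over a window is not modelled.  Expected
arrivals in a sampling slot `[t₁, t₂]` after an impulse of `N` molecules are
`N · (F(t₂) − F(t₁))` — exact, additive over adjacent slots, and already the
slot-averaged arrival rate times the slot width, so no further smoothing is
applied to the sampled series.  Channel-level degradation, flow, reflecting
boundaries and competing receivers are out of scope.

The deterministic pipeline works entirely with these continuous
expectations.  The Brownian walker ensemble exists only as an independent
verification oracle for `F`; it never feeds the pipeline.

### Walker discretisation

Walkers are absorbed when an end-of-step position lies inside the receiver
sphere.  End-of-step detection misses within-step crossings; the miss
probability is negligible only when `σ` is small against `r`.  At the
default oracle resolution (`Δt = 0.1 s`, `σ ≈ 11 µm` against `r = 1 µm`)
that bias would swamp the estimate, so steps that *start* within
`r + 5σ` of the receiver are advanced by finer sub-steps sized so that
`σ_fine ≤ r/3`.  This is statistically exact — a Gaussian step is the sum of
its Gaussian sub-steps — and keeps detection endpoint-only, with no
first-passage bridge formula that would share assumptions with the CDF being
verified.  The residual bias (an effective radius reduction of order
`0.3 σ_fine ≈ 0.1 µm`) is an order of magnitude below the 3-standard-error
Monte-Carlo band at 10⁴ walkers.  The plain single-resolution walk is kept
behind `WalkerConfig(boundary_refinement=False)`; with it, halving the step
moves the empirical CDF toward the closed form, which is how the bias is
documented and tested.

## Signal construction

A scenario is `(α, t_shift, t_s, M, bits)`: each bit-1 at symbol index `k`
releases `(1−α)·M` A_e molecules at `k·t_s` and `α·M` B_e molecules at
`k·t_s + t_shift`; bit-0 releases nothing.  Expected arrivals are computed
per 40 s sampling slot from slot differences of `F` and superposed over all
bit-1 symbols (the channel is linear).  Release instants need not lie on the
sampling grid — the slot integral is exact for arbitrary emission times, so
the 100 s design grid for `t_shift` needs no snapping onto the 40 s sampling
grid.  Counts stay continuous expectations; no Poisson sampling (the
molecule numbers involved, ~10⁵–10⁶ per release, make the deterministic
approximation appropriate).  Every message starts with two bit-0 warm-up
symbols so the circuit can settle; the warm-up is excluded from all
downstream statistics.

## Receiver circuit

Nine state variables (molecules per cell): the intracellular inducer pools
IPTG and aTc, the repressors LacI and TetR, the output mRNAs and proteins of
the two arms (mRNA_Ai/Ai, mRNA_Bi/Bi), and the Ai:Bi complex.  Seventeen
reactions: constitutive repressor synthesis and first-order decay, inducer
decay, repressible transcription of each output gene, mRNA decay,
translation, protein decay, irreversible Ai + Bi sequestration, complex
unbinding (zero by default) and complex decay.

Inducer–repressor binding is treated at rapid equilibrium: the free
repressor is the exact root of the 1:1 binding quadratic
`C² − (R + I + K_d)·C + R·I = 0`, `R_free = R − C`, evaluated inside the
rate laws (and exported as SBML assignment rules).  Transcription is
Hill-repressed by the free repressor, `k_tx·n_plasmid / (1 + (R_free/K)ⁿ)`;
a non-cooperative mass-action promoter-occupancy variant
(`1/(1 + R_free/K)`) is available via `promoter_model="occupancy"`.  The
readout used for detection and scoring is **free Ai only** — the unbound
remainder after subtraction — not Ai plus complex.

Arrival series enter the model as discrete additive events: at each 40 s
sample time the slot's expected arrivals are added to the matching inducer
pool, one event per sample, mirroring an event-driven SBML workflow.  An
output sample coinciding with an event reports the post-injection state
(a slot's arrivals are credited at the slot's end).

### Kinetic parameter fixture

The literature the circuit design draws on does not pin down a complete rate
set, so the package ships one documented fixture; every rate is
configurable, and all circuit-dependent results (symbol durations, retained
counts, scores) are fixture-relative.  The fixture (units: molecules/cell,
seconds):

| parameter | value | rationale |
|---|---|---|
| transcription rate (per plasmid copy) | 0.05 mRNA/s | strong promoter |
| plasmid copies | 10 | low-copy plasmid deployment |
| translation rate | 0.05 protein/s per mRNA | moderate RBS |
| mRNA decay | 0.01 /s | ~1 min half-life, typical bacterial mRNA |
| protein decay | 0.005 /s | ~2 min half-life, degradation-tagged |
| repressor synthesis (lumped) | 0.5 /s | steady-state pool of 100 repressors |
| repression K, Hill n | 10, 2 | tight, cooperative repression |
| inducer–repressor K_d | 10 | tight effective binding |
| inducer decay | 0.005 /s | dilution + export of small molecules |
| sequestration rate | 1e-3 /(molecule·s) | strong protein–protein pairing |
| complex decay | 0.005 /s | as tagged proteins |

Two choices matter and are deliberate.  First, fast (degradation-tagged)
protein turnover: a receiver whose proteins outlive the symbol slot
integrates the channel instead of tracking it, and no symbol duration under
`t_sMax` lets it recover.  Second, the repressor pool (100 copies) is small
against the arriving inducer bursts with tight binding (K_d = 10): the
sensing devices operate in a stoichiometric-titration regime, switching
essentially fully on when a burst overwhelms the repressor and staying on
until the inducer pool decays below the repressor level.  This
ultrasensitivity is what makes accumulated channel tails genuinely
disruptive (a train of bit-1 symbols keeps the data-carrier gene induced
through following bit-0 slots) — and what the antagonist arm cancels.  Both
arms are symmetric, so the native B_i/A_i ratio is exactly 1 and basal
expression is small but strictly positive (leaky repression, basal
A_i ≈ 3.1 copies under the fixture).

Units are molecule copy numbers throughout; the receiver diameter is
recorded in the channel configuration but no volume conversion to
concentrations is performed, avoiding an otherwise arbitrary cell-volume
assumption.

### Integration

The reaction network is held symbolically (sympy); the compiled
right-hand side and analytic Jacobian drive LSODA (stiff-capable) between
injection events, with the state clipped at zero against round-off
undershoot.  Defaults `rtol = atol = 1e-6`; halving the tolerances moves the
Ai trace by well under 0.1 % sup-norm on the standard one-shot scenario.
Integrator failures surface with the time reached.  SBML L3V1 export
serialises the same network (species, kinetic laws and assignment rules as
content MathML, one event per injection); a structural reader verifies the
round trip.

## Symbol-duration inference

The native state is the end of a long no-input simulation (seven 3000 s
symbols, i.e. 21 ks); convergence requires the trailing-10 % drift of
ρ = B_i/A_i to stay under 0.1 %.  For each `(α, t_shift)` pair the one-shot
message `0010000000000` is simulated at `t_sDefault = 1500 s`.  On the
trajectory rescaled to the standard [0, 1000] axis
(`dt = t_sDefault · n_bits / 1000` seconds per unit) the inference locates
`t_A` (argmax A_i) and `t_B` (argmax ρ), both restricted to post-warm-up
times, then the first output sample `t_R` after both with
`|ρ(t_R) − ρ₀| ≤ 0.02·ρ₀` (absolute closeness, not one-sided approach; the
first grid point counts, with no interpolation between the 40 s samples).
The optimum symbol duration is the span from the warm-up end to `t_R`; the
rescaling is an exact identity with the direct-seconds computation and is
unit-tested as such.  The 2 % ratio tolerance is a design default exposed as
`ratio_tolerance`; retained-scenario counts depend on it and on the kinetic
fixture.  Scenarios without a return within the simulated horizon, or with
`t_s_opt > t_sMax = 2000 s`, are discarded with a recorded reason.  Under
the default fixture the 10 × 11 grid retains 5 scenarios along a diagonal
band of the design space (larger antagonist shares pair with shorter
delays), the best at `α = 0.15, t_shift = 800 s, t_s = 1720 s`.

## MOL-eye score and detection

For a retained scenario the full message (default `0010111100101`) is
simulated at its `t_s_opt`.  Post-warm-up per-symbol A_i segments (seven
bit-1, four bit-0 for the default message) are linearly resampled onto a
common 200-point within-symbol grid; the score is
`t_s_opt · Σ_j max(0, min₁(τ_j) − max₀(τ_j))` — the positive area between
the lower bit-1 envelope and the upper bit-0 envelope, summed over grid
points and then multiplied by `t_s_opt`, in that order (the order matters
only when comparing scenarios with different `t_s`, and the stated order is
implemented literally).  Ranking is by descending score with a
deterministic `(α, t_shift)` tie-break.

Detection thresholds free A_i against `λ` per slot.  The decision statistic
is the within-slot maximum (any-time exceedance; the end-of-slot value is
available via `detection_statistic="end"`).  The default `λ` is the midpoint
between basal A_i and the scenario's one-shot peak A_i — a policy, not an
optimised threshold — and is configurable.

## What the defaults do and do not show

The default configuration reproduces the full workflow at the standard
conditions: `M = 3.5 × 10⁶` molecules per bit-1, the 10 × 11 design grid
(α ∈ [0.15, 0.60] step 0.05, t_shift ∈ [0, 1000] s step 100 s),
`t_sDefault = 1500 s`, `t_sMax = 2000 s`, 40 s sampling.  Under the shipped
fixture the pre-equalizer contrast is qualitative and reproducible: at the
best retained scenario the ninth symbol (the bit-0 after the 1111 train)
carries less than half the free-A_i residual of the `α = 0` baseline, and
midpoint-λ detection decodes the message error-free while the baseline
misdecodes every bit-0 after the train.  None of this certifies a wet-lab
circuit: the arrival process is noiseless by construction, gene expression
is deterministic, membrane transport of the inducers is instantaneous
(arrivals are credited directly to the intracellular pools), and resource
competition between devices is ignored.  Numbers tied to the kinetic
fixture — 1720 s, 5 retained, the score magnitudes — should be read as
properties of the fixture, not of any particular organism.

## Problem sizes

The shipped configuration is desk-scale: one design-space scan is 110
one-shot simulations of ~20 ks simulated seconds each (about half a minute
total), retained-scenario evaluation adds one full-message simulation per
survivor, and the Monte-Carlo channel validation uses 10⁴ walkers over a
2000 s horizon (~30 s).  The full test suite runs in a few minutes on one
CPU.
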