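# Methods

## Model overview

The package simulates one bipolar myosin II minifilament interacting with
one membrane-bound actin filament. Three ingredients are coupled:

1. **Chemistry.** Each head is an independent six-state cyclic Markov
   chain (detached·ATP → detached·ADP·Pᵢ → bound·ADP·Pᵢ → bound·ADP →
   rigor → bound·ATP → detached·ATP) with first-order exit rates
   k₁…k₆. Only k₅ = k_t[ATP] depends on conditions. There are no reverse
   transitions and no strain feedback on rates, so the analytic stationary
   occupancy is pᵢ ∝ 1/kᵢ and serves as an exact oracle for the
   simulation's time-in-state statistics at any ATP.
2. **Mechanics.** Attached heads are Hookean springs (κ = 1 pN nm⁻¹)
   anchored on the actin; the myofilament is rigid and massless, so after
   every powerstroke and every detachment it relocates instantaneously to
   the zero-net-force position — the mean of the anchor positions for
   equal stiffness. Binding creates a spring at zero strain, which leaves
   the equilibrium position unchanged; this is why equilibration is only
   triggered by steps and detachments. A leading-end powerstroke advances
   one anchor by d = 5 nm and hence the filament by d/N_attached.
3. **Buckling.** The bare-zone load (the magnitude of the summed
   trailing-end spring forces at equilibrium, equal and opposite to the
   leading-end sum) compresses the spanned actin segment. With bending
   enabled, whenever the signed compressive load would exceed the Euler
   force F_c = π²EI/l², the end-to-end distance of the segment shrinks by
   δ ≥ 0 — implemented as a uniform forward shift of trailing-end anchors —
   until the load is pinned at exactly F_c. Because the load is linear and
   strictly decreasing in δ, the pinning value is a closed-form root; the
   public `equilibrate_buckling` solves it by bracketed root-finding on
   the signed load (residual tolerance 1e-6 pN) and the simulator uses the
   equivalent closed form with O(1) running sums. δ relaxes back toward 0
   as the load drops, and collapses to 0 when either end loses all its
   heads.

The buckle is a first-mode shape y = A·sin(πx/l): arc-length conservation
gives A = (2/π)√(lδ) to leading order and a peak curvature
κ_max = (2π/l)√(δ/l), which is within 0.5 % of the numerically exact
arc-length solution at the curvatures that matter here (δ ≈ 3.2 nm at the
5.6 µm⁻¹ breaking point for l = 160 nm). Breakage resets δ, the load and
all spring strains to zero — the broken-off fragment releases the stress —
and the run continues, so repeated breakage on the same trace is possible
and a breakage rate is well defined.

## Event loop and sampling

Transitions are sampled with an exact Gillespie scheme: waiting times are
exponential in the summed exit rate, the firing head is chosen
proportionally to its exit rate (heads bucketed by state, O(1) per
event), and the new state is the unique cyclic successor. An event-driven
scheme was chosen over fixed time-stepping because the rates span five
orders of magnitude (k₃ = 10⁴ s⁻¹ vs k₅ = 0.4 s⁻¹ at 0.1 µM ATP); any
single Δt would be either biased or wasteful.

The simulator's hot loop draws from a single stdlib Mersenne-Twister
generator seeded per run (deterministic across platforms; the seed is
recorded in all outputs). Library-level sampling (`sample_next_event`)
and the data generators use seeded `numpy.random.Generator`s. Sweeps
derive independent per-replicate seeds from the base seed via
`numpy.random.SeedSequence`.

Means reported per run (tension, attached count) are exact time-weighted
integrals over the post-burn-in interval, not grid averages. Velocity is
the endpoint displacement (X(end) − X(burn-in))/(duration − burn-in),
so it reflects the full equilibration dynamics rather than step counts.

## Observation timescale and breakage

State is recorded on a uniform grid (`record_interval`, default 0.1 s),
and curvature/breakage are assessed **at the recorded samples**, not at
every chemical event. The quasi-static δ rule responds instantaneously to
the load, including sub-millisecond tension spikes; a real actin segment,
bending against membrane drag with a finite relaxation time, cannot
follow those. Requiring the critical curvature at a recorded sample
(0.1 s, comparable to and below the 0.2–0.4 s frame intervals of the
imaging this model is compared against) is the package's resolution of
that mismatch: brief force excursions at intermediate ATP then do not
break the filament, while the sustained near-cap load at low ATP does.
Doing the bookkeeping per event instead would add rare spurious breakages
at 10 µM ATP driven entirely by the unphysical instantaneous response.

How bending relaxes when the force drops is not uniquely determined by a
quasi-static model; the pinning rule used here (δ continuously tracks the
value that holds the load at F_c, relaxing to a straight filament when the
load falls below it) is one consistent reading, chosen for having no free
parameters. An explicit bending relaxation time would be the natural
extension.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| k₁…k₆, k_t | cycle rates / ATP-binding constant | 100, 30, 10⁴, 10³, k_t[ATP], 2·10³; k_t = 4 | s⁻¹; µM⁻¹s⁻¹ |
| n_m | interacting heads (15 leading / 15 trailing) | 30 | — |
| p_st | trailing-end step probability | 0 (alt. 0.1) | — |
| d | powerstroke step size | 5 | nm |
| κ | head stiffness | 1 | pN nm⁻¹ |
| l_bz | bare-zone length | 160 | nm |
| l_p | actin persistence length | 15 | µm |
| kT | thermal energy | 4.0 | pN nm |
| r_min | breaking bend radius | 0.18 | µm |
| duration / burn-in | single runs; sweep cells | 20 / 0; 100 / 5 | s |
| record_interval | trace grid = observation timescale | 0.1 | s |

The head counts follow from the geometry module: a 560 nm filament with a
160 nm bare zone carries 2·(200/14.5)·4 ≈ 110 head pairs; one quarter
face the actin and one head per pair is oriented to bind, giving 27.5,
reported to one significant figure as 30 (the exact value is also
exposed). The bending rigidity is taken as EI = l_p·kT = 6.0·10⁴ pN nm²,
the unique value consistent with both the 15 µm persistence length and
the ~23 pN buckling force at l = 160 nm; kT is configurable.

Actin is treated as a continuum: heads attach anywhere at zero strain
(no 5.5 nm lattice), motion is quasi-static (no diffusion when all heads
are detached — the filament freezes until the next attachment), and
membrane drag enters only implicitly through the quasi-static limit.

Burn-in (5 s for sweep statistics) discards the initial attachment
transient. Sweep cells default to 10 replicates of 100 s, which puts the
standard error of the mean tension below ~1 % of its value at the ATP
range of interest; 20 s traces are used for curvature/breakage runs,
matching the length of the curvature records the model is compared
against.

## Analysis procedures

`radial_velocity` computes v_t = |r_{t+nΔt} − r_t|/(nΔt) with n = 20,
Δt = 0.2 s by default — a chord, not an arc, so it underestimates speed on
curved paths; this is intentional and matches standard practice for noisy
single-particle data. `sliding_average` is a centered moving mean
(default 2 s window) with shrinking edge windows. `dwell_filter` keeps
tracks of duration ≥ 0.9 s (inclusive boundary). Quartiles use the linear
interpolation convention, stated in the CLI output. The
breakage-intensity ratio is the background-subtracted mean intensity in a
post-event window over a pre-event window; the image-level masked-
intensity measurement (thresholding one channel to define the averaging
region in another) is reduced here to paired per-frame traces — the
image-processing front end is an extension point, not core.

## Synthetic data

The generators emulate the statistical structure of the real
observations, not their imagery: piecewise-constant-velocity 2-D walks
with Gaussian localization noise and 0.2–0.4 s frames; intensity traces
that step to ~2× baseline at breakage events; lognormal length
populations specified by their median (0.56 µm by default, halved by
fragmentation); exponential attachment dwells. Lognormal and exponential
are modelling choices — the real populations are only known through
median/IQR summaries and a dwell cutoff — so passing round-trip tests
shows the analysis chain is correct and calibrated on data of this
structure, not that real data follow these distributions. Camera noise,
drift, track fragmentation and localization outliers are not modelled.

## Statistical testing conventions

Monotonicity claims are tested with 2-standard-error slack between
neighbouring cells. Independence claims (e.g. duty ratio independent of
ensemble size; velocity independent of n_m) are tested as equivalence
within max(2 s.e. of the difference, a small relative margin of 1–5 %),
because a bare 2 s.e. band around a true null is itself violated 5 % of
the time. Monte-Carlo/analytic agreement uses 3 s.e. on per-cycle dwell
times, whose standard errors are exact for exponential dwells.

## Known limitations

- Quasi-static bending has no intrinsic timescale; the recording grid
  supplies the observation timescale instead (see above).
- Strain-independent kinetics: no catch/slip-bond behaviour, no
  force-velocity feedback beyond the spring tug-of-war.
- One myofilament, one actin filament, one dimension of motion; no
  networks, no membrane mechanics, no second motor.
- The tension at very low ATP (< 0.5 µM) keeps rising in the bending-off
  mode; physically, ATP depletion would eventually stall the cycle
  entirely (rigor trap), which the model reproduces only in the
  [ATP] → 0 limit.
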