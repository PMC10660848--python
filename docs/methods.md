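# Methods

## Model

Sleep is treated as a probability wave confined by a one-dimensional Morse
potential `U(x) = U0 (e^{-2x/σ} - 2 e^{-x/σ})` over the regulating parameter
of state stability *x*. All energies are measured in units of the well
depth, so `U0 = 1` throughout and the spectrum

```
ε_j = -(1 - (j + ½)/(2σ))²,   j = 0 … j_max = ⌊2σ - ½⌋
```

depends on the single width parameter σ. The model's observables are
kinematic properties of a wavepacket that starts at level `j_in` at sleep
onset and steps down one level per sleep cycle:

* **NREM duration** is the semiclassical oscillation period
  `T_j = 2π/Δε(j)` with `Δε(j) = ε_j - ε_{j-1} = (2σ - j)/(2σ²)`.
* **NREM intensity** is the wave intensity `κ(ε) L(ε)²` with generation
  efficiency `κ ∝ 1/|ε|` and amplitude `L` equal to the distance between
  the classical turning points; only the ratio to cycle 1 is predicted.
* **REM intensity** is proportional to the energy gap released at the
  cycle's end; normalised to cycle 1 it is exactly linear in *n* with slope
  `1/(2σ - j_in)`.
* **REM duration** is the Lorentzian time delay
  `τ(ε) = (1/π)(Γ/2)/((ε - ε_res)² + (Γ/2)²)` accumulated where the sleep
  and wake waves interact, centred on the homeostatic threshold energy
  `ε_res = U(x_c)` with resonance width Γ. No additive background delay is
  included: the delay is the pure resonance term.

Dimensionless durations are converted to minutes by the free scales `A_NR`
and `A_REM`. The product of NREM duration and REM intensity — the
sleep-cycle invariant — equals `2π × const` in every cycle and is the
model's sharpest falsifiable prediction.

### Mass convention

The spectrum above implies a level density `N = 2σ`, which is consistent
with classical motion of mass `m = 2` (then the exact classical Morse
period is `2πσ/√|ε|`, matching `T_j` at the half-integer index
`ε_{j-½}`). The trajectory oracle and first-passage integrals therefore use
`m = 2`; with any other mass the quadrature period and the spectral period
would disagree by a constant factor.

### First-cycle curtailment

Sleep onset places the wavepacket between the walls rather than at a
turning point, so the first NREM episode is shorter than a full period.
For onset midway between the turning points of a near-harmonic well
(σ = 20, ground level), moving outward, the first passage to the inner wall
takes 0.763 of a period — a curtailment of ~¼, the basis of the 3/4
(prediction) and 4/3 (observed-data correction) factors. Starting exactly
at the potential minimum gives 0.775: the Morse anharmonicity makes the
outer half of the orbit slower, so the "quarter" is approximate and
depends slightly on the onset convention. The curtailment factor is never
applied silently: prediction, fitting and SCI routines each take an
explicit flag, and duration fits exclude cycle 1 by default.

## Parameters

| parameter | meaning | unit | default (generator) |
|---|---|---|---|
| σ | well width; grows with habitual sleep duration | – | 10 |
| j_in | onset level; grows with prior wakefulness | – | 16 |
| ε_res | homeostatic threshold energy U(x_c) | well depths | ε_14 = −0.075625 |
| Γ | resonance width (FWHM of the delay curve) | well depths | 0.05 |
| A_NR, A_REM | minutes per dimensionless period/delay | min | 0.29, 2.0 |
| i_nr1 | cycle-1 SWS minutes (generator only) | min | 45 |
| i_r1 | cycle-1 REM density (generator only) | events/min | 4 |

The defaults describe a regular-sleep group: five cycles, first NREM
episode ≈ 91 min falling to ≈ 46 min, REM duration bell-shaped with a
≈ 25 min peak at cycle 3, REM density climbing 4 → 8 events/min. They were
chosen once as a realistic mid-range night; the intensity scales are free
parameters because the model predicts intensities only relative to cycle 1.

## Fitting

Goodness of fit follows a one-sided upper-tail χ² with
`dof = n_indep − 1 − p_fitted` (the −1 accounts for cycle-1 normalisation;
duration fits pass the number of included cycles). SEM weights are used
when present, unit weights otherwise, and the choice is recorded in the
result. The NREM-duration fit is an exhaustive grid over integer `j_in`
crossed with a bounded scalar minimisation over σ (bounds [0.75, 60]),
with the time scale solved in closed form as a weighted least-squares
scale at each candidate; ties report the smallest `j_in`. The REM-duration
fit holds (σ, j_in) fixed and searches (ε_res, Γ) by seeded multi-start
Nelder–Mead with log-parametrised Γ in (1e-4, 1].

**Identifiability.** With the time scale free, NREM durations constrain
(σ, j_in) only through `c = 2σ − j_in`: the χ² surface has an exact ridge
(σ² is absorbed by the scale). The normalised NREM-intensity series breaks
the ridge because the depth normalisation `U0 = 1` fixes the energy scale
inside `L(ε)` and `1/|ε|`; passing it to `fit_nrem_durations` is therefore
required for separate σ and `j_in` estimates, and duration-only fits carry
a `sigma_jin_degenerate` flag. REM durations do not help here: a rigid
rescaling of all energies is absorbed by (ε_res, Γ, A_REM).

## Hypnogram segmentation

Stages `W, N1, N2, SWS, REM` over 30-s epochs (configurable). An NREM
episode runs from the first two consecutive N2 epochs to the first REM
epoch of the cycle; a REM episode is the interval to the next NREM episode
onset, or to the final awakening (the maximal trailing wake run). A cycle
is complete when NREM ≥ 10 min is followed by REM ≥ 3 min; the last
cycle's REM has no minimum. Decisions the scoring rules leave open, as
implemented here: a non-terminal REM run under 3 min is absorbed into the
ongoing NREM episode (logged per occurrence); the next cycle starts at the
first two consecutive N2 epochs after the REM episode ends; episodes are
intervals between anchors, so intervening wake counts toward episode span
(wake-free minutes are available via `pure_stage=True`); a terminal NREM
episode with no REM is emitted as an incomplete cycle. Sleep-efficiency
helpers use the 85% inclusion and 93% high-quality thresholds.

## Synthetic generator

The generator emulates a laboratory group study: per-cycle model means
under multiplicative log-normal observation noise drawn **once per night
and measure** (durations 8% CV, SWS 10% CV) — a night-level scale effect
standing in for night-to-night variation in overall sleep pressure — plus
a truncated-normal first-cycle fraction (mean 0.75, sd 0.08, bounds
(0.5, 1)) for the variable onset position, and Poisson eye-movement counts
at the model's density for REM epochs. Hypnograms are epoch-quantised:
each NREM episode opens with two N2 anchor epochs, carries its SWS minutes
as an early block (a fixture convention mirroring the physiological
front-loading of deep sleep), and REM episodes carry per-epoch Poisson
counts; a 5-min wake tail closes the night.

What this does and does not show: because the duration noise is shared
within a night, group cycle *ratios* converge on the exact model ratios,
so the parameter-recovery checks demonstrate estimator correctness under
the stated study conditions, not robustness to independent per-cycle
physiological variability. Under independent per-cycle noise of the same
magnitude, adjacent `j_in` candidates differ by only ~1–2 group-SEM in the
intensity series and exact `j_in` recovery is not statistically possible
at 40 nights; σ and `c` remain estimable. Arousals, stage-N1 dynamics,
body movements, skipped-REM nights and circadian modulation are not
emulated.

The semi-quantitative transform (equal-width bins with top-bin saturation,
default 3 bins saturating at 60% of the observed range) emulates ordinal
REM-density scoring; applied to generated densities it destroys the
observed constancy of the sleep-cycle invariant while the quantitative
densities preserve it.

## Numerical choices

* Trajectory integrals substitute `x = a + (b−a) sin²ψ`, which removes the
  inverse-square-root turning-point singularities exactly; quadrature
  tolerances 1e-10 relative, with a hard error if the estimated error
  exceeds 1e-6 relative.
* `j_max` at exact half-integers uses the floor convention (the boundary
  level is included).
* The two-state mixing parameter β is reported as `inf` at exact
  degeneracy rather than raising.
* σ minimisation tolerance 1e-10 (absolute, bounded Brent); REM fits run
  24 deterministic multi-starts spanning the ladder energies, shuffled by
  the recorded seed.
* Degenerate inputs: flat duration series → boundary-σ flag and undefined
  R² flag; series without SEMs → unit weights, flagged; constancy tests
  need ≥ 3 cycles.

## Known limitations

The model addresses average group architecture of normal adult sleep, not
single-night prediction; wake-state dynamics, circadian modulation of the
sleep–wake interaction, and the time-dependent two-component wave equation
behind the stationary picture are out of scope. Fitted σ and `j_in` should
be read jointly with the identifiability note above: duration data alone
support only their combination `2σ − j_in`.
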