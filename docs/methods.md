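# Methods

## Model and assumptions

The package models anodic electron transfer in a *Geobacter
sulfurreducens* biofilm as four elementary steps — acetate oxidation
charging an intracellular mediator pool (IM), transmembrane transfer to
outer-membrane cytochromes (Omc), conduction through the biofilm, and
interfacial discharge to the electrode — under three simplifying
assumptions:

1. **Acetate saturation.** Above a few mM the acetate oxidation rate
   depends only on the oxidized IM pool: rate `k_Ac·[IM_ox]`, first
   order, `k_Ac` in s⁻¹.
2. **Fast conduction.** Long-range conduction through e-pili is much
   faster than both the transmembrane and interfacial steps
   (`k_cond ≫ k_i, k_Omc`), so the spatially resolved cytochrome
   populations collapse into one well-mixed Omc pool.  No
   distance-resolved quantity appears anywhere in the package.
3. **Anodic-only interfacial kinetics.** The current readout
   `i = F·k_i·[Omc_red]/A` is non-negative by construction.  The small
   negative currents measured at strongly negative poised potentials
   (cathodic dominance) are not modelled; the correspondingly tiny fitted
   `k_i_before` absorbs the effect.

Amounts are nmol, time s, potentials V vs SHE, current density A·m⁻².
The single nmol→mol conversion (×10⁻⁹) lives in `current_density`.
`F = 96485.3 C·mol⁻¹` and `R = 8.314 C·V·K⁻¹·mol⁻¹` are module
constants; Butler-Volmer defaults `n = 1`, `T = 298.15 K` (neither is
constrained by the data; both configurable).

The bundled parameter sets (`eetkinetics.presets`) are the published
best-fit columns for the two wild-type step profiles (−101→499 mV,
−251→649 mV) and the ΔOmcS mutant, with the 3.3×10⁻³ m² electrode.  The
table prints "(nmol)" as the unit of `k_Ac` and `k_Omc`; this is treated
as a typographical slip — `k_Ac` is s⁻¹ and `k_Omc` nmol⁻¹·s⁻¹, the only
reading consistent with the rate equations and with the derived row
`k_Omc·[Omc]tot` printed in s⁻¹.  The published protocol text gives both
profiles a −101 mV start; the parameter table's −251 mV is taken as
authoritative for the second profile.

## Two-step protocol simulation

`run_protocol` pre-equilibrates at `k_i_before` (algebraic fixed point),
integrates each constant-`k_i` phase separately with LSODA
(rtol 1e−8, atol 1e−10), and joins the phases at the switch — the solver
never sees a discontinuous right-hand side, so the peak at the step is
captured exactly.  Samples at `t ≥ t_switch` use `k_i_after`; the state
is continuous while the current jumps by `k_i_after/k_i_before`.  A free
initial condition is available because holds as short as 60 s may not
fully equilibrate a real biofilm.  The default output grid is 10 Hz over
a 60 s + 240 s hold pair, matching the instrument cadence and a
transient that settles within ~100 s.

`steady_state` eliminates `[Omc_red]` through the Omc balance and solves
the remaining scalar IM balance with Brent's method on `[0, IM_tot]`,
then certifies the result by evaluating the full right-hand side
(failure raises, never silently returns).  Tests compare it against
≥20 relaxation times of high-accuracy integration (agreement to 0.1%).

## Trace fitting

The six constants are fitted by Nelder-Mead (the analysis this package
re-implements used MATLAB's fminsearch) on the squared current residual,
with all parameters log-transformed: they are positive and span 2–4
orders of magnitude, and the log map makes the simplex scale-free.
Convergence tolerances 1e−10 (simplex and objective), max 5000
iterations; non-convergence is flagged on the result, not raised.
Options: holding any subset fixed, a Huber loss (off by default) that
down-weights the brief negative artifact spike real traces show at the
step, and seeded multi-start for noisy data.  A near-constant trace
triggers an identifiability warning — a flat current constrains only one
combination of the six constants.

## Butler-Volmer fit and identifiability

`fit_butler_volmer` minimizes the linear-scale SSE of
`k_i = k0·exp[(1−α)nF/RT·(E−E⁰)]` over (k0, α, E⁰) by Nelder-Mead
(log-scale objective available).  Linear-scale SSE deliberately lets the
large high-overpotential rates dominate, which leaves the low-potential
point — where the neglected cathodic branch bites — as the visibly worst
residual, exactly the behaviour expected of this data.

The anodic expression can be rewritten `k_i = A·exp(B·E)` with
`B = (1−α)nF/RT` and `A = k0·exp(−B·E⁰)`: only (A, B) are functions of
the data.  α (through B) is therefore sharply identified, while (k0, E⁰)
form an objective-flat one-parameter family, and any reported pair is a
convention.  The package's convention: the optimizer starts from a
data-driven point (slope from the two largest rates, amplitude through
the largest) with E⁰ anchored at −0.212 V vs SHE, the formal potential
of OmcS — the cytochrome expected to dominate the interfacial couple in
this organism.  Users with an independent estimate of the formal
potential should pass `fixed={"e0": ...}`, which makes k0 well defined.
A fit with both Butler-Volmer branches would be identifiable but places
E⁰ at the most negative measured potential (it must explain the
near-zero net rate there), so it answers a different question and is not
the default.

## ΔOmcS variant

The mutant's reduced-cytochrome signal declines linearly after the step
— pseudo-zero-order kinetics, consistent with a saturated carrier in an
OmcS-independent route.  The variant therefore replaces the bimolecular
transfer with a logistic flux `φ = k_Omc/(1 + exp(−([IM_red]−θ)/s))`
(`k_Omc` now a flux in nmol·s⁻¹; defaults θ = 1500 nmol, s = 1 nmol,
the logistic scale read literally as printed).  Electron conservation
requires the same flux to enter the Omc pool; the implementation
additionally multiplies φ by the acceptor availability
`[Omc_ox]/[Omc]tot` before applying it to either pool.  Without that
factor a pre-step hold at small `k_i` pushes `[Omc_red]` beyond
`[Omc]tot`, violating conservation; with it the gate is ≈1 in the
post-step, mostly-oxidized regime where the pseudo-zero-order form
matters, so the printed IM equation is recovered where it was used.  The
exponent is clamped at ±500 so extreme arguments saturate rather than
overflow.

The variant's flux constant is not published (the mutant column of the
parameter table comes from fitting the *unmodified* model).  The bundled
default is 40 nmol·s⁻¹: slightly above the acetate supply rate
`k_Ac·([IM]tot − θ) ≈ 29.7 nmol·s⁻¹`, so transfer (not metabolism)
saturates, `[IM_red]` relaxes linearly down to θ after the step, and the
characteristic sharp-drop-then-linear-decline signature emerges.

## Raman analysis

`integrate_peak` draws a linear baseline between anchors taken as the
median of up to 3 samples strictly outside each edge of the 22 cm⁻¹
window (read as full width; configurable), clips negative residuals at
zero, and integrates by trapezoid.  The median of three samples of a
smooth spectrum is the middle one, so constant and linear baseline
contamination is removed exactly; median (not mean) keeps single-pixel
outliers out of the anchors.  The dedicated cosmic-ray and denoising
filters used on real spectrometer output are out of scope — the linear
baseline is the simplest method preserving the area invariance the rest
of the pipeline relies on.  Note that for the default synthetic band
(σ = 4 cm⁻¹) the tails cross the window edges, so the recovered area is
a fixed ≈0.94 multiple of the true band area; every downstream use is
scale-invariant (AUC normalization, least-squares alignment), so the
factor cancels.

`normalize_series` divides by the trapezoidal AUC over time;
`align_model` interpolates the modelled `[IM_red]+[Omc_red]` to the
Raman timestamps (configurable clock offset, since acquisition starts
30–60 s before the step) and applies the closed-form 1-D least-squares
scale `⟨m,y⟩/⟨m,m⟩`, reporting RMSE, SSE and Pearson correlation.

## Synthetic data

`generate_trace` overlays multiplicative Gaussian noise (default 1%),
an additive floor (default 0.002 A·m⁻²), and an optional additive
artifact spike confined to exactly 3 samples at the step (amplitude
−12 A·m⁻² reproduces the reported excursion) on the exact model current;
truth constants ride in the metadata for recovery studies.
`generate_spectra` places a Gaussian band (σ = 4 cm⁻¹ default;
Lorentzian available) at 747 cm⁻¹ whose area is
`gain·reduced_total(t) + floor` on a linear, optionally time-drifting
baseline with per-channel Gaussian shot-like noise, on a 400–1800 cm⁻¹
grid at 1 cm⁻¹, every 5 s.  One `numpy.random.Generator` seeded through
`NoiseModel` drives all randomness; identical seeds give bit-identical
output.

What the generator does *not* emulate: electrode fouling, biofilm
growth or laser-induced signal decline, heteroscedastic (Poisson) shot
noise, cosmic-ray spikes, or any mismatch between the model family and
the biofilm.  Passing recovery and closure tests therefore demonstrate
that the *pipeline* is consistent and well-conditioned at realistic
noise levels — not that the two-pool model is correct for a given real
biofilm; that judgement needs the Raman/model comparison on measured
data.

## Numerical choices

- LSODA for both phases (the `k_i` step spans ~3 orders of magnitude;
  pre-step dynamics can be stiff relative to the post-step relaxation).
- Integration output clipped to the conservation box only to absorb
  roundoff at the bounds (tolerances keep violations at machine level).
- Brent root-finding at xtol 1e−13 for steady states; residual certified
  against a scale set by the largest flux.
- Settling time, where reported, uses the standard 2% band: first
  post-step time after which the current stays within 2% of its final
  value.
- Nelder-Mead everywhere a published analysis used fminsearch, for
  procedural comparability; `scipy.optimize` supplies it.

## Known limitations

- Single lumped Omc pool: no information about the spatial distribution
  of redox states survives the fast-conduction limit.
- The anodic-only interfacial law cannot represent net cathodic
  currents; fits to traces with substantial negative segments rely on
  the Huber option to ignore them.
- (k0, E⁰) from the default Butler-Volmer fit are convention-dependent
  (see above); only α and the rate profile `k_i(E)` are data-backed.
- The six-constant trace fit assumes the switch time and sampling grid
  are known exactly; clock error between potentiostat and spectrometer
  is handled only by the manual Raman `time_offset`.
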