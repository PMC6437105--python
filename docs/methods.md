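# Methods

`phagechar` quantifies the standard in-vitro characterization workflow for
lytic bacteriophages: plaque-count titration and efficiency of plating
(EOP), host-range summarization, adsorption and one-step growth parameter
estimation, pH/temperature stability profiling, and a mechanistic model of
multi-phage "cocktail" killing assays. This note records the models, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Titer, MOI and EOP

A plaque assay plates volume *v* of a lysate at dilution *d*; the plaque
count is Poisson with mean *T·d·v* where *T* is the titer (PFU/mL). Pooling
counts across dilutions, the maximum-likelihood titer is

    T̂ = Σ c / Σ (d·v),   SE(T̂) = √(Σ c) / Σ (d·v).

Counts outside the countable range [30, 300] are flagged rather than
discarded; the estimator uses countable plates by default (pooling flagged
plates is exact for the MLE, but real uncountable plates carry
plate-saturation bias, so exclusion is the safer default). A series in
which every plate shows zero plaques is reported as below detection
(0 PFU/mL, SE 0) rather than as an error.

MOI is the plain ratio PFU/CFU at inoculation. EOP is the titer of a phage
on a test bacterium divided by its titer on the reference host at equal
input dose; dose mismatches are corrected by linear rescaling and flagged.
The four-level classification uses closed boundaries as conventionally
printed: High (EOP ≥ 0.5), Moderate (0.1 < EOP < 0.5), Low
(0.001 ≤ EOP ≤ 0.1), No activity (EOP < 0.001). Every non-negative EOP maps
to exactly one class; the boundary values 0.5 and 0.1/0.001 belong to High
and Low respectively.

Host-range summaries count spot-positive isolates and EOP classes per
bacterial group (pathotype, serotype or species) and report the group's sum
of EOP values. Percentages are rounded half-up to integers (58/80 → 73%),
matching how such tables are conventionally printed. The spot-vs-plaque
discordance is 100·(spot⁺ − plaque⁺)/spot⁺ per group, with plaque-positive
defined as measured EOP ≥ 0.001; raw counts are always reported alongside
because published percentage-difference figures for this quantity are often
not recoverable from any single formula.

The packaged reference screen (`hostrange.demo_matrix`) is synthetic at the
isolate level: only group-level counts and EOP sums of the underlying
published screen are transcribed, and isolates are expanded with
representative within-class EOP values (Moderate 0.25, Low 0.05) plus one
residual High value per group so that every group-level statistic — spot
counts and percentages, class counts, EOP sums — is reproduced exactly.
Nothing at the individual-isolate level should be interpreted as data.

## Adsorption kinetics

Free phage attaching to host cells at density *B* (CFU/mL) under mass
action decay as P(t) = P₀·exp(−k·B·t). The estimator regresses
ln(fraction free) on time over all points with fraction ≥ 0.01 (points
below that are dominated by counting noise near the detection limit) and
reports k = −slope/B, with R², residual SD and the number of points used as
diagnostics. Regression was preferred over the two-point endpoint formula
for noise robustness. A non-negative slope yields k = 0 with a "no
adsorption detected" warning rather than an error. *B* is an explicit
input: k carries units of mL/min and cannot be identified from the decay
curve alone; the package convention for synthetic recovery studies is
B = 10⁸ CFU/mL, the standard one-step inoculum.

## One-step growth: latent period and burst size

The one-step curve is baseline free-phage titer P₀ until the latent period
L, a rise as infected cells lyse, and a plateau at b·P₀ where b is the
burst size (final over initial free phage).

Latent-period detection: the rise is the first sample exceeding 2.0× the
running mean of all earlier samples; L is estimated as the midpoint of that
sampling interval, i.e. with resolution half the sampling step (2.5 min on
the standard 5-min grid). Threshold crossing with midpoint interpolation
was chosen over changepoint optimization because it matches the assay's
verbal definition and its sampling resolution; on the standard grid it
carries a small (≤ half-interval) upward bias, which is inside the
estimator's stated resolution.

Burst-size estimation: the baseline is the mean of the pre-rise samples.
The plateau is the mean of the trailing run of samples whose 3-point moving
average stays within 15% of the final smoothed value. An earlier variant
referenced the raw maximum instead of the smoothed final value; under
Poisson plate-counting noise the maximum of ~10 plateau points is ~1.5 SD
high and the within-band mean inherits a +10–14% selection bias, large
enough to break ±15% recovery. The smoothed-final-value reference is exact
on noiseless curves and unbiased under counting noise. If fewer than two
samples sit on the plateau the curve may still be rising and the burst is
flagged as a lower bound rather than guessed.

## Stability profiles

Viability is 100·(surviving titer)/(initial titer) per condition, capped at
100 for reporting. The stable window is the maximal contiguous run of
conditions with viability ≥ 50% (the floor is configurable); viability
below 1% is reported as inactivated (plaque-assay detection floor).

## Cocktail killing dynamics

The killing-assay model couples logistic host growth, mass-action
adsorption, and Erlang-delayed lysis (see the `cocktail` module docstring
for the equations). Design choices:

- **Delay.** Lysis delay is an n = 10 stage linear chain (Erlang with mean
  L, CV 1/√10) rather than a delay-differential solver: simpler, plays well
  with stiff integrators, and converges to the fixed delay as n grows
  (verified: the first-lysis time approaches L monotonically as n goes
  10 → 40). n is configurable per scenario.
- **Viable counting.** Only susceptible cells count as colony-forming by
  default: a cell that has adsorbed phage is committed to lysis and will
  not found a colony on the titration plate. The flag
  `viable_includes_infected=True` switches to counting infected cells as
  viable until lysis. This default matters: at 2 h in the two-phage
  scenarios the susceptible pool is essentially exhausted while
  lysis-committed cells are still ~10⁵–10⁶/mL, so the two conventions
  disagree by orders of magnitude at intermediate times (they agree at the
  endpoints once lysis completes).
- **Extinction.** A species whose *total* bacterial material (susceptible +
  infected) falls below 1 CFU/mL is clamped to zero and stays there — the
  deterministic reading of "no viable cells". Clamping on total material
  rather than on the viable count means phage production from
  lysis-committed cells is never cut off early. Reported viable counts are
  additionally floored to 0 below the threshold.
- **Adsorption sink.** Free phage adsorb only to susceptible cells; there
  is no adsorption loss to infected cells or debris, and no free-phage
  decay term. Both simplifications overstate free phage late in a run but
  have little effect before bacterial collapse.
- **Calibration.** All three species share r = 0.023/min (≈30 min doubling)
  and K = 10⁹ CFU/mL; the source assays report neither, and these are the
  documented defaults under which the endpoint checks are evaluated.
  Infectivity is diagonal: each phage infects only its own genus.
- **Numerics.** LSODA with rtol 1e-8, atol 1e-4 (states span 1 to 10⁹;
  extinction at 1 CFU/mL is resolved by the event function, not by atol).
  Integration restarts after each extinction event. State variables are
  clipped at zero inside the right-hand side to keep round-off excursions
  from feeding back. Internal time unit is minutes; reporting is at the
  assay hour marks 0/2/4/6/24 h.
- **Audit.** Two cumulative-flux states per (bacterium, phage) pair record
  total infections and total lyses, letting tests verify mass-action
  consistency (free phage removed = stage-1 cells created; infected pool =
  in − out) to integrator tolerance.

The scenario library encodes the published assay designs: each phage alone,
the three two-phage cocktails (Escherichia+Klebsiella, Klebsiella+
Enterobacter, Escherichia+Enterobacter), the three-phage cocktail, and a
phage-free control, at 10⁶ PFU/mL per phage. Bacterial inocula come in two
variants: `assay` (6×10⁶ CFU/mL total, as pipetted) and `normalized`
(10⁶ CFU/mL total, the density killing-curve endpoints are quoted from).
The write-up's "MOI of 1.0" for 10⁶ PFU/mL against 6×10⁶ CFU/mL does not
reconcile with either variant; the scenario stores the nominal MOI as
metadata without attempting to reconcile it. Killing summaries report both
log₁₀ and plain fold reductions because verbal "n-fold decrease" claims are
ambiguous between the two.

## Synthetic data generator

The generator produces every input the pipeline consumes, with the
statistical structure the estimators assume:

- **Plaque counts**: Poisson around T·d·v per plate.
- **Adsorption**: exact exponential decay, 4-min grid to 40 min.
- **One-step**: baseline → rise at L → plateau at b·P₀, 5-min grid to
  80 min. The rise is a cubic smoothstep in log titer starting exactly at L
  with width one sampling interval (5 min). A smoothstep was used rather
  than a logistic because a logistic has no exact baseline-departure point:
  the titer must equal the baseline for t < L for "latent period = start of
  rise" to be well defined at the estimator's half-interval resolution.
- **Stability**: trapezoidal viability profiles — 100% inside the stable
  window, 0 beyond the inactivation bounds, linear in between. The pH
  preset is stable over pH 4–11 with inactivation at ≤3 and ≥12. The
  temperature preset is stable to 55 °C with full inactivation set at
  64 °C, placing the 50% point between the 55 and 60 °C test conditions —
  the published finding is qualitative ("activity upheld to 55 °C, reduced
  above") and this is the package's quantitative encoding of it.
- **Killing curves**: noise wrapper around model-simulated trajectories.
- **Noise**: optional mean-preserving lognormal titer noise (default CV
  0.10, a conventional triplicate variability — no published error model
  exists) and optional plate-counting emulation: each point is re-plated at
  the dilution giving ~100 plaques and the count drawn Poisson, i.e. ~10%
  relative counting error. All randomness flows through one integer seed;
  identical seed and parameters give identical output.

What the generator does **not** emulate: adsorption-step losses and
chloroform treatment before one-step sampling (inputs are assumed already
corrected), eclipse periods, plate-to-plate efficiency differences,
resistant subpopulations, and any within-isolate EOP structure. Passing
recovery tests therefore show that the estimators invert the assumed data
model at realistic noise levels — not that they are robust to systematic
wet-lab artifacts outside that model.

## Problem sizes

Recovery tests use triplicate assays on the standard grids (11-point
adsorption, 17-point one-step) and sweep 200 seeded triplicates per preset
for the distributional checks; the titer-bias and dispersion checks use
1,000–10,000 simulated plates; cocktail scenarios integrate 24 h of model
time at 1-min output resolution. The full demo pipeline and the whole test
suite each run in seconds on one CPU.

## Known limitations

- The latent-period estimator's resolution is half the sampling interval;
  with 5-min sampling, presets 26/40/11 min are reported as 27.5/42.5/12.5
  on noiseless data. This is inherent to threshold detection on a grid.
- The cocktail model has no resistance evolution, lysogeny, phage decay or
  stochastic (small-number) effects; "extinction" is a deterministic clamp.
- Group summaries treat spot results as binary; clearance-time metadata is
  stored but not scored.
- EOP classification assumes the host-reference titer is measured without
  error; no uncertainty is propagated into the class assignment.
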