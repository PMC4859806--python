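# Methods

This note records the modeling assumptions, parameter conventions, numerical
choices and known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The equilibrium ensemble

The enhancer is modeled at thermodynamic equilibrium. A *configuration* is a
subset of annotated binding sites with no overlapping pair bound at once
(overlap = intersecting `[start, end)` intervals; competitive binding).
Site occupancy weights are `S_tf · A_i · conc_tf(x)`:

- `S_tf` — one scaling factor per transcription factor (Dorsal, Twist,
  Snail), absorbing absolute affinity and activity;
- `A_i` — the site's PWM score in bits divided by the matrix's maximum
  achievable score, giving a dimensionless affinity in (0, 1]. Raw-score and
  exponentiated-score mappings can be substituted, but the normalized form
  keeps scaling factors comparable across factors and is used throughout;
- `conc_tf(x)` — relative nuclear concentration at DV point x. The packaged
  fixture (`data/gradients.tsv`) holds the 17-point Dorsal, Twist and Snail
  arrays covering 0–40 % egg height, one point per 2.5 %.

Cooperativity acts between *adjacently bound* sites — no other bound site
between their centers — and multiplies the configuration weight by
`ω_class(d)` with `d` the center-to-center distance rounded half-up to
integer bp. Interaction classes are Dorsal–Dorsal, Twist–Twist,
Dorsal–Twist and Snail–Snail; activator–repressor adjacency carries no
cooperativity factor (`ω = 1`).

### Activity and quenching algebra

A configuration is *active* when at least one bound activator escapes
quenching. Each adjacently bound Snail represses an activator independently:
activator i survives with probability `p_i = ∏_r (1 − f(d_ir))` over its
adjacent bound repressors (at most two, one per side), and

```
P_active(c) = 1 − ∏_{i ∈ bound activators} (1 − p_i),      E(x) = Σ W·P_active / Σ W.
```

This independent-product rule is the engine's contract and the single most
consequential algebraic choice: the alternative of summing quench
probabilities when two repressors flank one activator would differ in the
doubly-flanked case. Configurations without bound activators are never
active, and `W(∅) = 1`.

### bHLH sites

The construct design includes two E-box (bHLH) sites, but the model has
exactly three scaling factors. bHLH sites are treated as Twist-class
activators: they share the Twist scaling factor, the Twist concentration
gradient and the Twist interaction classes (TT, DT, Snail-on-Twist
quenching). Twist is itself a bHLH factor binding E-boxes, and without this
identification the bHLH knockout constructs would carry no information.

### Evaluation paths

Two implementations coexist and are cross-checked to 1e-9:

- `predict_expression` — explicit enumeration over all valid configurations
  (capped at 22 sites ≈ 4M subsets; beyond that it refuses);
- `predict_expression_fast` — an O(m²) left-to-right transfer recursion over
  the most recently bound site. Sites are ordered by `(start, end)`; along
  that order non-overlap is transitive, so forbidding transitions between
  directly overlapping pairs is exact. The inactive-probability product is
  accumulated as a pending linear form `U + V·b` in the not-yet-known right
  quench fraction of the last bound activator, which closes at the next
  transition. All recursions are vectorized across the 17 DV points.

## Scheme inventory and parameter layouts

Cooperativity: C1 linear `a + b·d`, C2 logistic `2a/(1+e^(d/b))`, C3
gaussian `a·e^(−d²/b)` (one (a, b) pair shared by the homotypic classes
DD/TT/SS plus a separate DT pair); C4–C9 binned schemes (2 bins at 25/50/75
bp, 3 bins at 50/100, 60/120, 70/140 bp) with shared homotypic bins + DT
bins; C10–C15 the same edges with one bin set per class (DD, TT, DT, SS).
Last bins are open-ended so every distance is covered. Cooperativity
parameters live in [0, 1000]; 1 means no interaction and values below 1
(anti-cooperativity) are permitted.

Quenching: Q1 is a fixed, zero-parameter lookup curve shipped as
`data/q1_msb.json` — a clearly labelled synthetic stand-in for a published
non-monotonic short-range-repression profile (moderate at contact, peaking
near 50 bp, zero beyond 100 bp), overridable by the user. Q2–Q4 are
continuous with amplitude fixed at a = 1 and one free decay scale b per
repressed class (Snail→Dorsal, Snail→Twist). Q2 is implemented as the decay
`max(0, 1 − b·d)`: the literal increasing form `a + b·d` with b > 0
contradicts short-range repression (and the sibling forms are both labelled
decays); a flag restores the literal form. The gaussian exponent is read as
−d²/b. Q5–Q8 are binned fractions clipped to [0, 1] (4 bins at 25/35/45 bp
spacing; 10 bins of 10 bp), last bin open-ended.

Every layout starts with the three scaling factors; binned cooperativity
slots follow in class order, then quenching slots (Snail-on-Dorsal before
Snail-on-Twist). The parameter counts of all 120 combinations reproduce the
published per-model table and are locked by a test against a hard-coded
copy.

## Motif handling

PWMs are read from MEME minimal files (via Biopython), with a 0.01
pseudocount per cell and row renormalization. Hybrid matrices average two
position-probability matrices cell-wise; log-odds are taken after
averaging. Scanning uses log₂ odds against a uniform background
(configurable), reports both strands on forward coordinates, collapses
same-start opposite-strand hits to the better strand, and scores N bases as
0 bits.

Score thresholds for a target p-value are computed by exact dynamic
programming over the per-position score distribution on a grid of 1e-3 bits
(configurable). The returned threshold sits just below the lowest
*achievable* score level whose background tail probability is ≤ p, with a
slack of L·granularity absorbing per-position rounding; the admitted word
set is exact when distinct word scores differ by more than 2·L·granularity.
As p → 1 the threshold does not reach the minimum achievable score: the
tail at the minimum is always 1, so the last mass quantum stays excluded —
an unavoidable property of discrete score distributions.

The packaged PWMs are synthetic stand-ins built from the handful of
footprinted wild-type site sequences on the enhancer (4 Dorsal, 2 Twist, 3
Snail 10–11-mers); the published matrices are not redistributed. bHLH
E-boxes are matched literally as CANNTG hexamers (a matrix can be supplied
instead). In genome scans bHLH annotation is off by default — CANNTG occurs
every ~130 bp in random sequence and would place activator sites in every
window.

## Parameter estimation

The objective is the RMSE between predicted and measured 17-point profiles
over all constructs, every point weighted equally. Optimization uses a
compact (μ/μ_w, λ)-CMA-ES (standard rank-one + rank-μ covariance updates,
cumulative step-size adaptation) in an unconstrained space: positive slots
(scalings, cooperativities, decay scales) through exp, quench fractions
through a logistic map. Non-finite objective values are replaced by a large
penalty.

Defaults: population 4+⌊3 ln k⌋, 5000 evaluations per run, initial step
0.3, five restarts. The central initial point is scalings 0.5,
cooperativities 1, quench bins 0.5, decay scales 50 bp; each restart's
start is jittered by a seeded N(0, 1) offset in transformed space —
restarts from a single point were observed to re-enter the same basin,
while jittered starts explore distinct local minima (the landscape is
multimodal). A fit is flagged *stable* when at least three of five runs
agree in RMSE within 5 %. Tests and the acceptance suite use reduced
budgets (300–2000 evaluations, 1–3 restarts) so the default suite completes
in minutes; these are the package's own desk-scale defaults, and the best
restart at those budgets recovers synthetic-truth profiles to ≈0.01 RMSE.

Model comparison uses `AIC = n·ln(RMSE²) + 2k` with n the number of fitted
points and k the parameter count — the standard Gaussian-likelihood form
made explicit here because only the criterion's name, not its formula, is
conventionally stated.

## Validation

Systematic cross-validation uses the published mutation-class folds
(Dorsal {2,3,6,7,8,11,12,15,16}, Twist {4,5,17}, Dorsal+Twist
{9,10,13,14,18,19,20,21}, Snail {23–33}, bHLH {34–38}); constructs 1 and 22
belong to no class and always stay in training. Random five-fold CV
shuffles the 38 ids into folds of 8,8,8,7,7 with the package's seeded
generator; other registry sizes rescale proportionally (n//5 each,
remainder to the leading folds).

Sensitivity analysis perturbs each parameter by an independent ±20 %
log-uniform factor around the fitted value (n = 2048 Saltelli samples by
default) and decomposes the variance of the resulting RMSE with Jansen
estimators: first-order `S_i = 1 − E[(y_B − y_ABi)²]/(2 Var)`, total-order
`T_i = E[(y_A − y_ABi)²]/(2 Var)`, second-order reported as `T_i − S_i`
clipped at 0; each order is normalized to sum 1 over the reported
parameters. Slots never exercised by the construct set (empty distance
bins) are detected by a two-point probe — vary the slot alone and check all
predictions are bit-identical — and excluded before sampling. The exact
estimator of the original sensitivity methodology is not published; the
variance-based contract above, with its perturbation distribution and
sample count configurable, is this package's documented formalization.

## Genome scanning

Regions are tiled into 500-bp windows at 250-bp steps (50 % overlap; final
partial window dropped). Each window is scanned, a site map built, and
every panel model predicts its profile via the fast path. Aggregates:
uniform mean and SD; performance weighting ∝ (1 − RMSE) floored at 0; AIC
weighting by Akaike relative likelihood `exp(−(AIC − min AIC)/2)` — raw AIC
can be negative, so relative likelihood replaces direct weighting.

Pattern calls formalize the scoring-scale boundaries: *inactive* when the
profile maximum is below 0.1; *mesodermal* when point 4 (the Snail
repression checkpoint, 4th of the 17 points) holds ≥ 0.5 of the maximum and
the maximum lies in points 1–5; *neuroectodermal* when point 4 is < 0.3 of
the maximum and the peak lies in points 6–13 (the Snail gradient collapses
between points 6 and 7); otherwise *ambiguous*. All thresholds are config.

Out-of-sample enhancers are graded on the 4-point scales (neuroectodermal:
predicted expression at point 4 in bands <0.1 / 0.1–0.3 / 0.3–0.5 /
0.5–1.0; activation by peak difference at 0.2 / 0.5 / 0.7) and the
mesodermal 5-point activation / 4-point Snail scales (mesoderm activation
vs. 1.5× the neurectoderm peak; <0.1 absolute = strongest repression). The
published activation bands leave 0.4–0.5 unassigned; band 3 is extended
downward to cover it. Grades 4 vs 5 of the mesodermal activation scale
distinguish low vs high dorsal-ectoderm signal; with only 0–40 % of the
axis modeled, the dorsal-most points (14–17) stand in for the dorsal
ectoderm.

For detection statistics the package ranks windows by *mean activity* (the
mean of the ensemble-mean profile): planted-enhancer experiments compare
windows fully containing a planted element against the background
distribution, since a window sharing only a sliver of an element carries
only a sliver of its sites.

## Synthetic data

The generator emulates the study design: a 318-bp wild-type enhancer with
12 sites (4 Dorsal, 2 Twist, 4 Snail, 2 E-box) including the known
Snail4/Twist2 overlap, and 38 constructs in the published classes. Site
*positions* and per-construct knockout compositions beyond the class lists
are not published; the packaged layout embeds the printed site sequences at
plausible interleaved positions (every activator within short range of a
Snail site, as short-range repression of the real element requires) and the
registry assigns single/pairwise/multiple knockouts within each class, all
flagged `inferred`. Constructs 1 and 22 are wild-type-activator ensembles
(22 a replicate). Knockout = deletion from the site map; the sequence-level
path (mutate, rescan) exists for real sequences.

The packaged ground-truth parameter point (`demo_truth`) puts the system in
a cooperativity-dominated activation regime: activator scalings 0.75, Snail
scaling 40, short-range cooperativity 8 falling to a distance-independent
3, and near-complete short-range quenching (bins ≈ 0.98 decaying toward
0.96 at 100 bp; matched strengths for the continuous forms). Under these
values the wild-type map produces a lateral stripe (ventral ≈ 0.15–0.2 of
peak), single marginal sites in random sequence stay quiet, and planted
enhancers stand far out of the genomic background — the qualitative regime
the analysis assumes. Scaling-dominated alternatives (weak cooperativity,
strong scalings) reproduce the stripe equally well but light up random
background windows; that trade-off is intrinsic to the normalized-affinity
mapping, which spans only a ~4× range between threshold-level and perfect
sites.

Noise: per point, per embryo, additive Gaussian truncated at 0, i.i.d.;
profiles are embryo means with the standard error of the mean attached.
Raw-trace simulation upsamples the 17 points ×6 into a 102-pixel signal
region followed by an equally wide signal-free dorsal-ectoderm flank, adds
a quadratic background and a session intensity scale; preprocessing fits
the quadratic to the flank, subtracts, clips at 0, normalizes to the
same-session wild-type peak (mean of values above the 95th percentile) and
block-averages every 6 pixels back to 17 points. The flank is given the
same width as the signal region so the background fit interpolates rather
than extrapolates; with a short flank, quadratic extrapolation across the
signal region amplifies noise severalfold and dominates the recovered
profile. Planted genomes are i.i.d. uniform background with enhancer
sequences written in; default placement nudges each element to lie wholly
inside at least one 500/250 tiling window.

What passing tests on these data do *not* show: performance on real
embryo measurements (normalization artifacts, spatial correlations, embryo
staging variability are not simulated), correctness of the stand-in PWMs
or site positions, or identifiability of individual parameters (the
sensitivity analysis shows compensation is the norm).

## Monotone roles of sites — domain of validity

Within the cooperative regime — cooperativity factors ≥ 1 with binned
schemes, quenching non-increasing with distance, site maps without
overlapping pairs — deleting an activator site never increases predicted
expression at any DV point, and adding a non-overlapping Snail site never
increases it. Sketch: adding a repressor only adds or strengthens the
quenching on each neighbor (replacing a farther repressor's fraction with a
nearer, under monotone f, can only increase it), so per-configuration
activity falls; weight redistribution cannot invert the mixture when all
interaction factors are ≥ 1 and no competition is released.

Outside that domain the property genuinely fails, and the suite contains a
demonstration: (i) the continuous cooperativity forms decay to 0 at long
range — effective anti-cooperativity between distant adjacently bound
pairs, so removing an intervening activator can *raise* expression; (ii)
overlap competition — deleting an activator that overlaps another site
frees the latter; (iii) Snail–Snail cooperativity can stabilize a repressor
that competes out a stronger repressor via overlap; (iv) the fixed Q1 curve
is non-monotonic by design. These are properties of the model class, not
implementation artifacts, and the randomized monotonicity suite therefore
stays within the provable domain.

## Numerical conventions

- Coordinates are 0-based half-open; BED output follows suit.
- Center-to-center distances round half-up to integer bp.
- Enumeration cap 22 sites; the transfer recursion is exact for any count.
- Neutral-repressor cancellation and the Snail-free-region identity are
  asserted to 1e-12 (the two evaluation orders differ only by float
  regrouping); path equivalence to 1e-9.
- Measured profiles above 1.0 (derepressed constructs) are not clipped;
  predictions are clipped into [0, 1] only against float underflow.
- Expression is compared to measurements without rescaling (both on the
  wild-type-peak≈1 scale).
- CLI commands take flat flags and write JSON manifests (inputs, seeds,
  config hash); a YAML config layer was considered and dropped as
  redundant with the manifest + flags surface.

## Known limitations

- The Q1 curve, the PWMs, the site layout and the construct compositions
  are labelled stand-ins; users with the real resources should supply them.
- Absolute background activity in genome scans depends strongly on the
  affinity mapping; the normalized-score default compresses the
  strong/weak-site dynamic range.
- CMA-ES at desk-scale budgets finds profile-accurate fits but individual
  parameters remain sloppy; do not interpret single fitted values without
  the sensitivity report.
- Only 0–40 % of the DV axis is modeled; dorsal-ectoderm behavior is
  extrapolated in the mesodermal scoring scale.
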