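# Methods and design notes

## Scope and model

The pipeline operationalizes a three-criteria definition of a "core"
fermentation microbe — dominant, network hub, flavor-associated — with
functional validation by strain-omission experiments, followed by phase
analysis of the fermentation timeline and encoding of temporal SynCom
inoculation schedules. All statistics are nonparametric or classical:
Spearman rank correlation, Benjamini–Hochberg FDR control, one-/two-way
ANOVA with Tukey HSD, and PCA on the correlation scale.

## Statistical primitives

**Spearman correlation.** rho is the Pearson correlation of mid-rank
vectors (average ranks for ties). The two-sided p-value is exact for
n ≤ 9 samples — the proportion of all n! permutations of one rank
vector whose |rho| reaches the observed value (ties conditioned on the
observed tie pattern) — and uses the t-approximation with n − 2 df
above that. The n ≤ 9 cutoff balances fidelity and runtime: 9! ≈ 3.6e5
permutations per pair is the largest exhaustive enumeration that stays
interactive. Constant vectors yield an undefined rho and are dropped
from network testing with a warning rather than aborting a run, since
always-absent taxa are routine in community tables.

**BH step-up.** q_(i) = min_{j ≥ i} m·p_(j)/j, capped at 1, returned in
input order. Cross-checked in the tests against statsmodels and a
literal quadratic-loop implementation of the definition.

**Tukey HSD.** Tukey–Kramer with pooled within-group variance;
p-values from the tabulated studentized-range approximation
(`statsmodels psturng`), which is clipped to [0.001, 0.9] — adequate
for accept/reject decisions at α = 0.05 and orders of magnitude faster
than numerical integration of the studentized-range CDF. With
zero-variance degenerate data (exact replays of printed means) the
ANOVA F is undefined; unequal means are then treated as real effects so
that replayed outcomes prune as printed.

## Networks and selection criteria

Two co-occurrence networks resolve the two printed threshold sets: the
*analysis* network (|rho| > 0.6, q < 0.05, BH over all taxon pairs)
from which hubs are read (degree strictly > 9), and a stricter
*display* network (|rho| > 0.8, p < 0.01) intended only for plots.
Correlations use all samples (every timepoint × replicate) on relative
abundances, species level. No compositionality correction is applied by
default; a CLR pre-transform is available as an opt-in flag
(`build_cooccurrence(..., clr=True)`).

The candidate core is the strict intersection of the three criterion
sets; this reproduces the published nine-species candidate set from the
published per-criterion lists, which the package ships as constants
(`core_selection.DOMINANT_SPECIES`, `HUB_SPECIES`, `FLAVOR_SPECIES`,
`OMISSION_OUTCOMES`). Pruning keeps candidates whose omission
significantly moves at least one of the two indicators; candidates with
no omission group (the koji mold, without which koji cannot be made)
pass by default with a logged note. Replaying the encoded omission
outcomes prunes the two species with null effects on both indicators,
yielding the seven-species final core.

## Phase analysis

The source procedure reads four phases off PCA plots by eye; here the
segmentation is made reproducible: timepoints are partitioned into k
contiguous segments minimizing total within-segment SSE in the space of
the first two PC scores, solved exactly by dynamic programming
(O(T²k)), ties broken toward the earliest boundary. Boundary days are
reported as midpoints between adjacent sampled days. The pipeline
segments the replicate-averaged community trajectory on log10 relative
abundances (pseudocount 1e-6) after dropping taxa with mean RA ≤ 0.5%:
the log makes succession steps at low abundance as informative as at
high abundance, and the rare-taxon floor prevents pure-noise variables
from rivalling the succession signal when taxa far outnumber
timepoints (with T ≈ 9 observations, sample-PCA noise eigenvalues grow
like (1+√(p/T))² and would otherwise contaminate the score space).

**Indicator assignment.** PCA on *raw* z-scored trajectories cannot
split early from late indicators: glutamate (early riser) and
4-ethylguaiacol (late riser) are both monotone increasing and load with
the same sign on any overall-trend component. The assignment therefore
runs PCA on *rate* profiles — first differences of the z-scored
trajectory per day — where early-changing and late-changing indicators
anti-correlate. PC1's reflection ambiguity is pinned by orienting every
component so the earliest observation scores non-negative; indicators
with positive PC1 loading (changing early) are assigned "early", the
rest "late". The rule is antisymmetric (mirrored trajectories get
opposite sides) and excludes constant or under-observed indicators.

**Taxa–phase correspondence.** Metabolite classes are the seven
volatile classes plus pooled amino-acid indicators (glutamate, umami
amino acids, amino nitrogen) and organic acids (lactic acid); class
activity is the mean over members of per-timepoint z-scored
concentration. A core taxon maps to each phase in which a class it is
significantly *positively* rank-correlated with (BH within this family,
q < 0.05; exact permutation p at 9 timepoints) has its maximum mean
rate of change (first differences over days; intervals belong to the
phase containing their midpoint). Positive correlation is required
because production, not depletion, is the association of interest.

## Synthetic data generator

The generator emulates a 40-day moromi run: 55 bacterial + 28 fungal
taxa, 9 timepoints × 3 replicates, 128 volatiles in the seven-class
composition (scaled by largest remainder from the 16/6/10/21/26/47/9
class counts), and the standard indicator trajectories — glutamate
saturating near 8.5 g/L, umami amino acids ≈ 12 g/L, a three-wave
lactic-acid rise, a reducing-sugar hump peaking ≈ 21 g/L near day 10,
pH declining 6.8 → 4.7, and 4-ethylguaiacol near zero until the last
phase then rising to ≈ 71 μg/L.

Latent log-abundances are piecewise-logistic with smooth steps centred
between the sampled days flanking the planted changepoints (days 5, 15,
25 for the default grid, recorded as the last sampled day of each
phase). Two cliques share a latent each — an early-falling group
(Weissella/Lactiplantibacillus/Staphylococcus plus the koji mold) and a
late-rising group (Pediococcus/Tetragenococcus plus the yeasts) — with
clique size 12 (> hub threshold + 2) so every member's within-clique
degree exceeds the hub cutoff. Replicates share the latent and differ
only by multiplicative log-normal noise (default sd 0.3, a typical
replicate-level dispersion for amplicon relative abundances); a small
per-taxon timepoint wiggle (sd 0.08 clique / 0.12 background) keeps
trajectories from being exactly smooth.

Because closure is scale-invariant per sample, any time variation in
the *total* load of the succession groups would imprint its inverse on
every flat taxon as a shared trajectory and create spurious
correlations; the generator therefore rescales the time-varying taxa so
their combined expected load is constant. Base abundances are balanced
so that no group dominates a sample (largest single share ≈ 15%),
keeping per-sample closure noise from acting as a common mode.

Volatiles respond linearly: concentration = baseline × (1 + effect ×
RA/mean RA) + Gaussian noise (8% CV), with each of the nine core taxa
(plus designated decoys) driving six compounds, one above the
five-compound qualification threshold. Decoys make the intersection
non-trivial: clique members at low abundance (hub + flavor only), flat
abundant taxa (dominant only), an abundant out-of-clique producer
(dominant + flavor), low-abundance producers (flavor only), and sparse
taxa abundant in a mid-run window but absent elsewhere (failing only
prevalence).

Omission measurements are drawn around fixed control means (umami
10 g/L, 4-EG 70 μg/L) with each omission group's mean reduced by its
planted percent effect and 5% CV noise. By default every core member
gets a detectable (25%, 40%) effect so that end-to-end recovery
compares the full planted core; `EMULATED_OMISSION_EFFECTS` instead
plants the published outcome pattern, including the two null members
that pruning must remove.

**What the generator does not emulate:** real amplicon data's
sequencing-depth variation, zero inflation and taxonomic misassignment;
compositional effects beyond closure (no interaction-driven dynamics);
mechanistic salt/temperature kinetics; and volatile chemistry beyond a
linear producer response. Passing the planted-recovery tests therefore
shows the pipeline correctly implements its criteria and is calibrated
on null data — not that the criteria themselves would recover the true
functional core in any real fermentation.

## Schedules

The arrow grammar maps the k-th arrow group to the k-th slot day
(default 0/5/10/25; yeasts fixed at day 25). Formatting preserves the
written strain order within a `+` group so round-trips are exact, while
schedule equality and enumeration deduplication use (day, strain-set)
pairs — two of the seven published rows differ only in written order
and denote the same design, so the 12-schedule enumeration covers all
seven rows as six distinct designs. Doses default to 1e8 CFU/g for
bacteria and 1e7 CFU/g for yeasts. No fermentation-outcome simulator is
claimed: group comparison consumes measured (or generated) indicator
series; predicting outcomes from schedules is out of scope.

## Problem sizes and reproducibility

Monte-Carlo checks use 25 seeds for planted-recovery and noise-
monotonicity studies, 50 seeds for null calibration and 100 for
omission power — sizes at which the binomial uncertainty of the
reported rates is a few percent. One seed governs a whole run;
stage-local seeds derive from it by hashing, and generation is
bit-reproducible for a fixed seed. Table writers print floats with 17
significant digits and readers parse in round-trip mode, so all
tabular I/O is bit-exact.
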