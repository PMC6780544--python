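# Methods

## Isotope model

Each carbon atom of a metabolite grown on media with per-carbon ¹³C
probability *p* is assumed independently labeled, so the isotopologue
envelope over the ¹³C count *k* is Binomial(*n*, *p*) for an *n*-carbon
compound.  The sample channel uses *p* = 0.05 (95:5 ¹²C:¹³C media), the
pooled internal standard *p* = 0.95; both are `LabelingScheme` fields.
Envelopes are computed as explicit `comb(n,k)·(p^k q^(n−k))` products
rather than through a library pmf: the grouped product is bitwise symmetric
under *p* → 1−*p* (the mirror identity the classifier relies on) and does
not overflow at extreme enrichments.  Natural-abundance contributions of
H/N/O/S are ignored — the media labeling dominates the carbon envelope by
two orders of magnitude, and the pairing logic only needs the envelope's
orientation and the positions of its monoisotopic ends.  One consequence
worth knowing: the light envelope's maximum sits at *k* = 0 only up to
*n* = 19; beyond that the binomial mode moves to *k* = 1 (mode =
⌊(n+1)p⌋).  Channel classification therefore keys on overall envelope
shape, not on "first member is largest".

Physical constants: Δ(¹³C−¹²C) = 1.0033548 Da; proton 1.0072765 Da;
electron mass folded into adduct deltas so charged-species arithmetic is
consistent across modules.  Units everywhere: RT in seconds, m/z in
Thomson, intensities as unitless integrated areas.

## Peak-pair detection

Detection runs per run and polarity in four stages.

**Chaining.**  Peaks sorted by m/z are greedily chained into isotopologue
ladders: a peak joins a cluster whose last member sits one ¹³C spacing
below it (charge 1 by default, z ∈ {1,2} supported) and whose apex RT is
within `rt_tol` (default 6 s).  Every m/z window in this module is applied
to the **sum** of the two centroid m/z values being compared, because the
relevant error — the difference of two noisy centroids — scales with both.
A window of `ppm_tol` = 10 on that sum is ≈ 4.7σ of the link error at 3 ppm
centroid noise, so ladders essentially never fragment; the naive
single-m/z window is only ≈ 2.4σ and breaks several links per run.

**Channel classification.**  A cluster's normalized envelope is compared
by cosine against Binomial(*n*, 0.05) front-aligned (sample channel) and,
reversed, against Binomial(*n*, 1−0.95) (IS channel) over candidate carbon
counts; the better channel wins if it reaches `min_score` (default 0.95).
Single-member clusters stay unclassified: a lone centroid carries no
envelope information, and refusing to call it is what keeps unpaired
artifact signals out of the pair search.  A caveat on flat envelopes: a
50:50 doublet reaches ≈ 0.97 against the front of a Binomial(14, 0.05)
template, so with unbounded candidate *n* the 0.95 floor alone does not
reject it; bounding the candidate range (or raising the floor) does.

**Pairing.**  Two geometries occur, and both are handled.  For small
carbon counts the light and heavy envelopes interleave into one contiguous
U-shaped ladder (their coincident members merge into single centroids at
Orbitrap resolution, which the generator reproduces).  Such clusters are
decomposed by non-negative least squares onto the two binomial bases; the
merged interpretation is accepted only when the model matches at cosine
≥ 0.99, both channels carry ≥ 10% of the fitted area, and no co-eluting
centroid continues the ladder outside the cluster.  The thresholds are
deliberately strict: a one-sided envelope tail can reach ≈ 0.97 against a
small-*n* two-channel model while giving the phantom channel only a few
percent of the area, whereas a genuine two-channel ladder fits essentially
exactly and splits its area no worse than ≈ 1:10 for any plausible
regulation effect.  For larger carbon counts the channels arrive as two
clusters separated by sub-floor members; each sample-channel cluster is
matched to co-eluting IS-channel clusters whose monoisotopic gap rounds to
some *n* ∈ [2, 60] within the (sum-scaled) ppm window.  The carbon count
always comes from the gap; the envelope fit is a consistency check (reject
when it disagrees by more than ±1).  Ties break by smallest gap residual,
then closest RT, then larger IS area.  `n_min` = 2 suppresses spurious
one-carbon gaps.  Pair areas are summed envelope areas per channel by
default (robust across carbon counts); a monoisotopic-only switch exists.

**Alignment.**  Rows are seeded from the run with most pairs; a pair joins
a row on exact carbon-count match, m/z and RT within tolerance; collisions
keep the higher pair score; row ids follow (polarity, m/z, RT) order, so
alignment is deterministic and idempotent.

Known limitation: an artifact centroid that coincidentally lands within
the chaining window of a real ladder's next position (a ≈ 3σ event per
artifact; roughly one pair per few thousand at a 0.3 artifact load) can
extend that ladder and shift the detected monoisotopic ion by one spacing.
This is indistinguishable from signal without ground truth, and trimming
tight enough to catch it would also clip genuine 2σ end members.

## Quantitation and regulation

A cell of the ratio matrix is `area_sample / area_is` when both areas are
at least the LOQ, else missing; rows whose IS fails in half or more runs
are flagged unquantifiable.  Missing cells are imputed as **half the row's
minimum observed ratio** — a conservative censoring floor; the software
this re-implements names imputation but not its algorithm, so the rule is
ours, chosen to guarantee imputed < observed.  Imputation operates on
ratios, not areas.  Fold changes are log₂ of arithmetic group means
(geometric option available).  Regulation calls: *initiated* = all control
cells imputed-from-missing while at least half the treatment cells are
observed; *terminated* mirrored; otherwise *up*/*down* when |log₂FC| ≥ 1
and p ≤ 0.001 (both configurable); else *unchanged*.  Because the IS
cancels, rescaling any row's IS areas by a constant provably leaves the
treatment-vs-control comparison unchanged; a test asserts this.

## Statistics

Unpaired two-sample t-tests are pooled-variance Student by default (Welch
as a flag), on log₂ ratios by default (ratios are right-skewed).  Raw
p-values are reported to mirror the p < 0.001 convention of the source
workflow; Benjamini–Hochberg q-values are available.  Zero-variance rows
resolve to p = 1 (equal means) or p → 0 with t = ±∞.

PCA autoscales metabolites by default (scaling unstated upstream; unit
variance is the metabolomics convention), drops constants, and fixes each
component's sign so its largest-magnitude loading is positive.

The random forest is scikit-learn's (bootstrap per tree, √m features per
split, gini); the forest readouts are computed in-package from the per-tree
out-of-bag (OOB) bookkeeping: OOB error from majority OOB votes; **MDA**
as the mean over trees of (OOB accuracy − OOB accuracy with that
metabolite's values permuted among the tree's OOB samples) — the
permutation operationalization of "decrease in performance if the
metabolite were removed"; proximity as the fraction of trees co-locating
two samples in a terminal node, embedded in 2-D by classical (Torgerson)
MDS on 1 − proximity with a deterministic sign convention.  All randomness
derives from one seed; identical seed + input reproduces every output
bitwise.  With only 8 samples, trees that never see a discriminating
feature overfit bag noise, so OOB error approaches zero only when the
informative features dominate the feature set — the single-marker sanity
check therefore surrounds the marker with constant rows, which no tree can
split on.

## Formula assignment

Formulas live in CHNOSP space (S and P default-off) with two plausibility
gates: H ≤ 2C + 2 + N and integer RDBE = C − H/2 + (N+P)/2 + 1 ≥ 0.
Enumeration fixes the carbon count from the pair gap and scans N/O(/S/P)
with early mass pruning, solving H analytically — small enough to verify
against a brute-force nested-loop oracle, which a test and the acceptance
script both do.  Matching tolerance defaults to 10 ppm; the 16-carbon
worked example needs 15 ppm (its printed ion sits ≈ 11 ppm from the
theoretical mass), so both values are exposed in config and the wider one
is the formula-annotation default.  Library identification requires carbon
count, adduct m/z, RT, and polarity to agree simultaneously.

## Synthetic studies

The generator emulates the two-arm design: 4 + 4 replicates, 95:5/5:95
labeling, carbon counts 2–36 drawn from a curated pool of ≈ 70 plausible
CHNO metabolite formulas (real amino acids, organic acids, sugars,
nucleosides, diketopiperazines, peptide- and polyketide-sized species) so
masses and valences are realistic; repeated formula draws are forced ≥ 30 s
apart in RT.  Base abundances are lognormal (meanlog 12, sdlog 1 — the
intensity distribution is a judgment call, exposed in config); category
fractions default to 10% up, 10% down, 5% on, 5% off with 4-fold effects;
replicate (biological) noise is lognormal with CV 0.10 on the sample
channel only; a common per-run injection factor (CV 0.05) scales both
channels and cancels in the ratio; m/z noise is 3 ppm Gaussian per
centroid; RT jitter 1 s; LOQ 500 area units censors peaks; unpaired
artifact singletons are appended at `artifact_rate` × n per run.  The IS
level of each metabolite is the mean of the two group means — one pooled
mixture, identical across runs — which is exactly what makes on/off
metabolites detectable.  Coincident members of the two channels are summed
into single centroids (instrument resolution).

Not modeled: chromatographic peak shape, per-isotopologue shape noise,
adducts beyond one per mode, electronic noise, batch drift.  Passing the
simulation-based checks therefore shows the *logic* of detection,
imputation, classification, and statistics is correct under the stated
noise model; it does not certify performance on real chromatograms.

## Problem sizes and determinism

The test suite and acceptance script use a 200-metabolite, 8-run study
with a 0.3 artifact load (≈ 12k centroids), 10,000-row null simulations,
50 formula-oracle cases, and 500-tree forests — sizes chosen so the whole
suite runs in about a minute on one CPU while keeping every binomial
confidence band tight enough to be meaningful.  Every stochastic component
takes an explicit seed, and reruns are byte-identical.
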