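# Methods notes

## Profile model and preprocessing

A co-fractionation experiment yields, per protein group, condition
(native or crosslinked) and biological replicate, a vector of LFQ
intensities over SEC fractions (48 crosslinked, 40 native by default;
both are configuration, not hard-coded). Missing or unparseable cells are
zeros — no imputation, since a zero is itself evidence of absence at the
depth of the experiment. Each replicate is smoothed with a 3-fraction
sliding mean and then min/max normalized to [0, 1], in that order. Edge
fractions use truncated windows of size 2 rather than padding: padding
would invent data, but the truncation does bias the outermost fraction
upward when a peak sits within a fraction of the boundary, so apexes at
the first/last fraction should be read with caution. A constant profile
normalizes to all zeros ("no signal") rather than dividing by zero.
Replicates are aggregated into a per-fraction mean and sample SD over the
supplied replicates; a replicate that was not detected still contributes
its zeros to the mean (the alternative — averaging only detected
replicates — would inflate profiles of poorly reproduced proteins).

Apparent molecular weight is calibrated by least squares on
log10(kDa) versus fraction of the standards table, with linear
extrapolation beyond the outermost standards — the standard practice for
SEC columns, whose resolving range is log-linear to good approximation.
The fit requires ≥ 2 standards with strictly decreasing MW.

## Basic clustering

Mean profiles are clustered agglomeratively with Euclidean distance and
complete linkage. The "≈ 0.95" correlation target is operationalized as:
scan the distinct merge heights from the top; return the largest height
whose clusters (size ≥ 2 only — singletons carry no pairwise correlation)
reach a grand mean intra-cluster pairwise Pearson correlation ≥ 0.95,
pooling pairs across clusters. This is deterministic and, on co-elution
data, effectively monotone: raising the height merges in lower-correlation
pairs. Tiny non-monotonic up-steps (~10⁻³) can occur when a merge adds a
few above-average pairs; the cut scan is unaffected because it takes the
first qualifying height from the top. If no height qualifies, every
profile is its own cluster. A Pearson correlation involving a
zero-variance vector is defined as 0 throughout the package (no shape
evidence), applied consistently in clustering, known-complex scoring and
pair features.

## Peak extraction

Peaks are found by a continuous wavelet transform with Ricker (Mexican
hat) kernels of widths 2–8 fractions. The CWT is computed by zero-padded
convolution; per width, strict local maxima of the response are linked
greedily across adjacent widths (gap tolerance 2 fractions), and a ridge
surviving ≥ 2 widths yields a peak. The apex is taken from the smallest
(most localized) width on the ridge and snapped to the profile's local
maximum within ± 1 fraction — broad kernels can sit a fraction off a
sharp apex, and integer apexes must be exact for the coapex feature. The
best-responding width w sets the peak window [apex − w, apex + w]
(clipped to the grid); the Ricker kernel is positive exactly on
(−w, w), so the window spans the kernel's positive support, with profile
values outside zeroed. Flat or all-zero profiles yield no peaks.

The four filters run in a fixed order: (1) amplitude < 15% of the
profile's maximum; (2) apex apparent MW ≤ 2 × monomer MW — "approximately
equal to the dimer MW" is absorbed by a configurable multiplicative slack,
default 1.0 (strict dimer cut); (3) apex in the void region (fractions
1–4); (4) among closer-than-3-fraction apexes, the larger amplitude
survives (ties to the smaller apex). The order matters: a dimer-filtered
peak cannot suppress a neighbouring genuine peak via the separation rule.
Peaks are extracted both from mean profiles (complex prediction) and per
replicate (the coapex feature); which mode a peak came from is recorded.

## Pair features

Candidate pairs are unordered pairs of filtered mean-profile peaks from
distinct groups whose apexes differ by ≤ 1 fraction. An ordered
("permutation") mode is available for count comparisons only — the six
features are symmetric, so ordered duplicates add no information.

* **coapex** — a replicate counts when both groups have, in that
  replicate, a filtered peak at exactly the same fraction (exact equality,
  not ± 1: "the same peak fraction" is exact language); the count maps to
  {3: 1, 2: 0.6, 1: 0.3, 0: 0}.
* **NCC** — maximum over integer lags of the sliding dot product of the
  two peak value vectors, divided by the larger of the two self
  cross-correlation maxima (= peak energies, attained at lag 0). Always in
  [0, 1]; 1 for identical peaks; 0 if either peak has zero energy. The
  score is invariant under a common rescaling of both peaks but not under
  rescaling one side — the normalization is by the dominant energy, which
  is what makes a small peak against a large one score low.
* **PCC** — Pearson correlation of the two value vectors over the union
  of the two windows (the support where either peak has signal).
* **Literature scores** — three pairwise score tables (a STRING-style
  0–1000 `combined_score` column is autodetected and divided by 1000).
  A pair's score per table is the maximum over the cross-product of the
  two groups' accessions (a group is detected if any member accession is,
  so its best evidence applies); absent pairs score 0.

## Interaction classifier

Positives are candidate pairs whose groups are co-members of ≥ 1
catalogued complex; the negative pool holds pairs whose groups are both
catalogued but never co-annotated. Because a random negative draw can
contain real but unannotated interactions, 100 negative sets of size
|positives| are drawn (without replacement when the pool allows; with
replacement, with a warning, otherwise), and one logistic regression is
trained per set against the same positives. Each fit standardizes the six
features and applies light L2 regularization (C = 1, lbfgs) — the model
family is fixed but these hyperparameters are this package's defaults,
chosen to guard separable fits, not a claim about any other
implementation. Mean 10-fold stratified CV AUC is recorded per
classifier; ≥ 20 positives are required so the folds are non-degenerate.
A pair's final score is the median of the 100 predicted probabilities
(even counts: midpoint convention), and edges are pairs scoring strictly
above the 0.75 cut-off. All sub-seeds derive deterministically from the
master seed.

## Complex assembly

Nodes of the interaction network are peaks, not proteins — one protein
may appear in several predicted complexes via different elution peaks;
protein-level membership deduplicates the member peaks' groups.
Candidates are grown greedily from unclustered seeds in order of
decreasing weighted degree, at each step applying the single vertex
addition or removal that most increases cohesiveness
f(V) = w_in / (w_in + w_bound + p·|V|) with penalty p = 2 (ties broken by
node id; strict improvement required, so growth terminates). Grown
candidates with squared overlap |A∩B|²/(|A||B|) ≥ 0.8 are merged; a
single-pass haircut removes vertices whose internal weight is below
haircut × (2·w_in/|V|); clusters below size s = 2 or weighted density d
are discarded. Penalty, overlap threshold and seed ordering are fixed
configuration; d and haircut are tuned by a 10 × 10 grid (0.1–1.0, step
0.1) maximizing the number of gold-positive peak pairs placed in a common
complex, ties toward smaller d then smaller haircut. The growth + merge
phase does not depend on d or haircut, so the grid search computes it
once and reapplies only the post-processing per cell — identical output
to running the full algorithm per cell, which a test verifies. An
alternative objective (counting gold peaks placed in any cluster rather
than pairs co-clustered) is exposed as a flag-level choice through the
gold-pair set supplied by the caller.

## Synthetic data generator

The generator emulates the structure — not the physics — of a
crosslinked/native SEC-MS study. Defaults are the study conditions used
throughout the tests: 48/40 fractions, 3 replicates, 30 planted
complexes, 60 singletons, replicate apex jitter SD 0.3 fractions,
Gaussian peak widths 2–4 fractions (shared within a complex, so the
noiseless within-complex correlation is exactly 1), monomer peaks with
probability 0.3 at 0.3 relative amplitude, multiplicative lognormal noise
with CV 0.2, additive noise floor 0.01, 5% whole-replicate dropout, 20%
transmembrane-flagged proteins of which 80% collapse into the void (or
vanish) natively, and literature scores Beta(8, 2) for co-complex pairs
versus Beta(1, 9) for random pairs at 90% table coverage.

Design choices worth stating:

* A complex's apex is the calibrated fraction of the **sum of member
  monomer MWs** — a denatured-but-crosslinked assembly runs at roughly the
  sum of its parts. A direct consequence: a 2-mer's assembly peak sits at
  its dimer MW and is removed by the dimer filter, so planted sizes
  default to 3–6; heterodimers are a structural blind spot of this
  pipeline's filter set, not of the generator.
* Members of one complex share a size scale (uniform ± 15% around a
  lognormal base), keeping the summed MW safely above every member's
  dimer threshold.
* Half the singletons carry a spurious high-MW "aggregate" peak placed
  above their dimer MW; these create realistic decoy candidate pairs that
  the classifier must reject on the literature features.
* The default calibration is log-linear from ~2.8 MDa (fraction 4) to
  ~21 kDa (fraction 44), the working range of a high-pore SEC column; the
  native condition compresses the same range onto 40 fractions.
* One random stream is consumed in a fixed order (global structure, then
  per protein in id order, per condition, replicate and fraction), so
  outputs are byte-identical per seed regardless of downstream iteration.

What the generator does **not** emulate: peptide-level evidence and
protein inference, retention-time chromatography, correlated (structured)
noise between co-eluting proteins, partial complexes and substoichiometric
subunits, crosslinking efficiency gradients, or shared peptides between
groups. Passing the recovery tests therefore demonstrates the pipeline's
correctness and its behaviour under idealized co-elution with realistic
marginal noise — not performance on real data, where peak shapes are
asymmetric and the gold standard is far less aligned with the truth.

A fixed 6-protein, 2-complex, 12-fraction micro example with
hand-computable peaks, filters and coapex values is generated for unit
tests; on its short grid, sub-resolution decoy shoulders deliberately
merge into the main peaks, and only the well-separated void decoy is
extracted and then filtered.

## Problem sizes and numerical conventions

Tests run the full analysis at 30 complexes × 3–6 members + 60 singletons
(≈ 200 protein groups, ≈ 2,000–2,700 candidate pairs) for five seeds, a
size at which every stage's behaviour is already asymptotic (the negative
pool dwarfs the positives, the grid search is non-trivial) while one run
takes seconds. Tolerances: greedy-growth equivalence and NCC oracle
agreement are exact to 1e-12; stochastic recovery rates are asserted at
the thresholds stated in the tests with seeds pinned. Ties anywhere
(merge heights, equal amplitudes, equal cohesiveness gains, grid cells)
break deterministically toward input order / smaller values, so reruns
are byte-identical.

## Known limitations

* Heterodimers are invisible by design (dimer filter), and monomer peaks
  are discarded even when a protein genuinely functions as a monomer-sized
  complex component.
* The tree-cut and the classifier both assume three replicates in the
  coapex mapping; other replicate counts would need a re-derived mapping.
* The haircut is single-pass; an iterated haircut can trim further on
  pathological clusters.
* Peak windows are symmetric about the apex; strongly tailed
  chromatographic peaks are truncated on the tailing side.
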