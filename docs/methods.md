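# Methods

This note documents the statistical models, defaults and numerical choices
in ykofit, and the assumptions of its synthetic-data generator. All log
intensities are log2; "FD" is the fitness-defect score (positive =
depleted).

## Feature masking and tag summarization

Each tag is printed as k = 5 replicate features. A feature is flagged as an
artifact when |x − median| > `mad_k` · 1.4826 · MAD with `mad_k` = 4; the
1.4826 factor makes the MAD estimate a normal sd, so the rule is a ~4-sigma
trim that tolerates one large hybridization artifact among five features.
When the MAD is zero, at least half the features share one exact value and
the rule degenerates; the fallback flags any feature off that majority value
beyond a 1e-9 relative tolerance (the tolerance exists purely to absorb
floating-point rounding). Flagging never reduces a tag below `min_keep` = 3
surviving features — if it would, the three features closest to the median
are kept instead. The tag value is the mean of unflagged features; tags with
fewer than three finite features on an array are treated as missing there.
Every removed feature is recorded in a mask log with a reason code.

At the simulation's default feature noise (sd 0.3), the 4-MAD rule flags
roughly 4% of clean five-feature sets somewhere in a screen; these false
flags remove one feature from an otherwise clean set and are harmless to the
summary. At noise 0 the rule flags nothing and recovers planted single- and
double-feature artifacts (shift +4) with ≥ 95% recall.

## Presence calling

Present and absent tags on a control array form a bimodal log2 intensity
distribution. A two-component 1-D Gaussian mixture is fit per control array
by EM: initialized at the 25th/75th percentiles with equal weights and the
pooled sd; converged when the relative log-likelihood change is < 1e-8
(cap 1000 iterations); component variances floored at 1e-4. Components are
relabeled so the "present" mean is the larger one. If the fitted means are
closer than 0.5 pooled sd the fit carries no information about presence —
the function warns and calls everything present rather than dichotomizing
noise.

A tag is present on an array when its posterior probability of the upper
component is strictly > 0.5; a strain is present in a collection when
**all** of its tags pass on **all** control replicates. This conservative
AND-rule reflects the purpose of the call: downstream FD scores are only
meaningful for strains reliably measurable on every control. Strains with
no tags on the array are logged separately. Roster comparison enumerates
all 2^k − 1 presence regions across k collections.

## Fitness-defect scores

Within one (collection, media) set:

1. **Normalization** — uptags and downtags separately, each array is
   shifted so its tag-class median equals the median of per-array medians.
   Defining the target as the median-of-medians makes normalization exactly
   idempotent. Limitation: median alignment assumes most tags are
   unchanged; if a large fraction of strains is truly depleted (≈ 20% in
   the shared-signature scenario) all FDs shrink by the induced median
   shift (~0.2 log2 units there). The shift is condition-constant and
   cancels exactly in signature subtraction; it is negligible below ~5%
   depleted.
2. **Best tag** — per strain, the tag with the lower coefficient of
   variation of linear (2^log2) intensity across control replicates; ties
   go to the uptag. Requires ≥ 2 control arrays.
3. **Batch correction** — optional per-strain location/scale
   standardization within batches, restoring the pooled mean and sd; a
   single batch is an identity, singleton batches get location-only
   correction plus a warning.
4. **FD** — control median minus treatment value, per treatment array;
   `fd_median` is the median across replicates. A strain depleted for g
   doublings at per-generation defect d shows FD ≈ g·d (g = 5 in all
   defaults), which the generator reproduces exactly at noise 0.

## Significance

Two methods are provided:

* `method="t"` — per-strain one-sample t-test on replicate FDs (df = n−1;
  all-zero replicates give p = 1; zero variance at nonzero mean gives the
  smallest positive float).
* `method="robust_z"` (default in the pipeline) — z = (mean FD −
  median(mean FDs)) / (1.4826 · MAD of mean FDs across strains), with a
  normal two-sided p.

The robust z is the default for a power reason: with triplicates the
per-strain t has 2 degrees of freedom, and after BH correction across
thousands of strains the required |t| is ~22 — sensitivity for FD = 1 hits
is ~30% no matter how clean the screen. The across-strain null scale is
estimated from thousands of strains (the MAD ignores the few true hits), so
an FD = 1 hit sits ~8 sd out and is detected with near-unit sensitivity at
empirical FDR ≈ 5%. The cost is the assumption that most strains are null
and replicate-to-replicate consistency is not assessed per strain; the t
method remains available when per-strain error assessment matters.

p-values are BH-adjusted per condition (q-values); the robust-z null-scale
estimate uses per-strain mean FDs, so at least 2 replicates are required.

## Shared-signature definition and subtraction

For a condition group (e.g. three nutrient-dropout media), the profile is
each strain's median FD across the group. Members are strains with FD ≥
`threshold` (default 1.0) in **all** group conditions (`rule="any"` is
available); strains with an undefined FD in any group condition cannot be
members. Corrected FD = FD − profile; strains without a profile pass
through unchanged and are flagged. Cross-collection concordance
(`profile_correlation`) is the per-condition Pearson r over strains with FD
> 1 in at least one shared condition in either table (≥ 3 such strains,
else NaN).

## Bar-seq quantification

Reads are trimmed to 50 bases. The 20-base barcode is located by finding
the uptag/downtag primer anchor; the following window is matched against
the library first by exact hash lookup, then by vectorized Hamming
distance. A read without a clean anchor (e.g. errors in the primer) falls
back to scanning every offset. A hit counts only if the best distance is ≤
`max_mismatch` (default 2) **and** beats the runner-up by at least one
mismatch — equidistant reads are "ambiguous", not assigned. Per-sample
accounting satisfies matched + ambiguous + unmatched = total.

Tags with < 50 counts in any control replicate are removed (too noisy to
normalize against); surviving uptag and downtag counts are summed per
strain. Depth is corrected by DESeq-style median-of-ratios size factors
(strains with a zero count anywhere are excluded from the geometric-mean
reference). FD = log2(normalized control median + 0.5) − log2(normalized
treatment + 0.5); the 0.5 pseudo-count bounds the score for zero counts and
perturbs log2 ratios by < 0.01 at counts ≥ 100.

## Enrichment

Hypergeometric right tail, P(X ≥ k) via the survival function, for each
term with 5–300 genes inside the analysis universe; Holm step-down
adjustment; a term passes at adjusted p ≤ 5e-4. Query genes outside the
universe are dropped with a warning. The implementation matches exhaustive
combinatorial enumeration to < 1e-12 for all universes up to N = 15.

## Synthetic-data generator

Per-tag log2 baselines are drawn once — N(10, 0.8) for present tags,
N(6.5, 0.7) for absent tags, > 3 pooled sd of separation, the regime the
mixture model targets — and held fixed across arrays, so a noiseless screen
is exactly reproducible from the truth bundle. A treatment array's expected
value is baseline − g·d (+ optional batch offset); each tag renders as 5
features with independent N(0, noise_sd) noise (default 0.3, i.e. tag-level
sd 0.3/√5 ≈ 0.13); artifacts add +4 to single features at a configurable
rate. Dropouts are a deterministic fixed fraction (exact counts) of a
seeded shuffle. Per-condition planted hits are disjoint from each other and
from the shared signature, so "condition-specific" is true by construction.
Bar-seq reads are anchor + barcode + suffix padded to 100 bases; counts per
sample are one multinomial draw of `depth` reads with abundances ∝ 2^(−g·d)
(the returned expected matrix is that exact draw); per-base substitution
errors are applied uniformly; read names encode the source tag so matcher
recovery is checkable read-for-read. FASTQ output is byte-deterministic per
seed.

Realism limits: intensities have no spatial structure, saturation, dye or
sequence-composition effects; noise is homoscedastic and Gaussian; Bar-seq
errors are substitution-only (no indels, no quality correlation); barcode
cross-hybridization is absent; abundances ignore bottlenecks and drift, so
replicate cultures differ only by measurement noise. These are deliberate:
the generator validates the analysis chain against planted truth rather
than emulating instrument physics.

## Problem sizes and runtime

The validation scenarios run 4000-strain screens for mixture/FD recovery
(≈ 2 s), 300–500 strains for signature and cross-platform checks, and
20000–60000 reads per Bar-seq sample (≈ 6 s including 1%-error matching);
`scripts/acceptance.py` completes in ~10 s, the full test suite in ~15 s.
The matcher processes error-free reads via hash lookup (~10^6 reads/min
conservatively) and falls back to vectorized Hamming search only for
imperfect reads.

## Limitations

* The robust-z null assumes ≫ 50% null strains per condition; screens where
  most strains respond need the t method or an external null.
* Median normalization biases FD downward in heavily-depleted screens (see
  above).
* Presence calling needs ≥ 20 finite tag values per control array and a
  genuinely bimodal distribution; arrays measuring a pool with no absent
  strains are handled by the no-separation fallback (all present), not by
  a one-component model selection.
* The 50-count Bar-seq filter is applied per control replicate; shallowly
  sequenced controls can remove most of the library — depth should target
  ≥ 100 reads per tag in controls.
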