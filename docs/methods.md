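# Methods

This note records the statistical model, numerical conventions and default
parameters implemented by `mirlens`, together with the scope of the synthetic
generator and known limitations. Every empirical statement here is backed by
a test in `tests/` or by `scripts/acceptance.py`; nothing else is claimed.

## Differential miRNA expression

Intensity matrices (features × samples, two groups `case`/`control`) are
quantile normalized: each column is replaced by the across-column means of the
order statistics, assigned by average rank so ties are preserved; identical
columns are a fixed point. Group differences are then tested per feature with
Welch's unequal-variance *t*-test on log2 intensities. Degenerate features
with zero within-group variance use the convention p = 1 for equal means and
p = 0 otherwise. Benjamini–Hochberg q-values are reported across all tested
features but calls use the raw p-value, matching the reporting convention of
small-sample microarray screens: a feature is **up**/**down** when
|FC| ≥ 1.2 and p ≤ 0.05, else **unchanged**.

Fold changes are signed ratios of group means: +a/b if a ≥ b, else −(b/a), so
|FC| ≥ 1 always and swapping the groups flips the sign. For correlation the
signed FC is mapped to a symmetric signed log2 scale
(sign(FC)·log2|FC|).

Calibration: the test's type-I error is within 3 standard errors of the
nominal 0.05 on null simulations at 10 samples per group. At 3 per group the
Welch approximation is conservative (measured rejection rate ≈ 0.036 at the
0.05 level); the acceptance suite therefore asserts nominal calibration at
n = 10 and one-sided non-anticonservativeness at n = 3. This is an inherent
small-sample property of the unequal-variance *t*-test, not an implementation
artifact. An optional variance-shrinkage weight (`shrink` in
`differential_test`) moderates per-feature variances toward the global mean;
it is off by default.

## Inverse pairing and seed sites

Target predictions are score-filtered at ≥ 50 (inclusive) on a 0–100
confidence scale. Pairs retain target-map edges whose miRNA and mRNA carry
opposite differential calls; identifiers match case-insensitively, duplicate
edges collapse, and differentially expressed miRNAs absent from the map are
dropped with a logged warning. Pair counts are reported both as pairs and as
unique target mRNAs (a shared target counts once).

Seed sites follow the canonical hierarchy: the seed is miRNA nucleotides 2–7
(5'→3'); a UTR window whose sequence is the reverse complement of the seed is
a 6mer, strengthened to 7mer-m8 by a Watson–Crick match opposite miRNA
position 8, to 7mer-A1 by an adenosine opposite position 1, and to 8mer by
both. Pairing is strict Watson–Crick by default; G:U wobble can be enabled.
Site calls are verified in the tests against an independent brute-force
reverse-complement scan.

## Prioritization

Four evidence flags per pair: `de_p4`, `de_p30` (mRNA opposite its miRNA at
each stage) and `enriched_p4`, `enriched_p30` (present in the stage's
lens-enrichment table with expression intensity ≥ 100, inclusive, and
enrichment fold change > 1, strict). Default tier rules, applied first-match
top → high → promising:

```
top:        de_p4 AND de_p30 AND enriched_p4 AND enriched_p30
high:       de_p4 AND de_p30 AND (enriched_p4 OR enriched_p30)
promising:  de_p4 AND (enriched_p4 OR enriched_p30)
```

Rules are configurable via a small boolean grammar (AND/OR, parentheses) over
the four flags. Tier counts per miRNA-direction group are unique-mRNA counts
at the best tier each gene reaches. The global inverse-coupling statistic is
the Pearson correlation of paired signed-log2 fold changes (ranked pairs when
at least three exist, otherwise all pairs), with the two-sided p from the
*t* transform of *r*.

## Gene-set enrichment and clustering

Per-term significance is the upper-tail hypergeometric probability
P(X ≥ k) for overlap k between the query and a term of size n in a universe
of size M with N query genes, computed as `hypergeom.sf(k−1, M, n, N)` and
validated in the tests against exhaustive enumeration for every instance with
M ≤ 12. BH q-values are computed across all tested terms. Terms are grouped
by member-gene Jaccard similarity ≥ 0.5 with single linkage (connected
components); a cluster's enrichment score is −log10 of the geometric mean of
its member p-values, and reported "top" clusters need score > 1.0 and at
least one term at p ≤ 0.05.

## Regulatory network and concordance

Edge signs are expressed in the wild-type frame: a miRNA elevated in the
knockout implies the regulator normally **represses** it; a reduced miRNA
implies normal **activation**; miRNA → mRNA edges are always repressive.
Every differentially expressed miRNA gets a regulator edge and every pair one
miRNA→mRNA edge, so the edge count is n(DE miRNAs) + n(pairs). Exports are
SIF and GraphML.

Concordance asks, per network target, whether independent perturbation
datasets misexpress it (|FC| ≥ 1.2, p ≤ 0.05) in the same direction as the
reference knockout; gain-of-function datasets have their observed direction
inverted into the loss-of-function frame first. Targets absent from every
table are excluded from the denominator; the headline fraction conditions on
misexpressed targets (≥ 1 same-direction dataset among them).

## qPCR

ΔCt is the target Ct minus the arithmetic mean of the reference-assay Ct
values of the same (group, biological replicate) stratum — equivalent to the
geometric mean of the references' linear quantities. ΔΔCt is the difference
of group mean ΔCt (case − control) and relative expression is 2^−ΔΔCt.
Significance comes from the two-level nested ANOVA
ΔCt ~ group + bio_rep(group), with the group F statistic tested against the
biological-replicate mean square, so technical replicates only stabilize the
replicate means. The sums of squares reproduce a brute-force decomposition
(SS_total = SS_group + SS_bio + SS_resid on every input) and the null group
p-value is uniform over 500 simulated plates (KS test, seeded).

## Synthetic generator

`mirlens.synthetic.generate` writes a complete, self-consistent input bundle
with ground-truth tables. Model and defaults:

- **miRNA matrix**: 700 features, 3 vs 3 samples. Baselines follow a
  log10-exponential tail (most features low-intensity, a few in the
  thousands); multiplicative log-normal noise with sigma = 0.1; 14 planted
  up- and 8 down-regulated miRNAs with per-feature effect magnitudes between
  1.2 and 2.2, floored at baseline intensity 5 so they are detected.
- **Target map**: true targets drawn per planted miRNA at density 0.01 with
  scores in [50, 100]; decoy edges (30% of the map) score below 50; three
  planted miRNAs are deliberately absent from the map to exercise the
  drop-with-warning path.
- **mRNA tables**: planted targets move opposite their miRNA at the early
  stage with coupled magnitude (plus jitter, floored at 1.2); 60% stay
  differential at the later stage; background genes are unchanged except a 2%
  false-positive rate, which never touches planted genes so the recorded
  expected tiers remain exact. The later-stage table covers 90% of genes but
  always keeps planted later-stage-differential genes.
- **Enrichment tables**: 50% of planted targets are enriched per stage;
  non-enriched planted genes sometimes appear with a failing criterion (low
  intensity or depletion) to exercise both filter clauses.
- **Perturbation tables**: 7 datasets (one gain-of-function). Each target
  carries a per-target concordance coin at agreement = 0.8: all of its
  significant calls agree with the reference direction, or all disagree, so
  the "≥ 1 same-direction" summary estimates the coin directly without the
  upward bias an independent per-call coin would cause.
- **qPCR plates**: Ct = assay baseline + planted ΔΔCt (case, targets only) +
  replicate-wide offset (cancels in ΔCt) + per-assay biological effect
  (sd 0.15) + technical noise (sd 0.1), 3 biological × 3 technical
  replicates.
- **Determinism**: all randomness flows from one seed through independent
  `SeedSequence` spawn streams; identical designs produce bit-identical
  files.

The generator's defaults are study conditions, not tuning knobs. The
end-to-end acceptance run plants all effects at 2.0 because magnitudes of
1.2–1.3 are genuinely underpowered at 3 vs 3 with sigma 0.1; recovery there
would measure noise rather than correctness.

## Numerical choices

- Hypergeometric p-values are clamped to (ulp(0), 1] so downstream −log10
  scores are always finite.
- Expression matrices round-trip bit-identically through TSV (floats written
  with `repr`).
- BH q-values come from `statsmodels.stats.multitest.multipletests`;
  hypergeometric tails from `scipy.stats.hypergeom`; connected components
  from `networkx`.
- The quantile-normalization reference distribution is the mean of column
  order statistics; tied values receive the average of their rank positions.

## Limitations

- No probe-level preprocessing (background correction, median polish): the
  pipeline starts from summarized intensities.
- The DE test is a per-feature Welch *t*; no moderated/empirical-Bayes
  variance sharing beyond the optional shrinkage weight, and at 3 replicates
  per group it is conservative (see calibration above).
- Seed-site scanning covers canonical 6/7/8mer sites only — no 3' supplementary
  pairing, no site-context scoring.
- qPCR assumes perfect amplification efficiency (no Pfaffl correction) and
  performs no melt-curve QC.
- The synthetic generator writes already-summarized mRNA/perturbation tables
  rather than simulating those arrays from raw intensities.
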