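# Methods

## Model

A TO-GCN stratifies transcription factors by activation time using
only co-expression. For one condition with timepoints t = 1..T
(T ≥ 5), each gene's profile is the vector of per-timepoint expression
values (replicate means by default). The analysis assumes that TFs
acting at similar times have strongly positively correlated profiles,
that correlation decays with temporal distance, and that the earliest
TF is known or identifiable. Under these assumptions the thresholded
correlation graph is approximately a "chain of cliques" along time, and
breadth-first search from the earliest TF recovers temporal order as
graph distance: level(v) = 1 + d(seed, v). Levels are relative, not
calendar time; a different seed shifts all levels by approximately a
constant, which the comparison stage's threshold absorbs.

Only positive correlation defines co-expression. Cutoffs are strict
(PCC > c), either fixed per condition or calibrated as the (1 − α)
quantile of a permutation null built by independently shuffling each
gene's profile across timepoints and correlating random gene pairs —
this preserves each gene's marginal distribution while destroying
temporal coupling. With T points the null is coarse (T! arrangements
per gene), which is why the sample is taken over many random pairs.

The two-condition comparison assigns each TF d = level_A − level_B and
calls it A-specific (d ≥ t), B-specific (d ≤ −t) or common
(|d| ≤ t − 1), with t = 3 by default. TFs leveled in only one network
are reported as unassigned rather than forced into a class. Level gene
sets attach any expressed gene whose PCC with at least one TF of a
level exceeds the same cutoff; because neighboring levels correlate,
membership overlaps between adjacent levels, and that overlap is
reported. Over-representation uses the one-sided Fisher exact test
(equivalently the hypergeometric upper tail) with BH FDR across terms
within each level; a global family is available but off by default,
since each level's gene set is interpreted as its own hypothesis
family. Depletion is not tested.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| PCC cutoff | 0.92 / 0.90 per condition (fixed mode) | edge threshold; calibrated mode uses α = 0.05 with ≥ 10⁴ permutations |
| t | 3 | level-difference threshold for condition-specific calls |
| TPM filter | ≥ 1 in ≥ 1 library (inclusive) | definition of "expressed"; scope global or per-condition |
| UQ reference | mean of per-sample nonzero 75th percentiles | symmetric choice; no library is privileged |
| replicate_mode | mean | PCC over per-timepoint replicate means; `all` correlates across every replicate column instead |
| enrichment α | 0.05 (q) | BH-adjusted significance per level |

z-scores use the population (n-denominator) standard deviation so
heatmap values are exactly reproducible from the stated formula.
Quantiles use linear interpolation. Zero-variance profiles are excluded
from correlation with a warning naming them. The seed-suggestion score,
z(t₁) − max_{t>1} z(t), is a documented heuristic: it ranks genes
already at or past their peak at the first timepoint highest. It is
reliable when the earliest wave peaks near the start of the course and
ambiguous when all waves peak mid-course; an explicit seed always
overrides it, and a mis-chosen seed one level deep produces a constant
±1 level offset that the comparison threshold tolerates.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the method assumes, so that
recovery is a meaningful test of the inference rather than of the
simulator:

- **Activation waves.** Gene g at timepoint t has mean
  A·exp(−(t − c_g)² / 2w²) with amplitude A = 100 (TPM scale) and
  width w = 0.8 timepoint units. Each of the n_levels = 11 level
  groups shares a center; consecutive centers are spaced by a value
  solved at generation time (below). Condition defaults: 5 timepoints,
  3 replicates, 5 TFs per level (level 1 carries a single TF), 20
  co-expressed non-TF genes per level, 2,000 time-constant background
  genes with log-uniform baselines spanning 0.5–500.
- **Noise.** Each measurement adds Normal(0, (noise_sd·A)²) noise,
  clipped at zero to respect nonnegativity; noise_sd defaults to 0.1.
  Every sample also receives a log-normal library-size factor
  (sd 0.15), the between-sample artifact upper-quartile normalization
  exists to remove; the constant background population carries the
  quartile, as the non-temporal majority of genes does in real data.
- **Condition shifts.** 20 TF waves move by 4 level spacings between
  conditions, half earlier and half later, so both condition-specific
  classes are populated as in a real dual-condition comparison. Shifted
  TFs never land on level 1, and every level keeps at least two
  unshifted TFs so level identity is never carried by a single gene.
- **Spacing solver.** A spacing is feasible when, at zero noise on the
  sampled grid, every consecutive-level PCC exceeds the cutoff and
  every ≥ 2-apart PCC falls below it, each by a 0.015 guard that also
  absorbs residual normalization distortion. Noise attenuates observed
  correlations by roughly R = s²/(s² + σ²) per gene (σ the
  replicate-mean noise sd); the dominant failure mode of BFS leveling
  is a ≥ 2-apart pair fluctuating above the cutoff, which deletes a
  rung of the ladder, while an occasional sub-cutoff consecutive pair
  is rescued by the other pairs bridging the same levels. The solver
  therefore picks the feasible spacing minimizing the skip correlation
  subject to the attenuated consecutive correlation staying above the
  cutoff, falling back to best-effort when the requested noise makes
  that impossible (so degradation studies still get data). With the
  defaults this yields ≈ 0.235 timepoint units at noise 0.1 and
  ≈ 0.265 at zero noise.
- **Unique seed.** Level 1 holds one TF. Under level = distance + 1,
  any co-expressed peer of the seed sits at distance 1 and lands one
  level deep, so exact recovery requires the earliest gene to be
  unique — which is also what "the first upregulated TF" means. Its
  wave sits at a sub-spacing offset just before level 2, making the
  root link the strongest in the chain (the entire leveling hangs on
  it, and level 1 has no pair multiplicity to fall back on).
- **Annotations.** Planted terms cover one level's co-expressed genes
  plus random background padding (defaults: levels 2, 6 and 10, 30
  genes each); five random 50-gene null terms accompany them.

Not emulated: count overdispersion and mean–variance coupling,
multimodal or non-Gaussian temporal shapes, correlated noise between
genes, batch structure beyond a scalar library factor, unequal
replicate numbers, and gene-length effects (the TPM computation is
tested separately on random count matrices). Passing tests therefore
show that the implementation recovers the structure the method
assumes; they do not show that real feather transcriptomes satisfy
those assumptions.

## Recovery scoring

Level recovery reports Spearman correlation between inferred and
planted levels over genes leveled in both, plus the exact-match
fraction; condition B is scored against its own planted levels, since
shifted TFs genuinely sit elsewhere there. Comparison recovery reports
sensitivity and specificity of the specific-vs-common call among TFs
classified in both networks — the conditional definition standard for
diagnostics — together with a detection rate that counts unassigned
shifted TFs as misses and the unassigned count itself, which is always
reported. The distinction matters because a single broken
consecutive-level link disconnects everything downstream of it: the
conditional metrics measure the d-classification, the detection rate
measures the whole chain.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default design
(11 levels, 51 TFs, 220 co-expressed genes, 2,000 background genes,
two conditions × 5 timepoints × 3 replicates), ten simulation
replicates for the noise studies, 200 random graphs for the BFS
oracle, all 46,375 2×2 tables with N ≤ 30 for the Fisher identity,
10⁵ permutations (vs a 10⁶-draw oracle) for cutoff calibration, 300
null terms for the type-I check and 1,000 random matrices for the
normalization identities; unit tests use a 5-level miniature with
explicit seeds and no library-size factors, isolating chain recovery
from quantile-estimation noise on small gene universes. Edge-case
conventions: seed-suggestion ties break lexicographically; the
comparison table uses nullable integers with explicit NA for absent
levels; a calibrated cutoff may be nonpositive in degenerate settings
(α → 1) but building a graph from it is refused; manifests hash every
artifact with SHA-256, and all randomness flows from one seed.

## Known limitations

BFS leveling is brittle by construction: one shortcut edge compresses
the level ladder and one missing rung truncates it, and with only five
timepoints the sampling variance of a correlation coefficient is
large, so the method's resolution degrades quickly beyond noise_sd
≈ 0.15 at the default design. The spacing solver mitigates but cannot
remove this. Level numbers are comparable between networks only up to
the seed choice. The permutation null for cutoff calibration is one
defensible choice among several; with five timepoints its resolution
is limited and the fixed cutoffs remain the recommended default for
small T.
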