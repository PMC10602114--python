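# togcn — time-ordered gene co-expression network analysis

`togcn` orders transcription-factor (TF) activity in developmental
time-course transcriptomes, such as the embryonic-to-juvenile feather
transition in birds, where two conditions (natal down vs juvenile
feather) are each sampled at five or more developmental timepoints.
Bulk RNA-seq of whole tissue mixes many cell populations, so instead of
clustering expression directly, the time-ordered gene co-expression
network (TO-GCN) approach stratifies TFs by *when* they act:

1. **Co-expression graph.** Pearson correlation (PCC) is computed for
   every TF–TF pair across the condition's timepoint profiles. An edge
   joins pairs with PCC above a cutoff calibrated to p < 0.05 — either
   fixed (the shipped defaults are 0.92 and 0.90 for the two
   conditions) or estimated from a permutation null that shuffles each
   gene's profile across timepoints.
2. **BFS leveling.** Breadth-first search from a seed TF — the first
   upregulated gene, a user choice supported by an earliness heuristic —
   assigns each reachable TF a level: `level(v) = 1 + d(seed, v)`,
   interpreted as relative activation time. Unreachable TFs are
   reported, never silently dropped.
3. **Dual-network comparison.** With TO-GCNs for both conditions, each
   TF gets `d = level_A − level_B`. TFs with `d ≥ 3` are A-specific,
   `d ≤ −3` B-specific, and `|d| ≤ 2` common to both programs.
4. **Level gene sets and enrichment.** Non-TF genes attach to a level
   when they exceed the same PCC cutoff with any of its TFs; each
   level's gene set is tested for term over-representation with a
   one-sided Fisher exact test against all expressed genes,
   Benjamini–Hochberg FDR within each level (q < 0.05).

Preprocessing follows standard bulk practice: counts → TPM, keep genes
with TPM ≥ 1 in at least one library, upper-quartile normalization
across libraries, replicate means per timepoint.

Because suitable public time courses are not bundled, the package
ships a first-class simulator that plants Gaussian activation waves in
`n` level groups, shifts a chosen subset of TF waves between
conditions, plants annotation terms on chosen levels, and writes the
ground truth beside the data — every stage of the pipeline is
validated end-to-end against planted truth.

## Worked example

```python
import pandas as pd
from togcn import ExpressionMatrix, SimConfig, generate
from togcn.preprocess import (condition_mean_profiles, filter_expressed,
                              upper_quartile_normalize)
from togcn.network import (CoexpressionCutoff, assign_levels_bfs, build_gcn,
                           pairwise_pcc, suggest_seed)
from togcn.compare import align_networks, classify_tfs, summarize_classes
from togcn.synthetic import evaluate_recovery

sim = generate(SimConfig(noise_sd=0.1, rng_seed=1))   # two conditions, 11 levels
expr = ExpressionMatrix(pd.concat([sim.expr_a.values, sim.expr_b.values], axis=1), "TPM")
mat = upper_quartile_normalize(filter_expressed(expr))
print(f"{len(mat.genes)} of {len(expr.genes)} genes expressed (TPM >= 1)")

networks = {}
for cond in ("embryonic", "juvenile"):
    prof = condition_mean_profiles(mat, sim.samples, cond).values
    tf_prof = prof.loc[[g for g in prof.index if g in sim.annotation.tf_set]]
    gcn = build_gcn(pairwise_pcc(tf_prof), CoexpressionCutoff.fixed(0.92))
    networks[cond] = assign_levels_bfs(gcn, suggest_seed(tf_prof)[0])
    print(f"{cond}: {networks[cond].n_levels} levels, "
          f"{gcn.graph.number_of_edges()} edges")

comp = classify_tfs(align_networks(networks["embryonic"], networks["juvenile"]), t=3)
print(summarize_classes(comp)["counts"])
print(evaluate_recovery(comp, sim.truth))
```

Output:

```
2211 of 2271 genes expressed (TPM >= 1)
embryonic: 11 levels, 262 edges
juvenile: 11 levels, 263 edges
{'A-specific': 10, 'B-specific': 10, 'common': 31, 'unassigned': 0}
{'kind': 'comparison', 'n_tfs': 51, 'n_shifted': 20, 'n_unassigned': 0,
 'sensitivity': 1.0, 'specificity': 1.0, 'detection_rate': 1.0}
```

The simulator planted 20 TFs whose activation wave moves by four levels
between conditions (ten in each direction); at this noise level the
comparison recovers all of them as condition-specific and calls every
unshifted TF common.

The same pipeline is available from the shell:

```
togcn simulate --seed 1 --out data/
togcn run-all --config run.yaml          # normalize -> build x2 -> compare -> enrich
togcn build --expr norm.tsv --samples samples.tsv --tfs tfs.txt \
            --condition juvenile --seed-gene MYOD1 --fixed-cutoff 0.9 --out juv
togcn evaluate --levels juv.levels.tsv --truth data/truth.json
```

`run-all` writes a manifest JSON with a SHA-256 hash per artifact;
identical config and seed reproduce identical hashes.

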