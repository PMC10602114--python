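"""Level gene sets and per-level functional over-representation.

Non-TF genes are attached to a TO-GCN level when their profile's PCC
with at least one TF at that level exceeds the same co-expression
cutoff used to build the network; because neighboring levels are
themselves correlated, a gene may belong to several levels. Each
level's gene set is then tested for term over-representation with a
one-sided Fisher exact test against the background of all expressed
genes, with Benjamini-Hochberg FDR control across terms within each
level (a global family is available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneAnnotation
from .errors import ConfigError, ValidationError
from .network import TOGCN, CoexpressionCutoff, _as_frame

ENRICH_COLUMNS = [
    "level", "term_id", "k", "n", "K", "N", "odds_ratio", "p_value", "q_value",
]


@dataclass
class LevelGeneSets:
    """Gene sets attached to each TO-GCN level by co-expression."""

    sets: dict[int, set[str]]
    cutoff: CoexpressionCutoff
    seed_gene: str | None = None

    def overlap_counts(self) -> dict[tuple[int, int], int]:
        """Size of pairwise overlaps between level sets (reported, not an error)."""
        levels = sorted(self.sets)
        out = {}
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                shared = len(self.sets[a] & self.sets[b])
                if shared:
                    out[(a, b)] = shared
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lv, "gene_id": g}
            for lv in sorted(self.sets)
            for g in sorted(self.sets[lv])
        ]
        return pd.DataFrame(rows, columns=["level", "gene_id"])


def assign_level_genes(
    togcn: TOGCN,
    profiles,
    candidate_genes,
    cutoff: CoexpressionCutoff | None = None,
) -> LevelGeneSets:
    """Attach candidate genes to levels by PCC against each level's TFs.

    A gene joins level k iff its PCC with some TF at level k strictly
    exceeds the cutoff. Candidates may overlap the TF set; TFs keep
    their BFS level regardless. Zero-variance candidates attach nowhere.
    """
    if cutoff is None:
        cutoff = togcn.gcn.cutoff
    if cutoff is None:
        raise ConfigError("assign_level_genes requires a co-expression cutoff")
    df = _as_frame(profiles)
    missing = [g for g in togcn.level_of if g not in df.index]
    if missing:
        raise ValidationError(f"profiles lack leveled TF {missing[0]!r}")
    cand = [g for g in df.index if g in set(candidate_genes)]
    tf_genes = sorted(togcn.level_of)
    cvals = df.loc[cand].to_numpy(dtype=float)
    tvals = df.loc[tf_genes].to_numpy(dtype=float)

    def _std(x):
        x = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            return x / norm

    corr = _std(cvals) @ _std(tvals).T  # candidates x TFs
    sets: dict[int, set[str]] = {lv: set() for lv in sorted(set(togcn.level_of.values()))}
    tf_level = np.array([togcn.level_of[g] for g in tf_genes])
    above = corr > cutoff.pcc_threshold
    for i, gene in enumerate(cand):
        hit_levels = np.unique(tf_level[above[i]])
        for lv in hit_levels:
            sets[int(lv)].add(gene)
    return LevelGeneSets(sets=sets, cutoff=cutoff, seed_gene=togcn.seed_gene)


def fisher_greater_p(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """One-sided (over-representation) Fisher exact p and odds ratio.

    Table: [[k, K - k], [n - k, N - K - (n - k)]] for k hits among a
    level set of size n, a term of size K, background N.
    """
    table = [[k, K - k], [n - k, N - K - (n - k)]]
    if min(min(row) for row in table) < 0:
        raise ValidationError(f"inconsistent 2x2 margins: k={k} K={K} n={n} N={N}")
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(p), float(odds)


def fisher_enrich(
    level_sets: LevelGeneSets,
    annotation: GeneAnnotation,
    background,
    alpha: float = 0.05,
    family: str = "per-level",
) -> pd.DataFrame:
    """Per-(level, term) over-representation with BH FDR control.

    ``family`` chooses the BH family: "per-level" (default) adjusts
    across terms within each level; "global" adjusts across all
    (level, term) pairs jointly. Rows are sorted by q then p.
    """
    background = set(background)
    if not background:
        raise ValidationError("empty background gene set")
    if family not in ("per-level", "global"):
        raise ConfigError(f"unknown FDR family {family!r}")
    N = len(background)
    rows = []
    for lv in sorted(level_sets.sets):
        level_genes = level_sets.sets[lv] & background
        n = len(level_genes)
        for term in sorted(annotation.term_sets):
            term_genes = annotation.term_sets[term] & background
            K = len(term_genes)
            if K == 0:
                continue
            k = len(level_genes & term_genes)
            p, odds = fisher_greater_p(k, K, n, N)
            rows.append(
                {"level": lv, "term_id": term, "k": k, "n": n, "K": K, "N": N,
                 "odds_ratio": odds, "p_value": p}
            )
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    if df.empty:
        df["q_value"] = []
        return df
    df["q_value"] = np.nan
    if family == "global":
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        for lv, idx in df.groupby("level").groups.items():
            df.loc[idx, "q_value"] = multipletests(df.loc[idx, "p_value"], method="fdr_bh")[1]
    df["significant"] = df["q_value"] < alpha
    return df.sort_values(
        ["q_value", "p_value", "level", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
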