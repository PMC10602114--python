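"""Time-ordered gene co-expression network (TO-GCN) construction.

A co-expression graph is built over transcription-factor (TF) genes from
pairwise Pearson correlation of their temporal expression profiles: an
edge joins two TFs whose PCC exceeds a significance-calibrated cutoff.
Breadth-first search from a seed TF — chosen as the first-upregulated
gene — then stratifies the connected component into levels; a node's
level (seed = 1) is one plus its shortest-path distance from the seed
and is read as relative activation time.

The cutoff can be fixed (e.g. 0.92 at p < 0.05 for a 5-timepoint
course) or calibrated from an empirical null built by permuting each
gene's profile across timepoints, which destroys temporal coupling
while preserving each gene's marginal distribution.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .errors import ConfigError, ValidationError
from .preprocess import zscore_rows


def _as_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, ExpressionMatrix):
        return profiles.values
    return pd.DataFrame(profiles)


def pairwise_pcc(profiles, genes=None) -> pd.DataFrame:
    """Pearson correlation matrix of gene expression profiles.

    Zero-variance genes have no defined correlation; they are excluded
    from the result with a warning listing them.
    """
    df = _as_frame(profiles)
    if genes is not None:
        missing = [g for g in genes if g not in df.index]
        if missing:
            raise ValidationError(f"gene {missing[0]!r} not present in profiles")
        df = df.loc[[g for g in df.index if g in set(genes)]]
    if df.shape[1] < 3:
        raise ValidationError(
            f"PCC needs >= 3 profile columns, got {df.shape[1]}"
        )
    vals = df.to_numpy(dtype=float)
    flat = vals.std(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"pairwise_pcc excluded zero-variance gene(s): {sorted(df.index[flat])}",
            stacklevel=2,
        )
        df = df.loc[~flat]
        vals = vals[~flat]
    corr = np.atleast_2d(np.corrcoef(vals))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=df.index, columns=df.index)


@dataclass
class CoexpressionCutoff:
    """A PCC edge threshold, either fixed or calibrated from a permutation null."""

    pcc_threshold: float
    alpha: float | None = None
    method: str = "fixed"  # "fixed" | "empirical-permutation"
    n_permutations: int = 0
    rng_seed: int | None = None
    null_sample: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        # a calibrated threshold may be nonpositive in degenerate settings
        # (alpha -> 1); building a graph from it is refused separately,
        # since only positive correlation defines co-expression
        if not (-1 <= self.pcc_threshold <= 1):
            raise ConfigError(
                f"pcc_threshold must be in [-1, 1], got {self.pcc_threshold}"
            )
        if self.method not in ("fixed", "empirical-permutation"):
            raise ConfigError(f"unknown cutoff method {self.method!r}")

    @classmethod
    def fixed(cls, threshold: float) -> "CoexpressionCutoff":
        return cls(pcc_threshold=float(threshold), method="fixed")

    def to_dict(self) -> dict:
        return {
            "pcc_threshold": self.pcc_threshold,
            "alpha": self.alpha,
            "method": self.method,
            "n_permutations": self.n_permutations,
            "rng_seed": self.rng_seed,
        }


def _rowwise_pcc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=1) / denom


def determine_cutoff(
    profiles,
    genes=None,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> CoexpressionCutoff:
    """Calibrate the co-expression cutoff from a permutation null.

    Each null draw picks two distinct genes, independently permutes each
    profile across timepoints, and records their PCC; the threshold is
    the (1 - alpha) empirical quantile of the null sample.
    """
    if not (0 < alpha <= 1):
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    df = _as_frame(profiles)
    if genes is not None:
        df = df.loc[[g for g in df.index if g in set(genes)]]
    df = df.loc[df.std(axis=1) > 0]
    n_genes = len(df)
    if n_genes < 2:
        raise ValidationError(
            f"cutoff calibration needs >= 2 variable genes, got {n_genes}"
        )
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng_seed)
    vals = df.to_numpy(dtype=float)
    ia = rng.integers(0, n_genes, size=n_permutations)
    ib = rng.integers(0, n_genes - 1, size=n_permutations)
    ib[ib >= ia] += 1  # distinct pair, uniform over off-diagonal
    a = rng.permuted(vals[ia], axis=1)
    b = rng.permuted(vals[ib], axis=1)
    null = _rowwise_pcc(a, b)
    null = null[np.isfinite(null)]
    if alpha == 1.0:
        warnings.warn("alpha = 1.0 gives the degenerate minimum-null cutoff", stacklevel=2)
        threshold = float(null.min())
    else:
        threshold = float(np.quantile(null, 1.0 - alpha))
    return CoexpressionCutoff(
        pcc_threshold=threshold,
        alpha=alpha,
        method="empirical-permutation",
        n_permutations=n_permutations,
        rng_seed=rng_seed,
        null_sample=null,
    )


@dataclass
class GCN:
    """Undirected co-expression graph over TF genes.

    Edges carry the PCC as ``weight`` and exist only where PCC strictly
    exceeds the cutoff. Isolated nodes are retained.
    """

    graph: nx.Graph
    cutoff: CoexpressionCutoff

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def build_gcn(pcc_matrix: pd.DataFrame, cutoff: CoexpressionCutoff) -> GCN:
    """Threshold a PCC matrix into a co-expression graph.

    Only positive correlation defines co-expression, so the threshold
    must be > 0; anticorrelation never creates an edge.
    """
    if cutoff.pcc_threshold <= 0:
        raise ConfigError("co-expression requires a positive PCC threshold")
    mat = pcc_matrix.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValidationError("PCC matrix is not symmetric")
    genes = list(pcc_matrix.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(mat > cutoff.pcc_threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(genes[i], genes[j], weight=float(mat[i, j]))
    return GCN(graph=g, cutoff=cutoff)


@dataclass
class TOGCN:
    """A GCN with a BFS level assignment rooted at a seed TF.

    ``level_of`` maps each reachable gene to 1 + its shortest-path
    distance from the seed; genes unreachable from the seed are listed
    in ``excluded`` and never silently dropped.
    """

    gcn: GCN
    seed_gene: str
    level_of: dict[str, int]
    excluded: frozenset[str]

    @property
    def n_levels(self) -> int:
        return max(self.level_of.values()) if self.level_of else 0

    def genes_at_level(self, level: int) -> set[str]:
        return {g for g, lv in self.level_of.items() if lv == level}

    def level_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for lv in self.level_of.values():
            counts[lv] = counts.get(lv, 0) + 1
        return dict(sorted(counts.items()))


def assign_levels_bfs(gcn: GCN, seed_gene: str) -> TOGCN:
    """Assign time-order levels by breadth-first search from the seed.

    The seed is level 1; each search front becomes the next level until
    every reachable node is assigned. Levels equal shortest-path
    distance + 1, so the assignment is independent of node iteration
    order.
    """
    if seed_gene not in gcn.graph:
        raise ValidationError(f"seed gene {seed_gene!r} not in the network")
    level_of: dict[str, int] = {seed_gene: 1}
    queue: deque[str] = deque([seed_gene])
    while queue:
        node = queue.popleft()
        for nbr in gcn.graph.neighbors(node):
            if nbr not in level_of:
                level_of[nbr] = level_of[node] + 1
                queue.append(nbr)
    excluded = frozenset(gcn.graph.nodes) - level_of.keys()
    return TOGCN(gcn=gcn, seed_gene=seed_gene, level_of=level_of, excluded=frozenset(excluded))


def suggest_seed(profiles, genes=None) -> list[str]:
    """Rank candidate seed TFs by earliness of expression.

    The seed should be the first-upregulated TF, so genes are scored by
    (z-score at the first timepoint) - (max z-score at any later
    timepoint): a gene already at its peak when the course starts scores
    highest. Ties break lexicographically by gene id. The ranking is a
    heuristic; an explicit user choice always overrides it.
    """
    df = _as_frame(profiles)
    if genes is not None:
        df = df.loc[[g for g in df.index if g in set(genes)]]
    z = zscore_rows(df)
    score = z.iloc[:, 0] - z.iloc[:, 1:].max(axis=1)
    order = sorted(zip(-score, z.index))
    return [g for _, g in order]


@dataclass
class LevelProfile:
    """Per-level mean z-score profile and member counts."""

    profiles: pd.DataFrame  # index = level, columns = timepoints
    counts: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        out = self.profiles.copy()
        out.insert(0, "n_genes", [self.counts[lv] for lv in out.index])
        out.index.name = "level"
        return out


def level_profiles(togcn: TOGCN, zscored: pd.DataFrame) -> LevelProfile:
    """Mean z-score per level and timepoint (the level bar-chart data)."""
    missing = [g for g in togcn.level_of if g not in zscored.index]
    if missing:
        raise ValidationError(f"z-score matrix lacks leveled gene {missing[0]!r}")
    rows = {}
    counts = {}
    for lv in sorted(set(togcn.level_of.values())):
        members = sorted(togcn.genes_at_level(lv))
        rows[lv] = zscored.loc[members].mean(axis=0)
        counts[lv] = len(members)
    return LevelProfile(profiles=pd.DataFrame(rows).T, counts=counts)
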