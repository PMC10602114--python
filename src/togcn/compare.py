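"""Dual-network comparison: condition-specific vs common TFs.

Given TO-GCNs built separately for two conditions (e.g. embryonic natal
down vs juvenile feather), each TF's level difference d = level_A -
level_B measures how much earlier or later it acts in condition A.
TFs with |d| >= t (default t = 3) are called condition-specific —
A-specific when d >= t, B-specific when d <= -t — and TFs with
|d| <= t - 1 are common to both programs. TFs absent from one network
are reported as unassigned rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

CLASS_A = "A-specific"
CLASS_B = "B-specific"
CLASS_COMMON = "common"
CLASS_UNASSIGNED = "unassigned"
CLASSES = (CLASS_A, CLASS_B, CLASS_COMMON, CLASS_UNASSIGNED)


def _levels_of(obj) -> dict[str, int]:
    if hasattr(obj, "level_of"):
        return dict(obj.level_of)
    return dict(obj)


def align_networks(togcn_a, togcn_b) -> pd.DataFrame:
    """Pair per-TF levels from two TO-GCNs (or gene -> level mappings).

    Returns one row per gene appearing in either network, with nullable
    integer columns ``level_A`` and ``level_B``; a missing level is left
    explicitly absent (pd.NA).
    """
    la, lb = _levels_of(togcn_a), _levels_of(togcn_b)
    genes = sorted(set(la) | set(lb))
    return pd.DataFrame(
        {
            "level_A": pd.array([la.get(g) for g in genes], dtype="Int64"),
            "level_B": pd.array([lb.get(g) for g in genes], dtype="Int64"),
        },
        index=pd.Index(genes, name="gene_id"),
    )


@dataclass
class LevelComparison:
    """Per-TF paired levels, level difference d, and class labels."""

    table: pd.DataFrame  # columns: level_A, level_B, d (Int64), tf_class
    t: int


def classify_tfs(paired: pd.DataFrame, t: int = 3) -> LevelComparison:
    """Label each TF from d = level_A - level_B with threshold t.

    d >= t: A-specific; d <= -t: B-specific; |d| <= t - 1: common;
    either level absent: unassigned.
    """
    if t < 1:
        raise ConfigError(f"threshold t must be >= 1, got {t}")
    out = paired.copy()
    for col in ("level_A", "level_B"):
        if col not in out.columns:
            raise ValidationError(f"paired table missing column {col!r}")
        present = out[col].dropna().to_numpy(dtype=float)
        if len(present) and (present != np.round(present)).any():
            raise ValidationError(f"non-integer levels in column {col!r}")
        out[col] = out[col].astype("Float64").round().astype("Int64")
    out["d"] = (out["level_A"] - out["level_B"]).astype("Int64")
    d = out["d"]
    a_mask = (d >= t).fillna(False).to_numpy(dtype=bool)
    b_mask = (d <= -t).fillna(False).to_numpy(dtype=bool)
    out["tf_class"] = np.where(
        d.isna().to_numpy(),
        CLASS_UNASSIGNED,
        np.where(a_mask, CLASS_A, np.where(b_mask, CLASS_B, CLASS_COMMON)),
    )
    return LevelComparison(table=out, t=int(t))


def summarize_classes(comparison: LevelComparison) -> dict:
    """Counts and proportions per class; counts always sum to the TF total."""
    counts = {c: int((comparison.table["tf_class"] == c).sum()) for c in CLASSES}
    total = len(comparison.table)
    props = {c: (counts[c] / total if total else 0.0) for c in CLASSES}
    return {
        "t": comparison.t,
        "n_tfs": total,
        "counts": counts,
        "proportions": props,
    }
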