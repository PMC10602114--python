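"""Core in-memory containers: expression matrix, sample table, annotation.

All containers validate their invariants on construction and are thin
wrappers around :class:`pandas.DataFrame` so downstream code can use the
usual pandas idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

#: Allowed unit tags for an expression matrix.
VALID_UNITS = ("counts", "TPM", "UQ-normalized")

SAMPLE_COLUMNS = ("sample_id", "condition", "timepoint", "order", "replicate")


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x sample abundance matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    unit
        One of ``counts``, ``TPM`` or ``UQ-normalized``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(
                f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}"
            )
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene id {dup[0]!r}")
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample id {dup[0]!r}")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if vals.size and np.isnan(vals.astype(float)).any():
            gene = self.values.index[np.isnan(vals.astype(float)).any(axis=1)][0]
            raise ValidationError(f"missing value in gene {gene!r}")
        if vals.size and (vals < 0).any():
            gene = self.values.index[(vals < 0).any(axis=1)][0]
            raise ValidationError(f"negative expression value in gene {gene!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"gene {missing[0]!r} not present in matrix")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} not present in matrix")
        return ExpressionMatrix(self.values[list(samples)], self.unit)


@dataclass
class SampleTable:
    """Sample metadata: condition, ordinal timepoint and replicate per sample.

    Timepoint order is declared explicitly through the integer ``order``
    column rather than inferred from labels, so e.g. "D10" never sorts
    before "D3".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigError(f"sample table missing column(s) {missing}")
        t = self.table
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample id {dup.iloc[0]!r}")
        try:
            t["order"] = t["order"].astype(int)
            t["replicate"] = t["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"order/replicate columns must be integers: {exc}") from exc
        if (t["replicate"] < 1).any():
            bad = t.loc[t["replicate"] < 1, "sample_id"].iloc[0]
            raise ValidationError(f"replicate < 1 for sample {bad!r}")
        # one declared order per (condition, timepoint label)
        per = t.groupby(["condition", "timepoint"])["order"].nunique()
        if (per > 1).any():
            cond, tp = per[per > 1].index[0]
            raise ConfigError(
                f"timepoint {tp!r} in condition {cond!r} has conflicting order values"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def timepoints(self, condition: str) -> list[str]:
        """Timepoint labels of a condition in declared time order."""
        sub = self.table[self.table["condition"] == condition]
        if sub.empty:
            raise ConfigError(f"condition {condition!r} not present in sample table")
        return list(sub.drop_duplicates("timepoint").sort_values("order")["timepoint"])

    def samples_for(self, condition: str, timepoint: str) -> list[str]:
        sub = self.table[
            (self.table["condition"] == condition) & (self.table["timepoint"] == timepoint)
        ]
        return list(sub.sort_values("replicate")["sample_id"])

    def samples_in_time_order(self, condition: str) -> list[str]:
        """All replicate sample ids of a condition, outer-sorted by time."""
        out: list[str] = []
        for tp in self.timepoints(condition):
            out.extend(self.samples_for(condition, tp))
        return out

    def require_timecourse(self, condition: str, min_timepoints: int = 5) -> None:
        """Network construction needs at least five distinct timepoints."""
        n = len(self.timepoints(condition))
        if n < min_timepoints:
            raise ValidationError(
                f"condition {condition!r} has {n} timepoints; "
                f">= {min_timepoints} required for network construction"
            )


@dataclass
class GeneAnnotation:
    """TF gene universe plus functional gene sets (GMT-style)."""

    tf_set: set[str] = field(default_factory=set)
    term_sets: dict[str, set[str]] = field(default_factory=dict)
    term_desc: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_sets.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")
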