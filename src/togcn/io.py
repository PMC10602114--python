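"""Readers and writers for every on-disk artifact the pipeline touches.

Canonical tabular dialect: tab-separated UTF-8, ``#`` comment lines
ignored, decimal point ``.``. Floats are written at full repr precision
so every writer/reader pair is a lossless round trip. Gene identifiers
are opaque case-sensitive strings; no symbol/ID mapping is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SAMPLE_COLUMNS, ExpressionMatrix, GeneAnnotation, SampleTable
from .errors import ConfigError, ParseError, ValidationError

_TSV = dict(sep="\t", comment="#")


def _read_table(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **_TSV, **kw)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise ParseError(f"{path}: file not found") from exc


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (header = sample ids, first column = gene ids)."""
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    try:
        return ExpressionMatrix(df, unit)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression(mat: ExpressionMatrix, path) -> None:
    out = mat.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_samples(path) -> SampleTable:
    df = _read_table(path, dtype={"sample_id": str, "condition": str, "timepoint": str})
    if "order" not in df.columns:
        raise ConfigError(
            f"{path}: sample table must declare timepoint order in an 'order' column"
        )
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: sample table missing column(s) {missing}")
    return SampleTable(df.reset_index(drop=True))


def write_samples(samples: SampleTable, path) -> None:
    samples.table[list(SAMPLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_tf_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    tfs: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            tfs.add(line)
    if not tfs:
        raise ValidationError(f"{path}: TF set empty")
    return tfs


def write_tf_list(tfs, path) -> None:
    Path(path).write_text("\n".join(sorted(tfs)) + "\n")


def read_gmt(path, tf_set=None) -> GeneAnnotation:
    """Read gene sets in GMT format: term, description, then member genes."""
    term_sets: dict[str, set[str]] = {}
    term_desc: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                "expected term, description and >= 1 gene"
            )
        term, desc, *genes = fields
        if term in term_sets:
            raise ValidationError(f"{path}:{lineno}: duplicate term {term!r}")
        term_sets[term] = set(genes)
        term_desc[term] = desc
    return GeneAnnotation(tf_set=set(tf_set or ()), term_sets=term_sets, term_desc=term_desc)


def write_gmt(annotation: GeneAnnotation, path) -> None:
    lines = []
    for term in sorted(annotation.term_sets):
        desc = annotation.term_desc.get(term, "")
        lines.append("\t".join([term, desc, *sorted(annotation.term_sets[term])]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(gcn, path) -> None:
    """TSV gene_a, gene_b, pcc with gene_a < gene_b, sorted for determinism."""
    rows = sorted(
        (min(a, b), max(a, b), w) for a, b, w in gcn.graph.edges.data("weight")
    )
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tpcc\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_edge_list(path) -> pd.DataFrame:
    df = _read_table(path, dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "pcc"):
        if col not in df.columns:
            raise ParseError(f"{path}: edge list missing column {col!r}")
    return df


def write_level_table(togcn, path) -> None:
    """TSV gene_id, level; unreachable genes written with level 'NA'."""
    with open(path, "w") as fh:
        fh.write("gene_id\tlevel\n")
        for gene, level in sorted(togcn.level_of.items()):
            fh.write(f"{gene}\t{level}\n")
        for gene in sorted(togcn.excluded):
            fh.write(f"{gene}\tNA\n")


def read_level_table(path) -> dict[str, int]:
    """Read gene -> level (unreachable 'NA' rows are dropped)."""
    df = _read_table(path, dtype={"gene_id": str, "level": str}, keep_default_na=False)
    for col in ("gene_id", "level"):
        if col not in df.columns:
            raise ParseError(f"{path}: level table missing column {col!r}")
    out: dict[str, int] = {}
    for gene, level in zip(df["gene_id"], df["level"]):
        if level == "NA":
            continue
        try:
            out[gene] = int(level)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer level {level!r} for {gene!r}") from exc
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_results_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_results_json(path):
    with open(path) as fh:
        return json.load(fh)
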