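"""Expression preprocessing: TPM, expressed-gene filter, UQ normalization.

The pipeline order mirrors standard bulk RNA-seq practice for time-course
co-expression work: length-normalize counts to TPM, keep genes reaching
TPM >= 1 in at least one library, equalize between-library scale with
upper-quartile normalization, then collapse replicates to per-timepoint
condition means before correlation analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleTable
from .errors import ValidationError

DEFAULT_TPM_THRESHOLD = 1.0


def compute_tpm(counts: ExpressionMatrix, lengths: dict[str, float]) -> ExpressionMatrix:
    """Convert read counts to Transcripts Per Kilobase Million.

    For each sample: tpm_g = (count_g / length_g) / sum_h(count_h / length_h) * 1e6,
    so every column sums to 1e6.
    """
    if counts.unit != "counts":
        raise ValidationError(f"compute_tpm expects unit 'counts', got {counts.unit!r}")
    missing = [g for g in counts.genes if g not in lengths]
    if missing:
        raise ValidationError(f"no length for gene {missing[0]!r}")
    lens = np.array([float(lengths[g]) for g in counts.genes])
    if (lens <= 0).any():
        bad = counts.genes[int(np.argmax(lens <= 0))]
        raise ValidationError(f"non-positive length for gene {bad!r}")
    rate = counts.values.to_numpy(dtype=float) / lens[:, None]
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        sample = counts.samples[int(np.argmax(colsum == 0))]
        raise ValidationError(f"sample {sample!r} has all-zero counts; TPM undefined")
    tpm = rate / colsum[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns), "TPM"
    )


def filter_expressed(
    mat: ExpressionMatrix, threshold: float = DEFAULT_TPM_THRESHOLD
) -> ExpressionMatrix:
    """Keep genes whose expression reaches ``threshold`` in >= 1 sample.

    The boundary is inclusive: a gene at exactly the threshold in a single
    sample is retained. Gene order is preserved.
    """
    keep = mat.values.max(axis=1) >= threshold
    if not keep.any():
        warnings.warn("filter_expressed removed every gene", stacklevel=2)
    return ExpressionMatrix(mat.values.loc[keep], mat.unit)


def upper_quartile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so the 75th percentiles of nonzero values agree.

    Each sample is multiplied by (mean over samples of the per-sample
    nonzero upper quartile) / (that sample's nonzero upper quartile), so
    the common post-normalization quartile equals the pre-normalization
    mean quartile — a symmetric choice of reference that favours no
    particular library. Quantiles use linear interpolation.
    """
    vals = mat.values.to_numpy(dtype=float)
    uqs = np.empty(vals.shape[1])
    for j, sample in enumerate(mat.samples):
        nz = vals[:, j][vals[:, j] > 0]
        if nz.size == 0:
            raise ValidationError(f"sample {sample!r} has all-zero expression")
        if nz.size < 4:
            raise ValidationError(
                f"sample {sample!r} has only {nz.size} nonzero gene(s); "
                ">= 4 required for upper-quartile normalization"
            )
        uqs[j] = np.percentile(nz, 75)
    scale = uqs.mean() / uqs
    out = vals * scale[None, :]
    return ExpressionMatrix(
        pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns),
        "UQ-normalized",
    )


def condition_mean_profiles(
    mat: ExpressionMatrix, samples: SampleTable, condition: str
) -> ExpressionMatrix:
    """Average replicates into one column per timepoint, in declared order."""
    cols = {}
    for tp in samples.timepoints(condition):
        ids = [s for s in samples.samples_for(condition, tp) if s in mat.values.columns]
        if not ids:
            raise ValidationError(
                f"timepoint {tp!r} of condition {condition!r} has no samples in the matrix"
            )
        cols[tp] = mat.values[ids].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), mat.unit)


def zscore_rows(mat) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 (population denominator).

    Zero-variance rows cannot be standardized; they are excluded with a
    warning naming how many were dropped.
    """
    df = mat.values if isinstance(mat, ExpressionMatrix) else pd.DataFrame(mat)
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population (n denominator)
    flat = (sd[:, 0] == 0)
    if flat.any():
        warnings.warn(
            f"zscore_rows excluded {int(flat.sum())} zero-variance row(s)", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    return pd.DataFrame(z[~flat], index=df.index[~flat], columns=df.columns)
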