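"""Normalization and filtering of expression matrices.

Turns raw counts into the two working objects of the marker pipeline:
a TPM tissue profile (gene x tissue mean TPM) for specificity scoring,
and a filtered matrix for network construction; plus the
quantile-normalized and 0-10 BIN representations the tau stage uses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic_data import CountMatrix

__all__ = [
    "counts_to_tpm",
    "tissue_means",
    "filter_expressed",
    "filter_for_network",
    "quantile_normalize",
    "assign_bins",
    "row_zscore",
    "read_expression_tsv",
    "write_expression_tsv",
]


def counts_to_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized counts scaled to 1e6 per sample.

    TPM_ij = (c_ij / l_i) / sum_g (c_gj / l_g) * 1e6. Each column of the
    result sums to 1e6 (all-zero columns stay zero, with a warning).
    """
    rate = cm.counts.div(cm.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"all-zero columns left as zeros: {list(colsum.index[zero])}", stacklevel=2
        )
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def tissue_means(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns per tissue; tissue order follows the design."""
    missing = set(design["sample_id"]) - set(expr.columns)
    if missing:
        raise ValueError(f"design references samples absent from matrix: {sorted(missing)}")
    tissues = list(dict.fromkeys(design["tissue"]))
    cols = {
        t: expr[design.loc[design["tissue"] == t, "sample_id"]].mean(axis=1) for t in tissues
    }
    return pd.DataFrame(cols, columns=tissues)


def filter_expressed(
    profile: pd.DataFrame,
    min_tpm: float = 1.0,
    mode: str = "any_tissue",
    strict: bool = True,
) -> list[str]:
    """Genes expressed above ``min_tpm`` in at least one (or every) tissue.

    ``strict=True`` uses a strict > comparison (the default criterion);
    ``strict=False`` uses >=. Order-preserving.
    """
    if min_tpm < 0:
        raise ValueError("min_tpm must be nonnegative")
    passing = profile.gt(min_tpm) if strict else profile.ge(min_tpm)
    if mode == "any_tissue":
        keep = passing.any(axis=1)
    elif mode == "all_tissues":
        keep = passing.all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(profile.index[keep])


def filter_for_network(
    profile: pd.DataFrame, min_mean_tpm: float = 1.0, min_variance: float = 1.0
) -> list[str]:
    """Network gene filter: max tissue mean >= min_mean_tpm and variance > min_variance.

    Variance is the sample variance across the tissue means (low-variance
    genes carry no co-expression signal and are removed).
    """
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    keep = (profile.max(axis=1) >= min_mean_tpm) & (profile.var(axis=1, ddof=1) > min_variance)
    return list(profile.index[keep])


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common per-rank mean distribution.

    The reference distribution is the mean of the sorted columns; each
    column's values are replaced by the reference value at their rank,
    ties receiving the mean of the reference values over the tied ranks.
    Idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    x = matrix.to_numpy(dtype=float)
    order = np.sort(x, axis=0)
    ref = order.mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        idx = np.argsort(col, kind="stable")
        sorted_col = col[idx]
        # average the reference over runs of tied values
        vals = np.empty(n)
        start = 0
        while start < n:
            end = start
            while end + 1 < n and sorted_col[end + 1] == sorted_col[start]:
                end += 1
            vals[start : end + 1] = ref[start : end + 1].mean()
            start = end + 1
        out[idx, j] = vals
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def assign_bins(qn_profile: pd.DataFrame) -> pd.DataFrame:
    """Discretize each tissue column into integer expression levels 0-10.

    Zero expression maps to level 0. Nonzero values are placed on an
    equal-width grid over log2(v+1) between the tissue's nonzero minimum
    and maximum, rounded half-up, so the most-expressed gene gets 10.
    Monotone within each tissue.
    """
    x = qn_profile.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    out = np.zeros(x.shape, dtype=np.int64)
    for j in range(x.shape[1]):
        col = x[:, j]
        nz = col > 0
        if not nz.any():
            continue
        logv = np.log2(col[nz] + 1.0)
        m, big = logv.min(), logv.max()
        if big == m:
            out[nz, j] = 10
        else:
            out[nz, j] = np.floor(10.0 * (logv - m) / (big - m) + 0.5).astype(np.int64)
    return pd.DataFrame(out, index=qn_profile.index, columns=qn_profile.columns)


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row: z = (value - mean(row)) / sd(row), sample SD.

    Constant rows become all zeros (with a warning).
    """
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows set to zero", stacklevel=2)
        sd = sd.replace(0, np.nan)
    z = matrix.sub(mu, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


# ---------------------------------------------------------------------------
# TSV round-trip helpers (gene x column tables, '#' provenance headers)


def write_expression_tsv(matrix: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# floramark expression table\n")
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        matrix.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "gene_id"
    return df
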