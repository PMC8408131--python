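"""Tissue-specificity scoring with the tau index.

tau = sum_i (1 - x_i) / (N - 1), where x_i is a gene's expression in
tissue i divided by its maximum over the N tissues: 0 for a uniformly
expressed gene, 1 for a gene expressed in a single tissue. The
per-tissue tau expression fraction tau_ef = tau * qn / max allocates the
specificity to tissues, and the composite marker score (tau_ef plus the
0-1 min-max-scaled expression within a tissue, range 0-2) ranks genes
that are both specific and abundantly expressed. Housekeeping candidates
are genes that are constitutively expressed on their discretized (BIN)
profile and exceed 100 TPM in every tissue.

Classification thresholds: tau = 1 absolutely specific (ASG),
tau >= 0.85 highly specific (HSG; ASG counted inside HSG for set
reports), tau < 0.2 constitutive, otherwise intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_prep import assign_bins, quantile_normalize

__all__ = [
    "tau",
    "tau_profile_table",
    "tau_expression_fraction",
    "classify_specificity",
    "gene_score",
    "rank_optimum_genes",
    "housekeeping_genes",
    "TauTable",
    "build_tau_table",
]


def tau(profile) -> float:
    """Specificity index of one per-tissue expression vector.

    Scale-invariant; requires N >= 2 tissues and a positive maximum
    (all-zero profiles are undefined and raise).
    """
    v = np.asarray(profile, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("profile must be a vector over >= 2 tissues")
    if (v < 0).any():
        raise ValueError("expression must be nonnegative")
    m = v.max()
    if m == 0:
        raise ValueError("all-zero profile: tau undefined")
    x = v / m
    return float((1.0 - x).sum() / (v.size - 1))


def tau_profile_table(profile: pd.DataFrame) -> pd.Series:
    """Vectorized tau over a genes x tissues table (all-zero genes -> NaN)."""
    v = profile.to_numpy(dtype=float)
    m = v.max(axis=1)
    ok = m > 0
    out = np.full(v.shape[0], np.nan)
    x = v[ok] / m[ok, None]
    out[ok] = (1.0 - x).sum(axis=1) / (v.shape[1] - 1)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} all-zero genes excluded from tau", stacklevel=2)
    return pd.Series(out, index=profile.index, name="tau")


def tau_expression_fraction(tau_values, qn_profile: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue allocation tau_ef = tau * qn / max(qn); equals tau at the argmax tissue."""
    t = np.asarray(tau_values, dtype=float)
    v = qn_profile.to_numpy(dtype=float)
    m = v.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = v / m[:, None]
    frac = np.nan_to_num(frac, nan=0.0)
    return pd.DataFrame(
        t[:, None] * frac, index=qn_profile.index, columns=qn_profile.columns
    )


def classify_specificity(
    tau_values,
    asg_cut: float = 1.0,
    hsg_cut: float = 0.85,
    const_cut: float = 0.2,
) -> pd.Series | str:
    """Map tau to {ASG, HSG, intermediate, constitutive}.

    The classes partition genes (ASG is reported separately from HSG
    here; for set operations ASG genes are additionally counted as HSG).
    """
    scalar = np.isscalar(tau_values)
    t = np.atleast_1d(np.asarray(tau_values, dtype=float))
    klass = np.where(
        t >= asg_cut,
        "ASG",
        np.where(t >= hsg_cut, "HSG", np.where(t < const_cut, "constitutive", "intermediate")),
    )
    klass = np.where(np.isnan(t), "excluded", klass)
    if scalar:
        return str(klass[0])
    index = tau_values.index if isinstance(tau_values, pd.Series) else None
    return pd.Series(klass, index=index, name="klass")


def gene_score(tau_ef: pd.DataFrame, qn_profile: pd.DataFrame) -> pd.DataFrame:
    """Composite marker score: tau_ef plus within-tissue min-max-scaled expression.

    For each tissue the expression column is scaled across genes to
    [0, 1]; the score tau_ef + scaled expression lies in [0, 2] and is
    maximal (2) for a gene that is both perfectly specific and the
    tissue's most expressed. Constant columns scale to 0 with a warning.
    """
    v = qn_profile.to_numpy(dtype=float)
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant tissue columns scaled to 0", stacklevel=2)
        span = np.where(const, 1.0, span)
    norm = (v - lo) / span
    norm[:, const] = 0.0
    return pd.DataFrame(
        tau_ef.to_numpy(dtype=float) + norm, index=qn_profile.index, columns=qn_profile.columns
    )


def rank_optimum_genes(
    scores: pd.DataFrame, tau_values: pd.Series, k: int = 10
) -> dict[str, pd.DataFrame]:
    """Top-k marker genes per tissue by descending composite score.

    Ties broken by descending tau, then lexical gene id. Returns per
    tissue a table (gene_id index, columns score and tau).
    """
    if k > scores.shape[0]:
        warnings.warn("fewer genes than k; returning all", stacklevel=2)
    out = {}
    for tissue in scores.columns:
        df = pd.DataFrame({"score": scores[tissue], "tau": tau_values})
        df = (
            df.assign(gene=df.index)
            .sort_values(by=["score", "tau", "gene"], ascending=[False, False, True])
            .drop(columns="gene")
        )
        out[tissue] = df.head(k)
    return out


def housekeeping_genes(
    tau_values: pd.Series,
    tpm_profile: pd.DataFrame,
    tau_max: float = 0.2,
    min_tpm: float = 100.0,
) -> pd.DataFrame:
    """Constitutively, robustly expressed genes — candidate qPCR references.

    Keeps genes whose tau is below ``tau_max`` (strictly, unless
    ``tau_max`` is 0, where tau <= 0 is used so the exact-zero criterion
    is expressible) and whose TPM exceeds ``min_tpm`` in every tissue.
    Sorted ascending by the standard deviation of TPM across tissues
    (most stable first). Returns a table with tau and tpm_sd columns.
    """
    t = tau_values.reindex(tpm_profile.index)
    pass_tau = (t <= 0) if tau_max == 0 else (t < tau_max)
    pass_tpm = tpm_profile.gt(min_tpm).all(axis=1)
    keep = pass_tau.fillna(False) & pass_tpm
    sd = tpm_profile.std(axis=1, ddof=1)
    out = pd.DataFrame({"tau": t[keep], "tpm_sd": sd[keep]})
    return out.sort_values("tpm_sd")


@dataclass
class TauTable:
    """Per-gene specificity results.

    ``summary`` has columns tau (continuous, on the quantile-normalized
    tissue profile), tau_bin (on the 0-10 BIN profile; the scale on
    which exact constitutive calls are meaningful) and klass.
    ``tau_ef``, ``bins`` and ``scores`` are genes x tissues tables.
    """

    summary: pd.DataFrame
    tau_ef: pd.DataFrame
    bins: pd.DataFrame
    scores: pd.DataFrame
    qn: pd.DataFrame


def build_tau_table(
    profile: pd.DataFrame,
    tau_on_bins: bool = False,
    asg_cut: float = 1.0,
    hsg_cut: float = 0.85,
    const_cut: float = 0.2,
) -> TauTable:
    """Run the full specificity stage on a (filtered) tissue profile.

    Quantile-normalizes across tissues, assigns BIN levels, computes tau
    (continuous by default; on BIN levels if ``tau_on_bins``), tau
    expression fractions, and composite scores. Genes with all-zero
    profiles must be filtered out beforehand.
    """
    qn = quantile_normalize(profile)
    bins = assign_bins(qn)
    tau_cont = tau_profile_table(qn)
    zero_bin = bins.max(axis=1) == 0
    tau_bin = pd.Series(np.nan, index=bins.index, name="tau_bin")
    if (~zero_bin).any():
        tau_bin[~zero_bin] = tau_profile_table(bins.loc[~zero_bin]).to_numpy()
    primary = tau_bin.rename("tau") if tau_on_bins else tau_cont
    klass = classify_specificity(primary, asg_cut, hsg_cut, const_cut)
    tef = tau_expression_fraction(primary.to_numpy(), qn)
    scores = gene_score(tef, qn)
    summary = pd.DataFrame(
        {"tau": primary, "tau_bin": tau_bin, "klass": klass}, index=profile.index
    )
    return TauTable(summary=summary, tau_ef=tef, bins=bins, scores=scores, qn=qn)
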