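"""Signed weighted co-expression network construction and module detection.

Implements the standard weighted-correlation-network machinery: a signed
adjacency a_ij = ((1 + cor_ij)/2)^beta with automatic soft-threshold
selection against approximate scale-free topology (signed R^2 > 0.9),
topological-overlap dissimilarity, average-linkage module detection with
a minimum module size, eigengene computation (first principal component
of the standardized module expression), eigengene-based module merging,
module membership (kME) and gene significance statistics with Student-t
p-values, module-trait correlation, and hub-gene calling (kME > 0.9).

By default the network is built over tissue-mean columns of the
log2(TPM+1) profile; modules are labeled 1..M by decreasing size with 0
the grey/unassigned label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkModel",
    "signed_adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_membership",
    "gene_significance",
    "module_trait_correlation",
    "hub_genes",
    "trait_indicators",
    "dendrogram_newick",
]

_TINY_P = np.finfo(float).tiny


@dataclass
class NetworkModel:
    """Bundle of the network stage's matrices, aligned on one gene index."""

    genes: pd.Index
    correlation: np.ndarray
    beta: float
    adjacency: np.ndarray
    tom_dissimilarity: np.ndarray


def _check_square_symmetric(m: np.ndarray, name: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")


def signed_adjacency(cor_matrix: np.ndarray, beta: float = 12.0) -> np.ndarray:
    """Signed soft-thresholded adjacency a_ij = ((1 + cor_ij) / 2)^beta."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    cor = np.asarray(cor_matrix, dtype=float)
    if np.nanmax(np.abs(cor)) > 1 + 1e-10:
        raise ValueError("correlations must lie in [-1, 1]")
    adj = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed scale-free fit of a connectivity vector.

    Connectivities are discretized into ``n_bins`` equal-width bins;
    log10 frequency is regressed on log10 mean connectivity per occupied
    bin. Returns (signed R^2, slope) with signed R^2 = -sign(slope)*R^2,
    so a decreasing (power-law-like) p(k) gives a positive fit.
    """
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        dk.append(np.log10(mk))
        pk.append(np.log10(mask.mean()))
    if len(dk) < 3 or np.ptp(dk) < 1e-12:
        return np.nan, np.nan
    slope, _, r, _, _ = stats.linregress(dk, pk)
    return -np.sign(slope) * r**2, slope


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_powers: list[float] | None = None,
    r2_cut: float = 0.9,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Select the smallest power giving approximate scale-free topology.

    ``matrix`` is genes x columns. For each candidate power the signed
    adjacency is formed and whole-network connectivities are tested for
    a log-log linear frequency distribution. Returns the smallest power
    whose signed fit index reaches ``r2_cut``; if none does, the power
    maximizing the fit is returned and flagged in the table
    (``selected`` column, ``warning`` attribute).
    """
    powers = list(candidate_powers) if candidate_powers is not None else list(range(1, 21))
    if not powers:
        raise ValueError("candidate_powers must be nonempty")
    if sorted(powers) != powers:
        raise ValueError("candidate_powers must be ascending")
    x = matrix.to_numpy(dtype=float)
    cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    rows = []
    for p in powers:
        adj = signed_adjacency(cor, p)
        k = adj.sum(axis=1) - 1.0
        fit, slope = _scale_free_fit(k, n_bins)
        if np.isnan(fit):
            warnings.warn(f"degenerate connectivity at power {p}; skipped", stacklevel=2)
        rows.append(
            {"power": p, "fit": fit, "slope": slope, "mean_k": k.mean(), "max_k": k.max()}
        )
    table = pd.DataFrame(rows)
    ok = table["fit"] >= r2_cut
    if ok.any():
        beta = float(table.loc[ok, "power"].iloc[0])
        warn = False
    else:
        valid = table["fit"].notna()
        if not valid.any():
            raise ValueError("scale-free fit undefined at every candidate power")
        beta = float(table.loc[table.loc[valid, "fit"].idxmax(), "power"])
        warn = True
        warnings.warn(
            f"no power reached fit {r2_cut}; using best power {beta}", stacklevel=2
        )
    table["selected"] = table["power"] == beta
    table.attrs["warning"] = warn
    return beta, table


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity of a signed adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu * a_uj and k_i the connectivity of i;
    the result is 1 - TOM with a zero diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    _check_square_symmetric(a, "adjacency")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    # L_ij excludes u in {i, j}: subtract the diagonal contributions
    prod = a @ a
    L = prod - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    diss = np.clip(1.0 - tom, 0.0, 1.0)
    np.fill_diagonal(diss, 0.0)
    return diss


def _average_linkage(diss: np.ndarray) -> np.ndarray:
    d = np.asarray(diss, dtype=float)
    _check_square_symmetric(d, "dissimilarity")
    return linkage(squareform(d, checks=False), method="average")


def detect_modules(
    diss: np.ndarray,
    min_size: int = 30,
    cut_height: float | None = None,
    relative_cut: float = 0.98,
) -> np.ndarray:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    The tree is cut at ``cut_height`` (absolute dissimilarity) or, if
    None, at ``relative_cut`` of the tree height. Candidate clusters
    smaller than ``min_size`` are assigned the grey label 0; retained
    modules are labeled 1..M by decreasing size. Deterministic.
    """
    n = diss.shape[0]
    if n < min_size:
        warnings.warn("fewer genes than min_size; all genes grey", stacklevel=2)
        return np.zeros(n, dtype=np.int64)
    Z = _average_linkage(diss)
    height = Z[:, 2].max() if len(Z) else 0.0
    cut = cut_height if cut_height is not None else relative_cut * height
    raw = fcluster(Z, t=cut, criterion="distance")
    return _apply_min_size(raw, min_size)


def _apply_min_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    labels = np.zeros(raw.shape[0], dtype=np.int64)
    ids, counts = np.unique(raw, return_counts=True)
    keep = ids[counts >= min_size]
    # order retained modules by decreasing size, ties by first occurrence
    sizes = {i: c for i, c in zip(ids, counts)}
    first_pos = {i: int(np.argmax(raw == i)) for i in keep}
    ordered = sorted(keep, key=lambda i: (-sizes[i], first_pos[i]))
    for new, old in enumerate(ordered, start=1):
        labels[raw == old] = new
    return labels


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mu) / sd


def module_eigengenes(matrix: pd.DataFrame, assignment: np.ndarray) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Rows (genes) are standardized; the eigengene is the leading right
    singular vector across columns, unit norm, with sign fixed so it
    correlates nonnegatively with the module's mean standardized profile.
    Returns a modules x columns table indexed 'ME<label>'.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 columns for eigengenes")
    x = matrix.to_numpy(dtype=float)
    rows = {}
    for m in sorted(set(assignment) - {0}):
        sub = x[assignment == m]
        if sub.shape[0] < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        z = _standardize_rows(sub)
        const = np.isnan(z).any(axis=1)
        if const.all():
            warnings.warn(f"module {m} is all-constant; skipped", stacklevel=2)
            continue
        z = z[~const]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        rows[f"ME{m}"] = e
    return pd.DataFrame(rows, index=matrix.columns).T


def _eigengene_dissimilarity(eigengenes: pd.DataFrame) -> np.ndarray:
    cor = np.corrcoef(eigengenes.to_numpy())
    cor = np.atleast_2d(np.nan_to_num(cor, nan=0.0))
    return np.clip(1.0 - cor, 0.0, None)


def merge_modules(
    matrix: pd.DataFrame, assignment: np.ndarray, merge_height: float = 0.25
) -> np.ndarray:
    """Merge modules whose eigengenes are highly correlated.

    Iteratively clusters eigengenes by average linkage on 1 - cor and
    merges every group joined below ``merge_height``, recomputing
    eigengenes until the minimum pairwise dissimilarity among retained
    modules is >= merge_height. Labels are refreshed to 1..M by size.
    """
    labels = assignment.copy()
    for _ in range(100):
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        me = module_eigengenes(matrix, labels)
        order = [int(name[2:]) for name in me.index]
        diss = _eigengene_dissimilarity(me)
        if diss[np.triu_indices_from(diss, k=1)].min() >= merge_height:
            break
        Z = _average_linkage(diss)
        groups = fcluster(Z, t=merge_height, criterion="distance")
        mapping = {}
        for g in np.unique(groups):
            members = [order[i] for i in np.where(groups == g)[0]]
            target = min(members)
            for m in members:
                mapping[m] = target
        labels = np.array([mapping.get(v, v) if v != 0 else 0 for v in labels])
    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    mods, counts = np.unique(labels[labels != 0], return_counts=True)
    first_pos = {m: int(np.argmax(labels == m)) for m in mods}
    ordered = sorted(mods, key=lambda m: (-counts[list(mods).index(m)], first_pos[m]))
    for new, old in enumerate(ordered, start=1):
        out[labels == old] = new
    return out


def _cor_with_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlations of x (a x n) against y (b x n) with t-test p."""
    n = x.shape[1]
    xs = x - x.mean(axis=1, keepdims=True)
    ys = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xs**2).sum(axis=1))
    yn = np.sqrt((ys**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs @ ys.T) / np.outer(xn, yn)
    r = np.nan_to_num(r, nan=0.0)  # constant rows -> r = 0 by convention
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, _TINY_P, p)
    p = np.where(r == 0.0, 1.0, p)
    return r, np.clip(p, _TINY_P, 1.0)


def module_membership(
    matrix: pd.DataFrame, eigengenes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """kME: correlation of each gene with each module eigengene, plus p-values."""
    if list(matrix.columns) != list(eigengenes.columns):
        raise ValueError("matrix and eigengene columns differ")
    r, p = _cor_with_pvalues(matrix.to_numpy(dtype=float), eigengenes.to_numpy(dtype=float))
    kme = pd.DataFrame(r, index=matrix.index, columns=eigengenes.index)
    pv = pd.DataFrame(p, index=matrix.index, columns=eigengenes.index)
    return kme, pv


def trait_indicators(columns: list[str], design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Binary tissue-indicator traits over network columns.

    If ``design`` is given, columns are samples mapped to tissues;
    otherwise columns are taken to be the tissue labels themselves.
    Returns a traits x columns 0/1 table.
    """
    if design is not None:
        tissue_of = dict(zip(design["sample_id"], design["tissue"]))
        tissues = list(dict.fromkeys(design["tissue"]))
        data = {t: [1.0 if tissue_of[c] == t else 0.0 for c in columns] for t in tissues}
    else:
        data = {t: [1.0 if c == t else 0.0 for c in columns] for t in columns}
    return pd.DataFrame(data, index=columns).T


def gene_significance(
    matrix: pd.DataFrame, trait: pd.Series | np.ndarray, signed: bool = False
) -> pd.DataFrame:
    """Correlation strength of every gene with a binary trait.

    Returns columns GS (|r| by default, signed r optionally) and
    minus_log10_p from the Student-t test. Rejects constant traits.
    """
    t = np.asarray(trait, dtype=float)
    if t.std() == 0:
        raise ValueError("trait indicator has zero variance")
    r, p = _cor_with_pvalues(matrix.to_numpy(dtype=float), t[None, :])
    gs = r[:, 0] if signed else np.abs(r[:, 0])
    return pd.DataFrame(
        {"GS": gs, "minus_log10_p": -np.log10(p[:, 0])}, index=matrix.index
    )


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Module-trait correlation table and each trait's best module.

    ``traits`` is traits x columns (aligned with eigengene columns).
    Returns (r, p, best) with best mapping trait -> eigengene name of
    maximal correlation.
    """
    if eigengenes.shape[1] < 3:
        raise ValueError("need at least 3 columns")
    if list(eigengenes.columns) != list(traits.columns):
        raise ValueError("eigengene and trait columns differ")
    r, p = _cor_with_pvalues(
        eigengenes.to_numpy(dtype=float), traits.to_numpy(dtype=float)
    )
    rdf = pd.DataFrame(r, index=eigengenes.index, columns=traits.index)
    pdf = pd.DataFrame(p, index=eigengenes.index, columns=traits.index)
    best = {trait: rdf[trait].idxmax() for trait in rdf.columns}
    return rdf, pdf, best


def hub_genes(
    kme: pd.DataFrame, assignment: np.ndarray, mm_cut: float = 0.9
) -> dict[int, list[str]]:
    """Per-module hub genes: members with own-module kME above ``mm_cut``.

    Sorted by descending kME within each module.
    """
    out: dict[int, list[str]] = {}
    genes = kme.index
    for m in sorted(set(assignment) - {0}):
        col = f"ME{m}"
        if col not in kme.columns:
            out[m] = []
            continue
        members = genes[assignment == m]
        vals = kme.loc[members, col]
        hubs = vals[vals > mm_cut].sort_values(ascending=False)
        out[m] = list(hubs.index)
    return out


def dendrogram_newick(diss: np.ndarray, labels: list[str]) -> str:
    """Average-linkage tree of a dissimilarity matrix as a Newick string."""
    Z = _average_linkage(diss)
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
        del nodes[a], nodes[b]
    (root,) = nodes.values()
    return root + ";"
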