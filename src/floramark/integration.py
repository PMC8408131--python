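"""Combining specificity and network results into key hub genes.

A key hub gene is both highly tissue-specific (HSG by tau, with ASG
counted inside HSG) and a hub (kME > 0.9) of the co-expression module
best correlated with that tissue. This module also provides the
three-set Venn arithmetic against an external atlas flag list,
transcription-factor family screening against an annotation table, and
hypergeometric over-representation analysis with Benjamini-Hochberg FDR
over user-supplied gene sets (GMT).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "key_hub_genes",
    "venn_overlap",
    "screen_tf",
    "hypergeometric_enrichment",
    "atlas_cross",
    "read_gmt",
    "benjamini_hochberg",
]


def key_hub_genes(
    hsg_by_tissue: dict[str, list[str]],
    hub_by_module: dict[int, list[str]],
    module_tissue_map: dict[str, int],
) -> pd.DataFrame:
    """Intersect each tissue's HSG list with its mapped module's hub genes.

    ``module_tissue_map`` assigns every tissue its best-correlated module
    label. Returns per tissue the intersection (order of the hub list
    preserved), its size, and the percentage of the module's hub set it
    covers. Tissues without a mapped module yield empty rows with a
    warning.
    """
    rows = []
    for tissue, hsg in hsg_by_tissue.items():
        module = module_tissue_map.get(tissue)
        if module is None or module not in hub_by_module:
            warnings.warn(f"tissue {tissue!r} has no mapped module", stacklevel=2)
            rows.append(
                {"tissue": tissue, "module": None, "genes": [], "n": 0, "pct_of_hubs": 0.0}
            )
            continue
        hubs = hub_by_module[module]
        hsg_set = set(hsg)
        inter = [g for g in hubs if g in hsg_set]
        pct = 100.0 * len(inter) / len(hubs) if hubs else 0.0
        rows.append(
            {"tissue": tissue, "module": module, "genes": inter, "n": len(inter),
             "pct_of_hubs": pct}
        )
    return pd.DataFrame(rows).set_index("tissue")


def venn_overlap(set_a, set_b, set_c, names=("A", "B", "C")) -> dict[str, int]:
    """Counts of the 7 regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    na, nb, nc = names
    return {
        f"{na}_only": len(a - b - c),
        f"{nb}_only": len(b - a - c),
        f"{nc}_only": len(c - a - b),
        f"{na}_{nb}": len((a & b) - c),
        f"{na}_{nc}": len((a & c) - b),
        f"{nb}_{nc}": len((b & c) - a),
        f"{na}_{nb}_{nc}": len(a & b & c),
    }


def screen_tf(genes: list[str], tf_table: pd.DataFrame) -> pd.DataFrame:
    """Keep input genes annotated as transcription factors, grouped by family.

    ``tf_table`` has columns gene_id and family. Duplicated input ids are
    deduplicated before the join; output is sorted by descending family
    count then gene id.
    """
    if tf_table.empty:
        warnings.warn("empty TF annotation table", stacklevel=2)
        return pd.DataFrame(columns=["gene_id", "family"])
    uniq = list(dict.fromkeys(genes))
    hit = tf_table[tf_table["gene_id"].isin(uniq)][["gene_id", "family"]].drop_duplicates()
    counts = hit["family"].value_counts()
    hit = hit.assign(family_count=hit["family"].map(counts))
    return hit.sort_values(
        by=["family_count", "family", "gene_id"], ascending=[False, True, True]
    ).drop(columns="family_count").reset_index(drop=True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def hypergeometric_enrichment(
    query: list[str],
    collection: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query in gene sets.

    For a universe of N genes, a set of K, a query of n with overlap k:
    p = P[X >= k] under Hypergeom(N, K, n) and fold = (k/n)/(K/N).
    Set members outside the universe are dropped with a warning, as are
    query genes outside the universe. Rows sorted by p with BH FDR.
    """
    uni = set(universe)
    q = [g for g in dict.fromkeys(query) if g in uni]
    dropped = len(set(query)) - len(q)
    if dropped:
        warnings.warn(f"{dropped} query genes outside universe dropped", stacklevel=2)
    if not q:
        raise ValueError("empty query after universe restriction")
    N, n = len(uni), len(q)
    qset = set(q)
    rows = []
    for name, members in collection.items():
        mem = set(members) & uni
        if len(mem) < len(set(members)):
            warnings.warn(f"set {name!r}: members outside universe dropped", stacklevel=2)
        K = len(mem)
        k = len(mem & qset)
        fold = (k / n) / (K / N) if K else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {"set": name, "overlap": k, "query_size": n, "set_size": K,
             "universe_size": N, "fold_enrichment": fold, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    return df.sort_values(["p", "set"]).reset_index(drop=True)


def atlas_cross(
    genes_by_tissue: dict[str, list[str]], atlas_flags: pd.Series
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Restrict per-tissue gene lists to atlas-flagged (e.g. flower-specific) genes.

    ``atlas_flags`` maps gene id -> bool; genes absent from the table
    count as False and are tallied in the ``unmapped`` column of the
    summary. Returns (per-tissue filtered lists, summary table).
    """
    flags = atlas_flags.astype(bool)
    out: dict[str, list[str]] = {}
    rows = []
    for tissue, genes in genes_by_tissue.items():
        mapped = [g for g in genes if g in flags.index]
        kept = [g for g in mapped if flags[g]]
        out[tissue] = kept
        rows.append(
            {"tissue": tissue, "n_input": len(genes), "n_flagged": len(kept),
             "unmapped": len(genes) - len(mapped)}
        )
    return out, pd.DataFrame(rows).set_index("tissue")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: set name, description, then tab-separated members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
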