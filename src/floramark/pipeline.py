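"""End-to-end pipeline orchestration.

Runs the stages in method order — expression preparation, co-expression
network, tau specificity, integration, and (optionally) promoter motif
discovery — from a single configuration, writing machine-readable TSV
outputs, a JSON summary of the counts and tables each stage produced,
and a MANIFEST marking which stages completed. Fully deterministic given
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    coexpression_network as net,
    expression_prep as prep,
    integration,
    motif_discovery,
    synthetic_data,
    tau_specificity as tau_mod,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

log = logging.getLogger("floramark")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags controlling a pipeline run.

    The threshold defaults are the analysis constants of the emulated
    study: TPM > 1 expression filter, variance > 1 network filter,
    soft power 12 (or automatic scale-free selection), minimum module
    size 30, eigengene merge height 0.25, hub cut kME > 0.9, HSG
    tau >= 0.85, constitutive tau < 0.2, housekeeping TPM > 100,
    top-10 markers, and 8-mer motifs (10 motifs, 50 iterations).
    """

    # inputs (either counts+lengths or an expression matrix; all TSV)
    counts: str | None = None
    lengths: str | None = None
    expression: str | None = None
    design: str | None = None
    gene_sets: str | None = None
    tf_table: str | None = None
    atlas_flags: str | None = None
    promoters_fg: str | None = None
    promoters_bg: str | None = None

    # thresholds
    min_tpm: float = 1.0
    min_variance: float = 1.0
    beta: float | None = 12.0  # None -> automatic soft-threshold selection
    r2_cut: float = 0.9
    min_module_size: int = 30
    cut_height: float | None = None
    merge_height: float = 0.25
    mm_cut: float = 0.9
    hsg_cut: float = 0.85
    const_cut: float = 0.2
    hk_tau_max: float = 0.2
    hk_min_tpm: float = 100.0
    top_k: int = 10
    kmer: int = 8
    n_motifs: int = 10
    n_iter: int = 50

    seed: int = 0

    # flags
    tau_on_bins: bool = False
    sample_level_network: bool = False
    log2_transform: bool = True
    strict_expression_filter: bool = True
    expression_filter_mode: str = "any_tissue"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 <= self.hsg_cut <= 1 or not 0 <= self.const_cut <= 1:
            raise ValueError("tau thresholds must lie in [0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.merge_height <= 1:
            raise ValueError("merge_height must lie in [0, 1]")
        for name in ("counts", "lengths", "expression", "design", "gene_sets",
                     "tf_table", "atlas_flags", "promoters_fg", "promoters_bg"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p!r} does not exist")


def _load_inputs(config: PipelineConfig):
    if config.design is None:
        raise ValueError("a design table is required")
    design = pd.read_csv(config.design, sep="\t", comment="#")
    if config.expression is not None:
        expr = prep.read_expression_tsv(config.expression)
    elif config.counts is not None and config.lengths is not None:
        counts = prep.read_expression_tsv(config.counts)
        lengths = pd.read_csv(
            config.lengths, sep="\t", comment="#", index_col=0
        ).iloc[:, 0]
        expr = prep.counts_to_tpm(
            synthetic_data.CountMatrix(counts.astype(np.int64), lengths)
        )
    else:
        raise ValueError("provide either an expression matrix or counts + lengths")
    return expr, design


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute prep -> network -> tau -> integration -> motifs.

    Writes stage outputs under ``outdir`` and returns the summary dict
    (also written as summary.json). Raises StageError on failure, after
    writing a MANIFEST of the stages that completed.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {"config": {k: v for k, v in asdict(config).items()}}
    rng_seed = int(config.seed)

    def finish_manifest():
        (out / "MANIFEST").write_text(
            "\n".join(f"{s}\tcomplete" for s in completed) + "\n"
        )

    try:
        stage = "prep"
        log.info("stage %s", stage)
        expr, design = _load_inputs(config)
        profile = prep.tissue_means(expr, design)
        expressed = prep.filter_expressed(
            profile, config.min_tpm, config.expression_filter_mode,
            strict=config.strict_expression_filter,
        )
        net_genes = prep.filter_for_network(profile, config.min_tpm, config.min_variance)
        summary[stage] = {
            "n_genes_input": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
            "n_tissues": int(profile.shape[1]),
            "n_expressed": len(expressed),
            "n_network_genes": len(net_genes),
        }
        prep.write_expression_tsv(profile, out / "tissue_profile.tsv")
        completed.append(stage)

        stage = "network"
        log.info("stage %s", stage)
        if config.sample_level_network:
            mat = expr.loc[net_genes]
            traits = net.trait_indicators(list(mat.columns), design)
        else:
            mat = profile.loc[net_genes]
            traits = net.trait_indicators(list(mat.columns))
        if config.log2_transform:
            mat = np.log2(mat + 1.0)
        if config.beta is None:
            beta, fit_table = net.pick_soft_threshold(mat, r2_cut=config.r2_cut)
            fit_table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
        else:
            beta = float(config.beta)
        cor = np.nan_to_num(np.corrcoef(mat.to_numpy(dtype=float)), nan=0.0)
        adj = net.signed_adjacency(cor, beta)
        diss = net.topological_overlap(adj)
        labels = net.detect_modules(
            diss, min_size=config.min_module_size, cut_height=config.cut_height
        )
        if (labels != 0).any():
            labels = net.merge_modules(mat, labels, config.merge_height)
        modules = sorted(set(labels) - {0})
        if modules:
            me = net.module_eigengenes(mat, labels)
            kme, kme_p = net.module_membership(mat, me)
            rdf, pdf, best = net.module_trait_correlation(me, traits)
            hubs = net.hub_genes(kme, labels, config.mm_cut)
            me.to_csv(out / "eigengenes.tsv", sep="\t")
            rdf.to_csv(out / "module_trait_r.tsv", sep="\t")
            pdf.to_csv(out / "module_trait_p.tsv", sep="\t")
        else:
            me, kme, hubs, best = None, None, {}, {}
            warnings.warn("no modules detected", stacklevel=2)
        assign = pd.DataFrame({"module": labels}, index=mat.index)
        if kme is not None:
            own = [
                kme.at[g, f"ME{m}"] if m != 0 else np.nan
                for g, m in zip(mat.index, labels)
            ]
            assign["kME_own"] = own
        assign.to_csv(out / "modules.tsv", sep="\t")
        module_sizes = {int(m): int((labels == m).sum()) for m in modules}
        summary[stage] = {
            "beta": beta,
            "n_modules": len(modules),
            "module_sizes": module_sizes,
            "n_grey": int((labels == 0).sum()),
            "best_module_per_tissue": {t: b for t, b in best.items()},
            "n_hub_genes": {int(m): len(h) for m, h in hubs.items()},
        }
        completed.append(stage)

        stage = "tau"
        log.info("stage %s", stage)
        tau_profile = profile.loc[expressed]
        nonzero = tau_profile.max(axis=1) > 0
        tau_profile = tau_profile.loc[nonzero]
        table = tau_mod.build_tau_table(
            tau_profile,
            tau_on_bins=config.tau_on_bins,
            hsg_cut=config.hsg_cut,
            const_cut=config.const_cut,
        )
        markers = tau_mod.rank_optimum_genes(
            table.scores, table.summary["tau"], k=config.top_k
        )
        hk = tau_mod.housekeeping_genes(
            table.summary["tau_bin"], tau_profile,
            tau_max=config.hk_tau_max, min_tpm=config.hk_min_tpm,
        )
        table.summary.to_csv(out / "tau.tsv", sep="\t")
        hk.to_csv(out / "housekeeping.tsv", sep="\t")
        pd.concat(
            {t: m for t, m in markers.items()}, names=["tissue", "gene_id"]
        ).to_csv(out / "top_markers.tsv", sep="\t")
        klass = table.summary["klass"]
        summary[stage] = {
            "n_scored": int(table.summary.shape[0]),
            "n_asg": int((klass == "ASG").sum()),
            "n_hsg": int(klass.isin(["ASG", "HSG"]).sum()),
            "n_constitutive": int((klass == "constitutive").sum()),
            "n_housekeeping": int(hk.shape[0]),
        }
        completed.append(stage)

        stage = "integration"
        log.info("stage %s", stage)
        hsg_mask = klass.isin(["ASG", "HSG"])
        argmax_tissue = table.tau_ef.idxmax(axis=1)
        hsg_by_tissue = {
            t: list(table.summary.index[hsg_mask & (argmax_tissue == t)])
            for t in profile.columns
        }
        module_tissue_map = {
            t: int(b[2:]) for t, b in summary["network"]["best_module_per_tissue"].items()
        }
        key_hubs = integration.key_hub_genes(hsg_by_tissue, hubs, module_tissue_map)
        key_hubs.drop(columns="genes").to_csv(out / "key_hubs.tsv", sep="\t")
        summary[stage] = {
            "key_hub_counts": {t: int(n) for t, n in key_hubs["n"].items()},
            "key_hub_genes": {t: g for t, g in key_hubs["genes"].items()},
        }
        all_key = sorted({g for gl in key_hubs["genes"] for g in gl})
        all_hubs = sorted({g for h in hubs.values() for g in h})
        all_hsg = sorted(table.summary.index[hsg_mask])
        if config.atlas_flags is not None:
            flags = pd.read_csv(
                config.atlas_flags, sep="\t", comment="#", index_col=0
            ).iloc[:, 0]
            atlas_genes = list(flags.index[flags.astype(bool)])
            venn = integration.venn_overlap(
                atlas_genes, all_hsg, all_hubs, names=("atlas", "HSG", "WGCNA")
            )
            by_tissue, atlas_summary = integration.atlas_cross(
                {t: g for t, g in key_hubs["genes"].items()}, flags
            )
            (out / "venn.json").write_text(json.dumps(venn, indent=2))
            atlas_summary.to_csv(out / "atlas_cross.tsv", sep="\t")
            summary[stage]["venn"] = venn
            summary[stage]["atlas_specific_by_tissue"] = {
                t: len(g) for t, g in by_tissue.items()
            }
        if config.tf_table is not None:
            tf = pd.read_csv(config.tf_table, sep="\t", comment="#")
            tf_hits = integration.screen_tf(all_key or all_hsg, tf)
            tf_hits.to_csv(out / "tf_screen.tsv", sep="\t", index=False)
            summary[stage]["tf_family_counts"] = (
                tf_hits["family"].value_counts().to_dict()
            )
        if config.gene_sets is not None:
            sets = integration.read_gmt(config.gene_sets)
            query = all_key or all_hsg
            if query:
                enr = integration.hypergeometric_enrichment(
                    query, sets, list(profile.index)
                )
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                summary[stage]["n_enriched_fdr05"] = int((enr["fdr"] < 0.05).sum())
        completed.append(stage)

        if config.promoters_fg is not None and config.promoters_bg is not None:
            stage = "motifs"
            log.info("stage %s", stage)
            fg = _read_fasta(config.promoters_fg)
            bg = _read_fasta(config.promoters_bg)
            motifs = motif_discovery.discover_motifs(
                fg, bg, k=config.kmer, n_motifs=config.n_motifs, n_iter=config.n_iter
            )
            motif_discovery.write_meme(motifs, out / "motifs.meme")
            pd.concat(
                [m.sites.assign(motif=m.consensus) for m in motifs]
            ).to_csv(out / "motif_sites.tsv", sep="\t", index=False)
            summary[stage] = {
                "n_motifs": len(motifs),
                "consensi": [m.consensus for m in motifs],
                "n_confident": int(sum(not m.low_confidence for m in motifs)),
            }
            completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - report stage then re-raise
        finish_manifest()
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    summary["seed"] = rng_seed
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    finish_manifest()
    return summary


def _read_fasta(path) -> synthetic_data.PromoterSet:
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return synthetic_data.PromoterSet(ids, seqs)


def write_fasta(promoters: synthetic_data.PromoterSet, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(promoters.ids, promoters.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
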