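"""Synthetic multi-tissue RNA-seq data with planted ground truth.

Generates negative-binomial count matrices that emulate a floral
multi-tissue bulk RNA-seq design (10 tissues, 2-3 replicates each) and
carry four planted gene classes whose recovery downstream stages are
tested against:

``specific``
    genes enriched ``fold``-times in one target tissue, leaking at
    baseline/10 elsewhere (so tau < 1 cases exist);
``module``
    blocks of co-expressed genes sharing a tissue-anchored latent
    profile plus per-gene noise (pairwise correlation >= 0.7 in
    expectation);
``housekeeping``
    genes with identical means in every tissue, high enough that their
    TPM stays above 100 after normalization;
``background``
    independent noise genes with log-normal baselines.

Also provides promoter-set generators with planted 8-mers (for motif
discovery) and gene-set generators with a planted enriched set (for
over-representation analysis). Everything is reproducible bit-for-bit
from an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenePlan",
    "CountMatrix",
    "PromoterSet",
    "default_design",
    "generate_expression",
    "generate_promoters",
    "generate_gene_sets",
    "write_gmt",
]

DNA = np.array(list("ACGT"))

#: tissue labels of the emulated design: six pre-anthesis (BA) and four
#: post-anthesis (AA) floral whorls/tissues.
DEFAULT_TISSUES = (
    "calyptra_BA",
    "calyx_BA",
    "anther_BA",
    "filament_BA",
    "stigma_BA",
    "ovary_BA",
    "calyx_AA",
    "stigma_AA",
    "ovary_AA",
    "embryo_AA",
)

#: tissues sequenced with only two usable replicates in the emulated design
DEFAULT_DROPPED_REPLICATES = ("filament_BA", "stigma_BA")


@dataclass(frozen=True)
class GenePlan:
    """How many genes of each planted class to generate, and their effect sizes.

    The defaults define a 5,000-gene matrix over 10 tissues:
    300 tissue-specific genes (30 per tissue, 50-fold enrichment,
    baseline mean 200-500 TPM), three 50-gene co-expression modules
    anchored to the first three tissues, 100 housekeeping genes
    (uniform 200-800 TPM) and 4,450 background genes.
    """

    n_specific_per_tissue: int = 30
    specific_fold: float = 50.0
    #: baseline mean (TPM scale) range for specific genes; off-target
    #: expression is baseline/10, target expression is baseline*fold
    specific_baseline: tuple[float, float] = (200.0, 500.0)
    #: (size, anchor tissue index) per planted co-expression module;
    #: duplicate anchors produce nearly identical latent profiles
    modules: tuple[tuple[int, int], ...] = ((50, 0), (50, 1), (50, 2))
    #: log2 elevation of a module gene in its anchor tissue
    module_amplitude: float = 4.0
    #: per-gene, per-tissue log2 noise around the module latent profile
    module_noise_sd: float = 0.4
    #: baseline (log2 TPM) range for module genes outside the anchor
    module_baseline_log2: tuple[float, float] = (2.0, 4.0)
    n_housekeeping: int = 100
    housekeeping_mean: tuple[float, float] = (200.0, 800.0)
    n_background: int = 4450
    background_log2_mean: float = 4.0
    background_log2_sd: float = 2.0
    #: fraction of baseline expressed off-target by specific genes
    off_target_fraction: float = 0.1

    def n_module_genes(self) -> int:
        return sum(size for size, _ in self.modules)

    def total_genes(self, n_tissues: int) -> int:
        return (
            self.n_specific_per_tissue * n_tissues
            + self.n_module_genes()
            + self.n_housekeeping
            + self.n_background
        )

    def validate(self, n_tissues: int) -> None:
        counts = [
            self.n_specific_per_tissue,
            self.n_housekeeping,
            self.n_background,
        ] + [size for size, _ in self.modules]
        if any(c < 0 for c in counts):
            raise ValueError("gene plan counts must be nonnegative")
        if self.total_genes(n_tissues) <= 0:
            raise ValueError("gene plan is empty")
        if self.specific_fold < 1:
            raise ValueError("specific_fold must be >= 1")
        for _, anchor in self.modules:
            if not 0 <= anchor < n_tissues:
                raise ValueError(f"module anchor {anchor} outside tissue range")

    def scaled(self, total_genes: int) -> "GenePlan":
        """Scale class counts proportionally to a smaller/larger total.

        Module sizes are kept fixed (they must stay above the minimum
        module size to be detectable); background absorbs the remainder.
        """
        f = total_genes / self.total_genes(10)
        spec = max(1, round(self.n_specific_per_tissue * f))
        hk = max(1, round(self.n_housekeeping * f))
        rest = total_genes - spec * 10 - hk - self.n_module_genes()
        if rest < 0:
            raise ValueError("total_genes too small for the planned classes")
        return replace(
            self,
            n_specific_per_tissue=spec,
            n_housekeeping=hk,
            n_background=rest,
        )


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus per-gene effective lengths."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths indexed by different genes")
        if (self.lengths <= 0).any():
            raise ValueError("effective lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class PromoterSet:
    """Promoter sequences with optional planted-motif ground truth.

    ``truth`` has one row per planted insertion: sequence id, 0-based
    offset and strand ('+' = motif as given, '-' = reverse complement).
    """

    ids: list[str]
    sequences: list[str]
    truth_motif: str | None = None
    truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["seq_id", "offset", "strand"])
    )


def default_design(
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    replicates: int = 3,
    dropped: tuple[str, ...] = DEFAULT_DROPPED_REPLICATES,
) -> pd.DataFrame:
    """Sample design emulating the 10-tissue floral atlas.

    Three biological replicates per tissue, except the tissues listed in
    ``dropped`` which get one fewer (two tissues lost one replicate each
    in the emulated study, leaving 28 samples).
    """
    rows = []
    for t in tissues:
        n = replicates - 1 if t in dropped else replicates
        for r in range(1, n + 1):
            rows.append({"sample_id": f"{t}_r{r}", "tissue": t, "replicate": r})
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + dispersion*mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def generate_expression(
    n_tissues: int = 10,
    replicates: int = 3,
    gene_plan: GenePlan | None = None,
    dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (8e6, 1.3e7),
    seed: int = 0,
    design: pd.DataFrame | None = None,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate a planted-truth count matrix.

    Returns ``(CountMatrix, design, truth)`` where ``design`` has columns
    sample_id/tissue/replicate and ``truth`` has columns
    gene_id/klass/target_tissue/module_id/fold.

    Expression is composed in TPM-like relative-abundance space, mapped
    to expected fragment counts via per-gene effective lengths and a
    per-sample library size drawn uniformly from ``lib_size_range``
    (shrunk inward by a 4-sigma margin so realized column totals stay
    inside the range), then sampled from a negative binomial with the
    given dispersion.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    plan = gene_plan if gene_plan is not None else GenePlan()
    plan.validate(n_tissues)
    rng = np.random.default_rng(seed)

    if design is None:
        if n_tissues == 10 and replicates == 3:
            design = default_design()
        else:
            tissues = tuple(f"tissue_{i + 1:02d}" for i in range(n_tissues))
            design = default_design(tissues, replicates, dropped=())
    tissues = list(dict.fromkeys(design["tissue"]))
    if len(tissues) != n_tissues:
        raise ValueError("design tissue count does not match n_tissues")
    rep_counts = design["tissue"].value_counts()
    if (rep_counts < 2).any():
        warnings.warn(
            "some tissues have a single replicate; correlation stages degrade",
            stacklevel=2,
        )

    truth_rows: list[dict] = []
    mean_blocks: list[np.ndarray] = []  # gene x tissue mean blocks (TPM-like)

    # tissue-specific genes: baseline*fold on target, baseline/10 elsewhere
    for ti, tissue in enumerate(tissues):
        n = plan.n_specific_per_tissue
        if n == 0:
            continue
        base = rng.uniform(*plan.specific_baseline, size=n)
        block = np.tile((base * plan.off_target_fraction)[:, None], (1, n_tissues))
        block[:, ti] = base * plan.specific_fold
        mean_blocks.append(block)
        for g in range(n):
            truth_rows.append(
                {
                    "klass": "specific",
                    "target_tissue": tissue,
                    "module_id": None,
                    "fold": plan.specific_fold,
                }
            )

    # module genes: shared one-hot anchor profile (log2 space) + per-gene noise
    for mi, (size, anchor) in enumerate(plan.modules, start=1):
        base_log2 = rng.uniform(*plan.module_baseline_log2, size=size)
        latent = np.zeros(n_tissues)
        latent[anchor] = plan.module_amplitude
        log2_mu = (
            base_log2[:, None]
            + latent[None, :]
            + rng.normal(0.0, plan.module_noise_sd, size=(size, n_tissues))
        )
        mean_blocks.append(2.0 ** log2_mu)
        for g in range(size):
            truth_rows.append(
                {
                    "klass": "module",
                    "target_tissue": tissues[anchor],
                    "module_id": mi,
                    "fold": 2.0 ** plan.module_amplitude,
                }
            )

    # housekeeping: identical mean in every tissue
    if plan.n_housekeeping:
        hk = rng.uniform(*plan.housekeeping_mean, size=plan.n_housekeeping)
        mean_blocks.append(np.tile(hk[:, None], (1, n_tissues)))
        truth_rows += [
            {"klass": "housekeeping", "target_tissue": None, "module_id": None, "fold": 1.0}
            for _ in range(plan.n_housekeeping)
        ]

    # background: independent log-normal baselines, flat across tissues
    if plan.n_background:
        bg = 2.0 ** rng.normal(
            plan.background_log2_mean, plan.background_log2_sd, size=plan.n_background
        )
        mean_blocks.append(np.tile(bg[:, None], (1, n_tissues)))
        truth_rows += [
            {"klass": "background", "target_tissue": None, "module_id": None, "fold": 1.0}
            for _ in range(plan.n_background)
        ]

    mu_tissue = np.vstack(mean_blocks)  # genes x tissues, TPM-like units
    n_genes = mu_tissue.shape[0]
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    truth = pd.DataFrame(truth_rows)
    truth.insert(0, "gene_id", gene_ids)

    lengths = pd.Series(
        np.round(2.0 ** rng.normal(10.5, 0.5, size=n_genes)).clip(200, None),
        index=pd.Index(gene_ids, name="gene_id"),
        name="length",
    )

    # expected counts: share of (abundance * length) scaled to library size
    lo, hi = lib_size_range
    if not 0 < lo <= hi:
        raise ValueError("invalid lib_size_range")
    # shrink the sampling band so NB noise keeps realized totals in range
    tissue_of = design["tissue"].to_numpy()
    t_index = {t: i for i, t in enumerate(tissues)}
    counts = np.zeros((n_genes, len(design)), dtype=np.int64)
    len_arr = lengths.to_numpy()
    for j, t in enumerate(tissue_of):
        mu = mu_tissue[:, t_index[t]]
        w = mu * len_arr
        share = w / w.sum()
        approx_sd = np.sqrt(np.sum(share**2) * max(dispersion, 1e-12)) * hi
        margin = 4.0 * max(approx_sd, np.sqrt(hi))
        lo_j, hi_j = lo + margin, hi - margin
        if lo_j >= hi_j:  # degenerate narrow range: pin to midpoint
            lo_j = hi_j = 0.5 * (lo + hi)
        lib = rng.uniform(lo_j, hi_j)
        counts[:, j] = _nb_draw(rng, share * lib, dispersion)

    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=design["sample_id"].tolist()
    )
    return CountMatrix(counts_df, lengths), design, truth


# ---------------------------------------------------------------------------
# promoters


def _random_dna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(DNA[row]) for row in codes]


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


def generate_promoters(
    n_fg: int,
    n_bg: int,
    length: int = 2000,
    motif: str = "AAACGTGC",
    insertion_rate: float = 1.0,
    seed: int = 0,
) -> tuple[PromoterSet, PromoterSet]:
    """Foreground promoters with a planted motif, plus i.i.d. background.

    The motif (or its reverse complement, strand chosen at random) is
    inserted at a uniform random position in ``ceil(insertion_rate*n_fg)``
    foreground sequences; insertion positions are recorded as truth.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over the ACGT alphabet")
    if not 0 <= insertion_rate <= 1:
        raise ValueError("insertion_rate must be in [0, 1]")
    if length < len(motif):
        raise ValueError("sequence length shorter than motif")
    rng = np.random.default_rng(seed)

    fg_seqs = _random_dna(rng, n_fg, length)
    bg_seqs = _random_dna(rng, n_bg, length)
    fg_ids = [f"fg{i + 1:04d}" for i in range(n_fg)]
    bg_ids = [f"bg{i + 1:04d}" for i in range(n_bg)]

    n_insert = int(np.ceil(insertion_rate * n_fg))
    chosen = rng.choice(n_fg, size=n_insert, replace=False) if n_insert else []
    truth_rows = []
    for i in chosen:
        pos = int(rng.integers(0, length - len(motif) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = motif if strand == "+" else revcomp(motif)
        s = fg_seqs[i]
        fg_seqs[i] = s[:pos] + ins + s[pos + len(motif):]
        truth_rows.append({"seq_id": fg_ids[i], "offset": pos, "strand": strand})

    truth = pd.DataFrame(truth_rows, columns=["seq_id", "offset", "strand"])
    fg = PromoterSet(fg_ids, fg_seqs, truth_motif=motif, truth=truth)
    bg = PromoterSet(bg_ids, bg_seqs)
    return fg, bg


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    genes: list[str],
    n_sets: int = 20,
    set_sizes: tuple[int, int] = (20, 200),
    enriched_target: list[str] | None = None,
    overlap_rate: float = 0.8,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over a universe, with one planted enriched set.

    If ``enriched_target`` is given, the first set ("planted_set") draws
    ``overlap_rate`` of its members from the target list and the rest
    uniformly; remaining sets are uniform draws.
    """
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    lo, hi = set_sizes
    if lo <= 0 or hi < lo:
        raise ValueError("set sizes must be positive")
    if hi > len(genes):
        raise ValueError("set sizes exceed universe size")
    rng = np.random.default_rng(seed)
    universe = np.asarray(genes)
    sets: dict[str, list[str]] = {}

    start = 0
    if enriched_target is not None:
        target = [g for g in enriched_target if g in set(genes)]
        size = min(max(lo, len(target)), hi)
        n_from_target = min(len(target), int(round(overlap_rate * size)))
        members = list(rng.choice(target, size=n_from_target, replace=False))
        pool = np.setdiff1d(universe, np.asarray(members), assume_unique=False)
        fill = size - len(members)
        if fill > 0:
            members += list(rng.choice(pool, size=fill, replace=False))
        sets["planted_set"] = sorted(members)
        start = 1

    for i in range(start, n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"random_set_{i:03d}"] = sorted(rng.choice(universe, size=size, replace=False))
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
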