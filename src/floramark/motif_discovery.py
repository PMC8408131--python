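"""Discriminative k-mer motif discovery in promoter sets.

Greedy de novo discovery of fixed-length (default 8 bp) motifs enriched
in a foreground promoter set against a background: all k-mers are
counted on both strands, scored by a pseudocount log-odds of occurrence
rates with a sequence-level hypergeometric significance filter, and the
top k-mer is expanded into a position weight matrix from its
Hamming-distance-1 foreground sites; those sites are then masked and the
search repeats. Exactly ``n_motifs`` motifs are always reported (the
requested maximum), padding with the best remaining candidates flagged
low-confidence once no candidate clears the significance cut.

Also provides promoter extraction from a genome (2 kb upstream,
strand-aware) and ungapped column-correlation PWM matching against a
motif library (MEME-like text format).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import PromoterSet, revcomp

__all__ = [
    "MotifModel",
    "extract_promoters",
    "discover_motifs",
    "pwm_similarity",
    "match_motif_library",
    "write_meme",
    "read_meme",
]

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

BASES = "ACGT"


@dataclass
class MotifModel:
    """A discovered motif: consensus k-mer, PWM, and its evidence."""

    consensus: str
    pwm: np.ndarray  # 4 x k, columns sum to 1, rows ordered A,C,G,T
    enrichment: float  # log2 odds ratio of fg vs bg occurrence rates
    p: float  # hypergeometric tail p on sequence-level presence
    sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["seq_id", "offset", "strand"])
    )
    low_confidence: bool = False

    @property
    def k(self) -> int:
        return self.pwm.shape[1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_to_id(kmer: str) -> int:
    codes = _encode(kmer)
    if (codes < 0).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    return int(codes @ (4 ** np.arange(len(kmer) - 1, -1, -1)))


def _id_to_kmer(kid: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append(BASES[(kid >> (2 * j)) & 3])
    return "".join(out)


def _rc_map(k: int) -> np.ndarray:
    """Map every k-mer id to the id of its reverse complement."""
    ids = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(ids)
    tmp = ids.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


class _KmerIndex:
    """Per-sequence k-mer window ids with invalidation-aware counting."""

    def __init__(self, sequences: list[str], k: int):
        self.k = k
        powers = 4 ** np.arange(k - 1, -1, -1)
        self.codes = [_encode(s) for s in sequences]
        self.window_ids: list[np.ndarray] = []
        for c in self.codes:
            if len(c) < k:
                raise ValueError("sequence shorter than k")
            win = np.lib.stride_tricks.sliding_window_view(c, k)
            valid = (win >= 0).all(axis=1)
            ids = np.where(valid, win.astype(np.int64) @ powers, -1)
            self.window_ids.append(ids)

    def counts(self, rc: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
        """(occurrences, sequence presence, total windows, n sequences), both strands."""
        nk = len(rc)
        occ_fwd = np.zeros(nk, dtype=np.int64)
        presence = np.zeros(nk, dtype=np.int64)
        total = 0
        for ids in self.window_ids:
            valid = ids[ids >= 0]
            total += 2 * len(valid)
            if len(valid) == 0:
                continue
            occ_fwd += np.bincount(valid, minlength=nk)
            u = np.unique(valid)
            both = np.unique(np.concatenate([u, rc[u]]))
            presence[both] += 1
        occ = occ_fwd + occ_fwd[rc]
        return occ, presence, total, len(self.window_ids)

    def find_sites(self, kid: int, rc: np.ndarray, max_mismatch: int = 1):
        """(seq index, offset, strand) of windows within Hamming distance of kid."""
        neigh = _hamming_ball(kid, self.k, max_mismatch)
        neigh_set = np.zeros(len(rc), dtype=bool)
        neigh_set[neigh] = True
        rc_set = np.zeros(len(rc), dtype=bool)
        rc_set[rc[neigh]] = True
        sites = []
        for si, ids in enumerate(self.window_ids):
            valid = ids >= 0
            fwd = valid & neigh_set[np.clip(ids, 0, None)]
            rev = valid & rc_set[np.clip(ids, 0, None)] & ~fwd
            for pos in np.where(fwd)[0]:
                sites.append((si, int(pos), "+"))
            for pos in np.where(rev)[0]:
                sites.append((si, int(pos), "-"))
        return sites

    def mask(self, sites) -> None:
        """Invalidate all windows overlapping the given site positions."""
        k = self.k
        powers = 4 ** np.arange(k - 1, -1, -1)
        touched = set()
        for si, pos, _ in sites:
            self.codes[si][pos : pos + k] = -1
            touched.add(si)
        for si in touched:
            c = self.codes[si]
            win = np.lib.stride_tricks.sliding_window_view(c, k)
            valid = (win >= 0).all(axis=1)
            self.window_ids[si] = np.where(valid, win.astype(np.int64) @ powers, -1)


def _hamming_ball(kid: int, k: int, radius: int) -> np.ndarray:
    ids = {kid}
    frontier = {kid}
    for _ in range(radius):
        new = set()
        for x in frontier:
            for j in range(k):
                shift = 2 * (k - 1 - j)
                cur = (x >> shift) & 3
                for b in range(4):
                    if b != cur:
                        new.add((x & ~(3 << shift)) | (b << shift))
        ids |= new
        frontier = new
    return np.fromiter(ids, dtype=np.int64)


def _pwm_from_sites(index: _KmerIndex, sites, k: int, pseudocount: float) -> np.ndarray:
    counts = np.full((4, k), pseudocount, dtype=float)
    for si, pos, strand in sites:
        window = index.codes[si][pos : pos + k]
        if (window < 0).any():
            continue
        w = window if strand == "+" else 3 - window[::-1]
        for j, b in enumerate(w):
            counts[b, j] += 1.0
    return counts / counts.sum(axis=0, keepdims=True)


def _consensus(pwm: np.ndarray) -> str:
    return "".join(BASES[i] for i in pwm.argmax(axis=0))


def discover_motifs(
    fg: PromoterSet | list[str],
    bg: PromoterSet | list[str],
    k: int = 8,
    n_motifs: int = 10,
    n_iter: int = 50,
    pseudocount: float = 1.0,
    candidate_p: float = 1e-6,
) -> list[MotifModel]:
    """Greedy discriminative k-mer motif discovery.

    ``candidate_p`` is the sequence-level hypergeometric cut a k-mer must
    clear to count as a confident candidate (the default is a
    Bonferroni-style 0.05 / 4^8). Always returns exactly ``n_motifs``
    motifs; once the confident candidates are exhausted the remaining
    slots are filled with the best-scoring leftover k-mers flagged
    ``low_confidence``. ``n_iter`` bounds the total number of
    selection/refinement passes.
    """
    fg_seqs = fg.sequences if isinstance(fg, PromoterSet) else list(fg)
    bg_seqs = bg.sequences if isinstance(bg, PromoterSet) else list(bg)
    fg_ids = fg.ids if isinstance(fg, PromoterSet) else [f"fg{i}" for i in range(len(fg_seqs))]
    if len(fg_seqs) < 5:
        raise ValueError("need at least 5 foreground sequences")
    if len(bg_seqs) < len(fg_seqs):
        raise ValueError("background must be at least as large as foreground")
    if any(len(s) < k for s in fg_seqs + bg_seqs):
        raise ValueError("all sequences must be at least k long")

    rc = _rc_map(k)
    fg_index = _KmerIndex(fg_seqs, k)
    bg_index = _KmerIndex(bg_seqs, k)
    occ_bg, pres_bg, wbg, nbg = bg_index.counts(rc)
    nfg = len(fg_seqs)
    ntot = nfg + nbg

    emitted: list[MotifModel] = []
    emitted_ids: set[int] = set()
    iters = 0
    while len(emitted) < n_motifs and iters < n_iter:
        iters += 1
        occ_fg, pres_fg, wfg, _ = fg_index.counts(rc)
        with np.errstate(divide="ignore"):
            score = np.log2((occ_fg + pseudocount) / (wfg + pseudocount)) - np.log2(
                (occ_bg + pseudocount) / (wbg + pseudocount)
            )
        present_total = pres_fg + pres_bg
        pvals = stats.hypergeom.sf(pres_fg - 1, ntot, present_total, nfg)
        pvals = np.where(pres_fg == 0, 1.0, pvals)
        blocked = np.zeros(len(rc), dtype=bool)
        for kid in emitted_ids:
            blocked[kid] = True
            blocked[rc[kid]] = True
        confident = (pvals < candidate_p) & (score > 0) & ~blocked
        if confident.any():
            cand = np.where(confident)[0]
            low_conf = False
        else:
            cand = np.where(~blocked & (occ_fg + occ_bg > 0))[0]
            if len(cand) == 0:
                break
            low_conf = True
        kid = int(cand[np.argmax(score[cand])])
        kid = min(kid, int(rc[kid]))  # canonical strand of the pair

        sites = fg_index.find_sites(kid, rc, max_mismatch=1)
        if sites:
            pwm = _pwm_from_sites(fg_index, sites, k, pseudocount)
        else:
            pwm = _pwm_from_sites(fg_index, [], k, pseudocount)
            codes = _encode(_id_to_kmer(kid, k))
            for j, b in enumerate(codes):
                pwm[b, j] += 0.5
            pwm = pwm / pwm.sum(axis=0, keepdims=True)
        site_df = pd.DataFrame(
            [(fg_ids[si], pos, strand) for si, pos, strand in sites],
            columns=["seq_id", "offset", "strand"],
        )
        emitted.append(
            MotifModel(
                consensus=_id_to_kmer(kid, k),
                pwm=pwm,
                enrichment=float(score[kid]),
                p=float(pvals[kid]),
                sites=site_df,
                low_confidence=low_conf,
            )
        )
        emitted_ids.add(kid)
        if sites:
            fg_index.mask(sites)
    if len(emitted) < n_motifs:
        warnings.warn(
            f"iteration budget exhausted after {len(emitted)} motifs", stacklevel=2
        )
    return emitted[:n_motifs]


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoters(
    genome: dict[str, str], coordinates: pd.DataFrame, length: int = 2000
) -> PromoterSet:
    """Strand-aware upstream sequences from a genome.

    ``coordinates`` is BED-like (chrom, start, end, name, score, strand;
    0-based half-open). For + genes the promoter is [start-length, start);
    for - genes it is [end, end+length) reverse-complemented. Sequences
    are truncated at contig bounds with a warning; genes on missing
    contigs are skipped with a warning. Uppercase output.
    """
    ids, seqs = [], []
    for row in coordinates.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        strand = getattr(row, "strand", "+")
        name = getattr(row, "name", f"{chrom}:{start}-{end}")
        if chrom not in genome:
            warnings.warn(f"gene {name!r}: contig {chrom!r} missing; skipped", stacklevel=2)
            continue
        contig = genome[chrom]
        if strand == "+":
            lo, hi = start - length, start
            if lo < 0:
                warnings.warn(f"gene {name!r}: promoter truncated at contig start",
                              stacklevel=2)
                lo = 0
            seq = contig[lo:hi].upper()
        else:
            lo, hi = end, end + length
            if hi > len(contig):
                warnings.warn(f"gene {name!r}: promoter truncated at contig end",
                              stacklevel=2)
                hi = len(contig)
            seq = revcomp(contig[lo:hi].upper())
        if not seq:
            warnings.warn(f"gene {name!r}: empty promoter; skipped", stacklevel=2)
            continue
        ids.append(name)
        seqs.append(seq)
    return PromoterSet(ids, seqs)


# ---------------------------------------------------------------------------
# PWM comparison


def _pwm_rc(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability columns; 0 if either is uniform."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pwm_similarity(
    pwm_a: np.ndarray, pwm_b: np.ndarray, min_overlap: int = 4
) -> tuple[float, int, str]:
    """Best ungapped alignment score between two column-stochastic PWMs.

    Slides ``pwm_b`` (both orientations) against ``pwm_a`` over all
    offsets with at least ``min_overlap`` aligned columns; the score is
    the mean column-wise Pearson correlation (zero-variance columns
    contribute 0). Returns (score, offset of b relative to a, strand).
    """
    a = np.asarray(pwm_a, dtype=float)
    ka, kb = a.shape[1], np.asarray(pwm_b).shape[1]
    if not (np.allclose(a.sum(axis=0), 1.0, atol=1e-6)):
        raise ValueError("pwm_a columns must sum to 1")
    if min(ka, kb) < min_overlap:
        raise ValueError("PWMs too short for the required overlap")
    best = (-np.inf, 0, "+")
    for strand in "+-":
        b = np.asarray(pwm_b, dtype=float) if strand == "+" else _pwm_rc(
            np.asarray(pwm_b, dtype=float)
        )
        if not np.allclose(b.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("pwm_b columns must sum to 1")
        for offset in range(-(kb - min_overlap), ka - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(ka, offset + kb)
            cols = hi_a - lo_a
            if cols < min_overlap:
                continue
            sub_a = a[:, lo_a:hi_a]
            sub_b = b[:, lo_a - offset : hi_a - offset]
            score = float(
                np.mean([_column_corr(sub_a[:, j], sub_b[:, j]) for j in range(cols)])
            )
            key = (score, strand == "+", -abs(offset))
            best_key = (best[0], best[2] == "+", -abs(best[1]))
            if key > best_key:
                best = (score, offset, strand)
    return best


def match_motif_library(
    motif: MotifModel | np.ndarray,
    library: dict[str, np.ndarray],
    top_n: int = 5,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Rank library PWMs by similarity to a query motif."""
    if not library:
        raise ValueError("empty motif library")
    query = motif.pwm if isinstance(motif, MotifModel) else np.asarray(motif)
    rows = []
    for name, pwm in library.items():
        try:
            score, offset, strand = pwm_similarity(query, pwm, min_overlap)
        except ValueError:
            continue
        rows.append({"name": name, "score": score, "offset": offset, "strand": strand})
    df = pd.DataFrame(rows).sort_values(["score", "name"], ascending=[False, True])
    return df.head(top_n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# minimal MEME-like text format


def write_meme(motifs: list[MotifModel] | dict[str, np.ndarray], path) -> None:
    if isinstance(motifs, dict):
        items = [(name, pwm, None) for name, pwm in motifs.items()]
    else:
        items = [(m.consensus, m.pwm, m) for m in motifs]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for name, pwm, m in items:
            fh.write(f"MOTIF {name}\n")
            extra = ""
            if m is not None:
                extra = f" E= {m.p:.3g}"
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.shape[1]}{extra}\n"
            )
            for col in pwm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, np.ndarray]:
    library: dict[str, np.ndarray] = {}
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name and rows:
                    library[name] = np.array(rows, dtype=float).T
                name = line.split()[1]
                rows = []
            elif name and line and (line[0].isdigit() or line[0] == "."):
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
    if name and rows:
        library[name] = np.array(rows, dtype=float).T
    return library
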