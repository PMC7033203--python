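"""Paralog-divergence statistics and collinearity analysis.

Whole-genome duplications leave two genome-wide signatures: a peak in
the divergence distribution of paralog pairs (measured here as NG86
synonymous substitutions per synonymous site, Ks, and as 4DTv, the
transversion proportion at fourfold-degenerate third-codon sites) and a
characteristic syntenic depth (the number of regions in one genome that
align to a single region of another — 2 for a duplication, 3 for a
triplication). Ks converts to absolute time through the molecular clock
T = Ks / (2 r), with r the per-site substitution rate per year.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import EUDICOT_SUBST_RATE

logger = logging.getLogger(__name__)

BASES = "ACGT"
PURINES = frozenset("AG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# dinucleotide prefixes whose third codon position is fourfold degenerate
FOURFOLD_PREFIXES = frozenset({"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"})

_CODON_TABLE: dict[str, str] = {}


def _standard_code() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


class SaturationError(ValueError):
    """Raised when a divergence statistic is undefined (saturated input)."""


@dataclass(frozen=True)
class CodonPairAlignment:
    """Gap-free, in-frame aligned coding-sequence pair."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.pair_id}: unequal sequence lengths")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.pair_id}: length not a multiple of 3")
        for seq, tag in ((self.seq_a, "a"), (self.seq_b, "b")):
            if set(seq) - set(BASES):
                raise ValueError(f"{self.pair_id}/{tag}: non-ACGT characters (gaps?)")
            for i in range(0, len(seq) - 3, 3):
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(f"{self.pair_id}/{tag}: internal stop at codon {i // 3 + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass(frozen=True)
class KsResult:
    pair_id: str
    Ks: float | None
    Ka: float | None
    fourdtv: float | None
    T_mya: float | None
    saturated: bool


# -- fourfold-degenerate transversion rate --------------------------------

def fourfold_sites(p: CodonPairAlignment) -> list[int]:
    """0-based codon indices that are fourfold-degenerate in both sequences.

    A codon qualifies when the two sequences agree on the first two bases
    and that prefix makes the third position fourfold degenerate under the
    standard genetic code.
    """
    sites = []
    for idx, (ca, cb) in enumerate(p.codons()):
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            sites.append(idx)
    return sites


def _is_transversion(x: str, y: str) -> bool:
    return (x in PURINES) != (y in PURINES)


def fourdtv(p: CodonPairAlignment) -> float:
    """Proportion of fourfold-degenerate sites differing by a transversion."""
    sites = fourfold_sites(p)
    if not sites:
        raise SaturationError(f"{p.pair_id}: no fourfold-degenerate sites")
    tv = 0
    for idx in sites:
        a = p.seq_a[3 * idx + 2]
        b = p.seq_b[3 * idx + 2]
        if a != b and _is_transversion(a, b):
            tv += 1
    return tv / len(sites)


# -- NG86 Ka/Ks ------------------------------------------------------------

@lru_cache(maxsize=1)
def _site_counts() -> dict[str, float]:
    """Synonymous site count per codon (changes to stops count nonsynonymous)."""
    code = _standard_code()
    counts = {}
    for codon, aa in code.items():
        if aa == "*":
            continue
        syn = 0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if code[mut] == aa:       # stop codons translate to '*', never equal
                    syn += 1
        counts[codon] = syn / 3.0
    return counts


@lru_cache(maxsize=1)
def _pair_differences() -> dict[tuple[str, str], tuple[float, float]]:
    """Average (synonymous, nonsynonymous) differences per codon pair.

    Averaged over all minimal mutational pathways between the two codons;
    pathways passing through a stop codon are excluded. The rare codon
    pair whose pathways all hit stops maps to None and is skipped with a
    warning at computation time.
    """
    code = _standard_code()
    sense = [c for c in code if code[c] != "*"]
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for c1 in sense:
        for c2 in sense:
            diff_pos = [i for i in range(3) if c1[i] != c2[i]]
            if not diff_pos:
                table[(c1, c2)] = (0.0, 0.0)
                continue
            path_counts = []
            for order in itertools.permutations(diff_pos):
                current = c1
                sd = nd = 0
                blocked = False
                for pos in order:
                    nxt = current[:pos] + c2[pos] + current[pos + 1:]
                    if code[nxt] == "*":
                        blocked = True
                        break
                    if code[nxt] == code[current]:
                        sd += 1
                    else:
                        nd += 1
                    current = nxt
                if not blocked:
                    path_counts.append((sd, nd))
            if path_counts:
                table[(c1, c2)] = (
                    sum(s for s, _ in path_counts) / len(path_counts),
                    sum(n for _, n in path_counts) / len(path_counts),
                )
            else:
                table[(c1, c2)] = None  # type: ignore[assignment]
    return table


def _jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        raise SaturationError("proportion of differences at or beyond saturation (3/4)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ks_ng86(p: CodonPairAlignment, rate: float = EUDICOT_SUBST_RATE) -> KsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences; observed differences are classified by averaging over
    minimal mutational pathways. Ks = -(3/4) ln(1 - 4 pS / 3); the pair
    is flagged saturated when pS >= 3/4. T_mya applies the molecular
    clock T = Ks / (2 r) in million years.
    """
    sites = _site_counts()
    pairs = _pair_differences()
    S = N = Sd = Nd = 0.0
    for ca, cb in p.codons():
        s_site = (sites[ca] + sites[cb]) / 2.0
        S += s_site
        N += 3.0 - s_site
        d = pairs[(ca, cb)]
        if d is None:
            logger.warning("%s: codon pair %s/%s has no stop-free pathway; skipped",
                           p.pair_id, ca, cb)
            continue
        Sd += d[0]
        Nd += d[1]
    if S <= 0:
        raise SaturationError(f"{p.pair_id}: no synonymous sites")
    pS = Sd / S
    pN = Nd / N if N > 0 else 0.0
    try:
        four = fourdtv(p)
    except SaturationError:
        four = None
    if pS >= 0.75:
        return KsResult(p.pair_id, None, None, four, None, saturated=True)
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN) if pN < 0.75 else None
    return KsResult(p.pair_id, Ks, Ka, four, ks_to_time(Ks, rate), saturated=False)


def ks_to_time(Ks: float, r: float = EUDICOT_SUBST_RATE) -> float:
    """Molecular-clock conversion T = Ks / (2 r), in million years."""
    if Ks < 0:
        raise ValueError("Ks must be non-negative")
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return Ks / (2.0 * r) / 1e6


# -- distribution peaks ----------------------------------------------------

def detect_peaks(values: Sequence[float], bandwidth: float | str | None = None,
                 prominence_floor: float = 0.1, grid_size: int = 512) -> list[float]:
    """Modes of a Gaussian kernel density estimate, sorted ascending.

    bandwidth is passed to scipy's gaussian_kde bw_method (None = Scott's
    rule). Local maxima below prominence_floor times the global density
    maximum are discarded as ripple.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 20:
        raise ValueError(f"need at least 20 values, got {len(vals)}")
    kde = stats.gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    dens = kde(grid)
    floor = prominence_floor * dens.max()
    modes = []
    for i in range(1, grid_size - 1):
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1] and dens[i] >= floor:
            modes.append(float(grid[i]))
    return sorted(modes)


# -- gene order, collinearity, syntenic depth ------------------------------

class GeneOrder:
    """Ordered gene lists per chromosome with 1-based ranks."""

    def __init__(self, genome: str, chromosomes: Mapping[str, Sequence[str]]):
        self.genome = genome
        self.chromosomes = {c: list(genes) for c, genes in chromosomes.items()}
        self.rank: dict[str, tuple[str, int]] = {}
        for chrom, genes in self.chromosomes.items():
            for i, g in enumerate(genes, start=1):
                if g in self.rank:
                    raise ValueError(f"duplicate gene id {g!r} in genome {genome}")
                self.rank[g] = (chrom, i)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rank)

    @classmethod
    def from_tsv(cls, path: str | Path, genome: str | None = None) -> "GeneOrder":
        df = pd.read_csv(path, sep="\t")
        if genome is not None:
            df = df[df["genome"] == genome]
        else:
            genomes = df["genome"].unique()
            if len(genomes) != 1:
                raise ValueError(f"file holds several genomes {list(genomes)}; pass genome=")
            genome = genomes[0]
        chroms: dict[str, list[str]] = {}
        for chrom, sub in df.sort_values(["chrom", "rank"]).groupby("chrom", sort=True):
            chroms[str(chrom)] = sub["gene_id"].tolist()
        return cls(str(genome), chroms)

    def to_tsv(self, path: str | Path, mode: str = "w") -> None:
        rows = [(self.genome, chrom, i, g)
                for chrom, genes in sorted(self.chromosomes.items())
                for i, g in enumerate(genes, start=1)]
        df = pd.DataFrame(rows, columns=["genome", "chrom", "rank", "gene_id"])
        df.to_csv(path, sep="\t", index=False, mode=mode, header=(mode == "w"))


@dataclass
class SyntenyBlock:
    """Monotone chain of homologous gene pairs between two chromosomes."""

    chrom_a: str
    chrom_b: str
    pairs: list[tuple[str, str, int, int]]   # (gene_a, gene_b, rank_a, rank_b)
    orientation: int                          # +1 or -1

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def rank_interval_a(self) -> tuple[int, int]:
        ranks = [ra for _, _, ra, _ in self.pairs]
        return min(ranks), max(ranks)

    @property
    def rank_interval_b(self) -> tuple[int, int]:
        ranks = [rb for _, _, _, rb in self.pairs]
        return min(ranks), max(ranks)


def _longest_chain(points: list[tuple[int, int, int]], max_gap: int,
                   orientation: int) -> list[int]:
    """Longest monotone chain over (rank_a, rank_b, idx) with bounded gaps.

    O(n^2) dynamic program; deterministic tie-break toward the leftmost
    start. Returns indices into the points list.
    """
    pts = sorted(range(len(points)), key=lambda k: (points[k][0], orientation * points[k][1]))
    best_len = [1] * len(pts)
    prev = [-1] * len(pts)
    for i_pos, i in enumerate(pts):
        ra_i, rb_i, _ = points[i]
        for j_pos in range(i_pos):
            j = pts[j_pos]
            ra_j, rb_j, _ = points[j]
            da = ra_i - ra_j
            db = (rb_i - rb_j) * orientation
            if 0 < da <= max_gap and 0 < db <= max_gap:
                if best_len[j_pos] + 1 > best_len[i_pos]:
                    best_len[i_pos] = best_len[j_pos] + 1
                    prev[i_pos] = j_pos
    if not pts:
        return []
    end = max(range(len(pts)), key=lambda k: (best_len[k], -points[pts[k]][0]))
    chain = []
    k = end
    while k != -1:
        chain.append(pts[k])
        k = prev[k]
    chain.reverse()
    return chain


def collinear_blocks(order_a: GeneOrder, order_b: GeneOrder,
                     homologs: Iterable[tuple[str, str]],
                     min_genes: int = 5, max_gap: int = 10) -> list[SyntenyBlock]:
    """Greedy extraction of monotone homolog chains as syntenic blocks.

    Within each chromosome pair, the longest chain (ranks strictly
    monotone on both genomes, adjacent gaps at most max_gap ranks) is
    extracted, its pairs removed, and the search repeated until no chain
    of min_genes pairs remains. Both orientations are considered; ties go
    to the forward orientation and leftmost start.
    """
    by_chrom_pair: dict[tuple[str, str], list[tuple[str, str, int, int]]] = {}
    for ga, gb in homologs:
        if ga not in order_a.rank or gb not in order_b.rank:
            logger.warning("homolog pair (%s, %s) has unknown gene; skipped", ga, gb)
            continue
        ca, ra = order_a.rank[ga]
        cb, rb = order_b.rank[gb]
        by_chrom_pair.setdefault((ca, cb), []).append((ga, gb, ra, rb))

    blocks: list[SyntenyBlock] = []
    for (ca, cb), pair_list in sorted(by_chrom_pair.items()):
        remaining = list(pair_list)
        while len(remaining) >= min_genes:
            points = [(ra, rb, k) for k, (_, _, ra, rb) in enumerate(remaining)]
            fwd = _longest_chain(points, max_gap, orientation=+1)
            rev = _longest_chain(points, max_gap, orientation=-1)
            chain_idx, orientation = (fwd, +1) if len(fwd) >= len(rev) else (rev, -1)
            if len(chain_idx) < min_genes:
                break
            chosen = [remaining[points[k][2]] for k in chain_idx]
            blocks.append(SyntenyBlock(ca, cb, chosen, orientation))
            taken = {points[k][2] for k in chain_idx}
            remaining = [p for k, p in enumerate(remaining) if k not in taken]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.rank_interval_a[0]))
    return blocks


def syntenic_depth(blocks: Iterable[SyntenyBlock], reference: GeneOrder,
                   ) -> tuple[dict[str, int], dict[int, int]]:
    """Per-reference-gene syntenic depth and its histogram.

    A reference gene's depth is the number of distinct query blocks whose
    reference-side rank interval covers its rank (intervals inclusive on
    both ends).
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        intervals.setdefault(b.chrom_a, []).append(b.rank_interval_a)
    depth: dict[str, int] = {}
    for gene, (chrom, rank) in reference.rank.items():
        depth[gene] = sum(lo <= rank <= hi for lo, hi in intervals.get(chrom, []))
    hist: dict[int, int] = {}
    for d in depth.values():
        hist[d] = hist.get(d, 0) + 1
    return depth, hist


def modal_depth(hist: Mapping[int, int], min_depth: int = 1) -> int:
    """Most frequent depth at or above min_depth (ties -> smaller depth)."""
    eligible = {d: c for d, c in hist.items() if d >= min_depth}
    if not eligible:
        raise ValueError("no genes at or above the requested minimum depth")
    return min(sorted(eligible), key=lambda d: (-eligible[d], d))


# -- I/O -------------------------------------------------------------------

def ks_results_to_tsv(results: Iterable[KsResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.pair_id, r.Ks, r.Ka, r.fourdtv, r.T_mya, int(r.saturated)) for r in results],
        columns=["pair_id", "Ks", "Ka", "fourdtv", "T_mya", "saturated"])
    df.to_csv(path, sep="\t", index=False)


def blocks_to_tsv(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    rows = []
    for b in blocks:
        (a0, a1), (b0, b1) = b.rank_interval_a, b.rank_interval_b
        rows.append((b.chrom_a, b.chrom_b, a0, a1, b0, b1, b.length,
                     "+" if b.orientation > 0 else "-"))
    df = pd.DataFrame(rows, columns=["chrA", "chrB", "start_rankA", "end_rankA",
                                     "start_rankB", "end_rankB", "n_pairs", "orientation"])
    df.to_csv(path, sep="\t", index=False)


def read_homolog_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_homolog_pairs(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)
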