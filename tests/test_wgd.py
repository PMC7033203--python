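"""Divergence statistics: fourfold sites, 4DTv, NG86 Ks, peaks, collinearity."""

import itertools
import math
import warnings

import numpy as np
import pytest

from triptofunnel.config import SimulationConfig
from triptofunnel.synthetic import gen_paralog_pairs, gen_triplicated_map
from triptofunnel.wgd import (CodonPairAlignment, GeneOrder, SaturationError,
                              collinear_blocks, detect_peaks, fourdtv,
                              fourfold_sites, ks_ng86, ks_to_time, modal_depth,
                              syntenic_depth)

BASES = "ACGT"


def _random_pair(rng, n_codons=100, p_diff=0.2):
    """Random stop-free codon pair with independent per-site differences."""
    from triptofunnel.synthetic import _SENSE_CODONS

    stops = {"TAA", "TAG", "TGA"}
    a = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))
    b_codons = []
    for k in range(n_codons):
        codon = a[3 * k:3 * k + 3]
        while True:
            mutated = "".join(
                rng.choice([x for x in BASES if x != c]) if rng.random() < p_diff else c
                for c in codon)
            if mutated not in stops:
                break
        b_codons.append(mutated)
    return CodonPairAlignment("t", a, "".join(b_codons))


# -- fourfold sites and 4DTv ----------------------------------------------

def _fourfold_oracle(pair):
    """Lookup-table scan: third position fourfold iff all 4 codons code one AA."""
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    for s in standard_dna_table.stop_codons:
        code[s] = "*"
    sites = []
    for idx in range(pair.n_codons):
        ca = pair.seq_a[3 * idx:3 * idx + 3]
        cb = pair.seq_b[3 * idx:3 * idx + 3]
        if ca[:2] != cb[:2]:
            continue
        aas = {code[ca[:2] + b] for b in BASES}
        if len(aas) == 1 and "*" not in aas:
            sites.append(idx)
    return sites


def test_fourfold_site_identification():
    p = CodonPairAlignment("x", "GGTATG", "GGCATG")
    assert fourfold_sites(p) == [0]  # GG prefix is fourfold, AT is not


@pytest.mark.parametrize("seed", range(5))
def test_fourfold_sites_match_codon_table_oracle(seed):
    rng = np.random.default_rng(seed)
    for _ in range(10):
        pair = _random_pair(rng, n_codons=300)
        assert fourfold_sites(pair) == _fourfold_oracle(pair)


def test_fourdtv_identical_sequences_is_zero():
    p = CodonPairAlignment("x", "GGTGCCACA", "GGTGCCACA")
    assert fourdtv(p) == 0.0


def test_fourdtv_single_transversion_fraction():
    # ten 4D codons, one A<->C third-base transversion
    a = "GGA" + "GGT" * 9
    b = "GGC" + "GGT" * 9
    assert fourdtv(CodonPairAlignment("x", a, b)) == pytest.approx(0.1)


def test_fourdtv_matches_counting_oracle(rng):
    purines = set("AG")
    for _ in range(50):
        pair = _random_pair(rng, n_codons=200)
        sites = _fourfold_oracle(pair)
        if not sites:
            continue
        tv = sum((pair.seq_a[3 * i + 2] in purines) != (pair.seq_b[3 * i + 2] in purines)
                 and pair.seq_a[3 * i + 2] != pair.seq_b[3 * i + 2] for i in sites)
        assert fourdtv(pair) == pytest.approx(tv / len(sites), abs=1e-12)


def test_fourdtv_errors_without_fourfold_sites():
    with pytest.raises(SaturationError):
        fourdtv(CodonPairAlignment("x", "ATGATGATGATG", "ATGATGATGATG"))


def test_fourdtv_symmetry(rng):
    for _ in range(10):
        p = _random_pair(rng, n_codons=100)
        q = CodonPairAlignment(p.pair_id, p.seq_b, p.seq_a)
        assert fourdtv(p) == pytest.approx(fourdtv(q), abs=1e-12)


# -- NG86 ------------------------------------------------------------------

def test_ks_zero_on_identical_sequences():
    p = CodonPairAlignment("x", "GGTGCCACA" * 5, "GGTGCCACA" * 5)
    res = ks_ng86(p)
    assert res.Ks == 0.0 and res.Ka == 0.0 and not res.saturated


def test_ks_hand_computed_toy_pair():
    """One synonymous transition among ten GGN codons: pS = 0.1.

    Each GGN codon has exactly one synonymous site (its third position),
    so S = 10, Sd = 1, and Ks = -(3/4) ln(1 - 0.4/3) ~ 0.1073.
    """
    a = "GGT" + "GGT" * 9
    b = "GGC" + "GGT" * 9
    res = ks_ng86(CodonPairAlignment("x", a, b))
    assert res.Ks == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-12)
    assert res.Ka == 0.0


def test_ks_agrees_with_independent_ng86(rng):
    """Cross-check against Biopython's NG86 counting on random pairs.

    The two implementations weight stop-blocked mutational pathways
    slightly differently, so agreement is to a small tolerance rather
    than exact.
    """
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    for _ in range(10):
        pair = _random_pair(rng, n_codons=200, p_diff=0.15)
        mine = ks_ng86(pair)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dN, dS = cal_dn_ds(CodonSeq(pair.seq_a), CodonSeq(pair.seq_b), method="NG86")
        assert mine.Ks == pytest.approx(dS, abs=0.02)
        assert mine.Ka == pytest.approx(dN, abs=0.02)


def test_ks_symmetry(rng):
    for _ in range(10):
        p = _random_pair(rng, n_codons=100)
        q = CodonPairAlignment(p.pair_id, p.seq_b, p.seq_a)
        assert ks_ng86(p).Ks == pytest.approx(ks_ng86(q).Ks, abs=1e-12)


def test_ks_recovers_simulation_truth():
    """Mean Ks over simulated pairs approaches 2*T*r within sampling error."""
    cfg = SimulationConfig(seed=3, paralog_pairs=100, n_codons=1000,
                           true_divergence_times_mya=(21.0,))
    pairs, _ = gen_paralog_pairs(cfg)
    ks = np.array([ks_ng86(p).Ks for p in pairs])
    expected = 2 * 21e6 * cfg.subst_rate_per_site_per_year
    assert abs(ks.mean() - expected) < 3 * ks.std(ddof=1) / np.sqrt(len(ks))


@pytest.mark.parametrize("t_true", [5.0, 21.0, 50.0])
def test_clock_parameter_recovery(t_true):
    cfg = SimulationConfig(seed=11, paralog_pairs=150, n_codons=1000,
                           true_divergence_times_mya=(t_true,))
    pairs, _ = gen_paralog_pairs(cfg)
    t_hat = np.median([ks_ng86(p).T_mya for p in pairs])
    assert abs(t_hat - t_true) / t_true < 0.10


# -- clock conversion ------------------------------------------------------

def test_ks_to_time_examples():
    assert ks_to_time(0.0) == 0.0
    assert ks_to_time(0.13, 6.5e-9) == pytest.approx(10.0)
    assert ks_to_time(0.273, 6.5e-9) == pytest.approx(21.0)


def test_ks_to_time_is_linear(rng):
    for _ in range(20):
        k = float(rng.uniform(0, 2))
        assert ks_to_time(2 * k) == pytest.approx(2 * ks_to_time(k), rel=1e-12)


def test_ks_to_time_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ks_to_time(-0.1)
    with pytest.raises(ValueError):
        ks_to_time(0.1, r=0.0)


# -- distribution peaks ----------------------------------------------------

def test_detect_peaks_single_gaussian():
    rng = np.random.default_rng(5)
    values = rng.normal(0.3, 0.05, size=500)
    modes = detect_peaks(values)
    assert len(modes) == 1 and abs(modes[0] - 0.3) < 0.02


def test_detect_peaks_two_component_mixture():
    """Mixture mirroring a recent-WGT plus gamma-event divergence profile."""
    rng = np.random.default_rng(6)
    values = np.concatenate([rng.normal(0.09, 0.03, 500), rng.normal(0.48, 0.03, 500)])
    modes = detect_peaks(values, bandwidth=0.15)
    assert len(modes) == 2
    assert abs(modes[0] - 0.09) < 0.03 and abs(modes[1] - 0.48) < 0.03


def test_detect_peaks_needs_enough_values():
    with pytest.raises(ValueError):
        detect_peaks(list(range(10)))


# -- collinearity and depth ------------------------------------------------

def _brute_force_longest_chain(points, max_gap):
    """Exponential enumeration of monotone chains (both orientations)."""
    best = 0
    n = len(points)
    order = sorted(range(n), key=lambda k: points[k])

    def extend(chain_last, used_count, idx, orientation):
        nonlocal best
        best = max(best, used_count)
        for j in order[idx:]:
            ra, rb = points[j]
            if chain_last is None:
                extend((ra, rb), used_count + 1, idx + 1, orientation)
            else:
                da = ra - chain_last[0]
                db = (rb - chain_last[1]) * orientation
                if 0 < da <= max_gap and 0 < db <= max_gap:
                    extend((ra, rb), used_count + 1, idx + 1, orientation)

    for sign in (+1, -1):
        for i, j in enumerate(order):
            extend(None, 0, i, sign)
    return best


def _simple_orders(ref_genes, query_genes):
    ref = GeneOrder("ref", {"c1": ref_genes})
    query = GeneOrder("qry", {"c1": query_genes})
    return ref, query


def test_collinear_blocks_perfect_chain():
    genes = [f"g{i}" for i in range(10)]
    ref, query = _simple_orders(genes, [g + "q" for g in genes])
    blocks = collinear_blocks(ref, query, [(g, g + "q") for g in genes])
    assert len(blocks) == 1 and blocks[0].length == 10


def test_collinear_blocks_enforces_minimum_length():
    genes = [f"g{i}" for i in range(4)]
    ref, query = _simple_orders(genes, [g + "q" for g in genes])
    assert collinear_blocks(ref, query, [(g, g + "q") for g in genes]) == []


def test_collinear_blocks_split_by_large_gap():
    # two runs of 6 separated by a 15-rank gap on the query
    ref_genes = [f"g{i}" for i in range(12)]
    query_genes = [f"g{i}q" for i in range(6)] + [f"f{i}" for i in range(15)] + \
                  [f"g{i}q" for i in range(6, 12)]
    ref, query = _simple_orders(ref_genes, query_genes)
    homologs = [(g, g + "q") for g in ref_genes]
    blocks = collinear_blocks(ref, query, homologs, min_genes=5, max_gap=10)
    assert sorted(b.length for b in blocks) == [6, 6]


@pytest.mark.parametrize("seed", range(10))
def test_longest_block_matches_exhaustive_chain_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 14
    ra = rng.choice(40, size=n, replace=False) + 1
    rb = rng.choice(40, size=n, replace=False) + 1
    ref_genes = [f"r{k}" for k in range(41)]
    qry_genes = [f"q{k}" for k in range(41)]
    ref = GeneOrder("ref", {"c1": ref_genes})
    query = GeneOrder("qry", {"c1": qry_genes})
    homologs = [(f"r{a - 1}", f"q{b - 1}") for a, b in zip(ra, rb)]
    blocks = collinear_blocks(ref, query, homologs, min_genes=1, max_gap=8)
    longest = max((b.length for b in blocks), default=0)
    assert longest == _brute_force_longest_chain(list(zip(ra, rb)), max_gap=8)


def test_collinear_blocks_skips_unknown_genes():
    genes = [f"g{i}" for i in range(6)]
    ref, query = _simple_orders(genes, [g + "q" for g in genes])
    homologs = [(g, g + "q") for g in genes] + [("nope", "alsonope")]
    blocks = collinear_blocks(ref, query, homologs)
    assert len(blocks) == 1 and blocks[0].length == 6


def test_syntenic_depth_one_to_one():
    genes = [f"g{i}" for i in range(10)]
    ref, query = _simple_orders(genes, [g + "q" for g in genes])
    blocks = collinear_blocks(ref, query, [(g, g + "q") for g in genes])
    depth, hist = syntenic_depth(blocks, ref)
    assert set(depth.values()) == {1} and hist == {1: 10}


def test_syntenic_depth_full_triplication():
    cfg = SimulationConfig(seed=2, ancestral_gene_count=300, n_chromosomes=3,
                           triplication_loss_fraction=0.0, inversion_rate=0.0)
    ref, query, homologs, _ = gen_triplicated_map(cfg)
    blocks = collinear_blocks(ref, query, homologs)
    depth, hist = syntenic_depth(blocks, ref)
    assert set(depth.values()) == {3}
    assert modal_depth(hist) == 3


def test_syntenic_depth_matches_interval_stabbing_oracle():
    cfg = SimulationConfig(seed=4, ancestral_gene_count=400, n_chromosomes=4,
                           triplication_loss_fraction=0.4)
    ref, query, homologs, _ = gen_triplicated_map(cfg)
    blocks = collinear_blocks(ref, query, homologs, min_genes=5, max_gap=10)
    depth, _ = syntenic_depth(blocks, ref)
    for gene, (chrom, rank) in ref.rank.items():
        expected = sum(b.chrom_a == chrom
                       and b.rank_interval_a[0] <= rank <= b.rank_interval_a[1]
                       for b in blocks)
        assert depth[gene] == expected


# -- alignment-pair validation --------------------------------------------

def test_codon_pair_rejects_malformed_input():
    with pytest.raises(ValueError):
        CodonPairAlignment("x", "ATGA", "ATGA")          # not multiple of 3
    with pytest.raises(ValueError):
        CodonPairAlignment("x", "ATG", "ATGATG")         # unequal lengths
    with pytest.raises(ValueError):
        CodonPairAlignment("x", "ATGTAAGGG", "ATGGCAGGG")  # internal stop
    with pytest.raises(ValueError):
        CodonPairAlignment("x", "ATG-CA", "ATGGCA")      # gap characters
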