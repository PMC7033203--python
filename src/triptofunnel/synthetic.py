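"""Synthetic multi-omics benchmark with planted ground truth.

Every input the pipeline consumes can be generated here: a two-condition
elicitation time course plus tissue-panel expression matrix, an LC-MS
peak table, multi-species protein families, diverged paralog codon
pairs, and a triplicated gene-order map. Each generator plants a known
signal — a pathway gene set sharing a latent induction trajectory with
the target metabolites, a species-specific protein subfamily, a ~97%
tandem duplicate pair, paralog pairs at known divergence times, and a
1:3 syntenic structure with gene loss — and records it in a
PlantedTruth manifest so recovery can be scored exactly.

All randomness flows from the single config seed through named
per-generator streams, so identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .config import SimulationConfig, InvalidConfigError
from .expression import ExpressionMatrix
from .families import ProteinRecord, write_protein_fasta
from .peaks import PeakTable
from .wgd import (BASES, STOP_CODONS, CodonPairAlignment, GeneOrder,
                  write_homolog_pairs)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                 if a + b + c not in STOP_CODONS]

_STREAMS = {"expression": 0, "metabolome": 1, "families": 2,
            "paralogs": 3, "triplication": 4}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    pathway_gene_ids: set[str] = field(default_factory=set)
    bait_gene_ids: set[str] = field(default_factory=set)
    cyp_gene_ids: set[str] = field(default_factory=set)
    target_metabolite_ids: set[str] = field(default_factory=set)
    specific_gene_ids: set[str] = field(default_factory=set)
    tandem_pair: tuple[str, str] | None = None
    pair_true_times_mya: dict[str, float] = field(default_factory=dict)
    ortho_groups: dict[str, list[str]] = field(default_factory=dict)

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        self.pathway_gene_ids |= other.pathway_gene_ids
        self.bait_gene_ids |= other.bait_gene_ids
        self.cyp_gene_ids |= other.cyp_gene_ids
        self.target_metabolite_ids |= other.target_metabolite_ids
        self.specific_gene_ids |= other.specific_gene_ids
        if other.tandem_pair is not None:
            self.tandem_pair = other.tandem_pair
        self.pair_true_times_mya.update(other.pair_true_times_mya)
        self.ortho_groups.update(other.ortho_groups)
        return self

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "pathway_gene_ids": sorted(self.pathway_gene_ids),
            "bait_gene_ids": sorted(self.bait_gene_ids),
            "cyp_gene_ids": sorted(self.cyp_gene_ids),
            "target_metabolite_ids": sorted(self.target_metabolite_ids),
            "specific_gene_ids": sorted(self.specific_gene_ids),
            "tandem_pair": list(self.tandem_pair) if self.tandem_pair else None,
            "pair_true_times_mya": dict(sorted(self.pair_true_times_mya.items())),
            "ortho_groups": {k: sorted(v) for k, v in sorted(self.ortho_groups.items())},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            pathway_gene_ids=set(d["pathway_gene_ids"]),
            bait_gene_ids=set(d["bait_gene_ids"]),
            cyp_gene_ids=set(d["cyp_gene_ids"]),
            target_metabolite_ids=set(d["target_metabolite_ids"]),
            specific_gene_ids=set(d["specific_gene_ids"]),
            tandem_pair=tuple(d["tandem_pair"]) if d["tandem_pair"] else None,
            pair_true_times_mya=d["pair_true_times_mya"],
            ortho_groups=d["ortho_groups"],
        )


def latent_trajectory(time_points_h: Sequence[float], midpoint_h: float = 24.0,
                      scale_h: float = 12.0) -> np.ndarray:
    """Shared logistic induction trajectory, rescaled so max(latent) = 1.

    Models the slow build-up of elicitor-induced secondary metabolism: low
    at time zero, half-maximal around 24 h, saturating by the late time
    points.
    """
    t = np.asarray(time_points_h, dtype=float)
    raw = 1.0 / (1.0 + np.exp(-(t - midpoint_h) / scale_h))
    raw = raw - raw.min()
    return raw / raw.max()


# -- expression ------------------------------------------------------------

def time_course_columns(config: SimulationConfig) -> list[str]:
    cols = []
    for t in config.time_points_h:
        for cond in ("CM", "CC"):
            for r in range(1, config.n_replicates + 1):
                cols.append(f"{cond}_{t:g}h_r{r}")
    return cols


def tissue_columns(config: SimulationConfig) -> list[str]:
    return [f"tissue_{t}" for t in config.tissues]


def gen_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Counts matrix: elicitation time course x 2 conditions + tissue panel.

    Pathway genes (and the two bait diterpene synthases) share one latent
    logistic induction trajectory in the treated condition and dominate
    the focal tissue; every other gene is independent log-normal noise.
    """
    if config.n_pathway_genes > config.n_genes:
        raise InvalidConfigError("n_pathway_genes cannot exceed n_genes")
    rng = _rng(config, "expression")
    gene_ids = [f"TW{i + 1:06d}.1" for i in range(config.n_genes)]
    baits = ["TwCPS1", "TwMS"]
    all_ids = gene_ids + baits

    chosen = rng.choice(config.n_genes, size=min(config.n_pathway_genes + config.n_decoy_cyps,
                                                 config.n_genes), replace=False)
    pathway = [gene_ids[i] for i in chosen[:config.n_pathway_genes]]
    decoy_cyps = [gene_ids[i] for i in chosen[config.n_pathway_genes:]]
    coupled = set(pathway) | set(baits)

    latent = latent_trajectory(config.time_points_h)
    tc_cols = time_course_columns(config)
    ti_cols = tissue_columns(config)
    n_genes_total = len(all_ids)

    baseline = rng.lognormal(mean=np.log(80.0), sigma=1.0, size=n_genes_total)
    amplitude = config.induction_amplitude * rng.uniform(0.7, 1.3, size=n_genes_total)

    values = np.zeros((n_genes_total, len(tc_cols) + len(ti_cols)))
    col_index = {c: k for k, c in enumerate(tc_cols + ti_cols)}
    noise = lambda size: np.exp(rng.normal(0.0, config.noise_sd, size=size))

    for gi, gene in enumerate(all_ids):
        for ti, t in enumerate(config.time_points_h):
            induced = 1.0 + amplitude[gi] * latent[ti] if gene in coupled else 1.0
            for r in range(1, config.n_replicates + 1):
                values[gi, col_index[f"CM_{t:g}h_r{r}"]] = baseline[gi] * induced * noise(None)
                values[gi, col_index[f"CC_{t:g}h_r{r}"]] = baseline[gi] * noise(None)
        for tissue in config.tissues:
            if gene in coupled:
                level = baseline[gi] * (config.tissue_dominance_fold
                                        if tissue == config.focal_tissue else 1.0)
            else:
                level = baseline[gi] * np.exp(rng.normal(0.0, 0.8))
            values[gi, col_index[f"tissue_{tissue}"]] = level * noise(None)

    counts = np.rint(values).astype(float)
    df = pd.DataFrame(counts, index=all_ids, columns=tc_cols + ti_cols)
    lengths = {g: int(L) for g, L in zip(all_ids, rng.integers(900, 4500, size=n_genes_total))}
    truth = PlantedTruth(
        pathway_gene_ids=set(pathway),
        bait_gene_ids=set(baits),
        cyp_gene_ids=set(pathway) | set(decoy_cyps),
    )
    return ExpressionMatrix(df, lengths), truth


# -- metabolome ------------------------------------------------------------

def gen_metabolome(config: SimulationConfig, latent: np.ndarray | None = None,
                   ) -> tuple[PeakTable, PlantedTruth]:
    """LC-MS peak table whose target peaks track the latent trajectory.

    Target peaks sit inside the configured m/z window, carry fragments,
    reach the configured treated/control fold at the final time point, and
    are elevated in the focal tissue; decoy peaks are flat noise split
    among in-window / out-of-window and fragmentless classes.
    """
    if latent is None:
        latent = latent_trajectory(config.time_points_h)
    latent = np.asarray(latent, dtype=float)
    if len(latent) != len(config.time_points_h):
        raise InvalidConfigError("latent trajectory length must match time points")
    if config.n_target_metabolites > config.n_peaks:
        raise InvalidConfigError("more target metabolites than peaks")
    rng = _rng(config, "metabolome")
    low, high = config.mass_window
    n = config.n_peaks
    peak_ids = [f"M{i + 1:05d}" for i in range(n)]
    target_idx = rng.choice(n, size=config.n_target_metabolites, replace=False)
    targets = {peak_ids[i] for i in target_idx}

    tc_cols = time_course_columns(config)
    ti_cols = tissue_columns(config)
    col_index = {c: k for k, c in enumerate(tc_cols + ti_cols)}
    inten = np.zeros((n, len(tc_cols) + len(ti_cols)))
    mz = np.empty(n)
    rt = rng.uniform(0.5, 20.0, size=n)
    frag = np.empty(n, dtype=int)
    noise = lambda: np.exp(rng.normal(0.0, config.noise_sd))

    for i, pid in enumerate(peak_ids):
        is_target = pid in targets
        if is_target:
            mz[i] = rng.uniform(low, high)
            frag[i] = rng.integers(1, 12)
        else:
            if rng.random() < config.out_window_fraction:
                mz[i] = rng.uniform(100.0, low - 1e-6) if rng.random() < 0.5 \
                    else rng.uniform(high + 1e-6, 800.0)
            else:
                mz[i] = rng.uniform(low, high)
            frag[i] = 0 if rng.random() < config.fragmentless_fraction \
                else int(rng.integers(1, 12))
        base = rng.lognormal(mean=np.log(1e4), sigma=0.8)
        for ti, t in enumerate(config.time_points_h):
            fold = 1.0 + (config.target_fold - 1.0) * latent[ti] if is_target else 1.0
            for r in range(1, config.n_replicates + 1):
                inten[i, col_index[f"CM_{t:g}h_r{r}"]] = base * fold * noise()
                inten[i, col_index[f"CC_{t:g}h_r{r}"]] = base * noise()
        for tissue in config.tissues:
            if is_target:
                level = base * (config.tissue_dominance_fold
                                if tissue == config.focal_tissue else 1.0)
            else:
                level = base * np.exp(rng.normal(0.0, 0.8))
            inten[i, col_index[f"tissue_{tissue}"]] = level * noise()

    df = pd.DataFrame({"mz": mz, "rt": rt, "fragment_count": frag}, index=peak_ids)
    df = pd.concat([df, pd.DataFrame(inten, index=peak_ids, columns=tc_cols + ti_cols)], axis=1)
    df.index.name = "peak_id"
    return PeakTable(df), PlantedTruth(target_metabolite_ids=targets)


# -- protein families ------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_to_identity(seq: str, identity_pct: float, rng: np.random.Generator) -> str:
    """Point-substitute distinct positions to reach a target point identity."""
    if not 0 < identity_pct <= 100:
        raise InvalidConfigError(f"unattainable identity target: {identity_pct}")
    # floor keeps the realized point identity at or above the target, so a
    # tandem pair generated at 97 still satisfies an inclusive >=97 collapse
    n_mut = int(len(seq) * (1.0 - identity_pct / 100.0))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [aa for aa in AA20 if aa != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_protein_families(config: SimulationConfig,
                         focal_gene_ids: Sequence[str] | None = None,
                         specific_ids: Sequence[str] | None = None,
                         tandem_pair_ids: tuple[str, str] | None = None,
                         ) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Multi-species protein families with a planted specific subfamily.

    Shared families evolve from common roots by point substitution, so
    cross-species homologs stay well above the subfamily cutoff. The
    planted specific subfamily descends from a strongly diverged root
    found only in the focal species (best cross-species identity held
    ~10 points under the cutoff), and one tandem pair is duplicated at
    the configured near-identity.

    Gene ids for the focal species can be supplied so that the protein
    set shares ids with a generated expression matrix.
    """
    if len(config.species) < 2:
        raise InvalidConfigError("need at least two species")
    rng = _rng(config, "families")
    L = config.protein_length
    n_families, members_per_species = len(config.family_sizes), config.family_sizes

    records: list[ProteinRecord] = []
    focal_needed = sum(members_per_species)
    if specific_ids is None:
        focal_needed += config.n_specific_genes
    if tandem_pair_ids is None:
        focal_needed += 1  # the duplicated twin of an existing member
    if focal_gene_ids is None:
        focal_gene_ids = [f"TW{900000 + i}.1" for i in range(focal_needed)]
    elif len(focal_gene_ids) < focal_needed:
        raise InvalidConfigError(
            f"need {focal_needed} focal gene ids, got {len(focal_gene_ids)}")
    focal_iter = iter(focal_gene_ids)

    for fam, fam_size in enumerate(members_per_species):
        root = _random_protein(rng, L)
        for species in config.species:
            for m in range(fam_size):
                ident = rng.uniform(85.0, 92.0)
                seq = _mutate_to_identity(root, ident, rng)
                gid = next(focal_iter) if species == config.focal_species \
                    else f"{species}_F{fam + 1}G{m + 1}"
                records.append(ProteinRecord(gid, species, seq))

    # species-specific subfamily: diverged far below the cutoff from family 1's root
    fam_root = next(r for r in records if r.species != config.focal_species).sequence
    specific_root = _mutate_to_identity(
        fam_root, max(config.specific_subfamily_max_xspecies_identity - 10.0, 5.0), rng)
    if specific_ids is None:
        specific_ids = [next(focal_iter) for _ in range(config.n_specific_genes)]
    specific_set = set(specific_ids)
    for gid in specific_ids:
        seq = _mutate_to_identity(specific_root, rng.uniform(88.0, 95.0), rng)
        records.append(ProteinRecord(gid, config.focal_species, seq))

    # tandem near-duplicate pair inside the focal species
    if tandem_pair_ids is None:
        donor = [r for r in records if r.species == config.focal_species][0]
        twin_id = next(focal_iter)
        tandem_pair_ids = (donor.gene_id, twin_id)
        twin_seq = _mutate_to_identity(donor.sequence, config.tandem_pair_identity, rng)
        records.append(ProteinRecord(twin_id, config.focal_species, twin_seq))
    else:
        a_id, b_id = tandem_pair_ids
        seq_a = _random_protein(rng, L)
        seq_b = _mutate_to_identity(seq_a, config.tandem_pair_identity, rng)
        records.append(ProteinRecord(a_id, config.focal_species, seq_a))
        records.append(ProteinRecord(b_id, config.focal_species, seq_b))

    truth = PlantedTruth(specific_gene_ids=specific_set, tandem_pair=tuple(tandem_pair_ids))
    return records, truth


# -- paralog codon pairs ---------------------------------------------------

def _evolve_jc(ancestor: np.ndarray, p_branch: float,
               rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch: each site differs with probability p_branch."""
    derived = ancestor.copy()
    changed = rng.random(len(ancestor)) < p_branch
    shift = rng.integers(1, 4, size=changed.sum())
    derived[changed] = (derived[changed] + shift) % 4
    return derived


def _fix_stops(seq: np.ndarray, ancestor: np.ndarray, p_branch: float,
               rng: np.random.Generator) -> np.ndarray:
    """Re-draw codons that became stops until the frame is stop-free."""
    stop_codes = np.array([[3, 0, 0], [3, 0, 2], [3, 2, 0]])  # TAA TAG TGA
    codons = seq.reshape(-1, 3)
    anc_codons = ancestor.reshape(-1, 3)
    for _ in range(100):
        is_stop = (codons[:, None, :] == stop_codes[None, :, :]).all(axis=2).any(axis=1)
        if not is_stop.any():
            break
        idx = np.nonzero(is_stop)[0]
        redrawn = _evolve_jc(anc_codons[idx].ravel(), p_branch, rng)
        codons[idx] = redrawn.reshape(-1, 3)
    return codons.ravel()


_B2I = {b: i for i, b in enumerate(BASES)}


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def gen_paralog_pairs(config: SimulationConfig,
                      ) -> tuple[list[CodonPairAlignment], PlantedTruth]:
    """Paralog pairs diverged for known times under per-site Jukes-Cantor.

    Each pair descends from a random stop-free ancestor; both lineages
    evolve independently for T years at the configured rate, so the
    expected raw difference is p = 3/4 (1 - exp(-8 r T / 3)).
    """
    rng = _rng(config, "paralogs")
    r = config.subst_rate_per_site_per_year
    n_sites = config.n_codons * 3
    pairs: list[CodonPairAlignment] = []
    truth = PlantedTruth()
    times = list(config.true_divergence_times_mya)
    for k in range(config.paralog_pairs):
        T_mya = times[k % len(times)]
        t_years = T_mya * 1e6
        p_pair = 0.75 * (1.0 - np.exp(-8.0 * r * t_years / 3.0))
        if p_pair > 0.70:
            warnings.warn(
                f"pair {k}: expected difference {p_pair:.3f} is near saturation (3/4)",
                stacklevel=2)
        codon_idx = rng.integers(0, len(_SENSE_CODONS), size=config.n_codons)
        ancestor = np.array([_B2I[b] for ci in codon_idx for b in _SENSE_CODONS[ci]],
                            dtype=np.int64)
        p_branch = 0.75 * (1.0 - np.exp(-4.0 * r * t_years / 3.0))
        seq_a = _fix_stops(_evolve_jc(ancestor, p_branch, rng), ancestor, p_branch, rng)
        seq_b = _fix_stops(_evolve_jc(ancestor, p_branch, rng), ancestor, p_branch, rng)
        pair_id = f"pair{k + 1:04d}"
        pairs.append(CodonPairAlignment(pair_id, _decode(seq_a), _decode(seq_b)))
        truth.pair_true_times_mya[pair_id] = float(T_mya)
    return pairs, truth


# -- triplicated gene-order map -------------------------------------------

def gen_triplicated_map(config: SimulationConfig,
                        ) -> tuple[GeneOrder, GeneOrder, list[tuple[str, str]], PlantedTruth]:
    """Reference order plus a whole-genome-multiplied query with gene loss.

    The query genome carries `ploidy_copies` copies of every reference
    chromosome; each copy loses genes independently at the configured
    fraction and may undergo short local inversions. Homolog pairs link
    every retained query gene back to its reference progenitor.
    """
    if config.ancestral_gene_count < 50:
        raise InvalidConfigError("ancestral_gene_count must be at least 50")
    if not 0 <= config.triplication_loss_fraction < 1:
        raise InvalidConfigError("loss fraction must be in [0, 1)")
    rng = _rng(config, "triplication")
    genes_per_chrom = config.ancestral_gene_count // config.n_chromosomes
    ref_chroms: dict[str, list[str]] = {}
    g = 0
    for c in range(config.n_chromosomes):
        extra = 1 if c < config.ancestral_gene_count % config.n_chromosomes else 0
        chrom = f"chr{c + 1:02d}"
        ref_chroms[chrom] = [f"anc{g + i + 1:05d}" for i in range(genes_per_chrom + extra)]
        g += genes_per_chrom + extra
    reference = GeneOrder("reference", ref_chroms)

    query_chroms: dict[str, list[str]] = {}
    homologs: list[tuple[str, str]] = []
    ortho: dict[str, list[str]] = {gid: [] for gid in reference.gene_ids}
    for copy in range(1, config.ploidy_copies + 1):
        for chrom, genes in ref_chroms.items():
            keep = [gid for gid in genes
                    if rng.random() >= config.triplication_loss_fraction]
            # occasional short local inversions
            out = list(keep)
            i = 0
            while i < len(out):
                if rng.random() < config.inversion_rate:
                    seg = int(rng.integers(3, 11))
                    out[i:i + seg] = reversed(out[i:i + seg])
                    i += seg
                else:
                    i += 1
            qchrom = f"{chrom}_c{copy}"
            qgenes = [f"{gid}_c{copy}" for gid in out]
            query_chroms[qchrom] = qgenes
            for gid in keep:
                qid = f"{gid}_c{copy}"
                homologs.append((gid, qid))
                ortho[gid].append(qid)
    query = GeneOrder("query", query_chroms)
    truth = PlantedTruth(ortho_groups={k: v for k, v in ortho.items() if v})
    return reference, query, homologs, truth


# -- orchestration ---------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    expression: ExpressionMatrix
    peaks: PeakTable
    proteins: list[ProteinRecord]
    paralog_pairs: list[CodonPairAlignment]
    reference_order: GeneOrder
    query_order: GeneOrder
    homologs: list[tuple[str, str]]
    truth: PlantedTruth


def generate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator with coordinated gene ids.

    The focal-species protein set reuses the expression matrix's CYP gene
    ids: the planted specific subfamily and the tandem pair are pathway
    genes, so the candidate funnel can be scored end to end.
    """
    expr, truth = gen_expression(config)
    peaks, t2 = gen_metabolome(config)
    truth.merge(t2)

    pathway = sorted(truth.pathway_gene_ids)
    decoys = sorted(truth.cyp_gene_ids - truth.pathway_gene_ids)
    if len(pathway) < 4:
        raise InvalidConfigError("coordinated generation needs >=4 pathway genes")
    tandem = (pathway[0], pathway[1])
    n_spec = min(config.n_specific_genes, len(pathway) - 2 + len(decoys))
    spec_from_pathway = pathway[2:2 + max(0, min(2, n_spec))]
    spec_from_decoys = decoys[:n_spec - len(spec_from_pathway)]
    specific = spec_from_pathway + spec_from_decoys
    # remaining focal ids: rest of pathway + decoys, padded if short
    used = set(tandem) | set(specific)
    pool = [g for g in pathway + decoys if g not in used]
    needed = sum(config.family_sizes)
    focal_ids = (pool + [f"TW{800000 + i}.1" for i in range(needed)])[:needed]

    prots, t3 = gen_protein_families(config, focal_gene_ids=focal_ids,
                                     specific_ids=specific, tandem_pair_ids=tandem)
    truth.merge(t3)
    pairs, t4 = gen_paralog_pairs(config)
    truth.merge(t4)
    ref, query, homologs, t5 = gen_triplicated_map(config)
    truth.merge(t5)
    return SyntheticDataset(config, expr, peaks, prots, pairs, ref, query, homologs, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every generated artifact under outdir; returns the file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "expression": out / "expression_counts.tsv",
        "gene_lengths": out / "gene_lengths.tsv",
        "peaks": out / "peak_table.csv",
        "proteins": out / "proteins.faa",
        "cds_pairs": out / "paralog_pairs.fna",
        "gene_order": out / "gene_order.tsv",
        "homologs": out / "homolog_pairs.tsv",
        "truth": out / "truth.yaml",
    }
    ds.expression.to_tsv(files["expression"], files["gene_lengths"])
    ds.peaks.to_csv(files["peaks"])
    write_protein_fasta(ds.proteins, files["proteins"])
    with open(files["cds_pairs"], "w") as fh:
        for p in ds.paralog_pairs:
            fh.write(f">{p.pair_id}_a\n{p.seq_a}\n>{p.pair_id}_b\n{p.seq_b}\n")
    ds.reference_order.to_tsv(files["gene_order"])
    ds.query_order.to_tsv(files["gene_order"], mode="a")
    write_homolog_pairs(ds.homologs, files["homologs"])
    ds.truth.to_yaml(files["truth"])
    return files


def read_paralog_fasta(path: str | Path) -> list[CodonPairAlignment]:
    """Read pairs written by write_dataset (ids ``<pair>_a`` / ``<pair>_b``)."""
    from Bio import SeqIO
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    pairs = []
    for rid in sorted(seqs):
        if rid.endswith("_a"):
            pid = rid[:-2]
            if f"{pid}_b" not in seqs:
                raise ValueError(f"unpaired record {rid}")
            pairs.append(CodonPairAlignment(pid, seqs[rid], seqs[f"{pid}_b"]))
    return pairs
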