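"""Protein-family identity computations.

Cytochrome P450 nomenclature ties family and subfamily membership to
amino-acid identity bands: sequences below ~55% identity to everything in
another species sit in a species-specific subfamily, while near-identical
pairs (>=97%) typically reflect recent tandem duplication. This module
scores pairwise identity by global alignment (BLOSUM62, affine gaps),
finds homologs by coverage/identity thresholds, flags species-specific
genes, and collapses near-duplicates to single representatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    species: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in AA_ALPHABET:
                raise ValueError(f"{self.gene_id}: invalid residue {aa!r} at position {i + 1}")


@dataclass(frozen=True)
class IdentityHit:
    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    alignment_length: int


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> IdentityHit:
    """Percent identity and query coverage from one global alignment.

    Identity = matches / aligned columns, excluding terminal-gap columns
    (overhangs do not dilute identity, internal gaps do). Coverage is the
    fraction of query residues aligned opposite a subject residue; it is
    role-specific, while identity is symmetric under swapping a and b.
    """
    if len(a.sequence) < 10 or len(b.sequence) < 10:
        raise ValueError("sequences must be at least 10 residues long")
    aln = _ALIGNER.align(a.sequence, b.sequence)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # trim terminal-gap columns (leading/trailing overhang of either sequence)
    start = 0
    while s1[start] == "-" or s2[start] == "-":
        start += 1
    end = len(s1)
    while s1[end - 1] == "-" or s2[end - 1] == "-":
        end -= 1
    core1, core2 = s1[start:end], s2[start:end]
    matches = sum(c1 == c2 and c1 != "-" for c1, c2 in zip(core1, core2))
    columns = len(core1)
    paired_query = sum(c1 != "-" and c2 != "-" for c1, c2 in zip(s1, s2))
    return IdentityHit(
        query_id=a.gene_id,
        subject_id=b.gene_id,
        percent_identity=100.0 * matches / columns if columns else 0.0,
        query_coverage=100.0 * paired_query / len(a.sequence),
        alignment_length=columns,
    )


def find_homologs(seeds: Iterable[ProteinRecord], targets: Iterable[ProteinRecord],
                  min_cov: float = 50.0, min_id: float = 50.0) -> list[IdentityHit]:
    """All seed x target hits with coverage >= min_cov and identity > min_id.

    Coverage is evaluated on the seed (query) side; the identity threshold
    is strict, so a hit at exactly min_id is dropped.
    """
    hits = []
    for seed in seeds:
        for target in targets:
            hit = pairwise_identity(seed, target)
            if hit.query_coverage >= min_cov and hit.percent_identity > min_id:
                hits.append(hit)
    return hits


def species_specific(proteins: Iterable[ProteinRecord], focal: str,
                     cutoff: float = 55.0) -> set[str]:
    """Focal-species genes below the subfamily identity cutoff to all others.

    A gene is specific iff its maximum identity to any protein of any
    non-focal species is strictly below the cutoff.
    """
    records = list(proteins)
    species_present = {r.species for r in records}
    if len(species_present) < 2:
        raise ValueError("species specificity needs at least two species")
    if focal not in species_present:
        raise ValueError(f"focal species {focal!r} absent from the input")
    focal_recs = [r for r in records if r.species == focal]
    others = [r for r in records if r.species != focal]
    specific = set()
    for rec in focal_recs:
        best = max(pairwise_identity(rec, o).percent_identity for o in others)
        if best < cutoff:
            specific.add(rec.gene_id)
    return specific


def collapse_near_duplicates(genes: Iterable[ProteinRecord], cutoff: float = 97.0,
                             ) -> tuple[set[str], dict[str, str]]:
    """Single-linkage clustering at identity >= cutoff; one representative each.

    The representative is the longest sequence in a cluster, ties broken
    by lexicographically smallest gene id. Returns the representative set
    and a gene -> representative map covering every input.
    """
    records = sorted(genes, key=lambda r: r.gene_id)
    parent = {r.gene_id: r.gene_id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(records):
        for b in records[i + 1:]:
            if pairwise_identity(a, b).percent_identity >= cutoff:
                parent[find(a.gene_id)] = find(b.gene_id)

    by_id = {r.gene_id: r for r in records}
    clusters: dict[str, list[str]] = {}
    for r in records:
        clusters.setdefault(find(r.gene_id), []).append(r.gene_id)
    mapping: dict[str, str] = {}
    for members in clusters.values():
        rep = min(members, key=lambda g: (-len(by_id[g].sequence), g))
        for g in members:
            mapping[g] = rep
    return set(mapping.values()), mapping


# -- I/O ------------------------------------------------------------------

def read_protein_fasta(path: str | Path,
                       species_map: Mapping[str, str] | None = None) -> list[ProteinRecord]:
    """Load proteins from FASTA; species from a ``species=`` header tag or a map."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = None
        for token in rec.description.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        if species is None and species_map is not None:
            species = species_map.get(rec.id)
        if species is None:
            raise ValueError(f"{rec.id}: no species= tag and no mapping entry")
        records.append(ProteinRecord(rec.id, species, str(rec.seq)))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id} species={r.species}\n{r.sequence}\n")


def hits_to_tsv(hits: Iterable[IdentityHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.query_id, h.subject_id, h.percent_identity, h.query_coverage, h.alignment_length)
         for h in hits],
        columns=["query", "subject", "pct_identity", "query_coverage", "aln_length"])
    df.to_csv(path, sep="\t", index=False)


def clusters_to_tsv(mapping: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(mapping.items()), columns=["gene", "representative"])
    df.to_csv(path, sep="\t", index=False)
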