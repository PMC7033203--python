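"""Staged candidate-gene screen (the funnel).

Mirrors the screening logic that nominated triptolide-pathway P450s:
genes linked to the target metabolites in the correlation network are
required to be expressed, augmented with induced or tissue-dominant
species-specific genes, filtered for differential expression or
focal-tissue dominance plus co-expression with bait diterpene synthases,
and finally pruned of known-function genes and tandem near-duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .config import FunnelConfig
from .expression import (ExpressionMatrix, compute_rpkm, differential_expression,
                         de_gene_set, tissue_dominance, normalize_profiles)
from .families import ProteinRecord, collapse_near_duplicates
from .network import (CorrelationEdge, best_r_to_targets, genes_linked_to,
                      pearson_with_p)


@dataclass
class FamilyResults:
    """Sequence-side inputs to the funnel."""

    specific_gene_ids: set[str] = field(default_factory=set)
    proteins: list[ProteinRecord] = field(default_factory=list)


@dataclass
class FunnelStage:
    name: str
    rule: str
    genes: list[str]

    @property
    def count(self) -> int:
        return len(self.genes)


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)
    ranked_candidates: list[tuple[str, float]] = field(default_factory=list)

    def add(self, name: str, rule: str, genes: Iterable[str]) -> set[str]:
        gene_set = set(genes)
        self.stages.append(FunnelStage(name, rule, sorted(gene_set)))
        return gene_set

    @property
    def final_genes(self) -> set[str]:
        return set(self.stages[-1].genes) if self.stages else set()

    def summary(self) -> str:
        lines = ["stage\tcount\trule"]
        for s in self.stages:
            lines.append(f"{s.name}\t{s.count}\t{s.rule}")
        lines.append("")
        lines.append("rank\tgene\tbest_r_to_target")
        for i, (gene, r) in enumerate(self.ranked_candidates, start=1):
            lines.append(f"{i}\t{gene}\t{r:.4f}" if np.isfinite(r) else f"{i}\t{gene}\tNA")
        return "\n".join(lines) + "\n"


def run_funnel(expr: ExpressionMatrix, network: Iterable[CorrelationEdge],
               family: FamilyResults, cfg: FunnelConfig) -> FunnelReport:
    """Execute the five funnel stages and return the report.

    Stage 1: CYP genes with a network edge to a target metabolite.
    Stage 2: of those, RPKM above the expression floor in >=1 sample.
    Stage 3: union with species-specific CYPs that are induced or
             focal-tissue-dominant.
    Stage 4: differential expression at >=1 configured time point OR
             focal-tissue dominance, AND co-expression with a bait gene
             above the network r cutoff.
    Stage 5: drop the exclusion list, collapse near-duplicates.
    """
    edges = list(network)
    report = FunnelReport()
    missing_baits = [b for b in cfg.bait_gene_ids if b not in expr.values.index]
    if missing_baits:
        raise ValueError(f"bait genes absent from expression matrix: {missing_baits}")

    cyps = set(cfg.cyp_gene_ids) if cfg.cyp_gene_ids else set(expr.gene_ids)
    linked = genes_linked_to(edges, cfg.target_metabolite_ids) & cyps
    s1 = report.add("network_linked",
                    f"edge to a target metabolite (r>{cfg.r_cutoff}, p<{cfg.p_cutoff}) "
                    "restricted to annotated CYPs", linked)

    rpkm = compute_rpkm(expr) if expr.gene_lengths_bp else expr
    expressed_all = set(rpkm.values.index[(rpkm.values > cfg.rpkm_min).any(axis=1)])
    s2 = report.add("expressed", f"RPKM > {cfg.rpkm_min} in >=1 sample", s1 & expressed_all)

    de_results = differential_expression(expr, cfg.de_times_h, alpha=cfg.de_alpha,
                                         min_fold=cfg.de_min_fold)
    de_genes = de_gene_set(de_results)
    dominant = tissue_dominance(expr, cfg.focal_tissue, min_ratio=cfg.tissue_min_ratio)
    dominant_genes = {g for g, flag in dominant.items() if flag}
    specific_active = (family.specific_gene_ids & cyps & (de_genes | dominant_genes)
                       & expressed_all)
    s3 = report.add("specificity_augmented",
                    f"union with species-specific CYPs (cutoff {cfg.specificity_cutoff}%) "
                    "that are induced or focal-tissue-dominant", s2 | specific_active)

    bait_ok = _bait_similarity(expr, cfg.bait_gene_ids, s3, cfg.r_cutoff)
    s4 = report.add("differential_pattern",
                    f"DE at >=1 of {list(cfg.de_times_h)} h or {cfg.focal_tissue}-dominant, "
                    f"and r > {cfg.r_cutoff} to a bait gene",
                    {g for g in s3 if (g in de_genes or g in dominant_genes) and bait_ok[g]})

    survivors = s4 - set(cfg.exclusion_list)
    if family.proteins:
        prot_by_id = {p.gene_id: p for p in family.proteins}
        present = [prot_by_id[g] for g in sorted(survivors) if g in prot_by_id]
        if present:
            _, mapping = collapse_near_duplicates(present, cutoff=cfg.dup_cutoff)
            reps = set(mapping.values())
            survivors = {g for g in survivors if g not in mapping or g in reps}
    s5 = report.add("exclusions_dedup",
                    f"minus exclusion list, near-duplicates collapsed at "
                    f"{cfg.dup_cutoff}%", survivors)

    best_r = best_r_to_targets(edges, cfg.target_metabolite_ids)
    report.ranked_candidates = sorted(
        ((g, best_r.get(g, float("-inf"))) for g in s5),
        key=lambda item: (-item[1], item[0]))
    return report


def _bait_similarity(expr: ExpressionMatrix, bait_ids: Sequence[str],
                     genes: set[str], r_cutoff: float) -> dict[str, bool]:
    """Pearson r of each gene's normalized profile against every bait."""
    if not bait_ids:
        return {g: True for g in genes}
    norm, _ = normalize_profiles(expr.values)
    out = {}
    for g in genes:
        rs = []
        for b in bait_ids:
            x, y = norm.loc[g].to_numpy(), norm.loc[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, _, _ = pearson_with_p(x, y)
            rs.append(r)
        out[g] = bool(rs) and max(rs) > r_cutoff
    return out


def write_report(report: FunnelReport, outdir: str | Path) -> list[Path]:
    """One TSV per stage plus a summary; deterministic ordering and bytes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, stage in enumerate(report.stages, start=1):
        path = out / f"stage{i}_{stage.name}.tsv"
        with open(path, "w") as fh:
            fh.write("gene_id\n")
            for g in stage.genes:
                fh.write(g + "\n")
        written.append(path)
    summary = out / "funnel_summary.tsv"
    with open(summary, "w") as fh:
        fh.write(report.summary())
    written.append(summary)
    return written
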