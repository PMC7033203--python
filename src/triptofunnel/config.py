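"""Configuration objects shared across the pipeline.

All tunable thresholds live here so that a single YAML file can drive the
command-line interface end to end. Defaults mirror the study design the
package emulates: an eight-point methyl-jasmonate elicitation time course
with three replicates per condition, a seven-tissue panel, a diterpenoid
m/z window of 295-400 Da, a 55% amino-acid identity cutoff marking CYP
subfamily separation, and a eudicot substitution rate of 6.5e-9 per site
per year for the molecular clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_TIME_POINTS_H = (0.0, 4.0, 12.0, 24.0, 48.0, 72.0, 120.0, 240.0)
DEFAULT_TISSUES = (
    "root_bark",
    "root_wood",
    "stem_bark",
    "peeled_stem",
    "leaf",
    "flower",
    "fruit",
)
EUDICOT_SUBST_RATE = 6.5e-9  # substitutions / site / year


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-omics benchmark generator.

    The generator plants a known pathway gene set, target metabolites, a
    species-specific protein subfamily, a tandem near-duplicate pair,
    paralog pairs at known divergence times and a triplicated gene-order
    map, so that every downstream operation can be scored against ground
    truth.
    """

    seed: int = 0
    # expression
    n_genes: int = 200
    n_pathway_genes: int = 8
    n_decoy_cyps: int = 40
    time_points_h: Sequence[float] = DEFAULT_TIME_POINTS_H
    tissues: Sequence[str] = DEFAULT_TISSUES
    focal_tissue: str = "root_bark"
    n_replicates: int = 3
    noise_sd: float = 0.25          # log-scale sd of multiplicative noise
    induction_amplitude: float = 6.0  # peak fold-induction of pathway genes
    tissue_dominance_fold: float = 8.0
    # metabolome
    n_peaks: int = 300
    n_target_metabolites: int = 2
    mass_window: tuple[float, float] = (295.0, 400.0)
    target_fold: float = 3.6        # treated/control fold at the last time point
    fragmentless_fraction: float = 0.2
    out_window_fraction: float = 0.4
    # protein families
    species: Sequence[str] = ("Twilfordii", "Athaliana", "Ppersica", "Slycopersicum")
    focal_species: str = "Twilfordii"
    family_sizes: Sequence[int] = (4, 4, 4)   # shared families, members per species
    n_specific_genes: int = 4
    protein_length: int = 150
    specific_subfamily_max_xspecies_identity: float = 55.0
    tandem_pair_identity: float = 97.0
    # paralog pairs
    paralog_pairs: int = 100
    n_codons: int = 500
    # two planted events: a recent whole-genome triplication and an older
    # duplication, so the Ks distribution is bimodal like real paralog sets
    true_divergence_times_mya: Sequence[float] = (21.0, 65.0)
    subst_rate_per_site_per_year: float = EUDICOT_SUBST_RATE
    # triplicated map
    ancestral_gene_count: int = 600
    n_chromosomes: int = 6
    ploidy_copies: int = 3
    triplication_loss_fraction: float = 0.4
    inversion_rate: float = 0.02    # per-gene chance of starting a local inversion

    def __post_init__(self) -> None:
        low, high = self.mass_window
        if not low < high:
            raise InvalidConfigError(f"mass_window low must be < high, got {self.mass_window}")
        if self.n_pathway_genes > self.n_genes:
            raise InvalidConfigError("n_pathway_genes cannot exceed n_genes")
        for name in ("n_genes", "n_replicates", "n_peaks", "paralog_pairs",
                     "n_codons", "ancestral_gene_count", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive")
        if self.subst_rate_per_site_per_year <= 0:
            raise InvalidConfigError("substitution rate must be strictly positive")
        if any(t < 0 for t in self.true_divergence_times_mya):
            raise InvalidConfigError("divergence times must be non-negative")
        if not 0 <= self.triplication_loss_fraction < 1:
            raise InvalidConfigError("triplication_loss_fraction must be in [0, 1)")
        if not 0 < self.tandem_pair_identity <= 100:
            raise InvalidConfigError("tandem_pair_identity must be in (0, 100]")
        if not 0 < self.specific_subfamily_max_xspecies_identity <= 100:
            raise InvalidConfigError("specificity identity target must be in (0, 100]")
        if len(self.species) < 2:
            raise InvalidConfigError("at least two species are required")
        if self.focal_species not in self.species:
            raise InvalidConfigError("focal_species must be one of species")
        if self.focal_tissue not in self.tissues:
            raise InvalidConfigError("focal_tissue must be one of tissues")


@dataclass
class NetworkConfig:
    """Cutoffs of the gene-to-metabolite Pearson correlation network.

    Edges are kept when r > r_cutoff (strict) and p < p_cutoff; with
    positive_only the sign requirement is implied by the r cutoff but is
    kept explicit so |r| screening can be enabled independently.
    """

    r_cutoff: float = 0.7
    p_cutoff: float = 0.05
    positive_only: bool = True
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.r_cutoff <= 1:
            raise InvalidConfigError("r_cutoff must be within [0, 1]")
        if not 0 < self.p_cutoff <= 1:
            raise InvalidConfigError("p_cutoff must be within (0, 1]")


@dataclass
class PeakFilterConfig:
    """Thresholds of the LC-MS peak funnel."""

    mass_low: float = 295.0
    mass_high: float = 400.0
    alpha: float = 0.01
    min_maxfold: float = 2.0
    keep_changing: bool = True   # retain responsive peaks (see docs/methods.md)

    def __post_init__(self) -> None:
        if not self.mass_low < self.mass_high:
            raise InvalidConfigError("mass_low must be < mass_high")


@dataclass
class FunnelConfig:
    """Parameters of the staged candidate-gene screen."""

    target_metabolite_ids: Sequence[str] = ()
    bait_gene_ids: Sequence[str] = ()
    cyp_gene_ids: Sequence[str] = ()       # annotated CYP universe
    rpkm_min: float = 1.0
    de_times_h: Sequence[float] = (4.0, 12.0, 24.0, 48.0, 72.0)
    de_alpha: float = 0.05
    de_min_fold: float = 2.0
    focal_tissue: str = "root_bark"
    tissue_min_ratio: float = 2.0
    specificity_cutoff: float = 55.0
    dup_cutoff: float = 97.0
    r_cutoff: float = 0.7
    p_cutoff: float = 0.05
    exclusion_list: Sequence[str] = ()


def load_config(path: str | Path) -> dict:
    """Read a YAML config file into a plain mapping of section -> kwargs."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def simulation_config_from_yaml(path: str | Path, **overrides) -> SimulationConfig:
    data = load_config(path).get("simulation", {})
    data.update(overrides)
    if "mass_window" in data:
        data["mass_window"] = tuple(data["mass_window"])
    return SimulationConfig(**data)


def dump_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"simulation": asdict(cfg)}, fh, sort_keys=False)
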