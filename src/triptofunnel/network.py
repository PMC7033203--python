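"""Gene-to-metabolite Pearson correlation network.

Gene expression profiles and metabolite intensity profiles, each z-scored
per row, are correlated across their shared samples. An edge is kept when
the Pearson coefficient exceeds a strict cutoff (default r > 0.7) and its
two-sided p-value falls below a threshold (default p < 0.05), restricted
by default to positive correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import NetworkConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationEdge:
    gene_id: str
    metabolite_id: str
    r: float
    p: float
    n: int


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided p-value from the exact t reference.

    p derives from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("at least three paired observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p between rows of a and rows of b."""
    n = a.shape[1]
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    asd = np.sqrt((az ** 2).sum(axis=1, keepdims=True))
    bsd = np.sqrt((bz ** 2).sum(axis=1, keepdims=True))
    asd[asd == 0] = np.nan   # constant rows: undefined correlation
    bsd[bsd == 0] = np.nan
    r = (az / asd) @ (bz / bsd).T
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, p


def build_network(genes: pd.DataFrame, metabolites: pd.DataFrame,
                  cfg: NetworkConfig | None = None) -> list[CorrelationEdge]:
    """Correlate every gene row against every metabolite row.

    Sample columns are inner-joined on their ids; both inputs should be
    row-normalized beforehand (z-scoring makes edges scale-invariant).
    Edges require r > r_cutoff (strict) and p < p_cutoff; constant rows
    produce no edges.
    """
    cfg = cfg or NetworkConfig()
    shared = [c for c in genes.columns if c in set(metabolites.columns)]
    dropped = (len(genes.columns) - len(shared)) + (len(metabolites.columns) - len(shared))
    if dropped:
        logger.info("dropped %d unmatched sample columns", dropped)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared samples, found {len(shared)}")
    g = genes[shared].to_numpy(dtype=float)
    m = metabolites[shared].to_numpy(dtype=float)
    r, p = _pairwise_pearson(g, m)
    if cfg.bh_correct:
        flat = p.ravel()
        valid = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[valid] = _bh_adjust(flat[valid])
        p = adj.reshape(p.shape)
    keep = (r > cfg.r_cutoff) & (p < cfg.p_cutoff)
    if cfg.positive_only:
        keep &= r > 0
    keep &= ~np.isnan(r)
    gi, mi = np.nonzero(keep)
    n = len(shared)
    return [CorrelationEdge(genes.index[i], metabolites.index[j],
                            float(r[i, j]), float(p[i, j]), n)
            for i, j in zip(gi, mi)]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def union_networks(*edge_sets: Iterable[CorrelationEdge]) -> list[CorrelationEdge]:
    """Union of edges from separately built networks (e.g., cells + tissues).

    When the same gene-metabolite pair appears in several networks the
    edge with the larger r is kept.
    """
    best: dict[tuple[str, str], CorrelationEdge] = {}
    for edges in edge_sets:
        for e in edges:
            key = (e.gene_id, e.metabolite_id)
            if key not in best or e.r > best[key].r:
                best[key] = e
    return [best[k] for k in sorted(best)]


def genes_linked_to(network: Iterable[CorrelationEdge],
                    metabolite_ids: Iterable[str]) -> set[str]:
    """Genes incident to an edge touching any of the given metabolites."""
    edges = list(network)
    known = {e.metabolite_id for e in edges}
    wanted = set()
    for mid in metabolite_ids:
        if mid not in known:
            logger.warning("metabolite %s has no edges in the network; skipped", mid)
        else:
            wanted.add(mid)
    return {e.gene_id for e in edges if e.metabolite_id in wanted}


def best_r_to_targets(network: Iterable[CorrelationEdge],
                      metabolite_ids: Iterable[str]) -> dict[str, float]:
    """Per-gene maximum r over edges to the given metabolites (for ranking)."""
    targets = set(metabolite_ids)
    best: dict[str, float] = {}
    for e in network:
        if e.metabolite_id in targets:
            best[e.gene_id] = max(best.get(e.gene_id, -np.inf), e.r)
    return best


def edges_to_tsv(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    df = pd.DataFrame([(e.gene_id, e.metabolite_id, e.r, e.p, e.n) for e in edges],
                      columns=["gene", "metabolite", "r", "p", "n"])
    df.to_csv(path, sep="\t", index=False)


def edges_to_sif(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    """Simple interaction format for Cytoscape import."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.gene_id}\tpcc\t{e.metabolite_id}\n")
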