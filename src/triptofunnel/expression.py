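"""Expression-side computations: RPKM, differential expression, tissue dominance.

The expression matrix mixes two sample panels from the same experiment:
a two-condition elicitation time course (methyl-jasmonate-treated vs
control suspension cells, replicated at each sampled hour) and a
multi-tissue panel. Sample identity is encoded in the column name:
``CM_24h_r1`` (treated, 24 h, replicate 1), ``CC_24h_r1`` (control) or
``tissue_root_bark`` for the tissue panel.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

TREATED = "treated"
CONTROL = "control"
TISSUE = "tissue"

_SAMPLE_RE = re.compile(r"^(CM|CC)_(\d+(?:\.\d+)?)h_r(\d+)$")


@dataclass(frozen=True)
class SampleDesign:
    """Design annotation of one sample column."""

    sample_id: str
    condition: str                 # treated | control | tissue
    time_h: float | None = None
    tissue: str | None = None
    replicate: int | None = None

    def __post_init__(self):
        if self.condition == TISSUE and self.tissue is None:
            raise ValueError(f"tissue sample {self.sample_id} lacks a tissue label")
        if self.condition in (TREATED, CONTROL) and self.time_h is None:
            raise ValueError(f"time-course sample {self.sample_id} lacks a time point")


def parse_sample_id(sample_id: str) -> SampleDesign:
    """Decode a column name into its design annotation."""
    m = _SAMPLE_RE.match(sample_id)
    if m:
        cond = TREATED if m.group(1) == "CM" else CONTROL
        return SampleDesign(sample_id, cond, time_h=float(m.group(2)),
                            replicate=int(m.group(3)))
    if sample_id.startswith("tissue_"):
        return SampleDesign(sample_id, TISSUE, tissue=sample_id[len("tissue_"):])
    raise ValueError(f"unrecognized sample id: {sample_id!r}")


@dataclass(frozen=True)
class DEResult:
    """Per-gene, per-time-point two-condition comparison."""

    gene_id: str
    time_h: float
    fold_change: float   # treated mean / control mean (raw scale)
    p_value: float
    significant: bool


class ExpressionMatrix:
    """Genes x samples abundance table with design and gene lengths.

    Values may be raw counts or RPKM; operations that need one or the
    other say so. Gene ids must be unique and lengths strictly positive.
    """

    def __init__(self, values: pd.DataFrame, gene_lengths_bp: Mapping[str, int] | None = None):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("expression values must be finite and non-negative")
        self.values = values
        self.samples = [parse_sample_id(c) for c in values.columns]
        if gene_lengths_bp is not None:
            missing = [g for g in values.index if g not in gene_lengths_bp]
            if missing:
                raise ValueError(f"genes without lengths: {missing[:5]}")
            bad = [g for g in values.index if gene_lengths_bp[g] <= 0]
            if bad:
                raise ValueError(f"non-positive gene lengths: {bad[:5]}")
        self.gene_lengths_bp = dict(gene_lengths_bp) if gene_lengths_bp else None

    # -- convenience -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def columns_where(self, condition: str | None = None, time_h: float | None = None,
                      tissue: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if condition is not None and s.condition != condition:
                continue
            if time_h is not None and s.time_h != time_h:
                continue
            if tissue is not None and s.tissue != tissue:
                continue
            out.append(s.sample_id)
        return out

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 lengths_path: str | Path | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        lengths = None
        if lengths_path is not None:
            lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
            lengths = lt.iloc[:, 0].to_dict()
        return cls(df, lengths)

    def to_tsv(self, matrix_path: str | Path, lengths_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        if lengths_path is not None and self.gene_lengths_bp is not None:
            pd.Series(self.gene_lengths_bp, name="length_bp").to_csv(
                lengths_path, sep="\t", index_label="gene_id")


def compute_rpkm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    RPKM[g, s] = 1e9 * count[g, s] / (length_bp[g] * total_counts[s]).
    """
    if m.gene_lengths_bp is None:
        raise ValueError("gene lengths are required for RPKM")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    lengths = np.array([m.gene_lengths_bp[g] for g in m.values.index], dtype=float)
    rpkm = 1e9 * m.values.div(totals, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(rpkm, m.gene_lengths_bp)


def _pooled_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance Student t p-value with degenerate handling.

    When both groups have zero variance the t statistic is undefined:
    map to p=0 if the means differ, p=1 if they coincide.
    """
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 0.0 if a.mean() != b.mean() else 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p)


def differential_expression(m: ExpressionMatrix, time_points: Iterable[float],
                            alpha: float = 0.05, min_fold: float = 2.0,
                            pseudocount: float = 1.0) -> list[DEResult]:
    """Two-condition Student t-test per gene per requested time point.

    The t-test runs on log2(x + pseudocount); the reported fold change is
    the ratio of raw arithmetic means (pseudocount-protected). A result is
    significant when p < alpha and max(fold, 1/fold) >= min_fold.
    """
    results: list[DEResult] = []
    mat = m.values
    for t in time_points:
        treated_cols = m.columns_where(TREATED, time_h=t)
        control_cols = m.columns_where(CONTROL, time_h=t)
        if len(treated_cols) < 2 or len(control_cols) < 2:
            raise ValueError(
                f"time point {t} h lacks >=2 replicates in both conditions "
                f"(treated={len(treated_cols)}, control={len(control_cols)})")
        ta = np.log2(mat[treated_cols].to_numpy(dtype=float) + pseudocount)
        ca = np.log2(mat[control_cols].to_numpy(dtype=float) + pseudocount)
        t_means = mat[treated_cols].mean(axis=1).to_numpy() + pseudocount
        c_means = mat[control_cols].mean(axis=1).to_numpy() + pseudocount
        folds = t_means / c_means
        for i, gene in enumerate(mat.index):
            p = _pooled_t_p(ta[i], ca[i])
            fold = float(folds[i])
            sig = p < alpha and max(fold, 1.0 / fold) >= min_fold
            results.append(DEResult(gene, float(t), fold, p, sig))
    return results


def de_gene_set(results: Iterable[DEResult]) -> set[str]:
    """Genes significant at one or more tested time points."""
    return {r.gene_id for r in results if r.significant}


def tissue_dominance(m: ExpressionMatrix, focal: str, min_ratio: float = 2.0,
                     pseudocount: float = 1.0) -> dict[str, bool]:
    """Flag genes whose expression peaks in the focal tissue.

    A gene is dominant when the focal tissue holds the (strict-or-tied)
    maximum across tissues and exceeds min_ratio times the median of the
    remaining tissues (pseudocount-protected ratio).
    """
    tissue_cols = {s.tissue: s.sample_id for s in m.samples if s.condition == TISSUE}
    if len(tissue_cols) < 2:
        raise ValueError("tissue dominance needs at least two tissues")
    if focal not in tissue_cols:
        raise ValueError(f"focal tissue {focal!r} absent from the matrix")
    focal_vals = m.values[tissue_cols[focal]]
    other_cols = [c for t, c in tissue_cols.items() if t != focal]
    others = m.values[other_cols]
    is_max = focal_vals >= others.max(axis=1)
    ratio = (focal_vals + pseudocount) / (others.median(axis=1) + pseudocount)
    flags = is_max & (ratio >= min_ratio)
    return {g: bool(flags[g]) for g in m.values.index}


def normalize_profiles(values: pd.DataFrame, pseudocount: float = 1.0,
                       log_base: float = 2.0) -> tuple[pd.DataFrame, list[str]]:
    """Per-row z-scores of log-transformed abundances.

    Returns the transformed matrix and the ids of constant rows, which are
    mapped to all-zero rather than NaN.
    """
    logged = np.log(values.to_numpy(dtype=float) + pseudocount) / math.log(log_base)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    z = (logged - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=values.index, columns=values.columns)
    return out, list(values.index[constant])


def de_results_to_tsv(results: Iterable[DEResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.time_h, r.fold_change, r.p_value, int(r.significant)) for r in results],
        columns=["gene", "time_h", "fold", "p", "significant"])
    df.to_csv(path, sep="\t", index=False)
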