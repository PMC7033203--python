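"""LC-MS peak-table filtering.

The funnel reduces an untargeted feature table to diterpenoid-range
candidates in three stages: an m/z window (295-400 Da by default, the
expected mass range of diterpenoids), a responsiveness filter (one-way
ANOVA across sample groups on log intensities plus a max-fold gate), and
removal of features with no recorded MS/MS fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PeakFilterConfig

META_COLS = ["mz", "rt", "fragment_count"]


class PeakTable:
    """LC-MS feature table: m/z, retention time, fragment count, intensities."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"peak table lacks columns: {missing}")
        if df.index.has_duplicates:
            raise ValueError("duplicate peak ids")
        if (df["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        inten = df.drop(columns=META_COLS).to_numpy(dtype=float)
        if not np.all(np.isfinite(inten)) or (inten < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        self.df = df

    @property
    def peak_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLS]

    @property
    def intensities(self) -> pd.DataFrame:
        return self.df[self.sample_columns]

    def subset(self, peak_ids: Sequence[str]) -> "PeakTable":
        return PeakTable(self.df.loc[list(peak_ids)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="peak_id")


@dataclass
class PeakFilterReport:
    """Ordered per-stage survivors of the peak funnel."""

    stages: list[tuple[str, list[str]]] = field(default_factory=list)

    def add(self, name: str, surviving_ids: Sequence[str]) -> None:
        self.stages.append((name, list(surviving_ids)))

    @property
    def counts(self) -> list[tuple[str, int]]:
        return [(name, len(ids)) for name, ids in self.stages]

    def to_tsv(self, path: str | Path) -> None:
        rows = [(name, len(ids), ",".join(ids)) for name, ids in self.stages]
        pd.DataFrame(rows, columns=["stage", "n_surviving", "peak_ids"]).to_csv(
            path, sep="\t", index=False)


def filter_mass_window(t: PeakTable, low: float, high: float) -> PeakTable:
    """Retain peaks with low <= m/z <= high (both bounds inclusive)."""
    if not low < high:
        raise ValueError("mass window low must be < high")
    mask = (t.df["mz"] >= low) & (t.df["mz"] <= high)
    return PeakTable(t.df[mask])


def filter_fragmentless(t: PeakTable) -> PeakTable:
    """Drop features with no MS/MS fragments (fragment_count == 0)."""
    return PeakTable(t.df[t.df["fragment_count"] >= 1])


def anova_maxfold(t: PeakTable, groups: Mapping[str, Sequence[str]],
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-peak one-way ANOVA p-value and max-fold across sample groups.

    ANOVA runs on log2(intensity + pseudocount); max-fold is the ratio of
    the largest to the smallest raw group mean (pseudocount-protected).
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    for name, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has fewer than two replicates")
    inten = t.intensities
    logged = [np.log2(inten[list(cols)].to_numpy(dtype=float) + pseudocount)
              for cols in groups.values()]
    if len(t.df) == 0:
        return pd.DataFrame(columns=["p", "max_fold"], index=t.df.index)
    _, p = stats.f_oneway(*logged, axis=1)
    means = np.column_stack(
        [inten[list(cols)].mean(axis=1).to_numpy() + pseudocount for cols in groups.values()])
    maxfold = means.max(axis=1) / means.min(axis=1)
    # identical groups yield an undefined F; such peaks are non-responsive
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"p": p, "max_fold": maxfold}, index=t.df.index)


def filter_responsive(t: PeakTable, groups: Mapping[str, Sequence[str]],
                      alpha: float = 0.01, min_maxfold: float = 2.0,
                      keep_changing: bool = True) -> PeakTable:
    """ANOVA responsiveness filter.

    With keep_changing (default), retains peaks that change across groups:
    p < alpha and max-fold > min_maxfold. The inverted reading (retain
    stable peaks) is available via keep_changing=False.
    """
    res = anova_maxfold(t, groups)
    changing = (res["p"] < alpha) & (res["max_fold"] > min_maxfold)
    mask = changing if keep_changing else ~changing
    return PeakTable(t.df[mask.to_numpy()])


def run_peak_funnel(t: PeakTable, groups: Mapping[str, Sequence[str]],
                    cfg: PeakFilterConfig | None = None,
                    ) -> tuple[PeakTable, PeakFilterReport]:
    """Apply mass window, responsiveness, then fragment filter, with a report."""
    cfg = cfg or PeakFilterConfig()
    report = PeakFilterReport()
    report.add("input", t.peak_ids)
    t1 = filter_mass_window(t, cfg.mass_low, cfg.mass_high)
    report.add("mass_window", t1.peak_ids)
    t2 = filter_responsive(t1, groups, alpha=cfg.alpha, min_maxfold=cfg.min_maxfold,
                           keep_changing=cfg.keep_changing)
    report.add("responsiveness", t2.peak_ids)
    t3 = filter_fragmentless(t2)
    report.add("fragments", t3.peak_ids)
    return t3, report


def groups_from_samples(sample_ids: Sequence[str], by: str = "condition_time") -> dict[str, list[str]]:
    """Group time-course sample columns for the ANOVA.

    ``condition_time`` groups by (condition, time point); ``condition``
    pools all time points per condition. Tissue columns are ignored.
    """
    from .expression import parse_sample_id, TISSUE

    groups: dict[str, list[str]] = {}
    for sid in sample_ids:
        s = parse_sample_id(sid)
        if s.condition == TISSUE:
            continue
        key = f"{s.condition}_{s.time_h:g}h" if by == "condition_time" else s.condition
        groups.setdefault(key, []).append(sid)
    return groups
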