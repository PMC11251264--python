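"""Per-organoid screening readouts for probe prioritization.

Given a table of per-organoid mean probe intensities with line/day
metadata and a set of healthy-control lines, this module computes the
screening quantities used to rank fluorescence-guided-surgery probes:

* annotator-style positivity via per-probe intensity cutoffs (subtracted
  from the intensities, with a flag per organoid), and percent-positive
  per line;
* day/probe normalization by the 95th percentile of each (day, probe)
  group;
* in vitro tumor-to-background ratio (TBR): a line's mean intensity over
  the pooled healthy-control mean, with 1.5 as the conventional clinical
  acceptability cut-off;
* coverage: an organoid is covered by a probe when its raw intensity is at
  least one standard deviation above the healthy-control mean for that
  probe, and by a probe combination when at least one member probe covers
  it.  A 6-probe panel yields 57 combinations of two or more probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "ScreenTable",
    "TBR_CLINICAL_CUTOFF",
    "estimate_cutoffs",
    "apply_cutoff",
    "percent_positive",
    "normalize_day_probe",
    "tbr",
    "coverage_positivity",
    "combination_coverage",
    "enumerate_subsets",
    "probe_summary",
    "coverage_table",
]

#: conventional clinical acceptability cut-off for tumor-to-background ratio
TBR_CLINICAL_CUTOFF = 1.5


@dataclass
class ScreenTable:
    """A per-organoid intensity table plus the screen's metadata.

    ``df`` needs columns ``organoid_id``, ``line_id``, ``day_id`` and one
    column per probe in ``probe_panel``.  Lines in ``healthy_lines`` are the
    background reference; everything else is treated as tumor-derived.
    ``cutoffs`` maps probe -> positivity cutoff intensity (annotator-derived
    in the original screens; estimated or supplied here).
    """

    df: pd.DataFrame
    probe_panel: list[str]
    healthy_lines: set[str] = field(default_factory=set)
    cutoffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.probe_panel = list(self.probe_panel)
        self.healthy_lines = set(self.healthy_lines)
        missing = [p for p in self.probe_panel if p not in self.df.columns]
        if missing:
            raise ValueError(f"probe columns missing from table: {missing}")
        for col in ("organoid_id", "line_id", "day_id"):
            if col not in self.df.columns:
                raise ValueError(f"required column {col!r} missing")
        if self.df[self.probe_panel].isna().any().any():
            raise ValueError("probe intensities contain missing values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, probe_panel=None, healthy_lines=None, cutoffs=None):
        panel = probe_panel or df.attrs.get("probe_panel")
        if panel is None:
            raise ValueError("probe_panel not given and not stored on the dataframe")
        healthy = healthy_lines if healthy_lines is not None else df.attrs.get("healthy_lines", [])
        return cls(df.copy(), list(panel), set(healthy), dict(cutoffs or {}))

    @classmethod
    def from_csv(cls, path, probe_panel=None, healthy_lines=None, cutoffs=None):
        df = pd.read_csv(path)
        if probe_panel is None:
            reserved = {"organoid_id", "line_id", "day_id", "volume_um3", "saturated"}
            probe_panel = [c for c in df.columns if c not in reserved]
        return cls(df, list(probe_panel), set(healthy_lines or []), dict(cutoffs or {}))

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.df["line_id"]))

    @property
    def tumor_lines(self) -> list[str]:
        return [l for l in self.lines if l not in self.healthy_lines]

    def healthy_df(self) -> pd.DataFrame:
        if not self.healthy_lines:
            raise ValueError("no healthy-control lines defined")
        return self.df[self.df["line_id"].isin(self.healthy_lines)]

    def line_df(self, line: str) -> pd.DataFrame:
        sub = self.df[self.df["line_id"] == line]
        if sub.empty:
            raise ValueError(f"no records for line {line!r}")
        return sub

    def replace(self, **kw) -> "ScreenTable":
        return replace(self, **kw)


def estimate_cutoffs(table: ScreenTable, nbins: int = 256) -> dict[str, float]:
    """Two-component valley cutoff per probe (Otsu on pooled intensities).

    A stand-in for the original annotator-derived cutoffs, which cannot be
    reproduced computationally; supply annotator values via
    ``ScreenTable.cutoffs`` for a faithful re-analysis.
    """
    out = {}
    for probe in table.probe_panel:
        vals = table.df[probe].to_numpy(dtype=float)
        if np.min(vals) == np.max(vals):
            raise ValueError(f"cannot estimate a cutoff for constant probe {probe!r}")
        out[probe] = float(threshold_otsu(vals, nbins=nbins))
    return out


def apply_cutoff(table: ScreenTable) -> ScreenTable:
    """Subtract the per-probe cutoff and flag positive organoids.

    Intensities become ``max(0, intensity - cutoff)``; the positivity flag
    is strict (``intensity > cutoff``), so an organoid exactly at the
    cutoff is negative with residual intensity 0.  Flags are stored in
    ``<probe>_positive`` columns.
    """
    missing = [p for p in table.probe_panel if p not in table.cutoffs]
    if missing:
        raise ValueError(f"no cutoff defined for probes: {missing}")
    df = table.df.copy()
    for probe in table.probe_panel:
        cut = float(table.cutoffs[probe])
        raw = df[probe].to_numpy(dtype=float)
        df[f"{probe}_positive"] = raw > cut
        df[probe] = np.maximum(0.0, raw - cut)
    return table.replace(df=df)


def percent_positive(table: ScreenTable, line: str, probe: str) -> float:
    """Percentage of a line's organoids flagged positive for a probe."""
    flag_col = f"{probe}_positive"
    if flag_col not in table.df.columns:
        raise ValueError("run apply_cutoff first: positivity flags missing")
    sub = table.line_df(line)
    return 100.0 * float(sub[flag_col].sum()) / len(sub)


def normalize_day_probe(table: ScreenTable) -> ScreenTable:
    """Normalize intensities by the 95th percentile of each (day, probe) group.

    Uses the linear-interpolation quantile; afterwards each group's 95th
    percentile equals 1, removing day-to-day acquisition drift and
    probe-brightness differences before cross-probe comparison.
    """
    df = table.df.copy()
    for probe in table.probe_panel:
        for day, idx in df.groupby("day_id").groups.items():
            vals = df.loc[idx, probe].to_numpy(dtype=float)
            q95 = float(np.percentile(vals, 95.0))
            if q95 <= 0:
                raise ValueError(
                    f"95th percentile of (day={day!r}, probe={probe!r}) is not positive"
                )
            df.loc[idx, probe] = vals / q95
    return table.replace(df=df)


def tbr(table: ScreenTable, line: str, probe: str, per_line_healthy_mean: bool = False) -> float:
    """In vitro tumor-to-background ratio for a line and probe.

    Mean intensity over the line's organoids divided by the mean over the
    healthy-control organoids, pooled at the organoid level across all
    healthy lines (``per_line_healthy_mean=True`` averages per-line means
    instead).  Computed on whatever intensity scale the table carries;
    apply :func:`normalize_day_probe` first for the standard readout.
    """
    if probe not in table.probe_panel:
        raise ValueError(f"unknown probe {probe!r}")
    healthy = table.healthy_df()
    if per_line_healthy_mean:
        background = float(healthy.groupby("line_id")[probe].mean().mean())
    else:
        background = float(healthy[probe].mean())
    if background <= 0:
        raise ValueError(f"healthy-control mean for probe {probe!r} is not positive")
    return float(table.line_df(line)[probe].mean()) / background


def coverage_positivity(table: ScreenTable, probe: str) -> pd.Series:
    """Coverage flag per organoid: raw intensity >= healthy mean + 1 SD.

    The threshold is inclusive ("at least one standard deviation above"),
    with healthy statistics pooled over all healthy-control organoids per
    probe (sample standard deviation).  Intended for raw, pre-cutoff
    intensities — coverage is a separate binary readout from the
    annotator-cutoff positivity.
    """
    healthy_vals = table.healthy_df()[probe].to_numpy(dtype=float)
    if healthy_vals.size < 2:
        raise ValueError("need >= 2 healthy organoids for a defined standard deviation")
    thresh = healthy_vals.mean() + healthy_vals.std(ddof=1)
    return table.df[probe].astype(float) >= thresh


def combination_coverage(table: ScreenTable, line: str, subset) -> float:
    """Percent of a line's organoids positive for at least one probe in a subset."""
    subset = list(subset)
    if not subset:
        raise ValueError("probe subset must be non-empty")
    flags = pd.concat([coverage_positivity(table, p) for p in subset], axis=1).any(axis=1)
    in_line = table.df["line_id"] == line
    if not in_line.any():
        raise ValueError(f"no records for line {line!r}")
    return 100.0 * float(flags[in_line].sum()) / int(in_line.sum())


def enumerate_subsets(panel, min_size: int = 2) -> list[tuple[str, ...]]:
    """All probe subsets of size >= ``min_size``, ordered by (size, panel order).

    For a panel of n probes and ``min_size=2`` there are 2^n - 1 - n
    subsets; the six-probe screen therefore has 57 combinations (63
    counting singletons).
    """
    panel = list(panel)
    if not panel:
        raise ValueError("probe panel must be non-empty")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out: list[tuple[str, ...]] = []
    for k in range(min_size, len(panel) + 1):
        out.extend(combinations(panel, k))
    return out


def probe_summary(
    table: ScreenTable,
    normalized: bool = True,
    estimate_missing_cutoffs: bool = True,
) -> pd.DataFrame:
    """Line x probe summary: percent positive, normalized intensity, TBR.

    Follows the standard order of operations: cutoffs are applied on the
    raw scale for positivity, intensities are then day/probe-normalized and
    TBR computed on the normalized scale (``normalized=False`` uses raw
    intensities).  ``tbr_acceptable`` applies the 1.5 clinical cut-off.
    """
    work = table
    if estimate_missing_cutoffs and any(p not in work.cutoffs for p in work.probe_panel):
        cuts = dict(estimate_cutoffs(work))
        cuts.update(work.cutoffs)
        work = work.replace(cutoffs=cuts)
    flagged = apply_cutoff(work)
    scaled = normalize_day_probe(table) if normalized else table
    rows = []
    for line in table.lines:
        for probe in table.probe_panel:
            ratio = tbr(scaled, line, probe) if table.healthy_lines else np.nan
            rows.append(
                {
                    "line_id": line,
                    "probe": probe,
                    "percent_positive": percent_positive(flagged, line, probe),
                    "normalized_intensity": float(scaled.line_df(line)[probe].mean()),
                    "tbr": ratio,
                    "tbr_acceptable": bool(ratio > TBR_CLINICAL_CUTOFF)
                    if np.isfinite(ratio)
                    else False,
                }
            )
    return pd.DataFrame(rows)


def coverage_table(table: ScreenTable, min_size: int = 1, lines=None) -> pd.DataFrame:
    """Coverage percent for every line x probe subset, subsets joined by '+'."""
    subsets = enumerate_subsets(table.probe_panel, min_size=min_size)
    lines = list(lines) if lines is not None else table.tumor_lines
    flags = {p: coverage_positivity(table, p) for p in table.probe_panel}
    rows = []
    for line in lines:
        in_line = table.df["line_id"] == line
        n = int(in_line.sum())
        for subset in subsets:
            any_pos = pd.concat([flags[p] for p in subset], axis=1).any(axis=1)
            rows.append(
                {
                    "line_id": line,
                    "subset": "+".join(subset),
                    "subset_size": len(subset),
                    "coverage_percent": 100.0 * float(any_pos[in_line].sum()) / n,
                }
            )
    return pd.DataFrame(rows)
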