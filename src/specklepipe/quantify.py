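"""Per-ROI aggregation and two-group statistics.

Accepted condensate areas are binned on fixed µm² edges (defaults 1–5 µm²
at unit width plus an open last bin), one histogram per subject.  Groups
are compared per bin with an unpaired two-sample t-test on subject-level
counts (pooled-variance Student form by default, Welch optional), with
Holm–Šídák step-down adjustment across bins; the total count is tested
separately without correction.  The subject (animal / field), not the
condensate, is the statistical unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .images import Plane, RegionOfInterest
from .segment import CondensateRecord

__all__ = [
    "DEFAULT_BIN_EDGES",
    "AreaHistogram",
    "GroupComparison",
    "TTestOutcome",
    "histogram_areas",
    "histograms_from_table",
    "mean_intensity",
    "two_sample_t_test",
    "holm_sidak_adjust",
    "compare_groups",
]

#: default area bin edges in µm² (last edge opens an unbounded bin)
DEFAULT_BIN_EDGES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class AreaHistogram:
    """Binned accepted-condensate areas of one subject in one ROI.

    Bins are half-open [lo, hi); the last is [last_edge, ∞).  Areas below
    the first edge are excluded from the counts but reported in
    ``sub_threshold_count``.  ``total_count`` is the sum of the bin counts,
    i.e. the number of accepted objects with area ≥ first edge.
    """

    bin_edges_um2: tuple[float, ...]
    counts: tuple[int, ...]
    sub_threshold_count: int
    roi_name: str = ""
    subject_id: str = ""
    group: str = ""

    @property
    def total_count(self) -> int:
        return int(sum(self.counts))

    @property
    def bin_labels(self) -> tuple[str, ...]:
        e = self.bin_edges_um2
        labels = [f"[{e[i]:g},{e[i+1]:g})" for i in range(len(e) - 1)]
        labels.append(f"[{e[-1]:g},inf)")
        return tuple(labels)


def _validate_edges(bin_edges: Sequence[float]) -> np.ndarray:
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    return edges


def histogram_areas(
    records,
    bin_edges_um2: Sequence[float] = DEFAULT_BIN_EDGES,
    roi_name: str = "",
    subject_id: str = "",
    group: str = "",
) -> AreaHistogram:
    """Histogram accepted areas on half-open bins.

    ``records`` may be a list of :class:`CondensateRecord` (only accepted
    ones are counted) or a plain array of areas in µm².
    """
    edges = _validate_edges(bin_edges_um2)
    if len(records) and isinstance(records[0], CondensateRecord):
        areas = np.array([r.area_um2 for r in records if r.accepted], dtype=np.float64)
    else:
        areas = np.asarray(records, dtype=np.float64)
    counts, _ = np.histogram(areas, bins=np.append(edges, np.inf))
    sub = int(np.sum(areas < edges[0]))
    return AreaHistogram(
        bin_edges_um2=tuple(edges.tolist()),
        counts=tuple(int(c) for c in counts),
        sub_threshold_count=sub,
        roi_name=roi_name,
        subject_id=subject_id,
        group=group,
    )


def histograms_from_table(
    table: pd.DataFrame,
    bin_edges_um2: Sequence[float] = DEFAULT_BIN_EDGES,
    roi_name: str = "",
) -> list[AreaHistogram]:
    """One histogram per subject from a long table with columns
    subject_id, group, area_um2."""
    out = []
    for (subject, group), df in table.groupby(["subject_id", "group"], sort=True):
        out.append(
            histogram_areas(
                df["area_um2"].to_numpy(),
                bin_edges_um2,
                roi_name=roi_name,
                subject_id=str(subject),
                group=str(group),
            )
        )
    return out


def histograms_to_frame(histograms: Sequence[AreaHistogram]) -> pd.DataFrame:
    """Wide table, one row per subject histogram (the CSV schema)."""
    rows = []
    for h in histograms:
        row = {
            "subject_id": h.subject_id,
            "group": h.group,
            "roi_name": h.roi_name,
            "bin_edges_um2": ",".join(f"{e:g}" for e in h.bin_edges_um2),
        }
        row.update({f"count_{lab}": c for lab, c in zip(h.bin_labels, h.counts)})
        row["sub_threshold_count"] = h.sub_threshold_count
        row["total_count"] = h.total_count
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_histograms(frame: pd.DataFrame) -> list[AreaHistogram]:
    """Inverse of :func:`histograms_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        edges = tuple(float(x) for x in str(row["bin_edges_um2"]).split(","))
        count_cols = [c for c in frame.columns if c.startswith("count_")]
        out.append(
            AreaHistogram(
                bin_edges_um2=edges,
                counts=tuple(int(row[c]) for c in count_cols),
                sub_threshold_count=int(row["sub_threshold_count"]),
                roi_name=str(row["roi_name"]),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
            )
        )
    return out


def mean_intensity(raw: Plane, roi: RegionOfInterest) -> float:
    """Arithmetic mean of the raw intensities over the ROI pixels."""
    if roi.mask.shape != raw.shape:
        raise ValueError("ROI mask and plane must share one shape")
    if roi.n_pixels == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    return float(np.asarray(raw.data, dtype=np.float64)[roi.mask].mean())


class TTestOutcome(NamedTuple):
    t: float
    df: float
    p: float


def two_sample_t_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestOutcome:
    """Two-sided unpaired t-test; pooled-variance Student form by default,
    Welch with ``welch=True``.

    When both groups are constant and equal (zero standard error, zero
    difference) the result is t = 0, p = 1; a nonzero difference at zero
    standard error gives ±inf and p = 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain only finite values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        diff = a.mean() - b.mean()
        if diff == 0:
            return TTestOutcome(0.0, df, 1.0)
        return TTestOutcome(float(np.sign(diff) * np.inf), df, 0.0)
    with warnings.catch_warnings():
        # near-constant count vectors are routine in sparse area bins
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestOutcome(float(res.statistic), float(res.df), float(res.pvalue))


def holm_sidak_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Holm–Šídák step-down adjusted p-values, in the input order.

    Sorted ascending, adjusted p(i) = running max of 1 − (1 − p(j))^(m−j+1),
    capped at 1.
    """
    p = np.asarray(raw_p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 hits log1p(-1) internally
        return multipletests(p, method="holm-sidak")[1]


@dataclass(frozen=True)
class GroupComparison:
    """Per-bin and total-count comparison of two groups.

    ``per_bin`` has one row per area bin: group means ± SEM of the
    subject-level counts, t, df, raw p and Holm–Šídák-adjusted p.
    ``total`` is the same test on total counts, uncorrected.
    """

    group_names: tuple[str, str]
    n_per_group: tuple[int, int]
    per_bin: pd.DataFrame
    total: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Per-bin rows plus a final total-count row (the CSV schema)."""
        total_row = self.total.to_frame().T
        total_row.insert(0, "bin", "total")
        per = self.per_bin.copy()
        per = per.rename(columns={"bin_label": "bin"})
        out = pd.concat([per, total_row], ignore_index=True)
        return out


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_groups(
    histograms: Sequence[AreaHistogram], welch: bool = False
) -> GroupComparison:
    """Compare two groups of per-subject histograms.

    Requires exactly two group labels with at least two subjects each and a
    common bin layout.  Adjustment spans the area bins only; the total-count
    test is reported raw (it is a single test).
    """
    if not histograms:
        raise ValueError("no histograms given")
    edges = histograms[0].bin_edges_um2
    if any(h.bin_edges_um2 != edges for h in histograms):
        raise ValueError("histograms must share bin edges")
    groups: list[str] = []
    for h in histograms:
        if h.group not in groups:
            groups.append(h.group)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    counts_a = np.array([h.counts for h in histograms if h.group == ga], dtype=np.float64)
    counts_b = np.array([h.counts for h in histograms if h.group == gb], dtype=np.float64)
    if counts_a.shape[0] < 2 or counts_b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")

    labels = histograms[0].bin_labels
    rows = []
    raw_ps = []
    for j, label in enumerate(labels):
        res = two_sample_t_test(counts_a[:, j], counts_b[:, j], welch=welch)
        rows.append(
            {
                "bin_label": label,
                f"mean_{ga}": counts_a[:, j].mean(),
                f"sem_{ga}": _sem(counts_a[:, j]),
                f"mean_{gb}": counts_b[:, j].mean(),
                f"sem_{gb}": _sem(counts_b[:, j]),
                "t": res.t,
                "df": res.df,
                "p_raw": res.p,
            }
        )
        raw_ps.append(res.p)
    per_bin = pd.DataFrame(rows)
    per_bin["p_adj"] = holm_sidak_adjust(raw_ps)

    tot_a = counts_a.sum(axis=1)
    tot_b = counts_b.sum(axis=1)
    res = two_sample_t_test(tot_a, tot_b, welch=welch)
    total = pd.Series(
        {
            f"mean_{ga}": tot_a.mean(),
            f"sem_{ga}": _sem(tot_a),
            f"mean_{gb}": tot_b.mean(),
            f"sem_{gb}": _sem(tot_b),
            "t": res.t,
            "df": res.df,
            "p_raw": res.p,
            "p_adj": res.p,
        }
    )
    return GroupComparison(
        group_names=(ga, gb),
        n_per_group=(counts_a.shape[0], counts_b.shape[0]),
        per_bin=per_bin,
        total=total,
    )
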