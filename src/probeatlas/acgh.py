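"""Two-channel comparative genomic hybridization analytics.

A probe-selection array is hybridized with genomic DNA of the target species
(channel *t*) against a reference species (channel *r*), both on the log2
scale.  Probes are placed on an MA plane — here M = t − r and A = t + r, the
*sum* of the two log2 signals — and assigned to categories by three
thresholds:

* parameter I  — a strong target-channel signal (default log2 signal 10),
* parameter II — an intermediate target-channel signal (default 8),
* parameter III — a target/reference log2 ratio separating species-specific
  hybridization (default 1).

Category A: strong and specific (t > I, M > III).  Category B: intermediate
and specific (II < t ≤ I, M > III).  Category C: strong but non-specific
(t > I, M ≤ III).  Everything else is rejected.  Boundary convention: t = I
belongs to B, M = III belongs to C; the four outcomes partition the plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("A", "B", "C", "rejected")
SELECTED_CATEGORIES = frozenset({"A", "B", "C"})


@dataclass
class AcghThresholds:
    """The three signal-intensity parameters defining categories A/B/C."""

    param_I: float = 10.0
    param_II: float = 8.0
    param_III: float = 1.0

    def __post_init__(self) -> None:
        if not self.param_II < self.param_I:
            raise ValueError("require param_II < param_I")


@dataclass
class HybStats:
    """Per-probe two-channel statistics and assigned category."""

    probe_id: str
    t: float
    r: float
    M: float
    A: float
    category: str


def ma_stats(t: float, r: float) -> tuple[float, float]:
    """(M, A) = (t − r, t + r) from two log2 channel signals (A is summed,
    not averaged)."""
    if not (math.isfinite(t) and math.isfinite(r)):
        raise ValueError(f"non-finite channel signal: t={t}, r={r}")
    return t - r, t + r


def categorize_probe(t: float, M: float, th: AcghThresholds | None = None) -> str:
    """Category of a single probe from its target signal and log ratio."""
    th = th or AcghThresholds()
    if t > th.param_I:
        return "A" if M > th.param_III else "C"
    if th.param_II < t <= th.param_I and M > th.param_III:
        return "B"
    return "rejected"


def categorize_table(
    intensities: pd.DataFrame,
    th: AcghThresholds | None = None,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Vectorized MA statistics + categories for an intensity table.

    Expects columns (probe_id, t_log2, r_log2), already log2-transformed
    unless ``log2_transform`` is set.  Returns the table with M, A and
    category columns appended.  A hook point for user normalization exists
    upstream: signals are used exactly as supplied.
    """
    th = th or AcghThresholds()
    df = intensities.copy()
    t = df["t_log2"].to_numpy(dtype=float)
    r = df["r_log2"].to_numpy(dtype=float)
    if log2_transform:
        t, r = np.log2(t), np.log2(r)
        df["t_log2"], df["r_log2"] = t, r
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("non-finite channel signals in intensity table")
    M = t - r
    A = t + r
    cat = np.full(len(df), "rejected", dtype=object)
    strong = t > th.param_I
    specific = M > th.param_III
    cat[strong & specific] = "A"
    cat[(t > th.param_II) & ~strong & specific] = "B"
    cat[strong & ~specific] = "C"
    df["M"] = M
    df["A"] = A
    df["category"] = cat
    return df


def selection_rates(
    stats: pd.DataFrame, labels: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-origin selection rates (fraction with category in {A,B,C}).

    ``labels`` maps probe_id → origin (e.g. ngs_read, negative_control).
    Every probe must be labeled.  Returns one row per origin with n, counts
    per category, n_selected and rate_pct.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    unlabeled = stats.loc[~stats["probe_id"].isin(labels.index), "probe_id"]
    if len(unlabeled):
        raise ValueError(f"unlabeled probes: {list(unlabeled.head())}")
    df = stats.assign(origin=stats["probe_id"].map(labels))
    rows = []
    for origin, grp in df.groupby("origin", sort=True):
        counts = {c: int((grp["category"] == c).sum()) for c in CATEGORIES}
        n_sel = counts["A"] + counts["B"] + counts["C"]
        rows.append(
            {
                "origin": origin,
                "n": len(grp),
                **{f"n_{c}": counts[c] for c in CATEGORIES},
                "n_selected": n_sel,
                "rate_pct": round(100.0 * n_sel / len(grp), 1) if len(grp) else None,
            }
        )
    return pd.DataFrame(rows)


def gc_bin_profile(
    probes, signals: dict[str, float], bin_width: float = 0.05
) -> pd.DataFrame:
    """Signal distribution per GC bin (count, quartiles, median).

    Bins are [k·w, (k+1)·w) with the last bin closed at 1.0, mirroring a
    20-bin GC diagnostic at the default width of 5%.  Probes without a
    signal entry are skipped.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    binned: dict[int, list[float]] = {}
    for p in probes:
        if p.probe_id not in signals:
            continue
        k = min(int(p.gc / bin_width), n_bins - 1)  # last bin closed
        binned.setdefault(k, []).append(signals[p.probe_id])
    rows = []
    for k in range(n_bins):
        vals = np.asarray(binned.get(k, []), dtype=float)
        rows.append(
            {
                "bin_lo": round(k * bin_width, 10),
                "bin_hi": round((k + 1) * bin_width, 10),
                "count": len(vals),
                "q1": float(np.percentile(vals, 25)) if len(vals) else None,
                "median": float(np.median(vals)) if len(vals) else None,
                "q3": float(np.percentile(vals, 75)) if len(vals) else None,
            }
        )
    return pd.DataFrame(rows)
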