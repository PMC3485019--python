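"""Gene-expression-channel analytics: 3′ population calls, ranking, positions.

The expression experiment co-hybridizes two amplifications of the same mRNA
pool: a *regular* oligo-dT linear amplification (3′-biased cDNA, channel
``reg``) and a ddNTP-truncated amplification whose chain terminators restrict
labeled material tightly to the 3′ end (channel ``res``).  On the resulting
MA plane (M = reg − res, A = reg + res) three probe populations appear:

* ``three_prime`` — good signal in both protocols: the target sits near the
  transcript's 3′ end;
* ``middle``      — good regular but poor restricted signal: the target sits
  further 5′;
* ``absent``      — poor signal in both: target too far 5′, expressed below
  detection, or not present in the transcriptome at all.

The populations overlap, so selection does not threshold them; instead
probes are *ranked* by signal strength (restricted channel first — it is the
channel that certifies 3′ proximity) and the greedy selector consumes that
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POPULATIONS = ("three_prime", "middle", "absent")
RANK_KEYS = ("res", "reg", "sum")


@dataclass
class PositionRecord:
    """Relative position of a probe target on an isotig (0 = 5′, 1 = 3′)."""

    probe_id: str
    isotig_id: str
    rel_pos: float


def add_ma(records: pd.DataFrame) -> pd.DataFrame:
    """Append M_ge = reg − res and A_ge = reg + res columns."""
    df = records.copy()
    reg = df["reg_log2"].to_numpy(dtype=float)
    res = df["res_log2"].to_numpy(dtype=float)
    if not (np.isfinite(reg).all() and np.isfinite(res).all()):
        raise ValueError("non-finite signals in expression table")
    df["M_ge"] = reg - res
    df["A_ge"] = reg + res
    return df


def default_a_cut(records: pd.DataFrame, fallback: float = 16.0) -> float:
    """Data-driven combined-intensity cutoff: 75th percentile of the
    negative controls' A_ge when an ``origin`` column identifies them,
    else ``fallback``."""
    if "origin" in records.columns:
        neg = records.loc[records["origin"] == "negative_control"]
        if len(neg):
            neg = add_ma(neg) if "A_ge" not in neg.columns else neg
            return float(np.percentile(neg["A_ge"], 75))
    return fallback


def classify_population(
    records: pd.DataFrame,
    a_cut: float | None = None,
    m_cut: float = 2.0,
) -> pd.DataFrame:
    """Label each probe three_prime / middle / absent on the (A_ge, M_ge)
    plane.

    ``three_prime``: A_ge > a_cut and M_ge ≤ m_cut (both protocols deliver).
    ``middle``: A_ge > a_cut and M_ge > m_cut (restricted channel dropped
    out).  ``absent`` otherwise.  ``a_cut`` defaults to the negative-control
    75th A_ge percentile when controls are present.
    """
    df = records if "A_ge" in records.columns else add_ma(records)
    df = df.copy()
    if a_cut is None:
        a_cut = default_a_cut(df)
    pop = np.full(len(df), "absent", dtype=object)
    expressed = df["A_ge"].to_numpy(dtype=float) > a_cut
    m_high = df["M_ge"].to_numpy(dtype=float) > m_cut
    pop[expressed & ~m_high] = "three_prime"
    pop[expressed & m_high] = "middle"
    df["population"] = pop
    return df


def rank_probes(records: pd.DataFrame, key: str = "res") -> pd.DataFrame:
    """Assign a total selection order (rank 1..n, 1 = best).

    Primary key per ``key``: the restricted channel (default; certifies 3′
    proximity), the regular channel, or their sum.  Ties broken by the other
    channel descending, then probe_id ascending — a deterministic,
    input-order-independent total order.
    """
    if key not in RANK_KEYS:
        raise ValueError(f"rank key must be one of {RANK_KEYS}")
    df = records if "A_ge" in records.columns else add_ma(records)
    df = df.copy()
    if key == "res":
        cols, asc = ["res_log2", "reg_log2", "probe_id"], [False, False, True]
    elif key == "reg":
        cols, asc = ["reg_log2", "res_log2", "probe_id"], [False, False, True]
    else:
        cols, asc = ["A_ge", "res_log2", "probe_id"], [False, False, True]
    df = df.sort_values(cols, ascending=asc, kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def relative_positions(
    matches,
    isotigs: dict,
    probe_lengths: dict[str, int] | int = 60,
) -> list[PositionRecord]:
    """Midpoint of each match as a fraction of its isotig's length.

    rel_pos = (match_start + probe_len/2) / isotig_length, clipped to [0,1];
    isotig sequences are assumed stored 5′→3′, so 1.0 is the 3′ terminus.
    """
    out = []
    for m in matches:
        if m.target_id not in isotigs:
            raise KeyError(f"match references unknown isotig {m.target_id!r}")
        length = len(isotigs[m.target_id])
        plen = (
            probe_lengths
            if isinstance(probe_lengths, int)
            else probe_lengths[m.probe_id]
        )
        rel = (m.match_start + plen / 2.0) / length
        out.append(
            PositionRecord(m.probe_id, m.target_id, min(1.0, max(0.0, rel)))
        )
    return out


def positions_to_frame(positions: list[PositionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"probe_id": p.probe_id, "isotig_id": p.isotig_id, "rel_pos": p.rel_pos}
            for p in positions
        ],
        columns=["probe_id", "isotig_id", "rel_pos"],
    )


def position_density(
    positions: list[PositionRecord], bin_width: float = 0.02
) -> pd.DataFrame:
    """Binned rel_pos counts (default 0.02-wide bins), for density plots."""
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    vals = [p.rel_pos for p in positions]
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts.astype(int),
        }
    )
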