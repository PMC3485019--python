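"""Candidate-probe generation on reads/ESTs and sequence-level filtering.

Probes are fixed-length oligos (60-mers by default, the standard length for
high-density ink-jet arrays) tiled on the forward strand of each eligible
source.  A source is eligible if it is strictly longer than 60 bp and — by
default — free of unknown bases.  Candidate windows are screened for GC
content (hybridization background rises steeply with GC), homopolymer runs
and tandem dinucleotide repeats (low-complexity sequence cross-hybridizes),
and finally for long exact words shared between probes from unrelated
sources (a proxy for cross-hybridization on the array).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import groupby

import pandas as pd

from .core import SequenceRecord, write_table

DISCARD_REASONS = (
    "short_source",
    "has_n",
    "gc",
    "homopolymer",
    "dinucleotide",
    "cross_hyb",
)


@dataclass
class DesignConstraints:
    """Source- and window-level constraints for candidate probes.

    ``min_source_len`` is the smallest usable source length (61 ⇒ sources
    must be strictly longer than 60 bp).  ``gc_ramp_threshold`` is the GC
    fraction above which array background starts climbing; it is diagnostic
    only and does not filter.
    """

    min_source_len: int = 61
    forbid_n: bool = True
    probe_len: int = 60
    max_gc: float = 0.50
    gc_ramp_threshold: float = 0.45

    def __post_init__(self) -> None:
        if not 0 < self.probe_len <= self.min_source_len:
            raise ValueError("require 0 < probe_len <= min_source_len")
        if not 0 <= self.max_gc <= 1:
            raise ValueError("max_gc must be a fraction")


@dataclass
class ComplexityConstraints:
    """Low-complexity limits: longest allowed homopolymer run and longest
    allowed tandem repeat of a two-base unit (distinct bases)."""

    max_homopolymer_run: int = 7
    max_dinucleotide_repeats: int = 5

    def __post_init__(self) -> None:
        if self.max_homopolymer_run < 1 or self.max_dinucleotide_repeats < 1:
            raise ValueError("complexity limits must be >= 1")


@dataclass
class Probe:
    """A designed oligo: source, position (0-based, forward strand), sequence."""

    probe_id: str
    source_id: str
    start: int
    strand: str
    sequence: str
    gc: float
    origin: str = "ngs_read"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"probe {self.probe_id}: bad strand {self.strand!r}")


def gc_content(sequence: str) -> float:
    """GC fraction; N counts toward the length but not the GC tally."""
    if not sequence:
        raise ValueError("gc_content of empty sequence")
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def eligible_sources(
    records: list[SequenceRecord], c: DesignConstraints
) -> list[SequenceRecord]:
    """Sources long enough to design on and (optionally) free of N bases."""
    out = []
    for r in records:
        if len(r) < c.min_source_len:
            continue
        if c.forbid_n and r.has_n:
            continue
        out.append(r)
    return out


def max_homopolymer_run(sequence: str) -> int:
    return max((len(list(g)) for _, g in groupby(sequence)), default=0)


def homopolymer_ok(sequence: str, c: ComplexityConstraints) -> bool:
    """True iff the longest single-base run is within the allowed limit."""
    return max_homopolymer_run(sequence) <= c.max_homopolymer_run


_DINUC_RE_CACHE: dict[int, re.Pattern] = {}


def dinucleotide_ok(sequence: str, c: ComplexityConstraints) -> bool:
    """True iff no two-base unit XY (X ≠ Y) tandemly repeats more than the
    allowed number of times.  Homopolymers (XX units) are governed solely by
    the homopolymer rule."""
    k = c.max_dinucleotide_repeats
    pat = _DINUC_RE_CACHE.get(k)
    if pat is None:
        # lookahead so every start phase is examined, including repeats
        # overlapping an earlier match
        pat = re.compile(r"(?=(..)\1{%d,})" % k)
        _DINUC_RE_CACHE[k] = pat
    for m in pat.finditer(sequence):
        unit = m.group(1)
        if unit[0] != unit[1]:
            return False
    return True


def window_passes(
    window: str, c: DesignConstraints, cc: ComplexityConstraints
) -> str | None:
    """Reason code for rejecting a candidate window, or None if it passes."""
    if gc_content(window) > c.max_gc:
        return "gc"
    if not homopolymer_ok(window, cc):
        return "homopolymer"
    if not dinucleotide_ok(window, cc):
        return "dinucleotide"
    return None


@dataclass
class DiscardLog:
    """Accumulates per-source / per-probe discard records with reason codes."""

    rows: list[dict] = field(default_factory=list)

    def add(self, item_id: str, source_id: str, reason: str, detail: str = "") -> None:
        assert reason in DISCARD_REASONS, reason
        self.rows.append(
            {"id": item_id, "source_id": source_id, "reason": reason, "detail": detail}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "source_id", "reason", "detail"])

    def write(self, path) -> None:
        write_table(self.to_frame(), path)


def design_candidate_probes(
    sources: list[SequenceRecord],
    c: DesignConstraints,
    per_source: int = 1,
    cc: ComplexityConstraints | None = None,
    origin: str = "ngs_read",
    discard_log: DiscardLog | None = None,
) -> list[Probe]:
    """Tile probe windows on each source and keep the best ``per_source``.

    All ``probe_len`` windows on the forward strand are enumerated; windows
    failing GC or complexity are dropped (logged if a log is given).  Among
    passing windows, preference is (1) closest to the source 3′ end —
    expression arrays read out the 3′ end of transcripts — then (2) GC
    closest to 0.40, then lowest start.  Deterministic.
    """
    cc = cc or ComplexityConstraints()
    probes: list[Probe] = []
    for rec in sources:
        if len(rec) < c.probe_len:
            if discard_log is not None:
                discard_log.add(rec.id, rec.id, "short_source", f"len={len(rec)}")
            continue
        n_windows = len(rec) - c.probe_len + 1
        passing: list[tuple[int, str, float]] = []
        for start in range(n_windows):
            window = rec.sequence[start : start + c.probe_len]
            reason = window_passes(window, c, cc)
            if reason is None:
                passing.append((start, window, gc_content(window)))
            elif discard_log is not None:
                discard_log.add(f"{rec.id}:{start}", rec.id, reason)
        # 3'-most first; ties (impossible across distinct starts, kept for
        # clarity of intent) broken by GC proximity to 0.40.
        passing.sort(key=lambda t: (n_windows - 1 - t[0], abs(t[2] - 0.40), t[0]))
        for start, window, gc in passing[: max(per_source, 0)]:
            probes.append(
                Probe(
                    probe_id=f"{rec.id}|{start}",
                    source_id=rec.id,
                    start=start,
                    strand="+",
                    sequence=window,
                    gc=gc,
                    origin=origin,
                )
            )
    return probes


def cross_hyb_screen(
    probes: list[Probe],
    w: int = 24,
    max_shared: int = 0,
    isogroup_of_source: dict[str, str] | None = None,
    discard_log: DiscardLog | None = None,
) -> tuple[list[Probe], list[Probe]]:
    """Discard probes sharing long exact words across unrelated sources.

    A probe is discarded when more than ``max_shared`` of its ``w``-mers are
    also present in a probe from a different source — unless both sources map
    to the same isogroup under ``isogroup_of_source`` (shared exons within a
    gene are legitimate shared sequence).  Symmetric: both members of an
    offending pair are discarded.  Output is independent of input order.
    """
    def group_key(p: Probe) -> str:
        if isogroup_of_source and p.source_id in isogroup_of_source:
            return "ig:" + isogroup_of_source[p.source_id]
        return "src:" + p.source_id

    word_groups: dict[str, set[str]] = {}
    for p in probes:
        g = group_key(p)
        seq = p.sequence
        for i in range(len(seq) - w + 1):
            word_groups.setdefault(seq[i : i + w], set()).add(g)

    retained, discarded = [], []
    for p in probes:
        g = group_key(p)
        seq = p.sequence
        n_foreign = sum(
            1
            for i in range(len(seq) - w + 1)
            if word_groups.get(seq[i : i + w], set()) - {g}
        )
        if n_foreign > max_shared:
            discarded.append(p)
            if discard_log is not None:
                discard_log.add(
                    p.probe_id, p.source_id, "cross_hyb", f"shared_{w}mers={n_foreign}"
                )
        else:
            retained.append(p)
    return retained, discarded


def probes_to_frame(probes: list[Probe]) -> pd.DataFrame:
    cols = ["probe_id", "source_id", "start", "strand", "sequence", "gc", "origin"]
    return pd.DataFrame(
        [{c: getattr(p, c) for c in cols} for p in probes], columns=cols
    )


def probes_from_frame(df: pd.DataFrame) -> list[Probe]:
    return [
        Probe(
            probe_id=row.probe_id,
            source_id=row.source_id,
            start=int(row.start),
            strand=row.strand,
            sequence=row.sequence,
            gc=float(row.gc),
            origin=row.origin,
        )
        for row in df.itertuples(index=False)
    ]
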