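"""Probe-to-transcript local alignment, bit scores and isogroup uniqueness.

A probe has a *good match* to a transcript when the optimal Smith–Waterman
local alignment, converted to a bit score with the Karlin–Altschul relation
bits = (λ·S − ln K) / ln 2, exceeds a threshold (80 bits by default — a
perfect 60-mer scores ≈ 112 bits under the default +1/−2 scheme, so up to
roughly five mismatches still clear the bar).  Uniqueness is judged at the
isogroup level: shared exons legitimately place a probe on several isotigs
of one gene, but a probe touching two isogroups cannot be attributed.

The dynamic programming itself is delegated to Biopython's PairwiseAligner;
this module owns the scoring scheme, both-strand search, the bit conversion,
an optional provably score-safe word seeding prefilter, and the uniqueness
rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement

from .core import TranscriptomeAssembly, write_table


@dataclass
class ScoringScheme:
    """Nucleotide local-alignment scoring plus Karlin–Altschul constants.

    Gap convention: a gap of length L scores gap_open + (L−1)·gap_extend.
    λ and K approximate the ungapped +1/−2 nucleotide regime.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.lam <= 0 or not 0 < self.K < 1:
            raise ValueError("require lam > 0 and 0 < K < 1")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match_reward
        a.mismatch_score = self.mismatch_penalty
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a


@dataclass
class ProbeMatch:
    """A scored local alignment of a probe to one target sequence."""

    probe_id: str
    target_id: str
    target_level: str
    strand: str
    match_start: int
    raw_score: int
    bits: float
    good: bool


@dataclass
class AlignmentHit:
    raw_score: int
    strand: str
    target_start: int


def bit_score(raw_score: float, s: ScoringScheme | None = None) -> float:
    """Karlin–Altschul normalized score: (λ·S − ln K) / ln 2."""
    s = s or ScoringScheme()
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return (s.lam * raw_score - math.log(s.K)) / math.log(2)


def min_raw_score(threshold_bits: float, s: ScoringScheme | None = None) -> int:
    """Smallest integer raw score whose bit score strictly exceeds the
    threshold."""
    s = s or ScoringScheme()
    S = (threshold_bits * math.log(2) + math.log(s.K)) / s.lam
    return math.floor(S) + 1


def safe_seed_word(
    threshold_bits: float, query_len: int, s: ScoringScheme | None = None
) -> int:
    """Largest word size w such that *every* alignment clearing the bit
    threshold must contain an exact match of length w.

    Consider an alignment whose exact-match runs are all ≤ L = w − 1 long.
    With k runs, m matched bases obey m ≤ k·L; consecutive runs are
    separated by a mismatch (which also consumes one query base, so
    m ≤ query_len − #mismatch-separators) or by a query gap (consumes no
    query base but costs gap_open).  Maximizing the score over k and the
    separator mix bounds what such an alignment can reach; the returned w is
    the largest for which that bound stays below the minimum raw score — so
    seeding with w-mers can never discard a true hit.  The bound is tight
    (a clearing alignment with no (w+1)-mer exists).
    """
    s = s or ScoringScheme()
    need = min_raw_score(threshold_bits, s)

    def best_with_runs_at_most(L: int) -> float:
        best = -math.inf
        for k in range(1, query_len + 1):
            for a in range(k):  # a mismatch separators, k-1-a gap separators
                b = k - 1 - a
                m = min(k * L, query_len - a)
                if m < 1:
                    continue
                best = max(
                    best,
                    m * s.match_reward
                    + a * s.mismatch_penalty
                    + b * s.gap_open,
                )
        return best

    # grow L while alignments whose runs are all <= L still cannot clear the
    # threshold; the safe word size is one more than the largest such L
    L = 0
    while L < query_len and best_with_runs_at_most(L + 1) < need:
        L += 1
    return L + 1


def _shares_word(query: str, subject: str, w: int) -> bool:
    if w > len(query) or w > len(subject):
        return False
    words = {query[i : i + w] for i in range(len(query) - w + 1)}
    return any(subject[i : i + w] in words for i in range(len(subject) - w + 1))


def local_align(
    query: str, subject: str, s: ScoringScheme | None = None
) -> AlignmentHit:
    """Best Smith–Waterman local alignment of the query against both strands
    of the subject.

    Returns the raw score, the subject strand of the best hit ('+' preferred
    on ties) and the hit's start on the forward subject strand.  A score of
    0 means no positive-scoring local alignment exists.
    """
    s = s or ScoringScheme()
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = s.aligner()
    best = AlignmentHit(0, "+", 0)
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        score = aligner.score(subject, q)
        if score > best.raw_score:
            aln = next(iter(aligner.align(subject, q)))
            start = int(aln.coordinates[0][0])
            best = AlignmentHit(int(score), strand, start)
    return best


def good_matches(
    probe,
    assembly: TranscriptomeAssembly,
    s: ScoringScheme | None = None,
    threshold: float = 80.0,
    levels: tuple[str, ...] = ("isotig", "singleton"),
    seed: bool = True,
) -> list[ProbeMatch]:
    """All targets the probe aligns to above the bit threshold (strict >).

    With ``seed`` enabled, target sequences sharing no exact word of the
    provably safe size (see :func:`safe_seed_word`) with the probe (either
    strand) are skipped without alignment; this cannot lose a true hit.
    """
    s = s or ScoringScheme()
    seq = probe.sequence if hasattr(probe, "sequence") else str(probe)
    pid = getattr(probe, "probe_id", "query")
    w = safe_seed_word(threshold, len(seq), s) if seed else 0
    rc = reverse_complement(seq)
    need = min_raw_score(threshold, s)
    out: list[ProbeMatch] = []
    pools = {"isotig": assembly.isotigs, "singleton": assembly.singletons}
    for level in levels:
        for tid, rec in pools[level].items():
            subject = rec.sequence
            if w and not (
                _shares_word(seq, subject, w) or _shares_word(rc, subject, w)
            ):
                continue
            hit = local_align(seq, subject, s)
            if hit.raw_score < need:
                continue
            bits = bit_score(hit.raw_score, s)
            if bits > threshold:
                out.append(
                    ProbeMatch(
                        probe_id=pid,
                        target_id=tid,
                        target_level=level,
                        strand=hit.strand,
                        match_start=hit.target_start,
                        raw_score=hit.raw_score,
                        bits=bits,
                        good=True,
                    )
                )
    return out


def uniqueness(
    matches: list[ProbeMatch], assembly: TranscriptomeAssembly
) -> tuple[str | None, str | None]:
    """Attribute a probe's good matches to a single unit, if possible.

    Returns ``(unit_id, level)``: the isogroup id (level ``"isogroup"``) if
    every good isotig match falls in one isogroup; else, if the probe has no
    isotig matches and exactly one good singleton match, that singleton
    (level ``"singleton"``); else ``(None, None)``.
    """
    good = [m for m in matches if m.good]
    iso_matches = {m.target_id for m in good if m.target_level == "isotig"}
    sing_matches = {m.target_id for m in good if m.target_level == "singleton"}
    if iso_matches:
        ig_of = assembly.isogroup_of
        igs = {ig_of[t] for t in iso_matches}
        if len(igs) == 1:
            return igs.pop(), "isogroup"
        return None, None
    if len(sing_matches) == 1:
        return sing_matches.pop(), "singleton"
    return None, None


def matches_to_frame(matches: list[ProbeMatch]) -> pd.DataFrame:
    cols = [
        "probe_id",
        "target_id",
        "target_level",
        "strand",
        "match_start",
        "raw_score",
        "bits",
        "good",
    ]
    return pd.DataFrame(
        [{c: getattr(m, c) for c in cols} for m in matches], columns=cols
    )


def matches_from_frame(df: pd.DataFrame) -> list[ProbeMatch]:
    """Import externally produced tabular hits (e.g. from a standalone
    aligner run) into ProbeMatch records."""
    return [
        ProbeMatch(
            probe_id=r.probe_id,
            target_id=r.target_id,
            target_level=r.target_level,
            strand=r.strand,
            match_start=int(r.match_start),
            raw_score=int(r.raw_score),
            bits=float(r.bits),
            good=bool(r.good),
        )
        for r in df.itertuples(index=False)
    ]


def match_all(
    probes,
    assembly: TranscriptomeAssembly,
    s: ScoringScheme | None = None,
    threshold: float = 80.0,
    seed: bool = True,
) -> dict[str, list[ProbeMatch]]:
    """Good matches for every probe, keyed by probe_id (empty list allowed)."""
    s = s or ScoringScheme()
    return {
        p.probe_id: good_matches(p, assembly, s, threshold, seed=seed)
        for p in probes
    }


def write_uniqueness_table(
    assignments: dict[str, tuple[str | None, str | None]], path
) -> None:
    rows = [
        {"probe_id": pid, "assigned_unit": unit, "unit_level": level}
        for pid, (unit, level) in assignments.items()
    ]
    write_table(
        pd.DataFrame(rows, columns=["probe_id", "assigned_unit", "unit_level"]), path
    )
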