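"""Greedy rank-ordered probe selection and coverage reporting.

The final expression array should interrogate every transcript uniquely with
as few probes as possible.  After four independent per-probe filters —
(1) hybridization category from the genomic (aCGH) screen, (2) at least one
good match at the level being processed, (3) uniqueness to one isogroup (or
one singleton), (4) sequence-complexity constraints — the survivors are
walked in expression-rank order.  A probe is selected iff it good-matches at
least one isotig of its isogroup that is not yet covered; an isogroup stops
accepting probes once all its isotigs are covered.  The isotig set is
processed first, then the singleton set; a probe selected for the isotig set
is unavailable to the singleton set.  Greedy by rank is deliberately not
minimal set cover: rank encodes measured signal quality, which outranks
probe-count optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .acgh import SELECTED_CATEGORIES
from .align import ProbeMatch, uniqueness
from .core import TranscriptomeAssembly, write_table
from .design import ComplexityConstraints, dinucleotide_ok, homopolymer_ok

UNCOVERED_REASONS = ("no_candidate", "non_unique_only", "filtered_only")


@dataclass
class SelectionConfig:
    good_match_threshold: float = 80.0
    acgh_categories_allowed: frozenset = frozenset(SELECTED_CATEGORIES)
    complexity: ComplexityConstraints = field(default_factory=ComplexityConstraints)
    rank_key: str = "res"

    def __post_init__(self) -> None:
        self.acgh_categories_allowed = frozenset(self.acgh_categories_allowed)
        if not self.acgh_categories_allowed <= SELECTED_CATEGORIES:
            raise ValueError("allowed categories must be a subset of {A,B,C}")


@dataclass
class SelectionResult:
    """Selected probes, who they cover, and why the rest stayed uncovered."""

    selected: list[tuple[str, str, str]]  # (probe_id, assigned_unit, unit_level)
    coverage: dict[str, list[str]]  # isotig/singleton id -> covering probe ids
    uncovered: list[tuple[str, str, str]]  # (unit_id, level, reason)
    filter_log: pd.DataFrame  # probe_id, stage, detail for every dropped probe

    @property
    def selected_ids(self) -> list[str]:
        return [p for p, _, _ in self.selected]


def _complexity_ok(sequence: str, cc: ComplexityConstraints) -> bool:
    return homopolymer_ok(sequence, cc) and dinucleotide_ok(sequence, cc)


def select_probes(
    assembly: TranscriptomeAssembly,
    probes,
    categories: dict[str, str],
    ranks: dict[str, int],
    matches: dict[str, list[ProbeMatch]],
    cfg: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the full filter-then-greedy selection over both transcript sets.

    ``categories`` maps probe_id → aCGH category, ``ranks`` maps probe_id →
    selection rank (1 = best), ``matches`` maps probe_id → its good-match
    list (an empty list is a valid entry; a missing one is an error).
    """
    cfg = cfg or SelectionConfig()
    probes = list(probes)
    for p in probes:
        for name, table in (("category", categories), ("rank", ranks),
                            ("match set", matches)):
            if p.probe_id not in table:
                raise KeyError(f"probe {p.probe_id!r} has no {name}")

    flog: list[dict] = []

    def drop(pid: str, stage: str, detail: str = "") -> None:
        flog.append({"probe_id": pid, "stage": stage, "detail": detail})

    # independent per-probe filters (order immaterial; they commute)
    survivors: list = []
    unit_of: dict[str, tuple[str, str]] = {}
    for p in probes:
        if categories[p.probe_id] not in cfg.acgh_categories_allowed:
            drop(p.probe_id, "acgh", categories[p.probe_id])
            continue
        good = [m for m in matches[p.probe_id] if m.good]
        if not good:
            drop(p.probe_id, "no_good_match")
            continue
        unit, level = uniqueness(good, assembly)
        if unit is None:
            drop(p.probe_id, "non_unique")
            continue
        if not _complexity_ok(p.sequence, cfg.complexity):
            drop(p.probe_id, "complexity")
            continue
        survivors.append(p)
        unit_of[p.probe_id] = (unit, level)

    ordered = sorted(survivors, key=lambda p: ranks[p.probe_id])

    selected: list[tuple[str, str, str]] = []
    coverage: dict[str, list[str]] = {}
    consumed: set[str] = set()

    # pass 1: isotig set, greedy by rank within each isogroup
    remaining: dict[str, set[str]] = {
        ig: set(members) for ig, members in assembly.isogroups.items()
    }
    for p in ordered:
        unit, level = unit_of[p.probe_id]
        if level != "isogroup":
            continue
        hit_isotigs = {
            m.target_id
            for m in matches[p.probe_id]
            if m.good and m.target_level == "isotig"
        }
        new = hit_isotigs & remaining[unit]
        if not new:
            drop(p.probe_id, "redundant", unit)
            continue
        selected.append((p.probe_id, unit, "isogroup"))
        consumed.add(p.probe_id)
        for it in hit_isotigs:  # a selected probe covers every isotig it hits
            coverage.setdefault(it, []).append(p.probe_id)
        remaining[unit] -= hit_isotigs

    # pass 2: singleton set, over probes not consumed above
    uncovered_singletons = set(assembly.singletons)
    for p in ordered:
        if p.probe_id in consumed:
            continue
        unit, level = unit_of[p.probe_id]
        if level != "singleton":
            continue
        if unit not in uncovered_singletons:
            drop(p.probe_id, "redundant", unit)
            continue
        selected.append((p.probe_id, unit, "singleton"))
        consumed.add(p.probe_id)
        coverage.setdefault(unit, []).append(p.probe_id)
        uncovered_singletons.discard(unit)

    uncovered = _uncovered_reasons(assembly, probes, matches, unit_of, coverage)
    return SelectionResult(
        selected=selected,
        coverage=coverage,
        uncovered=uncovered,
        filter_log=pd.DataFrame(flog, columns=["probe_id", "stage", "detail"]),
    )


def _uncovered_reasons(
    assembly, probes, matches, unit_of, coverage
) -> list[tuple[str, str, str]]:
    """Why each uncovered unit stayed uncovered.

    no_candidate: no probe good-matches it at all; non_unique_only: matched
    only by probes attributable to more than one unit; filtered_only: matched
    by probes that fell to the category/complexity filters (or, for
    singletons, by probes consumed elsewhere).
    """
    hit_by: dict[str, list[str]] = {}
    for p in probes:
        for m in matches[p.probe_id]:
            if m.good:
                hit_by.setdefault(m.target_id, []).append(p.probe_id)
    survivor_unit = dict(unit_of)

    out = []
    for level, ids in (("isotig", assembly.isotigs), ("singleton", assembly.singletons)):
        for uid in ids:
            if uid in coverage:
                continue
            hitters = hit_by.get(uid, [])
            if not hitters:
                out.append((uid, level, "no_candidate"))
            elif any(pid in survivor_unit for pid in hitters):
                # a surviving unique probe hit it but was never selected for
                # it (e.g. attributed/consumed elsewhere)
                out.append((uid, level, "filtered_only"))
            else:
                # all hitters were dropped; distinguish uniqueness drops
                dropped_unique = [
                    pid for pid in hitters if pid not in survivor_unit
                ]
                non_unique = all(
                    _was_non_unique(pid, matches, assembly) for pid in dropped_unique
                )
                out.append(
                    (uid, level, "non_unique_only" if non_unique else "filtered_only")
                )
    return out


def _was_non_unique(pid, matches, assembly) -> bool:
    unit, _ = uniqueness([m for m in matches[pid] if m.good], assembly)
    return unit is None


def coverage_report(
    result: SelectionResult, assembly: TranscriptomeAssembly
) -> dict:
    """Counts and percentages (1 decimal) of what the selection targets."""
    isotigs_covered = [i for i in assembly.isotigs if i in result.coverage]
    singles_covered = [s for s in assembly.singletons if s in result.coverage]
    ig_of = assembly.isogroup_of
    igs_covered = {ig_of[i] for i in isotigs_covered}
    report = {
        "n_probes_selected": len(result.selected),
        "n_isotigs": assembly.n_isotigs(),
        "n_isotigs_covered": len(isotigs_covered),
        "isotig_coverage_pct": percentage(len(isotigs_covered), assembly.n_isotigs()),
        "n_isogroups": assembly.n_isogroups(),
        "n_isogroups_covered": len(igs_covered),
        "isogroup_coverage_pct": percentage(len(igs_covered), assembly.n_isogroups()),
        "n_singletons": assembly.n_singletons(),
        "n_singletons_covered": len(singles_covered),
        "singleton_coverage_pct": percentage(
            len(singles_covered), assembly.n_singletons()
        ),
        "uncovered_reasons": {
            reason: sum(1 for _, _, r in result.uncovered if r == reason)
            for reason in UNCOVERED_REASONS
        },
    }
    return report


def percentage(part: int, whole: int) -> float | None:
    """Percentage rounded to one decimal; None when the denominator is 0."""
    if whole == 0:
        return None
    return round(100.0 * part / whole, 1)


def result_to_frames(result: SelectionResult) -> dict[str, pd.DataFrame]:
    sel = pd.DataFrame(
        result.selected, columns=["probe_id", "assigned_unit", "unit_level"]
    )
    cov = pd.DataFrame(
        [
            {"unit_id": uid, "probe_id": pid}
            for uid, pids in sorted(result.coverage.items())
            for pid in pids
        ],
        columns=["unit_id", "probe_id"],
    )
    unc = pd.DataFrame(result.uncovered, columns=["unit_id", "level", "reason"])
    return {"selected": sel, "coverage": cov, "uncovered": unc,
            "filtered": result.filter_log}


def write_result(result: SelectionResult, outdir) -> None:
    import os

    frames = result_to_frames(result)
    for name, df in frames.items():
        write_table(df, os.path.join(outdir, f"{name}.tsv"))
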