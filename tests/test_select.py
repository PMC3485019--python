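import random

import pytest

from probeatlas.align import ProbeMatch, uniqueness
from probeatlas.core import SequenceRecord, TranscriptomeAssembly
from probeatlas.design import (
    ComplexityConstraints,
    Probe,
    dinucleotide_ok,
    homopolymer_ok,
)
from probeatlas.select import (
    SelectionConfig,
    coverage_report,
    percentage,
    select_probes,
)

BENIGN = ("ACGTTGCAAC" * 6)  # passes all complexity constraints


def probe(pid, seq=BENIGN):
    return Probe(pid, f"src_{pid}", 0, "+", seq, 0.5)


def pm(pid, target, level="isotig"):
    return ProbeMatch(pid, target, level, "+", 0, 60, 112.0, True)


def assembly(isogroups, singletons=()):
    isotigs = {
        it: SequenceRecord(it, "ACGT" * 30, "isotig")
        for members in isogroups.values()
        for it in members
    }
    singles = {
        s: SequenceRecord(s, "ACGT" * 20, "singleton") for s in singletons
    }
    return TranscriptomeAssembly(dict(isogroups), isotigs, singles)


def run(asm, probes, matches, cats=None, ranks=None, cfg=None):
    cats = cats or {p.probe_id: "A" for p in probes}
    ranks = ranks or {p.probe_id: i + 1 for i, p in enumerate(probes)}
    return select_probes(asm, probes, cats, ranks, matches, cfg)


class TestGreedyRule:
    def test_worked_example_greedy_not_minimal(self):
        """Rank order selects p1 then p2 (p2 adds IT2); p3 adds nothing.
        The minimal cover would be {p2} alone — greedy by rank differs."""
        asm = assembly({"IG1": ["IT1", "IT2"]})
        probes = [probe("p1"), probe("p2"), probe("p3")]
        matches = {
            "p1": [pm("p1", "IT1")],
            "p2": [pm("p2", "IT1"), pm("p2", "IT2")],
            "p3": [pm("p3", "IT2")],
        }
        res = run(asm, probes, matches)
        assert res.selected_ids == ["p1", "p2"]
        assert set(res.coverage) == {"IT1", "IT2"}

    def test_single_probe_single_isotig(self):
        asm = assembly({"IG1": ["IT1"]})
        res = run(asm, [probe("p")], {"p": [pm("p", "IT1")]})
        assert res.selected_ids == ["p"]
        assert res.coverage == {"IT1": ["p"]}

    def test_redundant_probe_skipped(self):
        asm = assembly({"IG1": ["IT1"]})
        probes = [probe("p"), probe("q")]
        matches = {"p": [pm("p", "IT1")], "q": [pm("q", "IT1")]}
        res = run(asm, probes, matches)
        assert res.selected_ids == ["p"]
        assert ("q", "redundant") in {
            (r.probe_id, r.stage) for r in res.filter_log.itertuples()
        }

    def test_singleton_set_after_isotig_set(self):
        asm = assembly({"IG1": ["IT1"]}, singletons=["SI1"])
        probes = [probe("a"), probe("b")]
        matches = {
            "a": [pm("a", "IT1")],
            "b": [pm("b", "SI1", "singleton")],
        }
        res = run(asm, probes, matches)
        assert ("a", "IG1", "isogroup") in res.selected
        assert ("b", "SI1", "singleton") in res.selected

    def test_missing_rank_is_error_naming_probe(self):
        asm = assembly({"IG1": ["IT1"]})
        with pytest.raises(KeyError, match="p"):
            select_probes(asm, [probe("p")], {"p": "A"}, {}, {"p": []})


class TestFilters:
    def setup_method(self):
        self.asm = assembly({"IG1": ["IT1"]}, singletons=["SI1"])

    def test_category_filter(self):
        res = run(
            self.asm,
            [probe("p")],
            {"p": [pm("p", "IT1")]},
            cats={"p": "rejected"},
        )
        assert res.selected == []
        assert res.filter_log.iloc[0]["stage"] == "acgh"

    def test_restricting_to_ab_drops_c(self):
        cfg = SelectionConfig(acgh_categories_allowed=frozenset({"A", "B"}))
        res = run(
            self.asm, [probe("p")], {"p": [pm("p", "IT1")]},
            cats={"p": "C"}, cfg=cfg,
        )
        assert res.selected == []

    def test_no_good_match_filter(self):
        res = run(self.asm, [probe("p")], {"p": []})
        assert res.filter_log.iloc[0]["stage"] == "no_good_match"

    def test_non_unique_filter(self):
        asm = assembly({"IG1": ["IT1"], "IG2": ["IT2"]})
        res = run(asm, [probe("p")], {"p": [pm("p", "IT1"), pm("p", "IT2")]})
        assert res.filter_log.iloc[0]["stage"] == "non_unique"

    def test_complexity_filter(self):
        bad = "A" * 60  # homopolymer
        res = run(self.asm, [probe("p", bad)], {"p": [pm("p", "IT1")]})
        assert res.filter_log.iloc[0]["stage"] == "complexity"

    def test_filters_commute(self):
        """The four pre-greedy filters are independent per-probe predicates:
        applying them in any order leaves the same survivor set."""
        rng = random.Random(13)
        asm = assembly({"IG1": ["IT1", "IT2"], "IG2": ["IT3"]}, ["SI1"])
        cc = ComplexityConstraints()
        cfg = SelectionConfig()
        probes, cats, matches = [], {}, {}
        for i in range(60):
            pid = f"p{i}"
            seq = (
                "A" * 60
                if rng.random() < 0.2
                else "".join(rng.choice("ACGT") for _ in range(60))
            )
            probes.append(probe(pid, seq))
            cats[pid] = rng.choice(["A", "B", "C", "rejected"])
            targets = rng.sample(["IT1", "IT2", "IT3"], rng.randint(0, 3))
            ms = [pm(pid, t) for t in targets]
            if rng.random() < 0.3:
                ms.append(pm(pid, "SI1", "singleton"))
            matches[pid] = ms
        res = run(asm, probes, matches, cats=cats)
        dropped_pre_greedy = set(
            res.filter_log.loc[res.filter_log["stage"] != "redundant", "probe_id"]
        )
        predicates = {
            "cat": lambda p: cats[p.probe_id] in cfg.acgh_categories_allowed,
            "match": lambda p: any(m.good for m in matches[p.probe_id]),
            "unique": lambda p: uniqueness(matches[p.probe_id], asm)[0] is not None,
            "cplx": lambda p: homopolymer_ok(p.sequence, cc)
            and dinucleotide_ok(p.sequence, cc),
        }
        names = list(predicates)
        for _ in range(6):
            rng.shuffle(names)
            survivors = set()
            for p in probes:
                if all(predicates[n](p) for n in names):
                    survivors.add(p.probe_id)
            assert survivors == {p.probe_id for p in probes} - dropped_pre_greedy


class TestDeterminismAndInvariants:
    def random_instance(self, rng):
        n_ig = rng.randint(1, 10)
        igs = {}
        count = 0
        for g in range(n_ig):
            members = [f"IT{count + i}" for i in range(rng.randint(1, 5))]
            count += len(members)
            igs[f"IG{g}"] = members
        singles = [f"SI{i}" for i in range(rng.randint(0, 3))]
        asm = assembly(igs, singles)
        all_its = [it for m in igs.values() for it in m]
        probes, cats, ranks, matches = [], {}, {}, {}
        order = list(range(rng.randint(1, 50)))
        rng.shuffle(order)
        for i, rk in enumerate(order):
            pid = f"p{i}"
            probes.append(probe(pid))
            cats[pid] = rng.choice(["A", "B", "C", "rejected"])
            ranks[pid] = rk + 1
            mode = rng.random()
            if mode < 0.15 and singles:
                matches[pid] = [pm(pid, rng.choice(singles), "singleton")]
            elif mode < 0.25:
                matches[pid] = []
            elif mode < 0.4 and len(all_its) >= 2:  # possibly cross-isogroup
                matches[pid] = [pm(pid, t) for t in rng.sample(all_its, 2)]
            else:  # within one isogroup
                ig = rng.choice(list(igs))
                k = rng.randint(1, len(igs[ig]))
                matches[pid] = [pm(pid, t) for t in rng.sample(igs[ig], k)]
        return asm, probes, cats, ranks, matches

    def test_identical_inputs_identical_results(self):
        rng = random.Random(99)
        asm, probes, cats, ranks, matches = self.random_instance(rng)
        r1 = select_probes(asm, probes, cats, ranks, matches)
        r2 = select_probes(asm, list(probes), dict(cats), dict(ranks), dict(matches))
        assert r1.selected == r2.selected
        assert r1.coverage == r2.coverage
        assert r1.uncovered == r2.uncovered

    def test_maximal_coverage_and_replay(self):
        """No uncovered isotig may have a surviving unique probe hitting it,
        and replaying rank order reproduces the selection exactly."""
        rng = random.Random(7)
        for _ in range(50):
            asm, probes, cats, ranks, matches = self.random_instance(rng)
            res = select_probes(asm, probes, cats, ranks, matches)
            survivors = {p.probe_id for p in probes} - set(
                res.filter_log.loc[
                    res.filter_log["stage"] != "redundant", "probe_id"
                ]
            )
            # maximal coverage
            for pid in survivors:
                unit, level = uniqueness(matches[pid], asm)
                if level == "isogroup":
                    for m in matches[pid]:
                        if m.target_level == "isotig":
                            assert m.target_id in res.coverage
                elif level == "singleton":
                    assert unit in res.coverage
            # replay
            replay = []
            remaining = {ig: set(m) for ig, m in asm.isogroups.items()}
            un_sing = set(asm.singletons)
            for pid in sorted(survivors, key=lambda q: ranks[q]):
                unit, level = uniqueness(matches[pid], asm)
                if level == "isogroup":
                    hits = {
                        m.target_id
                        for m in matches[pid]
                        if m.target_level == "isotig"
                    }
                    if hits & remaining[unit]:
                        replay.append((pid, unit, "isogroup"))
                        remaining[unit] -= hits
            for pid in sorted(survivors, key=lambda q: ranks[q]):
                unit, level = uniqueness(matches[pid], asm)
                if level == "singleton" and unit in un_sing:
                    replay.append((pid, unit, "singleton"))
                    un_sing.discard(unit)
            assert sorted(replay) == sorted(res.selected)


class TestCoverageReport:
    def test_percentages(self):
        assert percentage(22507, 23709) == 94.9
        assert percentage(23782, 135082) == 17.6
        assert percentage(0, 10) == 0.0
        assert percentage(3, 0) is None

    def test_zero_selected(self):
        asm = assembly({"IG1": ["IT1"]}, ["SI1"])
        res = run(asm, [probe("p")], {"p": []})
        rep = coverage_report(res, asm)
        assert rep["isotig_coverage_pct"] == 0.0
        assert rep["singleton_coverage_pct"] == 0.0
        assert rep["n_probes_selected"] == 0

    def test_uncovered_reason_codes(self):
        asm = assembly({"IG1": ["IT1"], "IG2": ["IT2"], "IG3": ["IT3"]})
        probes = [probe("px"), probe("pf")]
        matches = {
            "px": [pm("px", "IT1"), pm("px", "IT2")],  # non-unique
            "pf": [pm("pf", "IT3")],
        }
        res = run(asm, probes, matches, cats={"px": "A", "pf": "rejected"})
        reasons = {uid: r for uid, _, r in res.uncovered}
        assert reasons["IT1"] == "non_unique_only"
        assert reasons["IT2"] == "non_unique_only"
        assert reasons["IT3"] == "filtered_only"
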