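import math
import random

import pytest
from Bio.Seq import reverse_complement

from probeatlas.align import (
    ProbeMatch,
    ScoringScheme,
    bit_score,
    good_matches,
    local_align,
    match_all,
    min_raw_score,
    safe_seed_word,
    uniqueness,
)
from probeatlas.core import SequenceRecord, TranscriptomeAssembly
from probeatlas.design import Probe

S = ScoringScheme()


def enum_local_score(q, s, sc=S):
    """Exhaustive enumeration oracle: walk every monotone alignment path
    from every start cell, tracking affine gap state; independent of any
    dynamic-programming shortcut."""
    best = 0

    def extend(i, j, score, last_gap):
        nonlocal best
        if score > best:
            best = score
        if i < len(q) and j < len(s):
            step = sc.match_reward if q[i] == s[j] else sc.mismatch_penalty
            extend(i + 1, j + 1, score + step, None)
        if i < len(q):
            pen = sc.gap_extend if last_gap == "q" else sc.gap_open
            extend(i + 1, j, score + pen, "q")
        if j < len(s):
            pen = sc.gap_extend if last_gap == "s" else sc.gap_open
            extend(i, j + 1, score + pen, "s")

    for i0 in range(len(q)):
        for j0 in range(len(s)):
            extend(i0, j0, 0, None)
    return best


def enum_both_strands(q, s, sc=S):
    return max(enum_local_score(q, s, sc), enum_local_score(reverse_complement(q), s, sc))


def mutate(rng, seq, n_sub):
    out = list(seq)
    for i in rng.sample(range(len(out)), n_sub):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestLocalAlign:
    def test_perfect_sixty_mer(self):
        rng = random.Random(1)
        q = "".join(rng.choice("ACGT") for _ in range(60))
        hit = local_align(q, "TTTT" + q + "AAAA")
        assert hit.raw_score == 60
        assert hit.strand == "+"
        assert hit.target_start == 4

    def test_single_internal_mismatch(self):
        rng = random.Random(2)
        q = "".join(rng.choice("ACGT") for _ in range(60))
        subject = mutate(random.Random(3), q, 1)
        hit = local_align(q, subject)
        # 59 matches - 2 for the mismatch, unless the mismatch sits close
        # enough to an end that trimming it scores better
        assert hit.raw_score in (57, 58, 59)

    def test_reverse_complement_detected(self):
        rng = random.Random(4)
        q = "".join(rng.choice("ACGT") for _ in range(40))
        subject = "GG" + reverse_complement(q) + "CC"
        hit = local_align(q, subject)
        assert hit.raw_score == 40
        assert hit.strand == "-"

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_agrees_with_enumeration_on_short_pairs(self):
        rng = random.Random(7)
        for _ in range(40):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            assert local_align(q, s).raw_score == enum_both_strands(q, s)


class TestBitScore:
    def test_known_values(self):
        assert bit_score(60) == pytest.approx(111.92, abs=0.01)
        assert bit_score(0) == pytest.approx(-math.log(0.46) / math.log(2), rel=1e-12)

    def test_strictly_increasing(self):
        vals = [bit_score(s) for s in range(0, 100)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_min_raw_score_is_exact_boundary(self):
        need = min_raw_score(80.0)
        assert bit_score(need) > 80.0
        assert bit_score(need - 1) <= 80.0


class TestSeedSafety:
    def test_default_word_size(self):
        # runs <= 8 reach at most 54 - 12 = 42 < 43; runs of 9 reach
        # 54 - 10 = 44 >= 43, so 9 is the largest safe word
        assert safe_seed_word(80.0, 60) == 9

    def test_no_true_hit_lost_by_seeding(self):
        """Any pair clearing the bit threshold must share an exact word of
        the computed size — checked against the DP score directly."""
        rng = random.Random(11)
        w = safe_seed_word(80.0, 60, S)
        for _ in range(200):
            q = "".join(rng.choice("ACGT") for _ in range(60))
            subject = mutate(rng, q, rng.randint(0, 20))
            score = local_align(q, subject, S).raw_score
            if bit_score(score, S) > 80.0:
                shared = any(
                    q[i : i + w] in subject for i in range(60 - w + 1)
                )
                assert shared

    def test_unsafe_word_size_exists(self):
        # the bound is tight: an alignment over the threshold with no exact
        # (w+1)-mer is constructible, so a larger word would lose hits
        w = safe_seed_word(80.0, 60, S)
        rng = random.Random(55)
        runs = [
            "".join(rng.choice("ACGT") for _ in range(w)) for _ in range(6)
        ]
        q = "C".join(runs)
        subject = "G".join(runs)
        assert len(q) <= 60
        score = local_align(q, subject, S).raw_score
        assert bit_score(score, S) > 80.0
        assert not any(
            q[i : i + w + 1] in subject for i in range(len(q) - w)
        )


def make_assembly():
    rng = random.Random(21)
    seqs = {
        f"it{i}": "".join(rng.choice("ACGT") for _ in range(300)) for i in range(4)
    }
    # it0/it1 share an exon-like block inside one isogroup
    seqs["it1"] = seqs["it0"][:150] + seqs["it1"][150:]
    isotigs = {
        k: SequenceRecord(k, v, kind="isotig") for k, v in seqs.items()
    }
    singles = {
        f"si{i}": SequenceRecord(
            f"si{i}", "".join(rng.choice("ACGT") for _ in range(200)), "singleton"
        )
        for i in range(2)
    }
    return TranscriptomeAssembly(
        {"ig0": ["it0", "it1"], "ig1": ["it2", "it3"]}, isotigs, singles
    )


def probe_from(seq, pid="p"):
    return Probe(pid, "src", 0, "+", seq, 0.5)


class TestGoodMatches:
    def test_probe_from_isotig_found(self):
        asm = make_assembly()
        p = probe_from(asm.isotigs["it2"].sequence[100:160])
        hits = {m.target_id for m in good_matches(p, asm)}
        assert "it2" in hits

    def test_shared_exon_probe_hits_both_isotigs(self):
        asm = make_assembly()
        p = probe_from(asm.isotigs["it0"].sequence[40:100])
        hits = {m.target_id for m in good_matches(p, asm)}
        assert hits >= {"it0", "it1"}

    def test_threshold_is_strict(self):
        asm = make_assembly()
        p = probe_from(asm.isotigs["it2"].sequence[0:60])
        exact = bit_score(60)
        assert good_matches(p, asm, threshold=exact) == []
        assert any(
            m.target_id == "it2" for m in good_matches(p, asm, threshold=exact - 1e-9)
        )

    def test_random_probe_matches_nothing(self):
        asm = make_assembly()
        rng = random.Random(33)
        p = probe_from("".join(rng.choice("ACGT") for _ in range(60)))
        assert good_matches(p, asm) == []

    def test_seeding_does_not_change_results(self):
        asm = make_assembly()
        probes = [
            probe_from(asm.isotigs["it0"].sequence[i : i + 60], f"p{i}")
            for i in (0, 50, 120, 200)
        ]
        with_seed = match_all(probes, asm, seed=True)
        without = match_all(probes, asm, seed=False)
        for pid in with_seed:
            assert {(m.target_id, m.raw_score) for m in with_seed[pid]} == {
                (m.target_id, m.raw_score) for m in without[pid]
            }


def pm(pid, target, level="isotig", good=True):
    return ProbeMatch(pid, target, level, "+", 0, 60, 112.0, good)


class TestUniqueness:
    def setup_method(self):
        self.asm = make_assembly()

    def test_two_isotigs_one_isogroup(self):
        unit, level = uniqueness([pm("p", "it0"), pm("p", "it1")], self.asm)
        assert (unit, level) == ("ig0", "isogroup")

    def test_two_isogroups_is_none(self):
        unit, level = uniqueness([pm("p", "it0"), pm("p", "it2")], self.asm)
        assert unit is None

    def test_single_singleton(self):
        unit, level = uniqueness([pm("p", "si0", "singleton")], self.asm)
        assert (unit, level) == ("si0", "singleton")

    def test_singleton_plus_isotig_is_not_singleton_unique(self):
        unit, level = uniqueness(
            [pm("p", "si0", "singleton"), pm("p", "it3")], self.asm
        )
        # the isotig match wins attribution: unique to ig1
        assert (unit, level) == ("ig1", "isogroup")

    def test_two_singletons_is_none(self):
        unit, _ = uniqueness(
            [pm("p", "si0", "singleton"), pm("p", "si1", "singleton")], self.asm
        )
        assert unit is None

    def test_exhaustive_toy_enumeration(self):
        """All subsets of a toy target universe assign per the rules."""
        targets = ["it0", "it1", "it2", "si0"]
        from itertools import combinations

        for k in range(1, len(targets) + 1):
            for combo in combinations(targets, k):
                ms = [
                    pm("p", t, "singleton" if t.startswith("si") else "isotig")
                    for t in combo
                ]
                unit, level = uniqueness(ms, self.asm)
                isos = [t for t in combo if t.startswith("it")]
                sings = [t for t in combo if t.startswith("si")]
                igs = {self.asm.isogroup_of[t] for t in isos}
                if isos:
                    expect = (igs.pop(), "isogroup") if len(igs) == 1 else (None, None)
                elif len(sings) == 1:
                    expect = (sings[0], "singleton")
                else:
                    expect = (None, None)
                assert (unit, level) == expect
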