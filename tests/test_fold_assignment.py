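import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldbridge.fold_assignment import (
    CONFIDENT,
    CONFIDENT_STAR,
    CONFLICT,
    NO_AMBIGUITY,
    UNASSIGNED,
    FoldAssignment,
    assign_fold,
    clan_extension,
    classify,
    filter_hits,
    normalized_fold_frequency,
)
from foldbridge.io_formats import DataError, FoldMap, Hit, HitTable


def make_hit(target, evalue=1e-6, q_span=(1, 92), q_len=100):
    return Hit(
        query_id="q",
        target_id=target,
        evalue=evalue,
        bitscore=50.0,
        q_start=q_span[0],
        q_end=q_span[1],
        t_start=1,
        t_end=q_span[1] - q_span[0] + 1,
        q_len=q_len,
        t_len=120,
    )


def fold_map_for(targets: dict[str, str]) -> FoldMap:
    fm = FoldMap()
    for target, fold in targets.items():
        fm.add(target, f"fam_{fold}", fold)
    return fm


class TestFilterHits:
    def test_coverage_boundary_is_strict(self):
        # "better than 60%" coverage: 0.59 removed, 0.61 kept, 0.60 removed
        low = make_hit("t1", q_span=(1, 59))
        edge = make_hit("t2", q_span=(1, 60))
        high = make_hit("t3", q_span=(1, 61))
        kept = filter_hits(HitTable([low, edge, high]))
        assert [h.target_id for h in kept] == ["t3"]

    def test_evalue_boundary_is_strict(self):
        at = make_hit("t1", evalue=1e-4)
        below = make_hit("t2", evalue=0.99e-4)
        kept = filter_hits(HitTable([at, below]))
        assert [h.target_id for h in kept] == ["t2"]

    def test_empty_table(self):
        assert len(filter_hits(HitTable())) == 0

    def test_best_domain_per_target_kept(self):
        weak = make_hit("t1", evalue=1e-5, q_span=(1, 70))
        strong = make_hit("t1", evalue=1e-9, q_span=(1, 95))
        kept = filter_hits(HitTable([weak, strong]))
        assert len(kept) == 1
        assert kept[0].evalue == 1e-9


class TestNormalizedFoldFrequency:
    def test_four_one_split(self):
        fm = fold_map_for({f"a{i}": "A" for i in range(4)} | {"b0": "B"})
        table = HitTable([make_hit(t) for t in fm.entries])
        nff = normalized_fold_frequency(table, fm)
        assert nff == {"A": pytest.approx(0.8), "B": pytest.approx(0.2)}

    def test_single_fold_is_one(self):
        fm = fold_map_for({"a0": "A", "a1": "A"})
        nff = normalized_fold_frequency(HitTable([make_hit("a0"), make_hit("a1")]), fm)
        assert nff == {"A": 1.0}

    def test_three_fold_counts(self):
        targets = (
            {f"a{i}": "A" for i in range(5)}
            | {f"b{i}": "B" for i in range(3)}
            | {f"c{i}": "C" for i in range(2)}
        )
        fm = fold_map_for(targets)
        nff = normalized_fold_frequency(HitTable([make_hit(t) for t in targets]), fm)
        assert nff == {
            "A": pytest.approx(0.5),
            "B": pytest.approx(0.3),
            "C": pytest.approx(0.2),
        }
        assert sum(nff.values()) == pytest.approx(1.0, abs=1e-12)

    def test_unresolvable_target_listed(self):
        fm = fold_map_for({"known": "A"})
        with pytest.raises(DataError, match="mystery"):
            normalized_fold_frequency(
                HitTable([make_hit("known"), make_hit("mystery")]), fm
            )

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=6)
    )
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_and_matches_counting(self, counts):
        targets = {}
        for fold_idx, n in enumerate(counts):
            for k in range(n):
                targets[f"t{fold_idx}_{k}"] = f"F{fold_idx}"
        fm = fold_map_for(targets)
        nff = normalized_fold_frequency(HitTable([make_hit(t) for t in targets]), fm)
        assert sum(nff.values()) == pytest.approx(1.0, abs=1e-12)
        total = sum(counts)
        for fold_idx, n in enumerate(counts):
            assert nff[f"F{fold_idx}"] == pytest.approx(n / total)


class TestClassify:
    def test_single_fold_is_no_ambiguity_even_at_high_coverage(self):
        assert classify({"A": 1.0}, {"A": 0.97}) == ("A", NO_AMBIGUITY)

    def test_confident_star_at_95_coverage(self):
        assert classify({"A": 0.8, "B": 0.2}, {"A": 0.96, "B": 0.7}) == (
            "A",
            CONFIDENT_STAR,
        )
        # the boundary itself qualifies ("greater than or equal to 95%")
        assert classify({"A": 0.8, "B": 0.2}, {"A": 0.95, "B": 0.7}) == (
            "A",
            CONFIDENT_STAR,
        )

    def test_confident_when_top_fold_has_best_coverage_below_95(self):
        assert classify({"A": 0.6, "B": 0.4}, {"A": 0.9, "B": 0.7}) == (
            "A",
            CONFIDENT,
        )

    def test_conflict_when_top_fold_lacks_best_coverage(self):
        assert classify({"A": 0.6, "B": 0.4}, {"A": 0.7, "B": 0.9}) == (
            "A",
            CONFLICT,
        )

    def test_empty_input_unassigned(self):
        assert classify({}, {}) == (None, UNASSIGNED)

    def test_nff_tie_broken_by_coverage_then_id(self):
        fold, _ = classify({"A": 0.5, "B": 0.5}, {"A": 0.7, "B": 0.9})
        assert fold == "B"
        fold, _ = classify({"A": 0.5, "B": 0.5}, {"A": 0.8, "B": 0.8})
        assert fold == "A"

    def test_labels_mutually_exclusive_and_total(self):
        for nff_a in np.linspace(0.05, 0.95, 7):
            for cov_a in np.linspace(0.3, 1.0, 8):
                for cov_b in np.linspace(0.3, 1.0, 8):
                    fold, label = classify(
                        {"A": nff_a, "B": 1 - nff_a},
                        {"A": float(cov_a), "B": float(cov_b)},
                    )
                    assert label in {CONFIDENT_STAR, CONFIDENT, CONFLICT}
                    assert fold in {"A", "B"}


class TestAssignFold:
    def test_no_qualifying_hits_unassigned(self):
        fm = fold_map_for({"t1": "A"})
        table = HitTable([make_hit("t1", evalue=1.0)])
        fa = assign_fold("fam1", table, fm)
        assert fa.confidence == UNASSIGNED
        assert fa.fold_id is None
        assert fa.n_hits_used == 0

    def test_fixture_all_true_fold(self):
        fm = fold_map_for({f"t{i}": "A" for i in range(5)})
        table = HitTable([make_hit(f"t{i}", evalue=1e-6, q_span=(1, 92)) for i in range(5)])
        fa = assign_fold("fam1", table, fm)
        assert fa.fold_id == "A"
        assert fa.nff == pytest.approx(1.0)
        assert fa.confidence == NO_AMBIGUITY
        assert fa.high_confidence

    def test_pooling_equals_concatenation(self):
        fm = fold_map_for({"t1": "A", "t2": "A", "t3": "B"})
        rep1 = [make_hit("t1"), make_hit("t3", q_span=(1, 75))]
        rep2 = [make_hit("t2", q_span=(1, 97))]
        pooled = assign_fold("fam1", HitTable(rep1 + rep2), fm)
        concatenated = assign_fold("fam1", HitTable(list(HitTable(rep1)) + rep2), fm)
        assert pooled == concatenated

    def test_high_confidence_threshold(self):
        fm = fold_map_for(
            {f"a{i}": "A" for i in range(3)} | {"b0": "B", "b1": "B"}
        )
        table = HitTable([make_hit(t) for t in fm.entries])
        fa = assign_fold("fam1", table, fm)
        assert fa.nff == pytest.approx(0.6)
        assert not fa.high_confidence  # nff < 0.8

    def test_agrees_with_brute_force_recount(self):
        rng = np.random.default_rng(42)
        folds = ["A", "B", "C"]
        for _ in range(300):
            n = int(rng.integers(1, 12))
            targets = {f"t{i}": folds[rng.integers(0, 3)] for i in range(n)}
            fm = fold_map_for(targets)
            table = HitTable(
                [
                    make_hit(
                        t,
                        evalue=float(10.0 ** rng.uniform(-9, -2)),
                        q_span=(1, int(rng.integers(40, 101))),
                    )
                    for t in targets
                ]
            )
            fa = assign_fold("fam", table, fm)
            # explicit re-enumeration
            passing = [
                h
                for h in table
                if h.evalue < 1e-4 and (h.q_end - h.q_start + 1) / h.q_len > 0.6
            ]
            if not passing:
                assert fa.confidence == UNASSIGNED
                continue
            counts: dict[str, int] = {}
            for h in passing:
                counts[targets[h.target_id]] = counts.get(targets[h.target_id], 0) + 1
            assert fa.n_hits_used == len(passing)
            assert fa.nff == pytest.approx(counts[fa.fold_id] / len(passing))
            assert counts[fa.fold_id] == max(counts.values())


class TestClanExtension:
    def assignment(self, fam, fold, confidence, nff=1.0):
        return FoldAssignment(
            query_family=fam,
            fold_id=fold,
            nff=nff,
            best_query_coverage=0.9 if fold else 0.0,
            confidence=confidence,
            n_folds=1 if fold else 0,
            n_hits_used=5 if fold else 0,
        )

    def test_unassigned_member_inherits(self):
        assignments = [
            self.assignment("f1", "A", NO_AMBIGUITY),
            self.assignment("f2", None, UNASSIGNED),
        ]
        out, flagged = clan_extension(assignments, {"f1": "CL1", "f2": "CL1"})
        assert not flagged
        inferred = next(a for a in out if a.query_family == "f2")
        assert inferred.fold_id == "A"
        assert inferred.inferred_via_clan

    def test_disagreeing_clan_flagged_not_propagated(self):
        assignments = [
            self.assignment("f1", "A", NO_AMBIGUITY),
            self.assignment("f2", "B", CONFIDENT),
            self.assignment("f3", None, UNASSIGNED),
        ]
        out, flagged = clan_extension(
            assignments, {"f1": "CL1", "f2": "CL1", "f3": "CL1"}
        )
        assert flagged == {"CL1"}
        untouched = next(a for a in out if a.query_family == "f3")
        assert untouched.confidence == UNASSIGNED

    def test_direct_assignment_never_overwritten(self):
        assignments = [
            self.assignment("f1", "A", NO_AMBIGUITY),
            self.assignment("f2", "B", CONFIDENT),
        ]
        out, _ = clan_extension(assignments, {"f1": "CL1", "f2": "CL1"})
        kept = next(a for a in out if a.query_family == "f2")
        assert kept.fold_id == "B"
        assert not kept.inferred_via_clan

    def test_conflict_member_does_not_donate(self):
        assignments = [
            self.assignment("f1", "A", CONFLICT),
            self.assignment("f2", None, UNASSIGNED),
        ]
        out, flagged = clan_extension(assignments, {"f1": "CL1", "f2": "CL1"})
        still = next(a for a in out if a.query_family == "f2")
        assert still.confidence == UNASSIGNED
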