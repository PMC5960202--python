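import numpy as np
import pytest

from conftest import delta_column, make_profile
from foldbridge.io_formats import AA_INDEX, DataError, SequenceRecord
from foldbridge.linker_design import (
    combine_profiles,
    design_linkers,
    sample_linker,
    score_sequence,
)
from foldbridge.profiles import align_profiles, build_profile


def combined(a, b, weight_a=0.5, fold="f1"):
    return combine_profiles(a, b, align_profiles(a, b), weight_a, fold)


class TestCombineProfiles:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(20))
        a = make_profile([f, f])
        model = combined(a, a)
        for pos in model.positions:
            np.testing.assert_allclose(pos.merged_freqs, f, atol=1e-12)

    def test_disjoint_deltas_mix_evenly(self):
        a = make_profile([delta_column(AA_INDEX["A"])])
        b = make_profile([delta_column(AA_INDEX["G"])])
        model = combine_profiles(
            a, b, align_profiles(a, b, gap_open=50.0), weight_a=0.5
        )
        f = model.positions[0].merged_freqs
        assert f[AA_INDEX["A"]] == pytest.approx(0.5)
        assert f[AA_INDEX["G"]] == pytest.approx(0.5)

    def test_hand_arithmetic_mixture(self):
        # 0.25*(A .8, G .2) + 0.75*(A .4, C .6) = (A .5, G .05, C .45)
        fa = np.zeros(20)
        fa[AA_INDEX["A"]], fa[AA_INDEX["G"]] = 0.8, 0.2
        fb = np.zeros(20)
        fb[AA_INDEX["A"]], fb[AA_INDEX["C"]] = 0.4, 0.6
        model = combine_profiles(
            make_profile([fa]),
            make_profile([fb]),
            align_profiles(make_profile([fa]), make_profile([fb]), gap_open=50.0),
            weight_a=0.25,
        )
        f = model.positions[0].merged_freqs
        assert f[AA_INDEX["A"]] == pytest.approx(0.5)
        assert f[AA_INDEX["G"]] == pytest.approx(0.05)
        assert f[AA_INDEX["C"]] == pytest.approx(0.45)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = make_profile(rng.dirichlet(np.ones(20), size=5))
        b = make_profile(rng.dirichlet(np.ones(20), size=5))
        ab = combine_profiles(a, b, align_profiles(a, b), weight_a=0.3)
        ba = combine_profiles(b, a, align_profiles(b, a), weight_a=0.7)
        for pa, pb in zip(ab.positions, ba.positions):
            np.testing.assert_allclose(pa.merged_freqs, pb.merged_freqs, atol=1e-12)

    def test_positions_sum_to_one(self):
        rng = np.random.default_rng(2)
        a = make_profile(rng.dirichlet(np.ones(20), size=6))
        b = make_profile(rng.dirichlet(np.ones(20), size=4))
        model = combined(a, b)
        for pos in model.positions:
            assert pos.merged_freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_alignment_rejected(self):
        rng = np.random.default_rng(3)
        a = make_profile(rng.dirichlet(np.ones(20), size=4))
        b = make_profile(rng.dirichlet(np.ones(20), size=4))
        aln = align_profiles(a, b)
        c = make_profile(rng.dirichlet(np.ones(20), size=3))
        with pytest.raises(DataError, match="alignment"):
            combine_profiles(c, b, aln)


class TestSampleLinker:
    def test_degenerate_wheel_is_deterministic(self):
        a = make_profile([delta_column(AA_INDEX["W"])] * 4)
        model = combined(a, a)
        for seed in range(5):
            assert sample_linker(model, seed).residues == "WWWW"

    def test_binomial_frequency_of_even_wheel(self):
        # (A .5, G .5): fraction of A over 10,000 seeded draws within the
        # 99% binomial interval 0.5 +/- 0.015
        f = np.zeros(20)
        f[AA_INDEX["A"]] = f[AA_INDEX["G"]] = 0.5
        a = make_profile([f])
        model = combined(a, a)
        draws = [sample_linker(model, seed).residues for seed in range(10_000)]
        frac_a = sum(r == "A" for r in draws) / len(draws)
        assert abs(frac_a - 0.5) <= 0.015

    def test_same_seed_same_sequence(self):
        rng = np.random.default_rng(4)
        a = make_profile(rng.dirichlet(np.ones(20), size=10))
        model = combined(a, a)
        assert sample_linker(model, 99).residues == sample_linker(model, 99).residues

    def test_length_equals_emitted_positions(self):
        rng = np.random.default_rng(5)
        a = make_profile(rng.dirichlet(np.ones(20), size=7))
        model = combined(a, a)
        assert len(sample_linker(model, 0).residues) == model.n_emit


@pytest.fixture(scope="module")
def family_alignment():
    rng = np.random.default_rng(11)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    founder = "".join(letters[i] for i in rng.integers(0, 20, size=40))
    rows = []
    for k in range(12):
        chars = [
            letters[rng.integers(0, 20)] if rng.random() < 0.15 else c
            for c in founder
        ]
        rows.append(SequenceRecord(f"m{k}", "".join(chars)))
    return rows


class TestDesignLinkers:
    def test_serial_naming(self, family_alignment):
        records, fold_map = design_linkers(
            family_alignment, family_alignment, "f9", n=3, seed=5,
            fam_a_id="famA", fam_b_id="famB",
        )
        assert [r.id for r in records] == [
            "DS_f9_famA_famB_0001",
            "DS_f9_famA_famB_0002",
            "DS_f9_famA_famB_0003",
        ]
        assert all(fold_map.is_designed(r.id) for r in records)
        assert fold_map.entries[records[0].id].parent_families == ("famA", "famB")

    def test_self_design_matches_family_profile(self, family_alignment):
        # designing a family against itself: the linkers' empirical
        # per-column frequencies reproduce the profile distribution
        records, _ = design_linkers(
            family_alignment, family_alignment, "f1", n=1000, seed=3
        )
        prof = build_profile(family_alignment)
        aln = align_profiles(prof, prof)
        model = combine_profiles(prof, prof, aln, 0.5, "f1")
        freqs = model.emit_freq_matrix()
        counts = np.zeros_like(freqs)
        for rec in records:
            for pos, c in enumerate(rec.residues):
                counts[pos, AA_INDEX[c]] += 1
        empirical = counts / len(records)
        tv = 0.5 * np.abs(empirical - freqs).sum(axis=1)
        assert tv.max() <= 0.05

    def test_designed_sequences_score_above_random(self, family_alignment):
        records, _ = design_linkers(
            family_alignment, family_alignment, "f1", n=50, seed=8
        )
        prof = build_profile(family_alignment)
        model = combine_profiles(prof, prof, align_profiles(prof, prof), 0.5, "f1")
        rng = np.random.default_rng(0)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        length = len(records[0].residues)
        random_scores = [
            score_sequence(
                model, "".join(letters[i] for i in rng.integers(0, 20, size=length))
            )
            for _ in range(50)
        ]
        designed_scores = [score_sequence(model, r.residues) for r in records]
        assert np.mean(designed_scores) > np.mean(random_scores)

    def test_designed_length_constant(self, family_alignment):
        records, _ = design_linkers(
            family_alignment, family_alignment, "f1", n=20, seed=1
        )
        assert len({len(r.residues) for r in records}) == 1

    def test_n_below_one_rejected(self, family_alignment):
        with pytest.raises(DataError):
            design_linkers(family_alignment, family_alignment, "f1", n=0, seed=1)
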