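"""Discretization, mutual information, randomization tests, enrichment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from motifinfo import stats
from motifinfo.io import BehaviorProfile, Proteome
from motifinfo.motif import build_profile, parse_motif

from conftest import random_binary_profile


class TestDiscretize:
    def test_equal_population(self):
        classes = stats.discretize(np.arange(10)[::-1], 5)
        # smallest two values (9,8 at positions 1,0 reversed -> values 0,1) in class 0
        values = np.arange(10)[::-1]
        assert all(classes[values == v] == 0 for v in (0, 1))
        assert sorted(np.bincount(classes)) == [2, 2, 2, 2, 2]

    def test_larger_bins_first(self):
        classes = stats.discretize(np.arange(7), 3)
        assert list(np.bincount(classes)) == [3, 2, 2]

    def test_tie_order_by_input_position(self):
        classes = stats.discretize(np.zeros(5), 2)
        assert list(classes) == [0, 0, 0, 1, 1]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            stats.discretize([1.0, np.nan], 2)
        with pytest.raises(ValueError):
            stats.discretize([1.0, 2.0, 3.0], 5)

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=200), st.data())
    def test_contract(self, values, data):
        n_bins = data.draw(st.integers(1, len(values)))
        values = np.asarray(values, dtype=float)
        classes = stats.discretize(values, n_bins)
        sizes = np.bincount(classes, minlength=n_bins)
        # sizes differ by at most one and match the ceil/floor partition
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == len(values)
        # value-order preserving
        order = np.argsort(values, kind="stable")
        assert (np.diff(classes[order]) >= 0).all()


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 1] * 50)
        assert stats.mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_profile_is_zero(self):
        x = np.zeros(40, dtype=int)
        y = np.arange(40) % 4
        assert stats.mutual_information(x, y) == 0.0

    def test_hand_evaluated_joint(self):
        # joint counts {(0,0):30,(0,1):10,(1,0):10,(1,1):30}
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        expected = 2 * 0.375 * np.log2(1.5) + 2 * 0.125 * np.log2(0.5)
        assert expected == pytest.approx(0.18872, abs=1e-5)
        assert stats.mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(10, 500))
            cx, cy = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            x = rng.integers(0, cx, n)
            y = rng.integers(0, cy, n)
            mi = stats.mutual_information(x, y)
            assert mi == pytest.approx(stats.mutual_information(y, x), abs=1e-12)
            hx = stats.mutual_information(x, x)
            hy = stats.mutual_information(y, y)
            assert -1e-12 <= mi <= min(hx, hy) + 1e-12

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 300))
            x = rng.integers(0, rng.integers(2, 10), n)
            y = rng.integers(0, rng.integers(2, 10), n)
            assert stats.mutual_information(x, y) == pytest.approx(
                mutual_info_score(x, y) / np.log(2), abs=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            stats.mutual_information([0, 1], [0, 1, 0])


class TestShuffleTest:
    def test_perfectly_informative_profile_passes(self):
        behavior = np.array([0, 1] * 500)
        present = behavior.astype(bool)
        t = stats.shuffle_test(present, behavior, n_rand=999, seed=5)
        assert t.passed
        assert t.empirical_p == pytest.approx(1 / 1000)
        assert t.observed_mi == pytest.approx(1.0)
        assert t.z_score > 10

    def test_constant_presence_fails(self):
        behavior = np.array([0, 1] * 50)
        t = stats.shuffle_test(np.ones(100, bool), behavior, n_rand=99, seed=1)
        assert t.observed_mi == 0.0
        assert not t.passed
        assert t.z_score == 0.0

    def test_deterministic(self):
        behavior = np.arange(200) % 3
        present = random_binary_profile(200, 60, 9)
        a = stats.shuffle_test(present, behavior, n_rand=500, seed=4)
        b = stats.shuffle_test(present, behavior, n_rand=500, seed=4)
        assert (a.empirical_p, a.z_score, a.passed) == (b.empirical_p, b.z_score, b.passed)


class TestConditionalMI:
    def test_candidate_equals_given_fails(self):
        rng = np.random.default_rng(2)
        given = rng.random(400) < 0.4
        behavior = (rng.random(400) < 0.5).astype(int)
        behavior[given] = 0  # behavior depends on `given`
        t = stats.conditional_mi_test(given, behavior, given, n_rand=200, seed=3)
        assert t.observed_mi == pytest.approx(0.0, abs=1e-12)
        assert not t.passed

    def test_conditionally_informative_candidate_passes(self):
        # candidate informative only where given == 0
        rng = np.random.default_rng(8)
        n = 1000
        given = rng.random(n) < 0.5
        candidate = rng.random(n) < 0.3
        behavior = np.zeros(n, dtype=int)
        stratum = ~given
        behavior[stratum] = candidate[stratum].astype(int)  # perfect signal in stratum 0
        behavior[given] = rng.integers(0, 2, given.sum())
        t = stats.conditional_mi_test(candidate, behavior, given, n_rand=500, seed=4)
        assert t.passed

    def test_null_calibration(self):
        # behavior independent of candidate within strata: strict pass ~ 1/(n_rand+1)
        rng = np.random.default_rng(12)
        n_rand = 99
        passes = 0
        reps = 300
        for rep in range(reps):
            given = rng.random(500) < 0.5
            candidate = rng.random(500) < 0.3
            behavior = rng.integers(0, 2, 500)
            t = stats.conditional_mi_test(candidate, behavior, given, n_rand=n_rand, seed=rep)
            passes += t.passed
        expected = reps / (n_rand + 1)
        sd = np.sqrt(reps * (1 / (n_rand + 1)) * (1 - 1 / (n_rand + 1)))
        assert passes <= expected + 3 * sd


class TestRobustness:
    def _setup(self, seed):
        from motifinfo import synth

        prot = synth.random_proteome(300, 150, 30, seed=seed)
        beh = synth.random_class_profile(prot, [80, 220], seed=seed + 1)
        return prot, beh

    def test_planted_motif_scores_ten(self):
        from motifinfo import synth

        prot, beh = self._setup(20)
        m = parse_motif("SP.[RK]")
        prot, _ = synth.plant_motif(prot, beh, m, 0, 0.9, seed=22)
        score = stats.robustness(m, prot, beh, n_rand=199, seed=23)
        assert score == 10

    def test_uninformative_motif_scores_low(self):
        prot, beh = self._setup(30)
        m = parse_motif("L.[RK]")
        score = stats.robustness(m, prot, beh, n_rand=199, seed=31)
        assert score <= 1

    def test_same_seed_same_score(self):
        prot, beh = self._setup(40)
        m = parse_motif("A.[LV]")
        s1 = stats.robustness(m, prot, beh, n_rand=99, seed=7)
        s2 = stats.robustness(m, prot, beh, n_rand=99, seed=7)
        assert s1 == s2


class TestHypergeom:
    def test_k_zero_upper_is_one(self):
        assert stats.hypergeom_tail(0, 5, 4, 10, "upper") == 1.0

    def test_enumerated_example(self):
        # N=10, K=5, n=4, k=4: C(5,4)C(5,0)/C(10,4) = 5/210
        assert stats.hypergeom_tail(4, 5, 4, 10, "upper") == pytest.approx(5 / 210, abs=1e-12)

    def test_tail_identity(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(5)
        for _ in range(50):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            up = stats.hypergeom_tail(k, K, n, N, "upper")
            lo = stats.hypergeom_tail(k, K, n, N, "lower")
            pmf = hypergeom.pmf(k, N, K, n)
            assert up + lo - pmf == pytest.approx(1.0, abs=1e-9)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            stats.hypergeom_tail(6, 5, 4, 10)


class TestClassEnrichment:
    def _profile(self, present, ids):
        m = parse_motif("LK")
        return type("P", (), {"present": np.asarray(present, bool), "ids": ids, "motif": m})()

    def test_carriers_exactly_class_members(self):
        ids = [f"p{i}" for i in range(100)]
        classes = np.array([0] * 20 + [1] * 80)
        beh = BehaviorProfile(ids, classes, ["a", "b"])
        present = classes == 0
        cells = stats.class_enrichment(self._profile(present, ids), beh)
        assert cells[0].significant and cells[0].signed_score > 0
        assert cells[0].p_over < 1e-15

    def test_uniform_carriers_rarely_significant(self):
        rng = np.random.default_rng(77)
        ids = [f"p{i}" for i in range(400)]
        beh = BehaviorProfile(ids, np.arange(400) % 4, list("abcd"))
        clean = 0
        for rep in range(100):
            present = np.zeros(400, bool)
            present[rng.choice(400, 60, replace=False)] = True
            cells = stats.class_enrichment(self._profile(present, ids), beh)
            clean += not any(c.significant for c in cells)
        assert clean >= 95

    def test_interactor_scale_scenario(self):
        # 72% of a 225-protein class carry the motif vs 11% of 5,500 others
        N = 225 + 5500
        k = round(0.72 * 225)
        K = k + round(0.11 * 5500)
        p = stats.hypergeom_tail(k, K, 225, N, "upper")
        assert p < 1e-15

    def test_signed_score_sign_convention(self):
        ids = [f"p{i}" for i in range(60)]
        beh = BehaviorProfile(ids, np.array([0] * 30 + [1] * 30), ["a", "b"])
        present = np.array([True] * 25 + [False] * 35)  # over in class 0, under in 1
        cells = stats.class_enrichment(self._profile(present, ids), beh)
        assert cells[0].signed_score > 0
        assert cells[1].signed_score < 0


def test_derive_seed_stable_and_bounded():
    s1 = stats.derive_seed(42, "component", 3)
    assert s1 == stats.derive_seed(42, "component", 3)
    assert 0 <= s1 < 2**31
    assert s1 != stats.derive_seed(42, "component", 4)
    assert s1 != stats.derive_seed(43, "component", 3)
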