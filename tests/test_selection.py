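"""WMSE/AICc arithmetic, resampling plans, structure comparison."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import biohybrid as bh
from biohybrid.errors import ContractError, DomainError


class TestWmse:
    def test_perfect_prediction_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bh.wmse(x, x, np.ones(3)) == 0.0

    def test_hand_computed_example(self):
        """(1/1 + 4/4)/2 = 1 for residuals (1,2) with sigmas (1,2)."""
        assert bh.wmse(np.array([2.0, 4.0]), np.array([1.0, 2.0]),
                       np.array([1.0, 2.0])) == pytest.approx(1.0)

    @given(
        scale=st.floats(0.5, 4.0),
        seed=st.integers(0, 100),
    )
    def test_doubling_sigma_divides_by_four(self, scale, seed):
        rng = np.random.default_rng(seed)
        pred, meas = rng.normal(size=8), rng.normal(size=8)
        sig = rng.uniform(0.5, 2.0, 8)
        assert bh.wmse(pred, meas, 2 * sig) == pytest.approx(
            bh.wmse(pred, meas, sig) / 4.0
        )
        assert bh.wmse(pred, meas, scale * sig) == pytest.approx(
            bh.wmse(pred, meas, sig) / scale**2
        )

    def test_missing_measurements_excluded_from_T(self):
        meas = np.array([1.0, np.nan, 3.0])
        pred = np.array([2.0, 7.0, 3.0])
        sig = np.ones(3)
        assert bh.wmse(pred, meas, sig) == pytest.approx(0.5)  # 1 residual of 1, T=2

    def test_all_missing_is_contract_error(self):
        with pytest.raises(ContractError):
            bh.wmse(np.ones(2), np.full(2, np.nan), np.ones(2))


class TestAicc:
    def test_unit_wmse_example(self):
        """T=100, nw=10: 0 + 20 + 220/89."""
        assert bh.aicc(1.0, 100, 10) == pytest.approx(20 + 220 / 89, abs=5e-4)

    def test_e_wmse_example(self):
        """T=50, nw=5: 50 + 10 + 60/44."""
        assert bh.aicc(math.e, 50, 5) == pytest.approx(50 + 10 + 60 / 44, abs=5e-4)

    def test_monotone_in_wmse(self):
        assert bh.aicc(2.0, 60, 8) > bh.aicc(1.5, 60, 8) > bh.aicc(1.0, 60, 8)

    def test_small_sample_domain_error(self):
        with pytest.raises(DomainError):
            bh.aicc(1.0, 11, 10)

    @given(
        w=st.floats(0.05, 50.0),
        T=st.integers(20, 5000),
        nw=st.integers(1, 15),
    )
    def test_decomposition_identity(self, w, T, nw):
        """aicc(w) - aicc(1) = T ln w exactly (complexity terms cancel)."""
        assert bh.aicc(w, T, nw) - bh.aicc(1.0, T, nw) == pytest.approx(
            T * math.log(w), rel=1e-12, abs=1e-9
        )


class TestResamplePartitions:
    def test_partition_shapes_and_disjointness(self):
        ids = [f"b{i}" for i in range(24)]
        plan = bh.resample_partitions(ids, 10, 4, seed=3)
        assert len(plan) == 10
        for train, test in plan.pairs:
            assert len(test) == 4 and len(train) == 20
            assert set(train) | set(test) == set(ids)
            assert not set(train) & set(test)

    def test_fixed_seed_reproducible(self):
        ids = list("abcdefghi")
        p1 = bh.resample_partitions(ids, 5, 3, seed=11)
        p2 = bh.resample_partitions(ids, 5, 3, seed=11)
        assert p1.pairs == p2.pairs

    def test_label_exchangeability(self):
        """Relabeling experiments before planning permutes the plan the same
        way: the multiset of test-set POSITIONS is label-independent."""
        ids = [f"x{i}" for i in range(9)]
        relabeled = [f"y{i}" for i in range(9)]
        p1 = bh.resample_partitions(ids, 6, 4, seed=7)
        p2 = bh.resample_partitions(relabeled, 6, 4, seed=7)
        pos1 = [tuple(sorted(ids.index(t) for t in test)) for _, test in p1.pairs]
        pos2 = [tuple(sorted(relabeled.index(t) for t in test)) for _, test in p2.pairs]
        assert pos1 == pos2

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ContractError):
            bh.resample_partitions(list("abc"), 2, 3, 0)


class TestErrorModel:
    @pytest.fixture
    def species(self):
        return bh.SpeciesSet(("Xv", "P", "Glc"), np.array([10.0, 2.0, 40.0]))

    def test_relative_rule_uses_per_species_fractions(self, species):
        em = bh.ErrorModel.relative({"P": 0.05, "Xv": 0.10}, default_fraction=0.20)
        vals = np.array([[5.0, 1.0, 20.0]])
        sig = em.sigmas(vals, species)
        assert sig[0] == pytest.approx([0.5, 0.05, 4.0])

    def test_relative_rule_floors_at_fraction_of_cmax(self, species):
        em = bh.ErrorModel.relative({}, default_fraction=0.20, floor_fraction=0.02)
        sig = em.sigmas(np.zeros((1, 3)), species)
        assert sig[0] == pytest.approx(0.02 * species.cmax)

    def test_absolute_max_rule_is_value_independent(self, species):
        em = bh.ErrorModel.from_max(0.10)
        sig = em.sigmas(np.array([[1.0, 1.0, 1.0], [9.0, 1.9, 39.0]]), species)
        assert np.allclose(sig, 0.10 * species.cmax)


class TestCompareStructures:
    SHALLOW_EXP = {"train_wmse_mean": 1.57, "test_wmse_mean": 2.46, "n_weights": 1067}
    DEEP_EXP = {"train_wmse_mean": 1.35, "test_wmse_mean": 1.88, "n_weights": 2855}
    SHALLOW_SYN = {
        "train_wmse_mean": 1.54, "test_wmse_mean": 2.04,
        "test_wmse_noise_free_mean": 2.06, "n_weights": 649,
    }
    DEEP_SYN = {
        "train_wmse_mean": 0.982, "test_wmse_mean": 1.05,
        "test_wmse_noise_free_mean": 0.54, "n_weights": 765,
    }

    def test_experimental_style_published_deltas(self):
        out = bh.compare_structures(self.SHALLOW_EXP, self.DEEP_EXP)
        assert out["train_reduction_pct"] == pytest.approx(14.0, abs=0.06)
        assert out["test_reduction_pct"] == pytest.approx(23.6, abs=0.06)
        assert out["weights_increase_pct"] == pytest.approx(167.6, abs=0.06)
        assert out["test_increase_of_a_over_b_pct"] == pytest.approx(30.8, abs=0.06)
        assert out["train_increase_of_a_over_b_pct"] == pytest.approx(16.3, abs=0.06)

    def test_synthetic_style_published_deltas(self):
        out = bh.compare_structures(self.SHALLOW_SYN, self.DEEP_SYN)
        assert out["train_reduction_pct"] == pytest.approx(36.2, abs=0.06)
        assert out["test_noise_free_reduction_pct"] == pytest.approx(73.8, abs=0.06)
        assert out["test_reduction_pct"] == pytest.approx(48.5, abs=0.06)
        assert out["weights_increase_pct"] == pytest.approx(17.9, abs=0.06)

    def test_within_structure_overfit_ratio(self):
        out = bh.compare_structures(self.DEEP_EXP, self.DEEP_EXP)
        assert out["train_reduction_pct"] == 0.0
        # test error exceeds train error by 39.3% for the deep structure
        d = self.DEEP_EXP
        assert 100 * (d["test_wmse_mean"] - d["train_wmse_mean"]) / d[
            "train_wmse_mean"
        ] == pytest.approx(39.3, abs=0.06)

    def test_identical_reports_zero_deltas(self):
        out = bh.compare_structures(self.SHALLOW_EXP, self.SHALLOW_EXP)
        assert all(v == 0.0 for v in out.values())


class TestSelectionReport:
    def _stats(self, label, test_means):
        s = bh.StructureStats(label, (1,), "tanh", 10)
        s.train_wmse = [1.0]
        s.test_wmse = list(test_means)
        return s

    def test_chosen_structure_minimizes_mean_test_wmse(self):
        a = self._stats("a", [2.0, 3.0])
        b = self._stats("b", [1.5, 1.6])
        c = self._stats("c", [4.0])
        report = bh.SelectionReport([a, b, c], plan=None).finalize()
        assert report.chosen is b
        assert [s.chosen for s in report.structures] == [False, True, False]

    def test_unstable_structures_not_chosen(self):
        a = self._stats("a", [2.0])
        broken = bh.StructureStats("broken", (9,), "relu", 99)
        broken.n_unstable = 3
        report = bh.SelectionReport([broken, a], plan=None).finalize()
        assert report.chosen is a

    def test_sd_zero_when_partitions_identical(self):
        s = self._stats("s", [2.0, 2.0, 2.0])
        assert s.row()["test_wmse_sd"] == 0.0
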