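import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error

from brstnet.core_io import ValidationError
from brstnet.evaluation import (
    CLASS_NAMES,
    classify_pcc,
    evaluate,
    mae_rmse,
    pearson,
)


class TestMaeRmse:
    def test_perfect_prediction(self):
        assert mae_rmse([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_hand_example(self):
        mae, rmse = mae_rmse([1, 2, 3], [2, 2, 5])
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(5 / 3))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=30
        ),
        st.integers(0, 10**6),
    )
    def test_rmse_at_least_mae(self, y, seed):
        p = np.random.default_rng(seed).standard_normal(len(y)) * 100
        mae, rmse = mae_rmse(np.asarray(y), p)
        assert rmse >= mae - 1e-9 * max(1.0, rmse)

    def test_reference_agreement(self):
        """Agreement with scikit-learn's error metrics on seeded random pairs
        to near machine precision."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.standard_normal(n)
            p = rng.standard_normal(n)
            mae, rmse = mae_rmse(y, p)
            assert mae == pytest.approx(mean_absolute_error(y, p), abs=1e-10)
            assert rmse == pytest.approx(
                np.sqrt(mean_squared_error(y, p)), abs=1e-10
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mae_rmse([1.0], [1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mae_rmse([], [])


class TestPearson:
    def test_perfect_linear(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(a, 2 * a + 1) == pytest.approx(1.0)

    def test_perfect_anti_linear(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        assert pearson(a, b) == pytest.approx(pearson(b, a), abs=1e-12)
        assert pearson(3 * a + 2, b) == pytest.approx(pearson(a, b), abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_reference_agreement(self):
        """Agreement with scipy.stats.pearsonr on seeded random pairs."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            assert pearson(a, b) == pytest.approx(
                stats.pearsonr(a, b).statistic, abs=1e-10
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1.0], [2.0])


class TestClassifyPcc:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.6325, "strong"),
            (0.51, "strong"),
            (0.5, "medium"),  # strong means strictly greater than 0.50
            (0.3, "weak"),
            (0.1, "negligible"),
            (0.05, "negligible"),
            (0.0, "non_positive"),
            (-0.2, "non_positive"),
            (-1.0, "non_positive"),
            (1.0, "strong"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert classify_pcc(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_pcc(1.5)


def _toy_predictions(unit_values: dict, spots, genes):
    frames = []
    for unit, arr in unit_values.items():
        frames.append(
            pd.DataFrame(
                arr,
                index=pd.MultiIndex.from_product(
                    [[unit], spots], names=["unit", "spot"]
                ),
                columns=genes,
            )
        )
    return pd.concat(frames)


class TestEvaluate:
    spots = [f"s{i}" for i in range(6)]
    genes = ["ga", "gb"]

    def test_single_unit_median_is_that_unit(self):
        rng = np.random.default_rng(4)
        truth = pd.DataFrame(
            rng.standard_normal((6, 2)), index=self.spots, columns=self.genes
        )
        pred = _toy_predictions({"u0": truth.to_numpy() + 0.1}, self.spots, self.genes)
        rep = evaluate(pred, truth)
        for g in self.genes:
            assert rep.per_gene.loc[g, "median_pcc"] == pytest.approx(
                pearson(truth[g], truth[g] + 0.0), abs=1e-6
            )

    def test_median_across_units(self):
        rng = np.random.default_rng(5)
        truth = pd.DataFrame(
            rng.standard_normal((6, 1)), index=self.spots, columns=["ga"]
        )
        t = truth["ga"].to_numpy()
        noise = rng.standard_normal(6)

        def with_pcc(target_r):  # blend signal and noise to hit a target PCC
            z = target_r * (t - t.mean()) / t.std() + np.sqrt(
                1 - target_r**2
            ) * (noise - noise.mean()) / noise.std()
            return z[:, None]

        pred = _toy_predictions(
            {"u0": with_pcc(0.2), "u1": with_pcc(0.5), "u2": with_pcc(0.9)},
            self.spots,
            ["ga"],
        )
        rep = evaluate(pred, truth)
        pccs = rep.unit_pccs.loc["ga"].to_numpy()
        assert rep.per_gene.loc["ga", "median_pcc"] == pytest.approx(
            np.median(pccs)
        )

    def test_perfect_predictions(self):
        rng = np.random.default_rng(6)
        truth = pd.DataFrame(
            rng.standard_normal((6, 2)), index=self.spots, columns=self.genes
        )
        pred = _toy_predictions(
            {"u0": truth.to_numpy(), "u1": truth.to_numpy()}, self.spots, self.genes
        )
        rep = evaluate(pred, truth)
        assert (rep.per_gene["pcc_class"] == "strong").all()
        assert rep.aggregates["aMAE"] == 0.0
        assert rep.aggregates["aRMSE"] == 0.0

    def test_constant_gene_reported_undefined_not_zero(self):
        truth = pd.DataFrame(
            {"ga": np.arange(6.0), "gb": np.ones(6)}, index=self.spots
        )
        rng = np.random.default_rng(7)
        pred = _toy_predictions(
            {"u0": rng.standard_normal((6, 2))}, self.spots, self.genes
        )
        rep = evaluate(pred, truth)
        assert np.isnan(rep.per_gene.loc["gb", "median_pcc"])
        assert rep.per_gene.loc["gb", "pcc_class"] == "undefined"
        assert rep.aggregates["n_undefined_pcc"] == 1

    def test_class_counts_plus_undefined_total_genes(self):
        truth = pd.DataFrame(
            {"ga": np.arange(6.0), "gb": np.ones(6)}, index=self.spots
        )
        rng = np.random.default_rng(8)
        pred = _toy_predictions(
            {"u0": rng.standard_normal((6, 2))}, self.spots, self.genes
        )
        rep = evaluate(pred, truth)
        assert (
            sum(rep.class_counts.values()) + rep.aggregates["n_undefined_pcc"]
            == rep.aggregates["n_genes"]
        )

    def test_invariant_to_spot_order_within_units(self):
        rng = np.random.default_rng(9)
        truth = pd.DataFrame(
            rng.standard_normal((6, 2)), index=self.spots, columns=self.genes
        )
        arr = rng.standard_normal((6, 2))
        pred = _toy_predictions({"u0": arr}, self.spots, self.genes)
        perm = rng.permutation(6)
        shuffled = pred.iloc[perm]
        r1 = evaluate(pred, truth).per_gene["median_pcc"]
        r2 = evaluate(shuffled, truth).per_gene["median_pcc"]
        pd.testing.assert_series_equal(r1, r2)

    def test_missing_gene_rejected(self):
        truth = pd.DataFrame({"ga": np.arange(6.0)}, index=self.spots)
        rng = np.random.default_rng(10)
        pred = _toy_predictions(
            {"u0": rng.standard_normal((6, 2))}, self.spots, self.genes
        )
        with pytest.raises(ValidationError, match="gb"):
            evaluate(pred, truth)

    def test_histogram_counts_positive_genes(self):
        rng = np.random.default_rng(11)
        truth = pd.DataFrame(
            rng.standard_normal((20, 3)),
            index=[f"s{i}" for i in range(20)],
            columns=["ga", "gb", "gc"],
        )
        pred = _toy_predictions(
            {"u0": truth.to_numpy() + rng.standard_normal((20, 3))},
            list(truth.index),
            list(truth.columns),
        )
        rep = evaluate(pred, truth)
        counts, edges = rep.histogram()
        assert counts.sum() == len(rep.positive_pccs())
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(1.0)
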