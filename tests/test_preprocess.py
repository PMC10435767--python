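"""Preprocessing: normalisation, log transform, batch correction, peak
exclusion, derived traits and the rank inverse-normal transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from glycanclock import preprocess as pp
from glycanclock.combat import combat
from glycanclock.traits import TRAIT_FORMULAS

from conftest import toy_peak_table


class TestNormalizeTotalArea:
    def test_equal_peaks_become_uniform(self):
        df = pd.DataFrame([[3.0] * 24], columns=[f"GP{i}" for i in range(1, 25)])
        out = pp.normalize_total_area(df)
        np.testing.assert_allclose(out.to_numpy(), 100.0 / 24)

    def test_row_summing_to_100_unchanged(self):
        df = toy_peak_table()
        once = pp.normalize_total_area(df)
        pd.testing.assert_frame_equal(pp.normalize_total_area(once), once)

    def test_direct_arithmetic(self):
        row = [2.0] + [1.0] * 23  # total 25
        df = pd.DataFrame([row], columns=[f"GP{i}" for i in range(1, 25)])
        out = pp.normalize_total_area(df)
        assert out.iloc[0, 0] == pytest.approx(8.0)
        np.testing.assert_allclose(out.iloc[0, 1:], 4.0)

    def test_nonpositive_total_names_sample(self):
        df = toy_peak_table(3)
        df.loc["s1"] = 0.0
        with pytest.raises(ValueError, match="s1"):
            pp.normalize_total_area(df)

    def test_nonpositive_peak_reject_vs_floor(self):
        df = toy_peak_table(4)
        df.loc["s2", "GP3"] = 0.0
        with pytest.raises(ValueError, match="s2"):
            pp.normalize_total_area(df)
        out = pp.normalize_total_area(df, on_nonpositive="floor")
        assert (out > 0).all().all()


class TestLogTransform:
    def test_known_values_and_round_trip(self):
        df = toy_peak_table()
        logged = pp.log_transform(df)
        np.testing.assert_allclose(np.exp(logged), df, atol=1e-12)
        one = pd.DataFrame({"GP1": [1.0, np.e]})
        out = pp.log_transform(one)
        np.testing.assert_allclose(out["GP1"], [0.0, 1.0])

    def test_nonpositive_rejected(self):
        df = toy_peak_table()
        df.iloc[0, 0] = 0.0
        with pytest.raises(ValueError):
            pp.log_transform(df)


class TestExcludePeaks:
    def test_default_leaves_22(self):
        out = pp.exclude_peaks(toy_peak_table())
        assert out.shape[1] == 22
        assert "GP20" not in out.columns and "GP21" not in out.columns

    def test_empty_exclusion_identity(self):
        df = toy_peak_table()
        pd.testing.assert_frame_equal(pp.exclude_peaks(df, ()), df)

    def test_unknown_peak_and_total_exclusion(self):
        df = toy_peak_table()
        with pytest.raises(KeyError):
            pp.exclude_peaks(df, ("GP99",))
        with pytest.raises(ValueError):
            pp.exclude_peaks(df, tuple(df.columns))


class TestDerivedTraits:
    def test_g0_direct_sum(self):
        df = toy_peak_table(1)
        df.loc[:, :] = 1.0
        df.loc["s0", ["GP1", "GP2", "GP3", "GP4", "GP6"]] = [4, 1, 0.5, 18, 3]
        assert pp.derived_traits(df).loc["s0", "G0"] == pytest.approx(26.5)

    def test_term_counts(self):
        df = toy_peak_table(1)
        df.loc[:, :] = 1.0
        traits = pp.derived_traits(df)
        assert traits.loc["s0", "F"] == pytest.approx(14.0)
        assert traits.loc["s0", "B"] == pytest.approx(9.0)
        assert traits.loc["s0", "G0"] == pytest.approx(5.0)

    def test_zero_peaks_zero_traits(self):
        df = toy_peak_table(1) * 0.0
        assert (pp.derived_traits(df) == 0).all().all()

    def test_linearity_mixture(self):
        df = toy_peak_table(2)
        mix = df.iloc[[0]].to_numpy() * 0.5 + df.iloc[[1]].to_numpy() * 0.5
        mixed = pd.DataFrame(mix, columns=df.columns, index=["mix"])
        t = pp.derived_traits(pd.concat([df, mixed]))
        np.testing.assert_allclose(
            t.loc["mix"], (t.iloc[0] + t.iloc[1]) / 2, atol=1e-12
        )

    def test_missing_column_raises(self):
        df = toy_peak_table().drop(columns="GP4")
        with pytest.raises(KeyError, match="GP4"):
            pp.derived_traits(df)


class TestRankInverseNormal:
    def test_three_values_inverse_cdf_oracle(self):
        out = pp.rank_inverse_normal(np.array([10.0, -3.0, 5.0]))
        expected = norm.ppf([(2 - 0.5) / 3, (0.5) / 3, (1.5) / 3])
        # sorted positions: -3 -> rank1, 5 -> rank2, 10 -> rank3
        np.testing.assert_allclose(
            out, [norm.ppf(2.5 / 3), norm.ppf(0.5 / 3), 0.0], atol=1e-12
        )
        assert out[0] == pytest.approx(0.9674, abs=1e-4)
        assert out[1] == pytest.approx(-0.9674, abs=1e-4)

    def test_symmetric_input_sums_to_zero(self, rng):
        x = rng.normal(size=101)
        assert pp.rank_inverse_normal(x).sum() == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(min_value=-1000, max_value=1000),
                 min_size=3, max_size=40, unique=True)
    )
    def test_monotone_transform_invariance(self, values):
        x = np.array(values, dtype=float) / 25.0
        np.testing.assert_allclose(
            pp.rank_inverse_normal(x),
            pp.rank_inverse_normal(np.exp(x)),
            atol=1e-9,
        )

    def test_mean_zero_sd_one(self, rng):
        out = pp.rank_inverse_normal(rng.exponential(size=500))
        assert abs(out.mean()) < 1e-9
        assert out.std(ddof=1) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pp.rank_inverse_normal(np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            pp.rank_inverse_normal(np.array([1.0, 2.0]))


def _batch_frame(rng, n_per=100, offset=1.0, n_peaks=6):
    cols = [f"GP{i}" for i in range(1, n_peaks + 1)]
    a = rng.normal(0.0, 0.3, size=(n_per, n_peaks))
    b = rng.normal(0.0, 0.3, size=(n_per, n_peaks)) + offset
    df = pd.DataFrame(np.vstack([a, b]), columns=cols)
    df.index = pd.Index([f"s{i}" for i in range(2 * n_per)], name="sample_id")
    batch = pd.Series(["p0"] * n_per + ["p1"] * n_per, index=df.index)
    return df, batch


class TestBatchCorrect:
    def test_single_batch_identity(self):
        df = pp.log_transform(pp.normalize_total_area(toy_peak_table(8)))
        batch = pd.Series("p0", index=df.index)
        out, model = combat(df, batch)
        pd.testing.assert_frame_equal(out, df)
        assert (model.gamma_star.to_numpy() == 0).all()
        assert (model.delta_star.to_numpy() == 1).all()

    def test_two_batches_additive_offset_equalised(self, rng):
        """Two balanced batches differing by a pure additive log-offset
        (batch B an exact shifted copy of batch A, offset scaled per peak so
        the standardized batch effect is common): the corrected table equals
        the per-batch mean-subtraction oracle and batch means coincide."""
        n_per, n_peaks = 200, 6
        cols = [f"GP{i}" for i in range(1, n_peaks + 1)]
        a = rng.normal(0.0, 0.3, size=(n_per, n_peaks))
        offset = 1.5 * a.std(axis=0, ddof=0)
        df = pd.DataFrame(np.vstack([a, a + offset]), columns=cols)
        df.index = pd.Index([f"s{i}" for i in range(2 * n_per)], name="sample_id")
        batch = pd.Series(["p0"] * n_per + ["p1"] * n_per, index=df.index)
        out, _ = combat(df, batch)
        m0 = out[batch == "p0"].mean()
        m1 = out[batch == "p1"].mean()
        np.testing.assert_allclose(m0, m1, atol=1e-6)
        # oracle: per-batch mean subtraction equalises batch means at the
        # grand mean; the EB correction must land on the same batch means
        oracle = df.copy()
        for b in ("p0", "p1"):
            sel = batch == b
            oracle[sel] = df[sel] - df[sel].mean() + df.mean()
        for b in ("p0", "p1"):
            np.testing.assert_allclose(
                out[batch == b].mean(), oracle[batch == b].mean(), atol=1e-6
            )

    def test_gamma_delta_recovery(self, rng):
        """Known location/scale batch effects are recovered (n=500/batch)."""
        n, n_peaks = 500, 8
        cols = [f"GP{i}" for i in range(1, n_peaks + 1)]
        gamma_true, delta_true = 0.8, 1.5
        base = rng.normal(0.0, 1.0, size=(2 * n, n_peaks))
        base[n:] = base[n:] * delta_true + gamma_true
        df = pd.DataFrame(base, columns=cols)
        batch = pd.Series(["a"] * n + ["b"] * n, index=df.index)
        _, model = combat(df, batch)
        # gamma is on the pooled standardized scale; map back via pooled SD
        pooled_sd = np.sqrt(
            ((df - df.groupby(batch).transform("mean")) ** 2).mean() * 2 * n / (2 * n - 2)
        )
        gamma_raw = (model.gamma_star.loc["b"] - model.gamma_star.loc["a"]) * pooled_sd
        assert abs(gamma_raw.mean() - gamma_true) < 0.05
        ratio = (model.delta_star.loc["b"] / model.delta_star.loc["a"]).mean()
        assert ratio == pytest.approx(delta_true, rel=0.10)

    def test_group_effect_preserved_balanced(self, rng):
        """Batch correction does not eat a balanced group effect."""
        n = 200
        cols = [f"GP{i}" for i in range(1, 7)]
        group = np.tile(["control", "DS"], n)
        batch = np.repeat(["p0", "p1"], n)
        y = rng.normal(size=(2 * n, 6)) + 0.7 * (group == "DS")[:, None]
        y += 1.0 * (batch == "p1")[:, None]
        df = pd.DataFrame(y, columns=cols)
        meta = pd.DataFrame({
            "group": group, "plate": batch,
            "age": rng.uniform(20, 60, 2 * n), "sex": "F",
        }, index=df.index)
        df.attrs["stage"] = "log"
        corrected, _ = pp.batch_correct(df, meta, preserve=("group", "age"))
        before = df[group == "DS"].mean() - df[group == "control"].mean()
        after = corrected[group == "DS"].mean() - corrected[group == "control"].mean()
        np.testing.assert_allclose(after, before, atol=0.05)

    def test_confounded_plate_raises(self, rng):
        df, batch = _batch_frame(rng, n_per=20)
        df.attrs["stage"] = "log"
        meta = pd.DataFrame({
            "group": np.where(batch == "p0", "control", "DS"),
            "plate": batch, "age": 30.0, "sex": "F",
        }, index=df.index)
        with pytest.raises(ValueError, match="confounded|rank"):
            pp.batch_correct(df, meta, preserve=("group",))

    def test_scanpy_combat_cross_check(self, rng):
        """Independent oracle: our EB correction agrees with the scanpy
        implementation of the same parametric procedure."""
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        df, batch = _batch_frame(rng, n_per=80, offset=0.8)
        adata = anndata.AnnData(
            df.to_numpy(), obs=pd.DataFrame({"batch": batch.to_numpy()}, index=df.index)
        )
        scanpy.pp.combat(adata, key="batch")
        ours, _ = combat(df, batch)
        np.testing.assert_allclose(ours.to_numpy(), adata.X, atol=1e-6)


class TestPipeline:
    def test_full_chain_shapes_and_ranked_scale(self, small_cohort):
        peaks, meta = small_cohort
        res = pp.preprocess_pipeline(peaks, meta)
        assert res["corrected"].shape[1] == 22
        assert list(res["traits"].columns) == list(TRAIT_FORMULAS)
        ranked = res["ranked"]
        assert ranked.shape[1] == 28
        np.testing.assert_allclose(ranked.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(ranked.std(ddof=1), 1.0, atol=0.05)

    def test_missing_peak_rows_dropped(self, small_cohort):
        peaks, meta = small_cohort
        peaks = peaks.copy()
        peaks.iloc[0, 0] = np.nan
        res = pp.preprocess_pipeline(peaks, meta)
        assert res["n_dropped"] == 1
        assert len(res["traits"]) == len(peaks) - 1
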