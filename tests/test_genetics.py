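"""Feature encoding, univariate tests, stability selection and the trisomy caller."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stimscreen as ss
from stimscreen import genetics


@pytest.fixture
def raw_genetics():
    idx = pd.Index([f"S{i}" for i in range(10)], name="sample_id")
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "trisomy12": rng.integers(0, 2, 10).astype(float),
            "KRAS": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            "BRAF": [0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
            "NRAS": np.zeros(10),
            "mostly_missing": [np.nan] * 3 + [1.0] * 7,  # 30% missing
        },
        index=idx,
        dtype=float,
    )
    ann = pd.DataFrame(
        {
            "sample_id": idx,
            "IGHV": ["M", "U"] * 5,
            "methylation": ["LP", "IP", "HP", "IP", "LP"] * 2,
        }
    )
    return df, ann


class TestEncoding:
    def test_high_missingness_feature_dropped(self, raw_genetics):
        df, ann = raw_genetics
        enc = ss.encode_features(df, ann)
        assert "mostly_missing" in enc.dropped_features
        assert "mostly_missing" not in enc.values.columns

    def test_ras_raf_collapsed(self, raw_genetics):
        df, ann = raw_genetics
        enc = ss.encode_features(df, ann)
        assert not any(g in enc.values.columns for g in genetics.RAS_RAF_GENES)
        assert enc.values.loc["S0", "RAS_RAF"] == 1  # KRAS mutated
        assert enc.values.loc["S1", "RAS_RAF"] == 1  # BRAF mutated
        assert enc.values.loc["S2", "RAS_RAF"] == 0

    def test_ighv_and_methylation_encoding(self, raw_genetics):
        df, ann = raw_genetics
        enc = ss.encode_features(df, ann)
        assert enc.values.loc["S0", "IGHV"] == 1.0  # M
        assert enc.values.loc["S1", "IGHV"] == 0.0  # U
        assert enc.values.loc["S1", "methylation"] == 0.5  # IP
        assert enc.values.loc["S2", "methylation"] == 1.0  # HP


class TestUnivariateTests:
    def test_hand_computed_t(self):
        resp = pd.DataFrame(
            {"IL4": [0.9, 1.0, 1.1, -0.1, 0.0, 0.1]},
            index=[f"S{i}" for i in range(6)],
        )
        feats = pd.DataFrame(
            {"g": [1.0, 1, 1, 0, 0, 0]}, index=resp.index
        )
        out = ss.univariate_response_tests(resp, feats, min_positive=3)
        row = out.iloc[0]
        assert row.t == pytest.approx(12.2474487, abs=1e-6)
        # pooled-variance t with df = 4
        expected_p = 2 * stats.t.sf(12.2474487, 4)
        assert row.p == pytest.approx(expected_p, rel=1e-8)

    def test_identical_groups_give_null(self):
        resp = pd.DataFrame({"IL4": [0.1, 0.5, 0.9, 0.1, 0.5, 0.9]},
                            index=[f"S{i}" for i in range(6)])
        feats = pd.DataFrame({"g": [1.0, 1, 1, 0, 0, 0]}, index=resp.index)
        out = ss.univariate_response_tests(resp, feats, min_positive=3)
        assert out.iloc[0].t == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_rare_feature_excluded(self):
        resp = pd.DataFrame({"IL4": np.arange(6.0)}, index=[f"S{i}" for i in range(6)])
        feats = pd.DataFrame({"g": [1.0, 1, 0, 0, 0, 0]}, index=resp.index)
        out = ss.univariate_response_tests(resp, feats, min_positive=3)
        assert out.empty

    def test_matches_scipy_oracle_on_random_instances(self, rng):
        """Pooled t and p equal the textbook formula on 100 random splits."""
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(size=rng.integers(3, 12))
            res = ss.two_sample_t_test(x, y)
            nx, ny = len(x), len(y)
            sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
            p = 2 * stats.t.sf(abs(t), nx + ny - 2)
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-10)


class TestStabilitySelection:
    def test_frequencies_are_multiples_of_inverse_nboot(self, rng):
        X = pd.DataFrame(
            (rng.random((60, 5)) < 0.3).astype(float),
            columns=list("abcde"),
            index=[f"S{i}" for i in range(60)],
        )
        y = pd.Series(0.5 * X["a"] + rng.normal(0, 0.2, 60), index=X.index)
        sel = ss.lasso_stability_gaussian(X, y, n_boot=10, seed=0)
        assert np.allclose((sel.table.frequency * 10) % 1, 0.0)

    def test_kept_monotone_in_threshold(self, rng):
        X = pd.DataFrame(
            (rng.random((60, 5)) < 0.3).astype(float),
            columns=list("abcde"),
            index=[f"S{i}" for i in range(60)],
        )
        y = pd.Series(0.5 * X["a"] + rng.normal(0, 0.2, 60), index=X.index)
        kept_sets = []
        for thr in (0.5, 0.75, 0.9):
            sel = ss.lasso_stability_gaussian(X, y, n_boot=10, freq_threshold=thr, seed=0)
            kept_sets.append(set(sel.kept))
        assert kept_sets[2] <= kept_sets[1] <= kept_sets[0]

    def test_two_boots_require_unanimity(self, rng):
        X = pd.DataFrame(
            (rng.random((40, 3)) < 0.4).astype(float),
            columns=list("abc"),
            index=[f"S{i}" for i in range(40)],
        )
        y = pd.Series(0.8 * X["a"] + rng.normal(0, 0.1, 40), index=X.index)
        sel = ss.lasso_stability_gaussian(X, y, n_boot=2, freq_threshold=0.75, seed=0)
        tab = sel.table.set_index("feature")
        for feat, row in tab.iterrows():
            if row.kept:
                assert row.frequency == 1.0

    def test_constant_response_empty_selection(self, rng):
        X = pd.DataFrame(
            (rng.random((30, 3)) < 0.4).astype(float), index=[f"S{i}" for i in range(30)]
        )
        y = pd.Series(1.0, index=X.index)
        sel = ss.lasso_stability_gaussian(X, y, n_boot=5, seed=0)
        assert sel.kept == []

    def test_gaussian_deterministic(self, rng):
        X = pd.DataFrame(
            (rng.random((50, 4)) < 0.3).astype(float), index=[f"S{i}" for i in range(50)]
        )
        y = pd.Series(rng.normal(size=50), index=X.index)
        a = ss.lasso_stability_gaussian(X, y, n_boot=5, seed=3)
        b = ss.lasso_stability_gaussian(X, y, n_boot=5, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_gaussian_recovers_planted_effect(self):
        rng = np.random.default_rng(100)
        n = 100
        X = pd.DataFrame(
            (rng.random((n, 11)) < 0.3).astype(float),
            columns=["trisomy12"] + [f"noise{i}" for i in range(10)],
            index=[f"S{i}" for i in range(n)],
        )
        y = pd.Series(0.8 * X["trisomy12"] + rng.normal(0, 0.1, n), index=X.index)
        sel = ss.lasso_stability_gaussian(X, y, n_boot=30, seed=1)
        assert "trisomy12" in sel.kept
        tab = sel.table.set_index("feature")
        assert tab.loc["trisomy12", "mean_coef"] > 0

    def test_multinomial_permuted_labels_keep_almost_nothing(self):
        rng = np.random.default_rng(200)
        n = 200
        clusters = pd.Series(np.repeat(["C1", "C2", "C3", "C4"], n // 4))
        X = pd.DataFrame(
            {
                **{
                    f"feat_{c}": (
                        rng.random(n) < np.where(clusters == c, 0.9, 0.1)
                    ).astype(float)
                    for c in ["C1", "C2", "C3", "C4"]
                },
            }
        )
        permuted = pd.Series(rng.permutation(clusters.to_numpy()))
        sels = ss.lasso_stability_multinomial(X, permuted, seed=0)
        total_kept = sum(len(s.kept) for s in sels.values())
        assert total_kept < 2

    def test_modulator_pair_skipped_below_min_samples(self, rng):
        X = pd.DataFrame(
            (rng.random((5, 3)) < 0.4).astype(float), index=[f"S{i}" for i in range(5)]
        )
        bi = pd.DataFrame(
            {
                "sample_id": X.index,
                "drug": "d",
                "stimulus": "s",
                "beta_int": rng.normal(size=5),
            }
        )
        assert ss.interaction_modulators(bi, X, min_samples=10) == {}


class TestTrisomyCaller:
    def make_peaks(self, chr12_mean, other_mean):
        return pd.DataFrame(
            {
                "peak_id": [f"p{i}" for i in range(6)],
                "chrom": ["chr12"] * 3 + ["chr1", "chr2", "chr3"],
                "count": [chr12_mean] * 3 + [other_mean] * 3,
            }
        )

    def test_above_threshold_called(self):
        call, ratio = ss.call_trisomy12_from_atac(self.make_peaks(15, 10))
        assert call and ratio == pytest.approx(1.5)

    def test_boundary_is_strict(self):
        call, ratio = ss.call_trisomy12_from_atac(self.make_peaks(14, 10))
        assert not call and ratio == pytest.approx(1.4)

    def test_flat_counts_not_called(self):
        call, ratio = ss.call_trisomy12_from_atac(self.make_peaks(10, 10))
        assert not call and ratio == pytest.approx(1.0)

    def test_no_chr12_errors(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "count": [5]})
        with pytest.raises(ValueError, match="chr12"):
            ss.call_trisomy12_from_atac(peaks)
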