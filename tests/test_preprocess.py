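"""Background correction, quantile normalization, expression filter and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetscan import preprocess
from tetscan.preprocess import (
    ALPHA_FLOOR,
    SIGMA_FLOOR,
    EstimationError,
    NormexpParams,
    estimate_normexp_params,
    low_intensity_filter,
    normexp_correct,
    qc_summaries,
    quantile_normalize,
)


class TestEstimateNormexpParams:
    def test_degenerate_controls_floor_sigma(self):
        col = np.concatenate([np.full(20, 100.0), np.full(50, 600.0)])
        mask = np.concatenate([np.ones(20, bool), np.zeros(50, bool)])
        p = estimate_normexp_params(col, mask)
        assert p.mu == 100.0
        assert p.sigma == SIGMA_FLOOR
        assert p.alpha == pytest.approx(500.0)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(100, 10, size=10_000)
        reg = rng.normal(600, 50, size=10_000)
        col = np.concatenate([neg, reg])
        mask = np.concatenate([np.ones(10_000, bool), np.zeros(10_000, bool)])
        p = estimate_normexp_params(col, mask)
        assert p.mu == pytest.approx(100.0, abs=0.3)
        assert p.sigma == pytest.approx(10.0, abs=0.3)
        assert p.alpha == pytest.approx(500.0, abs=2.0)

    def test_alpha_floored_when_signal_below_background(self):
        col = np.concatenate([np.full(20, 100.0), np.full(20, 50.0)])
        mask = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        with pytest.warns(UserWarning):
            p = estimate_normexp_params(col, mask)
        assert p.alpha == ALPHA_FLOOR

    def test_too_few_controls_names_sample(self):
        with pytest.raises(EstimationError, match="s1"):
            estimate_normexp_params(np.arange(30.0), np.zeros(30, bool), sample="s1")


class TestNormexpCorrect:
    def test_noise_free_limit(self):
        p = NormexpParams(mu=100.0, sigma=SIGMA_FLOOR, alpha=500.0)
        assert normexp_correct(np.array([600.0]), p)[0] == pytest.approx(500.0, rel=1e-3)

    def test_closed_form_oracle(self):
        # independent evaluation of a + sigma*phi(a/sigma)/Phi(a/sigma)
        p = NormexpParams(mu=100.0, sigma=10.0, alpha=500.0)
        assert normexp_correct(np.array([100.0]), p)[0] == pytest.approx(7.9066, abs=1e-3)

    def test_positive_and_order_preserving(self):
        rng = np.random.default_rng(0)
        x = rng.normal(120, 80, size=2000)  # includes values far below background
        p = NormexpParams(mu=100.0, sigma=15.0, alpha=200.0)
        out = normexp_correct(x, p)
        assert (out > 0).all()
        assert (np.diff(out[np.argsort(x)]) >= 0).all()

    def test_non_finite_rejected(self):
        p = NormexpParams(mu=0.0, sigma=1.0, alpha=1.0)
        with pytest.raises(ValueError):
            normexp_correct(np.array([np.nan]), p)


def _quantile_oracle(values: np.ndarray) -> np.ndarray:
    """Sort/average/unsort re-implementation (no ties)."""
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[np.argsort(values[:, j]), j] = ref
    return out


class TestQuantileNormalize:
    def test_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_identical_columns_fixed_point(self):
        col = np.random.default_rng(1).normal(size=100)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        out = quantile_normalize(m)
        assert np.allclose(out.to_numpy(), m.to_numpy())

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(100, 6))
        out = quantile_normalize(pd.DataFrame(vals))
        assert np.allclose(out.to_numpy(), _quantile_oracle(vals))

    def test_sorted_columns_identical(self):
        rng = np.random.default_rng(3)
        out = quantile_normalize(pd.DataFrame(rng.normal(size=(200, 5)))).to_numpy()
        s = np.sort(out, axis=0)
        assert np.max(np.abs(s - s[:, [0]])) == 0.0

    def test_ties_get_mean_of_spanned_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(ref[:2].mean())
        assert out["a"].iloc[2] == ref[2]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


def _filter_oracle(matrix, mask, min_arrays, factor):
    """Independent double-loop re-implementation of the removal rule."""
    thresholds = {
        c: factor * np.percentile(matrix.loc[mask, c], 95) for c in matrix.columns
    }
    retained = []
    for probe in matrix.index[~mask.reindex(matrix.index).to_numpy(dtype=bool)]:
        n_below = sum(matrix.loc[probe, c] < thresholds[c] for c in matrix.columns)
        if n_below < min_arrays:
            retained.append(probe)
    return set(retained)


class TestLowIntensityFilter:
    @pytest.fixture
    def fixture(self):
        rng = np.random.default_rng(5)
        probes = [f"p{i}" for i in range(80)] + [f"n{i}" for i in range(20)]
        mask = pd.Series([False] * 80 + [True] * 20, index=probes)
        vals = np.vstack([
            rng.normal(8, 2, size=(80, 6)),
            rng.normal(5, 1, size=(20, 6)),
        ])
        return pd.DataFrame(vals, index=probes), mask

    def test_bright_probe_retained(self, fixture):
        matrix, mask = fixture
        matrix.loc["p0"] = 100.0
        retained, _ = low_intensity_filter(matrix, mask)
        assert "p0" in retained

    def test_boundary_at_min_arrays(self, fixture):
        matrix, mask = fixture
        thresholds = 0.9 * matrix.loc[mask].quantile(0.95, axis=0)
        matrix.loc["p1"] = thresholds.to_numpy() + 1.0
        matrix.iloc[matrix.index.get_loc("p1"), :3] = 0.5 * thresholds.iloc[:3].to_numpy()
        retained, _ = low_intensity_filter(matrix, mask, min_arrays=3)
        assert "p1" not in retained  # below threshold on exactly 3 of 6 arrays

    def test_matches_bruteforce_oracle(self, fixture):
        matrix, mask = fixture
        retained, _ = low_intensity_filter(matrix, mask, min_arrays=3, factor=0.9)
        assert set(retained) == _filter_oracle(matrix, mask, 3, 0.9)

    def test_controls_always_removed(self, fixture):
        matrix, mask = fixture
        matrix.loc[mask] = 1000.0  # even very bright controls are dropped
        retained, _ = low_intensity_filter(matrix, mask)
        assert not (set(retained) & set(matrix.index[mask]))

    def test_filter_monotone_in_factor_and_min_arrays(self, fixture):
        matrix, mask = fixture
        base, _ = low_intensity_filter(matrix, mask, min_arrays=3, factor=0.9)
        harsher_factor, _ = low_intensity_filter(matrix, mask, min_arrays=3, factor=1.1)
        fewer_arrays, _ = low_intensity_filter(matrix, mask, min_arrays=2, factor=0.9)
        assert set(harsher_factor) <= set(base)
        assert set(fewer_arrays) <= set(base)

    def test_min_arrays_exceeding_arrays_rejected(self, fixture):
        matrix, mask = fixture
        with pytest.raises(ValueError):
            low_intensity_filter(matrix, mask, min_arrays=7)


class TestQC:
    def test_identical_samples_zero_rle(self):
        col = np.random.default_rng(1).normal(size=50)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        qc = qc_summaries(m)
        assert np.allclose(qc["rle_median"], 0.0)

    def test_group_offset_separates_on_pc1(self):
        rng = np.random.default_rng(2)
        base = rng.normal(8, 1, size=(200, 6))
        base[:100, 3:] += 5.0  # half the probes shifted in samples 3-5
        qc = qc_summaries(pd.DataFrame(base, columns=list("abcdef")))
        pc1 = qc["pc_coords"]["PC1"].to_numpy()
        assert (np.sign(pc1[:3]) != np.sign(pc1[3:])).all()

    def test_variance_fractions_valid(self, small_experiment):
        qc = qc_summaries(np.log2(small_experiment.intensities))
        frac = qc["variance_explained"]
        assert all(f >= 0 for f in frac)
        assert sum(frac) <= 1.0 + 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            qc_summaries(pd.DataFrame({"a": [1.0, 2.0]}))


class TestStageIsolation:
    def test_other_stage_permutation_leaves_values_unchanged(self, small_experiment):
        """Normalizing one stage is unaffected by anything done to samples of
        another stage (per-stage processing)."""
        exp = small_experiment
        mask = pd.Series(exp.probes["gene_id"].eq("NEG").to_numpy(),
                         index=exp.probes["probe_id"])
        larva_cols = exp.samples.loc[exp.samples["stage"] == "larva", "sample_id"].tolist()
        norm1, _ = preprocess.normalize_stage(exp.intensities[larva_cols], mask)
        shuffled = exp.intensities[larva_cols]  # same set, different column order
        norm2, _ = preprocess.normalize_stage(shuffled[larva_cols[::-1]], mask)
        assert np.allclose(norm1.to_numpy(), norm2[larva_cols].to_numpy())


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_quantile_invariant_property(seed):
    """Post-normalization sorted columns coincide exactly for any input."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(30, 4))
    out = quantile_normalize(pd.DataFrame(vals)).to_numpy()
    s = np.sort(out, axis=0)
    assert np.max(np.abs(s - s[:, [0]])) == 0.0
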