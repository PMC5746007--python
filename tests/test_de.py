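"""Moderated t-test chain: pooled stats, prior estimation, moderation,
BH adjustment, gene collapse and DE calling."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tetscan import de
from tetscan.de import (
    ContrastError,
    ContrastSpec,
    EstimationError,
    ModerationParams,
    bh_adjust,
    call_de,
    collapse_to_genes,
    estimate_prior,
    moderated_t,
    probe_level_stats,
)


def _matrix(a, b):
    """Probe matrix with groups A (tet_off) and B (tet_on) as columns."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    cols = {f"A{i}": a[:, i] for i in range(a.shape[1])}
    cols.update({f"B{i}": b[:, i] for i in range(b.shape[1])})
    return pd.DataFrame(cols, index=[f"probe{i}" for i in range(a.shape[0])])


def _contrast(n_a, n_b):
    return ContrastSpec(
        strain="s", stage="larva",
        group_a=tuple(f"A{i}" for i in range(n_a)),
        group_b=tuple(f"B{i}" for i in range(n_b)),
    )


class TestProbeLevelStats:
    def test_hand_computation(self):
        m = _matrix([[2.0, 3.0, 4.0]], [[1.0, 2.0, 3.0]])
        s = probe_level_stats(m, _contrast(3, 3))
        assert s["beta"].iloc[0] == pytest.approx(1.0)
        assert s["s_sq"].iloc[0] == pytest.approx(1.0)
        assert s["df"].iloc[0] == 4
        assert s["v"].iloc[0] == pytest.approx(2 / 3)

    def test_equal_groups_zero_effect(self):
        m = _matrix([[1.0, 2.0, 5.0]], [[1.0, 2.0, 5.0]])
        assert probe_level_stats(m, _contrast(3, 3))["beta"].iloc[0] == 0.0

    def test_matches_textbook_pooled_formula(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(50, 3)), rng.normal(size=(50, 3))
        s = probe_level_stats(_matrix(A, B), _contrast(3, 3))
        expected = (A.var(axis=1, ddof=1) * 2 + B.var(axis=1, ddof=1) * 2) / 4
        assert np.allclose(s["s_sq"], expected)
        assert np.allclose(s["beta"], A.mean(axis=1) - B.mean(axis=1))

    def test_small_group_rejected(self):
        m = _matrix([[1.0, 2.0]], [[1.0, 2.0]])
        with pytest.raises(ContrastError):
            probe_level_stats(m, ContrastSpec("s", "larva", ("A0",), ("B0", "B1")))


class TestEstimatePrior:
    def test_zero_dispersion_limit(self):
        # equal variances: no excess dispersion, prior absorbs everything
        prior = estimate_prior(np.full(100, 0.25), 4.0)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25)

    def test_parameter_recovery_on_scaled_inv_chisq(self):
        rng = np.random.default_rng(8)
        d0, s0_sq, d_g = 4.0, 0.05, 4.0
        s_sq = s0_sq * d0 / rng.chisquare(d0, size=5000) * rng.chisquare(d_g, size=5000) / d_g
        prior = estimate_prior(s_sq, d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_single_gene_rejected(self):
        with pytest.raises(EstimationError):
            estimate_prior(np.array([0.5]), 4.0)

    def test_all_zero_rejected(self):
        with pytest.raises(EstimationError):
            estimate_prior(np.zeros(10), 4.0)


class TestModeratedT:
    def test_ordinary_t_limit(self):
        m = _matrix([[2.0, 3.0, 4.0]], [[1.0, 2.0, 3.0]])
        s = probe_level_stats(m, _contrast(3, 3))
        out = moderated_t(s, ModerationParams(d0=0.0, s0_sq=1.0))
        assert out["t"].iloc[0] == pytest.approx(1 / np.sqrt(2 / 3), abs=1e-12)
        assert out["df_total"].iloc[0] == 4
        assert out["p"].iloc[0] == pytest.approx(0.28786, abs=1e-4)

    def test_normal_limit(self):
        s = pd.DataFrame({"beta": [1.0], "s_sq": [0.5], "df": [4.0], "v": [2 / 3]})
        out = moderated_t(s, ModerationParams(d0=np.inf, s0_sq=1.0))
        assert out["t"].iloc[0] == pytest.approx(1 / np.sqrt(2 / 3), abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(0.22067, abs=1e-4)

    def test_null_effect_p_one(self):
        s = pd.DataFrame({"beta": [0.0], "s_sq": [0.5], "df": [4.0], "v": [2 / 3]})
        out = moderated_t(s, ModerationParams(d0=4.0, s0_sq=0.5))
        assert out["p"].iloc[0] == 1.0

    def test_shrinkage_monotone_in_d0(self):
        rng = np.random.default_rng(1)
        s = pd.DataFrame({
            "beta": rng.normal(size=50),
            "s_sq": rng.chisquare(4, size=50) / 4,
            "df": 4.0,
            "v": 2 / 3,
        })
        s0_sq = 1.0
        prev = moderated_t(s, ModerationParams(d0=1.0, s0_sq=s0_sq))["s_tilde_sq"]
        for d0 in (2.0, 8.0, 64.0):
            cur = moderated_t(s, ModerationParams(d0=d0, s0_sq=s0_sq))["s_tilde_sq"]
            assert (np.abs(cur - s0_sq) <= np.abs(prev - s0_sq) + 1e-12).all()
            prev = cur

    def test_whole_chain_equals_plain_t_when_unmoderated(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(1000, 3)), rng.normal(size=(1000, 3))
        s = probe_level_stats(_matrix(A, B), _contrast(3, 3))
        out = moderated_t(s, ModerationParams(d0=0.0, s0_sq=1.0))
        _t, p = sps.ttest_ind(A, B, axis=1)
        assert np.max(np.abs(out["p"].to_numpy() - p)) < 1e-12


def _bh_oracle(p):
    """O(m^2) step-up: adj_(i) = min over j >= i of m p_(j) / j, in input order."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


class TestBHAdjust:
    def test_hand_computation(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=1000)
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_dominance_and_rank_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=300)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestCollapseToGenes:
    def _stats(self, rows):
        df = pd.DataFrame(rows, columns=["probe", "p"]).set_index("probe")
        df["beta"] = 1.0
        df["t"] = 1.0
        df["adj_p"] = df["p"]
        return df

    def test_lowest_p_kept_per_gene(self):
        stats = self._stats([("pa", 0.2), ("pb", 0.04)])
        out = collapse_to_genes(stats, {"pa": "g1", "pb": "g1"})
        assert out.loc["g1", "p"] == 0.04
        assert out.loc["g1", "probe_id"] == "pb"

    def test_straddling_duplicates_removed_entirely(self):
        stats = self._stats([("dup", 0.03), ("dup", 0.2)])
        out = collapse_to_genes(stats, {"dup": "g1"})
        assert "g1" not in out.index

    def test_same_side_duplicates_retained(self):
        stats = self._stats([("dup", 0.01), ("dup", 0.03)])
        out = collapse_to_genes(stats, {"dup": "g1"})
        assert out.loc["g1", "p"] == 0.01

    def test_sequence_identity_column(self):
        stats = self._stats([("pa", 0.03), ("pb", 0.2)])
        stats["seq"] = "ACGT"  # same sequence printed under two ids
        out = collapse_to_genes(stats, {"pa": "g1", "pb": "g1"}, identity_col="seq")
        assert "g1" not in out.index

    def test_unmapped_probe_dropped(self):
        stats = self._stats([("pa", 0.01)])
        assert collapse_to_genes(stats, {}).empty


class TestCallDE:
    def test_boundary_inclusive(self):
        genes = pd.DataFrame({"adj_p": [0.10, 0.1000001]}, index=["g1", "g2"])
        out = call_de(genes, q=0.10)
        assert bool(out.loc["g1", "de"]) and not bool(out.loc["g2", "de"])

    def test_empty_input(self):
        out = call_de(pd.DataFrame({"adj_p": []}))
        assert len(out) == 0


class TestCalibration:
    def test_type_i_error_within_binomial_band(self):
        rng = np.random.default_rng(6)
        n_genes = 4000
        A, B = rng.normal(size=(n_genes, 3)), rng.normal(size=(n_genes, 3))
        s = probe_level_stats(_matrix(A, B), _contrast(3, 3))
        prior = estimate_prior(s["s_sq"].to_numpy(), s["df"].to_numpy())
        p = moderated_t(s, prior)["p"].to_numpy()
        frac = (p <= 0.05).mean()
        band = 2.576 * np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) < band + 0.005  # p values mildly discrete at df ~ 4

    def test_null_fdr_mean_false_positives_below_one(self):
        """BH at FDR 10% on a global null: on average < 1 called gene."""
        rng = np.random.default_rng(7)
        n_genes, counts = 5000, []
        for _ in range(20):
            A, B = rng.normal(size=(n_genes, 3)), rng.normal(size=(n_genes, 3))
            s = probe_level_stats(_matrix(A, B), _contrast(3, 3))
            prior = estimate_prior(s["s_sq"].to_numpy(), s["df"].to_numpy())
            out = moderated_t(s, prior)
            adj = bh_adjust(out["p"].to_numpy())
            counts.append(int((adj <= 0.10).sum()))
        assert np.mean(counts) <= 1.0


class TestAgainstLimma:
    def test_prior_and_p_match_limma_squeezevar(self, tmp_path):
        """Independent oracle: the reference empirical-Bayes implementation
        (limma::squeezeVar) on the same variances yields the same prior and
        the same moderated p values."""
        rng = np.random.default_rng(9)
        n = 200
        # genuinely over-dispersed variances so the finite-d0 branch is hit
        gene_sd = np.sqrt(0.05 * 4.0 / rng.chisquare(4.0, size=n))
        A = rng.normal(0, gene_sd[:, None], size=(n, 3))
        B = rng.normal(0, gene_sd[:, None], size=(n, 3))
        s = probe_level_stats(_matrix(A, B), _contrast(3, 3))
        prior = estimate_prior(s["s_sq"].to_numpy(), s["df"].to_numpy())
        mine = moderated_t(s, prior)

        data = tmp_path / "stats.csv"
        s.reset_index(drop=True)[["beta", "s_sq", "df", "v"]].to_csv(data, index=False)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            d <- read.csv(commandArgs(TRUE)[1])
            sv <- squeezeVar(d$s_sq, df = d$df)
            t <- d$beta / sqrt(sv$var.post * d$v)
            p <- 2 * pt(-abs(t), df = d$df + sv$df.prior)
            cat(sv$df.prior, sv$var.prior, "\\n")
            write.csv(data.frame(p = p), commandArgs(TRUE)[2], row.names = FALSE)
        """))
        out_csv = tmp_path / "p.csv"
        res = subprocess.run(
            ["Rscript", str(rscript), str(data), str(out_csv)],
            capture_output=True, text=True, timeout=120,
        )
        assert res.returncode == 0, res.stderr
        d0_r, s0_r = map(float, res.stdout.split())
        assert prior.d0 == pytest.approx(d0_r, rel=1e-4)
        assert prior.s0_sq == pytest.approx(s0_r, rel=1e-4)
        p_r = pd.read_csv(out_csv)["p"].to_numpy()
        assert np.max(np.abs(mine["p"].to_numpy() - p_r)) < 1e-8
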