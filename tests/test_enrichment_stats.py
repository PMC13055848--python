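import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from endoprofiler.enrichment_stats import (
    CALL_ENDO,
    CALL_NS,
    CALL_SURF,
    VariancePrior,
    adjust_bh,
    call_compartments,
    fit_variance_prior,
    log_transform,
    moderated_t,
)


def simulate_variances(rng, g, d0, s0_sq, df_resid):
    """Scaled inverse-chi-square truth plus chi-square sampling noise."""
    s2_true = s0_sq * d0 / rng.chisquare(d0, g)
    return s2_true * rng.chisquare(df_resid, g) / df_resid


def bh_brute_force(p):
    """Step-up definition: adj(k) = min(1, min_{i>=k} p(i) * m / i) in rank order."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(1.0, running)
    return adj


class TestLogTransform:
    def test_known_values_and_roundtrip(self, design):
        from endoprofiler.io_model import ProteinQuantTable
        from endoprofiler.tmt_quant import RatioTable, compute_nc_ratios

        from conftest import random_quant_frame

        rng = np.random.default_rng(0)
        table = ProteinQuantTable(data=random_quant_frame(rng, design, 10), design=design)
        ratios = compute_nc_ratios(table, design, pseudocount=0.0)
        logr = log_transform(ratios)
        exp = design.experimental_channels
        np.testing.assert_allclose(
            np.exp2(logr.to_numpy()), ratios.data[exp].to_numpy(), rtol=1e-12
        )
        manual = RatioTable(
            data=pd.DataFrame(
                {c: [2.0 if c == exp[0] else 1.0] for c in exp} | {"nc_mean": [1.0]},
                index=pd.Index(["P"], name="protein_id"),
            ),
            design=design,
        )
        vals = log_transform(manual)
        assert vals.loc["P", exp[0]] == pytest.approx(1.0)
        assert vals.loc["P", exp[1]] == pytest.approx(0.0)


class TestVariancePrior:
    def test_parameter_recovery_on_simulation(self):
        """d0 = 4, s0^2 = 1 recovered within 10% / 5% at G = 50,000."""
        rng = np.random.default_rng(42)
        s2 = simulate_variances(rng, 50_000, d0=4.0, s0_sq=1.0, df_resid=4)
        prior = fit_variance_prior(s2, 4)
        assert prior.prior_df == pytest.approx(4.0, rel=0.10)
        assert prior.prior_var == pytest.approx(1.0, rel=0.05)

    def test_constant_variances_give_infinite_prior(self):
        prior = fit_variance_prior(np.full(100, 0.7), 4)
        assert math.isinf(prior.prior_df)
        assert prior.prior_var == pytest.approx(0.7)

    def test_too_few_variances_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_variance_prior(np.ones(5) + np.arange(5) * 0.1, 4)


class TestModeratedT:
    def _groups(self, rng, g=200, delta=0.0, sd=0.5):
        a = pd.DataFrame(rng.normal(0.0, sd, (g, 3)))
        b = pd.DataFrame(rng.normal(delta, sd, (g, 3)))
        return a, b

    def test_identical_means_give_zero_t_and_p_one(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]] * 12)
        res = moderated_t(a, a.copy(), prior=VariancePrior(4.0, 1.0))
        np.testing.assert_allclose(res["t_mod"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_zero_prior_df_limit_equals_ordinary_t(self):
        """With d0 -> 0 the moderated statistic is the classic pooled
        two-sample t; scipy's implementation is the independent oracle."""
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = self._groups(rng, delta=0.4)
        res = moderated_t(a, b, prior=VariancePrior(1e-12, 1.0))
        t_ref, p_ref = stats.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t_ref, rtol=1e-6)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-5)

    def test_infinite_prior_df_closed_form(self):
        rng = np.random.default_rng(2)
        a, b = self._groups(rng)
        s0_sq = 0.8
        res = moderated_t(a, b, prior=VariancePrior(math.inf, s0_sq))
        np.testing.assert_allclose(res["s2_post"], s0_sq)
        expected_t = res["log2fc"] / math.sqrt(s0_sq * (2.0 / 3.0))
        np.testing.assert_allclose(res["t_mod"], expected_t, rtol=1e-12)

    def test_shrinkage_pulls_variances_toward_prior(self):
        prior = VariancePrior(4.0, 1.0)
        tiny = pd.DataFrame([[0.0, 0.001, -0.001]])
        huge = pd.DataFrame([[-3.0, 0.0, 3.0]])
        shift = pd.DataFrame([[1.0, 1.001, 0.999]])
        res_tiny = moderated_t(tiny, shift, prior=prior)
        assert res_tiny["s2_resid"].iloc[0] < res_tiny["s2_post"].iloc[0] < prior.prior_var
        res_huge = moderated_t(huge, huge + 1.0, prior=prior)
        assert prior.prior_var < res_huge["s2_post"].iloc[0] < res_huge["s2_resid"].iloc[0]

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        a, b = self._groups(rng, delta=0.3)
        prior = VariancePrior(4.0, 0.5)
        fwd = moderated_t(a, b, prior=prior)
        rev = moderated_t(b, a, prior=prior)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["t_mod"], -rev["t_mod"])
        np.testing.assert_allclose(fwd["p"], rev["p"])

    def test_null_calibration(self):
        """Under the null (both groups from one lognormal, G = 5,000) the
        raw-p rejection rate at 0.05 is 0.05 +/- 0.01."""
        rng = np.random.default_rng(2024)
        g = 5000
        s2 = simulate_variances(rng, g, d0=6.0, s0_sq=0.09, df_resid=4)
        sd = np.sqrt(s2)[:, None]
        a = pd.DataFrame(rng.normal(0.0, sd, (g, 3)))
        b = pd.DataFrame(rng.normal(0.0, sd, (g, 3)))
        res = moderated_t(a, b)
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Full pipeline (prior fit + moderation) cross-checked against the
        reference empirical-Bayes implementation in R/limma."""
        rng = np.random.default_rng(5)
        g = 150
        s2 = simulate_variances(rng, g, d0=4.0, s0_sq=1.0, df_resid=4)
        a = rng.normal(0, np.sqrt(s2)[:, None], (g, 3))
        b = rng.normal(0.5, np.sqrt(s2)[:, None], (g, 3))
        mat = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"P{i}" for i in range(g)],
            columns=["e1", "e2", "e3", "s1", "s2", "s3"],
        )
        mat.to_csv(tmp_path / "mat.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- read.delim("{tmp_path}/mat.tsv", row.names=1)\n'
            "design <- cbind(Intercept=1, Group=c(0,0,0,1,1,1))\n"
            "fit <- eBayes(lmFit(as.matrix(x), design))\n"
            'out <- data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"],'
            " d0=fit$df.prior, s02=fit$s2.prior)\n"
            f'write.table(out, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE, row.names=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, timeout=120
        )
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        res = moderated_t(pd.DataFrame(a), pd.DataFrame(b))
        prior = fit_variance_prior(res["s2_resid"].to_numpy(), 4)
        assert prior.prior_df == pytest.approx(ref["d0"][0], rel=1e-6)
        assert prior.prior_var == pytest.approx(ref["s02"][0], rel=1e-6)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6)


class TestBhAdjustment:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            got = adjust_bh(p)
            np.testing.assert_allclose(got, bh_brute_force(p), rtol=1e-12)
            assert (got >= p - 1e-15).all()


class TestCompartmentCalls:
    def test_call_rules(self):
        df = pd.DataFrame(
            {
                "log2fc": [2.0, -2.0, 3.0, 0.5],
                "p": [1e-4, 1e-4, 0.5, 0.04],
            },
            index=["up", "down", "flat", "weak"],
        )
        out = call_compartments(df, alpha=0.05)
        assert out.loc["up", "call"] == CALL_SURF
        assert out.loc["down", "call"] == CALL_ENDO
        assert out.loc["flat", "call"] == CALL_NS
        # adjusted p exceeds alpha for the borderline raw p after BH
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_raw_p_option(self):
        df = pd.DataFrame({"log2fc": [1.0, 1.0], "p": [0.04, 0.9]})
        raw = call_compartments(df, alpha=0.05, use_adjusted=False)
        assert list(raw["call"]) == [CALL_SURF, CALL_NS]
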