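import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_effect, random_correlation
from oracles import reml_loglik_brute
from parabias.phylo_meta import (
    MetaModel,
    MetaModelSpec,
    RankError,
    egger_test,
    fit_meta,
    influence_diagnostics,
    q_residual,
    refit_without_outliers,
)
from parabias.tree_tools import VCVMatrix


def random_instance(k, ns, rng, spec=MetaModelSpec(), shared_studies=False):
    sp_names = [f"sp{i}" for i in range(ns)]
    R = random_correlation(ns, rng)
    periods = ("breeding", "nonbreeding", "year_round")
    effects = []
    for i in range(k):
        study = f"study{i // 2}" if shared_studies else f"study{i}"
        effects.append(
            make_effect(
                rng.normal(0.3, 0.6),
                0.05 + rng.random() * 0.4,
                species=sp_names[i % ns],
                study=study,
                period=periods[i % 3],
            )
        )
    phylo = VCVMatrix(labels=sp_names, C=R)
    return effects, spec, phylo, R


class TestRemlAgainstBruteForce:
    @pytest.mark.parametrize("shared_studies", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_matches_textbook_formula(self, seed, shared_studies):
        rng = np.random.default_rng(seed)
        effects, spec, phylo, R = random_instance(
            6, 3, rng, MetaModelSpec(moderators=("period",)),
            shared_studies=shared_studies,
        )
        model = MetaModel(effects, spec, phylo)
        for theta in [(0.0, 0.0), (0.2, 0.1), (1.0, 0.5), (0.03, 1.2)]:
            ll = model.reml_loglik(*theta)
            ll_brute, _ = reml_loglik_brute(
                model.y, model.X, model.v, model.sp_idx, model.st_idx,
                model.R, *theta,
            )
            assert ll == pytest.approx(ll_brute, abs=1e-8)

    def test_beta_at_optimum_matches_brute_force(self):
        rng = np.random.default_rng(7)
        effects, spec, phylo, _ = random_instance(6, 3, rng)
        model = MetaModel(effects, spec, phylo)
        fit = model.fit()
        _, beta_brute = reml_loglik_brute(
            model.y, model.X, model.v, model.sp_idx, model.st_idx, model.R,
            fit.sigma2_phylo, fit.sigma2_study,
        )
        assert np.abs(fit.beta - beta_brute).max() < 1e-8

    def test_lowrank_and_dense_paths_agree(self):
        rng = np.random.default_rng(11)
        effects, spec, phylo, _ = random_instance(20, 7, rng)
        model = MetaModel(effects, spec, phylo)
        assert model._studies_unique
        for theta in [(0.0, 0.0), (0.3, 0.2), (1.5, 0.01)]:
            nll1, g1 = model._nll_grad_lowrank(np.array(theta))
            nll2, g2 = model._nll_grad_dense(np.array(theta))
            assert nll1 == pytest.approx(nll2, abs=1e-9)
            assert np.abs(g1 - g2).max() < 1e-8

    def test_optimum_dominates_feasible_points(self):
        rng = np.random.default_rng(13)
        effects, spec, phylo, _ = random_instance(12, 5, rng)
        model = MetaModel(effects, spec, phylo)
        fit = model.fit()
        assert fit.loglik_reml >= model.reml_loglik(0.0, 0.0) - 1e-9
        for _ in range(10):
            pt = rng.random(2) * 2
            assert fit.loglik_reml >= model.reml_loglik(*pt) - 1e-9


class TestClosedFormLimits:
    def test_two_effects_fixed_components(self):
        effects = [make_effect(0.0, 1.0, species="a", study="s1"),
                   make_effect(1.0, 1.0, species="b", study="s2")]
        model = MetaModel(effects)
        beta, cov = model.gls_beta(0.0, 0.0)
        assert beta[0] == pytest.approx(0.5, abs=1e-12)
        assert np.sqrt(cov[0, 0]) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_zero_component_estimate_is_inverse_variance_mean(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=8)
        v = 0.1 + rng.random(8)
        effects = [make_effect(yi, vi, species=f"s{i}", study=f"st{i}")
                   for i, (yi, vi) in enumerate(zip(y, v))]
        beta, _ = MetaModel(effects).gls_beta(0.0, 0.0)
        assert beta[0] == pytest.approx(np.sum(y / v) / np.sum(1 / v), abs=1e-10)

    def test_estimates_invariant_to_row_order_and_label_permutation(self):
        rng = np.random.default_rng(5)
        effects, spec, phylo, _ = random_instance(10, 4, rng)
        fit1 = fit_meta(effects, spec, phylo)
        perm = rng.permutation(len(effects))
        fit2 = fit_meta([effects[i] for i in perm], spec, phylo)
        assert fit1.estimate == pytest.approx(fit2.estimate, abs=1e-8)
        assert fit1.sigma2_phylo == pytest.approx(fit2.sigma2_phylo, abs=1e-7)
        assert fit1.loglik_reml == pytest.approx(fit2.loglik_reml, abs=1e-7)

    def test_low_power_flag_below_five_studies(self):
        effects = [make_effect(0.1 * i, 0.5, species=f"s{i}", study=f"st{i}")
                   for i in range(4)]
        assert fit_meta(effects).low_power_flag
        effects5 = effects + [make_effect(0.5, 0.5, species="s4", study="st4")]
        assert not fit_meta(effects5).low_power_flag

    def test_fewer_than_two_effects_rejected(self):
        with pytest.raises(ValueError):
            fit_meta([make_effect(0.0, 1.0)])

    def test_aliased_moderator_column_named(self):
        # all effects in one period level except a constant-coded duplicate:
        # intercept + single-level dummy is fine, but duplicating the level
        # pattern across period and detection aliases the design
        effects = [
            make_effect(0.1, 0.5, species="a", study="s1",
                        period="nonbreeding", detection="molecular"),
            make_effect(0.2, 0.5, species="b", study="s2",
                        period="nonbreeding", detection="molecular"),
            make_effect(0.3, 0.5, species="c", study="s3",
                        period="breeding", detection="microscopy"),
        ]
        with pytest.raises(RankError, match="detection"):
            MetaModel(effects, MetaModelSpec(moderators=("period", "detection")))


class TestQResidual:
    def test_perfect_homogeneity(self):
        effects = [make_effect(0.7, 0.5, species=f"s{i}", study=f"st{i}")
                   for i in range(4)]
        fit = fit_meta(effects)
        qe, df, p = q_residual(fit)
        assert qe == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_two_effect_hand_calculation(self):
        effects = [make_effect(-1.0, 1.0, species="a", study="s1"),
                   make_effect(1.0, 1.0, species="b", study="s2")]
        fit = fit_meta(effects)
        assert fit.QE == pytest.approx(2.0, abs=1e-10)
        assert fit.QE_df == 1
        assert fit.QE_p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-10)
        assert fit.QE_p == pytest.approx(0.15730, abs=1e-5)


class TestEgger:
    def test_classical_mode_matches_weighted_regression_logic(self):
        rng = np.random.default_rng(2)
        sei = 0.1 + rng.random(20)
        y = rng.normal(0.2, 0.1, 20) + 1.5 * sei
        effects = [make_effect(yi, s**2, species=f"sp{i}", study=f"st{i}")
                   for i, (yi, s) in enumerate(zip(y, sei))]
        res = egger_test(effects, mode="precision_regression")
        assert res.p < 0.10 and res.biased

    def test_se_moderator_mode_reports_sei_coefficient(self):
        rng = np.random.default_rng(4)
        sei = 0.1 + rng.random(25)
        y = rng.normal(0.0, 0.05, 25) + 2.0 * sei
        effects = [make_effect(yi, s**2, species=f"sp{i}", study=f"st{i}")
                   for i, (yi, s) in enumerate(zip(y, sei))]
        res = egger_test(effects, mode="se_moderator")
        assert res.mode == "se_moderator"
        assert res.estimate == pytest.approx(2.0, abs=1.0)
        assert res.biased

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValueError):
            egger_test([make_effect(0, 1), make_effect(1, 1, study="s2")])

    def test_equal_standard_errors_rejected(self):
        effects = [make_effect(0.1 * i, 0.25, species=f"s{i}", study=f"st{i}")
                   for i in range(5)]
        with pytest.raises(ValueError, match="aliased"):
            egger_test(effects, mode="precision_regression")


class TestInfluence:
    def build(self):
        effects = [make_effect(0.0, 1.0, species=f"sp{i}", study=f"st{i}")
                   for i in range(9)]
        effects.append(make_effect(10.0, 0.01, species="sp_out", study="st_out"))
        return effects

    def test_extreme_effect_flagged_and_refit_moves_toward_null(self):
        effects = self.build()
        fit = fit_meta(effects)
        report = influence_diagnostics(fit)
        assert report.flagged == [9]
        refit = refit_without_outliers(effects, MetaModelSpec(), None, report)
        assert abs(refit.estimate) < abs(fit.estimate)
        assert refit.k == 9 and refit.n_species == 9 and refit.n_studies == 9

    def test_exchangeable_effects_not_flagged(self):
        effects = [make_effect(0.5, 0.5, species=f"sp{i}", study=f"st{i}")
                   for i in range(6)]
        fit = fit_meta(effects)
        report = influence_diagnostics(fit)
        assert report.flagged == []
        assert np.abs(report.estimate_shift).max() < 1e-8

    def test_loo_estimate_reproduced_by_manual_refit(self):
        effects = self.build()
        fit = fit_meta(effects)
        report = influence_diagnostics(fit)
        manual = fit_meta(effects[:9])
        assert report.loo_estimate[9] == pytest.approx(manual.estimate, abs=1e-8)

    def test_hat_values_sum_to_design_rank(self):
        rng = np.random.default_rng(9)
        effects, spec, phylo, _ = random_instance(
            12, 4, rng, MetaModelSpec(moderators=("period",))
        )
        model = MetaModel(effects, spec, phylo)
        fit = model.fit()
        hat = model.hat_values(fit.sigma2_phylo, fit.sigma2_study)
        assert hat.sum() == pytest.approx(model.X.shape[1], abs=1e-8)

    def test_no_flags_is_noop_refit(self):
        effects = [make_effect(0.5, 0.5, species=f"sp{i}", study=f"st{i}")
                   for i in range(6)]
        fit = fit_meta(effects)
        report = influence_diagnostics(fit)
        out = refit_without_outliers(effects, MetaModelSpec(), None, report,
                                     original_fit=fit)
        assert out is fit


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_cross_check_against_metafor(tmp_path):
    """Independent oracle: metafor's rma.mv on the same data and matrix."""
    rng = np.random.default_rng(21)
    ns = 6
    sp = [f"sp{i}" for i in range(ns)]
    R = random_correlation(ns, rng)
    effects, rows = [], []
    sid = 0
    for i, s in enumerate(sp):
        for _ in range(3):
            sid += 1
            yi = rng.normal(0.4, 0.7)
            vi = 0.05 + rng.random() * 0.3
            effects.append(make_effect(yi, vi, species=s, study=f"st{sid}"))
            rows.append({"yi": yi, "vi": vi, "species": s, "study": f"st{sid}"})
    pd.DataFrame(rows).to_csv(tmp_path / "d.csv", index=False)
    pd.DataFrame(R, index=sp, columns=sp).to_csv(tmp_path / "R.csv")
    fit = fit_meta(effects, phylo=VCVMatrix(labels=sp, C=R))

    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent("""
        suppressMessages(library(metafor))
        args <- commandArgs(trailingOnly=TRUE)
        d <- read.csv(file.path(args[1], "d.csv"))
        Rm <- as.matrix(read.csv(file.path(args[1], "R.csv"), row.names=1))
        colnames(Rm) <- rownames(Rm)
        d$species <- factor(d$species, levels=rownames(Rm))
        f <- rma.mv(yi, vi, random=list(~1|species, ~1|study),
                    R=list(species=Rm), data=d, method="REML")
        cat(coef(f), f$se, f$sigma2[1], f$sigma2[2], sep="\\n")
    """))
    out = subprocess.run(
        ["Rscript", str(script), str(tmp_path)], capture_output=True, text=True,
        timeout=120,
    )
    assert out.returncode == 0, out.stderr
    est, se, s2sp, s2st = map(float, out.stdout.split())
    assert fit.estimate == pytest.approx(est, abs=1e-4)
    assert fit.se[0] == pytest.approx(se, abs=1e-4)
    assert fit.sigma2_phylo == pytest.approx(s2sp, abs=1e-3)
    assert fit.sigma2_study == pytest.approx(s2st, abs=1e-3)
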