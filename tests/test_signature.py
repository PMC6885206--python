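"""Signature fitting, frozen-model transfer, adjusted and sensitivity Cox."""

import logging

import numpy as np
import pandas as pd
import pytest

from clustsig.containers import ExpressionMatrix, SurvivalTable
from clustsig.errors import CollinearityError
from clustsig.signature import (
    ClusterSignature,
    adjusted_cox,
    apply_signature,
    fit_signature,
    sensitivity_drop,
)
from clustsig.simulate import SyntheticConfig, generate_cohort
from clustsig.survival import fit_cox


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    coh = small_cohort_module
    genes = coh.true_params["signature_genes"]
    sig = fit_signature(coh.expression.subset_genes(genes), coh.survival,
                        random_state=0)
    return coh, sig


@pytest.fixture(scope="module")
def small_cohort_module():
    cfg = SyntheticConfig(
        n_samples=450, n_genes=60, n_signature_genes=3, shift=2.5,
        true_log_hr=float(np.log(5.0)), seed=5,
    )
    return generate_cohort(cfg)


class TestFit:
    def test_paper_scale_recovery(self, fitted):
        coh, sig = fitted
        s = sig.training_summary_
        assert 0.03 <= s["adverse_fraction"] <= 0.08
        assert s["hr"] > 2.0 and s["p"] < 1e-3
        # adverse calls match the planted minority
        agree = (sig.training_labels_ == coh.true_labels).mean()
        assert agree > 0.97

    def test_vei_truth_ranks_high(self):
        rng = np.random.default_rng(11)
        n, d = 600, 3
        lab = rng.random(n) < 0.06
        A = np.array([1.6, 1.0, 0.625])
        lam = np.where(lab, 2.0, 0.5)[:, None]
        X = np.where(lab[:, None], 4.0, 0.0) + rng.normal(size=(n, d)) * np.sqrt(
            lam * A)
        expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(d)],
                            columns=[f"s{i}" for i in range(n)])
        t = np.where(lab, rng.exponential(2, n), rng.exponential(20, n))
        surv = pd.DataFrame({"time": t, "event": 1},
                            index=pd.Index(expr.columns))
        sig = ClusterSignature(random_state=0).fit(
            ExpressionMatrix(expr), SurvivalTable(surv))
        table = {k: v for k, v in sig.bic_table_.items()
                 if isinstance(v, float)}
        top2 = sorted(table, key=table.get, reverse=True)[:2]
        assert "VEI" in top2

    def test_needs_two_genes(self, small_cohort_module):
        coh = small_cohort_module
        one = coh.expression.subset_genes(coh.true_params["signature_genes"][:1])
        with pytest.raises(ValueError, match="at least 2"):
            fit_signature(one, coh.survival)

    def test_identical_hazards_fall_back_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        n = 80
        x = np.concatenate([rng.normal(0, 0.3, n // 2),
                            rng.normal(5, 0.3, n // 2)])
        y = np.concatenate([rng.normal(0, 0.3, n // 2),
                            rng.normal(5, 0.3, n // 2)])
        expr = pd.DataFrame([x, y], index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(n)])
        # identical survival pattern in both clusters -> equal hazard
        times = np.tile(np.arange(1, n // 2 + 1, dtype=float), 2)
        surv = pd.DataFrame({"time": times, "event": 1},
                            index=pd.Index(expr.columns))
        with caplog.at_level(logging.WARNING, logger="clustsig.signature"):
            sig = ClusterSignature(random_state=0).fit(
                ExpressionMatrix(expr), SurvivalTable(surv))
        assert sig.adverse_cluster_ == 1
        assert any("identical observed hazards" in r.message
                   for r in caplog.records)


class TestTransfer:
    def test_training_matrix_predicts_training_labels(self, fitted):
        coh, sig = fitted
        table = apply_signature(sig, coh.expression)
        assert np.array_equal(table["adverse"].to_numpy(),
                              sig.training_labels_.to_numpy())

    def test_equidistant_sample_is_borderline(self, fitted):
        _, sig = fitted
        mid = sig.mixture_.means_.mean(axis=0)
        # force a symmetric model so the midpoint is exactly ambiguous
        sym = ClusterSignature.from_dict(sig.to_dict())
        sym.mixture_.weights_ = np.array([0.5, 0.5])
        sym.mixture_.covariances_ = np.ones_like(sym.mixture_.covariances_)
        expr = pd.DataFrame(mid[:, None], index=sig.genes_, columns=["mid"])
        table = apply_signature(sym, expr)
        assert table.loc["mid", "adverse_posterior"] == pytest.approx(0.5)
        assert bool(table.loc["mid", "borderline"])

    def test_missing_gene_is_reported(self, fitted):
        _, sig = fitted
        expr = pd.DataFrame(np.zeros((1, 3)), index=[sig.genes_[0]],
                            columns=list("abc"))
        with pytest.raises(KeyError, match=sig.genes_[1]):
            apply_signature(sig, expr)

    def test_gene_order_enforced_at_prediction(self, fitted):
        coh, sig = fitted
        shuffled = coh.expression.values.iloc[::-1]
        table = apply_signature(sig, ExpressionMatrix(shuffled))
        ref = apply_signature(sig, coh.expression)
        assert np.array_equal(table["adverse_posterior"].to_numpy(),
                              ref["adverse_posterior"].to_numpy())

    def test_serialization_round_trip_bitwise(self, fitted, tmp_path):
        coh, sig = fitted
        path = tmp_path / "sig.json"
        sig.save_json(path)
        clone = ClusterSignature.load_json(path)
        a = apply_signature(sig, coh.expression)["adverse_posterior"]
        b = apply_signature(clone, coh.expression)["adverse_posterior"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestAdjustedCox:
    def test_empty_covariates_reduce_to_plain_fit(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_.to_numpy(float)
        adj = adjusted_cox(coh.survival, labels)
        plain = fit_cox(coh.survival, labels[:, None])
        assert adj.beta[0] == pytest.approx(plain.beta[0], abs=1e-10)

    def test_irrelevant_covariate_leaves_hr_unchanged(self, fitted, rng):
        coh, sig = fitted
        labels = sig.training_labels_.to_numpy(float)
        noise = pd.DataFrame(
            {"noise": (rng.random(len(labels)) < 0.5).astype(float)},
            index=coh.survival.sample_ids)
        adj = adjusted_cox(coh.survival, labels, noise)
        plain = fit_cox(coh.survival, labels[:, None])
        assert adj.hr[0] == pytest.approx(plain.hr[0], rel=0.15)

    def test_planted_confounder_attenuates_hr(self):
        rng = np.random.default_rng(77)
        n = 800
        cluster = (rng.random(n) < 0.2).astype(float)
        # confounder correlated with cluster and independently hazardous
        conf = np.where(rng.random(n) < 0.7, cluster,
                        (rng.random(n) < 0.2).astype(float))
        hazard = 0.05 * np.exp(0.8 * cluster + 1.2 * conf)
        t = rng.exponential(1 / hazard)
        surv = SurvivalTable(pd.DataFrame(
            {"time": t, "event": 1, "conf": conf},
            index=[f"s{i}" for i in range(n)]))
        unadj = fit_cox(surv, cluster[:, None])
        adj = adjusted_cox(surv, cluster, ["conf"])
        assert adj.hr[0] < unadj.hr[0]

    def test_collinear_covariates_named(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_.to_numpy(float)
        dup = pd.DataFrame({"dup": labels}, index=coh.survival.sample_ids)
        with pytest.raises(CollinearityError):
            adjusted_cox(coh.survival, labels, dup)

    def test_incomplete_cases_dropped(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_.to_numpy(float)
        cov = pd.DataFrame({"age": np.ones(len(labels))},
                           index=coh.survival.sample_ids)
        cov.iloc[:10, 0] = np.nan
        cov.iloc[10:, 0] = np.linspace(40, 80, len(labels) - 10)
        res = adjusted_cox(coh.survival, labels, cov)
        assert len(res.dropped_samples) == 10
        assert res.n == len(labels) - 10


class TestSensitivity:
    def test_empty_drop_is_identity(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_.to_numpy(float)
        out = sensitivity_drop(coh.survival, labels, [])
        assert out["full"].beta[0] == out["reduced"].beta[0]
        assert out["adverse_fraction_full"] == out["adverse_fraction_reduced"]

    def test_dropping_borderline_sample_is_stable(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_
        table = apply_signature(sig, coh.expression)
        # least certain adverse call
        adverse = table[table["adverse"] == 1]
        drop = [adverse["adverse_posterior"].idxmin()]
        out = sensitivity_drop(coh.survival, labels.to_numpy(float), drop)
        ratio = out["reduced"].hr[0] / out["full"].hr[0]
        assert 0.5 < ratio < 2.0

    def test_drop_nonadverse_updates_fraction(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_
        drop = [labels.index[labels == 0][0]]
        out = sensitivity_drop(coh.survival, labels.to_numpy(float), drop)
        n = len(labels)
        assert out["adverse_fraction_reduced"] == pytest.approx(
            labels.sum() / (n - 1))

    def test_dropping_every_adverse_sample_rejected(self, fitted):
        coh, sig = fitted
        labels = sig.training_labels_
        drop = list(labels.index[labels == 1])
        with pytest.raises(ValueError, match="every adverse"):
            sensitivity_drop(coh.survival, labels.to_numpy(float), drop)

    def test_unknown_ids_rejected(self, fitted):
        coh, sig = fitted
        with pytest.raises(KeyError):
            sensitivity_drop(coh.survival,
                             sig.training_labels_.to_numpy(float), ["nope"])
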