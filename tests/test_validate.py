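"""Validation battery: LOO shortcut, through-origin statistics, rm^2,
acceptability conditions, applicability domain."""

import numpy as np
import pytest

from phytoqsar import (
    ConfigurationError,
    QsarDataset,
    SyntheticQsarSpec,
    applicability_domain,
    external_metrics,
    fit_mlr,
    gen_qsar_dataset,
    golbraikh_tropsha_check,
    internal_metrics,
    load_fixture,
    mae_based_verdict,
    regression_through_origin,
    rm2_metrics,
)


def _dataset(X, y, ids=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    return QsarDataset(
        ids=ids or [f"c{i}" for i in range(n)],
        descriptor_names=[f"d{j}" for j in range(m)],
        X=X,
        y=np.asarray(y, dtype=float),
    )


def _brute_force_loo(ds, names):
    """Independent oracle: refit the model n times, each time leaving one out."""
    preds = np.empty(ds.n)
    for i in range(ds.n):
        keep = [j for j in range(ds.n) if j != i]
        sub = QsarDataset(
            ids=[ds.ids[j] for j in keep],
            descriptor_names=list(ds.descriptor_names),
            X=ds.X[keep],
            y=ds.y[keep],
        )
        model = fit_mlr(sub, names)
        preds[i] = model.predict_matrix(ds.descriptor_matrix(names)[[i]])[0]
    return preds


class TestInternalMetrics:
    def test_perfect_fit_statistics(self, planted_noiseless):
        ds, truth = planted_noiseless
        model = fit_mlr(ds, truth["informative"])
        rep = internal_metrics(model, ds)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)
        assert rep.q2_loo == pytest.approx(1.0, abs=1e-10)
        assert rep.see == pytest.approx(0.0, abs=1e-10)
        assert rep.press == pytest.approx(0.0, abs=1e-10)
        assert rep.avg_rm2_loo == pytest.approx(1.0)

    def test_press_shortcut_equals_explicit_refits_tiny(self):
        ds = _dataset([1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        model = fit_mlr(ds)
        rep = internal_metrics(model, ds)
        loo = _brute_force_loo(ds, ds.descriptor_names)
        press_brute = float(np.sum((ds.y - loo) ** 2))
        assert rep.press == pytest.approx(press_brute, abs=1e-10)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_press_shortcut_equals_explicit_refits_random(self, seed):
        ds, truth = gen_qsar_dataset(SyntheticQsarSpec(
            n_compounds=25, m_descriptors=6, k_informative=3,
            true_coefficients=(1.0, -0.5, 2.0), noise_sd=0.3, seed=seed))
        model = fit_mlr(ds, truth["informative"])
        rep = internal_metrics(model, ds)
        loo = _brute_force_loo(ds, truth["informative"])
        assert rep.press == pytest.approx(float(np.sum((ds.y - loo) ** 2)), abs=1e-8)
        sstot = float(np.sum((ds.y - ds.y.mean()) ** 2))
        assert rep.q2_loo == pytest.approx(1.0 - rep.press / sstot, abs=1e-12)

    def test_underdetermined_rejected(self):
        ds = _dataset(np.eye(3)[:, :2], [1.0, 2.0, 3.0])
        model = fit_mlr(_dataset(np.random.default_rng(0).standard_normal((10, 2)),
                                 np.random.default_rng(1).standard_normal(10)))
        with pytest.raises(ConfigurationError):
            internal_metrics(model, ds)


class TestThroughOrigin:
    def test_identity_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r0, r0p, k, kp = regression_through_origin(y, y)
        assert (r0, r0p, k, kp) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_doubled_predictions_scale_slopes(self):
        y = np.array([1.0, 2.0, 3.0])
        _, _, k, kp = regression_through_origin(y, 2.0 * y)
        assert k == pytest.approx(0.5)
        assert kp == pytest.approx(2.0)

    def test_direct_formula_oracle(self):
        y_obs = np.array([1.0, 2.0, 3.0])
        y_pred = np.array([1.1, 1.9, 3.2])
        r0, r0p, k, kp = regression_through_origin(y_obs, y_pred)
        # independent evaluation of the defining sums
        k_o = np.sum(y_obs * y_pred) / np.sum(y_pred**2)
        kp_o = np.sum(y_obs * y_pred) / np.sum(y_obs**2)
        r0_o = 1 - np.sum((y_pred - k_o * y_pred) ** 2) / np.sum((y_pred - y_pred.mean()) ** 2)
        r0p_o = 1 - np.sum((y_obs - kp_o * y_obs) ** 2) / np.sum((y_obs - y_obs.mean()) ** 2)
        assert (r0, r0p, k, kp) == pytest.approx((r0_o, r0p_o, k_o, kp_o), abs=1e-12)

    def test_r0_can_go_negative_without_clamping(self):
        # a terrible "prediction" drives the through-origin coefficient < 0
        y_obs = np.array([1.0, 1.1, 0.9, 10.0])
        y_pred = np.array([5.0, -4.0, 6.0, -5.0])
        r0, r0p, _, _ = regression_through_origin(y_obs, y_pred)
        assert r0 < 0 or r0p < 0

    def test_degenerate_input_rejected(self):
        with pytest.raises(Exception):
            regression_through_origin(np.zeros(3), np.array([1.0, 2.0, 3.0]))


class TestRm2:
    def test_perfect_predictions(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        rm2, rm2p, avg, delta = rm2_metrics(y, y)
        assert (rm2, rm2p, avg, delta) == pytest.approx((1.0, 1.0, 1.0, 0.0))

    def test_formula_oracle(self):
        y_obs = np.array([5.0, 6.0, 7.0, 8.0])
        y_pred = np.array([5.2, 5.9, 7.3, 7.8])
        rm2, rm2p, avg, delta = rm2_metrics(y_obs, y_pred)
        r2 = np.corrcoef(y_obs, y_pred)[0, 1] ** 2
        r0, r0p, _, _ = regression_through_origin(y_obs, y_pred)
        rm2_o = r2 * (1 - np.sqrt(max(r2 - r0, 0)))
        rm2p_o = r2 * (1 - np.sqrt(max(r2 - r0p, 0)))
        assert rm2 == pytest.approx(rm2_o, abs=1e-12)
        assert rm2p == pytest.approx(rm2p_o, abs=1e-12)
        assert avg == pytest.approx((rm2_o + rm2p_o) / 2, abs=1e-12)
        assert delta == pytest.approx(abs(rm2_o - rm2p_o), abs=1e-12)

    def test_scaling_changes_imperfect_fits_only(self):
        y_obs = np.array([5.0, 6.0, 7.0, 8.0])
        y_pred = np.array([5.5, 6.4, 6.9, 8.2])
        unscaled = rm2_metrics(y_obs, y_pred, scale=False)
        scaled = rm2_metrics(y_obs, y_pred, scale=True)
        assert unscaled[0] != pytest.approx(scaled[0])
        perfect = rm2_metrics(y_obs, y_obs, scale=True)
        assert perfect[0] == pytest.approx(1.0)


class TestGolbraikhTropsha:
    PTP1B = dict(q2_loo=0.873, r2_ext=0.867, r0_2=0.862, r0_prime_2=0.814,
                 k=1.001, k_prime=0.998)

    def test_published_ptp1b_metrics_pass_all_criteria(self):
        checks = golbraikh_tropsha_check(self.PTP1B)
        assert len(checks) == 5
        assert all(passed for _, _, _, passed in checks)
        ratio = next(v for name, v, _, _ in checks if name.startswith("III"))
        assert round(ratio, 3) == 0.006

    def test_out_of_range_slope_fails_branch(self):
        vals = dict(self.PTP1B, k=1.2, k_prime=1.2)
        checks = dict((name[:3].strip(":"), passed)
                      for name, _, _, passed in golbraikh_tropsha_check(vals))
        assert not checks["III"]

    def test_large_r0_difference_fails_criterion_iv(self):
        vals = dict(self.PTP1B, r0_prime_2=self.PTP1B["r0_2"] - 0.31)
        checks = {name.split(":")[0]: passed
                  for name, _, _, passed in golbraikh_tropsha_check(vals)}
        assert not checks["IV"]

    def test_missing_field_named_in_error(self):
        with pytest.raises(ConfigurationError, match="k_prime"):
            golbraikh_tropsha_check({k: v for k, v in self.PTP1B.items() if k != "k_prime"})


class TestExternalMetrics:
    def _fitted(self):
        ds, truth = gen_qsar_dataset(SyntheticQsarSpec(
            n_compounds=120, m_descriptors=10, k_informative=3,
            true_coefficients=(1.0, -1.5, 0.5), noise_sd=0.2, seed=13))
        train = ds.select_rows(ds.ids[:90])
        test = ds.select_rows(ds.ids[90:])
        model = fit_mlr(train, truth["informative"])
        return model, train, test

    def test_perfect_predictions_hit_the_ceiling(self, planted_noiseless):
        ds, truth = planted_noiseless
        model = fit_mlr(ds, truth["informative"])
        rep = external_metrics(model, ds, train_mean=float(ds.y.mean()))
        assert rep.r2_ext == pytest.approx(1.0)
        assert rep.q2_f1 == pytest.approx(1.0, abs=1e-10)
        assert rep.q2_f2 == pytest.approx(1.0, abs=1e-10)
        assert rep.rmsep == pytest.approx(0.0, abs=1e-10)
        assert rep.mae_95 == pytest.approx(0.0, abs=1e-10)
        assert rep.mae_verdict == "GOOD"

    def test_trimmed_mae_excludes_gross_outlier(self):
        model, train, test = self._fitted()
        test.y[0] += 50.0  # one gross outlier
        rep = external_metrics(model, test, train_mean=float(train.y.mean()))
        err = np.abs(model.predict_dataset(test) - test.y)
        n_drop = int(np.ceil(0.05 * test.n))
        kept = np.sort(err)[: test.n - n_drop]
        assert rep.mae_95 == pytest.approx(float(kept.mean()), abs=1e-12)
        assert rep.mae_95 < 1.0  # outlier's 50-unit error is out

    def test_small_test_set_flagged_unreliable(self):
        model, train, test = self._fitted()
        tiny = test.select_rows(test.ids[:2])
        rep = external_metrics(model, tiny, train_mean=float(train.y.mean()))
        assert rep.unreliable

    def test_verdict_thresholds(self):
        assert mae_based_verdict(0.1, 0.05, y_range=5.0) == "GOOD"
        assert mae_based_verdict(0.8, 0.2, y_range=5.0) == "BAD"
        assert mae_based_verdict(0.6, 0.1, y_range=5.0) == "MODERATE"


class TestApplicabilityDomain:
    def _study_shaped(self):
        ds, truth = gen_qsar_dataset(SyntheticQsarSpec(
            n_compounds=330, m_descriptors=20, k_informative=8,
            true_coefficients=(1, -1, 2, 0.5, -0.5, 1.5, -2, 0.8),
            noise_sd=0.2, seed=17))
        model = fit_mlr(ds, truth["informative"], autoscale=True)
        return model, ds

    def test_warning_leverage_for_study_shaped_model(self):
        model, ds = self._study_shaped()
        ad = applicability_domain(model, ds)
        assert ad.h_star == pytest.approx(27.0 / 330.0)

    def test_training_leverages_sum_to_p(self):
        model, ds = self._study_shaped()
        ad = applicability_domain(model, ds)
        train = ad.table[ad.table.set == "train"]
        assert train.leverage.sum() == pytest.approx(model.p, abs=1e-8)
        assert (train.leverage >= 0).all() and (train.leverage <= 1).all()

    def test_centroid_query_has_minimal_leverage(self):
        model, ds = self._study_shaped()
        centroid = ds.X[:, [ds.descriptor_names.index(d)
                            for d in model.descriptor_names]].mean(axis=0)
        query = QsarDataset(["centroid"], model.descriptor_names,
                            centroid[None, :], np.array([ds.y.mean()]))
        ad = applicability_domain(model, ds, query)
        h_query = ad.table[ad.table.set == "query"].leverage.iloc[0]
        assert h_query == pytest.approx(1.0 / ds.n, abs=1e-10)

    def test_williams_table_schema_and_export(self, tmp_path):
        model, ds = self._study_shaped()
        ad = applicability_domain(model, ds, ds.select_rows(ds.ids[:5]))
        assert list(ad.table.columns) == ["id", "leverage", "std_residual", "set", "in_domain"]
        out = tmp_path / "williams.tsv"
        ad.write_williams_tsv(out)
        assert out.read_text().startswith("id\tleverage")
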