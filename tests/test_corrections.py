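import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcan import (
    AnalyteMatrix,
    LmmAgeModel,
    ZCorrectionSpec,
    age_tertile_correct,
    apply_lmm_correction,
    fit_lmm_age_model,
    generate_cohort,
    select_vgb_affected,
    validate_metadata,
    zscore_unzscore_correct,
)
from episcan.synthetic_cohort import CohortConfig
from episcan.univariate import bh_adjust

from conftest import make_metadata


def matrix_from(values: np.ndarray, meta: pd.DataFrame, data_type="metabolite") -> AnalyteMatrix:
    sids = list(meta["sample_id"])
    return AnalyteMatrix(
        pd.DataFrame(values, index=[f"a{i}" for i in range(len(values))], columns=sids),
        data_type,
        "log2",
    )


def single_sample_meta(n: int, ages=None, batches=None, vgb=None) -> pd.DataFrame:
    rows = []
    for i in range(n):
        rows.append(
            dict(
                sample_id=f"s{i:03d}",
                subject_id=f"subj{i:03d}",
                age_weeks=float(ages[i]) if ages is not None else 10.0,
                batch=int(batches[i]) if batches is not None else 0,
                vgb=bool(vgb[i]) if vgb is not None else False,
                group="tsc",
                seizure_history=False,
                abnormal_eeg_at_draw=False,
                seizure_at_draw=False,
                drug_resistant_24m=False,
                presymptomatic_vgb=False,
                timepoint_label="t0",
            )
        )
    return validate_metadata(pd.DataFrame(rows))


class TestZUnZ:
    def test_single_group_is_identity(self):
        rng = np.random.default_rng(0)
        meta = single_sample_meta(20)
        m = matrix_from(rng.normal(10, 2, size=(5, 20)), meta)
        out = zscore_unzscore_correct(m, meta, ZCorrectionSpec("batch"))
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-12)

    def test_two_batch_closed_form(self):
        # batches {1,2,3} and {11,12,13}: both batch means move to the global
        # mean 7 and both batch SDs to the global SD
        meta = single_sample_meta(6, batches=[0, 0, 0, 1, 1, 1])
        m = matrix_from(np.array([[1.0, 2, 3, 11, 12, 13]]), meta)
        out = zscore_unzscore_correct(m, meta, ZCorrectionSpec("batch", "mean"))
        arr = out.values.to_numpy()[0]
        gsd = np.std([1, 2, 3, 11, 12, 13])
        assert np.allclose(arr[:3].mean(), 7.0)
        assert np.allclose(arr[3:].mean(), 7.0)
        assert np.allclose(np.std(arr[:3]), gsd)
        assert np.allclose(np.std(arr[3:]), gsd)

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_idempotent_and_rank_preserving(self, center):
        rng = np.random.default_rng(1)
        meta = single_sample_meta(40, batches=rng.integers(0, 3, 40))
        vals = rng.normal(8, 1.5, size=(10, 40))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        m = matrix_from(vals, meta)
        spec = ZCorrectionSpec("batch", center)
        once = zscore_unzscore_correct(m, meta, spec)
        twice = zscore_unzscore_correct(once, meta, spec)
        drift = np.nanmax(np.abs(once.values.to_numpy() - twice.values.to_numpy()))
        if center == "mean":
            assert drift < 1e-9  # exactly idempotent
        else:
            # median centering leaves group means slightly apart, so a second
            # pass is only approximately a no-op
            assert drift < 0.5
        # within-group rank order preserved per analyte
        batches = meta["batch"].to_numpy()
        for b in np.unique(batches):
            cols = batches == b
            for i in range(10):
                x, y = vals[i, cols], once.values.to_numpy()[i, cols]
                obs = ~np.isnan(x)
                assert np.array_equal(
                    np.argsort(np.argsort(x[obs])), np.argsort(np.argsort(y[obs]))
                )

    def test_batch_statistics_match_global_reference(self):
        rng = np.random.default_rng(2)
        batches = rng.integers(0, 4, 60)
        meta = single_sample_meta(60, batches=batches)
        vals = rng.normal(10, 2, size=(8, 60)) + batches[None, :] * 0.8
        m = matrix_from(vals, meta)
        out = zscore_unzscore_correct(m, meta, ZCorrectionSpec("batch", "mean"))
        arr = out.values.to_numpy()
        gmean, gsd = vals.mean(axis=1), vals.std(axis=1)
        for b in np.unique(batches):
            cols = batches == b
            assert np.allclose(arr[:, cols].mean(axis=1), gmean, atol=1e-9)
            assert np.allclose(arr[:, cols].std(axis=1), gsd, atol=1e-9)

    def test_constant_group_passes_through(self):
        meta = single_sample_meta(6, batches=[0, 0, 0, 1, 1, 1])
        m = matrix_from(np.array([[5.0, 5, 5, 1, 2, 3]]), meta)
        out = zscore_unzscore_correct(m, meta, ZCorrectionSpec("batch"))
        assert np.allclose(out.values.to_numpy()[0, :3], 5.0)

    def test_removes_planted_batch_separation(self):
        """After correction, batches are no longer separable (silhouette < 0.1)."""
        from sklearn.decomposition import PCA
        from sklearn.metrics import silhouette_score

        cfg = CohortConfig(n_analytes={"metabolite": 40}, batch_sd=1.0, vgb_effect_spec=[],
                           missingness_spec={})
        mats, meta, _ = generate_cohort(cfg, seed=12)
        m = mats["metabolite"]
        batches = meta.loc[m.sample_ids, "batch"].to_numpy()

        def silhouette(matrix):
            pcs = PCA(n_components=2).fit_transform(matrix.values.to_numpy().T)
            return silhouette_score(pcs, batches)

        assert silhouette(m) > 0.1  # planted offsets are visible
        corrected = zscore_unzscore_correct(m, meta, ZCorrectionSpec("batch"))
        assert silhouette(corrected) < 0.1


class TestVgbSelection:
    def test_planted_52_fold_detected(self):
        cfg = CohortConfig(
            n_analytes={"metabolite": 30},
            age_effect_fraction={"metabolite": 0.0},
            vgb_effect_spec=[("MET00001", 52.0)],
            missingness_spec={},
            noise_sd=0.3,
        )
        mats, meta, _ = generate_cohort(cfg, seed=13)
        hits = select_vgb_affected(mats["metabolite"], meta)
        assert hits == ["MET00001"]

    def test_null_rarely_selects(self):
        n_hits = 0
        for seed in range(10):
            cfg = CohortConfig(
                n_analytes={"metabolite": 100},
                age_effect_fraction={"metabolite": 0.0},
                vgb_effect_spec=[],
                missingness_spec={},
            )
            mats, meta, _ = generate_cohort(cfg, seed=200 + seed)
            n_hits += len(select_vgb_affected(mats["metabolite"], meta))
        assert n_hits <= 2

    def test_matches_brute_force_recomputation(self):
        cfg = CohortConfig(
            n_analytes={"metabolite": 25},
            age_effect_fraction={"metabolite": 0.0},
            vgb_effect_spec=[(f"MET{i + 1:05d}", f) for i, f in enumerate(
                np.geomspace(1.5, 52.0, 12))],
            missingness_spec={},
        )
        mats, meta, _ = generate_cohort(cfg, seed=14)
        m = mats["metabolite"]
        hits = select_vgb_affected(m, meta, min_age_weeks=40, fdr=0.05)
        rows = meta.loc[m.sample_ids]
        old = rows["age_weeks"].to_numpy(float) > 40
        vgb = rows["vgb"].to_numpy(bool)
        pvals = []
        for a in m.analyte_ids:
            v = m.values.loc[a].to_numpy(float)
            pvals.append(stats.mannwhitneyu(v[old & vgb], v[old & ~vgb],
                                            alternative="two-sided").pvalue)
        adj = bh_adjust(np.array(pvals))
        expected = sorted(np.array(m.analyte_ids)[adj < 0.05])
        assert hits == expected

    def test_empty_group_rejected(self):
        meta = single_sample_meta(10, ages=[50.0] * 10, vgb=[False] * 10)
        m = matrix_from(np.random.default_rng(0).normal(size=(3, 10)), meta)
        with pytest.raises(ValueError, match="empty"):
            select_vgb_affected(m, meta)


def lmm_meta(n_subj: int, ages_per_subj) -> pd.DataFrame:
    rows = []
    for i in range(n_subj):
        for j, age in enumerate(ages_per_subj[i]):
            rows.append(
                dict(
                    sample_id=f"S{i:03d}_t{j}",
                    subject_id=f"S{i:03d}",
                    age_weeks=float(age),
                    batch=0,
                    vgb=False,
                    group="tsc",
                    seizure_history=False,
                    abnormal_eeg_at_draw=False,
                    seizure_at_draw=False,
                    drug_resistant_24m=False,
                    presymptomatic_vgb=False,
                    timepoint_label=f"t{j}",
                )
            )
    return validate_metadata(pd.DataFrame(rows))


class TestLmm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(21)
        n = 80
        meta = lmm_meta(n, [[4.0, 26.0, 104.0]] * n)
        ages = meta["age_weeks"].to_numpy()
        subj_idx = np.repeat(np.arange(n), 3)
        b = rng.normal(0, 0.5, n)
        y = 10 + 0.05 * ages + b[subj_idx] + rng.normal(0, 0.2, 3 * n)
        m = AnalyteMatrix(
            pd.DataFrame([y], index=["a0"], columns=list(meta["sample_id"])), "protein", "log2"
        )
        model = fit_lmm_age_model(m, meta)
        assert model.params.loc["a0", "converged"]
        assert model.params.loc["a0", "slope_per_week"] == pytest.approx(0.05, rel=0.10)
        assert model.random_intercepts.loc["a0"].std() == pytest.approx(0.5, rel=0.25)
        # random intercepts centre on zero
        assert abs(model.random_intercepts.loc["a0"].mean()) < 0.05

    def test_noiseless_null_gives_zeros(self):
        n = 10
        meta = lmm_meta(n, [[4.0, 26.0, 104.0]] * n)
        y = np.full(3 * n, 7.5)
        m = AnalyteMatrix(
            pd.DataFrame([y], index=["a0"], columns=list(meta["sample_id"])), "protein", "log2"
        )
        model = fit_lmm_age_model(m, meta)
        assert abs(model.params.loc["a0", "slope_per_week"]) < 1e-8
        assert np.abs(model.random_intercepts.loc["a0"].to_numpy()).max() < 1e-6

    def test_single_sample_subjects_reduce_to_ols(self):
        rng = np.random.default_rng(22)
        n = 60
        ages = rng.uniform(0, 104, n)
        meta = lmm_meta(n, [[a] for a in ages])
        y = 5 + 0.03 * ages + rng.normal(0, 0.4, n)
        m = AnalyteMatrix(
            pd.DataFrame([y], index=["a0"], columns=list(meta["sample_id"])), "protein", "log2"
        )
        model = fit_lmm_age_model(m, meta)
        ols_slope = np.polyfit(ages, y, 1)[0]
        assert model.params.loc["a0", "slope_per_week"] == pytest.approx(ols_slope, abs=1e-6)
        # predicted intercepts are shrunk: never larger than the raw residual
        fitted = (
            model.params.loc["a0", "intercept"]
            + model.params.loc["a0", "slope_per_week"] * ages
        )
        resid = y - fitted
        b = model.random_intercepts.loc["a0", meta["subject_id"]].to_numpy()
        assert np.all(np.abs(b) <= np.abs(resid) + 1e-8)
        assert abs(b.mean()) < 0.1

    def test_noiseless_linear_correction_is_exact(self):
        n = 12
        meta = lmm_meta(n, [[4.0, 26.0, 104.0]] * n)
        ages = meta["age_weeks"].to_numpy()
        y = 3.0 + 0.08 * ages
        m = AnalyteMatrix(
            pd.DataFrame([y], index=["a0"], columns=list(meta["sample_id"])), "protein", "log2"
        )
        model = fit_lmm_age_model(m, meta)
        corrected = apply_lmm_correction(m, meta, model)
        out = corrected.values.to_numpy()[0]
        assert np.ptp(out) < 1e-6  # constant
        assert abs(np.polyfit(ages, out, 1)[0]) < 1e-6

    def test_hand_computed_correction(self):
        # given a = 2 and subject intercepts {-1, 0, 1}, the correction is
        # pure arithmetic: corrected = value - 2 * age - b[subject]
        meta = lmm_meta(3, [[1.0, 2.0], [1.0, 3.0], [2.0, 4.0]])
        vals = np.array([[10.0, 12.0, 7.0, 11.0, 9.0, 13.0]])
        m = AnalyteMatrix(
            pd.DataFrame(vals, index=["a0"], columns=list(meta["sample_id"])), "protein", "log2"
        )
        params = pd.DataFrame(
            dict(slope_per_week=[2.0], intercept=[0.0], resid_var=[1.0], converged=[True]),
            index=pd.Index(["a0"], name="analyte_id"),
        )
        b = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["a0"], columns=["S000", "S001", "S002"])
        model = LmmAgeModel(params=params, random_intercepts=b)
        out = apply_lmm_correction(m, meta, model).values.to_numpy()[0]
        expected = [10 - 2 * 1 + 1, 12 - 2 * 2 + 1, 7 - 2 * 1, 11 - 2 * 3, 9 - 2 * 2 - 1, 13 - 2 * 4 - 1]
        assert np.allclose(out, expected)

    def test_unknown_subject_rejected(self):
        meta = lmm_meta(2, [[1.0, 2.0], [1.0, 2.0]])
        vals = np.zeros((1, 4))
        m = AnalyteMatrix(
            pd.DataFrame(vals, index=["a0"], columns=list(meta["sample_id"])), "protein", "log2"
        )
        params = pd.DataFrame(
            dict(slope_per_week=[1.0], intercept=[0.0], resid_var=[1.0], converged=[True]),
            index=pd.Index(["a0"], name="analyte_id"),
        )
        b = pd.DataFrame([[0.0]], index=["a0"], columns=["OTHER"])
        with pytest.raises(KeyError):
            apply_lmm_correction(m, meta, LmmAgeModel(params=params, random_intercepts=b))

    def test_age_trend_removed_on_cohort(self):
        """Post-correction rank correlation with age collapses for linear trends."""
        cfg = CohortConfig(
            n_analytes={"protein": 20},
            age_effect_fraction={"protein": 1.0},
            missingness_spec={},
        )
        mats, meta, truth = generate_cohort(cfg, seed=23)
        m = mats["protein"]
        model = fit_lmm_age_model(m, meta)
        corrected = apply_lmm_correction(m, meta, model)
        ages = meta.loc[corrected.sample_ids, "age_weeks"].to_numpy()
        linear = [a for a, arch in truth.age_archetype.items()
                  if arch in ("monotone_up", "monotone_down") and a in corrected.values.index]
        ok = 0
        for a in linear:
            rho = stats.spearmanr(ages, corrected.values.loc[a].to_numpy()).statistic
            ok += abs(rho) < 0.25
        assert ok / len(linear) >= 0.9


class TestAgeTertileCorrection:
    def test_single_tertile_is_identity(self):
        meta = single_sample_meta(15, ages=np.linspace(0, 9, 15))
        rng = np.random.default_rng(5)
        m = matrix_from(rng.normal(size=(4, 15)), meta)
        out = age_tertile_correct(m, meta)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-12)

    def test_monotone_trend_equalized_across_tertiles(self):
        ages = np.concatenate([np.linspace(1, 9, 10), np.linspace(12, 38, 10), np.linspace(45, 100, 10)])
        meta = single_sample_meta(30, ages=ages)
        rng = np.random.default_rng(6)
        vals = 0.05 * ages[None, :] + rng.normal(0, 0.1, size=(5, 30))
        m = matrix_from(vals, meta)
        out = age_tertile_correct(m, meta)
        arr = out.values.to_numpy()
        for i in range(5):
            t_means = [arr[i, :10].mean(), arr[i, 10:20].mean(), arr[i, 20:].mean()]
            assert np.ptp(t_means) < 1e-9
        # a strongly increasing analyte flattens: post-correction tertile
        # medians are far closer together than the raw ones
        raw_medians = [np.median(vals[0, :10]), np.median(vals[0, 10:20]), np.median(vals[0, 20:])]
        t_medians = [np.median(arr[0, :10]), np.median(arr[0, 10:20]), np.median(arr[0, 20:])]
        assert np.ptp(t_medians) < 0.25 * np.ptp(raw_medians)
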