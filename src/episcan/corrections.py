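"""Confound corrections: batch, vigabatrin, and age.

Three nuisance effects are removed before association testing, in a fixed
order: batch -> vigabatrin -> age.

Batch and vigabatrin corrections use the Z-score / un-Z-score method: within
each confound group an analyte is standardized by the group's center and SD,
then rescaled by the center and SD of *all* samples computed before the
correction.  Group-level distributional differences are equalized while the
analyte keeps its overall scale; within-group rank order is preserved and the
operation is idempotent.

Age is corrected by two independent methods whose outputs are both retained
downstream: (1) the same Z/un-Z scheme within fixed postnatal-age strata
(0-10, 11-40, >40 weeks), and (2) a linear mixed model with a fixed slope per
week of age and a random intercept per subject, fitted by REML; the corrected
value subtracts the fitted age term and the subject's predicted random
intercept (the global intercept is deliberately left in, so corrected values
stay on the original scale).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalyteMatrix, assign_age_tertile
from .univariate import bh_adjust

log = logging.getLogger(__name__)

_MIN_SD = 1e-12


@dataclass
class ZCorrectionSpec:
    """Grouping and statistics for a Z/un-Z correction pass."""

    grouping: str  # "batch", "vgb", or "age_tertile"
    center_stat: str = "mean"  # "mean" or "median"

    def __post_init__(self) -> None:
        if self.grouping not in ("batch", "vgb", "age_tertile"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.center_stat not in ("mean", "median"):
            raise ValueError(f"unknown center_stat {self.center_stat!r}")

    def groups_for(self, meta: pd.DataFrame, sample_ids: list[str]) -> pd.Series:
        rows = meta.loc[sample_ids]
        if self.grouping == "batch":
            return rows["batch"].astype(int)
        if self.grouping == "vgb":
            return rows["vgb"].astype(bool)
        return assign_age_tertile(rows["age_weeks"])


def _center(values: np.ndarray, stat: str, axis: int = -1) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "mean":
            return np.nanmean(values, axis=axis)
        return np.nanmedian(values, axis=axis)


def _sd(values: np.ndarray, axis: int = -1) -> np.ndarray:
    # population SD: with ddof=0 the group-wise standardize/rescale composes
    # exactly (global variance = weighted mean of group variances once group
    # centers agree), making the correction idempotent to round-off
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(values, axis=axis, ddof=0)


def zscore_unzscore_correct(
    matrix: AnalyteMatrix,
    meta: pd.DataFrame,
    spec: ZCorrectionSpec,
    analyte_ids: list[str] | None = None,
) -> AnalyteMatrix:
    """Standardize within confound groups, rescale by global statistics.

    Per analyte: values in group g become
    ``(x - c_g) / s_g * s_all + c_all`` where (c, s) are the configured center
    statistic and the sample SD, and (c_all, s_all) are computed over all
    samples before correction.  Missing values are ignored in the statistics
    and stay masked.  An analyte/group combination with fewer than two
    non-missing values or SD below 1e-12 passes through unchanged (logged).
    ``analyte_ids`` restricts the correction to a subset of analytes.
    """
    values = matrix.values.copy()
    groups = spec.groups_for(meta, matrix.sample_ids)
    rows = values.index if analyte_ids is None else pd.Index(analyte_ids)
    unknown = rows.difference(values.index)
    if len(unknown):
        raise KeyError(f"analytes not in matrix: {list(unknown)[:5]}")

    sub = values.loc[rows].to_numpy(float)
    global_center = _center(sub, spec.center_stat)
    global_sd = _sd(sub)
    corrected = sub.copy()
    for g in pd.unique(groups):
        cols = (groups == g).to_numpy()
        block = sub[:, cols]
        n_obs = np.sum(~np.isnan(block), axis=1)
        c = _center(block, spec.center_stat)
        s = _sd(block)
        ok = (n_obs >= 2) & (s > _MIN_SD) & (global_sd > _MIN_SD)
        n_skip = int((~ok).sum())
        if n_skip:
            log.warning(
                "%s correction: %d analyte/group combinations constant or too "
                "sparse in group %r; passed through unchanged",
                spec.grouping,
                n_skip,
                g,
            )
        z = (block[ok] - c[ok, None]) / s[ok, None]
        out = np.zeros_like(block)
        out[:] = block
        out[ok] = z * global_sd[ok, None] + global_center[ok, None]
        corrected[:, cols] = out
    result = values.copy()
    result.loc[rows] = corrected
    return matrix.copy_with(result)


def select_vgb_affected(
    matrix: AnalyteMatrix,
    meta: pd.DataFrame,
    min_age_weeks: float = 40.0,
    fdr: float = 0.05,
) -> list[str]:
    """Analytes significantly different between drug-exposed and unexposed.

    Restricted to samples above ``min_age_weeks`` (where developmental effects
    are minimal), each analyte is tested with a two-sided Wilcoxon rank-sum
    test, p-values are Benjamini-Hochberg adjusted across analytes, and the
    analytes with adjusted p below ``fdr`` are returned (sorted).  Only these
    should be passed to the vigabatrin Z/un-Z correction.
    """
    rows = meta.loc[matrix.sample_ids]
    old = rows["age_weeks"].to_numpy(float) > min_age_weeks
    vgb = rows["vgb"].to_numpy(bool)
    on = old & vgb
    off = old & ~vgb
    if on.sum() == 0 or off.sum() == 0:
        raise ValueError("one exposure group is empty above the age cutoff")
    arr = matrix.values.to_numpy(float)
    pvals = np.ones(arr.shape[0])
    for i in range(arr.shape[0]):
        x = arr[i, on]
        y = arr[i, off]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2 or (np.ptp(np.concatenate([x, y])) == 0):
            continue
        pvals[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    adj = bh_adjust(pvals)
    hits = [matrix.analyte_ids[i] for i in np.nonzero(adj < fdr)[0]]
    return sorted(hits)


@dataclass
class LmmAgeModel:
    """Per-analyte random-intercept age models.

    ``params`` has one row per analyte with the fixed slope per week of age,
    the global intercept, the residual variance and a convergence flag;
    ``random_intercepts`` is analyte x subject with each subject's predicted
    (shrunk) intercept.
    """

    params: pd.DataFrame
    random_intercepts: pd.DataFrame

    def converged_analytes(self) -> list[str]:
        return list(self.params.index[self.params["converged"]])


def fit_lmm_age_model(matrix: AnalyteMatrix, meta: pd.DataFrame) -> LmmAgeModel:
    """Fit ``value ~ age_weeks + (1 | subject)`` per analyte by REML.

    Subjects with a single sample receive shrunk intercept predictions from
    the fitted model.  Analytes whose fit does not converge are flagged and
    later excluded from the corrected output.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    rows = meta.loc[matrix.sample_ids]
    ages = rows["age_weeks"].to_numpy(float)
    subjects = rows["subject_id"].to_numpy()
    uniq_subjects = pd.unique(subjects)
    if len(uniq_subjects) < 2:
        raise ValueError("need at least 2 subjects to fit a mixed model")

    records = []
    intercepts = pd.DataFrame(
        np.nan, index=matrix.values.index, columns=pd.Index(uniq_subjects, name="subject_id")
    )
    exog = np.column_stack([np.ones_like(ages), ages])
    for analyte in matrix.values.index:
        y = matrix.values.loc[analyte].to_numpy(float)
        obs = ~np.isnan(y)
        converged = False
        slope = intercept = resid_var = np.nan
        re_vals: dict = {}
        ols = None
        if obs.sum() >= 3 and np.ptp(ages[obs]) > 0:
            ols, ols_resid, *_ = np.linalg.lstsq(exog[obs], y[obs], rcond=None)
        if ols is not None and np.abs(y[obs] - exog[obs] @ ols).max() < 1e-10:
            # constant or exactly linear analyte: REML is degenerate (zero
            # residual variance) but the exact solution is the OLS line with
            # zero random effects
            converged = True
            intercept, slope = float(ols[0]), float(ols[1])
            resid_var = 0.0
            re_vals = {g: 0.0 for g in pd.unique(subjects[obs])}
        elif ols is not None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    model = sm.MixedLM(y[obs], exog[obs], groups=subjects[obs])
                    fit = model.fit(reml=True, maxiter=200)
                converged = bool(fit.converged)
                intercept, slope = float(fit.fe_params[0]), float(fit.fe_params[1])
                resid_var = float(fit.scale)
                re_vals = {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
            except Exception as exc:  # singular fits on degenerate analytes
                log.warning("LMM fit failed for %s: %s", analyte, exc)
        if not converged:
            log.warning("LMM did not converge for analyte %s; excluded from correction", analyte)
        records.append(
            dict(
                analyte_id=analyte,
                slope_per_week=slope,
                intercept=intercept,
                resid_var=resid_var,
                converged=converged,
            )
        )
        for subj, val in re_vals.items():
            intercepts.loc[analyte, subj] = val
    params = pd.DataFrame(records).set_index("analyte_id")
    return LmmAgeModel(params=params, random_intercepts=intercepts)


def apply_lmm_correction(
    matrix: AnalyteMatrix, meta: pd.DataFrame, model: LmmAgeModel
) -> AnalyteMatrix:
    """Subtract the fitted age term and subject intercept from each value.

    ``corrected = value - age * slope - subject_intercept``.  Analytes whose
    model did not converge are dropped from the output.  A sample whose
    subject has no fitted intercept for a converged analyte raises.
    """
    keep = model.converged_analytes()
    keep = [a for a in keep if a in matrix.values.index]
    rows = meta.loc[matrix.sample_ids]
    ages = rows["age_weeks"].to_numpy(float)
    subjects = rows["subject_id"].to_numpy()
    missing_subj = set(subjects) - set(model.random_intercepts.columns)
    if missing_subj:
        raise KeyError(f"no fitted intercept for subjects: {sorted(missing_subj)[:5]}")

    values = matrix.values.loc[keep].copy()
    slopes = model.params.loc[keep, "slope_per_week"].to_numpy(float)
    b = model.random_intercepts.loc[keep, subjects].to_numpy(float)
    b = np.nan_to_num(b)  # subjects unseen for an analyte: shrink fully to 0
    corrected = values.to_numpy(float) - slopes[:, None] * ages[None, :] - b
    return matrix.copy_with(pd.DataFrame(corrected, index=values.index, columns=values.columns))


def age_tertile_correct(
    matrix: AnalyteMatrix, meta: pd.DataFrame, center_stat: str = "mean"
) -> AnalyteMatrix:
    """Z/un-Z age correction within the fixed 0-10 / 11-40 / >40 week strata."""
    spec = ZCorrectionSpec(grouping="age_tertile", center_stat=center_stat)
    return zscore_unzscore_correct(matrix, meta, spec)


def correct_pipeline(
    matrices: dict[str, AnalyteMatrix],
    meta: pd.DataFrame,
    age_method: str = "both",
    center_stat: str = "mean",
    vgb_fdr: float = 0.05,
) -> dict[str, dict[str, AnalyteMatrix]]:
    """Run the full correction chain: batch -> vigabatrin -> age.

    Batch and drug corrections apply to metabolites only (the data types where
    those confounds arise); age correction applies to all continuous types.
    Returns ``{age_method: {data_type: corrected matrix}}`` with age methods
    ``"lmm"`` and/or ``"tertile"``.
    """
    if age_method not in ("lmm", "tertile", "both"):
        raise ValueError(f"unknown age_method {age_method!r}")
    staged: dict[str, AnalyteMatrix] = {}
    for data_type, m in matrices.items():
        if data_type == "metabolite":
            m = zscore_unzscore_correct(m, meta, ZCorrectionSpec("batch", center_stat))
            affected = select_vgb_affected(m, meta, fdr=vgb_fdr)
            if affected:
                m = zscore_unzscore_correct(
                    m, meta, ZCorrectionSpec("vgb", center_stat), analyte_ids=affected
                )
        staged[data_type] = m

    out: dict[str, dict[str, AnalyteMatrix]] = {}
    methods = ["lmm", "tertile"] if age_method == "both" else [age_method]
    for method in methods:
        out[method] = {}
        for data_type, m in staged.items():
            if m.scale == "categorical":
                out[method][data_type] = m
                continue
            if method == "tertile":
                out[method][data_type] = age_tertile_correct(m, meta, center_stat)
            else:
                model = fit_lmm_age_model(m, meta)
                out[method][data_type] = apply_lmm_correction(m, meta, model)
    return out
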