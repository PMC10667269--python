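"""Univariate association framework.

Two-group comparisons are assumption-gated: if both groups pass a
Shapiro-Wilk normality check and an F-test of variance homogeneity (all at
the 0.05 gate), a two-sided t-test is used; otherwise a two-sided Wilcoxon
rank-sum test.  Three-group comparisons use Kruskal-Wallis with Dunn's
post-hoc z-tests (tie-corrected, Benjamini-Hochberg across the three pairs).
P-values are BH-adjusted within each comparison, and an analyte is called
significant only when adjusted p < 0.05 AND the median fold change between
groups exceeds 1.5.  Because the age correction is run by two independent
methods, the conservative final call is the intersection of the analytes
significant under each method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalyteMatrix

MISSINGNESS_THRESHOLDS = {"protein": 0.7, "metabolite": 0.5, "rna": 0.5, "mirna": 0.5}

COMPARISONS = ("I", "II", "III", "IV", "Va", "Vb")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def filter_missingness(matrix: AnalyteMatrix, threshold: float | None = None) -> AnalyteMatrix:
    """Drop analytes observed (non-missing AND non-zero) in too few samples.

    Default thresholds by data type: 0.7 for protein, 0.5 for metabolite, RNA
    and miRNA.  Zero values count as unobserved even when unmasked.
    """
    if matrix.values.shape[1] == 0 or matrix.values.shape[0] == 0:
        raise ValueError("empty matrix")
    if threshold is None:
        threshold = MISSINGNESS_THRESHOLDS.get(matrix.data_type, 0.5)
    arr = matrix.values.to_numpy(float)
    seen = (~np.isnan(arr)) & (arr != 0.0)
    frac = seen.mean(axis=1)
    keep = matrix.values.index[frac >= threshold - 1e-12]
    return matrix.copy_with(matrix.values.loc[keep])


def median_fold_change(x, y, scale: str = "log2") -> tuple[float, str]:
    """Median fold change of group x over group y.

    log2-scale data: ``2 ** (median(x) - median(y))``; linear: ratio of
    medians (NaN-flagged when the denominator is 0).  Direction is "up" when
    the fold exceeds 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("groups must be non-empty")
    if scale == "log2":
        fold = float(2.0 ** (np.median(x) - np.median(y)))
    elif scale == "linear":
        my = np.median(y)
        fold = float(np.median(x) / my) if my != 0 else float("nan")
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return fold, ("up" if fold > 1.0 else "down")


@dataclass
class TwoGroupResult:
    test_used: str  # "t" or "wilcoxon"
    pvalue: float
    fold: float
    direction: str
    n1: int
    n2: int
    shapiro_p: tuple
    ftest_p: float


def _f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test of equal variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        return 0.0
    f = vx / vy
    cdf = stats.f.cdf(f, len(x) - 1, len(y) - 1)
    return float(2 * min(cdf, 1 - cdf))


def two_group_test(x, y, alpha_gate: float = 0.05, scale: str = "log2") -> TwoGroupResult:
    """Assumption-gated two-group test (see module docstring)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    fold, direction = median_fold_change(x, y, scale=scale)
    use_t = False
    sw = (np.nan, np.nan)
    fp = np.nan
    if len(x) >= 3 and len(y) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = (stats.shapiro(x).pvalue, stats.shapiro(y).pvalue)
        fp = _f_test(x, y)
        use_t = sw[0] > alpha_gate and sw[1] > alpha_gate and fp > alpha_gate
    if use_t:
        p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        test = "t"
    else:
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        test = "wilcoxon"
    return TwoGroupResult(test, p, fold, direction, len(x), len(y), sw, fp)


def dunn_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    Returns one row per group pair with the z statistic, raw two-sided p, and
    the BH-adjusted p across the pairs.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            var = (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (
                1.0 / sizes[i] + 1.0 / sizes[j]
            )
            if var <= 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
                p = float(2 * stats.norm.sf(abs(z)))
            rows.append(dict(group_a=i, group_b=j, z=float(z), pvalue=p))
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["pvalue"].to_numpy())
    return df


@dataclass
class ThreeGroupResult:
    kw_stat: float
    pvalue: float
    dunn: pd.DataFrame | None
    folds: dict  # (i, j) -> fold of group i over group j
    n: tuple


def three_group_test(
    groups: list, scale: str = "log2", dunn_alpha: float = 0.05, fold_min: float = 1.5
) -> ThreeGroupResult:
    """Kruskal-Wallis over three groups with Dunn's post-hoc on significance.

    A pair is flagged in the post-hoc table only when its BH-adjusted Dunn p
    is below ``dunn_alpha`` and the pairwise median fold change exceeds
    ``fold_min`` in either direction.
    """
    clean = []
    for g in groups:
        g = np.asarray(g, float)
        g = g[~np.isnan(g)]
        if len(g) < 2:
            raise ValueError("each group needs at least 2 non-missing values")
        clean.append(g)
    if len(clean) != 3:
        raise ValueError("exactly three groups expected")
    folds = {}
    for i in range(3):
        for j in range(3):
            if i != j:
                folds[(i, j)] = median_fold_change(clean[i], clean[j], scale=scale)[0]
    if np.ptp(np.concatenate(clean)) == 0:
        return ThreeGroupResult(0.0, 1.0, None, folds, tuple(len(g) for g in clean))
    stat, p = stats.kruskal(*clean)
    dunn = None
    if p < dunn_alpha:
        dunn = dunn_posthoc(clean)
        sig = []
        for _, row in dunn.iterrows():
            f = folds[(int(row["group_a"]), int(row["group_b"]))]
            big_fold = max(f, 1.0 / f) > fold_min
            sig.append(bool(row["p_adj"] < dunn_alpha and big_fold))
        dunn["significant"] = sig
    return ThreeGroupResult(float(stat), float(p), dunn, folds, tuple(len(g) for g in clean))


def dual_method_intersect(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Analytes significant under BOTH age-correction methods.

    Inputs are per-analyte result tables (indexed by analyte id) carrying a
    boolean ``significant`` column over the same analyte universe.
    """
    if set(results_a.index) != set(results_b.index):
        raise ValueError("result sets cover different analyte universes")
    both = results_a["significant"] & results_b.loc[results_a.index, "significant"]
    return results_a.loc[both].copy()


def hypergeom_enrich(
    hit_set: set, pathway_sets: dict[str, set], universe: set
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a hit set in named pathways.

    Pathways are intersected with the universe first; p-values are BH-adjusted
    across pathways.
    """
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_set)
    if not hits <= set(universe):
        raise ValueError("hit_set must be a subset of the universe")
    M, n_draw = len(universe), len(hits)
    rows = []
    for name, members in pathway_sets.items():
        members = set(members) & set(universe)
        overlap = len(members & hits)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(members), n_draw))
        rows.append(dict(pathway=name, size=len(members), overlap=overlap, pvalue=p))
    df = pd.DataFrame(rows).set_index("pathway")
    df["p_adj"] = bh_adjust(df["pvalue"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Clinical comparisons


def comparison_groups(
    comparison: str, meta: pd.DataFrame, stringency: str = "strict"
) -> dict[str, list[str]]:
    """Sample-group membership for the named clinical comparison.

    I    TSC (untreated, no seizure history at draw, any age) vs control.
    II   samples at/after first seizure vs samples from seizure-free subjects.
    III  abnormal epileptiform EEG at draw vs normal EEG (affected subjects).
    IV   24-month samples: drug-resistant epilepsy vs seizure-free/controlled.
    Va   24-month samples: seizure history vs none vs none-but-presymptomatic.
    Vb   enrollment samples: control vs TSC-no-epilepsy vs TSC-epilepsy;
         "strict" drops presymptomatically treated subjects from the
         no-epilepsy group and subjects with abnormal EEG at enrollment from
         both affected groups.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    m = meta
    tsc = m["group"] == "tsc"
    ctl = m["group"] == "control"
    seiz_hist = m["seizure_history"].astype(bool)
    presympt = m["presymptomatic_vgb"].astype(bool)
    at_draw = m["seizure_at_draw"].astype(bool)
    before = (
        m["seizure_before_draw"].astype(bool) if "seizure_before_draw" in m.columns else at_draw
    )
    eeg = m["abnormal_eeg_at_draw"].astype(bool)
    m24 = m["timepoint_label"] == "m24"
    enroll = m["timepoint_label"] == "enrollment"

    def ids(mask) -> list[str]:
        return list(m.loc[mask, "sample_id"])

    if comparison == "I":
        groups = {
            "tsc": ids(tsc & ~m["vgb"].astype(bool) & ~before),
            "control": ids(ctl),
        }
    elif comparison == "II":
        groups = {"seizure": ids(tsc & at_draw), "no_seizure": ids(tsc & ~seiz_hist)}
    elif comparison == "III":
        groups = {"abnormal_eeg": ids(tsc & eeg & ~at_draw), "normal_eeg": ids(tsc & ~eeg)}
    elif comparison == "IV":
        groups = {
            "drug_resistant": ids(tsc & m24 & m["drug_resistant_24m"].astype(bool)),
            "controlled": ids(tsc & m24 & ~m["drug_resistant_24m"].astype(bool)),
        }
    elif comparison == "Va":
        groups = {
            "seizure_history": ids(tsc & m24 & seiz_hist),
            "no_seizure": ids(tsc & m24 & ~seiz_hist & ~presympt),
            "no_seizure_presympt": ids(tsc & m24 & ~seiz_hist & presympt),
        }
    else:  # Vb
        if stringency not in ("strict", "relaxed"):
            raise ValueError(f"unknown stringency {stringency!r}")
        no_epi = tsc & enroll & ~seiz_hist
        epi = tsc & enroll & seiz_hist & ~at_draw
        if stringency == "strict":
            no_epi = no_epi & ~presympt & ~eeg
            epi = epi & ~eeg
        groups = {"control": ids(ctl), "tsc_no_epilepsy": ids(no_epi), "tsc_epilepsy": ids(epi)}
    for name, members in groups.items():
        if not members:
            raise ValueError(f"comparison {comparison}: group {name!r} is empty")
    return groups


def _test_matrix(
    matrix: AnalyteMatrix, groups: dict[str, list[str]], fold_min: float, fdr: float
) -> pd.DataFrame:
    """Run the two- or three-group test for every analyte of one matrix."""
    names = list(groups)
    cols = {name: [s for s in groups[name] if s in matrix.values.columns] for name in names}
    rows = []
    for analyte in matrix.values.index:
        vec = matrix.values.loc[analyte]
        vals = [vec[cols[name]].to_numpy(float) for name in names]
        vals = [v[~np.isnan(v)] for v in vals]
        if any(len(v) < 2 for v in vals):
            continue
        if len(names) == 2:
            try:
                res = two_group_test(vals[0], vals[1], scale=matrix.scale)
            except ValueError:
                continue
            fold = res.fold
            rows.append(
                dict(
                    analyte_id=analyte,
                    test=res.test_used,
                    pvalue=res.pvalue,
                    fold=fold,
                    max_fold=max(fold, 1.0 / fold) if fold > 0 else np.nan,
                )
            )
        else:
            res = three_group_test(vals, scale=matrix.scale, fold_min=fold_min)
            # fold vs the reference (first) group, either non-reference group
            f1 = res.folds[(1, 0)]
            f2 = res.folds[(2, 0)]
            max_fold = max(f1, 1.0 / f1, f2, 1.0 / f2)
            rows.append(
                dict(
                    analyte_id=analyte,
                    test="kruskal_wallis",
                    pvalue=res.pvalue,
                    fold=f2,
                    max_fold=max_fold,
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["test", "pvalue", "fold", "max_fold", "p_adj", "significant"]
        ).rename_axis("analyte_id")
    df = pd.DataFrame(rows).set_index("analyte_id")
    df["p_adj"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = (df["p_adj"] < fdr) & (df["max_fold"] > fold_min)
    return df


def run_comparison(
    comparison: str,
    corrected: dict[str, dict[str, AnalyteMatrix]],
    meta: pd.DataFrame,
    stringency: str = "strict",
    fold_min: float = 1.5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Run a clinical comparison per analyte under both age-correction methods.

    ``corrected`` maps age-correction method ("lmm", "tertile") to per-type
    corrected matrices.  Analytes are called significant only when they pass
    FDR < ``fdr`` and fold > ``fold_min`` under BOTH methods; the returned
    table is the intersection with per-method statistics side by side.
    """
    groups = comparison_groups(comparison, meta, stringency)
    methods = list(corrected)
    per_method: dict[str, list[pd.DataFrame]] = {meth: [] for meth in methods}
    for meth in methods:
        for data_type, matrix in corrected[meth].items():
            if matrix.scale == "categorical":
                continue
            res = _test_matrix(matrix, groups, fold_min, fdr)
            res.insert(0, "data_type", data_type)
            per_method[meth].append(res)
    tables = {meth: pd.concat(per_method[meth]) for meth in methods}
    if len(methods) == 1:
        out = tables[methods[0]]
        return out.loc[out["significant"]].copy()
    a, b = tables[methods[0]], tables[methods[1]]
    common = a.index.intersection(b.index)
    inter = dual_method_intersect(a.loc[common], b.loc[common])
    other = b.loc[inter.index, ["pvalue", "p_adj", "fold"]]
    inter = inter.join(other, rsuffix=f"_{methods[1]}")
    return inter
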