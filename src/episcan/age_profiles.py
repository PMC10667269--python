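"""Developmental-trajectory analysis.

Two views of how analytes change over the first two years of life: a
continuous one (Spearman rank correlation of each analyte with postnatal age,
BH-adjusted across analytes) and a categorical one (Kruskal-Wallis across the
three age strata, then complete-linkage hierarchical clustering of each
analyte's per-stratum median Z-score profile into trajectory clusters).  Both
run on matrices corrected for batch and drug effects but NOT for age — the
age signal is what is being profiled.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .data_model import AnalyteMatrix, assign_age_tertile
from .univariate import bh_adjust, three_group_test

log = logging.getLogger(__name__)

#: Cluster counts used for the trajectory clustering, per data type.
DEFAULT_K = {"protein": 6, "metabolite": 6, "rna": 8}


def spearman_age_association(matrix: AnalyteMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte Spearman correlation with age, BH-adjusted.

    Constant analytes (undefined correlation) are excluded and logged.
    """
    ages = meta.loc[matrix.sample_ids, "age_weeks"].to_numpy(float)
    rows = []
    for analyte in matrix.values.index:
        y = matrix.values.loc[analyte].to_numpy(float)
        obs = ~np.isnan(y)
        if obs.sum() < 3 or np.ptp(y[obs]) == 0 or np.ptp(ages[obs]) == 0:
            log.warning("Spearman: analyte %s constant or too sparse; excluded", analyte)
            continue
        rho, p = stats.spearmanr(ages[obs], y[obs])
        rows.append(dict(analyte_id=analyte, rho=float(rho), pvalue=float(p)))
    df = pd.DataFrame(rows).set_index("analyte_id")
    df["p_adj"] = bh_adjust(df["pvalue"].to_numpy())
    return df


def kw_age_association(matrix: AnalyteMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis test of each analyte across the three age strata."""
    tertiles = assign_age_tertile(meta.loc[matrix.sample_ids, "age_weeks"])
    masks = {t: (tertiles == t).to_numpy() for t in ("T1", "T2", "T3")}
    rows = []
    for analyte in matrix.values.index:
        y = matrix.values.loc[analyte].to_numpy(float)
        groups = []
        ok = True
        for t in ("T1", "T2", "T3"):
            g = y[masks[t]]
            g = g[~np.isnan(g)]
            if len(g) < 2:
                ok = False
                break
            groups.append(g)
        if not ok:
            continue
        res = three_group_test(groups, scale=matrix.scale)
        rows.append(dict(analyte_id=analyte, kw_stat=res.kw_stat, pvalue=res.pvalue))
    df = pd.DataFrame(rows).set_index("analyte_id")
    df["p_adj"] = bh_adjust(df["pvalue"].to_numpy())
    return df


def tertile_median_zscores(matrix: AnalyteMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte (T1, T2, T3) medians of the analyte's Z-scored values."""
    tertiles = assign_age_tertile(meta.loc[matrix.sample_ids, "age_weeks"])
    arr = matrix.values.to_numpy(float)
    mu = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (arr - mu) / sd
    out = {}
    for t in ("T1", "T2", "T3"):
        cols = (tertiles == t).to_numpy()
        with np.errstate(all="ignore"):
            out[t] = np.nanmedian(z[:, cols], axis=1) if cols.any() else np.full(len(arr), np.nan)
    return pd.DataFrame(out, index=matrix.values.index)


def cluster_age_trajectories(
    matrix: AnalyteMatrix,
    meta: pd.DataFrame,
    k: int,
    restrict_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster per-stratum median Z-score profiles into k trajectory groups.

    Profiles are clustered by complete-linkage hierarchical clustering on
    Euclidean distances and the dendrogram is cut into ``k`` clusters.
    ``restrict_ids`` usually holds the analytes significant in the age-strata
    Kruskal-Wallis test.  Returns the profile table (with cluster labels
    relabelled to contiguous integers, 1-based, in order of first appearance)
    and the linkage matrix.
    """
    profiles = tertile_median_zscores(matrix, meta)
    if restrict_ids is not None:
        profiles = profiles.loc[[a for a in profiles.index if a in set(restrict_ids)]]
    profiles = profiles.dropna()
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} clusterable analytes")
    # sort analytes by id so linkage tie-breaking is input-order independent
    profiles = profiles.sort_index()
    Z = linkage(profiles.to_numpy(), method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels.append(relabel[c])
    profiles = profiles.copy()
    profiles["cluster"] = labels
    return profiles, Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string (heights as lengths)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for idx, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + idx] = h
    return nodes[n + len(Z) - 1] + ";"
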