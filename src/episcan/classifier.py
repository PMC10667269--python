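"""Predictive-biomarker engine.

Feature pooling by univariate AUC, exhaustive enumeration of all 1-, 2- and
3-variable logistic models, per-model decision-threshold tuning, Monte-Carlo
cross-validation (repeated stratified 2/3 - 1/3 subsampling) scored by the
Matthews correlation coefficient, and a whole-experiment permutation test in
which feature selection and the full model search are re-run on
outcome-permuted data.

The logistic fits are performed by a batched Newton (IRLS) solver that fits
all Monte-Carlo subsamples of a model simultaneously; with ~10^5 models x
10^2 subsamples per search this is the only part of the pipeline where raw
speed matters.  A small L2 penalty (default 1e-4, slopes only) keeps the
optimum finite under complete separation, which is common with 11 negatives.

Seeding: the master seed plus a CRC32 of the model's sorted variable ids
spawns one child generator per model, so results do not depend on the order
in which models are evaluated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .data_model import AnalyteMatrix


# ---------------------------------------------------------------------------
# Filters, AUC, pooling


def prefilter_rna(
    counts: AnalyteMatrix,
    labels: pd.Series,
    min_reads: float = 3.0,
    min_fraction: float = 0.75,
    min_fold: float = 2.0,
) -> AnalyteMatrix:
    """Pre-filter an RNA count matrix for the classifier stage.

    Keeps genes with more than ``min_reads`` reads in at least
    ``min_fraction`` of samples AND at least a ``min_fold`` change between the
    class medians (either direction; zero medians compare via a 0.5
    pseudocount).  Returns an empty matrix (with a warning) if nothing passes.
    """
    if labels is None or len(labels) == 0:
        raise ValueError("labels required for the RNA prefilter")
    common = [s for s in counts.sample_ids if s in labels.index]
    arr = counts.values[common].to_numpy(float)
    y = labels.loc[common].to_numpy(int)
    with np.errstate(invalid="ignore"):
        frac = np.nanmean(arr > min_reads, axis=1)
    keep_depth = frac >= min_fraction - 1e-12
    med1 = np.nanmedian(arr[:, y == 1], axis=1)
    med0 = np.nanmedian(arr[:, y == 0], axis=1)
    hi = np.maximum(med1, med0) + 0.5
    lo = np.minimum(med1, med0) + 0.5
    keep_fold = hi / lo >= min_fold
    keep = counts.values.index[keep_depth & keep_fold]
    if len(keep) == 0:
        import logging

        logging.getLogger(__name__).warning("RNA prefilter retained no genes")
    return counts.copy_with(counts.values.loc[keep])


def compute_auc(values, labels) -> float:
    """Rank-based (Mann-Whitney) AUC of values for predicting label 1.

    Ties are handled by midranks; samples with a missing value are excluded
    pairwise.  Raises when a class is absent.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    obs = ~np.isnan(v)
    v, y = v[obs], y[obs]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(v)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def oriented_auc(values, labels) -> float:
    """AUC folded above 0.5 (a perfectly anti-predictive variable scores 1)."""
    a = compute_auc(values, labels)
    return max(a, 1.0 - a)


@dataclass
class FeaturePool:
    """Variables retained for the model search.

    ``table`` has one row per selected feature (feature id, data type,
    oriented AUC); ``data`` is the samples x features value matrix the search
    fits on (unstandardized — standardization happens inside each split).
    """

    table: pd.DataFrame
    data: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)


def build_feature_pool(
    matrices: dict[str, AnalyteMatrix],
    labels: pd.Series,
    auc_min: float = 0.6,
    per_type_cap: int = 30,
) -> FeaturePool:
    """Select up to ``per_type_cap`` features per data type by oriented AUC.

    Constant features are dropped; remaining features must exceed ``auc_min``
    oriented AUC and are ranked by descending AUC (ties broken by feature id).
    Raises if no feature survives in any type.
    """
    sample_ids = list(labels.index)
    y = labels.to_numpy(int)
    rows = []
    columns = {}
    for data_type in sorted(matrices):
        matrix = matrices[data_type]
        sub = matrix.values[[s for s in sample_ids if s in matrix.values.columns]]
        if list(sub.columns) != sample_ids:
            sub = sub.reindex(columns=sample_ids)
        scored = []
        for analyte in sub.index:
            v = sub.loc[analyte].to_numpy(float)
            obs = ~np.isnan(v)
            if obs.sum() < 4 or np.nanstd(v) == 0:
                continue
            if len(np.unique(y[obs])) < 2:
                continue
            scored.append((analyte, oriented_auc(v, y)))
        scored = [t for t in scored if t[1] > auc_min]
        scored.sort(key=lambda t: (-t[1], t[0]))
        for analyte, auc in scored[:per_type_cap]:
            rows.append(dict(feature=analyte, data_type=data_type, auc=auc))
            columns[analyte] = sub.loc[analyte]
    if not rows:
        raise ValueError(
            "no feature exceeded the AUC threshold; consider relaxing auc_min"
        )
    table = pd.DataFrame(rows).set_index("feature")
    data = pd.DataFrame(columns, index=sample_ids)[table.index]
    return FeaturePool(table=table, data=data)


def enumerate_models(
    feature_ids: Sequence[str] | FeaturePool, max_order: int = 3
) -> Iterator[tuple[str, ...]]:
    """Yield every subset of 1..max_order features exactly once, sorted."""
    if isinstance(feature_ids, FeaturePool):
        feature_ids = feature_ids.feature_ids
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    ids = sorted(feature_ids)
    for order in range(1, max_order + 1):
        yield from combinations(ids, order)


def count_models(n_features: int, max_order: int = 3) -> int:
    """Closed-form model-space size: sum of C(n, j) for j = 1..max_order."""
    from math import comb

    return sum(comb(n_features, j) for j in range(1, max_order + 1))


# ---------------------------------------------------------------------------
# Metrics


def matthews_cc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient of a confusion table.

    Ranges from -1 (complete disagreement) to 1 (complete agreement); defined
    as 0 when any marginal sum in the denominator is zero.  An all-zero table
    raises.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("no predictions made")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def _mcc_array(tp, tn, fp, fn) -> np.ndarray:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (tp * tn - fp * fn) / np.sqrt(denom)
    return np.where(denom > 0, out, 0.0)


# ---------------------------------------------------------------------------
# Monte-Carlo evaluation


@dataclass
class SearchConfig:
    """Knobs for the model search and its validation."""

    auc_min: float = 0.6
    per_type_cap: int = 30
    max_order: int = 3
    n_subsamples: int = 100
    train_frac: float = 2.0 / 3.0
    l2: float = 1e-4
    threshold_method: str = "train_mcc"  # "train_mcc", "fixed", "prevalence"
    fixed_threshold: float = 0.5
    standardize: str = "per_split"  # "per_split" (leak-free) or "all_data"
    n_permutations: int = 30
    perm_subsamples: int = 50
    alpha: float = 0.05
    seed: int = 0


@dataclass
class ModelRecord:
    """One evaluated candidate classifier."""

    variables: tuple
    n_total: int
    threshold: float
    mcc_mean: float
    mmce_mean: float
    ppv_mean: float
    npv_mean: float  # NaN when never defined across subsamples
    n_subsamples: int
    coefficients: np.ndarray = field(default=None, repr=False)

    def key(self) -> str:
        return "+".join(self.variables)


def _model_rng(master_seed: int, variables: Iterable[str]) -> np.random.Generator:
    crc = zlib.crc32("+".join(sorted(variables)).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**31), crc]))


def _stratified_masks(
    y: np.ndarray, n_subsamples: int, train_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (subsamples x n) training masks, stratified by class."""
    n = len(y)
    masks = np.zeros((n_subsamples, n), dtype=bool)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        if len(idx) < 2:
            raise ValueError("a class has fewer than 2 samples; cannot stratify")
        r = rng.random((n_subsamples, len(idx)))
        order = np.argsort(r, axis=1)[:, :n_tr]
        rows = np.repeat(np.arange(n_subsamples), n_tr)
        masks[rows, idx[order].ravel()] = True
    return masks


def _fit_logistic_batch(
    X: np.ndarray, y: np.ndarray, M: np.ndarray, l2: float, max_iter: int = 60, tol: float = 1e-9
) -> np.ndarray:
    """Batched penalized logistic fits.

    X: (s, n, q) per-subsample design (intercept first column); y: (n,) binary
    labels; M: (s, n) training masks.  Returns coefficients (s, q).
    """
    s, n, q = X.shape
    W = np.zeros((s, q))
    pen = np.full(q, l2)
    pen[0] = 0.0
    pen_mat = np.diag(pen) + 1e-10 * np.eye(q)
    Mf = M.astype(float)
    XT = np.ascontiguousarray(X.transpose(0, 2, 1))
    yb = y[None, :]
    for _ in range(max_iter):
        eta = np.matmul(X, W[:, :, None])[:, :, 0]
        np.clip(eta, -35, 35, out=eta)
        mu = expit(eta)
        resid = (mu - yb) * Mf
        g = np.matmul(XT, resid[:, :, None])[:, :, 0] + pen[None, :] * W
        wgt = mu * (1.0 - mu) * Mf + 1e-12
        H = np.matmul(XT, X * wgt[:, :, None]) + pen_mat[None, :, :]
        step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        norms = np.linalg.norm(step, axis=1)
        scale = np.minimum(1.0, 5.0 / np.maximum(norms, 1e-12))
        W -= step * scale[:, None]
        if float(np.max(norms)) < tol:
            break
    return W


def _tune_thresholds(
    P: np.ndarray, y: np.ndarray, M: np.ndarray, method: str, fixed: float
) -> np.ndarray:
    """Per-subsample decision thresholds chosen on the training set only.

    ``train_mcc`` scans the observed training probabilities and keeps the one
    maximizing training MCC (smallest such threshold on ties).
    """
    s, n = P.shape
    if method == "fixed":
        return np.full(s, fixed)
    if method == "prevalence":
        return (M * y[None, :]).sum(1) / M.sum(1)
    if method != "train_mcc":
        raise ValueError(f"unknown threshold method {method!r}")
    thr = np.where(M, P, np.inf)  # (s, n) candidate thresholds per subsample
    pred = P[:, None, :] >= thr[:, :, None]  # (s, cand, n)
    predf = pred.astype(np.float32)
    ymask = (M * y[None, :]).astype(np.float32)
    mmask = M.astype(np.float32)
    tp = np.matmul(predf, ymask[:, :, None])[:, :, 0]
    pos = np.matmul(predf, mmask[:, :, None])[:, :, 0]
    npos = ymask.sum(1)[:, None]
    ntr = mmask.sum(1)[:, None]
    fp = pos - tp
    fn = npos - tp
    tn = ntr - pos - fn
    mcc = _mcc_array(tp, tn, fp, fn)
    mcc = np.where(np.isfinite(thr), mcc, -np.inf)
    best = mcc.max(axis=1, keepdims=True)
    cand = np.where(mcc >= best - 1e-12, thr, np.inf)
    upper = cand.min(axis=1)
    # place the cut mid-way between the chosen candidate and the next train
    # probability below it, so borderline test samples are not split on the
    # training observation itself
    below = np.where(thr < upper[:, None], thr, -np.inf).max(axis=1)
    below = np.where(np.isfinite(below), below, 0.0)
    return (upper + below) / 2.0


def evaluate_model(
    variables: Sequence[str],
    data: pd.DataFrame,
    labels: pd.Series,
    config: SearchConfig,
    n_subsamples: int | None = None,
) -> ModelRecord:
    """Score one variable set by repeated stratified subsampling.

    Rows with a missing value in any of the variables are dropped
    (complete-case; the retained count is reported as ``n_total``).  Per
    subsample: standardize on the training rows, fit the penalized logistic
    model, tune the decision threshold on the training set, and score the
    held-out third.  Means of MCC, misclassification error, PPV and NPV are
    taken across subsamples (PPV/NPV over the subsamples where defined).
    """
    variables = tuple(sorted(variables))
    ns = int(n_subsamples or config.n_subsamples)
    X_raw = data[list(variables)].to_numpy(float)
    y_all = labels.loc[data.index].to_numpy(int)
    return _evaluate_arrays(variables, X_raw, y_all, config, ns)


def _evaluate_arrays(
    variables: tuple, X_raw: np.ndarray, y_all: np.ndarray, config: SearchConfig, ns: int
) -> ModelRecord:
    complete = ~np.isnan(X_raw).any(axis=1)
    X_raw, y = X_raw[complete], y_all[complete]
    n, p = X_raw.shape
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required after complete-case filtering")

    rng = _model_rng(config.seed, variables)
    M = _stratified_masks(y, ns, config.train_frac, rng)
    Mf = M.astype(float)
    ntr = Mf.sum(1)

    if config.standardize == "per_split":
        mu = (Mf @ X_raw) / ntr[:, None]
        ex2 = (Mf @ (X_raw**2)) / ntr[:, None]
        sd = np.sqrt(np.maximum(ex2 - mu**2, 0.0))
    elif config.standardize == "all_data":
        mu = np.broadcast_to(X_raw.mean(0), (ns, p)).copy()
        sd = np.broadcast_to(X_raw.std(0), (ns, p)).copy()
    else:
        raise ValueError(f"unknown standardize mode {config.standardize!r}")
    sd[sd < 1e-12] = 1.0
    Xs = (X_raw[None, :, :] - mu[:, None, :]) / sd[:, None, :]
    X = np.concatenate([np.ones((ns, n, 1)), Xs], axis=2)

    W = _fit_logistic_batch(X, y, M, config.l2)
    eta = np.einsum("snq,sq->sn", X, W)
    P = expit(np.clip(eta, -35, 35))
    thr = _tune_thresholds(P, y, M, config.threshold_method, config.fixed_threshold)

    Mt = (~M).astype(float)
    pred = (P >= thr[:, None]).astype(float)
    tp = (pred * Mt * y[None, :]).sum(1)
    pos = (pred * Mt).sum(1)
    npos = (Mt * y[None, :]).sum(1)
    nte = Mt.sum(1)
    fp = pos - tp
    fn = npos - tp
    tn = nte - pos - fn
    mcc = _mcc_array(tp, tn, fp, fn)
    mmce = (fp + fn) / nte
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        npv = np.where(tn + fn > 0, tn / (tn + fn), np.nan)

    def _nanmean(a: np.ndarray) -> float:
        return float(np.nanmean(a)) if np.isfinite(a).any() else float("nan")

    return ModelRecord(
        variables=variables,
        n_total=int(n),
        threshold=float(np.mean(thr[np.isfinite(thr)])) if np.isfinite(thr).any() else 0.5,
        mcc_mean=float(mcc.mean()),
        mmce_mean=float(mmce.mean()),
        ppv_mean=_nanmean(ppv),
        npv_mean=_nanmean(npv),
        n_subsamples=ns,
        coefficients=W.mean(axis=0),
    )


def run_search(
    pool: FeaturePool,
    labels: pd.Series,
    config: SearchConfig,
    n_subsamples: int | None = None,
) -> pd.DataFrame:
    """Evaluate every enumerated model; rank by mean test MCC (descending).

    Models that cannot be evaluated (e.g. a class lost to missingness) are
    skipped and logged.  Ties in MCC break deterministically on the variable
    ids.
    """
    import logging

    ns = int(n_subsamples or config.n_subsamples)
    A = pool.data.to_numpy(float)
    col = {f: i for i, f in enumerate(pool.data.columns)}
    y_all = labels.loc[pool.data.index].to_numpy(int)
    records = []
    for variables in enumerate_models(pool.feature_ids, config.max_order):
        try:
            X_raw = A[:, [col[v] for v in variables]]
            rec = _evaluate_arrays(tuple(variables), X_raw, y_all, config, ns)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logging.getLogger(__name__).warning("model %s skipped: %s", variables, exc)
            continue
        records.append(rec)
    df = pd.DataFrame(
        dict(
            features=[r.key() for r in records],
            n_total=[r.n_total for r in records],
            lr_threshold=[r.threshold for r in records],
            mcc_test_mean=[r.mcc_mean for r in records],
            mmce_test_mean=[r.mmce_mean for r in records],
            ppv_test_mean=[r.ppv_mean for r in records],
            npv_test_mean=[r.npv_mean for r in records],
        )
    )
    return df.sort_values(
        ["mcc_test_mean", "features"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-experiment permutation test


@dataclass
class PermutationResult:
    """Null distributions from outcome-permuted re-runs of the experiment.

    ``null_mcc`` pools the mean test MCC of every model from every
    permutation; ``null_max`` holds the best MCC per permutation.
    """

    null_mcc: np.ndarray
    null_max: np.ndarray
    threshold: float  # (1 - alpha) quantile of the pooled null
    n_permutations: int

    def p_pooled(self, mcc: float | np.ndarray) -> np.ndarray | float:
        """Fraction of all permuted models with MCC >= the given value.

        The permuted-data analogue of asking how often a random-outcome model
        matches a given model; valid for a model specified independently of
        the search ranking.
        """
        m = np.atleast_1d(np.asarray(mcc, float))
        out = (self.null_mcc[None, :] >= m[:, None]).mean(axis=1)
        return out if np.ndim(mcc) else float(out[0])

    def p_fwe(self, mcc: float | np.ndarray) -> np.ndarray | float:
        """Fraction of permutations whose BEST model reaches the given MCC.

        The family-wise quantity appropriate for a model selected as the best
        of the search.
        """
        m = np.atleast_1d(np.asarray(mcc, float))
        out = (self.null_max[None, :] >= m[:, None]).mean(axis=1)
        return out if np.ndim(mcc) else float(out[0])


def permutation_test(
    matrices: dict[str, AnalyteMatrix],
    labels: pd.Series,
    config: SearchConfig,
) -> PermutationResult:
    """Re-run feature selection + search on outcome-permuted labels.

    Each permutation shuffles the class labels, rebuilds the feature pool
    (AUC threshold and per-type cap are re-applied against the permuted
    labels, so any selection optimism is reproduced under the null), and
    evaluates every model with ``perm_subsamples`` subsamples.  All permuted
    models' mean test MCCs are pooled; the per-permutation maxima are kept
    separately for family-wise inference.
    """
    if config.n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    pooled: list[np.ndarray] = []
    maxima: list[float] = []
    for b in range(config.n_permutations):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2**31), 0x5EED, b])
        )
        perm = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index, name=labels.name
        )
        try:
            pool = build_feature_pool(matrices, perm, config.auc_min, config.per_type_cap)
        except ValueError:
            pooled.append(np.array([0.0]))
            maxima.append(0.0)
            continue
        perm_cfg = SearchConfig(**{**config.__dict__, "seed": (config.seed + 7919 * (b + 1)) % (2**31)})
        table = run_search(pool, perm, perm_cfg, n_subsamples=config.perm_subsamples)
        mccs = table["mcc_test_mean"].to_numpy(float)
        pooled.append(mccs)
        maxima.append(float(mccs.max()) if len(mccs) else 0.0)
    null_mcc = np.concatenate(pooled)
    null_max = np.asarray(maxima)
    return PermutationResult(
        null_mcc=null_mcc,
        null_max=null_max,
        threshold=float(np.quantile(null_mcc, 1.0 - config.alpha)),
        n_permutations=config.n_permutations,
    )


def attach_pvalues(table: pd.DataFrame, null: PermutationResult) -> pd.DataFrame:
    """Add pooled and family-wise permutation p-values to a search table."""
    out = table.copy()
    mcc = out["mcc_test_mean"].to_numpy(float)
    out["p_value"] = null.p_pooled(mcc)
    out["p_value_fwe"] = null.p_fwe(mcc)
    return out
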