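"""Synthetic longitudinal multi-omic cohort with a ground-truth ledger.

Generates a cohort with the statistical structure the analysis pipeline
assumes: 93 affected (TSC) infants sampled serially from enrollment to 104
weeks plus 58 single-sample controls; per-analyte developmental age
trajectories drawn from four archetypes; metabolite batch offsets; strong
multiplicative vigabatrin effects on selected metabolites; diagnostic-group
effects; analytes planted to predict seizure outcome at a chosen univariate
AUC; and missingness concentrated near a detection limit.  Every planted
effect is recorded in a :class:`GroundTruth` ledger so recovery can be tested.

Continuous analytes (protein, metabolite, miRNA) are simulated directly on the
log2 scale with additive Gaussian noise; RNA is simulated as negative-binomial
counts and converted to log2(CPM+1), matching the scales the corrections
operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .data_model import AnalyteMatrix, validate_metadata

ARCHETYPES = ("monotone_up", "monotone_down", "early_peak", "late_plateau")


def trajectory_value(archetype: str, age_weeks: np.ndarray) -> np.ndarray:
    """Unit-amplitude trajectory archetypes on postnatal age 0-104 weeks.

    All archetypes are nearly flat above ~45 weeks, emulating developmental
    effects that are strong in infancy and minimal past 40 weeks (the age
    range the drug-exposure comparison is restricted to).
    """
    t = np.asarray(age_weeks, dtype=float)
    if archetype == "monotone_up":
        return np.minimum(t, 40.0) / 40.0
    if archetype == "monotone_down":
        return -np.minimum(t, 40.0) / 40.0
    if archetype == "early_peak":
        return np.exp(-(((t - 20.0) / 10.0) ** 2))
    if archetype == "late_plateau":
        return 1.0 / (1.0 + np.exp(-(t - 35.0) / 4.0))
    raise ValueError(f"unknown archetype {archetype!r}")


def auc_to_shift(auc: float) -> float:
    """Mean shift (in units of the per-class SD) giving a normal-theory AUC.

    For two normal classes with equal SD sigma and mean difference delta, the
    rank AUC is Phi(delta / (sigma * sqrt(2))); inverting gives
    delta = sqrt(2) * Phi^{-1}(AUC) * sigma.
    """
    if not 0.5 < auc <= 1.0:
        raise ValueError("target AUC must be in (0.5, 1]")
    return float(np.sqrt(2.0) * ndtri(auc))


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_tsc: int = 93
    n_control: int = 58
    n_analytes: dict = field(
        default_factory=lambda: {"protein": 100, "metabolite": 80, "rna": 150, "mirna": 45}
    )
    age_effect_fraction: dict = field(
        default_factory=lambda: {"protein": 0.84, "metabolite": 0.69, "rna": 0.51, "mirna": 0.5}
    )
    batch_count: int = 4  # metabolites only
    batch_sd: float = 0.5  # SD of per-batch log2 offsets
    #: (analyte id, linear fold change) applied to vigabatrin-exposed samples;
    #: None -> a default panel of 8 folds from 1.5x up to the 52x extreme.
    vgb_effect_spec: list | None = None
    #: (analyte id, target univariate AUC) planted on enrollment samples of
    #: subjects who go on to develop seizures.
    planted_predictors: list = field(default_factory=list)
    #: (analyte id, log2 effect in TSC, extra log2 effect in TSC-epilepsy).
    group_effect_spec: list = field(default_factory=list)
    #: detection-limit quantile per type; values below it are masked (MNAR).
    missingness_spec: dict = field(
        default_factory=lambda: {"protein": 0.05, "metabolite": 0.05, "rna": 0.0, "mirna": 0.0}
    )
    class_balance: tuple = (54, 11)  # (seizure, seizure-free) after exclusions
    n_entry_seizure: int = 7  # excluded: subclinical seizures at study entry
    n_presympt_no_seizure: int = 14  # excluded: presymptomatic VGB, no seizures
    n_no_enrollment: int = 7  # excluded: no comparable enrollment sample
    trajectory_amplitude: float = 1.0  # log2 units
    amplitude_sd: float = 0.3
    subject_sd: float = 0.5  # subject random-intercept SD, log2 units
    noise_sd: float = 0.2  # within-subject residual SD, log2 units
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    rna_dispersion: float = 0.05
    drug_resistant_fraction: float = 0.4

    def __post_init__(self) -> None:
        for ty, f in self.age_effect_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"age_effect_fraction[{ty}] outside [0,1]")
        excluded = self.n_entry_seizure + self.n_presympt_no_seizure + self.n_no_enrollment
        if sum(self.class_balance) + excluded > self.n_tsc:
            raise ValueError("class_balance plus exclusions exceed n_tsc")
        if self.vgb_effect_spec is not None:
            for _, fold in self.vgb_effect_spec:
                if fold <= 0:
                    raise ValueError("fold changes must be > 0")
        for _, auc in self.planted_predictors:
            if not 0.5 < auc <= 1.0:
                raise ValueError("target AUC must be in (0.5, 1]")


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted, keyed by analyte id."""

    age_archetype: dict = field(default_factory=dict)  # analyte -> archetype or None
    age_amplitude: dict = field(default_factory=dict)  # analyte -> log2 amplitude
    batch_offsets: dict = field(default_factory=dict)  # batch -> log2 offset
    vgb_log2_effect: dict = field(default_factory=dict)  # analyte -> log2 fold
    group_effect: dict = field(default_factory=dict)  # analyte -> (tsc, epilepsy extra)
    planted_shift: dict = field(default_factory=dict)  # analyte -> (target AUC, log2 shift)


def _default_vgb_spec(metabolite_ids: list[str]) -> list:
    folds = [52.0, 20.0, 10.0, 5.0, 3.0, 2.5, 2.0, 1.5]
    return [(metabolite_ids[i], folds[i]) for i in range(min(len(folds), len(metabolite_ids)))]


def _enrollment_age(rng: np.random.Generator) -> float:
    # log-normal matched to enrollment ages: median 4.7 w, Q1-Q3 2.1-8.0 w
    mu, sigma = np.log(4.7), (np.log(8.0) - np.log(2.1)) / (2 * 0.6745)
    return float(np.clip(rng.lognormal(mu, sigma), 0.3, 17.0))


def _build_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subjects, roles, longitudinal timepoints and per-sample flags."""
    n = config.n_tsc
    roles = (
        ["entry_seizure"] * config.n_entry_seizure
        + ["presympt_no_seizure"] * config.n_presympt_no_seizure
        + ["no_enrollment"] * config.n_no_enrollment
        + ["seizure"] * config.class_balance[0]
        + ["seizure_free"] * config.class_balance[1]
    )
    roles += ["seizure_free"] * (n - len(roles))
    roles = list(rng.permutation(roles))

    rows = []
    for i, role in enumerate(roles):
        subject = f"TSC{i + 1:03d}"
        enroll_age = _enrollment_age(rng)
        has_seizures = role in ("entry_seizure", "seizure")
        presympt = role == "presympt_no_seizure"
        onset = None
        if role == "seizure":
            onset = float(np.clip(rng.lognormal(np.log(20.0), 0.6), enroll_age + 1.0, 90.0))
        elif role == "entry_seizure":
            onset = enroll_age  # subclinical seizures already at entry
        # vigabatrin start: at onset for seizure subjects, shortly after the
        # abnormal-EEG detection for presymptomatically treated subjects
        eeg_age = float(np.clip(enroll_age + rng.uniform(2.0, 20.0), 0.0, 95.0))
        vgb_start = None
        if has_seizures:
            vgb_start = onset
        elif presympt:
            vgb_start = eeg_age
        drug_resistant = bool(role == "seizure" and rng.random() < config.drug_resistant_fraction)

        timepoints = []
        if role != "no_enrollment":
            timepoints.append(("enrollment", enroll_age))
        if role == "seizure":
            timepoints.append(("seizure", float(min(onset + rng.uniform(0.0, 2.0), 100.0))))
        elif presympt:
            timepoints.append(("eeg", eeg_age))
        else:
            timepoints.append(("m6_12", float(rng.choice([26.0, 52.0]) + rng.uniform(-2, 2))))
        timepoints.append(("m24", float(104.0 + rng.uniform(-2, 2))))

        for label, age in timepoints:
            seizure_at_draw = bool(has_seizures and onset is not None and age >= onset - 1e-9)
            rows.append(
                dict(
                    sample_id=f"{subject}_{label}",
                    subject_id=subject,
                    age_weeks=round(age, 2),
                    batch=0,
                    vgb=bool(vgb_start is not None and age >= vgb_start - 1e-9),
                    group="tsc",
                    seizure_history=has_seizures,
                    abnormal_eeg_at_draw=bool(
                        label in ("eeg", "seizure")
                        or (has_seizures and age >= onset - 1e-9)
                        or (presympt and age >= eeg_age - 1e-9)
                        or (role == "entry_seizure")
                    ),
                    seizure_at_draw=seizure_at_draw,
                    drug_resistant_24m=drug_resistant,
                    presymptomatic_vgb=presympt,
                    timepoint_label=label,
                    seizure_before_draw=seizure_at_draw,
                )
            )

    for i in range(config.n_control):
        subject = f"CTL{i + 1:03d}"
        rows.append(
            dict(
                sample_id=f"{subject}_s1",
                subject_id=subject,
                age_weeks=round(float(rng.uniform(0.5, 104.0)), 2),
                batch=0,
                vgb=False,
                group="control",
                seizure_history=False,
                abnormal_eeg_at_draw=False,
                seizure_at_draw=False,
                drug_resistant_24m=False,
                presymptomatic_vgb=False,
                timepoint_label="control",
                seizure_before_draw=False,
            )
        )

    meta = pd.DataFrame(rows)
    meta["batch"] = rng.integers(0, max(config.batch_count, 1), size=len(meta))
    return validate_metadata(meta)


def _simulate_log2(
    ids: list[str],
    meta: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    frac_age: float,
    truth: GroundTruth,
    batch_offsets: np.ndarray | None,
) -> pd.DataFrame:
    """Baseline + age trajectory + subject intercept (+ batch) + noise, log2."""
    n_a, n_s = len(ids), len(meta)
    ages = meta["age_weeks"].to_numpy(float)
    subjects = meta["subject_id"].to_numpy()
    uniq_subj, subj_idx = np.unique(subjects, return_inverse=True)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n_a)
    n_age = int(round(frac_age * n_a))
    age_flags = np.zeros(n_a, dtype=bool)
    age_flags[rng.choice(n_a, size=n_age, replace=False)] = True
    archetypes = rng.choice(ARCHETYPES, size=n_a)
    amplitudes = np.abs(rng.normal(config.trajectory_amplitude, config.amplitude_sd, size=n_a))
    signs = rng.choice([-1.0, 1.0], size=n_a)
    intercepts = rng.normal(0.0, config.subject_sd, size=(n_a, len(uniq_subj)))
    noise = rng.normal(0.0, config.noise_sd, size=(n_a, n_s))

    values = baselines[:, None] + intercepts[:, subj_idx] + noise
    for i in range(n_a):
        if age_flags[i]:
            values[i] += signs[i] * amplitudes[i] * trajectory_value(archetypes[i], ages)
            truth.age_archetype[ids[i]] = str(archetypes[i])
            truth.age_amplitude[ids[i]] = float(signs[i] * amplitudes[i])
        else:
            truth.age_archetype[ids[i]] = None
            truth.age_amplitude[ids[i]] = 0.0
    if batch_offsets is not None:
        values += batch_offsets[meta["batch"].to_numpy(int)][None, :]
    return pd.DataFrame(values, index=ids, columns=meta["sample_id"].to_numpy())


def _apply_planted_effects(
    df: pd.DataFrame, meta: pd.DataFrame, config: CohortConfig, truth: GroundTruth, data_type: str
) -> None:
    vgb_mask = meta["vgb"].to_numpy(bool)
    specs = config.vgb_effect_spec
    if data_type == "metabolite":
        if specs is None:
            specs = _default_vgb_spec(list(df.index))
        for analyte, fold in specs:
            if analyte not in df.index:
                raise KeyError(f"VGB effect analyte {analyte!r} not in metabolite matrix")
            df.loc[analyte, vgb_mask] += np.log2(fold)
            truth.vgb_log2_effect[analyte] = float(np.log2(fold))

    for analyte, tsc_eff, epi_extra in config.group_effect_spec:
        if analyte not in df.index:
            continue
        tsc = (meta["group"] == "tsc").to_numpy()
        epi = tsc & meta["seizure_history"].to_numpy(bool)
        df.loc[analyte, tsc] += tsc_eff
        df.loc[analyte, epi] += epi_extra
        truth.group_effect[analyte] = (float(tsc_eff), float(epi_extra))

    if config.planted_predictors:
        sigma = float(np.hypot(config.subject_sd, config.noise_sd))
        target = (
            (meta["timepoint_label"] == "enrollment")
            & meta["seizure_history"].to_numpy(bool)
            & ~meta["seizure_at_draw"].to_numpy(bool)
        ).to_numpy()
        for analyte, auc in config.planted_predictors:
            if analyte not in df.index:
                continue
            delta = auc_to_shift(auc) * sigma
            df.loc[analyte, target] += delta
            truth.planted_shift[analyte] = (float(auc), float(delta))


def _mask_below_detection(df: pd.DataFrame, quantile: float) -> pd.DataFrame:
    if quantile <= 0:
        return df
    limit = np.nanquantile(df.to_numpy(), quantile)
    return df.mask(df < limit)


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[dict[str, AnalyteMatrix], pd.DataFrame, GroundTruth]:
    """Generate matrices per data type, sample metadata, and the ground truth.

    Deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    meta = _build_metadata(config, rng)

    batch_offsets = rng.normal(0.0, config.batch_sd, size=max(config.batch_count, 1))
    truth.batch_offsets = {int(b): float(v) for b, v in enumerate(batch_offsets)}

    matrices: dict[str, AnalyteMatrix] = {}
    for data_type, count in config.n_analytes.items():
        prefix = {"protein": "PROT", "metabolite": "MET", "rna": "ENSG", "mirna": "MIR"}.get(
            data_type, data_type.upper()
        )
        ids = [f"{prefix}{i + 1:05d}" for i in range(count)]
        frac = config.age_effect_fraction.get(data_type, 0.0)
        offs = batch_offsets if data_type == "metabolite" else None
        df = _simulate_log2(ids, meta, config, rng, frac, truth, offs)
        _apply_planted_effects(df, meta, config, truth, data_type)
        if data_type == "rna":
            # log2 signal -> NB counts -> log2(CPM + 1), centred at modest depth
            mean_counts = np.clip(2.0 ** (df.to_numpy() - config.baseline_mean + 5.0), 1e-6, None)
            shape = 1.0 / config.rna_dispersion
            lam = rng.gamma(shape, mean_counts / shape)
            counts = rng.poisson(lam).astype(float)
            lib = counts.sum(axis=0)
            lib[lib == 0] = 1.0
            cpm = counts / lib[None, :] * 1e6
            df = pd.DataFrame(np.log2(cpm + 1.0), index=df.index, columns=df.columns)
        df = _mask_below_detection(df, config.missingness_spec.get(data_type, 0.0))
        matrices[data_type] = AnalyteMatrix(values=df, data_type=data_type, scale="log2")
    return matrices, meta, truth


def plant_vgb_effect(
    matrix: AnalyteMatrix, meta: pd.DataFrame, spec: tuple[str, float]
) -> AnalyteMatrix:
    """Multiply vigabatrin-exposed samples of one analyte by a fold change.

    On a log2-scale matrix the effect is additive in log2(fold); on a linear
    matrix it is multiplicative.  Unexposed samples are untouched.
    """
    analyte, fold = spec
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if analyte not in matrix.values.index:
        raise KeyError(f"analyte {analyte!r} not in matrix")
    values = matrix.values.copy()
    exposed = meta.loc[list(values.columns), "vgb"].to_numpy(bool)
    if matrix.scale == "log2":
        values.loc[analyte, exposed] += np.log2(fold)
    else:
        values.loc[analyte, exposed] *= fold
    return matrix.copy_with(values)
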