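import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from episcan import generate_cohort, select_classifier_cohort, validate_metadata
from episcan.synthetic_cohort import CohortConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_metadata(
    n_subjects: int = 12,
    samples_per_subject: int = 3,
    seed: int = 0,
    group: str = "tsc",
) -> pd.DataFrame:
    """Minimal valid longitudinal metadata table for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        subject = f"S{i:03d}"
        n = samples_per_subject if group == "tsc" else 1
        ages = np.sort(rng.uniform(0, 104, size=n))
        for j, age in enumerate(ages):
            rows.append(
                dict(
                    sample_id=f"{subject}_t{j}",
                    subject_id=subject,
                    age_weeks=float(age),
                    batch=int(rng.integers(0, 3)),
                    vgb=bool(rng.random() < 0.3),
                    group=group,
                    seizure_history=False,
                    abnormal_eeg_at_draw=False,
                    seizure_at_draw=False,
                    drug_resistant_24m=False,
                    presymptomatic_vgb=False,
                    timepoint_label=f"t{j}",
                )
            )
    return validate_metadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the default study structure with a small analyte budget."""
    cfg = CohortConfig(n_analytes={"protein": 40, "metabolite": 40, "rna": 40, "mirna": 20})
    matrices, meta, truth = generate_cohort(cfg, seed=11)
    return cfg, matrices, meta, truth


@pytest.fixture(scope="session")
def classifier_cohort():
    """Cohort with three planted seizure predictors plus its selection."""
    cfg = CohortConfig(
        n_analytes={"protein": 25, "metabolite": 25, "mirna": 15},
        planted_predictors=[("PROT00001", 0.85), ("MET00002", 0.85), ("MIR00003", 0.85)],
    )
    matrices, meta, truth = generate_cohort(cfg, seed=5)
    selection = select_classifier_cohort(meta)
    sub = {t: m.subset_samples(selection.sample_ids) for t, m in matrices.items()}
    return sub, selection, truth
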