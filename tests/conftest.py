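import warnings

import numpy as np
import pandas as pd
import pytest

from momics import AnalysisConfig, GeneratorConfig, generate_dataset
from momics.datatypes import FeatureMatrix, MultiOmicsDataset, SubjectTable

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def fast_dataset():
    """Default-condition synthetic study (81 subjects, 5 cohorts, 200/100/150)."""
    return generate_dataset(GeneratorConfig.fast(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """Small, cheap dataset for pipeline mechanics (not for power checks)."""
    cfg = GeneratorConfig(
        n_subjects=30, n_ptb=14, n_cohorts=3,
        dims={"transcriptomics": 40, "proteomics": 25, "metabolomics": 30},
        latent_rank={"transcriptomics": 2, "proteomics": 3, "metabolomics": 4},
        ga_informative=6, ptb_informative=6, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def quick_config():
    return AnalysisConfig(
        seed=11, n_permutations=19, n_bootstrap=200, rf_trees=50,
        stacking_folds=3, k_top=10,
    )


def make_dataset(values_by_modality, cohorts, ga_sampling, ga_delivery,
                 storage=None, extra=None):
    """Assemble a MultiOmicsDataset from raw arrays for toy tests."""
    n = len(cohorts)
    ids = [f"S{i}" for i in range(n)]
    matrices = {}
    for mod, vals in values_by_modality.items():
        vals = np.asarray(vals, dtype=float)
        matrices[mod] = FeatureMatrix(
            mod, ids, [f"{mod[:1].upper()}{j}" for j in range(vals.shape[1])], vals
        )
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "cohort": cohorts,
            "ga_sampling_weeks": ga_sampling,
            "ga_delivery_weeks": ga_delivery,
            "storage_days": storage if storage is not None else np.arange(n) + 100.0,
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return MultiOmicsDataset(subjects=SubjectTable(df), matrices=matrices)
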