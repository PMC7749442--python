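"""Synthetic multi-cohort multiomics generator with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: 81 pregnant participants from 5 cohorts (39 preterm / 42 term by
construction), three feature matrices with modality-specific latent-factor
structure (transcriptomics has the most features but the lowest effective
rank), subtle per-cohort batch shifts, a gestational-age-correlated feature
module shared across cohorts, a partially cohort-specific PTB-informative
module, and a storage-time confound restricted to the urine metabolomics
matrix. Every planted signal is recorded in a :class:`GroundTruth` object so
recovery can be tested.

The generative model is a package choice: the emulated study reports cohort
summaries (maternal age 24.8 +/- 5.3 years, median sampling at 13.6 weeks,
assay dimensionalities 20659/1002/6630) but no data-generating process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from ._utils import MODALITIES, logger
from .datatypes import (
    FeatureMatrix,
    MultiOmicsDataset,
    PathwayCollection,
    SubjectTable,
    ValidationError,
)

FAST_DIMS = {"transcriptomics": 200, "proteomics": 100, "metabolomics": 150}
FULL_DIMS = {"transcriptomics": 20659, "proteomics": 1002, "metabolomics": 6630}

# Transcriptomics carries the most features but is the most internally
# correlated, so it gets the smallest latent rank.
DEFAULT_LATENT_RANK = {"transcriptomics": 3, "proteomics": 10, "metabolomics": 25}

_PREFIX = {"transcriptomics": "T", "proteomics": "P", "metabolomics": "M"}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Effect sizes are in units of the per-feature residual scale. Defaults are
    the conditions the rest of the package is exercised under; the ``fast``
    dims keep runtimes small while the ``full`` dims reproduce the real
    assay widths.
    """

    n_subjects: int = 81
    n_ptb: int = 39
    n_cohorts: int = 5
    dims: dict = field(default_factory=lambda: dict(FAST_DIMS))
    latent_rank: dict = field(default_factory=lambda: dict(DEFAULT_LATENT_RANK))
    cohort_effect_sd: float = 0.4
    ga_informative: int = 20
    ga_effect: float = 1.0
    ptb_informative: int = 20
    ptb_effect: float = 0.6
    cohort_heterogeneity: float = 0.5
    storage_confound_sd: float = 1.0
    noise_sd: float = 0.25
    maternal_age_mean: float = 24.8
    maternal_age_sd: float = 5.3
    ga_sampling_median: float = 13.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_ptb < self.n_subjects):
            raise ValidationError("need 0 < n_ptb < n_subjects")
        for name in ("cohort_effect_sd", "storage_confound_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.cohort_heterogeneity <= 1:
            raise ValidationError("cohort_heterogeneity must be in [0, 1]")
        for mod in MODALITIES:
            if self.dims[mod] < self.ga_informative + self.ptb_informative:
                raise ValidationError(
                    f"{mod}: dims must cover informative feature counts"
                )

    @classmethod
    def fast(cls, seed: int = 0, **kwargs) -> "GeneratorConfig":
        return cls(dims=dict(FAST_DIMS), seed=seed, **kwargs)

    @classmethod
    def full(cls, seed: int = 0, **kwargs) -> "GeneratorConfig":
        return cls(dims=dict(FULL_DIMS), seed=seed, **kwargs)


@dataclass
class GroundTruth:
    """Record of everything the generator planted, keyed by feature id."""

    feature_ids: dict              # modality -> list of feature ids
    ga_features: dict              # modality -> {feature_id: coefficient}
    ptb_features: dict             # modality -> {feature_id: {cohort: effect}}
    storage_features: list         # metabolomics feature ids carrying the confound
    latent_loadings: dict          # modality -> (rank x n_features) array
    cohorts: list
    planted_pathway_id: str | None = None

    def to_json(self, path: str | Path) -> None:
        """Serialize the planted-signal record (loadings omitted for size)."""
        payload = {
            "ga_features": self.ga_features,
            "ptb_features": self.ptb_features,
            "storage_features": self.storage_features,
            "cohorts": self.cohorts,
            "planted_pathway_id": self.planted_pathway_id,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _truncated_normal(
    rng: np.random.Generator, loc, scale, low, high, size
) -> np.ndarray:
    a = (np.asarray(low) - loc) / scale
    b = (np.asarray(high) - loc) / scale
    if np.any(a >= b):
        raise ValidationError("infeasible truncation bounds")
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_dataset(config: GeneratorConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Draw one synthetic study; the same seed yields bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n, n_ptb = config.n_subjects, config.n_ptb

    cohort_names = [f"cohort{i + 1}" for i in range(config.n_cohorts)]
    balanced = np.array(
        [cohort_names[i % config.n_cohorts] for i in range(n)], dtype=object
    )
    cohorts = rng.permutation(balanced)
    cohort_idx = np.array([cohort_names.index(c) for c in cohorts])

    ptb = np.zeros(n, dtype=bool)
    ptb[rng.permutation(n)[:n_ptb]] = True

    # GA at delivery: preterm block strictly below 37 weeks, term at/above.
    ga_delivery = np.empty(n)
    ga_delivery[ptb] = _truncated_normal(rng, 34.0, 1.5, -np.inf, 37.0, n_ptb)
    ga_delivery[~ptb] = _truncated_normal(rng, 39.5, 1.0, 37.0, np.inf, n - n_ptb)

    ga_sampling = _truncated_normal(
        rng, config.ga_sampling_median, 3.0, 8.0, ga_delivery - 4.0, n
    )
    storage_days = rng.uniform(100.0, 1000.0, n)

    z_ga = (ga_sampling - ga_sampling.mean()) / ga_sampling.std()
    z_store = (storage_days - storage_days.mean()) / storage_days.std()

    h = config.cohort_heterogeneity
    matrices: dict[str, FeatureMatrix] = {}
    truth_fids: dict[str, list[str]] = {}
    truth_ga: dict[str, dict[str, float]] = {}
    truth_ptb: dict[str, dict[str, dict[str, float]]] = {}
    truth_load: dict[str, np.ndarray] = {}
    storage_fids: list[str] = []
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    for mod in MODALITIES:
        p = config.dims[mod]
        r = config.latent_rank[mod]
        width = max(4, len(str(p)))
        fids = [f"{_PREFIX[mod]}{j + 1:0{width}d}" for j in range(p)]
        if mod == "proteomics":
            fids[0] = "PGF"  # named target for the urine-surrogate analysis

        # Loadings scaled so the latent part contributes ~unit variance per
        # feature in every modality; the rank alone controls redundancy.
        scores = rng.normal(size=(n, r))
        loadings = rng.normal(size=(r, p)) / np.sqrt(r)
        X = scores @ loadings
        X += rng.normal(0.0, config.cohort_effect_sd, size=(config.n_cohorts, p))[
            cohort_idx
        ]

        # GA module: shared across cohorts, proportional to GA at sampling.
        ga_idx = rng.choice(p, size=config.ga_informative, replace=False)
        if mod == "proteomics" and 0 not in ga_idx:
            ga_idx[0] = 0  # PGF always tracks gestational age
        ga_coef = config.ga_effect * rng.choice([-1.0, 1.0], size=config.ga_informative)
        if mod == "proteomics":
            ga_coef[np.where(ga_idx == 0)[0][0]] = abs(config.ga_effect)
        X[:, ga_idx] += np.outer(z_ga, ga_coef)

        # PTB module: a (1-h) share of the effect is shared, the rest is
        # redrawn per cohort (sign mixing), so case/control separation is
        # partially cohort-specific. On top of that, each cohort applies a
        # lognormal gain exp(h N(0,1)) to the informative columns — the kind
        # of site-specific assay-scale heterogeneity that makes per-cohort
        # standardization necessary. Both vanish at h = 0.
        remaining = np.setdiff1d(np.arange(p), ga_idx)
        ptb_idx = rng.choice(remaining, size=config.ptb_informative, replace=False)
        base_sign = rng.choice([-1.0, 1.0], size=config.ptb_informative)
        cohort_sign = rng.choice(
            [-1.0, 1.0], size=(config.n_cohorts, config.ptb_informative)
        )
        effect = config.ptb_effect * ((1 - h) * base_sign + h * cohort_sign)
        X[:, ptb_idx] += ptb[:, None] * effect[cohort_idx]
        gain = np.exp(h * rng.normal(size=(config.n_cohorts, config.ptb_informative)))

        if mod == "metabolomics" and config.storage_confound_sd > 0:
            n_conf = max(1, int(round(0.1 * p)))
            conf_idx = rng.choice(p, size=n_conf, replace=False)
            X[:, conf_idx] += config.storage_confound_sd * z_store[:, None]
            storage_fids = [fids[j] for j in conf_idx]

        X += rng.normal(0.0, config.noise_sd, size=(n, p))
        # cohort gain rescales the full measured value (signal and noise)
        X[:, ptb_idx] *= gain[cohort_idx]

        matrices[mod] = FeatureMatrix(mod, subject_ids, fids, X)
        truth_fids[mod] = fids
        truth_ga[mod] = {fids[j]: float(c) for j, c in zip(ga_idx, ga_coef)}
        truth_ptb[mod] = {
            fids[j]: {cohort_names[c]: float(effect[c, k]) for c in range(config.n_cohorts)}
            for k, j in enumerate(ptb_idx)
        }
        truth_load[mod] = loadings

    maternal_age = rng.normal(config.maternal_age_mean, config.maternal_age_sd, n)
    birthweight = (
        3300.0 - 180.0 * np.maximum(0.0, 40.0 - ga_delivery) + rng.normal(0, 150.0, n)
    )

    import pandas as pd

    subjects = SubjectTable(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                "cohort": cohorts,
                "ga_sampling_weeks": ga_sampling,
                "ga_delivery_weeks": ga_delivery,
                "storage_days": storage_days,
                "maternal_age_years": maternal_age,
                "birthweight_g": birthweight,
            }
        )
    )
    if int(subjects.ptb.sum()) != n_ptb:
        raise AssertionError("generator failed to plant the exact PTB count")

    truth = GroundTruth(
        feature_ids=truth_fids,
        ga_features=truth_ga,
        ptb_features=truth_ptb,
        storage_features=storage_fids,
        latent_loadings=truth_load,
        cohorts=cohort_names,
    )
    logger.info(
        "generated dataset: %d subjects (%d PTB), dims %s, seed %d",
        n, n_ptb, {m: config.dims[m] for m in MODALITIES}, config.seed,
    )
    return MultiOmicsDataset(subjects=subjects, matrices=matrices), truth


PLANTED_PATHWAY_ID = "PW_planted_ptb_module"


def generate_pathways(
    truth: GroundTruth, n_pathways: int, seed: int
) -> PathwayCollection:
    """Build a GMT-style fixture over the metabolomics universe.

    The first pathway is planted: it contains every PTB-informative
    metabolite (>= 70% overlap with the informative set by construction)
    padded with random metabolites; the rest are uniform draws of size 10-50.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth.feature_ids["metabolomics"])
    informative = sorted(truth.ptb_features["metabolomics"])
    if n_pathways < 1:
        raise ValidationError("n_pathways must be >= 1")
    if len(universe) < 50:
        raise ValidationError("metabolomics universe too small for pathway sizes 10-50")

    members = list(informative[:50])
    target_size = min(50, max(10, int(round(len(members) * 1.5))))
    pool = [f for f in universe if f not in set(members)]
    if target_size > len(members):
        members += list(rng.choice(pool, size=target_size - len(members), replace=False))
    pathways: dict[str, tuple[str, frozenset[str]]] = {
        PLANTED_PATHWAY_ID: ("planted PTB-informative metabolite set", frozenset(members))
    }
    for k in range(1, n_pathways):
        size = int(rng.integers(10, 51))
        draw = rng.choice(universe, size=size, replace=False)
        pathways[f"PW{k:03d}"] = (f"random metabolite set {k}", frozenset(map(str, draw)))
    truth.planted_pathway_id = PLANTED_PATHWAY_ID
    return PathwayCollection(pathways=pathways, universe=frozenset(universe))
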