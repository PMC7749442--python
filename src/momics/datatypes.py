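"""Core in-memory containers for the multiomics analysis.

A study consists of a subject metadata table and one feature matrix per
biological modality (plasma cell-free RNA transcriptomics, plasma targeted
proteomics, urine metabolomics). Preterm birth (PTB) is defined as delivery
before completion of 37 weeks of gestation; the flag is always derived from
gestational age (GA) at delivery, never trusted from input files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._utils import MODALITIES, logger

PTB_THRESHOLD_WEEKS = 37.0

REQUIRED_SUBJECT_COLUMNS = (
    "subject_id",
    "cohort",
    "ga_sampling_weeks",
    "ga_delivery_weeks",
    "storage_days",
)


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class FeatureMatrix:
    """One modality's subjects x features table of normalized abundances."""

    modality: str
    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        for name, ids in (("subject", self.subject_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValidationError(f"duplicate {name} id(s): {sorted(set(dupes))}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_ids,
        )

    def subset_subjects(self, subject_ids: Iterable[str]) -> "FeatureMatrix":
        order = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [order[s] for s in subject_ids]
        return FeatureMatrix(
            self.modality, list(subject_ids), list(self.feature_ids), self.values[idx]
        )


@dataclass
class SubjectTable:
    """Per-subject metadata, clinical covariates, and the derived PTB outcome."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"subject table missing required column(s): {missing}")
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject id(s): {dupes}")
        for col in ("ga_sampling_weeks", "ga_delivery_weeks", "storage_days"):
            df[col] = pd.to_numeric(df[col])
        bad = df["ga_delivery_weeks"] <= df["ga_sampling_weeks"]
        if bad.any():
            raise ValidationError(
                "ga_delivery_weeks <= ga_sampling_weeks for subject(s): "
                f"{df.loc[bad, 'subject_id'].tolist()}"
            )
        if (df["storage_days"] < 0).any():
            raise ValidationError("negative storage_days")
        derived = df["ga_delivery_weeks"] < PTB_THRESHOLD_WEEKS
        if "ptb" in df.columns and not (df["ptb"].astype(bool) == derived).all():
            logger.warning(
                "input 'ptb' column disagrees with ga_delivery_weeks < 37; "
                "it is ignored and recomputed"
            )
        df["ptb"] = derived
        counts = df["cohort"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"cohort(s) with fewer than 2 subjects: {small.index.tolist()}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    @property
    def cohort(self) -> np.ndarray:
        return self.df["cohort"].to_numpy()

    @property
    def ptb(self) -> np.ndarray:
        return self.df["ptb"].to_numpy(dtype=bool)

    @property
    def ga_sampling_weeks(self) -> np.ndarray:
        return self.df["ga_sampling_weeks"].to_numpy(dtype=float)

    @property
    def ga_delivery_weeks(self) -> np.ndarray:
        return self.df["ga_delivery_weeks"].to_numpy(dtype=float)

    @property
    def storage_days(self) -> np.ndarray:
        return self.df["storage_days"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, subject_ids: Iterable[str]) -> "SubjectTable":
        ids = list(subject_ids)
        sub = self.df.set_index("subject_id").loc[ids].reset_index()
        return SubjectTable(sub)


@dataclass
class MultiOmicsDataset:
    """Aligned subject table plus one feature matrix per available modality."""

    subjects: SubjectTable
    matrices: dict[str, FeatureMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValidationError("dataset must contain at least one modality")
        ids = self.subjects.subject_ids
        for mod, mat in self.matrices.items():
            if mat.subject_ids != ids:
                raise ValidationError(
                    f"matrix for {mod} is not aligned with the subject table"
                )

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if m in self.matrices]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def concatenated(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Stack all modalities column-wise; returns (values, feature_ids, tags)."""
        blocks, fids, tags = [], [], []
        for mod in self.modalities:
            mat = self.matrices[mod]
            blocks.append(mat.values)
            fids.extend(mat.feature_ids)
            tags.extend([mod] * mat.n_features)
        return np.hstack(blocks), fids, tags


@dataclass
class PathwayCollection:
    """Named feature sets (pathways) over a feature universe, as read from GMT."""

    pathways: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway {pid} is empty")
            extra = members - self.universe
            if extra:
                raise ValidationError(
                    f"pathway {pid} has members outside the universe: {sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class AnalysisConfig:
    """Tunable settings shared by the cross-validated analyses.

    All randomized operations derive their generators from ``seed`` so a run
    is reproducible end to end. Counts are deliberately generous defaults;
    tests and quick exploratory runs pass smaller values.
    """

    seed: int = 0
    outer_folds: int = 10
    inner_folds: int = 5
    stacking_folds: int = 5
    k_top: int = 50
    n_permutations: int = 1000
    n_bootstrap: int = 2000
    rf_trees: int = 500
    logistic_C_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    lasso_n_alphas: int = 30
    tsne_perplexity: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "outer_folds", "inner_folds", "stacking_folds", "k_top",
            "n_permutations", "n_bootstrap", "rf_trees", "lasso_n_alphas",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        self.seed = int(self.seed)

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kwargs = dict(d)
        if "logistic_C_grid" in kwargs:
            kwargs["logistic_C_grid"] = tuple(kwargs["logistic_C_grid"])
        return cls(**kwargs)
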