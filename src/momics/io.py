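"""Readers and writers for the TSV/GMT/JSON formats the pipeline uses.

Feature matrices are plain TSV: header row of feature ids, first column of
subject ids. Empty cells are imputed at load time with the per-feature median
(computed on the full column); the imputation count is logged. The subject
table is TSV with a fixed set of required columns; any additional columns are
carried along as clinical covariates.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import logger
from .datatypes import (
    REQUIRED_SUBJECT_COLUMNS,
    AnalysisConfig,
    FeatureMatrix,
    MultiOmicsDataset,
    PathwayCollection,
    SubjectTable,
    ValidationError,
)


def read_feature_matrix(path: str | Path, modality: str) -> FeatureMatrix:
    """Load one modality's TSV table, imputing empty cells with column medians."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate subject id(s): {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature id(s): {dupes}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at subject {df.index[r]!r}, "
            f"feature {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        medians = numeric.median(axis=0)
        if medians.isna().any():
            empty = medians.index[medians.isna()].tolist()
            raise ValidationError(f"{path}: feature(s) entirely missing: {empty}")
        numeric = numeric.fillna(medians)
        logger.info("imputed %d missing cell(s) in %s with feature medians", n_missing, path)
    return FeatureMatrix(
        modality=modality,
        subject_ids=df.index.tolist(),
        feature_ids=[str(c) for c in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_subject_table(path: str | Path) -> SubjectTable:
    """Load the subject metadata TSV; the PTB flag is derived, never read."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")
    return SubjectTable(df)


def write_subject_table(subjects: SubjectTable, path: str | Path) -> None:
    # ptb is derived at load time, never stored
    subjects.df.drop(columns=["ptb"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def align_dataset(
    subjects: SubjectTable, matrices: list[FeatureMatrix]
) -> MultiOmicsDataset:
    """Intersect subject ids across the table and all matrices; impose one order."""
    common = set(subjects.subject_ids)
    for mat in matrices:
        common &= set(mat.subject_ids)
    if not common:
        raise ValidationError("no subjects shared by the subject table and all matrices")
    ordered = [s for s in subjects.subject_ids if s in common]
    dropped = sorted(
        (set(subjects.subject_ids) | set().union(*(set(m.subject_ids) for m in matrices)))
        - common
    )
    if dropped:
        logger.info("align_dataset dropped %d subject(s): %s", len(dropped), dropped)
    return MultiOmicsDataset(
        subjects=subjects.subset(ordered),
        matrices={m.modality: m.subset_subjects(ordered) for m in matrices},
    )


def read_gmt(path: str | Path, universe: set[str] | None = None) -> PathwayCollection:
    """Parse a GMT file: one pathway per line (id, description, members...)."""
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            pid, desc, *members = fields
            members = [m for m in members if m]
            if pid in pathways:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = (desc, frozenset(members))
    if not pathways:
        raise ValidationError(f"{path}: no pathways found")
    if universe is None:
        universe = set().union(*(m for _, m in pathways.values()))
    return PathwayCollection(pathways=pathways, universe=frozenset(universe))


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, (desc, members) in collection.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    outdir: str | Path,
    stage: str,
    config: AnalysisConfig | None = None,
    inputs: list[str | Path] | None = None,
    extra: dict | None = None,
) -> Path:
    """Record stage, config, seed, and input checksums beside the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict() if config is not None else None,
        "inputs": {
            str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    if extra:
        manifest.update(extra)
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
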