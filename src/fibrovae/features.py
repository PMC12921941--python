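"""Clinical-table encoding, z-score normalization and multimodal fusion.

The model input for patient *i* is x_i = [clinical block | embedding block]:
the a-priori core clinical feature set (continuous variables z-scored, binary
indicators passed through as 0/1) concatenated with the z-scored imaging
embedding.  Normalization statistics are fitted on the full cohort — the
analysis is descriptive and uses no train/validation split — and are stored so
anomaly scores are exactly reproducible.

No imputation is performed: the core feature set is required to be complete,
and any missing value is an error naming the affected patients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CORE_BINARY, CORE_COLUMNS, CORE_CONTINUOUS

__all__ = [
    "NormalizationStats",
    "MultimodalMatrix",
    "encode_binaries",
    "fit_normalizer",
    "build_multimodal_matrix",
    "BINARY_CODING",
]

# Documented 0/1 coding dictionaries for the binary indicators:
# female -> 0 / male -> 1; no -> 0 / yes -> 1.
BINARY_CODING: dict[str, dict] = {
    "sex": {"F": 0, "f": 0, "female": 0, "M": 1, "m": 1, "male": 1},
    "_default": {"no": 0, "yes": 1, "No": 0, "Yes": 1, False: 0, True: 1},
}


def encode_binaries(table: pd.DataFrame) -> pd.DataFrame:
    """Map binary columns to {0, 1} by the documented coding dictionaries.

    Columns already coded {0, 1} are left unchanged.  A binary column with
    three or more categories is an error naming the column.
    """
    out = table.copy()
    for col in CORE_BINARY:
        if col not in out.columns:
            continue
        values = out[col]
        uniques = pd.unique(values.dropna())
        if set(uniques) <= {0, 1, 0.0, 1.0}:
            out[col] = values.astype(int)
            continue
        if len(uniques) > 2:
            raise ValueError(
                f"binary column {col!r} has {len(uniques)} categories: {sorted(map(str, uniques))}"
            )
        coding = BINARY_CODING.get(col, BINARY_CODING["_default"])
        try:
            out[col] = values.map(lambda v: coding[v]).astype(int)
        except KeyError as exc:
            raise ValueError(f"binary column {col!r}: unknown category {exc}") from exc
    return out


@dataclass
class NormalizationStats:
    """Per-column mean/SD for continuous clinical columns and embedding
    dimensions (sample SD, n-1 denominator), plus the zero-variance columns
    dropped from the model input."""

    clinical_mean: dict[str, float]
    clinical_sd: dict[str, float]
    embed_mean: list[float]
    embed_sd: list[float]
    dropped: list[str] = field(default_factory=list)
    clinical_columns: list[str] = field(default_factory=lambda: list(CORE_COLUMNS))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        return cls(**json.loads(Path(path).read_text()))


def _check_complete(table: pd.DataFrame, columns: list[str]) -> None:
    missing_mask = table[columns].isna().any(axis=1)
    if missing_mask.any():
        ids = list(table.index[missing_mask])
        raise ValueError(
            f"core feature set incomplete (no imputation is performed); "
            f"patients with missing values: {ids}"
        )


def fit_normalizer(
    table: pd.DataFrame, embeddings: pd.DataFrame | None = None
) -> NormalizationStats:
    """Fit z-score statistics over the full cohort.

    Continuous clinical columns and every embedding dimension get a mean and
    sample SD; zero-variance columns are recorded as dropped (with a warning)
    rather than epsilon-inflated.
    """
    present = [c for c in CORE_COLUMNS if c in table.columns]
    _check_complete(table, present)
    cont = [c for c in CORE_CONTINUOUS if c in table.columns]

    dropped: list[str] = []
    cmean: dict[str, float] = {}
    csd: dict[str, float] = {}
    for c in cont:
        x = table[c].astype(float).to_numpy()
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd <= 0.0:
            dropped.append(c)
            continue
        cmean[c] = float(np.mean(x))
        csd[c] = sd

    emean: list[float] = []
    esd: list[float] = []
    if embeddings is not None:
        E = embeddings.to_numpy(dtype=float)
        if np.isnan(E).any():
            bad = list(embeddings.index[np.isnan(E).any(axis=1)])
            raise ValueError(f"embeddings contain missing values for patients: {bad}")
        mu = E.mean(axis=0)
        sd = E.std(axis=0, ddof=1) if E.shape[0] > 1 else np.zeros(E.shape[1])
        for j, (m, s) in enumerate(zip(mu, sd)):
            if s <= 0.0:
                dropped.append(str(embeddings.columns[j]))
                emean.append(float(m))
                esd.append(0.0)
            else:
                emean.append(float(m))
                esd.append(float(s))

    if dropped:
        warnings.warn(f"dropping zero-variance columns from model input: {dropped}", stacklevel=2)
    return NormalizationStats(
        clinical_mean=cmean,
        clinical_sd=csd,
        embed_mean=emean,
        embed_sd=esd,
        dropped=dropped,
        clinical_columns=present,
    )


@dataclass
class MultimodalMatrix:
    """The fused model input: one row per patient, clinical block first.

    ``block_boundary`` is the column index where the embedding block starts.
    """

    x: np.ndarray
    patient_ids: list[str]
    columns: list[str]
    block_boundary: int

    @property
    def d(self) -> int:
        return self.x.shape[1]


def build_multimodal_matrix(
    table: pd.DataFrame,
    embeddings: pd.DataFrame | None,
    stats: NormalizationStats,
) -> MultimodalMatrix:
    """Concatenate the z-scored clinical block and embedding block.

    Rows are ordered by sorted patient id.  Binary indicators pass through
    unscaled; zero-variance columns recorded in ``stats.dropped`` are absent
    from the output.  The two inputs must cover identical patient-id sets.
    """
    if embeddings is not None:
        tab_ids, emb_ids = set(table.index), set(embeddings.index)
        if tab_ids != emb_ids:
            diff = sorted(map(str, tab_ids.symmetric_difference(emb_ids)))
            raise ValueError(f"patient-id mismatch between clinical table and embeddings: {diff}")

    ids = sorted(map(str, table.index))
    table = table.loc[ids]
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for c in stats.clinical_columns:
        if c in stats.dropped:
            continue
        if c in CORE_BINARY:
            v = table[c].astype(float).to_numpy()
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError(f"binary column {c!r} not coded 0/1; run encode_binaries first")
            blocks.append(v)
        else:
            v = table[c].astype(float).to_numpy()
            blocks.append((v - stats.clinical_mean[c]) / stats.clinical_sd[c])
        cols.append(c)
    boundary = len(cols)

    if embeddings is not None:
        embeddings = embeddings.loc[ids]
        E = embeddings.to_numpy(dtype=float)
        mu = np.asarray(stats.embed_mean)
        sd = np.asarray(stats.embed_sd)
        keep = sd > 0.0
        Z = (E[:, keep] - mu[keep]) / sd[keep]
        blocks.extend(Z.T)
        cols.extend(str(c) for c, k in zip(embeddings.columns, keep) if k)

    if not blocks:
        raise ValueError("no usable columns: every column was dropped as zero-variance")
    X = np.column_stack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("multimodal matrix contains non-finite values")
    return MultimodalMatrix(x=X, patient_ids=ids, columns=cols, block_boundary=boundary)
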