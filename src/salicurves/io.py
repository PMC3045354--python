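"""Readers and writers for the package's plain-text interchange formats.

Activity tables, structure files (SMILES-CSV and SDF) and square similarity
matrices all travel as UTF-8 CSV (or SD files) with mandatory headers.
Ids are strings and matched exactly, never case-folded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

PREDICTION_PREFIX = "predicted_"


@dataclass
class CompoundRecord:
    """One compound: unique id, optional SMILES, optional descriptor vector."""

    id: str
    smiles: str | None = None
    descriptors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("compound id must be non-empty")


@dataclass
class ActivityTable:
    """Observed activities plus any number of named prediction columns.

    All values are finite floats; every prediction column covers every id.
    Row order is preserved on read/write but never affects downstream
    SALI or metric values.
    """

    ids: list[str]
    observed: np.ndarray
    predictions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate compound ids: {dupes[:5]}")
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (len(self.ids),):
            raise ValidationError("observed activities do not match the id list")
        if not np.all(np.isfinite(self.observed)):
            raise ValidationError("observed activities contain non-finite values")
        for name, col in self.predictions.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (len(self.ids),):
                raise ValidationError(f"prediction column {name!r} does not cover every id")
            if not np.all(np.isfinite(col)):
                raise ValidationError(f"prediction column {name!r} contains non-finite values")
            self.predictions[name] = col

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def models(self) -> list[str]:
        return list(self.predictions)

    def subset(self, ids: Sequence[str]) -> "ActivityTable":
        pos = {c: k for k, c in enumerate(self.ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise ValidationError(f"ids absent from activity table: {missing[:5]}")
        idx = np.array([pos[c] for c in ids])
        return ActivityTable(
            list(ids),
            self.observed[idx],
            {m: v[idx] for m, v in self.predictions.items()},
        )

    def transform_observed(self, fn) -> "ActivityTable":
        """Apply `fn` to observed and every prediction column (e.g. log10)."""
        return ActivityTable(
            list(self.ids),
            fn(self.observed),
            {m: fn(v) for m, v in self.predictions.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "observed": self.observed}
        for m, v in self.predictions.items():
            data[f"{PREDICTION_PREFIX}{m}"] = v
        return pd.DataFrame(data)


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() | ~np.isfinite(vals.fillna(np.inf))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r} at data row {row + 1}"
        )
    return vals.to_numpy(dtype=float)


def read_activity_table(
    path,
    id_col: str = "id",
    observed_col: str = "observed",
    prediction_cols: Sequence[str] | None = None,
) -> ActivityTable:
    """Read an activity CSV.

    Prediction columns default to every column named ``predicted_<model>``;
    the model name is the suffix. Explicit `prediction_cols` are used verbatim
    as model names.
    """
    df = pd.read_csv(path, dtype={id_col: str})
    for col in (id_col, observed_col):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: required column {col!r} not found")
    if prediction_cols is None:
        pred_map = {
            c[len(PREDICTION_PREFIX):]: c
            for c in df.columns
            if c.startswith(PREDICTION_PREFIX)
        }
    else:
        missing = [c for c in prediction_cols if c not in df.columns]
        if missing:
            raise ConfigurationError(f"{path}: prediction columns not found: {missing}")
        pred_map = {c: c for c in prediction_cols}
    ids = df[id_col].astype(str).tolist()
    observed = _numeric_column(df, observed_col, path)
    predictions = {m: _numeric_column(df, c, path) for m, c in pred_map.items()}
    return ActivityTable(ids, observed, predictions)


def write_activity_table(table: ActivityTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_structures(
    path,
    fmt: str | None = None,
    id_col: str = "id",
    smiles_col: str = "smiles",
    sdf_id_prop: str | None = None,
) -> list[CompoundRecord]:
    """Read structures from a SMILES-CSV or an SD file.

    Unparseable molecules are skipped with a logged warning (their ids are
    recorded); downstream operations then work on the intersection of ids.
    Zero valid molecules is an error.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smiles-csv"
    records: list[CompoundRecord] = []
    skipped: list[str] = []
    if fmt == "smiles-csv":
        df = pd.read_csv(path, dtype=str)
        for col in (id_col, smiles_col):
            if col not in df.columns:
                raise ConfigurationError(f"{path}: required column {col!r} not found")
        for cid, smi in zip(df[id_col], df[smiles_col]):
            cid = str(cid)
            if pd.isna(smi) or Chem.MolFromSmiles(str(smi)) is None:
                skipped.append(cid)
                continue
            records.append(CompoundRecord(cid, str(smi)))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for k, mol in enumerate(supplier):
            if mol is None:
                skipped.append(f"<entry {k}>")
                continue
            if sdf_id_prop and mol.HasProp(sdf_id_prop):
                cid = mol.GetProp(sdf_id_prop)
            elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                cid = mol.GetProp("_Name").strip()
            else:
                cid = f"mol{k}"
            records.append(CompoundRecord(cid, Chem.MolToSmiles(mol)))
    else:
        raise ConfigurationError(f"unknown structure format {fmt!r}")
    if skipped:
        logger.warning("%s: skipped %d unparseable molecule(s): %s", path, len(skipped), skipped[:10])
    if not records:
        raise ParseError(f"{path}: no valid molecules")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate structure ids")
    return records


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a square similarity CSV with matching row/column id headers."""
    df = pd.read_csv(path, index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValidationError(f"{path}: row and column ids do not match")
    values = df.to_numpy(dtype=float)
    try:
        return SimilarityMatrix(row_ids, values)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path)
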