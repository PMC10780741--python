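"""Domain containers for multimodal maternal-fetal cohorts.

A cohort is a plain rectangular table: one row per subject, one numeric
column per feature, plus one continuous positive target (birth weight in
grams).  Features are grouped into named *modalities* — measurement routes
such as maternal anthropometrics, fetal ultrasound biometry, Doppler
velocimetry and maternal ultrasound — and the modality partition drives the
per-block kernels of the multiple-kernel regressor.

Files are comma-separated UTF-8 with one header row; the modality schema is
a small YAML document mapping each feature to its modality.  Loading is
strict: missing cells, duplicate names or features absent from the schema
are errors, never silently repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureTable",
    "ModalitySchema",
    "StandardizationParams",
    "load_table",
    "write_table",
    "write_schema",
    "standardize",
    "correlation_map",
]


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix with a continuous positive target.

    Parameters
    ----------
    sample_ids : list of str
        Opaque per-subject identifiers, unique.
    feature_names : list of str
        Ordered feature names, unique.
    values : ndarray of shape (n_samples, n_features)
        Numeric feature matrix; units are per feature (cm, kg, mm, ...).
    target : ndarray of shape (n_samples,)
        Strictly positive outcome values (grams for birth weight).
    target_name : str
        Label of the target column, default ``"BW"``.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    target: np.ndarray
    target_name: str = "BW"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        target = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "target", target)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = values.shape
        if n < 1 or d < 1:
            raise ValueError("need at least one sample and one feature")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match values")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if target.shape != (n,):
            raise ValueError("target length does not match values")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite entries")
        if not np.all(np.isfinite(target)):
            raise ValueError("target contains non-finite entries")
        if np.any(target <= 0):
            raise ValueError("all target values must be > 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return one feature column by name."""
        return self.values[:, self.feature_names.index(name)]

    def select_features(self, names: list[str]) -> "FeatureTable":
        """Restrict to the given features, preserving the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(self, feature_names=list(names), values=self.values[:, idx])

    def subset(self, sample_ids: list[str]) -> "FeatureTable":
        """Restrict to the given samples, preserving the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            values=self.values[idx],
            target=self.target[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "ID", self.sample_ids)
        df[self.target_name] = self.target
        return df


@dataclass(frozen=True)
class ModalitySchema:
    """Assignment of every feature to exactly one named modality."""

    modalities: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.modalities) < 1:
            raise ValueError("need at least one modality")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError("modality names must be unique")
        unknown = {m for m in self.assignment.values() if m not in self.modalities}
        if unknown:
            raise ValueError(f"assignment references undeclared modalities: {sorted(unknown)}")

    def features_of(self, modality: str) -> list[str]:
        return [f for f, m in self.assignment.items() if m == modality]

    def validate_against(self, table: FeatureTable) -> None:
        """Check the schema covers the table's features exactly once each."""
        missing = [f for f in table.feature_names if f not in self.assignment]
        if missing:
            raise ValueError(f"features missing from schema: {missing}")

    def restrict(self, feature_names: list[str]) -> "ModalitySchema":
        """Keep only the given features; drop modalities left empty."""
        assignment = {f: self.assignment[f] for f in feature_names}
        modalities = [m for m in self.modalities if m in set(assignment.values())]
        if not modalities:
            raise ValueError("restriction leaves no modality with features")
        return ModalitySchema(modalities=modalities, assignment=assignment)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature z-score location/scale, fitted on training data only.

    Uses the sample standard deviation (n-1 denominator).  Constant columns
    get scale 1 and location equal to the constant, so they transform to 0.
    """

    feature_names: list[str]
    location: np.ndarray
    scale: np.ndarray
    target_location: float = 0.0
    target_scale: float = 1.0

    @classmethod
    def fit(cls, table: FeatureTable) -> "StandardizationParams":
        loc = table.values.mean(axis=0)
        if table.n_samples > 1:
            scale = table.values.std(axis=0, ddof=1)
            t_scale = float(np.std(table.target, ddof=1))
        else:
            scale = np.zeros(table.n_features)
            t_scale = 0.0
        scale = np.where(scale > 0, scale, 1.0)
        t_scale = t_scale if t_scale > 0 else 1.0
        return cls(
            feature_names=list(table.feature_names),
            location=loc,
            scale=scale,
            target_location=float(table.target.mean()),
            target_scale=t_scale,
        )


def standardize(
    table: FeatureTable, params: StandardizationParams | None = None
) -> tuple[FeatureTable, StandardizationParams]:
    """Z-score the feature columns of *table*.

    With ``params=None`` the location/scale are fitted on *table* itself;
    otherwise the given parameters are applied unchanged — the contract for
    transforming validation/test folds with training-fold statistics.  The
    target column is never touched here.
    """
    if params is None:
        params = StandardizationParams.fit(table)
    elif list(params.feature_names) != list(table.feature_names):
        raise ValueError("standardization params were fitted on different features")
    values = (table.values - params.location) / params.scale
    return replace(table, values=values), params


def correlation_map(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlation matrix over all features plus the target.

    Constant columns get correlation 0 against everything (diagonal stays 1)
    with a warning, since the Pearson coefficient is undefined for them.
    """
    if table.n_samples < 2:
        raise ValueError("correlation requires at least 2 samples")
    names = list(table.feature_names) + [table.target_name]
    data = np.column_stack([table.values, table.target])
    sd = data.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant columns reported with zero correlation: "
            f"{[n for n, c in zip(names, constant) if c]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def write_table(table: FeatureTable, path) -> None:
    """Write a cohort as CSV (UTF-8, '.' decimal, header row)."""
    # default str() formatting is the shortest exact representation, so
    # write -> load round-trips bit-identically
    table.to_frame().to_csv(path, index=False)


def write_schema(schema: ModalitySchema, path) -> None:
    """Write a modality schema as YAML."""
    doc = {
        "modalities": list(schema.modalities),
        "features": dict(schema.assignment),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schema(path) -> ModalitySchema:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "features" not in doc:
        raise ValueError(f"schema file {path} must map 'features' to modality names")
    assignment = dict(doc["features"])
    modalities = list(doc.get("modalities") or dict.fromkeys(assignment.values()))
    return ModalitySchema(modalities=modalities, assignment=assignment)


def load_table(
    path, target_name: str = "BW", schema_path=None, id_column: str = "ID"
) -> tuple[FeatureTable, ModalitySchema | None]:
    """Load a cohort CSV and, optionally, its modality schema.

    Strict complete-case loading: any missing or non-numeric cell is an
    error naming the offending row and column.  Every non-target column must
    appear in the schema when one is given.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if target_name not in df.columns:
        raise ValueError(f"target column {target_name!r} not found in {path}")
    if id_column in df.columns:
        sample_ids = [str(s) for s in df[id_column]]
        df = df.drop(columns=[id_column])
    else:
        sample_ids = [str(i) for i in range(len(df))]
    feature_names = [c for c in df.columns if c != target_name]
    if len(set(feature_names)) != len(feature_names):
        raise ValueError("duplicate feature names in header")

    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        stripped = df[col].str.strip()
        empty = stripped == ""
        if empty.any():
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise ValueError(f"missing value at row {row + 2}, column {col!r}")
        values = np.empty(len(stripped))
        for i, cell in enumerate(stripped):
            try:
                # Python's float() is an exact IEEE-754 parse, so loading
                # reproduces written values bit-identically
                values[i] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at row {i + 2}, column {col!r}"
                ) from None
        numeric[col] = values

    table = FeatureTable(
        sample_ids=sample_ids,
        feature_names=feature_names,
        values=numeric[feature_names].to_numpy(),
        target=numeric[target_name].to_numpy(),
        target_name=target_name,
    )
    schema = None
    if schema_path is not None:
        schema = load_schema(schema_path)
        schema.validate_against(table)
    return table, schema
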