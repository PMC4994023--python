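"""Typed containers and delimited-text I/O for the core matrices.

The learning problem is posed on two aligned tables: a cell-line-by-feature
matrix ``X`` (expression / copy-number / binary mutation columns, complete
after upstream preprocessing) and a cell-line-by-drug response matrix ``Y``
(activity area, AUC, or -log10 GI50 depending on the screen).  Responses may
be missing per (cell line, drug) pair, which is what makes the transductive
setting possible; that missingness is carried as an explicit boolean mask.
Features are never missing.

All on-disk formats are plain delimited text: matrices as TSV/CSV with a
header row of column ids and a first column of row ids, drug annotations as
two-column TSV, and gene sets as GMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "FeatureMatrix",
    "ResponseMatrix",
    "read_feature_matrix",
    "read_response_matrix",
    "write_feature_matrix",
    "write_response_matrix",
    "align",
    "read_drug_annotation",
    "read_gmt",
    "GeneSetCollection",
]


class DataValidationError(ValueError):
    """An input table violates a structural invariant (labels, shape, dtype)."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what}: {dups}")


@dataclass
class FeatureMatrix:
    """N cell lines x P molecular features, fully observed.

    Mixed continuous and {0,1} mutation-indicator columns are allowed; the
    container does not distinguish them.
    """

    values: np.ndarray
    cell_line_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_line_ids = [str(c) for c in self.cell_line_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise DataValidationError(
                f"feature matrix needs N>=2 rows and P>=1 columns, got {n}x{p}"
            )
        if len(self.cell_line_ids) != n or len(self.feature_ids) != p:
            raise DataValidationError("label lengths do not match matrix shape")
        _check_unique(self.cell_line_ids, "cell line ids")
        _check_unique(self.feature_ids, "feature ids")
        if not np.isfinite(self.values).all():
            raise DataValidationError("feature matrix contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_line_ids, columns=self.feature_ids)


@dataclass
class ResponseMatrix:
    """N cell lines x T drugs with an observed-entry mask.

    ``mask[i, t]`` is True exactly where a response was measured; masked-out
    entries hold NaN-like placeholders and must never influence a fit.
    """

    values: np.ndarray
    mask: np.ndarray
    cell_line_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.cell_line_ids = [str(c) for c in self.cell_line_ids]
        self.drug_ids = [str(d) for d in self.drug_ids]
        if self.values.shape != self.mask.shape:
            raise DataValidationError("response mask shape does not match values")
        n, t = self.values.shape
        if len(self.cell_line_ids) != n or len(self.drug_ids) != t:
            raise DataValidationError("label lengths do not match matrix shape")
        _check_unique(self.cell_line_ids, "cell line ids")
        _check_unique(self.drug_ids, "drug ids")
        if not np.isfinite(self.values[self.mask]).all():
            raise DataValidationError("observed responses contain non-finite entries")
        empty = np.flatnonzero(self.mask.sum(axis=0) == 0)
        for t_idx in empty:
            warnings.warn(
                f"drug {self.drug_ids[t_idx]!r} has no observed responses",
                stacklevel=2,
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    def observed_counts(self) -> np.ndarray:
        return self.mask.sum(axis=0)

    def to_frame(self, na_token: str = "NA") -> pd.DataFrame:
        vals = self.values.astype(object)
        vals[~self.mask] = na_token
        return pd.DataFrame(vals, index=self.cell_line_ids, columns=self.drug_ids)


def _read_table(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    if df.index.hasnans or df.columns.hasnans:
        raise DataValidationError(f"{path}: missing row or column label")
    return df


def read_feature_matrix(path, delimiter: str = "\t") -> FeatureMatrix:
    """Read a TSV/CSV with feature ids in the header and cell-line ids in column 0."""
    df = _read_table(path, delimiter)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValidationError(f"{path}: non-numeric feature value ({exc})") from exc
    return FeatureMatrix(values, list(df.index), list(df.columns))


def write_feature_matrix(fm: FeatureMatrix, path, delimiter: str = "\t") -> None:
    fm.to_frame().to_csv(path, sep=delimiter, index_label="")


def read_response_matrix(path, na_token: str = "NA", delimiter: str = "\t") -> ResponseMatrix:
    """Read a response table; cells equal to ``na_token`` become mask=False."""
    df = _read_table(path, delimiter)
    raw = df.to_numpy(dtype=object)
    mask = raw != na_token
    values = np.zeros(raw.shape, dtype=float)
    try:
        values[mask] = raw[mask].astype(float)
    except ValueError as exc:
        raise DataValidationError(f"{path}: non-numeric response value ({exc})") from exc
    values[~mask] = np.nan
    return ResponseMatrix(values, mask, list(df.index), list(df.columns))


def write_response_matrix(
    rm: ResponseMatrix, path, na_token: str = "NA", delimiter: str = "\t"
) -> None:
    rm.to_frame(na_token).to_csv(path, sep=delimiter, index_label="")


def align(fm: FeatureMatrix, rm: ResponseMatrix) -> tuple[FeatureMatrix, ResponseMatrix]:
    """Restrict both matrices to their common cell lines, sorted by id.

    The sorted order (rather than either input order) keeps every seeded
    downstream split reproducible regardless of file row order.  Idempotent.
    """
    common = sorted(set(fm.cell_line_ids) & set(rm.cell_line_ids))
    if not common:
        raise DataValidationError("feature and response matrices share no cell lines")
    f_pos = {c: i for i, c in enumerate(fm.cell_line_ids)}
    r_pos = {c: i for i, c in enumerate(rm.cell_line_ids)}
    f_idx = [f_pos[c] for c in common]
    r_idx = [r_pos[c] for c in common]
    fm_out = FeatureMatrix(fm.values[f_idx], common, list(fm.feature_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # row subsetting may empty a drug; caller decides
        rm_out = ResponseMatrix(rm.values[r_idx], rm.mask[r_idx], common, list(rm.drug_ids))
    return fm_out, rm_out


def read_drug_annotation(path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column table mapping drug_id -> mechanism-of-action class."""
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected two columns (drug_id, class)")
    mapping: dict[str, str] = {}
    for drug, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if drug in mapping and mapping[drug] != cls:
            raise DataValidationError(f"{path}: drug {drug!r} annotated twice")
        mapping[drug] = cls
    return mapping


@dataclass
class GeneSetCollection:
    """Named feature sets plus the background universe they are tested against.

    Set members are intersected with the background on construction so the
    hypergeometric contingency is always well defined.
    """

    sets: dict[str, list[str]]
    background: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.background:
            universe: set[str] = set()
            for members in self.sets.values():
                universe |= set(members)
            self.background = sorted(universe)
        bg = set(self.background)
        trimmed = {}
        for name, members in self.sets.items():
            kept = [m for m in dict.fromkeys(members) if m in bg]
            if kept:
                trimmed[name] = kept
        if not trimmed:
            raise DataValidationError("no gene set has members in the background")
        self.sets = trimmed

    def restrict_background(self, features: list[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: m for n, m in self.sets.items()},
            background=sorted(set(self.background) & set(features)),
        )


def read_gmt(path, background: list[str] | None = None) -> GeneSetCollection:
    """Read GMT: one set per line, ``name<TAB>description<TAB>member...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    if not sets:
        raise DataValidationError(f"{path}: no gene sets parsed")
    return GeneSetCollection(sets, background=background or [])
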