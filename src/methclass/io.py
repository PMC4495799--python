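"""Reading, writing and merging beta-value matrices, labels and blacklists.

Beta matrices are delimited text (TSV or CSV, autodetected) in the style of
GEO series-matrix exports: one header row of sample IDs and one leading
column of probe IDs (or the transpose, with ``orientation="samples_as_rows"``).
Missing cells may be empty, ``NA`` or ``NaN`` (case-insensitive). Internally
a matrix is always probes × samples with ``NaN`` marking missing betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from .errors import ClassifierFormatError, InputError

logger = logging.getLogger(__name__)

#: Missing-value tokens accepted in delimited input (case-insensitive).
MISSING_TOKENS = ("", "NA", "NaN", "NAN", "nan", "na", "Na", "naN", "nA")

#: Version string embedded in serialized classifiers.
FORMAT_VERSION = "1"


@dataclass(frozen=True)
class BetaMatrix:
    """Probes × samples grid of methylation beta values in [0, 1].

    Wraps a :class:`pandas.DataFrame` whose index holds probe IDs and whose
    columns hold sample IDs; missing betas are ``NaN``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df.index.name = None
        self.df.columns.name = None
        if self.df.shape[0] == 0 or self.df.shape[1] == 0:
            raise InputError("beta matrix is empty")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate probe IDs: {dups[:5]}")
        if self.df.columns.has_duplicates:
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.df.to_numpy()
        if not np.issubdtype(vals.dtype, np.floating):
            raise InputError("beta matrix must be numeric")
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InputError(
                "beta out of range: value "
                f"{vals[i, j]!r} at probe {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        """Probe × sample float array (NaN = missing)."""
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @property
    def n_missing(self) -> int:
        return int(self.df.isna().to_numpy().sum())

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.df.index]
        if missing:
            raise InputError(f"probes absent from matrix: {missing[:10]}")
        return BetaMatrix(self.df.loc[list(probe_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.df.columns]
        if missing:
            raise InputError(f"samples absent from matrix: {missing[:10]}")
        return BetaMatrix(self.df[list(sample_ids)])


@dataclass(frozen=True)
class LabelMap:
    """Mapping sample_id → class label."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise InputError("label map is empty")

    @property
    def classes(self) -> list[str]:
        """Class labels, lexicographically sorted (fixed report order)."""
        return sorted(set(self.mapping.values()))

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise InputError(f"samples without a class label: {missing[:10]}")
        return np.array([self.mapping[s] for s in sample_ids], dtype=object)

    def __getitem__(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class ProbeBlacklist:
    """Set of probe IDs to exclude (SNP-overlapping, repeats, multi-mappers)."""

    probes: frozenset[str]

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "ProbeBlacklist":
        return cls(frozenset(ids))

    def __len__(self) -> int:
        return len(self.probes)


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise InputError(f"{path}: cannot detect delimiter (no tab or comma in header)")


def read_beta_matrix(path, orientation: str = "probes_as_rows") -> BetaMatrix:
    """Read a delimited beta matrix.

    Parameters
    ----------
    path
        TSV/CSV file with one header row of IDs and one leading ID column.
    orientation
        ``"probes_as_rows"`` (default) or ``"samples_as_rows"``; the result
        is always normalized to probes as rows.
    """
    if orientation not in ("probes_as_rows", "samples_as_rows"):
        raise InputError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
            dtype=str,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"{path}: malformed delimited file: {exc}") from exc
    if df.index.isna().any() or any(c.startswith("Unnamed:") for c in df.columns):
        raise InputError(f"{path}: malformed header row or ID column")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise InputError(f"{path}: non-numeric cell: {exc}") from exc
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_as_rows":
        df = df.T
    return BetaMatrix(df)


def write_beta_matrix(m: BetaMatrix, path, sep: str = "\t") -> None:
    """Write probes-as-rows delimited text; missing cells become ``NA``."""
    m.df.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


def read_labels(path) -> LabelMap:
    """Read a two-column sample_id / class_label table (TSV or CSV)."""
    path = Path(path)
    sep = _sniff_sep(path)
    rows = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if rows.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (sample_id, class_label)")
    if rows.iloc[0, 0] in ("sample_id", "sample"):
        rows = rows.iloc[1:]
    ids = rows.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate sample IDs in label table")
    return LabelMap(dict(zip(ids, rows.iloc[:, 1].tolist())))


def write_labels(labels: LabelMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, cls in labels.mapping.items():
            fh.write(f"{sid}\t{cls}\n")


def read_blacklist(path) -> ProbeBlacklist:
    """Read a plain-text blacklist, one probe ID per line."""
    with open(path, "r", encoding="utf-8") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return ProbeBlacklist.from_iterable(ids)


def merge_datasets(matrices: Sequence[BetaMatrix]) -> BetaMatrix:
    """Merge multi-study matrices on their common probe set.

    Probes that do not appear in every input are dropped; samples are
    concatenated. Probe order follows the first input; values are copied
    unchanged.
    """
    if len(matrices) == 0:
        raise InputError("merge_datasets requires at least one matrix")
    if len(matrices) == 1:
        return matrices[0]
    seen: set[str] = set()
    for m in matrices:
        overlap = seen.intersection(m.sample_ids)
        if overlap:
            raise InputError(f"duplicate sample IDs across inputs: {sorted(overlap)[:10]}")
        seen.update(m.sample_ids)
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise InputError("probe intersection across datasets is empty")
    ordered = [p for p in matrices[0].probe_ids if p in common]
    merged = pd.concat([m.df.loc[ordered] for m in matrices], axis=1)
    logger.info(
        "merged %d datasets: %d common probes, %d samples",
        len(matrices), len(ordered), merged.shape[1],
    )
    return BetaMatrix(merged)


def apply_blacklist(m: BetaMatrix, bl: ProbeBlacklist) -> BetaMatrix:
    """Drop blacklisted probes, preserving probe order."""
    present = [p for p in m.probe_ids if p in bl.probes]
    unknown = len(bl.probes) - len(set(present))
    if unknown:
        logger.warning("%d blacklist entries not present in the matrix", unknown)
    if not present:
        logger.info("blacklist removed 0 probes")
        return m
    keep = [p for p in m.probe_ids if p not in bl.probes]
    if not keep:
        raise InputError("blacklist removes every probe")
    logger.info("blacklist removed %d of %d probes", len(present), m.shape[0])
    return BetaMatrix(m.df.loc[keep])


def save_classifier(clf, path) -> None:
    """Serialize a trained classifier to a single file (joblib payload)."""
    payload = {"format_version": FORMAT_VERSION, "classifier": clf}
    joblib.dump(payload, path)


def load_classifier(path):
    """Load a classifier written by :func:`save_classifier`.

    The round trip is exact: the loaded forest produces bit-identical
    probabilities. Corrupted files and unknown format versions raise
    :class:`~methclass.errors.ClassifierFormatError`.
    """
    try:
        payload = joblib.load(path)
    except Exception as exc:  # pickle/joblib raise a zoo of exceptions
        raise ClassifierFormatError(f"{path}: corrupted classifier file: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ClassifierFormatError(f"{path}: not a serialized classifier")
    version = payload["format_version"]
    if version != FORMAT_VERSION:
        raise ClassifierFormatError(
            f"{path}: format version {version!r} not supported "
            f"(this build reads version {FORMAT_VERSION!r})"
        )
    return payload["classifier"]
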