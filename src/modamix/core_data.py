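"""Core data containers and delimited-text I/O.

The data model mirrors the transfer-learning setting the trainer expects:
a labeled *source* cohort and an unlabeled *target* cohort, each measured on
the same ``O`` omics modalities over a shared per-modality feature space.
Within a domain, the modalities are sample-aligned by shared sample IDs.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE = "source"
TARGET = "target"

_NA_STRINGS = ("", "NA", "NaN", "nan", "NAN")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class OmicsMatrix:
    """One modality's samples-by-features matrix for one domain.

    ``missing_mask`` is True where a value is unobserved; observed values must
    be finite.  Only methylation-style matrices headed for imputation should
    carry missing entries — the trainer refuses any remaining missingness.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality: str
    domain: str
    missing_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValidationError("matrix must have at least one sample and one feature")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.feature_ids) != m:
            raise ValidationError(f"{len(self.feature_ids)} feature_ids for {m} columns")
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.feature_ids, "feature_ids")
        if self.domain not in (SOURCE, TARGET):
            raise ValidationError(f"domain must be '{SOURCE}' or '{TARGET}', got {self.domain!r}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValidationError("missing_mask shape does not match values")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise ValidationError("non-finite observed values outside missing_mask")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``sample_ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return OmicsMatrix(
            values=self.values[rows],
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            modality=self.modality,
            domain=self.domain,
            missing_mask=self.missing_mask[rows],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        cols = [index[f] for f in feature_ids]
        return OmicsMatrix(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            modality=self.modality,
            domain=self.domain,
            missing_mask=self.missing_mask[:, cols],
        )


@dataclass
class MultiOmicsDataset:
    """``O`` sample-aligned modalities for one domain, with optional labels.

    Labels are 1-based class indices into ``class_names`` (classes are
    abstract categories ``k in {1..K}``; names are kept for reporting only).
    """

    matrices: list[OmicsMatrix]
    domain: str
    labels: Optional[np.ndarray] = None
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValidationError("dataset needs at least one modality")
        ids0 = self.matrices[0].sample_ids
        for mat in self.matrices:
            if mat.sample_ids != ids0:
                raise ValidationError(
                    f"modality {mat.modality!r} sample_ids differ from first modality"
                )
            if mat.domain != self.domain:
                raise ValidationError(
                    f"modality {mat.modality!r} domain {mat.domain!r} != dataset domain {self.domain!r}"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(ids0):
                raise ValidationError("labels length does not match sample count")
            k = self.n_classes
            if self.labels.min() < 1 or (k and self.labels.max() > k):
                raise ValidationError("labels must lie in {1..K}")

    @property
    def n_samples(self) -> int:
        return self.matrices[0].n_samples

    @property
    def n_modalities(self) -> int:
        return len(self.matrices)

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices[0].sample_ids

    @property
    def n_classes(self) -> int:
        if self.class_names is not None:
            return len(self.class_names)
        if self.labels is not None:
            return int(self.labels.max())
        return 0

    @property
    def feature_dims(self) -> list[int]:
        return [m.n_features for m in self.matrices]

    def arrays(self) -> list[np.ndarray]:
        return [m.values for m in self.matrices]


@dataclass
class EmbeddingResult:
    """Integrated latent coordinates plus class posteriors for one dataset."""

    latent: np.ndarray
    posteriors: np.ndarray
    predicted_labels: np.ndarray
    sample_ids: list[str]
    domain: str
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.latent = np.asarray(self.latent, dtype=float)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=int)
        n = self.latent.shape[0]
        if n == 0:
            raise ValidationError("empty embedding result refused")
        if self.posteriors.shape[0] != n or len(self.predicted_labels) != n:
            raise ValidationError("latent / posteriors / labels disagree on n")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length mismatch")
        sums = self.posteriors.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("posterior rows must sum to 1 within 1e-6")
        # argmax with ties broken toward the lowest class index (np.argmax does)
        expect = np.argmax(self.posteriors, axis=1) + 1
        if not np.array_equal(expect, self.predicted_labels):
            raise ValidationError("predicted_labels must be the posterior argmax")

    @property
    def n_samples(self) -> int:
        return self.latent.shape[0]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(
    path: str,
    orientation: str = "samples_in_rows",
    modality: str = "omics",
    domain: str = SOURCE,
) -> OmicsMatrix:
    """Read a delimited matrix (tab or comma, auto-detected) into an OmicsMatrix.

    The file has one header row and one leading ID column.  Empty, ``NA`` and
    ``NaN`` cells are flagged in ``missing_mask``; any other non-numeric cell
    is a parse error reported with its row/column coordinates.  Matrices
    stored features-in-rows are transposed to samples-in-rows internally.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    raw = df.to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else raw[i, j]
            if cell in _NA_STRINGS:
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
    if orientation == "features_in_rows":
        values, mask = values.T, mask.T
        sample_ids, feature_ids = col_ids, row_ids
    else:
        sample_ids, feature_ids = row_ids, col_ids
    return OmicsMatrix(values, sample_ids, feature_ids, modality, domain, mask)


def write_matrix(mat: OmicsMatrix, path: str) -> None:
    """Write samples-in-rows delimited text; missing cells become ``NA``."""
    out = mat.values.astype(object)
    out[mat.missing_mask] = "NA"
    df = pd.DataFrame(out, index=mat.sample_ids, columns=mat.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_labels(path: str) -> pd.DataFrame:
    """Read a two-column (sample_id, class name) label table."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label table needs two columns (sample_id, label)")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "label"]
    return df


def assemble_dataset(
    matrices: list[OmicsMatrix],
    labels: Optional[pd.DataFrame] = None,
    class_names: Optional[list[str]] = None,
) -> MultiOmicsDataset:
    """Align modalities on the intersection of their sample IDs and attach labels.

    Samples missing from any modality are dropped (count logged).  The
    retained order follows the first matrix.  A label table referencing
    unknown samples warns and drops the extras.
    """
    if not matrices:
        raise ValidationError("need at least one matrix")
    domain = matrices[0].domain
    for m in matrices:
        if m.domain != domain:
            raise ValidationError("all matrices must share one domain tag")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValidationError("no sample IDs shared across all modalities")
    kept = [s for s in matrices[0].sample_ids if s in common]
    dropped = sum(m.n_samples - len(kept) for m in matrices)
    if dropped:
        logger.info("assemble_dataset: dropped %d sample slots lacking a modality", dropped)
    aligned = [m.subset_samples(kept) for m in matrices]

    label_arr = None
    if labels is not None:
        table = labels.set_index("sample_id")["label"]
        unknown = [s for s in table.index if s not in common]
        if unknown:
            warnings.warn(
                f"label table references {len(unknown)} unknown sample(s); dropped",
                stacklevel=2,
            )
        missing = [s for s in kept if s not in table.index]
        if missing:
            raise ValidationError(f"samples lack labels: {missing[:5]}")
        if class_names is None:
            class_names = sorted(set(table.loc[kept]))
        name_to_idx = {c: i + 1 for i, c in enumerate(class_names)}
        label_arr = np.array([name_to_idx[table.loc[s]] for s in kept], dtype=int)

    return MultiOmicsDataset(aligned, domain=domain, labels=label_arr, class_names=class_names)


def write_result(result: EmbeddingResult, out_dir: str) -> dict[str, str]:
    """Write latent, posteriors and predictions as delimited text files."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "latent": os.path.join(out_dir, "latent.tsv"),
        "posteriors": os.path.join(out_dir, "posteriors.tsv"),
        "predictions": os.path.join(out_dir, "predictions.tsv"),
    }
    k = result.posteriors.shape[1]
    names = result.class_names or [f"class_{j + 1}" for j in range(k)]
    lat = pd.DataFrame(
        result.latent,
        index=result.sample_ids,
        columns=[f"latent_{j + 1}" for j in range(result.latent.shape[1])],
    )
    lat.index.name = "sample_id"
    lat.to_csv(paths["latent"], sep="\t", float_format="%.12g")
    post = pd.DataFrame(result.posteriors, index=result.sample_ids, columns=names)
    post.index.name = "sample_id"
    post.to_csv(paths["posteriors"], sep="\t", float_format="%.12g")
    pred = pd.DataFrame(
        {
            "sample_id": result.sample_ids,
            "predicted_label": [names[i - 1] for i in result.predicted_labels],
        }
    )
    pred.to_csv(paths["predictions"], sep="\t", index=False)
    return paths


def read_result(out_dir: str, domain: str = TARGET) -> EmbeddingResult:
    """Re-read the three files produced by :func:`write_result`."""
    lat = pd.read_csv(os.path.join(out_dir, "latent.tsv"), sep="\t", index_col=0)
    post = pd.read_csv(os.path.join(out_dir, "posteriors.tsv"), sep="\t", index_col=0)
    names = [str(c) for c in post.columns]
    posteriors = post.to_numpy(dtype=float)
    return EmbeddingResult(
        latent=lat.to_numpy(dtype=float),
        posteriors=posteriors,
        predicted_labels=np.argmax(posteriors, axis=1) + 1,
        sample_ids=[str(s) for s in lat.index],
        domain=domain,
        class_names=names,
    )
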