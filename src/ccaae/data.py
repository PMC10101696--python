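"""Loading, validation and preprocessing of per-modality cell x feature matrices.

The canonical in-memory objects are :class:`OmicsMatrix` (one modality) and
:class:`PairedDataset` (both modalities over a shared, co-assayed cell
population with known pairing).  Supported on-disk layouts:

* dense delimited text (CSV/TSV): cells as rows, a header row of feature
  names, first column cell identifiers;
* MatrixMarket MTX with ``barcodes.tsv`` / ``features.tsv`` sidecars, 10x
  convention (features as MTX rows; transposed on load to cell x feature).

Labels are two-column ``cell_id<TAB/COMMA>label`` text, matched by cell id,
never by row order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.model_selection import train_test_split

__all__ = [
    "OmicsMatrix",
    "PairedDataset",
    "PreprocessConfig",
    "load_matrix",
    "write_matrix",
    "preprocess",
    "pair_matrices",
    "split_dataset",
]

Modality = Literal["rna", "atac"]


class ValidationError(ValueError):
    """Raised when a matrix or label file violates the data contract."""


@dataclass
class OmicsMatrix:
    """One modality's cell x feature matrix plus identifiers and labels."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: Modality
    labels: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cell x feature matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValidationError(
                f"{self.values.shape[0]} rows but {len(self.cell_ids)} cell_ids"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ValidationError(
                f"{self.values.shape[1]} columns but {len(self.feature_ids)} feature_ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = _first_duplicates(self.cell_ids)
            raise ValidationError(f"duplicate cell_ids, e.g. {dupes}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _first_duplicates(self.feature_ids)
            raise ValidationError(f"duplicate feature_ids, e.g. {dupes}")
        if self.modality not in ("rna", "atac"):
            raise ValidationError(f"modality must be 'rna' or 'atac', got {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain NaN or Inf")
        if self.labels is not None:
            if len(self.labels) != self.n_cells:
                raise ValidationError(
                    f"{len(self.labels)} labels for {self.n_cells} cells"
                )
            if any(str(l) == "" for l in self.labels):
                raise ValidationError("labels must be non-empty strings")

    def subset(self, idx: np.ndarray) -> "OmicsMatrix":
        idx = np.asarray(idx)
        return OmicsMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            modality=self.modality,
            labels=None if self.labels is None else self.labels[idx],
            provenance=list(self.provenance),
        )


def _first_duplicates(items: Sequence[str], k: int = 5) -> list[str]:
    seen, dupes = set(), []
    for it in items:
        if it in seen and it not in dupes:
            dupes.append(it)
            if len(dupes) == k:
                break
        seen.add(it)
    return dupes


# --------------------------------------------------------------------- loading
def _read_labels(labels_path: str | Path) -> dict[str, str]:
    df = pd.read_csv(labels_path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(
            f"label file {labels_path} must have two columns (cell_id, label)"
        )
    # tolerate an optional header row
    first = str(df.iloc[0, 0]).lower()
    if first in ("cell_id", "barcode", "cell", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _match_labels(cell_ids: list[str], mapping: dict[str, str]) -> np.ndarray:
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells missing from label file; first offenders: "
            f"{missing[:5]}"
        )
    return np.asarray([mapping[c] for c in cell_ids], dtype=object)


def load_matrix(
    path: str | Path,
    format: Literal["csv", "tsv", "mtx"],
    modality: Modality,
    labels_path: str | Path | None = None,
) -> OmicsMatrix:
    """Read one modality from disk and return a validated :class:`OmicsMatrix`.

    For ``mtx``, ``path`` is the ``matrix.mtx`` file; ``barcodes.tsv`` and
    ``features.tsv`` sidecars must sit in the same directory (10x layout,
    features as MTX rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
            values = df.to_numpy(dtype=np.float64)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValidationError(f"could not parse {path}: {exc}") from exc
        cell_ids = [str(c) for c in df.index]
        feature_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        barcodes = path.parent / "barcodes.tsv"
        features = path.parent / "features.tsv"
        for side in (barcodes, features):
            if not side.exists():
                raise FileNotFoundError(f"missing MTX sidecar {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=np.float64).T  # features x cells -> cells x features
        cell_ids = barcodes.read_text().split()
        feature_ids = [ln.split("\t")[0] for ln in features.read_text().splitlines() if ln]
    else:
        raise ValueError(f"unknown format {format!r}")

    labels = None
    if labels_path is not None:
        labels = _match_labels(cell_ids, _read_labels(labels_path))
    return OmicsMatrix(values, cell_ids, feature_ids, modality, labels)


def write_matrix(m: OmicsMatrix, path: str | Path, format: Literal["csv", "tsv", "mtx"]) -> None:
    """Write a matrix back to disk in the layout :func:`load_matrix` reads.

    Provenance (applied preprocessing steps) goes to ``<path>.provenance.json``.
    """
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.feature_ids)
        df.to_csv(path, sep=sep, float_format="%.17g")  # exact float64 round-trip
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values.T), precision=17)
        (path.parent / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        (path.parent / "features.tsv").write_text("\n".join(m.feature_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    if m.provenance:
        Path(str(path) + ".provenance.json").write_text(json.dumps(m.provenance))


# ---------------------------------------------------------------- preprocessing
@dataclass
class PreprocessConfig:
    """Preprocessing switches, applied in the fixed order log1p ->
    binarize -> standardize.

    Defaults follow standard single-cell practice: RNA counts are
    log1p-transformed and z-scored per gene; ATAC activities are used as
    loaded (optionally binarized) and z-scored per peak.  Standardisation
    uses the population convention (ddof=0); zero-variance features are
    centred and left at zero.
    """

    log1p: bool | None = None  # None -> modality default (rna: True, atac: False)
    binarize: bool = False
    standardize: bool = True


def preprocess(m: OmicsMatrix, config: PreprocessConfig | None = None) -> OmicsMatrix:
    config = config or PreprocessConfig()
    log1p = config.log1p if config.log1p is not None else (m.modality == "rna")
    values = m.values.copy()
    provenance = list(m.provenance)
    if log1p:
        if "log1p" in provenance:
            raise ValidationError("log1p already applied (per provenance); refusing to repeat")
        if np.any(values < 0):
            raise ValidationError("log1p requested on matrix with negative values")
        values = np.log1p(values)
        provenance.append("log1p")
    if config.binarize:
        values = (values > 0).astype(np.float64)
        if "binarize" not in provenance:
            provenance.append("binarize")
    if config.standardize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)  # ddof=0
        values = values - mu
        nz = sd > 0
        values[:, nz] /= sd[nz]
        provenance.append("standardize")
    return OmicsMatrix(values, m.cell_ids, m.feature_ids, m.modality, m.labels, provenance)


# -------------------------------------------------------------- paired dataset
@dataclass
class PairedDataset:
    """Two modality views of the same cells with ground-truth pairing.

    Row ``i`` of ``rna.values`` and row ``i`` of ``atac.values`` measure the
    same cell; ``labels`` is the shared per-cell cell-type assignment.
    ``meta`` may carry the synthetic generator's signal/noise decomposition.
    """

    rna: OmicsMatrix
    atac: OmicsMatrix
    labels: np.ndarray | None = None
    split_assignment: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rna.n_cells != self.atac.n_cells:
            raise ValidationError(
                f"rna has {self.rna.n_cells} cells but atac has {self.atac.n_cells}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.n_cells:
                raise ValidationError("labels length must equal cell count")

    @property
    def n_cells(self) -> int:
        return self.rna.n_cells

    def subset(self, idx: np.ndarray) -> "PairedDataset":
        idx = np.asarray(idx)
        meta = dict(self.meta)
        for key in list(meta):
            if key.endswith(("_signal", "_noise")) or key == "latent":
                meta[key] = meta[key][idx]
        return PairedDataset(
            rna=self.rna.subset(idx),
            atac=self.atac.subset(idx),
            labels=None if self.labels is None else self.labels[idx],
            split_assignment=None,
            meta=meta,
        )

    @property
    def train(self) -> "PairedDataset":
        return self._by_split("train")

    @property
    def test(self) -> "PairedDataset":
        return self._by_split("test")

    def _by_split(self, tag: str) -> "PairedDataset":
        if self.split_assignment is None:
            raise ValidationError("dataset has no split_assignment; call split_dataset first")
        return self.subset(np.flatnonzero(self.split_assignment == tag))


def pair_matrices(rna: OmicsMatrix, atac: OmicsMatrix) -> PairedDataset:
    """Pair two modality matrices into one dataset.

    Cells are matched by cell_id when both sides carry ids that coincide as
    sets; otherwise row order is used with a loud warning (co-assay data
    usually shares barcodes).  Labels must agree across the two sides of
    every pair when present on both.
    """
    if set(rna.cell_ids) == set(atac.cell_ids):
        order = {c: i for i, c in enumerate(atac.cell_ids)}
        atac = atac.subset(np.asarray([order[c] for c in rna.cell_ids]))
    else:
        warnings.warn(
            "cell_ids of the two modalities do not coincide; pairing by row order",
            stacklevel=2,
        )
        if rna.n_cells != atac.n_cells:
            raise ValidationError("cannot pair by row order: cell counts differ")
    labels = rna.labels if rna.labels is not None else atac.labels
    if rna.labels is not None and atac.labels is not None:
        if not np.array_equal(rna.labels, atac.labels):
            bad = [
                rna.cell_ids[i]
                for i in range(rna.n_cells)
                if rna.labels[i] != atac.labels[i]
            ][:5]
            raise ValidationError(f"labels disagree across modalities, e.g. cells {bad}")
    return PairedDataset(rna=rna, atac=atac, labels=labels)


def split_dataset(
    d: PairedDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> PairedDataset:
    """Stratified-by-label train/test split, pairing preserved.

    Returns a copy of ``d`` with ``split_assignment`` set; the two sides of
    every pair always land in the same split.  Deterministic given ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(d.n_cells)
    strat = None
    if stratify:
        if d.labels is None:
            raise ValidationError("stratified split requires labels; pass stratify=False")
        vals, counts = np.unique(d.labels.astype(str), return_counts=True)
        singletons = vals[counts < 2]
        if len(singletons):
            raise ValidationError(
                f"labels {list(singletons)} have a single cell; stratified splitting is "
                "impossible — pass stratify=False"
            )
        strat = d.labels.astype(str)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=strat
    )
    assignment = np.empty(d.n_cells, dtype=object)
    assignment[train_idx] = "train"
    assignment[test_idx] = "test"
    return replace(d, split_assignment=assignment)
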