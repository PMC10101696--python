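"""Evaluation of alignment and integration in the coordinated subspace.

Two criteria, both exact (brute-force nearest neighbours, no approximate
search):

* **integration accuracy** — for each ATAC embedding, find the single
  nearest RNA embedding by Euclidean distance; the match is correct when
  the two cells share a cell-type label; report the correct fraction;
* **recall@k** — for each ATAC embedding, the fraction whose true paired
  RNA embedding lies among its k nearest RNA embeddings (k in
  {10, 20, 30, 40, 50} by default).  A flag switches the indicator to
  cell-type membership of the k-neighbourhood instead of the true pair.

Ties are broken deterministically: smaller distance first, then lower RNA
index.  Label transfer assigns each ATAC cell the label of its nearest RNA
embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .networks import LatentEmbedding

__all__ = [
    "EvaluationReport",
    "integration_accuracy",
    "recall_at_k",
    "transfer_labels",
    "export_embeddings",
]

DEFAULT_KS = (10, 20, 30, 40, 50)


def _coords(emb) -> np.ndarray:
    if isinstance(emb, LatentEmbedding):
        return emb.coords
    return np.asarray(emb, dtype=np.float64)


def _nearest_rna(emb_atac, emb_rna) -> np.ndarray:
    """Index of each ATAC cell's nearest RNA embedding (ties: lowest index)."""
    a, r = _coords(emb_atac), _coords(emb_rna)
    if r.shape[0] == 0:
        raise ValueError("rna embedding pool is empty")
    if a.shape[1] != r.shape[1]:
        raise ValueError(
            f"latent dimensions differ: atac {a.shape[1]} vs rna {r.shape[1]}"
        )
    D = cdist(a, r, metric="euclidean")
    return D.argmin(axis=1)  # argmin returns the first (lowest) index on ties


def integration_accuracy(emb_atac, emb_rna, labels_atac, labels_rna=None) -> float:
    """Fraction of ATAC cells whose nearest RNA embedding shares their label."""
    labels_atac = np.asarray(labels_atac)
    labels_rna = labels_atac if labels_rna is None else np.asarray(labels_rna)
    nn = _nearest_rna(emb_atac, emb_rna)
    return float(np.mean(labels_rna[nn] == labels_atac))


def recall_at_k(
    emb_atac,
    emb_rna,
    pairing: Sequence[int] | None,
    k: int,
    by_label: bool = False,
    labels_atac=None,
    labels_rna=None,
) -> float:
    """Fraction of ATAC cells whose true RNA partner is among the k nearest.

    ``pairing[i]`` is the RNA row index paired with ATAC row ``i``
    (identity when ``None``).  With ``by_label=True`` the indicator instead
    asks whether any of the k nearest RNA embeddings shares the ATAC cell's
    label (alternative reading of the k-neighbourhood criterion).
    """
    a, r = _coords(emb_atac), _coords(emb_rna)
    n_atac, n_rna = a.shape[0], r.shape[0]
    if not 1 <= k <= n_rna:
        raise ValueError(f"k must be in [1, {n_rna}], got {k}")
    D = cdist(a, r, metric="euclidean")
    if by_label:
        if labels_atac is None or labels_rna is None:
            raise ValueError("by_label recall needs labels for both sides")
        labels_atac = np.asarray(labels_atac)
        labels_rna = np.asarray(labels_rna)
        hits = 0
        for i in range(n_atac):
            order = np.lexsort((np.arange(n_rna), D[i]))[:k]
            hits += int(np.any(labels_rna[order] == labels_atac[i]))
        return hits / n_atac
    pairing = np.arange(n_atac) if pairing is None else np.asarray(pairing)
    if len(pairing) != n_atac:
        raise ValueError("pairing must give one rna index per atac cell")
    d_true = D[np.arange(n_atac), pairing]
    # rank of the true partner under (distance, index) ordering
    closer = (D < d_true[:, None]).sum(axis=1)
    tied_lower = ((D == d_true[:, None]) & (np.arange(n_rna)[None, :] < pairing[:, None])).sum(
        axis=1
    )
    return float(np.mean(closer + tied_lower < k))


def transfer_labels(
    emb_atac, emb_rna, rna_labels, true_atac_labels=None
) -> tuple[np.ndarray, float | None]:
    """Assign each ATAC cell the label of its nearest RNA embedding.

    Returns the transferred labels and, when the true ATAC labels are
    given, the agreement rate.
    """
    rna_labels = np.asarray(rna_labels)
    nn = _nearest_rna(emb_atac, emb_rna)
    transferred = rna_labels[nn]
    agreement = None
    if true_atac_labels is not None:
        agreement = float(np.mean(transferred == np.asarray(true_atac_labels)))
    return transferred, agreement


@dataclass
class EvaluationReport:
    """Integration accuracy and recall@k with the settings that produced them."""

    integration_accuracy: float
    recall_at_k: dict[int, float]
    n_test_cells: int
    distance_metric: str = "euclidean"
    pairing_used: bool = True
    label_transfer_accuracy: float | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        props = [self.integration_accuracy, *self.recall_at_k.values()]
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("all reported proportions must lie in [0, 1]")
        ks = sorted(self.recall_at_k)
        vals = [self.recall_at_k[k] for k in ks]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("recall@k must be non-decreasing in k")

    def to_json(self) -> str:
        payload = {
            "integration_accuracy": self.integration_accuracy,
            "recall_at_k": {str(k): v for k, v in sorted(self.recall_at_k.items())},
            "n_test_cells": self.n_test_cells,
            "distance_metric": self.distance_metric,
            "pairing_used": self.pairing_used,
            "label_transfer_accuracy": self.label_transfer_accuracy,
            "settings": self.settings,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": "integration_accuracy", "value": self.integration_accuracy}]
        rows += [
            {"metric": f"recall@{k}", "value": v} for k, v in sorted(self.recall_at_k.items())
        ]
        if self.label_transfer_accuracy is not None:
            rows.append(
                {"metric": "label_transfer_accuracy", "value": self.label_transfer_accuracy}
            )
        return pd.DataFrame(rows)


def evaluate_embeddings(
    emb_atac,
    emb_rna,
    labels,
    ks: Sequence[int] = DEFAULT_KS,
    pairing: Sequence[int] | None = None,
) -> EvaluationReport:
    """Full report on co-assayed test embeddings (shared labels, known pairs)."""
    n = _coords(emb_atac).shape[0]
    ks = [k for k in ks if k <= _coords(emb_rna).shape[0]]
    transferred, agreement = transfer_labels(emb_atac, emb_rna, labels, labels)
    return EvaluationReport(
        integration_accuracy=integration_accuracy(emb_atac, emb_rna, labels),
        recall_at_k={int(k): recall_at_k(emb_atac, emb_rna, pairing, int(k)) for k in ks},
        n_test_cells=n,
        label_transfer_accuracy=agreement,
    )


def export_embeddings(nets, dataset, path: str | Path) -> Path:
    """Write both modality embeddings to one CSV for external plotting.

    Columns: cell_id, modality, label, z0..z{d-1}; fixed float format so the
    file is byte-identical across runs at the same seed.
    """
    path = Path(path)
    frames = []
    for modality in ("rna", "atac"):
        m = getattr(dataset, modality)
        emb = nets.encode(m)
        df = pd.DataFrame(
            emb.coords, columns=[f"z{i}" for i in range(emb.coords.shape[1])]
        )
        df.insert(0, "cell_id", m.cell_ids)
        df.insert(1, "modality", modality)
        labels = dataset.labels if dataset.labels is not None else [""] * m.n_cells
        df.insert(2, "label", labels)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def plot_embeddings(csv_path: str | Path, out_png: str | Path) -> None:  # pragma: no cover
    """Convenience 2-D scatter of exported embeddings via PCA (untested)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA

    df = pd.read_csv(csv_path)
    coords = df[[c for c in df.columns if c.startswith("z")]].to_numpy()
    xy = PCA(n_components=2).fit_transform(coords) if coords.shape[1] > 2 else coords
    fig, ax = plt.subplots(figsize=(6, 5))
    for label in sorted(df["label"].astype(str).unique()):
        for modality, marker in (("rna", "o"), ("atac", "^")):
            sel = (df["label"].astype(str) == label) & (df["modality"] == modality)
            ax.scatter(xy[sel, 0], xy[sel, 1], s=8, marker=marker, alpha=0.6,
                       label=f"{label}/{modality}")
    ax.legend(fontsize=6, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
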