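"""Loss terms of the coupled adversarial autoencoder.

Conventions (all configurable through :class:`LossWeights`):

* the distance ``d`` defaults to squared Euclidean averaged over
  dimensions (``squared_l2``); ``l2`` and ``l1`` (also dimension-averaged)
  are available;
* adversarial training uses the standard GAN binary cross-entropy: the
  discriminator minimises label BCE (target 1 for RNA embeddings, 0 for
  ATAC) on embeddings treated as fixed inputs, while the encoders minimise
  the non-saturating flipped-label BCE through the live embedding path;
* the triplet loss applies a hinge ``max(0, d(a,p) - d(a,n) + margin)`` —
  the margin objective implies zero loss once the inequality holds, and an
  unhinged difference is unbounded below;
* hard mining is exhaustive within the given pool (both modalities pooled
  and treated equally), positives at maximum distance within the anchor's
  label, negatives at minimum distance outside it, ties broken by lowest
  index, anchors never paired with themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor, as_tensor
from .networks import CoupledNets

__all__ = [
    "LossWeights",
    "rowwise_distance",
    "reconstruction_loss",
    "adversarial_losses",
    "cycle_consistency_loss",
    "mine_hard_triplets",
    "contrastive_loss",
    "classifier_loss",
    "mmd_loss",
    "anchor_loss",
]

DistanceName = Literal["squared_l2", "l2", "l1"]


@dataclass
class LossWeights:
    """Relative weights of the training objective's terms.

    Defaults follow the convention that the reconstruction and adversarial
    parts are trained with the same weight; the anchor (pairwise
    supervision) term is off by default — training is unsupervised with
    respect to cell pairing.
    """

    w_recon: float = 1.0
    w_adv: float = 1.0
    w_cyc: float = 1.0
    w_con: float = 1.0
    w_cls: float = 1.0
    w_anchor: float = 0.0
    margin_alpha: float = 1.0
    distance: DistanceName = "squared_l2"

    def __post_init__(self):
        for name in ("w_recon", "w_adv", "w_cyc", "w_con", "w_cls", "w_anchor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.margin_alpha <= 0:
            raise ValueError("margin_alpha must be positive")
        if self.distance not in ("squared_l2", "l2", "l1"):
            raise ValueError(f"unknown distance {self.distance!r}")


_EPS = 1e-12


def rowwise_distance(a: Tensor, b: Tensor, distance: DistanceName = "squared_l2") -> Tensor:
    """Per-row distance d(a_i, b_i), averaged over dimensions."""
    diff = a - b
    dim = float(a.shape[-1])
    if distance == "squared_l2":
        return (diff * diff).sum(axis=-1) / dim
    if distance == "l2":
        return (((diff * diff).sum(axis=-1) + _EPS) ** 0.5) / dim
    if distance == "l1":
        return diff.abs().sum(axis=-1) / dim
    raise ValueError(f"unknown distance {distance!r}")


def _pairwise_numpy(x: np.ndarray, y: np.ndarray, distance: DistanceName) -> np.ndarray:
    dim = x.shape[1]
    if distance == "squared_l2":
        return cdist(x, y, metric="sqeuclidean") / dim
    if distance == "l2":
        return cdist(x, y, metric="euclidean") / dim
    if distance == "l1":
        return cdist(x, y, metric="cityblock") / dim
    raise ValueError(f"unknown distance {distance!r}")


def _check_batch(x, name: str) -> Tensor:
    x = as_tensor(x)
    if x.shape[0] == 0:
        raise ValueError(f"{name} batch is empty")
    return x


# ----------------------------------------------------------------- autoencoder
def reconstruction_loss(
    nets: CoupledNets,
    batch_rna,
    batch_atac,
    distance: DistanceName = "squared_l2",
) -> Tensor:
    """Mean d(x, Dec(Enc(x))) over RNA cells plus the same over ATAC cells."""
    total = None
    for batch, modality in ((batch_rna, "rna"), (batch_atac, "atac")):
        x = _check_batch(batch, modality)
        z = nets.encode_t(x, modality)
        xhat = nets.decoder(modality)(z)
        term = rowwise_distance(x, xhat, distance).mean()
        total = term if total is None else total + term
    return total


def adversarial_losses(nets: CoupledNets, emb_rna, emb_atac) -> tuple[Tensor, Tensor]:
    """(discriminator loss, generator loss) under the standard GAN BCE.

    ``disc_loss`` sees the embeddings as fixed inputs (detached);
    ``gen_loss`` flows gradients through the live embedding path so the
    encoders can make the two modalities indistinguishable.
    """
    z_rna, z_atac = as_tensor(emb_rna), as_tensor(emb_atac)
    for z, name in ((z_rna, "rna"), (z_atac, "atac")):
        if z.shape[0] == 0:
            raise ValueError(f"{name} embedding batch is empty")
        if not np.all(np.isfinite(z.data)):
            raise ValueError(f"{name} embeddings contain non-finite values")

    def bce_with_logits(logits: Tensor, target: float) -> Tensor:
        # softplus(l) - t*l == -[t log sigma(l) + (1-t) log(1-sigma(l))]
        return (logits.softplus() - target * logits).mean()

    n_r, n_a = z_rna.shape[0], z_atac.shape[0]

    def mean_over_both(loss_rna: Tensor, loss_atac: Tensor) -> Tensor:
        return (loss_rna * float(n_r) + loss_atac * float(n_a)) / float(n_r + n_a)

    logit_r_fixed = nets.discriminator.logits(z_rna.detach())
    logit_a_fixed = nets.discriminator.logits(z_atac.detach())
    disc_loss = mean_over_both(
        bce_with_logits(logit_r_fixed, 1.0), bce_with_logits(logit_a_fixed, 0.0)
    )

    logit_r = nets.discriminator.logits(z_rna)
    logit_a = nets.discriminator.logits(z_atac)
    gen_loss = mean_over_both(
        bce_with_logits(logit_r, 0.0), bce_with_logits(logit_a, 1.0)
    )
    return disc_loss, gen_loss


def cycle_consistency_loss(
    nets: CoupledNets,
    batch_rna,
    batch_atac,
    distance: DistanceName = "squared_l2",
) -> Tensor:
    """Latent cycle consistency through the *other* modality's decoder/encoder.

    For an RNA cell x: compare Ej(x) with Ei(Di(Ej(x))) in latent space,
    where Ej is the RNA encoder and Di/Ei the ATAC decoder/encoder; the
    symmetric term for ATAC cells runs through the RNA side.
    """
    total = None
    for batch, modality, other in ((batch_rna, "rna", "atac"), (batch_atac, "atac", "rna")):
        x = _check_batch(batch, modality)
        z = nets.encode_t(x, modality)
        cycled = nets.encoder(other)(nets.decoder(other)(z))
        term = rowwise_distance(z, cycled, distance).mean()
        total = term if total is None else total + term
    return total


# ------------------------------------------------------------------ contrastive
def mine_hard_triplets(
    coords: np.ndarray,
    labels: Sequence,
    distance: DistanceName = "squared_l2",
) -> list[tuple[int, int, int]]:
    """Exhaustive hard mining: (anchor, hard positive, hard negative) triples.

    For every anchor whose label has at least one other member: the positive
    is the same-label point at maximum distance, the negative the
    different-label point at minimum distance.  Deterministic tie-break by
    lowest index; anchors are never their own positive.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("triplet mining needs at least two labels in the pool")
    D = _pairwise_numpy(coords, coords, distance)
    n = coords.shape[0]
    triples = []
    for a in range(n):
        same = (labels == labels[a])
        same[a] = False
        if not same.any():
            continue  # anchor's label has a single member: skipped
        pos_candidates = np.flatnonzero(same)
        p = pos_candidates[np.argmax(D[a, pos_candidates])]
        neg_candidates = np.flatnonzero(labels != labels[a])
        nidx = neg_candidates[np.argmin(D[a, neg_candidates])]
        triples.append((a, int(p), int(nidx)))
    return triples


def contrastive_loss(
    emb_pool: Tensor | np.ndarray,
    labels: Sequence,
    margin_alpha: float = 1.0,
    distance: DistanceName = "squared_l2",
) -> Tensor:
    """Hard-mined triplet margin loss over the pooled embeddings.

    Mean over anchors of ``max(0, d(a, p) - d(a, n) + margin_alpha)``;
    mining runs on the detached coordinates, gradients flow through the
    anchor/positive/negative rows.
    """
    z = as_tensor(emb_pool)
    triples = mine_hard_triplets(z.data, labels, distance)
    if not triples:
        raise ValueError("no eligible anchors (every label has a single member)")
    idx = np.asarray(triples)
    za = z.take_rows(idx[:, 0])
    zp = z.take_rows(idx[:, 1])
    zn = z.take_rows(idx[:, 2])
    hinge = (
        rowwise_distance(za, zp, distance)
        - rowwise_distance(za, zn, distance)
        + margin_alpha
    ).relu()
    return hinge.mean()


# -------------------------------------------------------------------- classifier
def classifier_loss(nets: CoupledNets, emb_pool: Tensor | np.ndarray, labels: Sequence) -> Tensor:
    """Cross-entropy of the simple classifier over pooled embeddings."""
    if nets.classifier is None:
        raise ValueError("model was built without a classifier (no label vocabulary)")
    z = as_tensor(emb_pool)
    class_index = {c: i for i, c in enumerate(nets.classes)}
    unseen = sorted({str(l) for l in labels} - set(class_index))
    if unseen:
        raise ValueError(f"labels {unseen} not in the classifier's vocabulary")
    y = np.asarray([class_index[str(l)] for l in labels])
    logp = nets.classifier.logits(z).log_softmax(axis=-1)
    picked = (logp * Tensor(np.eye(len(nets.classes))[y])).sum(axis=-1)
    return -picked.mean()


# --------------------------------------------------------------------------- MMD
def mmd_loss(
    emb_rna: Tensor | np.ndarray,
    emb_atac: Tensor | np.ndarray,
    bandwidths: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> Tensor:
    """Unbiased multi-kernel Gaussian MMD^2 between the two embedding clouds.

    Kernel ``k(x, y) = mean_b exp(-||x-y||^2 / (2 b^2))``; the unbiased
    estimator omits diagonal terms and is clipped at zero.  Used as the
    distribution-matching term in the MMD ablation variant.
    """
    x, y = as_tensor(emb_rna), as_tensor(emb_atac)
    n, m = x.shape[0], y.shape[0]
    if n < 2 or m < 2:
        raise ValueError("unbiased MMD^2 needs at least 2 points per side")

    def sq_dists(a: Tensor, b: Tensor) -> Tensor:
        a2 = (a * a).sum(axis=1).reshape(-1, 1)
        b2 = (b * b).sum(axis=1).reshape(1, -1)
        return a2 + b2 - 2.0 * (a @ b.T)

    def kernel(d2: Tensor) -> Tensor:
        terms = [(-1.0 / (2.0 * b * b) * d2).exp() for b in bandwidths]
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out / float(len(bandwidths))

    kxx = kernel(sq_dists(x, x))
    kyy = kernel(sq_dists(y, y))
    kxy = kernel(sq_dists(x, y))
    # off-diagonal sums (diagonal of kxx/kyy is k(0)=1 exactly)
    sum_xx = kxx.sum() - float(n)
    sum_yy = kyy.sum() - float(m)
    mmd2 = (
        sum_xx / float(n * (n - 1))
        + sum_yy / float(m * (m - 1))
        - 2.0 * kxy.mean()
    )
    return mmd2.relu()


# ------------------------------------------------------------------------ anchor
def anchor_loss(
    nets: CoupledNets,
    batch_rna,
    batch_atac,
    distance: DistanceName = "squared_l2",
) -> Tensor:
    """Mean latent distance over known cross-modality cell pairs.

    ``batch_rna[i]`` and ``batch_atac[i]`` must be the same cell (pairwise
    supervision).  Weight 0 by default: the method is unsupervised with
    respect to pairing.
    """
    x = _check_batch(batch_rna, "rna")
    y = _check_batch(batch_atac, "atac")
    if x.shape[0] != y.shape[0]:
        raise ValueError("anchor loss requires paired batches of equal size")
    zr = nets.encode_t(x, "rna")
    za = nets.encode_t(y, "atac")
    return rowwise_distance(zr, za, distance).mean()
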