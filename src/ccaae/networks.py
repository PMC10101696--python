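"""The five trainable components of the coupled adversarial autoencoder.

Two encoders map the RNA and ATAC feature spaces into one shared latent
(coordinated) subspace; two decoders map back; a discriminator scores the
probability that a latent point came from the RNA encoder; a single-layer
softmax classifier predicts the cell type from a latent point.  All are
small MLPs built on :mod:`ccaae.nn`; hidden widths and latent dimension are
configuration, not architecture constants.

Construction fans a single seed out into named substreams (one per
network), so the RNA autoencoder initialised inside the coupled model is
bitwise identical to one initialised on its own with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .data import OmicsMatrix
from .nn import MLP, Linear, Module

__all__ = ["CoupledNets", "LatentEmbedding", "build_networks", "named_stream"]


def named_stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child RNG stream of a base seed."""
    digest = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(digest,)))


@dataclass
class LatentEmbedding:
    """Cell x latent-dim coordinates in the coordinated subspace."""

    coords: np.ndarray
    modality: str
    cell_ids: list[str]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("one latent row per cell required")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


class Discriminator(Module):
    """Latent -> probability the embedding came from the RNA encoder."""

    def __init__(self, latent_dim: int, hidden: tuple[int, ...], rng: np.random.Generator):
        self.net = MLP(latent_dim, hidden, 1, rng)

    def logits(self, z: Tensor) -> Tensor:
        return self.net(z)

    def forward(self, z: Tensor) -> Tensor:
        p = self.logits(z).sigmoid()
        # keep the reported probability strictly inside (0, 1) even where
        # the sigmoid saturates in float64; losses always use the logits
        p.data = np.clip(p.data, 5e-324, np.nextafter(1.0, 0.0))
        return p


class Classifier(Module):
    """Single linear layer + softmax over cell types ("simple classifier")."""

    def __init__(self, latent_dim: int, n_classes: int, rng: np.random.Generator):
        self.lin = Linear(latent_dim, n_classes, rng)

    def logits(self, z: Tensor) -> Tensor:
        return self.lin(z)

    def forward(self, z: Tensor) -> Tensor:
        return self.logits(z).log_softmax(axis=-1).exp()


@dataclass
class CoupledNets:
    """Container for the five networks plus the label vocabulary."""

    encoder_rna: MLP
    encoder_atac: MLP
    decoder_rna: MLP
    decoder_atac: MLP
    discriminator: Discriminator
    classifier: Classifier | None
    latent_dim: int
    dim_rna: int
    dim_atac: int
    classes: list[str]

    def encoder(self, modality: str) -> MLP:
        return self.encoder_rna if modality == "rna" else self.encoder_atac

    def decoder(self, modality: str) -> MLP:
        return self.decoder_rna if modality == "rna" else self.decoder_atac

    def generator_parameters(self) -> list[Tensor]:
        params = (
            self.encoder_rna.parameters()
            + self.encoder_atac.parameters()
            + self.decoder_rna.parameters()
            + self.decoder_atac.parameters()
        )
        if self.classifier is not None:
            params += self.classifier.parameters()
        return params

    # ------------------------------------------------------------- inference
    def encode_t(self, x: Tensor, modality: str) -> Tensor:
        enc = self.encoder(modality)
        if x.shape[-1] != enc.n_in:
            raise ValueError(
                f"{modality} encoder expects {enc.n_in} features, got {x.shape[-1]}"
            )
        return enc(x)

    def encode(self, m: OmicsMatrix | np.ndarray, modality: str | None = None) -> LatentEmbedding:
        """Deterministically embed a matrix (inference mode, no grad)."""
        if isinstance(m, OmicsMatrix):
            values, cell_ids, modality = m.values, m.cell_ids, m.modality
        else:
            if modality is None:
                raise ValueError("modality required when passing a bare array")
            values = np.asarray(m, dtype=np.float64)
            cell_ids = [str(i) for i in range(values.shape[0])]
        with no_grad():
            coords = self.encode_t(Tensor(values), modality).data
        return LatentEmbedding(coords=coords, modality=modality, cell_ids=cell_ids)

    # ------------------------------------------------------------ persistence
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for name, mod in self._modules():
            for i, p in enumerate(mod.parameters()):
                arrays[f"{name}.{i}"] = p.data
        return arrays

    def _modules(self):
        mods = [
            ("encoder_rna", self.encoder_rna),
            ("encoder_atac", self.encoder_atac),
            ("decoder_rna", self.decoder_rna),
            ("decoder_atac", self.decoder_atac),
            ("discriminator", self.discriminator),
        ]
        if self.classifier is not None:
            mods.append(("classifier", self.classifier))
        return mods

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights plus the architecture spec."""
        spec = {
            "latent_dim": self.latent_dim,
            "dim_rna": self.dim_rna,
            "dim_atac": self.dim_atac,
            "classes": self.classes,
            "hidden": [l.n_out for l in self.encoder_rna.layers[:-1]],
            "disc_hidden": [l.n_out for l in self.discriminator.net.layers[:-1]],
        }
        np.savez(path, __spec__=np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "CoupledNets":
        with np.load(path) as arc:
            spec = json.loads(bytes(arc["__spec__"].tobytes()).decode())
            nets = build_networks(
                dim_rna=spec["dim_rna"],
                dim_atac=spec["dim_atac"],
                latent_dim=spec["latent_dim"],
                hidden=tuple(spec["hidden"]),
                disc_hidden=tuple(spec["disc_hidden"]),
                classes=spec["classes"],
                seed=0,
            )
            for name, mod in nets._modules():
                for i, p in enumerate(mod.parameters()):
                    p.data = arc[f"{name}.{i}"]
        return nets


def build_networks(
    dim_rna: int,
    dim_atac: int,
    latent_dim: int = 50,
    hidden: tuple[int, ...] = (64, 64),
    disc_hidden: tuple[int, ...] = (64,),
    classes: list[str] | None = None,
    seed: int = 0,
) -> CoupledNets:
    """Construct all five networks with named per-network init streams."""
    classes = list(classes) if classes else []
    nets = CoupledNets(
        encoder_rna=MLP(dim_rna, hidden, latent_dim, named_stream(seed, "init_encoder_rna")),
        encoder_atac=MLP(dim_atac, hidden, latent_dim, named_stream(seed, "init_encoder_atac")),
        decoder_rna=MLP(latent_dim, hidden, dim_rna, named_stream(seed, "init_decoder_rna")),
        decoder_atac=MLP(latent_dim, hidden, dim_atac, named_stream(seed, "init_decoder_atac")),
        discriminator=Discriminator(latent_dim, disc_hidden, named_stream(seed, "init_disc")),
        classifier=(
            Classifier(latent_dim, len(classes), named_stream(seed, "init_classifier"))
            if classes
            else None
        ),
        latent_dim=latent_dim,
        dim_rna=dim_rna,
        dim_atac=dim_atac,
        classes=classes,
    )
    return nets
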