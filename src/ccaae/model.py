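"""Model / Results interface for the contrastive cycle-consistent AAE.

:class:`ContrastiveCycleAAE` is built from a :class:`~ccaae.data.PairedDataset`
(two modality views of the same cells); :meth:`ContrastiveCycleAAE.fit` runs
the two-stage adversarial training and returns a
:class:`ContrastiveCycleAAEResults` carrying the trained networks, the full
loss log, and evaluation of alignment (recall@k) and integration (nearest
cross-modal neighbour cell-type accuracy) on the held-out split.

Example
-------
>>> from ccaae import synthetic, ContrastiveCycleAAE
>>> data = synthetic.generate(synthetic.SyntheticConfig(n_cells=600, seed=0))
>>> res = ContrastiveCycleAAE(data, latent_dim=8, seed=0).fit(n_outer_iterations=200)
>>> report = res.evaluate()
>>> 0.0 <= report.integration_accuracy <= 1.0
True
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import OmicsMatrix, PairedDataset, pair_matrices, split_dataset
from .evaluation import (
    DEFAULT_KS,
    EvaluationReport,
    evaluate_embeddings,
    export_embeddings,
    transfer_labels,
)
from .losses import LossWeights
from .networks import CoupledNets, LatentEmbedding, build_networks
from .training import TrainConfig, TrainLog, train

__all__ = ["ContrastiveCycleAAE", "ContrastiveCycleAAEResults"]


class ContrastiveCycleAAE:
    """Coupled adversarial autoencoder over a paired two-modality dataset.

    Parameters
    ----------
    data
        Paired RNA/ATAC dataset.  If it has no train/test split one is made
        (stratified 80/20) at ``fit`` time using the model seed.
    latent_dim
        Dimension of the coordinated subspace.
    hidden, disc_hidden
        Hidden-layer widths of the encoder/decoder MLPs and of the
        discriminator.
    loss_weights
        Relative weights and distance convention of the loss terms.
    seed
        Fans out into named substreams for initialisation, splitting and
        batch sampling; fixing it makes the whole fit bitwise reproducible.
    """

    def __init__(
        self,
        data: PairedDataset,
        latent_dim: int = 50,
        hidden: tuple[int, ...] = (64, 64),
        disc_hidden: tuple[int, ...] = (64,),
        loss_weights: LossWeights | None = None,
        test_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.data = data
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        self.disc_hidden = tuple(disc_hidden)
        self.loss_weights = loss_weights or LossWeights()
        self.test_fraction = test_fraction
        self.seed = seed
        self.classes = (
            sorted(np.unique(data.labels.astype(str))) if data.labels is not None else []
        )

    @classmethod
    def from_matrices(cls, rna: OmicsMatrix, atac: OmicsMatrix, **kwargs) -> "ContrastiveCycleAAE":
        """Build the model from two modality matrices (paired by cell_id)."""
        return cls(pair_matrices(rna, atac), **kwargs)

    def build(self, seed: int | None = None) -> CoupledNets:
        return build_networks(
            dim_rna=self.data.rna.n_features,
            dim_atac=self.data.atac.n_features,
            latent_dim=self.latent_dim,
            hidden=self.hidden,
            disc_hidden=self.disc_hidden,
            classes=self.classes,
            seed=self.seed if seed is None else seed,
        )

    def fit(
        self,
        n_outer_iterations: int = 2000,
        config: TrainConfig | None = None,
        **config_overrides,
    ) -> "ContrastiveCycleAAEResults":
        """Train and return a results object.

        Either pass a full :class:`TrainConfig` or override fields of the
        default one by keyword (e.g. ``batch_size=32``).
        """
        if config is None:
            config = TrainConfig(
                n_outer_iterations=n_outer_iterations,
                seed=self.seed,
                loss_weights=self.loss_weights,
                **config_overrides,
            )
        elif config_overrides:
            config = dc_replace(config, **config_overrides)
        data = self.data
        if data.split_assignment is None:
            data = split_dataset(
                data,
                test_fraction=self.test_fraction,
                seed=self.seed,
                stratify=data.labels is not None,
            )
        nets = self.build(seed=config.seed)
        nets, log = train(nets, data.train, config)
        return ContrastiveCycleAAEResults(model=self, nets=nets, log=log,
                                          data=data, config=config)


@dataclass
class ContrastiveCycleAAEResults:
    """Fitted model: trained networks, training log, and evaluation helpers."""

    model: ContrastiveCycleAAE
    nets: CoupledNets
    log: TrainLog
    data: PairedDataset
    config: TrainConfig

    # ------------------------------------------------------------- embeddings
    def encode(self, which: str = "test") -> dict[str, LatentEmbedding]:
        """Embed both modalities of a split ('train', 'test' or 'all')."""
        subset = self.data if which == "all" else getattr(self.data, which)
        return {m: self.nets.encode(getattr(subset, m)) for m in ("rna", "atac")}

    # -------------------------------------------------------------- evaluation
    def evaluate(self, which: str = "test", ks: Sequence[int] = DEFAULT_KS) -> EvaluationReport:
        subset = self.data if which == "all" else getattr(self.data, which)
        emb = self.encode(which)
        report = evaluate_embeddings(emb["atac"], emb["rna"], subset.labels, ks=ks)
        report.settings = {
            "split": which,
            "latent_dim": self.model.latent_dim,
            "seed": self.config.seed,
            "n_outer_iterations": self.config.n_outer_iterations,
        }
        return report

    def transfer_labels(self, which: str = "test"):
        """Nearest-RNA-neighbour label transfer onto the ATAC cells."""
        subset = self.data if which == "all" else getattr(self.data, which)
        emb = self.encode(which)
        return transfer_labels(emb["atac"], emb["rna"], subset.labels, subset.labels)

    def export_embeddings(self, path, which: str = "test") -> Path:
        subset = self.data if which == "all" else getattr(self.data, which)
        return export_embeddings(self.nets, subset, path)

    def save(self, path) -> None:
        self.nets.save(path)

    # ---------------------------------------------------------------- summary
    def summary(self, ks: Sequence[int] = DEFAULT_KS) -> str:
        report = self.evaluate(ks=ks)
        gen = self.log.to_frame()
        gen = gen[gen["stage"] == "generator"]
        last = gen.iloc[-1] if len(gen) else None
        lines = [
            "Contrastive cycle-consistent adversarial autoencoder",
            "====================================================",
            f"cells (train/test):    {self.data.train.n_cells}/{self.data.test.n_cells}",
            f"features (rna/atac):   {self.nets.dim_rna}/{self.nets.dim_atac}",
            f"latent dim:            {self.nets.latent_dim}",
            f"cell types:            {len(self.nets.classes)}",
            f"outer iterations:      {self.config.n_outer_iterations} "
            f"(k1={self.config.k1}, k2={self.config.k2}, batch={self.config.batch_size})",
            f"seed:                  {self.config.seed}",
            "",
            "Final generator-stage losses:",
        ]
        if last is not None:
            for comp in ("recon", "cyc", "con", "cls", "adv_gen", "mmd", "anchor"):
                if comp in last and np.isfinite(last.get(comp, np.nan)):
                    lines.append(f"  {comp:<10} {last[comp]:.4f}")
        lines += ["", "Test-set performance:"]
        lines.append(f"  integration accuracy   {report.integration_accuracy:.4f}")
        for k, v in sorted(report.recall_at_k.items()):
            lines.append(f"  recall@{k:<3}             {v:.4f}")
        if report.label_transfer_accuracy is not None:
            lines.append(f"  label transfer         {report.label_transfer_accuracy:.4f}")
        return "\n".join(lines)
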