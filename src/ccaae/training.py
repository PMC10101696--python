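"""Two-stage alternating optimisation of the coupled adversarial autoencoder.

Each outer iteration runs ``k1`` generator-group steps (encoders, decoders
and classifier descend the weighted sum of reconstruction, cycle,
contrastive, classifier, adversarial-generator and optional anchor terms)
followed by ``k2`` discriminator steps (the discriminator alone descends
its binary cross-entropy).  Mini-batches are sampled independently per
modality — pairing is never used unless the anchor weight is positive —
and hard triplet mining happens inside each generator step on the current
two-modality batch pool.

Every random draw comes from a named substream of the config seed, so runs
are bitwise reproducible and the per-modality batch streams of a joint run
coincide with those of a single-autoencoder run at the same seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .autodiff import Tensor, cat
from .data import PairedDataset
from .evaluation import EvaluationReport, evaluate_embeddings
from .losses import (
    LossWeights,
    adversarial_losses,
    anchor_loss,
    classifier_loss,
    contrastive_loss,
    cycle_consistency_loss,
    mmd_loss,
    reconstruction_loss,
)
from .networks import CoupledNets, build_networks, named_stream
from .nn import Adam

__all__ = ["TrainConfig", "TrainLog", "train", "ablation_run", "standard_variants"]

AdversarialMode = Literal["adv", "mmd", "none"]


@dataclass
class TrainConfig:
    """Optimisation settings for :func:`train`.

    ``k1``/``k2`` are the generator-group and discriminator steps per outer
    iteration; ``batch_size`` is the per-modality mini-batch size m.  The
    iteration budget is fixed (no early stopping) so runs are
    deterministic.
    """

    n_outer_iterations: int = 2000
    k1: int = 1
    k2: int = 2
    batch_size: int = 64
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    adversarial_mode: AdversarialMode = "adv"
    mmd_bandwidths: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)

    def __post_init__(self):
        for name in ("n_outer_iterations", "k1", "k2", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.adversarial_mode not in ("adv", "mmd", "none"):
            raise ValueError(f"unknown adversarial_mode {self.adversarial_mode!r}")


@dataclass
class TrainLog:
    """Per-step loss records; exactly ``n_outer * (k1 + k2)`` entries."""

    records: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        for key, value in record.items():
            if isinstance(value, float) and not np.isfinite(value):
                raise RuntimeError(f"non-finite {key} recorded")
        self.records.append(record)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def loss_sequence(self, component: str = "total") -> np.ndarray:
        return np.asarray(
            [r[component] for r in self.records if component in r], dtype=np.float64
        )

    def __len__(self) -> int:
        return len(self.records)


def _component_value(name: str, tensor: Tensor) -> float:
    value = float(tensor.data)
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss component {name!r}; aborting training")
    return value


def train(
    nets: CoupledNets, data: PairedDataset, config: TrainConfig
) -> tuple[CoupledNets, TrainLog]:
    """Run the two-stage scheme on the (train-split) dataset; returns the log.

    The generator group and discriminator have disjoint optimisers; each
    group's parameters stay frozen during the other's stage.
    """
    w = config.loss_weights
    need_labels = w.w_con > 0 or w.w_cls > 0
    if need_labels:
        if data.labels is None:
            raise ValueError("contrastive/classifier losses need per-cell labels")
        if w.w_con > 0 and len(np.unique(data.labels.astype(str))) < 2:
            raise ValueError("contrastive loss needs at least two cell-type labels")

    x_rna = data.rna.values
    x_atac = data.atac.values
    labels = None if data.labels is None else data.labels.astype(str)
    n = data.n_cells
    bs = min(config.batch_size, n)

    streams = {
        name: named_stream(config.seed, name)
        for name in ("batch_rna", "batch_atac", "disc_rna", "disc_atac")
    }
    gen_opt = Adam(nets.generator_parameters(), lr=config.lr_generator, betas=config.betas)
    disc_params = nets.discriminator.parameters()
    disc_opt = Adam(disc_params, lr=config.lr_discriminator, betas=config.betas)

    log = TrainLog()
    t0 = time.perf_counter()
    for outer in range(config.n_outer_iterations):
        for step in range(config.k1):
            idx_r = streams["batch_rna"].integers(0, n, size=bs)
            idx_a = streams["batch_atac"].integers(0, n, size=bs)
            xr, xa = Tensor(x_rna[idx_r]), Tensor(x_atac[idx_a])

            components: dict[str, float] = {}
            total = None

            def add(name: str, weight: float, term: Tensor):
                nonlocal total
                components[name] = _component_value(name, term)
                weighted = weight * term
                total = weighted if total is None else total + weighted

            if w.w_recon > 0:
                add("recon", w.w_recon, reconstruction_loss(nets, xr, xa, w.distance))
            if w.w_cyc > 0:
                add("cyc", w.w_cyc, cycle_consistency_loss(nets, xr, xa, w.distance))
            if w.w_con > 0 or w.w_cls > 0 or config.adversarial_mode != "none":
                zr = nets.encode_t(xr, "rna")
                za = nets.encode_t(xa, "atac")
            if w.w_con > 0:
                pool_labels = np.concatenate([labels[idx_r], labels[idx_a]])
                if len(np.unique(pool_labels)) >= 2:
                    add(
                        "con",
                        w.w_con,
                        contrastive_loss(cat([zr, za]), pool_labels, w.margin_alpha, w.distance),
                    )
                else:  # degenerate batch: a single label has no negatives
                    components["con"] = 0.0
            if w.w_cls > 0:
                pool_labels = np.concatenate([labels[idx_r], labels[idx_a]])
                add("cls", w.w_cls, classifier_loss(nets, cat([zr, za]), pool_labels))
            if w.w_adv > 0 and config.adversarial_mode == "adv":
                _, gen_adv = adversarial_losses(nets, zr, za)
                add("adv_gen", w.w_adv, gen_adv)
            elif w.w_adv > 0 and config.adversarial_mode == "mmd":
                add("mmd", w.w_adv, mmd_loss(zr, za, config.mmd_bandwidths))
            if w.w_anchor > 0:
                # anchor supervision uses the rna batch's true partners
                add("anchor", w.w_anchor, anchor_loss(nets, xr, Tensor(x_atac[idx_r]), w.distance))

            if total is None:
                raise ValueError("all loss weights are zero; nothing to train")
            gen_opt.zero_grad()
            disc_opt.zero_grad()
            total.backward()
            gen_opt.step()
            log.append(
                stage="generator",
                outer=outer,
                step=step,
                total=_component_value("total", total),
                wall_time=time.perf_counter() - t0,
                **components,
            )

        for step in range(config.k2):
            idx_r = streams["disc_rna"].integers(0, n, size=bs)
            idx_a = streams["disc_atac"].integers(0, n, size=bs)
            if config.adversarial_mode == "adv" and w.w_adv > 0:
                zr = nets.encode(x_rna[idx_r], "rna").coords
                za = nets.encode(x_atac[idx_a], "atac").coords
                disc_loss, _ = adversarial_losses(nets, Tensor(zr), Tensor(za))
                gen_opt.zero_grad()
                disc_opt.zero_grad()
                disc_loss.backward()
                disc_opt.step()
                value = _component_value("disc", disc_loss)
            else:  # mmd / none variants have no discriminator to train
                value = 0.0
            log.append(
                stage="discriminator",
                outer=outer,
                step=step,
                total=value,
                disc=value,
                wall_time=time.perf_counter() - t0,
            )
    return nets, log


# ------------------------------------------------------------------- ablations
#: toggle vocabulary for ablation variants
TOGGLES = {"no_adv", "mmd", "no_cyc", "no_con", "no_cls", "anchor"}


def standard_variants() -> dict[str, set[str]]:
    """The standard ablation layout: three adversarial regimes x loss combos."""
    base = {
        "base": {"no_cyc", "no_con"},
        "+anchor": {"no_cyc", "no_con", "anchor"},
        "+cyc": {"no_con"},
        "+con": {"no_cyc"},
        "+cyc+con": set(),
    }
    out: dict[str, set[str]] = {}
    for prefix, extra in (("noadv", {"no_adv"}), ("mmd", {"mmd"}), ("adv", set())):
        for name, toggles in base.items():
            out[f"{prefix}:{name}"] = toggles | extra
    return out


def _apply_toggles(config: TrainConfig, toggles: set[str]) -> TrainConfig:
    unknown = toggles - TOGGLES
    if unknown:
        raise ValueError(f"unknown ablation toggles {sorted(unknown)}")
    if "no_adv" in toggles and "mmd" in toggles:
        raise ValueError("no_adv and mmd are mutually exclusive")
    w = replace(config.loss_weights)
    mode = config.adversarial_mode
    if "no_adv" in toggles:
        mode = "none"
    if "mmd" in toggles:
        mode = "mmd"
    if "no_cyc" in toggles:
        w = replace(w, w_cyc=0.0)
    if "no_con" in toggles:
        w = replace(w, w_con=0.0)
    if "no_cls" in toggles:
        w = replace(w, w_cls=0.0)
    if "anchor" in toggles:
        w = replace(w, w_anchor=1.0)
    return replace(config, loss_weights=w, adversarial_mode=mode)


def ablation_run(
    data: PairedDataset,
    base_config: TrainConfig,
    variants: dict[str, set[str]] | None = None,
    latent_dim: int = 8,
    hidden: tuple[int, ...] = (64, 64),
    disc_hidden: tuple[int, ...] = (64,),
    ks: tuple[int, ...] = (10,),
) -> tuple[pd.DataFrame, dict[str, EvaluationReport]]:
    """Train one model per variant (shared seed and split) and evaluate each.

    ``data`` must carry a split_assignment; every variant trains on the
    shared train split and is scored on the shared test split.  Returns a
    labelled table plus the full per-variant reports.
    """
    if variants is None:
        variants = {"full": set(), "no_cyc_no_con": {"no_cyc", "no_con"}, "no_adv": {"no_adv"}}
    train_split, test_split = data.train, data.test
    classes = sorted(np.unique(data.labels.astype(str))) if data.labels is not None else []
    rows, reports = [], {}
    for name, toggles in variants.items():
        cfg = _apply_toggles(base_config, toggles)
        nets = build_networks(
            dim_rna=data.rna.n_features,
            dim_atac=data.atac.n_features,
            latent_dim=latent_dim,
            hidden=hidden,
            disc_hidden=disc_hidden,
            classes=classes,
            seed=cfg.seed,
        )
        nets, _ = train(nets, train_split, cfg)
        report = evaluate_embeddings(
            nets.encode(test_split.atac), nets.encode(test_split.rna), test_split.labels, ks=ks
        )
        reports[name] = report
        row = {"variant": name, "toggles": ",".join(sorted(toggles)),
               "integration_accuracy": report.integration_accuracy}
        row.update({f"recall@{k}": v for k, v in report.recall_at_k.items()})
        rows.append(row)
    return pd.DataFrame(rows), reports
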