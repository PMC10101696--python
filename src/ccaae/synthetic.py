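"""Paired two-modality synthetic data with known clusters, pairing and SNR.

Generative procedure (deterministic given the seed):

1. draw one latent centroid per cell type from an isotropic Gaussian scaled
   by ``centroid_scale`` so inter-centroid distances exceed the within-type
   spread (``jitter_sd``);
2. each cell's latent position is its type centroid plus isotropic
   within-type jitter;
3. each modality view is an independent random linear map of the latent
   position passed through a fixed smooth nonlinearity (tanh) — the two
   views share only the latent, so neither is a linear function of the
   other and matching must go through the latent structure;
4. isotropic Gaussian noise is added, scaled so the per-modality global
   variance ratio satisfies ``10*log10(var(signal)/var(noise)) == snr_db``
   (``snr_db=inf`` disables noise);
5. optionally a fraction of ATAC entries is zeroed (dropout mask).

Cells are allocated to types by the deterministic largest-remainder rule,
so with uniform proportions per-type counts differ by at most one.  The
ground-truth pairing is by construction (row ``i`` is the same cell in both
views); the signal/noise decomposition and the true latent are stored in
``PairedDataset.meta`` so the realised SNR can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import OmicsMatrix, PairedDataset

__all__ = ["SyntheticConfig", "generate", "snr_empirical", "paper_grid"]

#: dataset sizes and SNR levels of the standard simulation grid
GRID_SIZES = (1200, 2100, 3000, 6000)
GRID_SNRS_DB = (0, 5, 10, 15, 20, 25)


@dataclass
class SyntheticConfig:
    """Settings for one synthetic paired dataset.

    ``snr_db`` is the per-modality signal-to-noise ratio in decibels
    (``np.inf`` for noise-free data).  ``type_proportions`` defaults to
    uniform.
    """

    n_cells: int = 1200
    n_types: int = 4
    latent_dim_true: int = 10
    dim_rna: int = 200
    dim_atac: int = 300
    snr_db: float = 25.0
    type_proportions: Sequence[float] | None = None
    seed: int = 0
    centroid_scale: float = 3.0
    jitter_sd: float = 1.0
    atac_dropout: float = 0.0

    def __post_init__(self):
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if self.n_cells < self.n_types:
            raise ValueError("n_cells must be >= n_types")
        if min(self.dim_rna, self.dim_atac, self.latent_dim_true) < 2:
            raise ValueError("latent and view dimensions must be >= 2")
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")
        if self.type_proportions is not None:
            p = np.asarray(self.type_proportions, dtype=float)
            if len(p) != self.n_types:
                raise ValueError("type_proportions length must equal n_types")
            if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("type_proportions must be positive and sum to 1")
        if not 0.0 <= self.atac_dropout < 1.0:
            raise ValueError("atac_dropout must be in [0, 1)")


def _allocate_counts(n_cells: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``n_cells`` across types."""
    exact = proportions * n_cells
    counts = np.floor(exact).astype(int)
    if np.any(exact < 1.0):
        bad = np.flatnonzero(exact < 1.0)
        raise ValueError(
            f"infeasible type_proportions: types {list(bad)} have expected count < 1"
        )
    remainder = exact - counts
    short = n_cells - counts.sum()
    # ties broken by lowest type index (stable sort on negated remainder)
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def _view(latent: np.ndarray, dim_out: int, rng: np.random.Generator) -> np.ndarray:
    d = latent.shape[1]
    W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, dim_out))
    b = rng.normal(0.0, 0.1, size=dim_out)
    return np.tanh(latent @ W + b)


def generate(config: SyntheticConfig) -> PairedDataset:
    """Generate one paired dataset under ``config`` (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    k, n = config.n_types, config.n_cells
    props = (
        np.full(k, 1.0 / k)
        if config.type_proportions is None
        else np.asarray(config.type_proportions, dtype=float)
    )
    counts = _allocate_counts(n, props)
    type_idx = np.repeat(np.arange(k), counts)

    centroids = rng.normal(0.0, config.centroid_scale, size=(k, config.latent_dim_true))
    latent = centroids[type_idx] + rng.normal(
        0.0, config.jitter_sd, size=(n, config.latent_dim_true)
    )

    views: dict[str, np.ndarray] = {}
    meta: dict = {"config": config, "latent": latent, "type_idx": type_idx}
    for modality, dim in (("rna", config.dim_rna), ("atac", config.dim_atac)):
        signal = _view(latent, dim, rng)
        sig_var = signal.var()
        if np.isinf(config.snr_db):
            noise = np.zeros_like(signal)
        else:
            noise_var = sig_var / (10.0 ** (config.snr_db / 10.0))
            noise = rng.normal(0.0, np.sqrt(noise_var), size=signal.shape)
        values = signal + noise
        if modality == "atac" and config.atac_dropout > 0:
            mask = rng.random(signal.shape) < config.atac_dropout
            values = np.where(mask, 0.0, values)
        views[modality] = values
        meta[f"{modality}_signal"] = signal
        meta[f"{modality}_noise"] = noise

    labels = np.asarray([f"type_{t}" for t in type_idx], dtype=object)
    cell_ids = [f"cell_{i:06d}" for i in range(n)]
    rna = OmicsMatrix(
        views["rna"], cell_ids, [f"gene_{j}" for j in range(config.dim_rna)], "rna", labels
    )
    atac = OmicsMatrix(
        views["atac"], cell_ids, [f"peak_{j}" for j in range(config.dim_atac)], "atac", labels
    )
    return PairedDataset(rna=rna, atac=atac, labels=labels, meta=meta)


def snr_empirical(d: PairedDataset) -> dict[str, float]:
    """Realised per-modality SNR in dB, ``10*log10(var(signal)/var(noise))``.

    Requires the signal/noise decomposition stored by :func:`generate`.
    """
    out = {}
    for modality in ("rna", "atac"):
        sig = d.meta.get(f"{modality}_signal")
        noise = d.meta.get(f"{modality}_noise")
        if sig is None or noise is None:
            raise ValueError(
                "dataset lacks the generator's signal/noise decomposition metadata"
            )
        noise_var = noise.var()
        out[modality] = (
            np.inf if noise_var == 0 else 10.0 * np.log10(sig.var() / noise_var)
        )
    return out


def paper_grid(seed: int = 0, **overrides) -> list[SyntheticConfig]:
    """The standard 24-dataset grid: sizes 1200/2100/3000/6000 x SNR 0–25 dB."""
    configs = []
    for i, n in enumerate(GRID_SIZES):
        for j, snr in enumerate(GRID_SNRS_DB):
            configs.append(
                SyntheticConfig(
                    n_cells=n, snr_db=float(snr), seed=seed + 100 * i + j, **overrides
                )
            )
    return configs
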