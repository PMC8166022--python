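"""Synthetic multi-layer pharmacogenomic datasets with planted structure.

The generator emulates, at desk scale, the data inventory an ML-CDN is
built from: cell lines and drugs fall into latent blocks; the response of
cell line i to drug j is a block-level mean plus Gaussian noise, so that
similar cell lines and similar drugs respond similarly -- the core modelling
assumption.  Each similarity layer is a noisy view of the block structure:
a continuous pathway-activity-like layer (block centroids plus noise), two
binary status layers per side (block-specific bit patterns with per-entity
bit flips), and a drug sensitivity layer derived from the response itself
with independent noise (as pan-cancer IC50 profiles are in practice).
The noiseless block-mean matrix is kept as ground truth so parameter
recovery can be scored against signal rather than irreducible noise.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BINARY, CONTINUOUS, FeatureMatrix, ResponseMatrix
from .model import PredictionResult

__all__ = ["SynthConfig", "SyntheticDataset", "SynthTruth", "generate", "truth_eval"]

_BLOCK_BIT_DENSITY = 0.5


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a 50-cell-line / 40-drug screen with 5 cell blocks
    and 4 drug blocks, block means spread with sd 1.0, within-block
    response noise sd 0.1, and 20% of responses missing at random.
    """

    n_cells: int = 50
    n_drugs: int = 40
    n_cell_blocks: int = 5
    n_drug_blocks: int = 4
    n_pathway_features: int = 50
    n_binary_features_per_layer: int = 100
    fingerprint_bits: int = 256
    block_response_sd: float = 1.0
    noise_sd: float = 0.1
    feature_noise_sd: float = 0.3
    bit_flip_prob: float = 0.05
    missing_frac: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        counts = {
            "n_cells": self.n_cells,
            "n_drugs": self.n_drugs,
            "n_cell_blocks": self.n_cell_blocks,
            "n_drug_blocks": self.n_drug_blocks,
            "n_pathway_features": self.n_pathway_features,
            "n_binary_features_per_layer": self.n_binary_features_per_layer,
            "fingerprint_bits": self.fingerprint_bits,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_cell_blocks > self.n_cells:
            raise ValueError("n_cell_blocks cannot exceed n_cells")
        if self.n_drug_blocks > self.n_drugs:
            raise ValueError("n_drug_blocks cannot exceed n_drugs")
        for name, v in (
            ("bit_flip_prob", self.bit_flip_prob),
            ("missing_frac", self.missing_frac),
        ):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name, v in (
            ("block_response_sd", self.block_response_sd),
            ("noise_sd", self.noise_sd),
            ("feature_noise_sd", self.feature_noise_sd),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class SynthTruth:
    """Planted structure: block labels and the noiseless block-mean
    response expanded to the full cell x drug grid."""

    cell_blocks: np.ndarray
    drug_blocks: np.ndarray
    block_means: np.ndarray  # n_cell_blocks x n_drug_blocks
    matrix: pd.DataFrame  # noiseless cell x drug means


@dataclass
class SyntheticDataset:
    config: SynthConfig
    cell_layers: dict  # path (continuous), cnv, mut (binary)
    drug_layers: dict  # stru, targ (binary), sens (continuous, drugs x cells)
    response: ResponseMatrix
    truth: SynthTruth


def _binary_block_layer(rng, blocks, n_features, flip_prob, ids, prefix):
    patterns = (rng.random((blocks.max() + 1, n_features)) < _BLOCK_BIT_DENSITY).astype(float)
    bits = patterns[blocks]
    flips = rng.random(bits.shape) < flip_prob
    bits = np.abs(bits - flips.astype(float))
    cols = [f"{prefix}{k}" for k in range(n_features)]
    return FeatureMatrix(pd.DataFrame(bits, index=ids, columns=cols), BINARY)


def generate(config: SynthConfig = SynthConfig()) -> SyntheticDataset:
    """Draw a complete synthetic dataset under the given study conditions.

    Entities are assigned to blocks round-robin and then shuffled; block
    response means are N(0, block_response_sd); responses add
    N(0, noise_sd) within-block noise; layers are noisy views of the same
    blocks; missing_frac of the response entries are masked uniformly at
    random.  Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cell_ids = [f"C{i:03d}" for i in range(config.n_cells)]
    drug_ids = [f"D{j:03d}" for j in range(config.n_drugs)]

    cell_blocks = np.arange(config.n_cells) % config.n_cell_blocks
    rng.shuffle(cell_blocks)
    drug_blocks = np.arange(config.n_drugs) % config.n_drug_blocks
    rng.shuffle(drug_blocks)

    mu = rng.normal(0.0, config.block_response_sd, (config.n_cell_blocks, config.n_drug_blocks))
    truth_matrix = mu[cell_blocks][:, drug_blocks]
    resp = truth_matrix + rng.normal(0.0, config.noise_sd, truth_matrix.shape)

    centroids = rng.normal(0.0, 1.0, (config.n_cell_blocks, config.n_pathway_features))
    path_vals = centroids[cell_blocks] + rng.normal(
        0.0, config.feature_noise_sd, (config.n_cells, config.n_pathway_features)
    )
    path = FeatureMatrix(
        pd.DataFrame(path_vals, index=cell_ids, columns=[f"P{k}" for k in range(config.n_pathway_features)]),
        CONTINUOUS,
    )
    cnv = _binary_block_layer(
        rng, cell_blocks, config.n_binary_features_per_layer, config.bit_flip_prob, cell_ids, "G"
    )
    mut = _binary_block_layer(
        rng, cell_blocks, config.n_binary_features_per_layer, config.bit_flip_prob, cell_ids, "G"
    )

    stru = _binary_block_layer(
        rng, drug_blocks, config.fingerprint_bits, config.bit_flip_prob, drug_ids, "bit"
    )
    targ = _binary_block_layer(
        rng, drug_blocks, config.n_binary_features_per_layer, config.bit_flip_prob, drug_ids, "T"
    )
    sens_vals = resp.T + rng.normal(0.0, config.noise_sd, (config.n_drugs, config.n_cells))
    sens = FeatureMatrix(pd.DataFrame(sens_vals, index=drug_ids, columns=cell_ids), CONTINUOUS)

    values = resp.copy()
    total = config.n_cells * config.n_drugs
    n_missing = int(round(config.missing_frac * total))
    if n_missing:
        flat = rng.choice(total, size=n_missing, replace=False)
        values.ravel()[flat] = np.nan
    response = ResponseMatrix(pd.DataFrame(values, index=cell_ids, columns=drug_ids))

    truth = SynthTruth(
        cell_blocks=cell_blocks,
        drug_blocks=drug_blocks,
        block_means=mu,
        matrix=pd.DataFrame(truth_matrix, index=cell_ids, columns=drug_ids),
    )
    return SyntheticDataset(
        config=config,
        cell_layers={"path": path, "cnv": cnv, "mut": mut},
        drug_layers={"stru": stru, "targ": targ, "sens": sens},
        response=response,
        truth=truth,
    )


def truth_eval(dataset: SyntheticDataset, predictions: PredictionResult) -> tuple[float, float]:
    """Score predictions on the masked (held-out) entries against the
    noiseless block means.

    Returns (pearson_r, rmse) versus ground truth, not the noisy draws, so
    model error is separated from irreducible noise.  Requires the
    predictions to cover every masked entry.
    """
    from .evaluate import pearson_and_rmse

    observed = dataset.response.observed_mask.to_numpy()
    masked = ~observed
    if not masked.any():
        raise ValueError("dataset has no masked (held-out) entries")
    pred = predictions.values.reindex(
        index=dataset.response.cell_ids, columns=dataset.response.drug_ids
    ).to_numpy()
    pred_v = pred[masked]
    if not np.isfinite(pred_v).all():
        raise ValueError("predictions do not cover every masked entry")
    truth_v = dataset.truth.matrix.to_numpy()[masked]
    return pearson_and_rmse(truth_v, pred_v)
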