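"""Static (atemporal) autoencoder baseline over last-observation vectors.

Each period is collapsed to the last observed value of every feature within
its 365-day window (0 where never observed); the squared-error loss is
summed only over observed cells, so the zero-imputed entries never drive
the reconstruction. Architecture: linear encoder to a tanh bottleneck,
linear decoder. Fold assignments are shared with the temporal model so the
two embeddings are directly comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from aomphen.errors import ConfigError, ContractError
from aomphen.models.optim import Adam
from aomphen.models.training import FoldResult, TrainConfig


def init_sae_params(n_features: int, hidden: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    k = 1.0 / np.sqrt(max(n_features, hidden))
    return {
        "W1": rng.uniform(-k, k, size=(n_features, hidden)),
        "b1": np.zeros(hidden),
        "W2": rng.uniform(-k, k, size=(hidden, n_features)),
        "b2": np.zeros(n_features),
    }


def sae_forward(params, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bottleneck code and reconstruction for a batch of static vectors."""
    h = np.tanh(V @ params["W1"] + params["b1"])
    return h, h @ params["W2"] + params["b2"]


def masked_loss(v_bar: np.ndarray, V: np.ndarray, mask: np.ndarray) -> float:
    """Squared error summed over observed (mask=1) cells only."""
    if v_bar.shape != V.shape or mask.shape != V.shape:
        raise ContractError("value, reconstruction and mask shapes must match")
    return float(np.sum(mask * (v_bar - V) ** 2))


def _sae_backward(params, V, mask):
    h, vbar = sae_forward(params, V)
    dvbar = 2.0 * mask * (vbar - V)
    grads = {
        "W2": h.T @ dvbar,
        "b2": dvbar.sum(axis=0),
    }
    dh = dvbar @ params["W2"].T
    da = dh * (1.0 - h ** 2)
    grads["W1"] = V.T @ da
    grads["b1"] = da.sum(axis=0)
    loss = float(np.sum(mask * (vbar - V) ** 2))
    return loss, grads


def train_sae(
    values: np.ndarray | list[np.ndarray],
    masks: np.ndarray | list[np.ndarray],
    config: TrainConfig,
    folds: list[np.ndarray],
    period_ids: np.ndarray,
) -> list[FoldResult]:
    """Train the static autoencoder with the same fold assignments as the
    temporal model; fully masked samples are excluded from training.

    ``values``/``masks`` may be per-fold lists when normalization statistics
    are fold-specific, or single arrays shared across folds.
    """
    if isinstance(values, np.ndarray):
        values = [values] * config.n_folds
    if isinstance(masks, np.ndarray):
        masks = [masks] * config.n_folds
    if len(folds) != config.n_folds or len(values) != config.n_folds:
        raise ConfigError("fold count must match config.n_folds")
    n, D = values[0].shape
    results = []
    all_idx = np.arange(n)
    for k, test_idx in enumerate(folds):
        fold_values, fold_masks = values[k], masks[k]
        empty = np.flatnonzero(fold_masks.sum(axis=1) == 0)
        if empty.size:
            warnings.warn(
                f"{empty.size} fully masked static vectors excluded from training", stacklevel=2
            )
        train_idx = np.setdiff1d(np.setdiff1d(all_idx, test_idx), empty)
        params = init_sae_params(D, config.bottleneck, seed=config.seed + 2000 * (k + 1))
        opt = Adam(params, lr=config.lr)
        rng = np.random.default_rng(config.seed + 2000 * (k + 1) + 1)
        history = []
        best, stale = np.inf, 0
        for _ in range(config.epochs):
            order = rng.permutation(train_idx)
            total = 0.0
            for lo in range(0, len(order), config.batch_size):
                b = order[lo : lo + config.batch_size]
                loss, grads = _sae_backward(params, fold_values[b], fold_masks[b])
                total += loss
                for key in grads:
                    grads[key] /= len(b)
                opt.step(params, grads)
            history.append(total / max(len(train_idx), 1))
            if history[-1] < best - config.min_delta * max(1.0, abs(best)):
                best, stale = history[-1], 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        h, _ = sae_forward(params, fold_values)
        emb = pd.DataFrame(h, columns=[f"h_{j}" for j in range(h.shape[1])])
        emb.insert(0, "period_id", period_ids)
        emb.insert(1, "split", np.where(np.isin(all_idx, test_idx), "test", "train"))
        results.append(FoldResult(fold_id=k, params=params, history=history, embeddings=emb))
    return results
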