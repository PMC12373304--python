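"""Cross-validated training of the recurrent autoencoder.

Periods are partitioned into folds grouped by patient by default, so no
patient contributes periods to both the training and held-out split of a
fold. Each fold's model is trained on the other folds' periods and emits
embeddings for every period, flagged train/test. Normalization statistics
are fold-specific (fitted upstream on the training split only), so the
caller passes one featurized dataset per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aomphen.errors import ConfigError
from aomphen.featurize import TemporalDataset
from aomphen.models.grud import grud_backward, grud_forward, init_grud_params
from aomphen.models.optim import Adam


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 5
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    bottleneck: int = 120
    detach_targets: bool = True
    hidden_decay: bool = True
    fold_by: str = "patient"  # or "period"
    patience: int = 10
    min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.bottleneck < 1:
            raise ConfigError("bottleneck must be >= 1")
        if self.fold_by not in ("patient", "period"):
            raise ConfigError("fold_by must be 'patient' or 'period'")


@dataclass
class FoldResult:
    fold_id: int
    params: dict[str, np.ndarray]
    history: list[float]
    embeddings: pd.DataFrame = field(repr=False)  # period_id, split, h_0..h_{H-1}


def make_folds(person_ids: np.ndarray, config: TrainConfig) -> list[np.ndarray]:
    """Return per-fold held-out index arrays partitioning the periods.

    With patient grouping, patients (not periods) are shuffled and split so
    that all periods of a patient land in one fold.
    """
    person_ids = np.asarray(person_ids)
    n = len(person_ids)
    rng = np.random.default_rng(config.seed)
    if config.fold_by == "patient":
        patients = np.unique(person_ids)
        if len(patients) < config.n_folds:
            raise ConfigError(
                f"{len(patients)} patients cannot populate {config.n_folds} folds"
            )
        patients = rng.permutation(patients)
        folds = []
        for chunk in np.array_split(patients, config.n_folds):
            folds.append(np.flatnonzero(np.isin(person_ids, chunk)))
        return folds
    if n < config.n_folds:
        raise ConfigError(f"{n} periods cannot populate {config.n_folds} folds")
    return [np.sort(c) for c in np.array_split(rng.permutation(n), config.n_folds)]


def _epoch_loss(params, ds: TemporalDataset, idx: np.ndarray) -> float:
    _, xhat, xbar = grud_forward(
        params, ds.X[idx], ds.M[idx], ds.Delta[idx], ds.last_obs[idx], ds.x_mean
    )
    return float(np.sum((xhat - xbar) ** 2) / len(idx))


def train_fold(
    ds: TemporalDataset,
    train_idx: np.ndarray,
    config: TrainConfig,
    fold_seed: int,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Train one fold's autoencoder; returns (params, per-epoch mean loss)."""
    D = ds.X.shape[2]
    params = init_grud_params(D, config.bottleneck, fold_seed, hidden_decay=config.hidden_decay)
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(fold_seed + 1)
    history = [_epoch_loss(params, ds, train_idx)]
    best, stale = history[0], 0
    for _ in range(config.epochs):
        order = rng.permutation(train_idx)
        total = 0.0
        for lo in range(0, len(order), config.batch_size):
            b = order[lo : lo + config.batch_size]
            _, xhat, xbar, cache = grud_forward(
                params, ds.X[b], ds.M[b], ds.Delta[b], ds.last_obs[b], ds.x_mean,
                return_cache=True,
            )
            total += float(np.sum((xhat - xbar) ** 2))
            grads = grud_backward(params, cache, detach_targets=config.detach_targets)
            for k in grads:
                grads[k] /= len(b)
            opt.step(params, grads)
        history.append(total / len(train_idx))
        if history[-1] < best - config.min_delta * max(1.0, abs(best)):
            best, stale = history[-1], 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return params, history


def _embed_frame(params, ds: TemporalDataset, test_idx: np.ndarray) -> pd.DataFrame:
    h, _, _ = grud_forward(params, ds.X, ds.M, ds.Delta, ds.last_obs, ds.x_mean)
    split = np.where(np.isin(np.arange(len(ds)), test_idx), "test", "train")
    out = pd.DataFrame(h, columns=[f"h_{j}" for j in range(h.shape[1])])
    out.insert(0, "period_id", ds.period_ids)
    out.insert(1, "split", split)
    return out


def train_grud_ae(
    fold_datasets: list[TemporalDataset] | TemporalDataset,
    config: TrainConfig,
    folds: list[np.ndarray] | None = None,
) -> list[FoldResult]:
    """Cross-validated training; one model and embedding table per fold.

    ``fold_datasets`` is one dataset per fold (fold-specific normalization)
    or a single dataset reused for every fold. Fold k's model trains on all
    periods outside fold k and embeds every period.
    """
    if isinstance(fold_datasets, TemporalDataset):
        fold_datasets = [fold_datasets] * config.n_folds
    if len(fold_datasets) != config.n_folds:
        raise ConfigError("need one dataset per fold (or a single shared dataset)")
    ref = fold_datasets[0]
    if folds is None:
        folds = make_folds(ref.person_ids, config)
    if len(ref) < config.n_folds:
        raise ConfigError("fewer periods than folds")
    results = []
    all_idx = np.arange(len(ref))
    for k, test_idx in enumerate(folds):
        ds = fold_datasets[k]
        train_idx = np.setdiff1d(all_idx, test_idx)
        params, history = train_fold(ds, train_idx, config, fold_seed=config.seed + 1000 * (k + 1))
        results.append(
            FoldResult(fold_id=k, params=params, history=history,
                       embeddings=_embed_frame(params, ds, test_idx))
        )
    return results
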