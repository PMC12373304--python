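"""Fixed-grid featurization of pre-treatment periods.

Each 365-day pre-treatment window is sampled on a fixed grid of 13 points
spaced 30 days apart, the newest 5 days before treatment initiation and the
oldest 365 days before. Every point carries a 30-day look-back window,
half-open ``(t_k - 30, t_k]``, so adjacent windows never double-count a day;
the newest window therefore spans days 35 to 5 before initiation.

For every measurement feature and grid point we record the mean of the
observations falling in the look-back window (mask 1) or mark the cell
missing (mask 0). The per-cell ``delta`` channel is the time since the last
actual observation, scaled by the 30-day grid spacing: 0 at an observed step
(and at the cold start), otherwise the previous delta plus 30 days. Binary
CCS diagnosis channels are treated as always-observed (absence is an
observed 0), so decay imputation downstream only acts on measurements.

Measurements are z-scored with statistics fitted on the training fold only;
zero-variance features are dropped. A period's *data quality* is the average
over the 13 points of the fraction of measurement channels observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aomphen.cohort import PreAOMPeriod
from aomphen.errors import ConfigError, ContractError, FeatureError

N_POINTS = 13
SPACING_DAYS = 30
LEAD_DAYS = 5
LOOKBACK_DAYS = 30


@dataclass(frozen=True)
class SamplingGrid:
    """The 13 sampling points of one period, ordered oldest to newest."""

    session_start_day: int
    points: tuple[int, ...]
    lookback_days: int = LOOKBACK_DAYS

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_intervals(self) -> int:
        return len(self.points) - 1

    def lookback_window(self, point: int) -> tuple[int, int]:
        """Half-open day window (lo, hi] covered by a sampling point."""
        return point - self.lookback_days, point


def build_sampling_grid(session_start_day: int) -> SamplingGrid:
    """Grid points t_k = start - 5 - 30k for k = 12..0 (oldest first)."""
    points = tuple(session_start_day - LEAD_DAYS - SPACING_DAYS * k for k in reversed(range(N_POINTS)))
    return SamplingGrid(session_start_day=session_start_day, points=points)


@dataclass(frozen=True)
class Normalizer:
    """Train-fold z-scoring statistics for measurement features.

    ``emp_mean`` is the empirical mean of the *normalized* observed training
    values (the decay-to-mean target of the autoencoder; ~0 by construction
    but computed, not assumed). Zero-variance features are dropped.
    """

    feature_ids: tuple[int, ...]
    mean: np.ndarray
    sd: np.ndarray
    emp_mean: np.ndarray
    dropped: tuple[int, ...] = ()

    def normalize(self, feature_id: int, values: np.ndarray) -> np.ndarray:
        i = self.index(feature_id)
        return (np.asarray(values, dtype=float) - self.mean[i]) / self.sd[i]

    def index(self, feature_id: int) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise FeatureError(f"unknown measurement feature id {feature_id!r}") from None


@dataclass
class TemporalTensor:
    """One period's (values, mask, delta, carry-forward) arrays, 13 x D.

    Measurement channels come first, CCS channels after; ``n_meas`` splits
    them. ``delta`` is scaled by the 30-day spacing; ``last_obs`` carries the
    most recent observed normalized value forward (0, the normalized training
    mean, before any observation).
    """

    period_id: int
    X: np.ndarray
    M: np.ndarray
    Delta: np.ndarray
    last_obs: np.ndarray
    n_meas: int

    def __post_init__(self) -> None:
        for a in (self.X, self.M, self.Delta, self.last_obs):
            if a.shape != self.X.shape:
                raise ContractError("tensor components must share one shape")
        if self.X.shape[0] != N_POINTS:
            raise ContractError(f"temporal tensor must have {N_POINTS} time steps")
        if not np.isin(self.M, (0.0, 1.0)).all():
            raise ContractError("mask must be binary")
        if (self.Delta < 0).any():
            raise ContractError("delta must be non-negative")


@dataclass
class TemporalDataset:
    """Stacked tensors for a set of periods (n, 13, D) plus bookkeeping."""

    period_ids: np.ndarray
    person_ids: np.ndarray
    X: np.ndarray
    M: np.ndarray
    Delta: np.ndarray
    last_obs: np.ndarray
    n_meas: int
    feature_names: tuple[str, ...]
    x_mean: np.ndarray  # decay-to-mean target per channel

    def __len__(self) -> int:
        return len(self.period_ids)


@dataclass(frozen=True)
class StaticVector:
    """Last observed value per feature in the window; 0 + mask=0 if never."""

    period_id: int
    values: np.ndarray
    mask: np.ndarray


def _window_values(
    events: pd.DataFrame, lo: int, hi: int
) -> pd.DataFrame:
    """Events with lo < day <= hi."""
    day = events["day"]
    return events[(day > lo) & (day <= hi)]


def _person_groups(events: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {pid: g for pid, g in events.groupby("person_id")} if len(events) else {}


def _window_cell_means(
    days: np.ndarray, cols: np.ndarray, vals: np.ndarray, lo: int, hi: int, n_cols: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean of values with lo < day <= hi; returns (mean, count)."""
    sel = (days > lo) & (days <= hi)
    total = np.zeros(n_cols)
    count = np.zeros(n_cols)
    np.add.at(total, cols[sel], vals[sel])
    np.add.at(count, cols[sel], 1.0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
    return mean, count


def fit_normalizer(
    train_periods: list[PreAOMPeriod],
    measurements: pd.DataFrame,
    feature_ids: list[int],
) -> Normalizer:
    """Fit per-feature z-score statistics on training-fold periods only.

    Statistics are computed over the window-aggregated observed cells (one
    value per period, grid point and feature — the same aggregation the
    tensors use), so a feature observed many times in one window is not
    over-weighted. Features with zero variance are dropped with a warning.
    """
    col_of = {f: i for i, f in enumerate(feature_ids)}
    groups = _person_groups(measurements)
    cells: dict[int, list[float]] = {f: [] for f in feature_ids}
    for period in train_periods:
        ev = groups.get(period.person_id)
        if ev is None:
            continue
        known = ev["feature_id"].isin(col_of)
        days = ev["day"].to_numpy()[known.to_numpy()]
        cols = ev["feature_id"].map(col_of).to_numpy(dtype=float)[known.to_numpy()].astype(int)
        vals = ev["value"].to_numpy()[known.to_numpy()]
        grid = build_sampling_grid(period.window_end)
        for point in grid.points:
            lo, hi = grid.lookback_window(point)
            mean, count = _window_cell_means(days, cols, vals, lo, hi, len(feature_ids))
            for j in np.flatnonzero(count > 0):
                cells[feature_ids[j]].append(float(mean[j]))
    kept, dropped, means, sds = [], [], [], []
    for f in feature_ids:
        vals = np.asarray(cells[f], dtype=float)
        sd = vals.std(ddof=0) if vals.size else 0.0
        if vals.size < 2 or sd <= 1e-12:
            dropped.append(f)
            continue
        kept.append(f)
        means.append(vals.mean())
        sds.append(sd)
    if dropped:
        warnings.warn(f"dropping zero-variance measurement features: {dropped}", stacklevel=2)
    if not kept:
        raise ConfigError("no measurement feature has nonzero variance in the training fold")
    mean = np.asarray(means)
    sd = np.asarray(sds)
    emp = np.array(
        [float(np.mean((np.asarray(cells[f]) - m) / s)) for f, m, s in zip(kept, mean, sd)]
    )
    return Normalizer(
        feature_ids=tuple(kept), mean=mean, sd=sd, emp_mean=emp, dropped=tuple(dropped)
    )


def extract_temporal_tensor(
    period: PreAOMPeriod,
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    ccs_ids: list[int],
    normalizer: Normalizer,
) -> TemporalTensor:
    """Build one period's (X, M, Delta, last_obs) tensor on the 13-point grid.

    Measurement cells take the mean of the observations in the look-back
    window, z-scored with the (train-fold) normalizer. CCS cells are 1 when
    any qualifying diagnosis falls in the window, else 0, always observed.
    """
    ev_m = measurements[measurements["person_id"] == period.person_id]
    ev_d = diagnoses[diagnoses["person_id"] == period.person_id]
    return _extract_tensor_arrays(period, ev_m, ev_d, ccs_ids, normalizer)


def _extract_tensor_arrays(
    period: PreAOMPeriod,
    ev_m: pd.DataFrame,
    ev_d: pd.DataFrame,
    ccs_ids: list[int],
    normalizer: Normalizer,
) -> TemporalTensor:
    meas_ids = list(normalizer.feature_ids)
    n_meas, n_ccs = len(meas_ids), len(ccs_ids)
    D = n_meas + n_ccs
    grid = build_sampling_grid(period.window_end)
    col_of = {f: i for i, f in enumerate(meas_ids)}
    unknown = set(ev_m["feature_id"].unique()) - set(meas_ids) - set(normalizer.dropped)
    if unknown:
        raise FeatureError(f"unknown measurement feature id {sorted(unknown)[0]!r}")
    known = ev_m["feature_id"].isin(col_of).to_numpy() if len(ev_m) else np.zeros(0, bool)
    m_days = ev_m["day"].to_numpy()[known] if len(ev_m) else np.zeros(0, int)
    m_cols = (
        ev_m["feature_id"].map(col_of).to_numpy(dtype=float)[known].astype(int)
        if len(ev_m) else np.zeros(0, int)
    )
    m_raw = ev_m["value"].to_numpy()[known] if len(ev_m) else np.zeros(0)
    m_vals = (m_raw - normalizer.mean[m_cols]) / normalizer.sd[m_cols] if len(m_raw) else m_raw
    ccs_col = {c: i for i, c in enumerate(ccs_ids)}
    d_known = ev_d["ccs_id"].isin(ccs_col).to_numpy() if len(ev_d) else np.zeros(0, bool)
    d_days = ev_d["day"].to_numpy()[d_known] if len(ev_d) else np.zeros(0, int)
    d_cols = (
        ev_d["ccs_id"].map(ccs_col).to_numpy(dtype=float)[d_known].astype(int)
        if len(ev_d) else np.zeros(0, int)
    )

    X = np.zeros((N_POINTS, D))
    M = np.zeros((N_POINTS, D))
    Delta = np.zeros((N_POINTS, D))
    last = np.zeros((N_POINTS, D))
    carry = np.zeros(D)  # normalized training mean = 0
    prev_days = np.zeros(D)
    for t, point in enumerate(grid.points):
        lo, hi = grid.lookback_window(point)
        mean, count = _window_cell_means(m_days, m_cols, m_vals, lo, hi, n_meas)
        X[t, :n_meas] = mean
        M[t, :n_meas] = (count > 0).astype(float)
        _, d_count = _window_cell_means(d_days, d_cols, np.ones_like(d_days, dtype=float), lo, hi, n_ccs)
        X[t, n_meas:] = (d_count > 0).astype(float)
        M[t, n_meas:] = 1.0  # CCS channels are always observed
        # time since last observation: 0 at an observed step and at the cold
        # start; otherwise the previous delta plus one 30-day interval
        days = np.zeros(D) if t == 0 else np.where(M[t] == 1.0, 0.0, prev_days + SPACING_DAYS)
        Delta[t] = days / SPACING_DAYS
        prev_days = days
        last[t] = carry
        carry = np.where(M[t] == 1.0, X[t], carry)
    return TemporalTensor(
        period_id=period.period_id, X=X, M=M, Delta=Delta, last_obs=last, n_meas=n_meas
    )


def build_dataset(
    periods: list[PreAOMPeriod],
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    ccs_ids: list[int],
    normalizer: Normalizer,
) -> TemporalDataset:
    """Stack per-period tensors into one dataset."""
    m_groups = _person_groups(measurements)
    d_groups = _person_groups(diagnoses)
    empty_m = measurements.iloc[0:0]
    empty_d = diagnoses.iloc[0:0]
    tensors = [
        _extract_tensor_arrays(
            p, m_groups.get(p.person_id, empty_m), d_groups.get(p.person_id, empty_d),
            ccs_ids, normalizer,
        )
        for p in periods
    ]
    n_meas = len(normalizer.feature_ids)
    x_mean = np.concatenate([normalizer.emp_mean, np.zeros(len(ccs_ids))])
    names = tuple(f"meas_{f}" for f in normalizer.feature_ids) + tuple(
        f"ccs_{c}" for c in ccs_ids
    )
    return TemporalDataset(
        period_ids=np.array([p.period_id for p in periods]),
        person_ids=np.array([p.person_id for p in periods]),
        X=np.stack([t.X for t in tensors]),
        M=np.stack([t.M for t in tensors]),
        Delta=np.stack([t.Delta for t in tensors]),
        last_obs=np.stack([t.last_obs for t in tensors]),
        n_meas=n_meas,
        feature_names=names,
        x_mean=x_mean,
    )


def compute_quality(tensor: TemporalTensor) -> float:
    """Average over the 13 points of the observed measurement-channel fraction."""
    if tensor.n_meas == 0:
        raise ConfigError("quality requires at least one measurement channel")
    return float(tensor.M[:, : tensor.n_meas].mean())


def quality_table(dataset: TemporalDataset) -> pd.DataFrame:
    """Per-period quality with population quartile labels (Q1 low .. Q4 high)."""
    q = dataset.M[:, :, : dataset.n_meas].mean(axis=(1, 2))
    edges = np.quantile(q, [0.25, 0.5, 0.75])
    labels = np.array(["Q1", "Q2", "Q3", "Q4"])[np.searchsorted(edges, q, side="left")]
    return pd.DataFrame({"period_id": dataset.period_ids, "quality": q, "quartile": labels})


def static_transform(
    period: PreAOMPeriod,
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    ccs_ids: list[int],
    normalizer: Normalizer,
) -> StaticVector:
    """Last observed value per feature within the 365-day window.

    Never-observed measurement features are imputed with 0 and flagged in the
    mask so the static autoencoder can exclude them from its loss. CCS
    channels are binary "any diagnosis in the window" indicators, always
    observed.
    """
    meas_ids = list(normalizer.feature_ids)
    D = len(meas_ids) + len(ccs_ids)
    values = np.zeros(D)
    mask = np.zeros(D)
    ev = measurements[
        (measurements["person_id"] == period.person_id)
        & (measurements["day"] >= period.window_start)
        & (measurements["day"] < period.window_end)
    ]
    for j, f in enumerate(meas_ids):
        sub = ev[ev["feature_id"] == f]
        if len(sub):
            last_day = sub["day"].max()
            vals = sub.loc[sub["day"] == last_day, "value"].to_numpy()
            values[j] = normalizer.normalize(f, vals).mean()
            mask[j] = 1.0
    dv = diagnoses[
        (diagnoses["person_id"] == period.person_id)
        & (diagnoses["day"] >= period.window_start)
        & (diagnoses["day"] < period.window_end)
    ]
    present = set(dv["ccs_id"].unique())
    for j, c in enumerate(ccs_ids):
        values[len(meas_ids) + j] = 1.0 if c in present else 0.0
        mask[len(meas_ids) + j] = 1.0
    return StaticVector(period_id=period.period_id, values=values, mask=mask)


def compute_presence_rates(
    periods: list[PreAOMPeriod],
    events: pd.DataFrame,
    feature_col: str,
    *,
    n_windows: int = 24,
    window_days: int = 30,
) -> pd.DataFrame:
    """Per-feature presence rate across 30-day windows around treatment start.

    Window j covers days ``(start - 365 + 30j, start - 365 + 30(j+1)]``
    relative to each period's treatment start, so j=0..11 tile the
    pre-treatment year (j=11 is the day -35 to -5 interval) and j=12..23
    extend past initiation. The rate is the fraction of periods with at
    least one event of the feature in the window.
    """
    features = sorted(events[feature_col].unique())
    counts = pd.DataFrame(0, index=features, columns=range(n_windows), dtype=float)
    for period in periods:
        start = period.window_end
        ev = events[events["person_id"] == period.person_id]
        if ev.empty:
            continue
        offset = ev["day"].to_numpy() - (start - 365)
        win = np.ceil(offset / window_days - 1e-9).astype(int) - 1  # (0,30] -> 0
        ok = (win >= 0) & (win < n_windows)
        seen = set(zip(ev[feature_col].to_numpy()[ok], win[ok]))
        for f, w in seen:
            counts.loc[f, w] += 1
    rates = counts / max(len(periods), 1)
    rates.index.name = feature_col
    rates.columns = [f"{-365 + window_days * j}_{-365 + window_days * (j + 1)}" for j in range(n_windows)]
    return rates
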