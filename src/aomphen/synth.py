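"""Synthetic OMOP-style EHR generator with planted phenotype clusters.

Emits the four flat tables the pipeline consumes — person, drug_exposure,
measurement, condition — plus a separate latent-label table used only for
evaluation. Exposure records are generated so that every session-building
rule (same-ingredient continuation, subset continuation, early add-on,
gap break, short isolated off-label noise) is exercised at configurable
rates. Clinical events follow a latent-cluster model: each patient carries a
phenotype that sets per-feature measurement means (on the z scale), linear
drift per 30-day step, and per-CCS-category diagnosis prevalences.
Measurement presence is Bernoulli per 30-day sampling window, with a
multiplicative presence spike in the window immediately before treatment
start (days -35 to -5), mimicking the care-intensification bump seen in
real pre-treatment data.

All dates are integer day offsets from a fixed epoch (day 0 = 2010-01-01);
intervals are closed on both ends. Identical configuration (including seed)
yields byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aomphen.errors import ConfigError

EPOCH_YEAR = 2010
DAYS_PER_YEAR = 365

# Ingredient vocabularies; on-label (FDA-approved for obesity) vs off-label.
F_AOM_INGREDIENTS = (
    "bupropion-naltrexone",
    "orlistat",
    "phentermine",
    "phentermine-topiramate",
    "liraglutide",
    "semaglutide",
    "tirzepatide",
)
O_AOM_INGREDIENTS = (
    "metformin",
    "topiramate",
    "canagliflozin",
    "dapagliflozin",
    "empagliflozin",
    "lisdexamfetamine",
    "zonisamide",
)

GENDERS = ("F", "M")
RACES = ("White", "Black", "Hispanic", "Asian", "Other")
RACE_PROBS = (0.45, 0.20, 0.25, 0.07, 0.03)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Latent cluster: measurement means (z units), drift, CCS prevalences."""

    label: int
    meas_means: np.ndarray
    ccs_prevalence: np.ndarray
    trend_slopes: np.ndarray

    def validate(self, n_meas: int, n_ccs: int) -> None:
        if self.meas_means.shape != (n_meas,) or not np.all(np.isfinite(self.meas_means)):
            raise ConfigError(f"phenotype {self.label}: meas_means must be {n_meas} finite values")
        if self.trend_slopes.shape != (n_meas,) or not np.all(np.isfinite(self.trend_slopes)):
            raise ConfigError(f"phenotype {self.label}: trend_slopes must be {n_meas} finite values")
        if self.ccs_prevalence.shape != (n_ccs,) or np.any(
            (self.ccs_prevalence < 0) | (self.ccs_prevalence > 1)
        ):
            raise ConfigError(f"phenotype {self.label}: ccs_prevalence must be {n_ccs} probabilities")


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    ``base_presence`` is the per-feature probability that a measurement is
    observed in any given 30-day sampling window; ``pre_index_spike``
    multiplies it (capped at 1) in the window nearest treatment start.
    """

    n_patients: int
    n_meas_features: int = 15
    n_ccs_features: int = 10
    k_phenotypes: int = 4
    base_presence: float | tuple[float, ...] = 0.5
    pre_index_spike: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    # demographics
    p_female: float = 0.64
    age_range: tuple[int, int] = (18, 75)
    # exposure-pattern rates (per patient, independent)
    emit_primary: bool = True
    p_extend_same: float = 0.30
    p_extend_subset: float = 0.15
    p_extend_superset: float = 0.10
    p_break: float = 0.20
    p_oaom_noise: float = 0.20
    primary_len_range: tuple[int, int] = (150, 300)
    # latent structure
    phenotype_separation: float = 2.0
    ccs_base_prevalence: float = 0.05
    ccs_marker_prevalence: float = 0.70
    trend_slope_sd: float = 0.0
    p_duplicate_obs: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        for name in ("n_meas_features", "n_ccs_features", "k_phenotypes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for p in np.atleast_1d(np.asarray(self.base_presence, dtype=float)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("base_presence entries must lie in [0, 1]")
        for name in ("p_female", "p_extend_same", "p_extend_subset", "p_extend_superset",
                     "p_break", "p_oaom_noise", "p_duplicate_obs"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.pre_index_spike < 0:
            raise ConfigError("noise_sd and pre_index_spike must be non-negative")

    @property
    def presence_vector(self) -> np.ndarray:
        p = np.asarray(self.base_presence, dtype=float)
        if p.ndim == 0:
            return np.full(self.n_meas_features, float(p))
        if p.shape != (self.n_meas_features,):
            raise ConfigError("per-feature base_presence length must equal n_meas_features")
        return p


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent substreams so each table is reproducible in isolation
    return np.random.default_rng([config.seed, stream])


def default_phenotypes(config: SynthConfig) -> list[PhenotypeSpec]:
    """Build K planted phenotypes from the config.

    Means are ``separation`` times a seed-determined random sign pattern, so
    any two phenotypes differ by ~2*separation z units on roughly half the
    features. Each phenotype additionally elevates two 'marker' CCS
    categories from the base prevalence to the marker prevalence.
    """
    rng = _rng(config, 91)
    k, d, c = config.k_phenotypes, config.n_meas_features, config.n_ccs_features
    signs = rng.choice([-1.0, 1.0], size=(k, d))
    # guarantee distinct sign patterns for small d
    for j in range(1, k):
        while any(np.array_equal(signs[j], signs[i]) for i in range(j)):
            signs[j] = rng.choice([-1.0, 1.0], size=d)
    slopes = rng.normal(0.0, config.trend_slope_sd, size=(k, d)) if config.trend_slope_sd > 0 else np.zeros((k, d))
    phenos = []
    for j in range(k):
        prev = np.full(c, config.ccs_base_prevalence)
        prev[[(2 * j) % c, (2 * j + 1) % c]] = config.ccs_marker_prevalence
        phenos.append(
            PhenotypeSpec(
                label=j,
                meas_means=config.phenotype_separation * signs[j],
                ccs_prevalence=prev,
                trend_slopes=slopes[j],
            )
        )
    return phenos


def gen_population(config: SynthConfig, *, allow_empty: bool = False) -> pd.DataFrame:
    """Generate the person table (person_id, gender, birth_year, race)."""
    if config.n_patients <= 0:
        if allow_empty and config.n_patients == 0:
            return pd.DataFrame(columns=["person_id", "gender", "birth_year", "race"])
        raise ConfigError("n_patients must be positive")
    rng = _rng(config, 1)
    n = config.n_patients
    gender = np.where(rng.random(n) < config.p_female, "F", "M")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    race = rng.choice(RACES, size=n, p=RACE_PROBS)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "gender": gender,
            "birth_year": EPOCH_YEAR - age,
            "race": race,
        }
    )


def _format_ingredients(ingredients: tuple[str, ...]) -> str:
    return "|".join(sorted(ingredients))


def gen_exposures(persons: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Generate raw drug-exposure records.

    Each patient receives a primary on-label record long enough to qualify as
    medium/long exposure, plus (at configured rates) records exercising each
    session rule: a same-ingredient continuation within the 40-day gap, a
    short subset continuation, a short early add-on, a gap break opening a
    second (short, non-qualifying) session, and an isolated short off-label
    record that the cohort filter should remove.
    """
    if persons.empty:
        raise ConfigError("persons table is empty")
    rng = _rng(config, 2)
    rows: list[dict] = []
    for pid in persons["person_id"].to_numpy():
        base = tuple(rng.choice(F_AOM_INGREDIENTS, size=2, replace=False))
        start = int(rng.integers(500, 3000))
        if config.emit_primary:
            length = int(rng.integers(*config.primary_len_range))
            rows.append(
                dict(person_id=pid, ingredient_set=_format_ingredients(base),
                     start_day=start, end_day=start + length - 1, is_off_label=False)
            )
            union = set(base)
            cur_end = start + length - 1
            n_extra = 0
            if rng.random() < config.p_extend_superset and n_extra < 3:
                # add-on within 40 d of session start, short record; starts
                # strictly after the primary so chronological order is stable
                s = start + int(rng.integers(1, 41))
                e = s + int(rng.integers(10, 41)) - 1
                added = str(rng.choice([i for i in F_AOM_INGREDIENTS if i not in union]))
                rows.append(dict(person_id=pid, ingredient_set=_format_ingredients(tuple(union | {added})),
                                 start_day=s, end_day=e, is_off_label=False))
                union.add(added)
                cur_end = max(cur_end, e)
                n_extra += 1
            if rng.random() < config.p_extend_subset and n_extra < 3:
                s = cur_end + int(rng.integers(0, 41))
                e = s + int(rng.integers(10, 41)) - 1
                sub = tuple(sorted(union))[:-1]  # drop one component
                rows.append(dict(person_id=pid, ingredient_set=_format_ingredients(sub),
                                 start_day=s, end_day=e, is_off_label=False))
                cur_end = max(cur_end, e)
                n_extra += 1
            if rng.random() < config.p_extend_same and n_extra < 3:
                s = cur_end + int(rng.integers(0, 41))
                e = s + int(rng.integers(30, 121)) - 1
                rows.append(dict(person_id=pid, ingredient_set=_format_ingredients(tuple(union)),
                                 start_day=s, end_day=e, is_off_label=False))
                cur_end = max(cur_end, e)
                n_extra += 1
            if rng.random() < config.p_break and n_extra < 3:
                # gap > 40 d opens a new session; kept short so it never
                # reaches the medium/long exposure threshold
                s = cur_end + int(rng.integers(41, 201))
                e = s + int(rng.integers(30, 100)) - 1
                rows.append(dict(person_id=pid, ingredient_set=_format_ingredients(tuple(union)),
                                 start_day=s, end_day=e, is_off_label=False))
                n_extra += 1
        if rng.random() < config.p_oaom_noise or not config.emit_primary:
            # isolated short off-label record, far from everything else
            s = start - int(rng.integers(600, 1000))
            e = s + int(rng.integers(5, 26)) - 1
            rows.append(dict(person_id=pid, ingredient_set=str(rng.choice(O_AOM_INGREDIENTS)),
                             start_day=s, end_day=e, is_off_label=True))
    df = pd.DataFrame(rows, columns=["person_id", "ingredient_set", "start_day", "end_day", "is_off_label"])
    return df.sort_values(["person_id", "start_day", "end_day"], kind="mergesort").reset_index(drop=True)


def anchor_days(exposures: pd.DataFrame) -> pd.Series:
    """Intended treatment-start day per patient: earliest on-label record start."""
    on_label = exposures[~exposures["is_off_label"]]
    return on_label.groupby("person_id")["start_day"].min()


def gen_clinical_events(
    persons: pd.DataFrame,
    anchors: pd.Series,
    phenotype_assignment: np.ndarray,
    config: SynthConfig,
    phenotypes: list[PhenotypeSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate measurement and diagnosis events driven by latent phenotypes.

    Observed value of feature d at step s (0 = oldest of the 13 sampling
    windows) is ``mean[d] + slope[d]*s + N(0, noise_sd)``; each 30-day window
    is observed with the per-feature presence probability (spiked in the
    newest window). Diagnoses are emitted per CCS category with
    phenotype-specific prevalence, at random days inside the pre-treatment
    year. Returns (measurements, diagnoses, latent_labels); the labels are
    for evaluation only and never enter the feature tables.
    """
    if phenotypes is None:
        phenotypes = default_phenotypes(config)
    for ph in phenotypes:
        ph.validate(config.n_meas_features, config.n_ccs_features)
    assignment = np.asarray(phenotype_assignment)
    if assignment.shape != (len(persons),):
        raise ConfigError("phenotype_assignment must provide one label per person")
    if assignment.min(initial=0) < 0 or assignment.max(initial=0) >= len(phenotypes):
        raise ConfigError("phenotype_assignment labels out of range")
    rng = _rng(config, 3)
    presence = config.presence_vector
    meas_rows: list[tuple] = []
    diag_rows: list[tuple] = []
    label_rows: list[tuple] = []
    for pid, label in zip(persons["person_id"].to_numpy(), assignment):
        label_rows.append((pid, int(label)))
        if pid not in anchors.index:
            continue
        start = int(anchors.loc[pid])
        ph = phenotypes[label]
        for k in range(13):  # k = 0 newest window, 12 oldest
            t_k = start - 5 - 30 * k
            step = 12 - k
            spike = config.pre_index_spike if k == 0 else 1.0
            p_obs = np.minimum(presence * spike, 1.0)
            observed = rng.random(config.n_meas_features) < p_obs
            for d in np.flatnonzero(observed):
                n_obs = 2 if rng.random() < config.p_duplicate_obs else 1
                for _ in range(n_obs):
                    day = int(rng.integers(t_k - 29, t_k + 1))
                    value = ph.meas_means[d] + ph.trend_slopes[d] * step + rng.normal(0.0, config.noise_sd)
                    meas_rows.append((pid, int(d), float(value), day))
        present = rng.random(config.n_ccs_features) < ph.ccs_prevalence
        for c in np.flatnonzero(present):
            for _ in range(int(rng.integers(1, 3))):
                day = int(rng.integers(start - 364, start - 4))
                diag_rows.append((pid, int(c), day))
    measurements = pd.DataFrame(meas_rows, columns=["person_id", "feature_id", "value", "day"])
    diagnoses = pd.DataFrame(diag_rows, columns=["person_id", "ccs_id", "day"])
    labels = pd.DataFrame(label_rows, columns=["person_id", "phenotype"])
    return measurements, diagnoses, labels


def gen_controls(
    case_periods: pd.DataFrame,
    persons_pool: pd.DataFrame,
    config: SynthConfig,
    *,
    age_jitter_years: float = 0.5,
    date_jitter_days: int = 200,
) -> pd.DataFrame:
    """Emit candidate normal-BMI control periods from a non-obese pool.

    Each pool patient contributes one candidate anchored near a randomly
    chosen case period (jittered in age and date) so that realistic pools
    produce a mix of matchable and unmatchable candidates.
    """
    if persons_pool.empty:
        warnings.warn("empty control pool: no candidates generated", stacklevel=2)
        return pd.DataFrame(columns=["control_id", "person_id", "gender", "age_years", "anchor_day"])
    if case_periods.empty:
        raise ConfigError("case_periods must be nonempty")
    rng = _rng(config, 4)
    cases = case_periods.reset_index(drop=True)
    rows = []
    for i, (pid, gender, birth_year) in enumerate(
        zip(persons_pool["person_id"], persons_pool["gender"], persons_pool["birth_year"])
    ):
        case = cases.iloc[int(rng.integers(0, len(cases)))]
        anchor = int(case["anchor_day"]) + int(rng.integers(-date_jitter_days, date_jitter_days + 1))
        age = (EPOCH_YEAR + anchor / DAYS_PER_YEAR) - birth_year + rng.uniform(-age_jitter_years, age_jitter_years)
        rows.append(dict(control_id=i, person_id=pid, gender=gender, age_years=float(age), anchor_day=anchor))
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic dataset as a dict of tables."""
    persons = gen_population(config)
    exposures = gen_exposures(persons, config)
    rng = _rng(config, 5)
    assignment = rng.integers(0, config.k_phenotypes, size=len(persons))
    measurements, diagnoses, labels = gen_clinical_events(
        persons, anchor_days(exposures), assignment, config
    )
    return {
        "person": persons,
        "drug_exposure": exposures,
        "measurement": measurements,
        "condition": diagnoses,
        "labels": labels,
    }


def write_dataset(tables: dict[str, pd.DataFrame], out_dir) -> None:
    """Write each table as CSV under ``out_dir`` (labels kept separate)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
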