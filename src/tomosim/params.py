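"""Parameter schema, published default estimates, config loading and validation.

The parameter set bundles everything the simulator needs: population
statistics (lifetime risk, onset-age distribution, breast-density
distribution by age), tumour growth and radiation-induction models, the
two screening modalities (digital mammography, DM, and digital breast
tomosynthesis, DBT), unit costs, the screening schedule, discounting
schemes and experiment-level settings.  Auxiliary natural-history
parameters (life table, self-detection hazard, post-diagnosis survival)
are not published point estimates; their defaults are calibrated so that
the DM reference scenario reproduces the published screening outcomes
(see :mod:`tomosim.runner`).
"""

from __future__ import annotations

import importlib.resources
import io
import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "ModalityProfile",
    "AuxParameters",
    "DiscountScheme",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "validate_parameters",
    "serialise_parameters",
    "ConfigurationError",
]

#: Upper edges of the age bands used for the breast-density distribution.
DENSITY_BAND_EDGES = (40.0, 50.0, 60.0, 70.0, math.inf)
DENSITY_BAND_LABELS = ("<40", "40-50", "50-60", "60-70", ">70")

#: Upper edges of the age bands used for tumour volume-doubling times.
DOUBLING_BAND_EDGES = (50.0, 70.0, math.inf)
DOUBLING_BAND_LABELS = ("<50", "50-70", ">70")

#: Upper edges (mm) of the tumour-size categories used for treatment
#: costs, cure fractions and reporting: <2 cm, 2-5 cm, >5 cm.
SIZE_CATEGORY_EDGES_MM = (20.0, 50.0, math.inf)
SIZE_CATEGORY_LABELS = ("<2cm", "2-5cm", ">5cm")


class ConfigurationError(ValueError):
    """Raised for unknown keys or malformed values in a config document."""


@dataclass(frozen=True)
class ModalityProfile:
    """Screening modality: detection performance, cost and dose."""

    name: str
    sensitivity_by_density: tuple[float, float, float, float]
    specificity: float
    cost_per_screen: float
    mgd_mean: float  # mean glandular dose per screen, mGy
    mgd_sd: float  # between-exam dose variability, mGy
    detection_threshold: float  # mm; below this sensitivity is zero

    def sensitivity(self, density: int) -> float:
        """Sensitivity for a BI-RADS density category in 1..4."""
        return self.sensitivity_by_density[density - 1]


@dataclass(frozen=True)
class DiscountScheme:
    """Annual discount rates for costs and health effects.

    ``reference_age`` is time zero: an event at that age is undiscounted.
    """

    name: str
    cost_rate: float
    effect_rate: float
    reference_age: float = 50.0


@dataclass(frozen=True)
class AuxParameters:
    """Auxiliary natural-history parameters.

    The published model inputs do not fix the background life table, the
    tumour self-detection hazard or post-diagnosis survival; these live
    here.  ``self_detect_*`` parametrise a logistic hazard in tumour
    diameter, h(d) = hmax / (1 + exp(-(d - midpoint)/slope)) per year.
    ``cure_*`` parametrise the probability that treatment is curative as
    a logistic, *decreasing* in tumour diameter at detection,
    c(d) = cure_max / (1 + exp((d - midpoint)/slope)); an uncured cancer
    is fatal after an exponential survival time with mean
    ``mean_survival_years`` anchored at the age the tumour would have
    surfaced clinically.
    """

    life_table: tuple[tuple[float, float], ...]  # (age, annual death prob)
    self_detect_hmax: float = 7.5  # per year, calibrated
    self_detect_midpoint_mm: float = 34.0  # calibrated
    self_detect_slope_mm: float = 5.0  # calibrated
    cure_max: float = 0.452  # calibrated
    cure_midpoint_mm: float = 32.0  # calibrated
    cure_slope_mm: float = 4.0  # calibrated
    mean_survival_years: float = 5.0
    initial_diameter_mm: float = 0.0019  # calibrated back-extrapolation seed
    max_diameter_mm: float = 128.0
    radiation_latency_years: float = 10.0
    min_doubling_time_days: float = 10.0

    def self_detection_hazard(self, diameter_mm):
        """Annual self-detection hazard at a given tumour diameter."""
        d = np.asarray(diameter_mm, dtype=float)
        z = (d - self.self_detect_midpoint_mm) / self.self_detect_slope_mm
        return self.self_detect_hmax / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def cure_probability(self, diameter_mm):
        """Probability that treatment cures, given diameter at detection."""
        d = np.asarray(diameter_mm, dtype=float)
        z = (d - self.cure_midpoint_mm) / self.cure_slope_mm
        return self.cure_max / (1.0 + np.exp(np.clip(z, -60, 60)))


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated parameter set for the micro-simulation."""

    # population
    lifetime_risk: float = 0.226  # cumulative breast cancer risk by age 70
    onset_age_mean: float = 72.9
    onset_age_sd: float = 21.1
    density_distribution: tuple[tuple[float, float, float, float], ...] = (
        (0.05, 0.30, 0.48, 0.17),  # <40
        (0.06, 0.34, 0.47, 0.13),  # 40-50
        (0.08, 0.50, 0.37, 0.05),  # 50-60
        (0.15, 0.53, 0.29, 0.03),  # 60-70
        (0.18, 0.54, 0.26, 0.02),  # >70
    )
    participation_rate: float = 0.80
    # tumour induction (linear no-threshold in cumulative glandular dose)
    err_per_gy: float = 0.51
    # tumour growth: (mean, sd) volume-doubling time in days per age band
    doubling_time_bands: tuple[tuple[float, float], ...] = (
        (80.0, 28.0),
        (157.0, 25.0),
        (188.0, 52.0),
    )
    # modalities
    dm: ModalityProfile = ModalityProfile(
        name="DM",
        sensitivity_by_density=(0.87, 0.84, 0.73, 0.65),
        specificity=0.965,
        cost_per_screen=64.0,
        mgd_mean=3.0,
        mgd_sd=1.0,
        detection_threshold=5.0,
    )
    dbt: ModalityProfile = ModalityProfile(
        name="DBT",
        sensitivity_by_density=(0.80, 0.80, 0.80, 0.80),
        specificity=0.965,
        cost_per_screen=96.0,
        mgd_mean=4.0,
        mgd_sd=1.3,
        detection_threshold=5.0,
    )
    # costs in case of a positive finding
    cost_biopsy: float = 176.0
    treatment_cost_by_size: tuple[float, float, float] = (6438.0, 7128.0, 7701.0)
    # screening schedule
    screening_start_age: float = 50.0
    screening_end_age: float = 75.0  # exclusive
    screening_interval: float = 2.0
    # economics
    discount_schemes: tuple[DiscountScheme, ...] = (
        DiscountScheme("undiscounted", 0.0, 0.0),
        DiscountScheme("international", 0.03, 0.03),
        DiscountScheme("dutch", 0.04, 0.015),
    )
    wtp: float = 20000.0  # willingness to pay, EUR per life year gained
    # experiment structure
    cohort_size: int = 100_000
    repetitions: int = 10
    master_seed: int = 2020
    # behavioural flags
    risk_model: str = "net"  # "net": P(onset<=70)=lifetime_risk ignoring death
    participation_model: str = "per_woman"  # habitual attenders; or "per_round"
    interval_window_years: float | None = None  # default: screening_interval
    discrete_lyg_discounting: bool = False
    common_random_numbers: bool = True
    aux: AuxParameters = field(default_factory=lambda: AuxParameters(
        life_table=()))

    def __post_init__(self):
        if not self.aux.life_table:
            object.__setattr__(
                self, "aux", replace(self.aux, life_table=_bundled_life_table())
            )

    # -- convenience accessors -------------------------------------------

    def density_row(self, age: float) -> tuple[float, float, float, float]:
        """BI-RADS density probabilities for the age band containing ``age``."""
        idx = int(np.searchsorted(DENSITY_BAND_EDGES, age, side="right"))
        return self.density_distribution[min(idx, len(DENSITY_BAND_EDGES) - 1)]

    def doubling_time_params(self, age: float) -> tuple[float, float]:
        """(mean, sd) doubling time in days for the age band of ``age``."""
        idx = int(np.searchsorted(DOUBLING_BAND_EDGES, age, side="right"))
        return self.doubling_time_bands[min(idx, len(DOUBLING_BAND_EDGES) - 1)]

    def modality(self, name: str) -> ModalityProfile:
        if name.upper() == "DM":
            return self.dm
        if name.upper() == "DBT":
            return self.dbt
        raise KeyError(name)

    def scheme(self, name: str) -> DiscountScheme:
        for s in self.discount_schemes:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def interval_window(self) -> float:
        return (
            self.screening_interval
            if self.interval_window_years is None
            else self.interval_window_years
        )


def size_category(diameter_mm) -> np.ndarray:
    """Tumour size category index (0: <2 cm, 1: 2-5 cm, 2: >5 cm)."""
    d = np.asarray(diameter_mm, dtype=float)
    return np.searchsorted(np.asarray(SIZE_CATEGORY_EDGES_MM[:2]), d, side="left")


def _bundled_life_table() -> tuple[tuple[float, float], ...]:
    text = (
        importlib.resources.files("tomosim.data")
        .joinpath("life_table_female.tsv")
        .read_text()
    )
    return _parse_life_table(io.StringIO(text))


def _parse_life_table(handle) -> tuple[tuple[float, float], ...]:
    rows = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        age_s, q_s = line.split()
        rows.append((float(age_s), float(q_s)))
    return tuple(rows)


def load_life_table(path) -> tuple[tuple[float, float], ...]:
    """Read a two-column (age, annual death probability) text file."""
    with open(path) as fh:
        return _parse_life_table(fh)


def default_parameters() -> ModelParameters:
    """The published default parameter set plus calibrated auxiliaries."""
    return ModelParameters()


# ---------------------------------------------------------------------------
# flat key-path serialisation
# ---------------------------------------------------------------------------

def _flatten(p: ModelParameters) -> dict[str, Any]:
    out: dict[str, Any] = {
        "lifetime_risk": p.lifetime_risk,
        "onset_age_mean": p.onset_age_mean,
        "onset_age_sd": p.onset_age_sd,
        "participation_rate": p.participation_rate,
        "err_per_gy": p.err_per_gy,
        "cost_biopsy": p.cost_biopsy,
        "wtp": p.wtp,
        "cohort_size": p.cohort_size,
        "repetitions": p.repetitions,
        "master_seed": p.master_seed,
        "screening.start_age": p.screening_start_age,
        "screening.end_age": p.screening_end_age,
        "screening.interval": p.screening_interval,
        "flags.risk_model": p.risk_model,
        "flags.participation_model": p.participation_model,
        "flags.interval_window_years": p.interval_window_years,
        "flags.discrete_lyg_discounting": p.discrete_lyg_discounting,
        "flags.common_random_numbers": p.common_random_numbers,
    }
    for label, row in zip(DENSITY_BAND_LABELS, p.density_distribution):
        out[f"density.{label}"] = list(row)
    for label, (m, s) in zip(DOUBLING_BAND_LABELS, p.doubling_time_bands):
        out[f"doubling_time.{label}"] = [m, s]
    for label, c in zip(SIZE_CATEGORY_LABELS, p.treatment_cost_by_size):
        out[f"treatment_cost.{label}"] = c
    for mod in (p.dm, p.dbt):
        k = mod.name.lower()
        out[f"{k}.sensitivity"] = list(mod.sensitivity_by_density)
        out[f"{k}.specificity"] = mod.specificity
        out[f"{k}.cost_per_screen"] = mod.cost_per_screen
        out[f"{k}.mgd_mean"] = mod.mgd_mean
        out[f"{k}.mgd_sd"] = mod.mgd_sd
        out[f"{k}.detection_threshold"] = mod.detection_threshold
    for s in p.discount_schemes:
        out[f"discount.{s.name}"] = [s.cost_rate, s.effect_rate]
        out["discount.reference_age"] = s.reference_age
    a = p.aux
    out.update(
        {
            "aux.self_detect_hmax": a.self_detect_hmax,
            "aux.self_detect_midpoint_mm": a.self_detect_midpoint_mm,
            "aux.self_detect_slope_mm": a.self_detect_slope_mm,
            "aux.cure_max": a.cure_max,
            "aux.cure_midpoint_mm": a.cure_midpoint_mm,
            "aux.cure_slope_mm": a.cure_slope_mm,
            "aux.mean_survival_years": a.mean_survival_years,
            "aux.initial_diameter_mm": a.initial_diameter_mm,
            "aux.max_diameter_mm": a.max_diameter_mm,
            "aux.radiation_latency_years": a.radiation_latency_years,
            "aux.min_doubling_time_days": a.min_doubling_time_days,
            "aux.life_table": [list(row) for row in a.life_table],
        }
    )
    return out


def serialise_parameters(p: ModelParameters) -> str:
    """Canonical flat key-path YAML document for ``p`` (round-trip safe)."""
    return yaml.safe_dump(_flatten(p), sort_keys=True, default_flow_style=None)


def _coerce(path: str, value: Any, template: Any) -> Any:
    try:
        if isinstance(template, bool):
            if not isinstance(value, bool):
                raise TypeError("expected a boolean")
            return value
        if isinstance(template, int) and not isinstance(template, bool):
            if isinstance(value, float) and not value.is_integer():
                raise TypeError("expected an integer")
            return int(value)
        if isinstance(template, float):
            return float(value)
        if isinstance(template, str):
            if not isinstance(value, str):
                raise TypeError("expected a string")
            return value
        if isinstance(template, list):
            if not isinstance(value, (list, tuple)):
                raise TypeError("expected a list")
            return [float(v) for v in value]
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed value for '{path}': {exc}") from exc
    return value


def load_parameters(source: str | Mapping[str, Any] | None = None) -> ModelParameters:
    """Build a parameter set from a flat key-path config document.

    ``source`` may be a mapping, a YAML string, a path to a YAML file or
    None (defaults).  Unknown keys are rejected; every override is type-
    checked against the default schema and the resulting set is validated.
    """
    if source is None:
        doc: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = source
        if "\n" not in str(source) and str(source).endswith((".yaml", ".yml", ".json")):
            with open(source) as fh:
                text = fh.read()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config document must be a key-value mapping")
        doc = loaded

    base = default_parameters()
    flat = _flatten(base)
    special = {"aux.life_table", "flags.interval_window_years"}
    for key, value in doc.items():
        if key not in flat:
            raise ConfigurationError(f"unknown configuration key: '{key}'")
        if key in special:
            continue
        doc[key] = _coerce(key, value, flat[key])

    def get(key, default):
        return doc.get(key, default)

    def _row4(key, default):
        row = get(key, list(default))
        if len(row) != 4:
            raise ConfigurationError(f"'{key}' must have 4 entries")
        return tuple(float(v) for v in row)

    def _pair(key, default):
        pair = get(key, list(default))
        if len(pair) != 2:
            raise ConfigurationError(f"'{key}' must have 2 entries")
        return float(pair[0]), float(pair[1])

    def _modality(base_mod: ModalityProfile) -> ModalityProfile:
        k = base_mod.name.lower()
        return ModalityProfile(
            name=base_mod.name,
            sensitivity_by_density=_row4(
                f"{k}.sensitivity", base_mod.sensitivity_by_density
            ),
            specificity=get(f"{k}.specificity", base_mod.specificity),
            cost_per_screen=get(f"{k}.cost_per_screen", base_mod.cost_per_screen),
            mgd_mean=get(f"{k}.mgd_mean", base_mod.mgd_mean),
            mgd_sd=get(f"{k}.mgd_sd", base_mod.mgd_sd),
            detection_threshold=get(
                f"{k}.detection_threshold", base_mod.detection_threshold
            ),
        )

    ref_age = get("discount.reference_age", 50.0)
    schemes = tuple(
        DiscountScheme(s.name, *_pair(f"discount.{s.name}", (s.cost_rate, s.effect_rate)), ref_age)
        for s in base.discount_schemes
    )
    life_table = base.aux.life_table
    if "aux.life_table" in doc:
        raw = doc["aux.life_table"]
        if not isinstance(raw, (list, tuple)):
            raise ConfigurationError("malformed value for 'aux.life_table'")
        life_table = tuple((float(a), float(q)) for a, q in raw)
    aux = AuxParameters(
        life_table=life_table,
        self_detect_hmax=get("aux.self_detect_hmax", base.aux.self_detect_hmax),
        self_detect_midpoint_mm=get(
            "aux.self_detect_midpoint_mm", base.aux.self_detect_midpoint_mm
        ),
        self_detect_slope_mm=get(
            "aux.self_detect_slope_mm", base.aux.self_detect_slope_mm
        ),
        cure_max=get("aux.cure_max", base.aux.cure_max),
        cure_midpoint_mm=get("aux.cure_midpoint_mm", base.aux.cure_midpoint_mm),
        cure_slope_mm=get("aux.cure_slope_mm", base.aux.cure_slope_mm),
        mean_survival_years=get(
            "aux.mean_survival_years", base.aux.mean_survival_years
        ),
        initial_diameter_mm=get(
            "aux.initial_diameter_mm", base.aux.initial_diameter_mm
        ),
        max_diameter_mm=get("aux.max_diameter_mm", base.aux.max_diameter_mm),
        radiation_latency_years=get(
            "aux.radiation_latency_years", base.aux.radiation_latency_years
        ),
        min_doubling_time_days=get(
            "aux.min_doubling_time_days", base.aux.min_doubling_time_days
        ),
    )
    window = doc.get("flags.interval_window_years", base.interval_window_years)
    if window is not None:
        window = float(window)
    p = ModelParameters(
        lifetime_risk=get("lifetime_risk", base.lifetime_risk),
        onset_age_mean=get("onset_age_mean", base.onset_age_mean),
        onset_age_sd=get("onset_age_sd", base.onset_age_sd),
        density_distribution=tuple(
            _row4(f"density.{lab}", row)
            for lab, row in zip(DENSITY_BAND_LABELS, base.density_distribution)
        ),
        participation_rate=get("participation_rate", base.participation_rate),
        err_per_gy=get("err_per_gy", base.err_per_gy),
        doubling_time_bands=tuple(
            _pair(f"doubling_time.{lab}", band)
            for lab, band in zip(DOUBLING_BAND_LABELS, base.doubling_time_bands)
        ),
        dm=_modality(base.dm),
        dbt=_modality(base.dbt),
        cost_biopsy=get("cost_biopsy", base.cost_biopsy),
        treatment_cost_by_size=tuple(
            float(get(f"treatment_cost.{lab}", c))
            for lab, c in zip(SIZE_CATEGORY_LABELS, base.treatment_cost_by_size)
        ),
        screening_start_age=get("screening.start_age", base.screening_start_age),
        screening_end_age=get("screening.end_age", base.screening_end_age),
        screening_interval=get("screening.interval", base.screening_interval),
        discount_schemes=schemes,
        wtp=get("wtp", base.wtp),
        cohort_size=get("cohort_size", base.cohort_size),
        repetitions=get("repetitions", base.repetitions),
        master_seed=get("master_seed", base.master_seed),
        risk_model=get("flags.risk_model", base.risk_model),
        participation_model=get(
            "flags.participation_model", base.participation_model
        ),
        interval_window_years=window,
        discrete_lyg_discounting=get(
            "flags.discrete_lyg_discounting", base.discrete_lyg_discounting
        ),
        common_random_numbers=get(
            "flags.common_random_numbers", base.common_random_numbers
        ),
        aux=aux,
    )
    violations = validate_parameters(p)
    if violations:
        raise ConfigurationError("; ".join(violations))
    return p


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _prob(name: str, value: float, out: list[str]) -> None:
    if not 0.0 <= value <= 1.0:
        out.append(f"{name} must be a probability in [0, 1], got {value!r}")


def validate_parameters(p: ModelParameters) -> list[str]:
    """Return the list of invariant violations (empty iff valid)."""
    v: list[str] = []
    _prob("lifetime_risk", p.lifetime_risk, v)
    _prob("participation_rate", p.participation_rate, v)
    if p.onset_age_sd <= 0:
        v.append("onset_age_sd must be positive")
    if p.err_per_gy < 0:
        v.append("err_per_gy must be non-negative")
    if len(p.density_distribution) != len(DENSITY_BAND_LABELS):
        v.append("density_distribution must have one row per age band")
    for label, row in zip(DENSITY_BAND_LABELS, p.density_distribution):
        if abs(sum(row) - 1.0) > 1e-9:
            v.append(f"density_distribution row {label} does not sum to 1")
        for q in row:
            _prob(f"density_distribution[{label}]", q, v)
    for label, (m, s) in zip(DOUBLING_BAND_LABELS, p.doubling_time_bands):
        if m <= 0 or s < 0:
            v.append(f"doubling_time_bands[{label}] must have mean > 0 and sd >= 0")
    for mod in (p.dm, p.dbt):
        for i, s in enumerate(mod.sensitivity_by_density, start=1):
            _prob(f"{mod.name}.sensitivity[BI-RADS {i}]", s, v)
        _prob(f"{mod.name}.specificity", mod.specificity, v)
        if mod.cost_per_screen < 0:
            v.append(f"{mod.name}.cost_per_screen must be >= 0")
        if mod.mgd_mean <= 0:
            v.append(f"{mod.name}.mgd_mean must be > 0")
        if mod.mgd_sd < 0:
            v.append(f"{mod.name}.mgd_sd must be >= 0")
        if mod.detection_threshold <= 0:
            v.append(f"{mod.name}.detection_threshold must be > 0")
    if p.cost_biopsy < 0:
        v.append("cost_biopsy must be >= 0")
    for label, c in zip(SIZE_CATEGORY_LABELS, p.treatment_cost_by_size):
        if c < 0:
            v.append(f"treatment_cost[{label}] must be >= 0")
    if p.screening_interval <= 0:
        v.append("screening interval must be > 0")
    if p.screening_start_age >= p.screening_end_age:
        v.append("screening start age must be below end age")
    for s in p.discount_schemes:
        if s.cost_rate < 0 or s.effect_rate < 0:
            v.append(f"discount rates for scheme '{s.name}' must be >= 0")
    if p.wtp <= 0:
        v.append("wtp must be > 0")
    if p.cohort_size <= 0:
        v.append("cohort_size must be > 0")
    if p.repetitions < 1:
        v.append("repetitions must be >= 1")
    if p.risk_model not in ("net", "crude"):
        v.append("flags.risk_model must be 'net' or 'crude'")
    if p.participation_model not in ("per_round", "per_woman"):
        v.append("flags.participation_model must be 'per_round' or 'per_woman'")
    a = p.aux
    if a.self_detect_hmax < 0:
        v.append("aux.self_detect_hmax must be >= 0")
    if a.self_detect_slope_mm <= 0:
        v.append("aux.self_detect_slope_mm must be > 0")
    _prob("aux.cure_max", a.cure_max, v)
    if a.cure_slope_mm <= 0:
        v.append("aux.cure_slope_mm must be > 0")
    if a.cure_midpoint_mm <= 0:
        v.append("aux.cure_midpoint_mm must be > 0")
    if a.mean_survival_years <= 0:
        v.append("aux.mean_survival_years must be > 0")
    if not 0 < a.initial_diameter_mm < p.dm.detection_threshold:
        v.append("aux.initial_diameter_mm must lie in (0, detection threshold)")
    if a.max_diameter_mm <= p.dm.detection_threshold:
        v.append("aux.max_diameter_mm must exceed the detection threshold")
    if a.radiation_latency_years < 0:
        v.append("aux.radiation_latency_years must be >= 0")
    if a.min_doubling_time_days <= 0:
        v.append("aux.min_doubling_time_days must be > 0")
    if len(a.life_table) < 2:
        v.append("aux.life_table must have at least two rows")
    else:
        ages = [row[0] for row in a.life_table]
        if any(b <= a_ for a_, b in zip(ages, ages[1:])):
            v.append("aux.life_table ages must be strictly increasing")
        for age, q in a.life_table:
            _prob(f"aux.life_table[q({age:g})]", q, v)
    return v
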