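"""Natural history of breast cancer absent screening.

Samples each woman's life course: age at death from other causes (from a
bundled female life table), whether and when an invasive breast tumour
arises, its volume-doubling time, the woman's breast-density trajectory,
the age at which she would notice the tumour herself, and survival after
diagnosis.  Radiation-induced tumours from screening doses follow a
linear no-threshold excess-relative-risk model.

All random draws for a cohort are materialised up front in a
:class:`LifeCourses` container so that screening scenarios can be run on
identical life courses (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .params import (
    DENSITY_BAND_EDGES,
    DOUBLING_BAND_EDGES,
    AuxParameters,
    ModelParameters,
)

__all__ = [
    "LifeCourses",
    "Woman",
    "Tumor",
    "sample_life_courses",
    "sample_woman",
    "diameter_at",
    "age_at_diameter",
    "sample_self_detection_age",
    "self_detection_delay",
    "sample_death_after_diagnosis",
    "cancer_death_age",
    "sample_radiation_induction",
    "onset_probability",
    "expand_life_table",
    "ONSET_LOW",
    "ONSET_HIGH",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25
#: Truncation bounds (years) for the Normal onset-age distribution.
ONSET_LOW, ONSET_HIGH = 20.0, 100.0
#: Everybody is dead by this age.
MAX_AGE = 110.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Tumor:
    """One invasive tumour growing exponentially in volume."""

    onset_age: float
    initial_diameter: float  # mm
    doubling_time: float  # days (volume doubling)
    induced: bool = False


@dataclass
class Woman:
    """One simulated life course absent screening."""

    id: int
    natural_death_age: float
    onset_age: Optional[float]
    density_latent: float  # latent uniform mapped through each band's CDF
    tumor: Optional[Tumor] = None

    def density_at(self, age: float, p: ModelParameters) -> int:
        return int(density_category(np.array([self.density_latent]), age, p)[0])


@dataclass
class LifeCourses:
    """Struct-of-arrays container of pre-drawn life courses for a cohort.

    Per-round matrices have one column per scheduled screening round so
    the same draws drive every scenario (common random numbers).  The
    ``*_induced`` fields hold the independent draws used by a possible
    radiation-induced second tumour.
    """

    natural_death_age: np.ndarray  # (n,)
    onset_age: np.ndarray  # (n,), inf when no spontaneous tumour
    doubling_time: np.ndarray  # (n,) days
    density_latent: np.ndarray  # (n,)
    e_self: np.ndarray  # (n,) Exp(1) draws for self-detection
    u_cure: np.ndarray  # (n,)
    u_surv: np.ndarray  # (n,) in (0, 1)
    attendance: np.ndarray  # (n, R) bool
    u_detect: np.ndarray  # (n, R)
    u_fp: np.ndarray  # (n, R)
    z_dose: np.ndarray  # (n, R) standard normals
    u_rad: np.ndarray  # (n,)
    u_dt_induced: np.ndarray  # (n,)
    e_self_induced: np.ndarray  # (n,)
    u_cure_induced: np.ndarray  # (n,)
    u_surv_induced: np.ndarray  # (n,)

    @property
    def n(self) -> int:
        return self.natural_death_age.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.attendance.shape[1]


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

def expand_life_table(table: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Single-year survival curve S(0..MAX_AGE) from an abridged table.

    Annual death probabilities between tabulated ages are interpolated
    log-linearly; survival is forced to zero at ``MAX_AGE``.
    """
    ages = np.array([row[0] for row in table], float)
    qx = np.array([row[1] for row in table], float)
    grid = np.arange(0.0, MAX_AGE)
    logq = np.interp(grid, ages, np.log(np.maximum(qx, 1e-12)))
    q = np.exp(logq)
    q = np.clip(q, 0.0, 1.0)
    surv = np.empty(int(MAX_AGE) + 1)
    surv[0] = 1.0
    np.cumprod(1.0 - q, out=surv[1:])
    surv[-1] = 0.0
    return surv


def _sample_death_ages(surv: np.ndarray, u: np.ndarray) -> np.ndarray:
    # S is decreasing; death in year x when S(x) >= u > S(x+1)
    x = np.searchsorted(-surv, -u, side="right") - 1
    x = np.clip(x, 0, len(surv) - 2)
    s0, s1 = surv[x], surv[x + 1]
    frac = np.where(s0 > s1, (s0 - u) / np.maximum(s0 - s1, 1e-300), 0.5)
    return x + np.clip(frac, 0.0, 1.0)


# ---------------------------------------------------------------------------
# onset
# ---------------------------------------------------------------------------

def _onset_dist(p: ModelParameters):
    a = (ONSET_LOW - p.onset_age_mean) / p.onset_age_sd
    b = (ONSET_HIGH - p.onset_age_mean) / p.onset_age_sd
    return stats.truncnorm(a, b, loc=p.onset_age_mean, scale=p.onset_age_sd)


def onset_probability(p: ModelParameters) -> float:
    """Per-woman probability of ever developing a spontaneous tumour.

    Chosen so that the cumulative risk of onset by age 70 equals the
    configured lifetime risk.  Under the default ``net`` interpretation
    death from other causes is ignored; under ``crude`` the 22.6% is the
    probability of developing cancer by 70 *while alive*, which requires
    a slightly larger underlying onset probability.
    """
    dist = _onset_dist(p)
    if p.risk_model == "net":
        denom = dist.cdf(70.0)
    else:  # crude: P(onset <= 70 and alive at onset)
        surv = expand_life_table(p.aux.life_table)
        grid = np.linspace(ONSET_LOW, 70.0, 2001)
        s_at = np.interp(grid, np.arange(len(surv)), surv)
        denom = float(np.trapezoid(dist.pdf(grid) * s_at, grid))
    prob = p.lifetime_risk / denom
    if prob > 1.0:
        raise ValueError(
            f"lifetime_risk {p.lifetime_risk} is unattainable: implied onset "
            f"probability {prob:.3f} exceeds 1"
        )
    return prob


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def density_category(latent: np.ndarray, age: float, p: ModelParameters) -> np.ndarray:
    """BI-RADS category (1..4) at ``age`` for latent uniforms ``latent``.

    The same latent uniform is pushed through each age band's cumulative
    distribution (comonotone coupling), which reproduces the marginal
    distribution per band and makes density non-increasing with age.
    """
    idx = min(
        int(np.searchsorted(np.asarray(DENSITY_BAND_EDGES), age, side="right")),
        len(DENSITY_BAND_EDGES) - 1,
    )
    cum = np.cumsum(np.asarray(p.density_distribution[idx]))
    return 1 + np.searchsorted(cum[:3], latent, side="left")


# ---------------------------------------------------------------------------
# tumour growth
# ---------------------------------------------------------------------------

def diameter_at(
    initial_diameter: float | np.ndarray,
    doubling_time_days: float | np.ndarray,
    years_since_onset: float | np.ndarray,
    max_diameter: float = 128.0,
) -> np.ndarray | float:
    """Tumour diameter after ``years_since_onset`` of exponential growth.

    Volume doubles every ``doubling_time_days``; the diameter therefore
    doubles every three doubling times.  Growth is capped at
    ``max_diameter`` mm.
    """
    t_days = np.asarray(years_since_onset, float) * DAYS_PER_YEAR
    if np.any(t_days < -1e-9):
        raise ValueError("age before tumour onset")
    expo = t_days / (3.0 * np.asarray(doubling_time_days, float))
    d = np.asarray(initial_diameter, float) * np.exp2(np.minimum(expo, 64.0))
    out = np.minimum(d, max_diameter)
    return float(out) if np.isscalar(years_since_onset) and out.ndim == 0 else out


def age_at_diameter(
    tumor: Tumor, diameter_mm: float, max_diameter: float = 128.0
) -> float:
    """Age at which the tumour first reaches ``diameter_mm`` (inverse growth)."""
    if diameter_mm > max_diameter:
        return math.inf
    t_days = 3.0 * tumor.doubling_time * math.log2(diameter_mm / tumor.initial_diameter)
    return tumor.onset_age + max(t_days, 0.0) / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# self-detection
# ---------------------------------------------------------------------------

class _HazardIntegral:
    """Lookup for G(d) = ∫_{d0}^{d} h(x)/x dx on a log-spaced grid.

    With exponential growth d(t) = d0·e^{κt} the cumulative self-detection
    hazard is H(t) = G(d(t))/κ, so one grid serves every doubling time.
    """

    def __init__(self, aux: AuxParameters, n_grid: int = 4096):
        d0, dmax = aux.initial_diameter_mm, aux.max_diameter_mm
        x = np.geomspace(d0, dmax, n_grid)
        integrand = aux.self_detection_hazard(x) / x
        dG = 0.5 * (integrand[1:] + integrand[:-1]) * np.diff(x)
        self.grid = x
        self.G = np.concatenate([[0.0], np.cumsum(dG)])
        self.G_max = float(self.G[-1])
        self.h_max_tail = float(aux.self_detection_hazard(dmax))
        self.d0 = d0
        self.dmax = dmax

    def delay_years(self, e: np.ndarray, doubling_time_days: np.ndarray) -> np.ndarray:
        """Years from onset to self-detection for Exp(1) draws ``e``."""
        kappa = DAYS_PER_YEAR * math.log(2.0) / (3.0 * np.asarray(doubling_time_days))
        target = np.asarray(e) * kappa
        within = target <= self.G_max
        d_star = np.interp(np.minimum(target, self.G_max), self.G, self.grid)
        t = np.log(d_star / self.d0) / kappa
        if self.h_max_tail > 0:
            t_cap = math.log(self.dmax / self.d0) / kappa
            extra = (np.asarray(e) - self.G_max / kappa) / self.h_max_tail
            t = np.where(within, t, t_cap + extra)
        else:
            t = np.where(within, t, np.inf)
        return t


def self_detection_delay(
    e: np.ndarray, doubling_time_days: np.ndarray, aux: AuxParameters
) -> np.ndarray:
    """Years from onset until self-detection given Exp(1) draws ``e``."""
    return _HazardIntegral(aux).delay_years(e, doubling_time_days)


def sample_self_detection_age(
    tumor: Tumor, p: ModelParameters, rng: np.random.Generator
) -> Optional[float]:
    """Age of clinical (self-)detection, or None if the hazard never fires."""
    e = rng.exponential()
    delay = float(
        self_detection_delay(np.array([e]), np.array([tumor.doubling_time]), p.aux)[0]
    )
    return None if math.isinf(delay) else tumor.onset_age + delay


# ---------------------------------------------------------------------------
# survival after diagnosis
# ---------------------------------------------------------------------------

def cancer_death_age(
    anchor_age: np.ndarray,
    diameter_at_dx: np.ndarray,
    natural_death_age: np.ndarray,
    u_cure: np.ndarray,
    u_surv: np.ndarray,
    aux: AuxParameters,
) -> np.ndarray:
    """Death age after a diagnosis at diameter ``diameter_at_dx``.

    Treatment is curative with a probability that decreases with tumour
    diameter at detection; a cured woman dies at her natural death age.
    An uncured cancer is fatal ``Exp(mean_survival_years)`` after
    ``anchor_age`` — the age at which the tumour surfaces clinically.
    Using the clinical-surfacing age (not the possibly earlier screen
    detection age) as the anchor removes lead-time bias: with shared
    ``u_cure``/``u_surv`` draws, earlier detection can only improve or
    leave unchanged the woman's death age.
    """
    cure_p = aux.cure_probability(diameter_at_dx)
    cured = np.asarray(u_cure) < cure_p
    t_fatal = -aux.mean_survival_years * np.log(np.maximum(u_surv, 1e-300))
    death = np.minimum(natural_death_age, anchor_age + t_fatal)
    return np.where(cured, natural_death_age, death)


def sample_death_after_diagnosis(
    diameter_at_dx: float,
    age_at_dx: float,
    natural_death_age: float,
    p: ModelParameters,
    rng: np.random.Generator,
) -> float:
    """Death age for a single clinically diagnosed woman."""
    if diameter_at_dx <= 0:
        raise ValueError("diameter at diagnosis must be positive")
    out = cancer_death_age(
        np.array([age_at_dx]),
        np.array([diameter_at_dx]),
        np.array([natural_death_age]),
        np.array([rng.uniform()]),
        np.array([rng.uniform(1e-12, 1.0)]),
        p.aux,
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# radiation induction
# ---------------------------------------------------------------------------

def induction_probability(cumulative_dose_mgy, p: ModelParameters):
    """Lifetime probability of a radiation-induced tumour (linear no-threshold)."""
    dose_gy = np.asarray(cumulative_dose_mgy, float) / 1000.0
    return p.lifetime_risk * p.err_per_gy * dose_gy


def sample_radiation_induction(
    dose_history: list[tuple[float, float]],
    p: ModelParameters,
    rng: np.random.Generator,
) -> Optional[Tumor]:
    """Induced tumour for a dose history of (age, mGy) pairs, or None.

    The induction probability is linear in cumulative dose; when a tumour
    is induced it is attributed to an exposure in proportion to its dose
    and onset follows that exposure by the configured latency.
    """
    if not dose_history:
        return None
    doses = np.array([d for _, d in dose_history], float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    total = doses.sum()
    prob = float(induction_probability(total, p))
    u = rng.uniform()
    if u >= prob:
        return None
    # attribute to the exposure where the cumulative probability crosses u
    cum = np.cumsum(doses) / total * prob
    idx = int(np.searchsorted(cum, u, side="right"))
    idx = min(idx, len(doses) - 1)
    exposure_age = dose_history[idx][0]
    onset = exposure_age + p.aux.radiation_latency_years
    dt = _sample_doubling_time(np.array([onset]), np.array([rng.uniform()]), p)[0]
    return Tumor(
        onset_age=onset,
        initial_diameter=p.aux.initial_diameter_mm,
        doubling_time=float(dt),
        induced=True,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_doubling_time(
    onset_age: np.ndarray, u: np.ndarray, p: ModelParameters
) -> np.ndarray:
    """Truncated-normal doubling time (days) from the age band at onset."""
    idx = np.searchsorted(np.asarray(DOUBLING_BAND_EDGES), onset_age, side="right")
    idx = np.minimum(idx, len(DOUBLING_BAND_EDGES) - 1)
    means = np.array([m for m, _ in p.doubling_time_bands])[idx]
    sds = np.array([s for _, s in p.doubling_time_bands])[idx]
    lo = p.aux.min_doubling_time_days
    a = (lo - means) / np.maximum(sds, 1e-12)
    return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, np.inf, loc=means, scale=sds)


def sample_life_courses(
    p: ModelParameters, rng: np.random.Generator, n: int, n_rounds: int
) -> LifeCourses:
    """Draw ``n`` complete life courses with ``n_rounds`` screening columns."""
    surv = expand_life_table(p.aux.life_table)
    death = _sample_death_ages(surv, rng.uniform(size=n))

    p_onset = onset_probability(p)
    has_onset = rng.uniform(size=n) < p_onset
    onset = np.full(n, np.inf)
    if has_onset.any():
        dist = _onset_dist(p)
        onset[has_onset] = dist.ppf(
            np.clip(rng.uniform(size=int(has_onset.sum())), 1e-12, 1 - 1e-12)
        )
    dt = np.full(n, np.nan)
    if has_onset.any():
        dt[has_onset] = _sample_doubling_time(
            onset[has_onset], rng.uniform(size=int(has_onset.sum())), p
        )

    if p.participation_model == "per_round":
        attendance = rng.uniform(size=(n, n_rounds)) < p.participation_rate
    else:  # fixed always/never attenders
        attender = rng.uniform(size=n) < p.participation_rate
        attendance = np.repeat(attender[:, None], n_rounds, axis=1)

    return LifeCourses(
        natural_death_age=death,
        onset_age=onset,
        doubling_time=dt,
        density_latent=rng.uniform(size=n),
        e_self=rng.exponential(size=n),
        u_cure=rng.uniform(size=n),
        u_surv=np.clip(rng.uniform(size=n), 1e-12, 1.0),
        attendance=attendance,
        u_detect=rng.uniform(size=(n, n_rounds)),
        u_fp=rng.uniform(size=(n, n_rounds)),
        z_dose=rng.standard_normal(size=(n, n_rounds)),
        u_rad=rng.uniform(size=n),
        u_dt_induced=rng.uniform(size=n),
        e_self_induced=rng.exponential(size=n),
        u_cure_induced=rng.uniform(size=n),
        u_surv_induced=np.clip(rng.uniform(size=n), 1e-12, 1.0),
    )


def sample_woman(p: ModelParameters, rng: np.random.Generator, id: int = 0) -> Woman:
    """Sample one woman's life course (scalar convenience API)."""
    courses = sample_life_courses(p, rng, 1, n_rounds=1)
    onset = courses.onset_age[0]
    tumor = None
    if np.isfinite(onset):
        tumor = Tumor(
            onset_age=float(onset),
            initial_diameter=p.aux.initial_diameter_mm,
            doubling_time=float(courses.doubling_time[0]),
        )
    return Woman(
        id=id,
        natural_death_age=float(courses.natural_death_age[0]),
        onset_age=float(onset) if np.isfinite(onset) else None,
        density_latent=float(courses.density_latent[0]),
        tumor=tumor,
    )
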