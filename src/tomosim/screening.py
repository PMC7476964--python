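"""Screening engine: applies a policy to sampled life courses.

For every woman the engine walks the biennial schedule, resolves
attendance, detection (true/false positives), dose accrual and possible
radiation-induced second tumours, classifies the detection mode
(screen-detected, interval, other self-detected, none) and produces the
paired no-screening counterfactual on the *same* natural-history draws,
so the life-years gained of each woman are a within-woman difference.

The cohort path is fully vectorised; scalar convenience wrappers expose
the per-woman operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import natural_history as nh
from .params import ModalityProfile, ModelParameters, size_category

__all__ = [
    "ScreeningPolicy",
    "ScreenEvent",
    "WomanOutcome",
    "CohortOutcomes",
    "ScenarioResult",
    "SCENARIOS",
    "build_schedule",
    "modality_for",
    "screen",
    "simulate_outcomes",
    "simulate_woman",
    "simulate_cohort",
    "aggregate",
]

SCENARIOS = ("reference", "scenario1", "scenario2")

#: detection-mode codes
MODE_NONE, MODE_SCREEN, MODE_INTERVAL, MODE_SELF = 0, 1, 2, 3
MODE_LABELS = {
    MODE_NONE: "none",
    MODE_SCREEN: "screen",
    MODE_INTERVAL: "interval",
    MODE_SELF: "self_no_screen_effect",
}


@dataclass(frozen=True)
class ScreeningPolicy:
    """Which modality each woman receives at each round.

    ``scenario`` is one of ``reference`` (DM for all), ``scenario1``
    (DBT for dense breasts, BI-RADS 3-4; DM otherwise) or ``scenario2``
    (DBT for all).  ``dbt_sensitivity`` is a single value applied to all
    densities (None: use the DBT profile's per-density values).  When
    ``first_round_dbt_for_density`` is set, every woman gets DBT in the
    first round so that her density can be assessed from the synthetic
    mammogram.
    """

    scenario: str = "reference"
    dbt_sensitivity: Optional[float] = None
    dbt_cost: Optional[float] = None  # EUR; None: use the DBT profile cost
    first_round_dbt_for_density: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        if self.dbt_sensitivity is not None and not (
            0.0 <= self.dbt_sensitivity <= 1.0
        ):
            raise ValueError("dbt_sensitivity must lie in [0, 1]")


@dataclass
class ScreenEvent:
    age: float
    modality: str
    attended: bool
    outcome: str  # TP | FN | FP | TN
    tumour_diameter: Optional[float]
    dose: float  # mGy delivered (0 if not attended)


@dataclass
class WomanOutcome:
    """Paired screened-versus-unscreened result for one woman."""

    detection_mode: str
    age_at_detection: Optional[float]
    diameter_at_detection: Optional[float]
    death_age_screened: float
    death_age_unscreened: float
    lyg: float
    induced_tumour: bool
    events: list[ScreenEvent] = field(default_factory=list)


@dataclass
class CohortOutcomes:
    """Per-woman result arrays for one simulated cohort."""

    schedule: np.ndarray  # (R,)
    mode: np.ndarray  # (n,) int codes
    dx_age: np.ndarray  # (n,), nan when never diagnosed
    dx_diameter: np.ndarray  # (n,), nan when never diagnosed
    dx_induced: np.ndarray  # (n,) bool: detected tumour was induced
    death_screened: np.ndarray  # (n,)
    death_unscreened: np.ndarray  # (n,)
    lyg: np.ndarray  # (n,)
    n_tumours: np.ndarray  # (n,) tumours arising before removal/death
    n_induced_arising: np.ndarray  # (n,)
    # screening event matrices (n, R)
    active: np.ndarray  # attended screens that actually took place
    is_dbt: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    dose: np.ndarray  # mGy


@dataclass
class ScenarioResult:
    """Cohort-level totals for one repetition of one scenario cell.

    Monetary components are kept separate and pre-discounted per scheme
    so that any DBT price level can be costed after the fact:
    ``cost = dm_price*dm_screens + dbt_price*dbt_screens
    + biopsy_price*biopsies + treatment``.  Scheme order follows
    ``ModelParameters.discount_schemes``.
    """

    n_women: int
    screen_detected: float
    interval: float
    other_detected: float
    undetected: float
    total_tumours: float
    induced_tumours: float
    false_positives: float
    screens_dm: float
    screens_dbt: float
    lyg: float
    # per-scheme discounted aggregates (len(discount_schemes) arrays)
    lyg_disc: np.ndarray
    dm_screens_disc: np.ndarray
    dbt_screens_disc: np.ndarray
    biopsies_disc: np.ndarray
    treatment_disc: np.ndarray

    def per_10k(self, value: float) -> float:
        return value * 10_000.0 / self.n_women


# ---------------------------------------------------------------------------
# schedule and modality rule
# ---------------------------------------------------------------------------

def build_schedule(p: ModelParameters) -> np.ndarray:
    """Screening ages: start, start+interval, ... strictly below end age."""
    if p.screening_start_age >= p.screening_end_age:
        raise ValueError("screening start age must be below end age")
    if p.screening_interval <= 0:
        raise ValueError("screening interval must be positive")
    n = int(
        np.ceil(
            (p.screening_end_age - p.screening_start_age) / p.screening_interval
            - 1e-12
        )
    )
    return p.screening_start_age + p.screening_interval * np.arange(n)


def modality_for(
    policy: ScreeningPolicy,
    density: int,
    round_index: int,
    p: ModelParameters,
) -> ModalityProfile:
    """The modality a woman of the given BI-RADS density receives."""
    if not 1 <= density <= 4:
        raise ValueError("density must be a BI-RADS category in 1..4")
    if policy.scenario == "scenario2":
        return p.dbt
    if policy.scenario == "scenario1":
        if policy.first_round_dbt_for_density and round_index == 0:
            return p.dbt
        return p.dbt if density >= 3 else p.dm
    return p.dm


# ---------------------------------------------------------------------------
# single-screen operation
# ---------------------------------------------------------------------------

def screen(
    tumour_diameter: Optional[float],
    modality: ModalityProfile,
    density: int,
    age: float,
    rng: np.random.Generator,
    attended: bool = True,
    sensitivity_override: Optional[float] = None,
) -> ScreenEvent:
    """One screening examination with attendance already resolved.

    A tumour below the detection threshold can never be a true positive;
    a cancer-free screen is a false positive with probability
    1 - specificity.  The delivered dose is Normal(mgd_mean, mgd_sd)
    truncated at zero.
    """
    if not attended:
        return ScreenEvent(age, modality.name, False, "TN", tumour_diameter, 0.0)
    dose = max(0.0, modality.mgd_mean + modality.mgd_sd * rng.standard_normal())
    if tumour_diameter is not None:
        if tumour_diameter >= modality.detection_threshold:
            sens = (
                sensitivity_override
                if sensitivity_override is not None
                else modality.sensitivity(density)
            )
            outcome = "TP" if rng.uniform() < sens else "FN"
        else:
            outcome = "FN"  # not detectable below the threshold
    else:
        outcome = "FP" if rng.uniform() >= modality.specificity else "TN"
    return ScreenEvent(age, modality.name, True, outcome, tumour_diameter, dose)


# ---------------------------------------------------------------------------
# vectorised cohort simulation
# ---------------------------------------------------------------------------

def _density_matrix(
    latent: np.ndarray, schedule: np.ndarray, p: ModelParameters
) -> np.ndarray:
    cats = np.empty((latent.shape[0], len(schedule)), dtype=np.int8)
    for r, age in enumerate(schedule):
        cats[:, r] = nh.density_category(latent, float(age), p)
    return cats


def _dbt_mask(policy: ScreeningPolicy, density: np.ndarray) -> np.ndarray:
    if policy.scenario == "scenario2":
        return np.ones_like(density, dtype=bool)
    if policy.scenario == "scenario1":
        mask = density >= 3
        if policy.first_round_dbt_for_density:
            mask = mask.copy()
            mask[:, 0] = True
        return mask
    return np.zeros_like(density, dtype=bool)


def _first_true_age(valid: np.ndarray, schedule: np.ndarray) -> np.ndarray:
    """Age of the first True per row, inf when a row has none."""
    any_ = valid.any(axis=1)
    idx = np.argmax(valid, axis=1)
    out = np.full(valid.shape[0], np.inf)
    out[any_] = schedule[idx[any_]]
    return out


def _tumour_diameters(
    onset: np.ndarray,
    dt_days: np.ndarray,
    schedule: np.ndarray,
    p: ModelParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """(present, diameter) matrices for one tumour per woman."""
    a_row = schedule[None, :]
    years_since = a_row - onset[:, None]
    present = np.isfinite(onset)[:, None] & (years_since >= 0)
    diam = np.zeros_like(years_since)
    if present.any():
        dt_safe = np.where(np.isfinite(onset), dt_days, 157.0)
        diam[present] = nh.diameter_at(
            p.aux.initial_diameter_mm,
            np.broadcast_to(dt_safe[:, None], years_since.shape)[present],
            years_since[present],
            p.aux.max_diameter_mm,
        )
    return present, diam


def simulate_outcomes(
    courses: nh.LifeCourses, policy: ScreeningPolicy, p: ModelParameters
) -> CohortOutcomes:
    """Run the screening policy over pre-drawn life courses."""
    schedule = build_schedule(p)
    R = len(schedule)
    if courses.n_rounds < R:
        raise ValueError("life courses were drawn with too few rounds")
    n = courses.n
    a_row = schedule[None, :]
    death_nat = courses.natural_death_age
    onset = courses.onset_age
    has_onset = np.isfinite(onset)
    d0 = p.aux.initial_diameter_mm
    dmax = p.aux.max_diameter_mm

    alive = a_row < death_nat[:, None]
    attend = courses.attendance[:, :R] & alive

    present, diam = _tumour_diameters(onset, courses.doubling_time, schedule, p)

    # modality, sensitivity and specificity per (woman, round)
    density = _density_matrix(courses.density_latent, schedule, p)
    is_dbt = _dbt_mask(policy, density)
    dm_sens = np.asarray(p.dm.sensitivity_by_density)[density - 1]
    if policy.dbt_sensitivity is None:
        dbt_sens = np.asarray(p.dbt.sensitivity_by_density)[density - 1]
    else:
        dbt_sens = np.full_like(dm_sens, policy.dbt_sensitivity)
    sens = np.where(is_dbt, dbt_sens, dm_sens)
    specificity = np.where(is_dbt, p.dbt.specificity, p.dm.specificity)
    threshold = np.where(
        is_dbt, p.dbt.detection_threshold, p.dm.detection_threshold
    )

    # clinical surfacing of the spontaneous tumour (same in both arms)
    integral = nh._HazardIntegral(p.aux)
    t_clin = np.full(n, np.inf)
    if has_onset.any():
        t_clin[has_onset] = onset[has_onset] + integral.delay_years(
            courses.e_self[has_onset], courses.doubling_time[has_onset]
        )

    detectable = present & (diam >= threshold)
    tp_cand = attend & detectable & (courses.u_detect[:, :R] < sens)
    valid_tp = tp_cand & (a_row < t_clin[:, None])
    scr_age = _first_true_age(valid_tp, schedule)
    clin_age = np.where(t_clin < death_nat, t_clin, np.inf)

    # provisional diagnosis from the spontaneous tumour alone; this fixes
    # the dose history used for radiation induction (an induced diagnosis
    # can only shorten the dose history slightly, a second-order effect)
    dx_age0 = np.minimum(scr_age, clin_age)
    active0 = attend & (a_row <= dx_age0[:, None])
    mgd_mean = np.where(is_dbt, p.dbt.mgd_mean, p.dm.mgd_mean)
    mgd_sd = np.where(is_dbt, p.dbt.mgd_sd, p.dm.mgd_sd)
    dose_full = np.maximum(mgd_mean + mgd_sd * courses.z_dose[:, :R], 0.0)
    dose0 = np.where(active0, dose_full, 0.0)

    # ----- radiation-induced second tumour (rare; subset pass) ------------
    cum_dose = dose0.sum(axis=1)
    p_ind = nh.induction_probability(cum_dose, p)
    induced = courses.u_rad < p_ind
    onset2 = np.full(n, np.inf)
    t_clin2 = np.full(n, np.inf)
    scr2_age = np.full(n, np.inf)
    dt2 = np.full(n, np.nan)
    if induced.any():
        idx_w = np.flatnonzero(induced)
        # attribute the induction to the exposure at which the cumulative
        # dose-proportional probability crosses the woman's uniform draw
        cdose = np.cumsum(dose0[idx_w], axis=1)
        target = courses.u_rad[idx_w] / p_ind[idx_w] * cum_dose[idx_w]
        round_idx = np.array(
            [
                min(int(np.searchsorted(c, t, side="left")), R - 1)
                for c, t in zip(cdose, target)
            ]
        )
        onset2[idx_w] = schedule[round_idx] + p.aux.radiation_latency_years
        dt2[idx_w] = nh._sample_doubling_time(
            onset2[idx_w], courses.u_dt_induced[idx_w], p
        )
        t_clin2[idx_w] = onset2[idx_w] + integral.delay_years(
            courses.e_self_induced[idx_w], dt2[idx_w]
        )
        present2, diam2 = _tumour_diameters(
            onset2[idx_w], dt2[idx_w], schedule, p
        )
        tp2_cand = (
            attend[idx_w]
            & present2
            & (diam2 >= threshold[idx_w])
            & (courses.u_detect[idx_w, :R] < sens[idx_w])
            & (a_row < t_clin2[idx_w, None])
        )
        scr2_age[idx_w] = _first_true_age(tp2_cand, schedule)

    clin2_age = np.where(t_clin2 < death_nat, t_clin2, np.inf)

    # the first of the four candidate events wins; any earlier diagnosis
    # would have stopped screening, which the minimum respects
    events = np.stack([scr_age, clin_age, scr2_age, clin2_age])
    dx_age = events.min(axis=0)
    which = events.argmin(axis=0)
    diagnosed = np.isfinite(dx_age)
    dx_by_screen = diagnosed & ((which == 0) | (which == 2))
    dx_is_induced = diagnosed & (which >= 2)

    # final event matrices
    active = attend & (a_row <= dx_age[:, None])
    dose = np.where(active, dose_full, 0.0)
    tp = np.zeros((n, R), dtype=bool)
    scr_rows = np.flatnonzero(dx_by_screen)
    if scr_rows.size:
        r_idx = np.searchsorted(schedule, dx_age[scr_rows])
        tp[scr_rows, r_idx] = True
    # false positives require a cancer-free breast at the screening moment
    tumour_free = ~present & ~(a_row >= onset2[:, None])
    fp = active & tumour_free & (courses.u_fp[:, :R] >= specificity)

    # diameter of the detected tumour at diagnosis
    dx_diam = np.full(n, np.nan)
    i = np.flatnonzero(diagnosed & ~dx_is_induced)
    if i.size:
        dx_diam[i] = nh.diameter_at(
            d0, courses.doubling_time[i], dx_age[i] - onset[i], dmax
        )
    j = np.flatnonzero(diagnosed & dx_is_induced)
    if j.size:
        dx_diam[j] = nh.diameter_at(d0, dt2[j], dx_age[j] - onset2[j], dmax)

    # ----- detection-mode classification ----------------------------------
    mode = np.full(n, MODE_NONE, dtype=np.int8)
    mode[dx_by_screen] = MODE_SCREEN
    dx_by_self = diagnosed & ~dx_by_screen
    if dx_by_self.any():
        before = a_row < dx_age[:, None]
        has_prev = before.any(axis=1)
        last_prev = np.where(
            has_prev, R - 1 - np.argmax(before[:, ::-1], axis=1), 0
        )
        attended_prev = attend[np.arange(n), last_prev] & has_prev
        within = dx_age - schedule[last_prev] <= p.interval_window + 1e-12
        is_interval = dx_by_self & attended_prev & within
        mode[is_interval] = MODE_INTERVAL
        mode[dx_by_self & ~is_interval] = MODE_SELF

    # ----- death ages and life years gained -------------------------------
    # unscreened counterfactual: the spontaneous tumour surfaces clinically
    death_unscr = death_nat.copy()
    u_clin = np.isfinite(clin_age)
    i = np.flatnonzero(u_clin)
    if i.size:
        diam_u = nh.diameter_at(
            d0, courses.doubling_time[i], t_clin[i] - onset[i], dmax
        )
        death_unscr[i] = nh.cancer_death_age(
            t_clin[i], diam_u, death_nat[i],
            courses.u_cure[i], courses.u_surv[i], p.aux,
        )

    # screened arm, spontaneous-tumour component
    death_scr_spont = death_nat.copy()
    spont_dx = diagnosed & ~dx_is_induced
    i = np.flatnonzero(spont_dx)
    if i.size:
        death_scr_spont[i] = nh.cancer_death_age(
            t_clin[i],
            dx_diam[i],
            death_nat[i],
            courses.u_cure[i],
            courses.u_surv[i],
            p.aux,
        )
    # a spontaneous tumour the screened arm never diagnoses (or that is
    # pre-empted by an induced diagnosis) follows its clinical course
    # exactly as in the counterfactual
    follow_clinical = u_clin & ~spont_dx
    death_scr_spont[follow_clinical] = death_unscr[follow_clinical]

    death_scr = death_scr_spont.copy()
    k = np.flatnonzero(dx_is_induced)
    if k.size:
        death_ind = nh.cancer_death_age(
            t_clin2[k],
            dx_diam[k],
            death_nat[k],
            courses.u_cure_induced[k],
            courses.u_surv_induced[k],
            p.aux,
        )
        death_scr[k] = np.minimum(death_scr_spont[k], death_ind)

    lyg = death_scr - death_unscr

    # ----- tumour accounting ----------------------------------------------
    # a tumour "arises" if its onset precedes removal from simulation
    # (diagnosis) and the woman's death in the screened arm
    end_obs = np.minimum(np.where(diagnosed, dx_age, np.inf), death_scr)
    arising_spont = (has_onset & (onset < end_obs)) | spont_dx
    arising_induced = induced & ((onset2 < end_obs) | dx_is_induced)
    n_tumours = arising_spont.astype(np.int32) + arising_induced.astype(np.int32)

    return CohortOutcomes(
        schedule=schedule,
        mode=mode,
        dx_age=np.where(diagnosed, dx_age, np.nan),
        dx_diameter=dx_diam,
        dx_induced=dx_is_induced,
        death_screened=death_scr,
        death_unscreened=death_unscr,
        lyg=lyg,
        n_tumours=n_tumours,
        n_induced_arising=arising_induced.astype(np.int32),
        active=active,
        is_dbt=is_dbt,
        tp=tp,
        fp=fp,
        dose=dose,
    )


# ---------------------------------------------------------------------------
# aggregation and entry points
# ---------------------------------------------------------------------------

def _discount_factors(ages: np.ndarray, rate: float, ref_age: float) -> np.ndarray:
    if rate == 0.0:
        return np.ones_like(np.asarray(ages, dtype=float))
    return (1.0 + rate) ** (-(np.asarray(ages, dtype=float) - ref_age))


def _lyg_discounted(
    death_unscr: np.ndarray,
    death_scr: np.ndarray,
    rate: float,
    ref_age: float,
    discrete: bool,
) -> np.ndarray:
    """Present value of the stream of gained life years per woman."""
    if rate == 0.0:
        return death_scr - death_unscr
    if not discrete:
        log1r = np.log1p(rate)
        lo = (1.0 + rate) ** (-(death_unscr - ref_age))
        hi = (1.0 + rate) ** (-(death_scr - ref_age))
        return (lo - hi) / log1r
    out = np.zeros_like(death_unscr)
    max_years = int(np.ceil(max(float(death_scr.max()), ref_age) - ref_age)) + 1
    for j in range(max_years):
        overlap = np.clip(
            np.minimum(death_scr, ref_age + j + 1.0)
            - np.maximum(death_unscr, ref_age + j),
            0.0,
            None,
        )
        out += overlap * (1.0 + rate) ** (-j)
    return out


def aggregate(outcomes: CohortOutcomes, p: ModelParameters) -> ScenarioResult:
    """Cohort totals (one repetition) from per-woman outcome arrays."""
    schemes = p.discount_schemes
    n = outcomes.mode.shape[0]
    schedule = outcomes.schedule
    treat_cost = np.asarray(p.treatment_cost_by_size)

    dm_active = outcomes.active & ~outcomes.is_dbt
    dbt_active = outcomes.active & outcomes.is_dbt
    diagnosed = np.isfinite(outcomes.dx_age)
    dx_age = outcomes.dx_age[diagnosed]
    dx_size = size_category(outcomes.dx_diameter[diagnosed])

    n_schemes = len(schemes)
    lyg_disc = np.empty(n_schemes)
    dm_disc = np.empty(n_schemes)
    dbt_disc = np.empty(n_schemes)
    biopsy_disc = np.empty(n_schemes)
    treat_disc = np.empty(n_schemes)
    for s_idx, s in enumerate(schemes):
        df_rounds = _discount_factors(schedule, s.cost_rate, s.reference_age)
        dm_disc[s_idx] = float(dm_active.sum(axis=0) @ df_rounds)
        dbt_disc[s_idx] = float(dbt_active.sum(axis=0) @ df_rounds)
        fp_disc = float(outcomes.fp.sum(axis=0) @ df_rounds)
        df_dx = _discount_factors(dx_age, s.cost_rate, s.reference_age)
        biopsy_disc[s_idx] = fp_disc + float(df_dx.sum())
        treat_disc[s_idx] = float((treat_cost[dx_size] * df_dx).sum())
        lyg_disc[s_idx] = float(
            _lyg_discounted(
                outcomes.death_unscreened,
                outcomes.death_screened,
                s.effect_rate,
                s.reference_age,
                p.discrete_lyg_discounting,
            ).sum()
        )

    return ScenarioResult(
        n_women=n,
        screen_detected=float((outcomes.mode == MODE_SCREEN).sum()),
        interval=float((outcomes.mode == MODE_INTERVAL).sum()),
        other_detected=float((outcomes.mode == MODE_SELF).sum()),
        undetected=float(outcomes.n_tumours.sum() - int(diagnosed.sum())),
        total_tumours=float(outcomes.n_tumours.sum()),
        induced_tumours=float(outcomes.n_induced_arising.sum()),
        false_positives=float(outcomes.fp.sum()),
        screens_dm=float(dm_active.sum()),
        screens_dbt=float(dbt_active.sum()),
        lyg=float(outcomes.lyg.sum()),
        lyg_disc=lyg_disc,
        dm_screens_disc=dm_disc,
        dbt_screens_disc=dbt_disc,
        biopsies_disc=biopsy_disc,
        treatment_disc=treat_disc,
    )


def simulate_cohort(
    policy: ScreeningPolicy,
    p: ModelParameters,
    seed: int | np.random.SeedSequence | None = None,
    n: Optional[int] = None,
    courses: Optional[nh.LifeCourses] = None,
) -> ScenarioResult:
    """Simulate one cohort repetition under ``policy`` and aggregate it."""
    if courses is None:
        if seed is None:
            raise ValueError("either a seed or pre-drawn courses is required")
        rng = np.random.Generator(np.random.PCG64(seed))
        courses = nh.sample_life_courses(
            p, rng, n or p.cohort_size, len(build_schedule(p))
        )
    return aggregate(simulate_outcomes(courses, policy, p), p)


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def _events_for(
    courses: nh.LifeCourses,
    outcomes: CohortOutcomes,
    i: int,
    p: ModelParameters,
) -> list[ScreenEvent]:
    events: list[ScreenEvent] = []
    schedule = outcomes.schedule
    dx = outcomes.dx_age[i]
    stop = min(
        courses.natural_death_age[i],
        dx + 1e-9 if np.isfinite(dx) else np.inf,
    )
    for r, age in enumerate(schedule):
        if age > stop or age >= courses.natural_death_age[i]:
            break
        mod = p.dbt if outcomes.is_dbt[i, r] else p.dm
        if not outcomes.active[i, r]:
            events.append(ScreenEvent(float(age), mod.name, False, "TN", None, 0.0))
            continue
        onset = courses.onset_age[i]
        diam = None
        if np.isfinite(onset) and age >= onset:
            diam = float(
                nh.diameter_at(
                    p.aux.initial_diameter_mm,
                    courses.doubling_time[i],
                    age - onset,
                    p.aux.max_diameter_mm,
                )
            )
        if outcomes.tp[i, r]:
            outcome = "TP"
        elif outcomes.fp[i, r]:
            outcome = "FP"
        elif diam is not None:
            outcome = "FN"
        else:
            outcome = "TN"
        events.append(
            ScreenEvent(
                float(age), mod.name, True, outcome, diam, float(outcomes.dose[i, r])
            )
        )
    return events


def simulate_woman(
    woman: nh.Woman,
    policy: ScreeningPolicy,
    p: ModelParameters,
    rng: np.random.Generator,
    courses: Optional[nh.LifeCourses] = None,
) -> WomanOutcome:
    """Simulate one woman (scalar API over the vectorised engine)."""
    if courses is None:
        courses = nh.sample_life_courses(p, rng, 1, len(build_schedule(p)))
        courses.natural_death_age[0] = woman.natural_death_age
        courses.onset_age[0] = (
            woman.onset_age if woman.onset_age is not None else np.inf
        )
        courses.density_latent[0] = woman.density_latent
        if woman.tumor is not None:
            courses.doubling_time[0] = woman.tumor.doubling_time
    outcomes = simulate_outcomes(courses, policy, p)
    dx = outcomes.dx_age[0]
    return WomanOutcome(
        detection_mode=MODE_LABELS[int(outcomes.mode[0])],
        age_at_detection=float(dx) if np.isfinite(dx) else None,
        diameter_at_detection=(
            float(outcomes.dx_diameter[0]) if np.isfinite(dx) else None
        ),
        death_age_screened=float(outcomes.death_screened[0]),
        death_age_unscreened=float(outcomes.death_unscreened[0]),
        lyg=float(outcomes.lyg[0]),
        induced_tumour=bool(outcomes.dx_induced[0]),
        events=_events_for(courses, outcomes, 0, p),
    )
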