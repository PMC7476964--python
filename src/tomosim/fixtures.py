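"""Scripted cohorts and independent oracles for validating the engine.

``make_forced_cohort`` builds :class:`~tomosim.natural_history.LifeCourses`
whose random draws are replaced by scripted values, so unit tests can
force any pathway (never-attender, guaranteed detection, forced false
positive, ...).  ``brute_force_woman`` re-simulates one woman with a
literal day-stepping reading of the model rules and serves as an oracle
for the vectorised engine; ``expected_fp_count`` is the first-order
closed form for false-positive counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import natural_history as nh
from .params import (
    DENSITY_BAND_EDGES,
    DOUBLING_BAND_EDGES,
    ModelParameters,
    size_category,
)
from .screening import (
    MODE_INTERVAL,
    MODE_LABELS,
    MODE_NONE,
    MODE_SCREEN,
    MODE_SELF,
    ScreeningPolicy,
    build_schedule,
)

__all__ = [
    "ForcedWoman",
    "ScriptError",
    "make_forced_cohort",
    "expected_fp_count",
    "brute_force_woman",
    "OracleOutcome",
]


class ScriptError(ValueError):
    """Raised for internally inconsistent scripted specifications."""


@dataclass
class ForcedWoman:
    """Scripted values for one woman; unset fields use neutral defaults.

    ``detect_u`` / ``fp_u`` may be a scalar (applied to all rounds) or a
    per-round sequence; a detect uniform of 0 forces detection whenever
    the tumour is detectable, 1 suppresses it.  An ``fp_u`` of 1 forces a
    false positive on a cancer-free attended round, 0 suppresses it.
    ``self_detect_e`` is the Exp(1) draw driving self-detection
    (``inf``: never).
    """

    natural_death_age: float = 100.0
    onset_age: Optional[float] = None
    doubling_time: float = 157.0
    density: int = 2
    attend: bool | Sequence[bool] = True
    detect_u: float | Sequence[float] = 1.0
    fp_u: float | Sequence[float] = 0.0
    self_detect_e: float = np.inf
    cure_u: float = 0.999999
    surv_u: float = 0.5
    rad_u: float = 0.999999
    dose_z: float = 0.0

    def validate(self) -> None:
        if self.natural_death_age <= 0:
            raise ScriptError("natural_death_age must be positive")
        if self.onset_age is not None and self.onset_age < 20:
            raise ScriptError("onset_age must be >= 20")
        if self.doubling_time <= 0:
            raise ScriptError("doubling_time must be positive")
        if not 1 <= self.density <= 4:
            raise ScriptError("density must be a BI-RADS category 1..4")
        if self.onset_age is None and np.isfinite(self.self_detect_e):
            if self.self_detect_e <= 0:
                raise ScriptError("self-detection scripted without a tumour")


def _per_round(value, n_rounds: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_rounds, float(arr))
    if arr.shape[0] != n_rounds:
        raise ScriptError(f"per-round script must have {n_rounds} entries")
    return arr.astype(float)


def _latent_for_density(density: int, p: ModelParameters, age: float = 55.0) -> float:
    """Latent uniform putting the woman in ``density`` at screening ages."""
    idx = min(
        int(np.searchsorted(np.asarray(DENSITY_BAND_EDGES), age, side="right")),
        len(DENSITY_BAND_EDGES) - 1,
    )
    cum = np.concatenate([[0.0], np.cumsum(p.density_distribution[idx])])
    return float(0.5 * (cum[density - 1] + cum[density]))


def make_forced_cohort(
    specs: Sequence[ForcedWoman], p: ModelParameters
) -> nh.LifeCourses:
    """LifeCourses whose draws are replaced by the scripted values."""
    n = len(specs)
    R = len(build_schedule(p))
    for s in specs:
        s.validate()
    attend = np.zeros((n, R), dtype=bool)
    u_detect = np.ones((n, R))
    u_fp = np.zeros((n, R))
    for i, s in enumerate(specs):
        attend[i] = np.asarray(s.attend, dtype=bool) if not np.isscalar(s.attend) else bool(s.attend)
        u_detect[i] = np.clip(_per_round(s.detect_u, R), 0.0, 1.0)
        u_fp[i] = np.clip(_per_round(s.fp_u, R), 0.0, 1.0)
    return nh.LifeCourses(
        natural_death_age=np.array([s.natural_death_age for s in specs], float),
        onset_age=np.array(
            [np.inf if s.onset_age is None else s.onset_age for s in specs], float
        ),
        doubling_time=np.array([s.doubling_time for s in specs], float),
        density_latent=np.array(
            [_latent_for_density(s.density, p) for s in specs], float
        ),
        e_self=np.array([s.self_detect_e for s in specs], float),
        u_cure=np.array([s.cure_u for s in specs], float),
        u_surv=np.array([s.surv_u for s in specs], float),
        attendance=attend,
        u_detect=u_detect,
        u_fp=u_fp,
        z_dose=np.repeat(np.array([[s.dose_z] for s in specs], float), R, axis=1),
        u_rad=np.array([s.rad_u for s in specs], float),
        u_dt_induced=np.full(n, 0.5),
        e_self_induced=np.full(n, np.inf),
        u_cure_induced=np.full(n, 0.999999),
        u_surv_induced=np.full(n, 0.5),
    )


def expected_fp_count(
    n_women: int,
    n_rounds: int,
    participation: float,
    specificity: float,
    cancer_free_fraction: float = 1.0,
) -> float:
    """First-order expected false-positive count for a cohort.

    ``n x fraction x rounds x participation x (1 - specificity)``,
    ignoring censoring by death and by earlier detection.
    """
    return (
        n_women
        * cancer_free_fraction
        * n_rounds
        * participation
        * (1.0 - specificity)
    )


# ---------------------------------------------------------------------------
# brute-force daily oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleOutcome:
    detection_mode: str
    dx_age: Optional[float]
    dx_diameter: Optional[float]
    dx_induced: bool
    death_screened: float
    death_unscreened: float
    lyg: float
    n_fp: int
    n_screens_dm: int
    n_screens_dbt: int
    undiscounted_cost: float
    events: list = field(default_factory=list)


def _oracle_density(u: float, age: float, p: ModelParameters) -> int:
    """Literal re-reading of the comonotone density rule."""
    for edge, row in zip(DENSITY_BAND_EDGES, p.density_distribution):
        if age < edge:
            acc = 0.0
            for cat, q in enumerate(row, start=1):
                acc += q
                if u < acc or cat == 4:
                    return cat
    raise AssertionError("unreachable")


def _oracle_diam(d0: float, dt: float, years: float, dmax: float) -> float:
    return min(d0 * 2.0 ** (years * nh.DAYS_PER_YEAR / (3.0 * dt)), dmax)


def _oracle_self_detect(
    onset: float, dt: float, e: float, p: ModelParameters, step_days: float = 1.0
) -> float:
    """Clinical surfacing age by daily accumulation of the hazard."""
    if not np.isfinite(e):
        return np.inf
    aux = p.aux
    horizon_years = 120.0
    t = np.arange(0.0, horizon_years, step_days / nh.DAYS_PER_YEAR)
    d = np.minimum(
        aux.initial_diameter_mm
        * 2.0 ** np.minimum(t * nh.DAYS_PER_YEAR / (3.0 * dt), 64.0),
        aux.max_diameter_mm,
    )
    h = np.asarray(aux.self_detection_hazard(d))
    dt_y = step_days / nh.DAYS_PER_YEAR
    big_h = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * dt_y)])
    if big_h[-1] < e:
        return np.inf
    k = int(np.searchsorted(big_h, e))
    # linear interpolation within the crossing step
    t_cross = t[k - 1] + (e - big_h[k - 1]) / max(big_h[k] - big_h[k - 1], 1e-300) * dt_y
    return onset + t_cross


def _oracle_dt_for(onset_age: float, u: float, p: ModelParameters) -> float:
    for edge, (m, s) in zip(DOUBLING_BAND_EDGES, p.doubling_time_bands):
        if onset_age < edge:
            a = (p.aux.min_doubling_time_days - m) / s
            return float(stats.truncnorm.ppf(u, a, np.inf, loc=m, scale=s))
    raise AssertionError("unreachable")


def _oracle_cancer_death(
    anchor: float,
    diameter: float,
    natural_death: float,
    u_cure: float,
    u_surv: float,
    p: ModelParameters,
) -> float:
    aux = p.aux
    cure = aux.cure_max / (
        1.0 + np.exp((diameter - aux.cure_midpoint_mm) / aux.cure_slope_mm)
    )
    if u_cure < cure:
        return natural_death
    t_fatal = -p.aux.mean_survival_years * np.log(max(u_surv, 1e-300))
    return min(natural_death, anchor + t_fatal)


def brute_force_woman(
    courses: nh.LifeCourses, i: int, policy: ScreeningPolicy, p: ModelParameters
) -> OracleOutcome:
    """Day-stepping literal re-simulation of woman ``i`` of a cohort.

    Independent of the vectorised engine: densities, growth, hazards,
    screening rules and survival are re-read directly from the model
    description, consuming the same pre-drawn uniforms.
    """
    schedule = list(build_schedule(p))
    death_nat = float(courses.natural_death_age[i])
    onset = float(courses.onset_age[i])
    has_onset = np.isfinite(onset)
    dt1 = float(courses.doubling_time[i]) if has_onset else np.nan
    u_dens = float(courses.density_latent[i])
    d0 = p.aux.initial_diameter_mm
    dmax = p.aux.max_diameter_mm

    t_clin = (
        _oracle_self_detect(onset, dt1, float(courses.e_self[i]), p)
        if has_onset
        else np.inf
    )

    def round_modality(r: int, density: int):
        if policy.scenario == "scenario2":
            return p.dbt
        if policy.scenario == "scenario1":
            if policy.first_round_dbt_for_density and r == 0:
                return p.dbt
            return p.dbt if density >= 3 else p.dm
        return p.dm

    def sensitivity(mod, density: int) -> float:
        if mod.name == "DBT" and policy.dbt_sensitivity is not None:
            return policy.dbt_sensitivity
        return mod.sensitivity(density)

    def walk(tumours):
        """Sequential pass over the schedule; returns (dx, events, dose)."""
        dx = None  # (age, diameter, induced, 'screen'|'clinical', prev_round)
        events = []
        dose_hist = []
        last_attended_neg_round = None
        clin_events = sorted(
            [(tc, k) for k, (o, dtk, tc, ind) in enumerate(tumours) if np.isfinite(tc)]
        )
        for r, age in enumerate(schedule):
            if age >= death_nat:
                break
            surfaced = [
                (tc, k) for tc, k in clin_events if tc < age and tc < death_nat
            ]
            if surfaced:
                tc, k = surfaced[0]
                o, dtk, _, ind = tumours[k]
                dx = (tc, _oracle_diam(d0, dtk, tc - o, dmax), ind, "clinical")
                break
            if not courses.attendance[i, r]:
                continue
            density = _oracle_density(u_dens, age, p)
            mod = round_modality(r, density)
            dose_hist.append(
                (age, max(0.0, mod.mgd_mean + mod.mgd_sd * float(courses.z_dose[i, r])))
            )
            present = [
                (k, _oracle_diam(d0, dtk, age - o, dmax))
                for k, (o, dtk, tc, ind) in enumerate(tumours)
                if age >= o
            ]
            detected = None
            for k, diam in present:
                if diam >= mod.detection_threshold and float(
                    courses.u_detect[i, r]
                ) < sensitivity(mod, density):
                    detected = (k, diam)
                    break
            if detected is not None:
                k, diam = detected
                dx = (age, diam, tumours[k][3], "screen")
                events.append((age, mod.name, "TP"))
                break
            if not present and float(courses.u_fp[i, r]) >= mod.specificity:
                events.append((age, mod.name, "FP"))
            else:
                events.append((age, mod.name, "FN" if present else "TN"))
        if dx is None:
            surfaced = [
                (tc, k) for tc, k in clin_events if tc < death_nat
            ]
            if surfaced:
                tc, k = surfaced[0]
                o, dtk, _, ind = tumours[k]
                dx = (tc, _oracle_diam(d0, dtk, tc - o, dmax), ind, "clinical")
        return dx, events, dose_hist

    # pass 1: spontaneous tumour only, to fix the dose history
    tumours1 = [(onset, dt1, t_clin, False)] if has_onset else []
    _, _, dose_hist = walk(tumours1)
    total_dose = sum(d for _, d in dose_hist)
    p_ind = p.lifetime_risk * p.err_per_gy * total_dose / 1000.0
    tumours = list(tumours1)
    induced_meta = None
    if float(courses.u_rad[i]) < p_ind:
        target = float(courses.u_rad[i]) / p_ind * total_dose
        acc = 0.0
        exposure_age = dose_hist[-1][0]
        for age, d in dose_hist:
            acc += d
            if acc >= target:
                exposure_age = age
                break
        onset2 = exposure_age + p.aux.radiation_latency_years
        dt2 = _oracle_dt_for(onset2, float(courses.u_dt_induced[i]), p)
        t_clin2 = _oracle_self_detect(
            onset2, dt2, float(courses.e_self_induced[i]), p
        )
        tumours.append((onset2, dt2, t_clin2, True))
        induced_meta = (onset2, dt2, t_clin2)

    dx, events, dose_hist = walk(tumours)

    # detection-mode classification
    if dx is None:
        mode = MODE_NONE
    elif dx[3] == "screen":
        mode = MODE_SCREEN
    else:
        dx_age = dx[0]
        prev = [(r, a) for r, a in enumerate(schedule) if a < dx_age]
        mode = MODE_SELF
        if prev:
            r_prev, a_prev = prev[-1]
            if (
                courses.attendance[i, r_prev]
                and a_prev < death_nat
                and dx_age - a_prev <= p.interval_window + 1e-12
            ):
                mode = MODE_INTERVAL

    # unscreened counterfactual
    death_unscr = death_nat
    if np.isfinite(t_clin) and t_clin < death_nat:
        diam_u = _oracle_diam(d0, dt1, t_clin - onset, dmax)
        death_unscr = _oracle_cancer_death(
            t_clin, diam_u, death_nat,
            float(courses.u_cure[i]), float(courses.u_surv[i]), p,
        )

    # screened arm
    death_spont = death_nat
    if dx is not None and not dx[2]:
        death_spont = _oracle_cancer_death(
            t_clin, dx[1], death_nat,
            float(courses.u_cure[i]), float(courses.u_surv[i]), p,
        )
    elif np.isfinite(t_clin) and t_clin < death_nat:
        death_spont = death_unscr
    death_scr = death_spont
    if dx is not None and dx[2]:
        death_ind = _oracle_cancer_death(
            induced_meta[2], dx[1], death_nat,
            float(courses.u_cure_induced[i]), float(courses.u_surv_induced[i]), p,
        )
        death_scr = min(death_spont, death_ind)

    # undiscounted costs
    cost = 0.0
    n_dm = n_dbt = n_fp = 0
    for age, mod_name, outc in events:
        mod = p.modality(mod_name)
        cost += mod.cost_per_screen
        if mod_name == "DM":
            n_dm += 1
        else:
            n_dbt += 1
        if outc in ("TP", "FP"):
            cost += p.cost_biopsy
        if outc == "FP":
            n_fp += 1
    if dx is not None:
        cost += p.treatment_cost_by_size[int(size_category(dx[1]))]
        if dx[3] == "clinical":
            cost += p.cost_biopsy

    return OracleOutcome(
        detection_mode=MODE_LABELS[mode],
        dx_age=None if dx is None else dx[0],
        dx_diameter=None if dx is None else dx[1],
        dx_induced=False if dx is None else dx[2],
        death_screened=death_scr,
        death_unscreened=death_unscr,
        lyg=death_scr - death_unscr,
        n_fp=n_fp,
        n_screens_dm=n_dm,
        n_screens_dbt=n_dbt,
        undiscounted_cost=cost,
        events=events,
    )
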