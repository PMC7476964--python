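"""Experiment orchestration: the full scenario × sensitivity grid.

Runs the three screening scenarios over the DBT-sensitivity grid with a
fixed number of cohort repetitions, using common random numbers across
scenarios within a repetition (the same women and the same detection
uniforms), aggregates mean and standard error of every outcome, and
emits the difference table (screening outcomes) and the ICER table.
Also hosts the calibration harness that fits the auxiliary self-detection
and survival parameters to reference-scenario targets.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from . import econ
from . import natural_history as nh
from .params import AuxParameters, ModelParameters, serialise_parameters
from .screening import (
    SCENARIOS,
    ScenarioResult,
    ScreeningPolicy,
    build_schedule,
    simulate_outcomes,
    aggregate,
)

__all__ = [
    "ExperimentPlan",
    "ResultBundle",
    "default_plan",
    "cell_seed",
    "run_plan",
    "make_table2",
    "make_table3",
    "icer_grid",
    "calibrate_aux_defaults",
    "summarise",
]

DEFAULT_SENSITIVITY_GRID = tuple(np.round(np.arange(0.65, 1.001, 0.05), 2))
#: Reference-scenario calibration targets per 10,000 women:
#: (screen-detected cancers, interval cancers, life years gained).
CALIBRATION_TARGETS = (536.0, 272.0, 1353.0)
#: Full-sensitivity contrast pinning the sensitivity response: differences
#: (screen-detected, LYG) of DBT-for-all at sensitivity 1.00 vs reference.
CALIBRATION_CONTRAST = (91.0, 254.0)


@dataclass(frozen=True)
class ExperimentPlan:
    scenarios: tuple[str, ...] = SCENARIOS
    sensitivity_grid: tuple[float, ...] = DEFAULT_SENSITIVITY_GRID
    dbt_costs: tuple[float, ...] = (96.0, 80.0)
    repetitions: int = 10
    cohort_size: int = 100_000
    master_seed: int = 2020
    common_random_numbers: bool = True

    def __post_init__(self):
        for s in self.sensitivity_grid:
            if not 0.0 <= s <= 1.0:
                raise ValueError("sensitivity grid values must lie in [0, 1]")
        if self.repetitions < 2:
            raise ValueError("at least 2 repetitions are needed for an SE")


def default_plan(p: ModelParameters, **overrides) -> ExperimentPlan:
    base = dict(
        repetitions=p.repetitions,
        cohort_size=p.cohort_size,
        master_seed=p.master_seed,
        common_random_numbers=p.common_random_numbers,
    )
    base.update(overrides)
    return ExperimentPlan(**base)


def cell_seed(
    master_seed: int,
    scenario: str | None,
    sensitivity: float | None,
    repetition: int,
    crn: bool = True,
) -> np.random.SeedSequence:
    """Deterministic, order-independent seed for one simulation cell.

    With common random numbers the seed depends only on (master seed,
    repetition): every scenario and sensitivity reuses the same life
    courses.  Without CRN the scenario and sensitivity enter the seed.
    The DBT price level never enters: prices are deterministic
    multipliers applied after simulation.
    """
    if crn:
        return np.random.SeedSequence([int(master_seed), 7919, int(repetition)])
    scen_id = 0 if scenario is None else SCENARIOS.index(scenario) + 1
    sens_id = 0 if sensitivity is None else int(round(sensitivity * 1000)) + 1
    return np.random.SeedSequence(
        [int(master_seed), scen_id, sens_id, int(repetition)]
    )


CellKey = tuple[str, Optional[float]]  # (scenario, DBT sensitivity)


@dataclass
class ResultBundle:
    """All per-repetition results of a plan, plus full provenance."""

    plan: ExperimentPlan
    parameters: ModelParameters
    cells: dict[CellKey, list[ScenarioResult]] = field(default_factory=dict)

    def reps(self, scenario: str, sensitivity: Optional[float] = None):
        key = (scenario, None if scenario == "reference" else sensitivity)
        if key not in self.cells:
            raise KeyError(f"missing cell {key}; run the plan first")
        return self.cells[key]

    def per10k(
        self, scenario: str, sensitivity: Optional[float], attr: str,
        scheme_index: Optional[int] = None,
    ) -> np.ndarray:
        """Per-repetition per-10,000-women values of one aggregate."""
        out = []
        for r in self.reps(scenario, sensitivity):
            v = getattr(r, attr)
            if scheme_index is not None:
                v = v[scheme_index]
            out.append(r.per_10k(v))
        return np.array(out)

    def costs10k(
        self, scenario: str, sensitivity: Optional[float], scheme_index: int,
        dbt_price: Optional[float],
    ) -> np.ndarray:
        return np.array(
            [
                r.per_10k(econ.scenario_costs(r, self.parameters, scheme_index, dbt_price))
                for r in self.reps(scenario, sensitivity)
            ]
        )

    def metadata(self) -> dict:
        return {
            "plan": dataclasses.asdict(self.plan),
            "parameters": serialise_parameters(self.parameters),
        }


def summarise(values) -> tuple[float, float]:
    """(mean, standard error of the mean) across repetitions."""
    v = np.asarray(values, float)
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), se


def _cell_keys(plan: ExperimentPlan) -> list[CellKey]:
    keys: list[CellKey] = []
    for scen in plan.scenarios:
        if scen == "reference":
            keys.append((scen, None))
        else:
            keys.extend((scen, s) for s in plan.sensitivity_grid)
    return keys


def run_plan(
    plan: ExperimentPlan,
    p: ModelParameters,
    progress: Optional[Callable[[str], None]] = None,
) -> ResultBundle:
    """Run every cell of the plan for every repetition."""
    keys = _cell_keys(plan)
    bundle = ResultBundle(plan=plan, parameters=p)
    bundle.cells = {k: [] for k in keys}
    n_rounds = len(build_schedule(p))
    for rep in range(plan.repetitions):
        courses = None
        if plan.common_random_numbers:
            rng = np.random.Generator(
                np.random.PCG64(cell_seed(plan.master_seed, None, None, rep, True))
            )
            courses = nh.sample_life_courses(p, rng, plan.cohort_size, n_rounds)
        for scen, sens in keys:
            local = courses
            if local is None:
                rng = np.random.Generator(
                    np.random.PCG64(
                        cell_seed(plan.master_seed, scen, sens, rep, False)
                    )
                )
                local = nh.sample_life_courses(p, rng, plan.cohort_size, n_rounds)
            policy = ScreeningPolicy(scenario=scen, dbt_sensitivity=sens)
            bundle.cells[(scen, sens)].append(
                aggregate(simulate_outcomes(local, policy, p), p)
            )
            if progress is not None:
                progress(f"rep {rep + 1}/{plan.repetitions} {scen} sens={sens}")
    return bundle


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

COMPARISON_PAIRS = (
    ("scenario1", "reference"),
    ("scenario2", "reference"),
    ("scenario2", "scenario1"),
)


def _pair_sens(scenario: str, sens: float) -> Optional[float]:
    return None if scenario == "reference" else sens


def make_table2(bundle: ResultBundle) -> pd.DataFrame:
    """Differences in screening outcomes per 10,000 women, with SEs.

    One row per (comparison, DBT sensitivity): Δ screen-detected,
    Δ interval cancers and Δ LYG under each discount scheme.
    """
    p = bundle.parameters
    scheme_names = [s.name for s in p.discount_schemes]
    rows = []
    for a, b in COMPARISON_PAIRS:
        for sens in bundle.plan.sensitivity_grid:
            row: dict = {"comparison": f"{a}-{b}", "sensitivity": sens}
            for attr, label in (
                ("screen_detected", "screen_detected"),
                ("interval", "interval"),
            ):
                da = bundle.per10k(a, _pair_sens(a, sens), attr)
                db = bundle.per10k(b, _pair_sens(b, sens), attr)
                m, se = summarise(da - db)
                row[f"d_{label}"], row[f"d_{label}_se"] = m, se
            for s_idx, s_name in enumerate(scheme_names):
                da = bundle.per10k(a, _pair_sens(a, sens), "lyg_disc", s_idx)
                db = bundle.per10k(b, _pair_sens(b, sens), "lyg_disc", s_idx)
                m, se = summarise(da - db)
                row[f"d_lyg_{s_name}"], row[f"d_lyg_{s_name}_se"] = m, se
            rows.append(row)
    return pd.DataFrame(rows)


def icer_grid(
    bundle: ResultBundle,
    pair: tuple[str, str],
    dbt_price: float,
    scheme: str = "international",
    wtp: Optional[float] = None,
) -> dict[float, econ.Comparison]:
    """Comparison (with delta-method ICER SE) per sensitivity grid point."""
    p = bundle.parameters
    s_idx = [s.name for s in p.discount_schemes].index(scheme)
    wtp = p.wtp if wtp is None else wtp
    a, b = pair
    out = {}
    for sens in bundle.plan.sensitivity_grid:
        ca = bundle.costs10k(a, _pair_sens(a, sens), s_idx, dbt_price)
        cb = bundle.costs10k(b, _pair_sens(b, sens), s_idx, dbt_price)
        la = bundle.per10k(a, _pair_sens(a, sens), "lyg_disc", s_idx)
        lb = bundle.per10k(b, _pair_sens(b, sens), "lyg_disc", s_idx)
        out[float(sens)] = econ.compare_reps(ca, la, cb, lb, wtp)
    return out


def make_table3(
    bundle: ResultBundle,
    wtp: Optional[float] = None,
    scheme: str = "international",
) -> pd.DataFrame:
    """ICERs (thousand EUR per LYG) per sensitivity and DBT price level.

    Dominated cells carry an empty ICER and the status marks the reason.
    """
    rows = []
    for price in bundle.plan.dbt_costs:
        for a, b in COMPARISON_PAIRS:
            grid = icer_grid(bundle, (a, b), price, scheme, wtp)
            for sens, comp in grid.items():
                rows.append(
                    {
                        "dbt_cost": price,
                        "comparison": f"{a}-{b}",
                        "sensitivity": sens,
                        "icer_kEUR": comp.icer / 1000.0
                        if not np.isnan(comp.icer)
                        else np.nan,
                        "icer_se_kEUR": comp.se_icer / 1000.0
                        if not np.isnan(comp.se_icer)
                        else np.nan,
                        "status": comp.status,
                        "d_cost": comp.delta_cost,
                        "d_lyg": comp.delta_lyg,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration of auxiliary defaults
# ---------------------------------------------------------------------------

def _calibration_outcomes(
    p: ModelParameters, n: int, reps: int, master_seed: int, contrast: bool
) -> np.ndarray:
    """Reference triplet (+ optional full-sensitivity contrast) per 10,000."""
    k = 5 if contrast else 3
    vals = np.zeros(k)
    n_rounds = len(build_schedule(p))
    for rep in range(reps):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([master_seed, 104729, rep]))
        )
        courses = nh.sample_life_courses(p, rng, n, n_rounds)
        ref = aggregate(simulate_outcomes(courses, ScreeningPolicy("reference"), p), p)
        row = [
            ref.per_10k(ref.screen_detected),
            ref.per_10k(ref.interval),
            ref.per_10k(ref.lyg),
        ]
        if contrast:
            s2 = aggregate(
                simulate_outcomes(
                    courses, ScreeningPolicy("scenario2", dbt_sensitivity=1.0), p
                ),
                p,
            )
            row += [
                s2.per_10k(s2.screen_detected) - row[0],
                s2.per_10k(s2.lyg) - row[2],
            ]
        vals += np.array(row)
    return vals / reps


def calibrate_aux_defaults(
    p: ModelParameters,
    targets: tuple[float, float, float] = CALIBRATION_TARGETS,
    contrast_targets: Optional[tuple[float, float]] = CALIBRATION_CONTRAST,
    n: int = 100_000,
    reps: int = 2,
    master_seed: int = 7,
    maxiter: int = 120,
    weights: Optional[tuple[float, ...]] = None,
    verbose: bool = False,
) -> dict:
    """Fit the auxiliary natural-history parameters to published outcomes.

    The auxiliary model (initial back-extrapolation diameter, logistic
    self-detection hazard ceiling/midpoint/slope, maximum cure
    probability) is underidentified by the reference triplet alone, so
    the objective also matches the full-sensitivity contrast — the
    (screen-detected, LYG) differences of DBT-for-all at sensitivity 1.00
    versus the reference — unless ``contrast_targets`` is None.
    Nelder-Mead minimises the weighted summed squared relative error;
    failure to reach tolerance is reported, not raised.  Returns the
    fitted :class:`AuxParameters` plus a residual report.
    """
    if min(targets) <= 0:
        raise ValueError("calibration targets must be positive")
    use_contrast = contrast_targets is not None
    tgt = np.asarray(
        tuple(targets) + (tuple(contrast_targets) if use_contrast else ()), float
    )
    w = np.asarray(
        weights if weights is not None
        else ((1.0, 1.0, 1.0, 1.5, 2.0) if use_contrast else (1.0, 1.0, 1.0)),
        float,
    )

    def unpack(x) -> AuxParameters:
        return replace(
            p.aux,
            initial_diameter_mm=float(np.exp(x[0])),
            self_detect_midpoint_mm=float(np.exp(x[1])),
            self_detect_hmax=float(np.exp(x[2])),
            self_detect_slope_mm=float(np.exp(x[3])),
            cure_max=float(1.0 / (1.0 + np.exp(-x[4]))),
        )

    def objective(x) -> float:
        aux = unpack(x)
        got = _calibration_outcomes(
            replace(p, aux=aux), n, reps, master_seed, use_contrast
        )
        err = float(np.sum(w * ((got - tgt) / tgt) ** 2))
        if verbose:
            print(
                f"  d0={aux.initial_diameter_mm:.5f}"
                f" dmid={aux.self_detect_midpoint_mm:.2f}"
                f" hmax={aux.self_detect_hmax:.2f}"
                f" slope={aux.self_detect_slope_mm:.2f}"
                f" cure_max={aux.cure_max:.3f} -> {np.round(got, 1)} err={err:.5f}",
                file=sys.stderr,
            )
        return err

    a0 = p.aux
    x0 = np.array(
        [
            np.log(a0.initial_diameter_mm),
            np.log(a0.self_detect_midpoint_mm),
            np.log(a0.self_detect_hmax),
            np.log(a0.self_detect_slope_mm),
            np.log(a0.cure_max / (1 - a0.cure_max)),
        ]
    )
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 4e-3, "fatol": 4e-4},
    )
    aux = unpack(res.x)
    achieved = _calibration_outcomes(
        replace(p, aux=aux), n, reps, master_seed, use_contrast
    )
    rel = np.abs((achieved - tgt) / tgt)
    return {
        "aux": aux,
        "achieved": tuple(float(v) for v in achieved),
        "targets": tuple(float(v) for v in tgt),
        "max_relative_error": float(rel.max()),
        "converged": bool(res.success),
        "n_evaluations": int(res.nfev),
    }
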