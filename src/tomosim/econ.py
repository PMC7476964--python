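"""Health economics: discounting, costs, ICERs and threshold sensitivity.

Costs are direct medical costs only: screening examinations, biopsies
following a positive finding and treatment priced by tumour size at
detection.  Effects are life years gained (LYG) against the paired
no-screening counterfactual.  Scenarios are compared through the
incremental cost-effectiveness ratio ICER = Δcost / ΔLYG, judged against
a willingness-to-pay ceiling (default EUR 20,000 per LYG, "cost-effective"
meaning strictly below).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .params import DiscountScheme, ModelParameters, size_category
from .screening import ScenarioResult, WomanOutcome, _lyg_discounted

__all__ = [
    "Comparison",
    "ComparisonError",
    "discount_value",
    "woman_costs",
    "life_years_components",
    "scenario_costs",
    "compare",
    "compare_reps",
    "threshold_sensitivity",
]

STATUS_CE = "cost_effective"
STATUS_NOT_CE = "not_cost_effective"
STATUS_DOMINANT = "dominant"
STATUS_DOMINATED = "dominated"


class ComparisonError(ValueError):
    """Raised when two scenario results are not comparable."""


@dataclass
class Comparison:
    """Incremental comparison of two scenarios (per 10,000 women)."""

    delta_cost: float  # EUR per 10,000 women
    delta_lyg: float  # life years per 10,000 women
    icer: float  # EUR per LYG; nan when delta_lyg <= 0
    status: str
    se_delta_cost: float = math.nan
    se_delta_lyg: float = math.nan
    se_icer: float = math.nan

    @property
    def qualifies(self) -> bool:
        """True when the scenario is an acceptable buy (dominant or CE)."""
        return self.status in (STATUS_CE, STATUS_DOMINANT)


def discount_value(
    x: float, event_age: float, scheme: DiscountScheme, which: str = "cost"
) -> float:
    """Present value at the scheme's reference age of ``x`` at ``event_age``."""
    if event_age < scheme.reference_age - 1e-12:
        raise ValueError(
            f"event age {event_age} precedes reference age {scheme.reference_age}"
        )
    rate = scheme.cost_rate if which == "cost" else scheme.effect_rate
    return x / (1.0 + rate) ** (event_age - scheme.reference_age)


def woman_costs(
    outcome: WomanOutcome, p: ModelParameters, scheme: DiscountScheme
) -> float:
    """Discounted direct medical costs of one woman's screening pathway."""
    total = 0.0
    for ev in outcome.events:
        if not ev.attended:
            continue
        mod = p.modality(ev.modality)
        total += discount_value(mod.cost_per_screen, ev.age, scheme)
        if ev.outcome in ("TP", "FP"):
            total += discount_value(p.cost_biopsy, ev.age, scheme)
    if outcome.age_at_detection is not None:
        cat = int(size_category(outcome.diameter_at_detection))
        total += discount_value(
            p.treatment_cost_by_size[cat], outcome.age_at_detection, scheme
        )
        if outcome.detection_mode != "screen":
            # clinically surfacing cancers are confirmed by biopsy too
            total += discount_value(p.cost_biopsy, outcome.age_at_detection, scheme)
    return total


def life_years_components(
    outcome: WomanOutcome, scheme: DiscountScheme, discrete: bool = False
) -> tuple[float, float]:
    """(raw, discounted) life years gained for one woman.

    The discounted value treats the gained years as a continuous stream
    between the two death ages (or an annual approximation when
    ``discrete`` is set) discounted at the effect rate.
    """
    raw = outcome.death_age_screened - outcome.death_age_unscreened
    disc = float(
        _lyg_discounted(
            np.array([outcome.death_age_unscreened]),
            np.array([outcome.death_age_screened]),
            scheme.effect_rate,
            scheme.reference_age,
            discrete,
        )[0]
    )
    return raw, disc


def scenario_costs(
    result: ScenarioResult,
    p: ModelParameters,
    scheme_index: int,
    dbt_price: Optional[float] = None,
) -> float:
    """Total discounted cohort cost under a given DBT price level."""
    price = p.dbt.cost_per_screen if dbt_price is None else dbt_price
    return (
        p.dm.cost_per_screen * result.dm_screens_disc[scheme_index]
        + price * result.dbt_screens_disc[scheme_index]
        + p.cost_biopsy * result.biopsies_disc[scheme_index]
        + result.treatment_disc[scheme_index]
    )


def _classify(delta_cost: float, delta_lyg: float, wtp: float) -> tuple[float, str]:
    if delta_lyg > 0:
        if delta_cost <= 0:
            return math.nan, STATUS_DOMINANT
        icer = delta_cost / delta_lyg
        # strictly below the ceiling; guard the exact-boundary case against
        # floating-point round-off
        below = icer < wtp and not math.isclose(icer, wtp, rel_tol=1e-9)
        return icer, STATUS_CE if below else STATUS_NOT_CE
    if delta_cost > 0:
        return math.nan, STATUS_DOMINATED
    return math.nan, STATUS_NOT_CE


def compare_reps(
    cost_a: Iterable[float],
    lyg_a: Iterable[float],
    cost_b: Iterable[float],
    lyg_b: Iterable[float],
    wtp: float,
) -> Comparison:
    """Compare two scenarios from paired repetition-level values.

    Inputs are per-10,000-women costs and LYG per repetition, paired by
    common random numbers.  The ICER is the ratio of mean deltas; its
    standard error comes from the delta method on the paired deltas.
    """
    dc = np.asarray(list(cost_a), float) - np.asarray(list(cost_b), float)
    dl = np.asarray(list(lyg_a), float) - np.asarray(list(lyg_b), float)
    if dc.shape != dl.shape or dc.size == 0:
        raise ComparisonError("mismatched or empty repetition vectors")
    k = dc.size
    mc, ml = float(dc.mean()), float(dl.mean())
    icer, status = _classify(mc, ml, wtp)
    se_c = float(dc.std(ddof=1) / math.sqrt(k)) if k > 1 else math.nan
    se_l = float(dl.std(ddof=1) / math.sqrt(k)) if k > 1 else math.nan
    se_icer = math.nan
    if k > 1 and ml > 0 and not math.isnan(icer):
        var_c = dc.var(ddof=1)
        var_l = dl.var(ddof=1)
        cov = float(np.cov(dc, dl, ddof=1)[0, 1])
        var_r = (
            var_c / ml**2
            + mc**2 * var_l / ml**4
            - 2.0 * mc * cov / ml**3
        ) / k
        se_icer = math.sqrt(max(var_r, 0.0))
    return Comparison(mc, ml, icer, status, se_c, se_l, se_icer)


def compare(
    a: ScenarioResult,
    b: ScenarioResult,
    p: ModelParameters,
    wtp: Optional[float] = None,
    scheme: str = "international",
    dbt_price_a: Optional[float] = None,
    dbt_price_b: Optional[float] = None,
) -> Comparison:
    """Compare two single-repetition scenario results (a minus b)."""
    if a.n_women != b.n_women:
        raise ComparisonError(
            f"cohort sizes differ: {a.n_women} vs {b.n_women}"
        )
    wtp = p.wtp if wtp is None else wtp
    s_idx = [s.name for s in p.discount_schemes].index(scheme)
    dc = a.per_10k(scenario_costs(a, p, s_idx, dbt_price_a)) - b.per_10k(
        scenario_costs(b, p, s_idx, dbt_price_b)
    )
    dl = a.per_10k(a.lyg_disc[s_idx]) - b.per_10k(b.lyg_disc[s_idx])
    icer, status = _classify(dc, dl, wtp)
    return Comparison(dc, dl, icer, status)


def threshold_sensitivity(
    grid: Mapping[float, Comparison], wtp: float | None = None
) -> Optional[float]:
    """Smallest DBT sensitivity at which the scenario qualifies.

    A scenario qualifies when it is dominant or its ICER lies strictly
    below the willingness-to-pay ceiling.  When ``wtp`` is given, ICERs
    are re-judged against it; otherwise each comparison's stored status
    is used.  Returns None when no grid point qualifies.
    """
    for sens in sorted(grid):
        comp = grid[sens]
        if wtp is None:
            ok = comp.qualifies
        else:
            ok = comp.status == STATUS_DOMINANT or (
                not math.isnan(comp.icer) and comp.icer < wtp
            )
        if ok:
            return sens
    return None
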