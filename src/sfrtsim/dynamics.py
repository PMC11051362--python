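"""Tumor-volume evolution during and after radiotherapy, and outcome calculus.

During therapy, dose events reduce each viable sub-volume multiplicatively
by its LQ surviving fraction (with the compartment's OER); inter-fraction
Gompertz regrowth of the proliferating compartment is off by default (the
usual negligible-regrowth assumption over a 10-day course) but can be
enabled.

After the last fraction (day ``n``), the proliferating volume follows

    V(t) = V(n+) * exp(L(t)),
    L(t) = ln(V_inf/V(n+)) * (1 - exp(-k (t - n))) - A(t) - B(t),

the Gompertz solution in log space with two cumulative log-kill offsets:
the radiotherapy-activated immune response ``A`` and the immunotherapy
effect ``B``.  With A and B zero this is exactly the closed-form Gompertz
regrowth curve.  The sign of L drives the clinical outcome:

* L < 0 for all time  — the volume stays below its end-of-therapy value;
  with the detection floor eventually crossed: complete recovery;
* L crosses 0 from below at t* — transient shrinkage, then regrowth
  beginning at t*;
* L > 0 immediately after therapy — immediate regrowth.

Under constant A and no B the regrowth time has the closed form
``t* - n = -(1/k) ln(1 - A / ln(V_inf/V(n+)))``; time-dependent A or B are
handled by bracketed root finding on the daily grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._exceptions import ModelDomainError, NoRegrowthError
from .config import Scenario
from .growth import (
    GompertzParameters,
    ImmuneActivation,
    ImmunotherapyEffect,
    grow_volume,
    log_lethal_ratio,
)
from .radiobiology import TARGET_VERTICES, surviving_fraction
from .segmentation import compartment_targets

__all__ = [
    "COMPLETE_RECOVERY",
    "TRANSIENT_REGROWTH",
    "IMMEDIATE_REGROWTH",
    "OutcomeReport",
    "TrajectoryResult",
    "post_therapy_log_ratio",
    "recovery_condition",
    "early_condition_value",
    "regrowth_time_closed_form",
    "regrowth_time_implicit",
    "simulate",
]

COMPLETE_RECOVERY = "complete-recovery"
TRANSIENT_REGROWTH = "transient-shrinkage-then-regrowth"
IMMEDIATE_REGROWTH = "immediate-regrowth"

#: Root refinement tolerance for regrowth times, in days.
_ROOT_XTOL = 1e-9


def _require_gompertz(gompertz: GompertzParameters) -> None:
    if gompertz.law != "gompertz":
        raise ModelDomainError(
            "the post-therapy recovery/regrowth calculus is derived for the "
            f"Gompertz law; got law={gompertz.law!r}"
        )


def post_therapy_log_ratio(
    t_days: float,
    v_end_cm3: float,
    gompertz: GompertzParameters,
    immune: ImmuneActivation,
    immunotherapy: ImmunotherapyEffect,
    n_end_day: float,
) -> float:
    """L(t) = ln(V_inf/V(n+)) (1 - e^{-k(t-n)}) - A(t) - B(t).

    The post-therapy viable volume is ``V(n+) * exp(L(t))``; L < 0 means
    the volume sits below its end-of-therapy value.
    """
    _require_gompertz(gompertz)
    if t_days < n_end_day:
        raise ModelDomainError(
            f"t={t_days} precedes the end of therapy (day {n_end_day})"
        )
    ratio = log_lethal_ratio(v_end_cm3, gompertz)
    elapsed = t_days - n_end_day
    return (
        ratio * (1.0 - math.exp(-gompertz.k_per_day * elapsed))
        - immune.at(elapsed)
        - immunotherapy.at(t_days)
    )


def recovery_condition(
    v_end_cm3: float, gompertz: GompertzParameters, immune: ImmuneActivation
) -> tuple[bool, float]:
    """Recovery-from-activation-alone test: ln(V_inf/V(n+)) - A(0) < 0.

    Returns ``(recovered, margin)`` with ``margin = ln(V_inf/V(n+)) - A(0)``;
    recovery (strict inequality) corresponds to a negative margin.  When it
    fails, the immune response activated by radiotherapy alone cannot
    prevent regrowth toward the lethal volume.
    """
    margin = log_lethal_ratio(v_end_cm3, gompertz) - immune.at(0.0)
    return margin < 0, margin


def early_condition_value(
    v_end_cm3: float,
    gompertz: GompertzParameters,
    immune: ImmuneActivation,
    m_days: float,
) -> float:
    """First-order early-progression margin k m ln(V_inf/V(n+)) - A(0).

    Valid for k*m << 1; negative means the volume is still shrinking ``m``
    days after the end of therapy.  This is the small-time linearization of
    :func:`post_therapy_log_ratio` with constant A and no immunotherapy.
    """
    ratio = log_lethal_ratio(v_end_cm3, gompertz)
    return gompertz.k_per_day * m_days * ratio - immune.at(0.0)


def regrowth_time_closed_form(
    v_end_cm3: float, gompertz: GompertzParameters, a0: float
) -> float:
    """Days after therapy end at which regrowth begins, constant A, no B.

    Solves L(t) = 0 in closed form:
    ``-(1/k) ln(1 - a0 / ln(V_inf/V(n+)))``.  Zero activation gives zero
    (regrowth immediate); ``a0 >= ln(V_inf/V(n+))`` is the recovery regime
    where no regrowth time exists.
    """
    _require_gompertz(gompertz)
    if a0 < 0:
        raise ModelDomainError(f"a0 must be >= 0, got {a0}")
    ratio = log_lethal_ratio(v_end_cm3, gompertz)
    if a0 >= ratio:
        raise NoRegrowthError(
            f"recovery regime: activation {a0:g} >= ln(V_inf/V) = {ratio:g}, "
            "no regrowth time exists"
        )
    return -math.log(1.0 - a0 / ratio) / gompertz.k_per_day


def regrowth_time_implicit(
    v_end_cm3: float,
    gompertz: GompertzParameters,
    immune: ImmuneActivation,
    immunotherapy: ImmunotherapyEffect,
    n_end_day: float = 0.0,
    horizon_days: float = 730.0,
) -> float | None:
    """Earliest upward zero crossing of L(t), as days after therapy end.

    Scans the daily grid from the end of therapy to the horizon and refines
    each bracketed sign change by bisection (Brent) to well below 1e-6 day.
    Returns ``None`` when L stays negative over the whole horizon (no
    regrowth within it).
    """
    _require_gompertz(gompertz)
    if horizon_days <= n_end_day:
        raise ModelDomainError(
            f"horizon {horizon_days} must exceed the end of therapy {n_end_day}"
        )

    def L(t: float) -> float:
        return post_therapy_log_ratio(
            t, v_end_cm3, gompertz, immune, immunotherapy, n_end_day
        )

    t_prev = n_end_day
    l_prev = L(t_prev)
    if l_prev >= 0.0:
        return 0.0  # no shrinkage phase at all
    # march one day at a time; the grid step matches the clinical dt
    t = math.floor(n_end_day) + 1.0
    while t <= horizon_days:
        l_now = L(t)
        if l_now >= 0.0:
            root = brentq(L, t_prev, t, xtol=_ROOT_XTOL)
            return root - n_end_day
        t_prev, l_prev = t, l_now
        t += 1.0
    return None


@dataclass(frozen=True)
class OutcomeReport:
    """Outcome classification with its supporting condition values.

    ``regrowth_day`` (absolute day) is present exactly when the
    classification is transient shrinkage followed by regrowth.
    ``conditions`` carries the evaluated decision quantities: the
    recovery margin, the first-order early margin, L at the first
    post-therapy day and at the horizon, the volume minimum, and — when a
    transient crossing exists under a recovery outcome — its day.
    """

    classification: str
    regrowth_day: float | None
    conditions: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.classification == TRANSIENT_REGROWTH) != (self.regrowth_day is not None):
            raise ModelDomainError(
                "regrowth_day must be present exactly for the "
                "transient-shrinkage-then-regrowth classification"
            )


@dataclass(frozen=True)
class TrajectoryResult:
    """Daily trajectory table plus outcome report and key scalars.

    ``frame`` columns: day, necrotic, hypoxic_viable, normoxic_viable,
    total_viable, A, B, L (L is NaN during the therapy phase).
    """

    frame: pd.DataFrame
    outcome: OutcomeReport
    n_end_day: float
    v_end_theoretical_normoxic_cm3: float
    v_end_theoretical_hypoxic_cm3: float
    v_post_start_cm3: float
    a0_used: float


def _apply_event_kills(sub: dict[str, float], event, lq, oer) -> None:
    """Multiply viable sub-volumes by the event's surviving fractions in place."""
    vertices_only = event.target == TARGET_VERTICES
    sf_nor = surviving_fraction(event.dose_gy, lq, oer.normoxic)
    sf_hyp = surviving_fraction(event.dose_gy, lq, oer.hypoxic)
    sub["nor_in"] *= sf_nor
    sub["hyp_in"] *= sf_hyp
    if not vertices_only:
        sub["nor_out"] *= sf_nor
        sub["hyp_out"] *= sf_hyp


def simulate(scenario: Scenario, horizon_days: float = 730.0) -> TrajectoryResult:
    """Run the full during- and post-therapy evolution of a scenario.

    Therapy phase: the dose schedule acts multiplicatively on the viable
    sub-volumes (vertex events only inside the vertex spheres); optional
    inter-fraction Gompertz growth of the normoxic compartment between
    daily events.  The necrotic core is inert bookkeeping.

    Post-therapy phase: the proliferating volume follows
    ``V(t) = V(n+) exp(L(t))``; the starting volume is the observed (or
    assumed) end-of-therapy measurement when present, otherwise the LQ
    prediction.  The non-proliferating hypoxic remnant is carried constant.

    Immune activation: an explicit ``scenario.immune`` wins; otherwise it
    is inferred from the observed/assumed volume against the LQ
    prediction; with neither, A = 0.
    """
    sched = scenario.schedule
    n_end = scenario.end_of_therapy_day
    if horizon_days <= n_end:
        raise ModelDomainError(
            f"horizon {horizon_days} must exceed the end of therapy (day {n_end})"
        )
    targets = compartment_targets(scenario.segmentation, scenario.vertices)
    lq, oer, gompertz = scenario.lq, scenario.oer, scenario.gompertz

    sub = {
        "nor_in": targets.normoxic_in_vertex_cm3,
        "nor_out": targets.normoxic_outside_cm3,
        "hyp_in": targets.hypoxic_in_vertex_cm3,
        "hyp_out": targets.hypoxic_outside_cm3,
    }
    necrotic = scenario.segmentation.necrotic_volume_cm3

    start_day = min((e.day for e in sched), default=0.0)
    start_day = min(start_day, 0.0)

    rows: list[dict[str, float]] = []

    def record(day: float, a: float = 0.0, b: float = 0.0, l: float = float("nan")) -> None:
        nor = sub["nor_in"] + sub["nor_out"]
        hyp = sub["hyp_in"] + sub["hyp_out"]
        rows.append(
            {
                "day": day,
                "necrotic": necrotic,
                "hypoxic_viable": hyp,
                "normoxic_viable": nor,
                "total_viable": nor + hyp,
                "A": a,
                "B": b,
                "L": l,
            }
        )

    # ---- therapy phase -------------------------------------------------
    events_by_day: dict[float, list] = {}
    for e in sched:
        events_by_day.setdefault(e.day, []).append(e)

    day = math.floor(start_day)
    prev_day: float | None = None
    while day <= n_end:
        if scenario.include_interfraction_growth and prev_day is not None:
            nor_total = sub["nor_in"] + sub["nor_out"]
            if nor_total > 0:
                grown = grow_volume(nor_total, day - prev_day, gompertz)
                scale = grown / nor_total
                sub["nor_in"] *= scale
                sub["nor_out"] *= scale
        for event in events_by_day.get(float(day), []):
            _apply_event_kills(sub, event, lq, oer)
        record(float(day))
        prev_day = float(day)
        day += 1

    v_end_nor = sub["nor_in"] + sub["nor_out"]
    v_end_hyp = sub["hyp_in"] + sub["hyp_out"]

    # ---- post-therapy phase --------------------------------------------
    observed = scenario.observed_end_volume_cm3 or scenario.assumed_end_volume_cm3
    v_post = observed if observed is not None else v_end_nor
    if v_post <= 0:
        raise ModelDomainError(
            "post-therapy starting volume is non-positive; nothing to evolve"
        )

    if scenario.immune is not None:
        immune = scenario.immune
    elif observed is not None and v_end_nor > 0:
        from .growth import activation_from_volumes

        immune = ImmuneActivation(a0=max(0.0, activation_from_volumes(observed, v_end_nor)))
    else:
        immune = ImmuneActivation(a0=0.0)
    immunotherapy = scenario.immunotherapy

    post_days = np.arange(math.floor(n_end) + 1.0, math.floor(horizon_days) + 1.0)
    min_vol, min_day = v_post, n_end
    floor_day: float | None = None
    for t in post_days:
        l_t = post_therapy_log_ratio(t, v_post, gompertz, immune, immunotherapy, n_end)
        vol = v_post * math.exp(l_t)
        a_t = immune.at(t - n_end)
        b_t = immunotherapy.at(t)
        nor = vol
        hyp = v_end_hyp
        rows.append(
            {
                "day": float(t),
                "necrotic": necrotic,
                "hypoxic_viable": hyp,
                "normoxic_viable": nor,
                "total_viable": nor + hyp,
                "A": a_t,
                "B": b_t,
                "L": l_t,
            }
        )
        if vol < min_vol:
            min_vol, min_day = vol, float(t)
        if floor_day is None and vol < scenario.detection_floor_cm3:
            floor_day = float(t)

    frame = pd.DataFrame(rows)

    # ---- outcome classification ----------------------------------------
    first_post = float(post_days[0])
    l_first = post_therapy_log_ratio(first_post, v_post, gompertz, immune, immunotherapy, n_end)
    l_horizon = post_therapy_log_ratio(
        float(post_days[-1]), v_post, gompertz, immune, immunotherapy, n_end
    )
    crossing = regrowth_time_implicit(
        v_post, gompertz, immune, immunotherapy, n_end_day=n_end, horizon_days=horizon_days
    )
    recovered, margin = recovery_condition(v_post, gompertz, immune)
    conditions: dict[str, Any] = {
        "recovery_margin": margin,
        "early_margin_m1": early_condition_value(v_post, gompertz, immune, 1.0),
        "L_first_post_day": l_first,
        "L_horizon": l_horizon,
        "min_volume_cm3": min_vol,
        "min_volume_day": min_day,
        "horizon_days": float(horizon_days),
    }

    if floor_day is not None:
        classification, regrowth_day = COMPLETE_RECOVERY, None
        conditions["detection_floor_day"] = floor_day
        if crossing is not None:
            conditions["transient_crossing_day"] = n_end + crossing
    elif l_first > 0.0:
        classification, regrowth_day = IMMEDIATE_REGROWTH, None
        if crossing is not None:
            conditions["transient_crossing_day"] = n_end + crossing
    elif crossing is not None:
        classification, regrowth_day = TRANSIENT_REGROWTH, n_end + crossing
    else:
        classification, regrowth_day = COMPLETE_RECOVERY, None

    outcome = OutcomeReport(
        classification=classification, regrowth_day=regrowth_day, conditions=conditions
    )
    return TrajectoryResult(
        frame=frame,
        outcome=outcome,
        n_end_day=n_end,
        v_end_theoretical_normoxic_cm3=v_end_nor,
        v_end_theoretical_hypoxic_cm3=v_end_hyp,
        v_post_start_cm3=v_post,
        a0_used=immune.at(0.0),
    )
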