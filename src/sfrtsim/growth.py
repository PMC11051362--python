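"""Tumor growth laws and immune / immunotherapy effect terms.

Untreated (re)growth follows the Gompertz law

    dV/dt = k * V * ln(V_inf / V),

with specific-rate constant ``k`` (day^-1) and lethal carrying volume
``V_inf`` (cm^3, ~10^12 cells; 1 liter in the default configuration).  Its
closed-form solution is ``V(t) = V_inf * exp(ln(V0/V_inf) * exp(-k t))``.
A logistic alternative is provided behind the same pure-growth interface.

Two dimensionless cumulative log-kill terms modify post-radiotherapy
evolution:

* ``A(t, n*dt)`` — the immune response *activated by radiotherapy*,
  inferred at the end of therapy from the gap between the observed volume
  and the volume the LQ model alone predicts: ``A(0) = -ln(V_obs/V_th)``.
  Over clinical time scales of a few weeks it is taken constant, with a
  hook for a user-supplied decay profile.
* ``B(t, start)`` — cumulative effect of post-radiotherapy immunotherapy,
  the time integral of a per-time effect ``I(t)``.  Constant ``I`` gives a
  linear ``B``; an ``I ~ 1/t`` tail gives a logarithmic ``B``; arbitrary
  integrands are integrated numerically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

from scipy.integrate import quad

from ._exceptions import ConfigurationError, ModelDomainError

__all__ = [
    "GompertzParameters",
    "ImmuneActivation",
    "ImmunotherapyEffect",
    "activation_from_volumes",
    "log_lethal_ratio",
    "immunotherapy_cumulative",
    "gompertz_volume",
    "logistic_volume",
    "grow_volume",
]


@dataclass(frozen=True)
class GompertzParameters:
    """Gompertz growth law: specific rate k (day^-1), lethal volume V_inf (cm^3).

    ``law`` selects the pure-growth solution used for untreated evolution;
    the post-therapy recovery/regrowth calculus is derived for the Gompertz
    law and rejects other choices.
    """

    k_per_day: float
    v_inf_cm3: float = 1000.0
    law: str = "gompertz"

    def __post_init__(self) -> None:
        if self.k_per_day <= 0:
            raise ConfigurationError(f"growth rate k must be > 0, got {self.k_per_day}")
        if self.v_inf_cm3 <= 0:
            raise ConfigurationError(f"V_inf must be > 0, got {self.v_inf_cm3}")
        if self.law not in ("gompertz", "logistic"):
            raise ConfigurationError(f"unknown growth law {self.law!r}")


@dataclass(frozen=True)
class ImmuneActivation:
    """Radiotherapy-activated immune response A(t) as cumulative log-kill.

    ``a0`` is the value at the end of radiotherapy, ``A(0, n*dt)``.  The
    default profile is constant at ``a0``; ``profile`` may supply a
    non-negative function of time-since-end-of-therapy for a decaying
    response.
    """

    a0: float
    profile: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise ConfigurationError(f"immune activation a0 must be >= 0, got {self.a0}")

    def at(self, t_since_end_days: float) -> float:
        """A evaluated ``t_since_end_days`` after the end of radiotherapy."""
        if self.profile is None:
            return self.a0
        value = self.profile(t_since_end_days)
        if value < 0:
            raise ModelDomainError(
                f"immune profile returned A={value} < 0 at t={t_since_end_days}"
            )
        return value


@dataclass(frozen=True)
class ImmunotherapyEffect:
    """Cumulative immunotherapy log-kill B(t) starting at ``start_day``.

    Forms:
      * ``none``        — B = 0 (no immunotherapy);
      * ``linear``      — B = coefficient * (t - start_day), from a constant
        per-time effect I;
      * ``logarithmic`` — B = coefficient * ln(t / start_day), from an
        I ~ 1/t tail;
      * ``custom``      — B = integral of ``integrand`` I(t) from
        ``start_day`` to t, computed numerically.

    B is zero for t <= start_day in every form.
    """

    form: str = "none"
    coefficient: float = 0.0
    start_day: float = 0.0
    integrand: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("none", "linear", "logarithmic", "custom"):
            raise ConfigurationError(f"unknown immunotherapy form {self.form!r}")
        if self.coefficient < 0:
            raise ConfigurationError(
                f"immunotherapy coefficient must be >= 0, got {self.coefficient}"
            )
        if self.form == "logarithmic" and self.start_day <= 0:
            raise ConfigurationError("logarithmic form needs start_day > 0")
        if self.form == "custom" and self.integrand is None:
            raise ConfigurationError("custom form needs an integrand I(t)")

    def at(self, t_days: float) -> float:
        return immunotherapy_cumulative(self, t_days)


def activation_from_volumes(v_exp_cm3: float, v_th_cm3: float) -> float:
    """Immune activation A(0, n*dt) = -ln(V_observed / V_theoretical).

    Positive when the observed end-of-therapy volume undershoots the pure
    LQ prediction — the surplus kill attributed to the radiotherapy-
    activated immune response.  An observed volume *above* the prediction
    yields a negative value with a warning (the model assumes the ratio
    is below 1).
    """
    if v_exp_cm3 <= 0 or v_th_cm3 <= 0:
        raise ModelDomainError(
            f"volumes must be > 0, got observed={v_exp_cm3}, theoretical={v_th_cm3}"
        )
    a0 = -math.log(v_exp_cm3 / v_th_cm3)
    if a0 < 0:
        warnings.warn(
            "observed end-of-therapy volume exceeds the LQ prediction "
            f"({v_exp_cm3:g} > {v_th_cm3:g} cm^3): negative immune activation "
            f"A={a0:.4g}; the model assumes observed <= theoretical",
            stacklevel=2,
        )
    return a0


def log_lethal_ratio(v_cm3: float, gompertz: GompertzParameters) -> float:
    """ln(V_inf / V): log-distance of the current volume from the lethal one."""
    if v_cm3 <= 0:
        raise ModelDomainError(f"volume must be > 0, got {v_cm3}")
    if v_cm3 >= gompertz.v_inf_cm3:
        raise ModelDomainError(
            f"volume {v_cm3} cm^3 is at or beyond the lethal volume "
            f"{gompertz.v_inf_cm3} cm^3"
        )
    return math.log(gompertz.v_inf_cm3 / v_cm3)


def immunotherapy_cumulative(effect: ImmunotherapyEffect, t_days: float) -> float:
    """Cumulative immunotherapy effect B(t); zero before onset."""
    if t_days < 0:
        raise ModelDomainError(f"time must be >= 0, got {t_days}")
    if effect.form == "none" or t_days <= effect.start_day:
        return 0.0
    if effect.form == "linear":
        return effect.coefficient * (t_days - effect.start_day)
    if effect.form == "logarithmic":
        return effect.coefficient * math.log(t_days / effect.start_day)
    value, _ = quad(effect.integrand, effect.start_day, t_days, epsabs=1e-8, epsrel=1e-8)
    return value


def gompertz_volume(v0_cm3: float, t_days: float, gompertz: GompertzParameters) -> float:
    """Closed-form Gompertz solution V(t) from V(0) = v0."""
    if v0_cm3 <= 0:
        raise ModelDomainError(f"volume must be > 0, got {v0_cm3}")
    v_inf = gompertz.v_inf_cm3
    return v_inf * math.exp(math.log(v0_cm3 / v_inf) * math.exp(-gompertz.k_per_day * t_days))


def logistic_volume(v0_cm3: float, t_days: float, gompertz: GompertzParameters) -> float:
    """Closed-form logistic solution of dV/dt = k V (1 - V/V_inf)."""
    if v0_cm3 <= 0:
        raise ModelDomainError(f"volume must be > 0, got {v0_cm3}")
    v_inf = gompertz.v_inf_cm3
    return v_inf / (1.0 + (v_inf / v0_cm3 - 1.0) * math.exp(-gompertz.k_per_day * t_days))


def grow_volume(v0_cm3: float, t_days: float, gompertz: GompertzParameters) -> float:
    """Pure untreated growth over ``t_days`` under the configured law."""
    if gompertz.law == "logistic":
        return logistic_volume(v0_cm3, t_days, gompertz)
    return gompertz_volume(v0_cm3, t_days, gompertz)
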