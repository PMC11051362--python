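"""Scenario configuration: schema, validation, YAML/JSON round trip.

A *scenario* bundles everything one simulation or clinical assessment
needs: the tumor segmentation and vertex set, the dose schedule, the
radiosensitivity and oxygen-enhancement parameters, the growth law, and
the immune/immunotherapy terms.  Keys carry explicit unit suffixes
(``_cm3``, ``_gy``, ``_days``/``_per_day``) so a config cannot be
unit-ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from ._exceptions import ConfigurationError
from .growth import GompertzParameters, ImmuneActivation, ImmunotherapyEffect
from .radiobiology import (
    DoseEvent,
    LQParameters,
    OxygenModifier,
    default_lq_parameters,
)
from .segmentation import TumorSegmentation, VertexSet

__all__ = ["Scenario", "load_scenario", "save_scenario", "scenario_from_dict", "scenario_to_dict"]

_TOP_LEVEL_KEYS = {
    "segmentation",
    "schedule",
    "lq",
    "oer",
    "gompertz",
    "immune",
    "immunotherapy",
    "observed_end_volume_cm3",
    "assumed_end_volume_cm3",
    "options",
}


@dataclass(frozen=True)
class Scenario:
    """Validated scenario configuration.

    ``observed_end_volume_cm3`` is the measured end-of-therapy volume of
    the proliferating (normoxic) compartment; ``assumed_end_volume_cm3``
    is the stand-in used when the residual lesion is below detection.
    ``immune`` set to ``None`` means "infer the activation from the
    observed/assumed end volume" (or zero when neither is available).
    """

    segmentation: TumorSegmentation
    vertices: VertexSet
    schedule: tuple[DoseEvent, ...]
    gompertz: GompertzParameters
    lq: LQParameters = field(default_factory=default_lq_parameters)
    oer: OxygenModifier = field(default_factory=OxygenModifier)
    immune: ImmuneActivation | None = None
    immunotherapy: ImmunotherapyEffect = field(default_factory=ImmunotherapyEffect)
    observed_end_volume_cm3: float | None = None
    assumed_end_volume_cm3: float | None = None
    include_interfraction_growth: bool = False
    detection_floor_cm3: float = 1e-6
    reporting_resolution_cm3: float = 1e-3

    def __post_init__(self) -> None:
        days = [e.day for e in self.schedule]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ConfigurationError("schedule events must be sorted by day")
        for name in ("observed_end_volume_cm3", "assumed_end_volume_cm3"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        if self.detection_floor_cm3 <= 0:
            raise ConfigurationError("detection_floor_cm3 must be > 0")
        if self.reporting_resolution_cm3 < 0:
            raise ConfigurationError("reporting_resolution_cm3 must be >= 0")

    def with_(self, **changes: Any) -> "Scenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @property
    def end_of_therapy_day(self) -> float:
        """Day of the last dose event (0 for an empty schedule)."""
        return max((e.day for e in self.schedule), default=0.0)


def _require(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"missing required key {key!r} in {context}")
    return mapping[key]


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def scenario_from_dict(raw: Mapping[str, Any]) -> Scenario:
    """Build a validated :class:`Scenario` from a plain nested mapping."""
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"scenario must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, _TOP_LEVEL_KEYS, "scenario")

    seg_raw = dict(_require(raw, "segmentation", "scenario"))
    vert_raw = dict(seg_raw.pop("vertices", {"count": 0, "diameter_cm": 1.0}))
    _check_keys(
        seg_raw,
        {"gtv_cm3", "necrotic_cm3", "hypoxic_cm3", "normoxic_cm3", "rel_tol"},
        "segmentation",
    )
    segmentation = TumorSegmentation(
        gtv_volume_cm3=float(_require(seg_raw, "gtv_cm3", "segmentation")),
        necrotic_volume_cm3=float(_require(seg_raw, "necrotic_cm3", "segmentation")),
        hypoxic_volume_cm3=float(_require(seg_raw, "hypoxic_cm3", "segmentation")),
        normoxic_volume_cm3=float(_require(seg_raw, "normoxic_cm3", "segmentation")),
        rel_tol=float(seg_raw.get("rel_tol", 1e-6)),
    )
    _check_keys(
        vert_raw,
        {"count", "diameter_cm", "fraction_in_hypoxic", "fraction_in_necrotic"},
        "segmentation.vertices",
    )
    vertices = VertexSet(
        count=int(vert_raw.get("count", 0)),
        diameter_cm=float(vert_raw.get("diameter_cm", 1.0)),
        fraction_in_hypoxic=float(vert_raw.get("fraction_in_hypoxic", 1.0)),
        fraction_in_necrotic=float(vert_raw.get("fraction_in_necrotic", 0.0)),
    )

    schedule = []
    for i, ev in enumerate(_require(raw, "schedule", "scenario")):
        _check_keys(ev, {"day", "dose_gy", "target"}, f"schedule[{i}]")
        schedule.append(
            DoseEvent(
                day=float(_require(ev, "day", f"schedule[{i}]")),
                dose_gy=float(_require(ev, "dose_gy", f"schedule[{i}]")),
                target=str(ev.get("target", "whole-tumor")),
            )
        )

    gom_raw = dict(_require(raw, "gompertz", "scenario"))
    _check_keys(gom_raw, {"k_per_day", "v_inf_cm3", "law"}, "gompertz")
    gompertz = GompertzParameters(
        k_per_day=float(_require(gom_raw, "k_per_day", "gompertz")),
        v_inf_cm3=float(gom_raw.get("v_inf_cm3", 1000.0)),
        law=str(gom_raw.get("law", "gompertz")),
    )

    if "lq" in raw and raw["lq"] is not None:
        lq_raw = dict(raw["lq"])
        _check_keys(lq_raw, {"alpha_per_gy", "beta_per_gy2"}, "lq")
        lq = LQParameters(
            alpha_per_gy=float(_require(lq_raw, "alpha_per_gy", "lq")),
            beta_per_gy2=float(_require(lq_raw, "beta_per_gy2", "lq")),
        )
    else:
        lq = default_lq_parameters()

    oer_raw = dict(raw.get("oer") or {})
    _check_keys(oer_raw, {"hypoxic", "normoxic"}, "oer")
    oer = OxygenModifier(
        hypoxic=float(oer_raw.get("hypoxic", 1.5)),
        normoxic=float(oer_raw.get("normoxic", 1.0)),
    )

    immune = None
    if raw.get("immune") is not None:
        imm_raw = dict(raw["immune"])
        _check_keys(imm_raw, {"a0"}, "immune")
        immune = ImmuneActivation(a0=float(_require(imm_raw, "a0", "immune")))

    if raw.get("immunotherapy") is not None:
        it_raw = dict(raw["immunotherapy"])
        _check_keys(it_raw, {"form", "coefficient", "start_day"}, "immunotherapy")
        immunotherapy = ImmunotherapyEffect(
            form=str(it_raw.get("form", "none")),
            coefficient=float(it_raw.get("coefficient", 0.0)),
            start_day=float(it_raw.get("start_day", 0.0)),
        )
    else:
        immunotherapy = ImmunotherapyEffect()

    opt_raw = dict(raw.get("options") or {})
    _check_keys(
        opt_raw,
        {"include_interfraction_growth", "detection_floor_cm3", "reporting_resolution_cm3"},
        "options",
    )

    try:
        return Scenario(
            segmentation=segmentation,
            vertices=vertices,
            schedule=tuple(schedule),
            gompertz=gompertz,
            lq=lq,
            oer=oer,
            immune=immune,
            immunotherapy=immunotherapy,
            observed_end_volume_cm3=(
                float(raw["observed_end_volume_cm3"])
                if raw.get("observed_end_volume_cm3") is not None
                else None
            ),
            assumed_end_volume_cm3=(
                float(raw["assumed_end_volume_cm3"])
                if raw.get("assumed_end_volume_cm3") is not None
                else None
            ),
            include_interfraction_growth=bool(
                opt_raw.get("include_interfraction_growth", False)
            ),
            detection_floor_cm3=float(opt_raw.get("detection_floor_cm3", 1e-6)),
            reporting_resolution_cm3=float(opt_raw.get("reporting_resolution_cm3", 1e-3)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Serialize a scenario to a plain nested dict (YAML/JSON-safe).

    Callable hooks (custom immunotherapy integrands, immune decay profiles)
    cannot be serialized and are rejected.
    """
    if scenario.immunotherapy.form == "custom":
        raise ConfigurationError("custom immunotherapy integrands cannot be serialized")
    if scenario.immune is not None and scenario.immune.profile is not None:
        raise ConfigurationError("immune decay profiles cannot be serialized")
    out: dict[str, Any] = {
        "segmentation": {
            "gtv_cm3": scenario.segmentation.gtv_volume_cm3,
            "necrotic_cm3": scenario.segmentation.necrotic_volume_cm3,
            "hypoxic_cm3": scenario.segmentation.hypoxic_volume_cm3,
            "normoxic_cm3": scenario.segmentation.normoxic_volume_cm3,
            "vertices": {
                "count": scenario.vertices.count,
                "diameter_cm": scenario.vertices.diameter_cm,
                "fraction_in_hypoxic": scenario.vertices.fraction_in_hypoxic,
                "fraction_in_necrotic": scenario.vertices.fraction_in_necrotic,
            },
        },
        "schedule": [
            {"day": e.day, "dose_gy": e.dose_gy, "target": e.target}
            for e in scenario.schedule
        ],
        "lq": {
            "alpha_per_gy": scenario.lq.alpha_per_gy,
            "beta_per_gy2": scenario.lq.beta_per_gy2,
        },
        "oer": {"hypoxic": scenario.oer.hypoxic, "normoxic": scenario.oer.normoxic},
        "gompertz": {
            "k_per_day": scenario.gompertz.k_per_day,
            "v_inf_cm3": scenario.gompertz.v_inf_cm3,
            "law": scenario.gompertz.law,
        },
        "immunotherapy": {
            "form": scenario.immunotherapy.form,
            "coefficient": scenario.immunotherapy.coefficient,
            "start_day": scenario.immunotherapy.start_day,
        },
        "options": {
            "include_interfraction_growth": scenario.include_interfraction_growth,
            "detection_floor_cm3": scenario.detection_floor_cm3,
            "reporting_resolution_cm3": scenario.reporting_resolution_cm3,
        },
    }
    if scenario.immune is not None:
        out["immune"] = {"a0": scenario.immune.a0}
    if scenario.observed_end_volume_cm3 is not None:
        out["observed_end_volume_cm3"] = scenario.observed_end_volume_cm3
    if scenario.assumed_end_volume_cm3 is not None:
        out["assumed_end_volume_cm3"] = scenario.assumed_end_volume_cm3
    return out


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML (or JSON) file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse scenario file {path}: {exc}") from exc
    if raw is None:
        raise ConfigurationError(f"scenario file {path} is empty")
    return scenario_from_dict(raw)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario to YAML (JSON files also parse back, YAML superset)."""
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))
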