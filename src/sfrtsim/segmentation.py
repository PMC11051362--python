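"""Concentric-compartment tumor geometry for Lattice/GRID radiotherapy.

The gross tumor volume (GTV) is segmented into three concentric
compartments reflecting the oxygenation pattern of a bulky lesion:

* a **necrotic** core of dead cells (inert: never grows, never a
  radiotherapy target),
* a **hypoxic** mid-layer of viable but non-proliferating cells
  (radiosensitive with an oxygen enhancement ratio, excluded from growth),
* a **normoxic** outer rim of proliferating, well-oxygenated cells.

Lattice therapy additionally delineates a set of small high-dose spheres
("vertices") inside the hypoxic layer, possibly overlapping the necrotic
core.  All geometry is carried as volumes (cm^3); no voxel coordinates are
involved.  Vertex/compartment overlap is therefore expressed as explicit
volume fractions rather than computed from 3-D shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._exceptions import ConfigurationError, VertexOverflowError

__all__ = [
    "TumorSegmentation",
    "VertexSet",
    "CompartmentTargets",
    "SegmentationReport",
    "total_vertex_volume",
    "validate_segmentation",
    "compartment_targets",
]

#: Default relative tolerance for the volume-conservation check.
DEFAULT_REL_TOL = 1e-6


@dataclass(frozen=True)
class TumorSegmentation:
    """Compartment volumes of a segmented tumor, all in cm^3.

    The three compartment volumes must sum to ``gtv_volume_cm3`` within
    ``rel_tol`` (volume conservation).  Construction raises
    :class:`~sfrtsim._exceptions.ConfigurationError` on violation, with
    negative volumes reported distinctly from conservation failures.
    """

    gtv_volume_cm3: float
    necrotic_volume_cm3: float
    hypoxic_volume_cm3: float
    normoxic_volume_cm3: float
    rel_tol: float = DEFAULT_REL_TOL

    def __post_init__(self) -> None:
        report = validate_segmentation(self, rel_tol=self.rel_tol)
        if not report.passed:
            raise ConfigurationError("; ".join(report.issues))

    @property
    def viable_volume_cm3(self) -> float:
        """Hypoxic + normoxic volume (everything that is alive)."""
        return self.hypoxic_volume_cm3 + self.normoxic_volume_cm3


@dataclass(frozen=True)
class VertexSet:
    """High-dose vertex spheres and their attribution to compartments.

    ``fraction_in_hypoxic`` / ``fraction_in_necrotic`` give the fraction of
    the total vertex volume lying inside each compartment; the remainder is
    attributed to the normoxic rim.
    """

    count: int
    diameter_cm: float
    fraction_in_hypoxic: float = 1.0
    fraction_in_necrotic: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigurationError(f"vertex count must be >= 0, got {self.count}")
        if self.diameter_cm <= 0:
            raise ConfigurationError(
                f"vertex diameter must be > 0 cm, got {self.diameter_cm}"
            )
        for name in ("fraction_in_hypoxic", "fraction_in_necrotic"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {f}")
        if self.fraction_in_hypoxic + self.fraction_in_necrotic > 1.0 + 1e-12:
            raise ConfigurationError(
                "fraction_in_hypoxic + fraction_in_necrotic must be <= 1"
            )

    @property
    def fraction_in_normoxic(self) -> float:
        return max(0.0, 1.0 - self.fraction_in_hypoxic - self.fraction_in_necrotic)


@dataclass(frozen=True)
class SegmentationReport:
    """Outcome of :func:`validate_segmentation`."""

    passed: bool
    issues: tuple[str, ...] = ()
    conservation_error: float = 0.0  # |sum - gtv| / gtv


@dataclass(frozen=True)
class CompartmentTargets:
    """Per-compartment volumes split into inside- and outside-vertex parts.

    The inside-vertex sub-volumes receive the vertex dose events in
    addition to whole-tumor fractions; outside-vertex sub-volumes receive
    whole-tumor fractions only.
    """

    necrotic_in_vertex_cm3: float
    necrotic_outside_cm3: float
    hypoxic_in_vertex_cm3: float
    hypoxic_outside_cm3: float
    normoxic_in_vertex_cm3: float
    normoxic_outside_cm3: float

    @property
    def total_cm3(self) -> float:
        return (
            self.necrotic_in_vertex_cm3
            + self.necrotic_outside_cm3
            + self.hypoxic_in_vertex_cm3
            + self.hypoxic_outside_cm3
            + self.normoxic_in_vertex_cm3
            + self.normoxic_outside_cm3
        )


def total_vertex_volume(vertices: VertexSet) -> float:
    """Total volume (cm^3) of the vertex spheres: count * (pi/6) * d^3."""
    return vertices.count * (math.pi / 6.0) * vertices.diameter_cm**3


def validate_segmentation(
    segmentation: TumorSegmentation | None = None,
    rel_tol: float = DEFAULT_REL_TOL,
    *,
    gtv_cm3: float | None = None,
    necrotic_cm3: float | None = None,
    hypoxic_cm3: float | None = None,
    normoxic_cm3: float | None = None,
) -> SegmentationReport:
    """Check non-negativity and volume conservation of a segmentation.

    Accepts either a :class:`TumorSegmentation` or raw volumes via keyword
    arguments (the raw form is what the constructor itself uses, so that
    invalid volumes can be reported rather than raising on construction).

    A negative volume and an inconsistent (non-conserving) segmentation are
    flagged as distinct issues.
    """
    if segmentation is not None:
        gtv = segmentation.gtv_volume_cm3
        nec = segmentation.necrotic_volume_cm3
        hyp = segmentation.hypoxic_volume_cm3
        nor = segmentation.normoxic_volume_cm3
    else:
        if None in (gtv_cm3, necrotic_cm3, hypoxic_cm3, normoxic_cm3):
            raise TypeError("provide a TumorSegmentation or all four volumes")
        gtv, nec, hyp, nor = gtv_cm3, necrotic_cm3, hypoxic_cm3, normoxic_cm3

    issues: list[str] = []
    for name, v in (
        ("gtv", gtv),
        ("necrotic", nec),
        ("hypoxic", hyp),
        ("normoxic", nor),
    ):
        if v < 0:
            issues.append(f"negative volume: {name} = {v} cm^3")

    conservation_error = 0.0
    if gtv > 0:
        conservation_error = abs(nec + hyp + nor - gtv) / gtv
        if conservation_error > rel_tol:
            issues.append(
                "inconsistent segmentation: compartments sum to "
                f"{nec + hyp + nor:g} cm^3 but GTV is {gtv:g} cm^3 "
                f"(relative error {conservation_error:.3g})"
            )
    elif gtv == 0 and (nec + hyp + nor) != 0:
        issues.append("inconsistent segmentation: zero GTV with non-zero compartments")

    return SegmentationReport(
        passed=not issues, issues=tuple(issues), conservation_error=conservation_error
    )


def compartment_targets(
    segmentation: TumorSegmentation, vertices: VertexSet
) -> CompartmentTargets:
    """Split each compartment into inside-/outside-vertex sub-volumes.

    Raises :class:`VertexOverflowError` when the vertex volume attributed
    to a compartment exceeds that compartment's volume.  The six returned
    sub-volumes always sum to the GTV.
    """
    v_total = total_vertex_volume(vertices)
    in_hyp = v_total * vertices.fraction_in_hypoxic
    in_nec = v_total * vertices.fraction_in_necrotic
    in_nor = v_total * vertices.fraction_in_normoxic

    for name, inside, host in (
        ("hypoxic", in_hyp, segmentation.hypoxic_volume_cm3),
        ("necrotic", in_nec, segmentation.necrotic_volume_cm3),
        ("normoxic", in_nor, segmentation.normoxic_volume_cm3),
    ):
        if inside > host * (1.0 + 1e-12):
            raise VertexOverflowError(
                f"vertex overflow: {inside:g} cm^3 of vertex volume attributed to "
                f"the {name} compartment, which holds only {host:g} cm^3"
            )

    return CompartmentTargets(
        necrotic_in_vertex_cm3=in_nec,
        necrotic_outside_cm3=segmentation.necrotic_volume_cm3 - in_nec,
        hypoxic_in_vertex_cm3=in_hyp,
        hypoxic_outside_cm3=segmentation.hypoxic_volume_cm3 - in_hyp,
        normoxic_in_vertex_cm3=in_nor,
        normoxic_outside_cm3=segmentation.normoxic_volume_cm3 - in_nor,
    )
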