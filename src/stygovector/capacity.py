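"""Geometric "hitch-hiker" capacity model.

How many prokaryote cells fit as a monolayer on a stygofauna body, how many
cells the same body volume of groundwater would hold, and the resulting
enrichment in orders of magnitude.  Capacity is area / rectangular cell
footprint with no packing discount, which makes it a deliberate lower bound:
attached communities form biofilms, which are multilayered and are not
modeled here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "Morphometrics",
    "ProkaryoteGeometry",
    "CapacityEstimate",
    "box_surface_area",
    "attachment_capacity",
    "body_volume",
    "groundwater_equivalent",
    "enrichment_orders",
    "ultrasmall_capacity",
    "capacity_estimate",
    "round_sig",
]


@dataclass(frozen=True)
class Morphometrics:
    """Animal body dimensions (mm) and, if imaged, total surface area (mm^2).

    ``leg_area_factor`` inflates the box surface area to stand in for
    appendages when no imaged area is available; it is ignored when
    ``surface_area_mm2`` is given.
    """

    length_mm: float
    width_mm: float
    height_mm: float
    surface_area_mm2: float | None = None
    leg_area_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_mm, self.height_mm) <= 0:
            raise ValueError("all body dimensions must be positive")
        if self.leg_area_factor <= 0:
            raise ValueError("leg_area_factor must be positive")
        if self.surface_area_mm2 is not None:
            box = 2 * (
                self.length_mm * self.width_mm
                + self.length_mm * self.height_mm
                + self.width_mm * self.height_mm
            )
            if self.surface_area_mm2 < box:
                raise ValueError(
                    f"measured surface area {self.surface_area_mm2} mm^2 is below "
                    f"the bounding-box area {box:.3g} mm^2"
                )


@dataclass(frozen=True)
class ProkaryoteGeometry:
    """Mean prokaryote cell dimensions (um) and ultra-small scaling knobs.

    ``ultrasmall_volume_factor`` is how many times smaller in volume
    ultra-small groundwater bacteria can be than the mixed-community mean;
    ``area_scaling_exponent`` converts that volume shrinkage into a footprint
    shrinkage (area ~ volume^(2/3) for isometric cells).
    """

    cell_length_um: float = 1.25
    cell_width_um: float = 0.36
    ultrasmall_volume_factor: float = 56.0
    area_scaling_exponent: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.cell_length_um, self.cell_width_um) <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.ultrasmall_volume_factor < 1:
            raise ValueError("ultrasmall_volume_factor must be >= 1")

    @property
    def footprint_um2(self) -> float:
        return self.cell_length_um * self.cell_width_um


@dataclass(frozen=True)
class CapacityEstimate:
    """Attachment capacity versus the equivalent groundwater cell count."""

    attachable_cells: int
    ultrasmall_attachable_cells: int
    body_volume_ul: float
    groundwater_cells_per_l: float
    equivalent_cells: int
    enrichment_orders: int


def box_surface_area(m: Morphometrics) -> float:
    """Rectangular-box surface area in mm^2, scaled by the leg-area factor.

    Fallback for when no imaged surface area is available.
    """
    return (
        2
        * (
            m.length_mm * m.width_mm
            + m.length_mm * m.height_mm
            + m.width_mm * m.height_mm
        )
        * m.leg_area_factor
    )


def attachment_capacity(m: Morphometrics, g: ProkaryoteGeometry) -> int:
    """Monolayer attachment capacity: floor(surface area / cell footprint).

    Uses the imaged surface area when present, else the box fallback.
    """
    area_mm2 = m.surface_area_mm2 if m.surface_area_mm2 is not None else box_surface_area(m)
    area_um2 = area_mm2 * 1e6
    if g.footprint_um2 <= 0:
        raise ValueError("cell footprint must be positive")
    return math.floor(area_um2 / g.footprint_um2)


def body_volume(m: Morphometrics) -> float:
    """Body volume in ul (length x width x height; 1 mm^3 = 1 ul)."""
    return m.length_mm * m.width_mm * m.height_mm


def groundwater_equivalent(volume_ul: float, cells_per_l: float) -> int:
    """Cells held by ``volume_ul`` of groundwater at the given concentration."""
    if volume_ul < 0 or cells_per_l < 0:
        raise ValueError("volume and concentration must be non-negative")
    return round(volume_ul * 1e-6 * cells_per_l)


def enrichment_orders(attachable: float, equivalent: float) -> int:
    """Orders-of-magnitude enrichment: round-half-up of log10(attachable/equivalent)."""
    if attachable <= 0 or equivalent <= 0:
        raise ValueError("cell counts must be positive")
    return math.floor(math.log10(attachable / equivalent) + 0.5)


def ultrasmall_capacity(base_capacity: int, g: ProkaryoteGeometry) -> int:
    """Capacity if cells are ultra-small: footprint shrinks as volume^exponent."""
    if base_capacity <= 0:
        raise ValueError("base capacity must be positive")
    if not 0 <= g.area_scaling_exponent <= 1:
        warnings.warn(
            f"area scaling exponent {g.area_scaling_exponent} outside [0, 1]",
            stacklevel=2,
        )
    return math.floor(base_capacity * g.ultrasmall_volume_factor**g.area_scaling_exponent)


def capacity_estimate(
    m: Morphometrics, g: ProkaryoteGeometry, groundwater_cells_per_l: float
) -> CapacityEstimate:
    """Full capacity/enrichment pipeline for one animal."""
    attach = attachment_capacity(m, g)
    vol = body_volume(m)
    equiv = groundwater_equivalent(vol, groundwater_cells_per_l)
    return CapacityEstimate(
        attachable_cells=attach,
        ultrasmall_attachable_cells=ultrasmall_capacity(attach, g),
        body_volume_ul=vol,
        groundwater_cells_per_l=groundwater_cells_per_l,
        equivalent_cells=equiv,
        enrichment_orders=enrichment_orders(attach, equiv),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (for reporting; internals stay exact)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))
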