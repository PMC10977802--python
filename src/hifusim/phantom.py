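"""Voxel tissue phantoms for treatment simulation.

A :class:`TissuePhantom` is a uniform voxel grid (axes x, y, z with z the
beam axis, focus/lesion at the grid center) carrying thermal properties, a
lesion mask, and the acoustic medium of the focal region.  The perfusion
dichotomy that motivates parameter optimization is encoded in the scenario
label: a uterine fibroid perfuses like skeletal muscle, whereas focal
adenomyosis perfuses like the (much better perfused) uterine myometrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustic import FAT, MUSCLE, MYOMETRIUM, WATER, AcousticMedium
from .bioheat import ThermalTissue

__all__ = [
    "Ellipsoid",
    "TissueLayer",
    "DEFAULT_BEAM_PATH",
    "PERFUSION",
    "TissuePhantom",
    "generate_phantom",
]

#: Default perfusion rates [kg/(m³ s)] for the two tissue scenarios.
PERFUSION = {
    "fibroid-muscle": 0.7,
    "adenomyosis-myometrium": 2.5,
}


@dataclass(frozen=True)
class Ellipsoid:
    """Lesion ellipsoid: center and semi-axes in mm (axes aligned to grid)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")

    @property
    def volume_cm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c * 1e-3

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        d = (np.asarray(points_mm) - np.asarray(self.center_mm)) / np.asarray(
            self.semi_axes_mm
        )
        return (d * d).sum(axis=-1) <= 1.0


@dataclass(frozen=True)
class TissueLayer:
    """One layer of the transabdominal beam path."""

    medium: AcousticMedium
    thickness_mm: float


#: Water standoff, 10 mm fat, 15 mm muscle, then myometrium to the focus.
DEFAULT_BEAM_PATH = (
    TissueLayer(WATER, 50.0),
    TissueLayer(FAT, 10.0),
    TissueLayer(MUSCLE, 15.0),
    TissueLayer(MYOMETRIUM, np.inf),
)


@dataclass
class TissuePhantom:
    """Voxel grid of tissue properties with a labelled lesion.

    Arrays are indexed ``[ix, iy, iz]``; the grid center (where the lesion
    sits and where single-point plans focus) is at physical coordinate
    (0, 0, 0); z increases away from the transducer (deeper).
    """

    voxel_mm: float
    shape: tuple[int, int, int]
    w_b: np.ndarray  # perfusion rate per voxel
    lesion_mask: np.ndarray
    lesion: Ellipsoid
    scenario: str
    k: float = 0.56
    rho: float = 1050.0
    c_p: float = 3600.0
    c_b: float = 3617.0
    T_a: float = 37.0
    focal_medium: AcousticMedium = MYOMETRIUM
    beam_path: tuple[TissueLayer, ...] = DEFAULT_BEAM_PATH

    def __post_init__(self) -> None:
        if self.lesion_mask.dtype != bool:
            raise ValueError("lesion mask must be boolean")
        if self.w_b.shape != self.shape or self.lesion_mask.shape != self.shape:
            raise ValueError("property grids must be congruent with the phantom shape")

    def axes_mm(self) -> tuple[np.ndarray, ...]:
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * self.voxel_mm for n in self.shape
        )

    def thermal_tissue(self) -> ThermalTissue:
        return ThermalTissue(
            k=self.k, rho=self.rho, c_p=self.c_p, w_b=self.w_b,
            c_b=self.c_b, T_a=self.T_a,
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm**3

    def with_uniform_perfusion(self, w_b: float) -> "TissuePhantom":
        """Copy of the phantom with w_b set everywhere (sweep helper)."""
        if w_b < 0:
            raise ValueError("perfusion must be non-negative")
        out = TissuePhantom(
            voxel_mm=self.voxel_mm, shape=self.shape,
            w_b=np.full(self.shape, float(w_b)), lesion_mask=self.lesion_mask,
            lesion=self.lesion, scenario=f"uniform-wb-{w_b:g}",
            k=self.k, rho=self.rho, c_p=self.c_p, c_b=self.c_b, T_a=self.T_a,
            focal_medium=self.focal_medium, beam_path=self.beam_path,
        )
        return out


def generate_phantom(
    domain_mm: tuple[float, float, float],
    voxel_mm: float,
    lesion_semi_axes_mm: tuple[float, float, float],
    scenario: str,
    background_w_b: float | None = None,
    clearance_mm: float = 5.0,
) -> TissuePhantom:
    """Deterministically build a lesion-in-myometrium phantom.

    The lesion ellipsoid is centered in the domain; lesion voxels get the
    scenario's perfusion (fibroid → muscle, adenomyosis → myometrium), the
    background keeps the myometrium default.  The lesion must fit inside
    the domain with ``clearance_mm`` to every face, and the voxel must
    resolve the smallest semi-axis.
    """
    if scenario not in PERFUSION:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {sorted(PERFUSION)}"
        )
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    if voxel_mm > min(lesion_semi_axes_mm):
        raise ValueError("voxel size exceeds the smallest lesion semi-axis")
    for extent, semi in zip(domain_mm, lesion_semi_axes_mm):
        if semi + clearance_mm > extent / 2.0:
            raise ValueError("lesion does not fit in the domain with clearance")

    shape = tuple(int(round(e / voxel_mm)) for e in domain_mm)
    lesion = Ellipsoid(center_mm=(0.0, 0.0, 0.0), semi_axes_mm=lesion_semi_axes_mm)
    ax = tuple((np.arange(n) - (n - 1) / 2.0) * voxel_mm for n in shape)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    mask = lesion.contains(np.stack([X, Y, Z], axis=-1))

    bg = background_w_b if background_w_b is not None else PERFUSION[
        "adenomyosis-myometrium"
    ]
    w_b = np.full(shape, float(bg))
    w_b[mask] = PERFUSION[scenario]
    return TissuePhantom(
        voxel_mm=voxel_mm, shape=shape, w_b=w_b, lesion_mask=mask,
        lesion=lesion, scenario=scenario,
    )
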