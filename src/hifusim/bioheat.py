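"""Pennes bioheat solver and CEM43 thermal-dose accumulation.

The temperature field obeys

    ρ c_p ∂T/∂t = ∇·(k ∇T) + Q − w_b c_b (T − T_a)

with volumetric acoustic heating Q [W/m³] and a distributed perfusion sink
proportional to the local blood perfusion rate w_b [kg/(m³ s)].  The solver
is explicit forward-time centered-space (FTCS) on a uniform voxel grid with
the domain faces clamped to arterial temperature; a stability guard refuses
unstable time steps and suggests a safe one.

Thermal dose uses the cumulative-equivalent-minutes convention:
CEM43 = Σ R^(43 − T) Δt with R = 0.5 above 43 °C and 0.25 below; tissue is
conventionally considered ablated at ≥ 240 equivalent minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermalTissue",
    "HeatSource",
    "DoseField",
    "heat_source_from_intensity",
    "stable_dt",
    "pennes_solve",
    "pennes_step",
    "cem43_increment",
    "cem43_accumulate",
    "ablated_volume",
    "ABLATION_THRESHOLD_MIN",
]

#: Conventional coagulative-ablation threshold, equivalent minutes at 43 °C.
ABLATION_THRESHOLD_MIN = 240.0

R_ABOVE = 0.5  # dose-rate base for T >= 43 °C
R_BELOW = 0.25  # dose-rate base for T < 43 °C


class StabilityError(ValueError):
    """Raised when the requested explicit time step is unstable."""


@dataclass
class ThermalTissue:
    """Per-voxel (or scalar) thermal properties.

    k [W/(m K)], rho [kg/m³], c_p [J/(kg K)], w_b [kg/(m³ s)],
    c_b [J/(kg K)], T_a [°C].
    """

    k: np.ndarray | float = 0.56
    rho: np.ndarray | float = 1050.0
    c_p: np.ndarray | float = 3600.0
    w_b: np.ndarray | float = 0.0
    c_b: float = 3617.0
    T_a: float = 37.0

    def __post_init__(self) -> None:
        for name in ("rho", "c_p"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        # k = 0 (no conduction) is a legitimate degenerate case, useful for
        # verifying the perfusion term in isolation
        if np.any(np.asarray(self.k) < 0):
            raise ValueError("thermal conductivity must be non-negative")
        if np.any(np.asarray(self.w_b) < 0):
            raise ValueError("perfusion rate w_b must be non-negative")
        if self.c_b <= 0:
            raise ValueError("blood specific heat must be positive")
        if not (30.0 <= self.T_a <= 40.0):
            raise ValueError("arterial temperature outside the physiologic range")


@dataclass
class HeatSource:
    """Volumetric power deposition Q [W/m³] on the thermal grid."""

    Q: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.Q < 0):
            raise ValueError("power deposition must be non-negative")


@dataclass
class DoseField:
    """Cumulative CEM43 [min] per voxel; non-decreasing over a simulation."""

    cem43: np.ndarray
    threshold_min: float = ABLATION_THRESHOLD_MIN

    def __post_init__(self) -> None:
        if np.any(self.cem43 < 0):
            raise ValueError("thermal dose cannot be negative")


def heat_source_from_intensity(
    I_w_cm2: np.ndarray,
    absorption_np_m: np.ndarray | float,
) -> HeatSource:
    """Absorption heating Q = 2 α_abs I, converting I from W/cm² to W/m².

    ``absorption_np_m`` is the absorption coefficient (attenuation ×
    absorption fraction, dB/cm already converted to Np/m) per voxel or
    scalar; it must broadcast against the intensity grid.
    """
    I = np.asarray(I_w_cm2, dtype=float)
    a = np.asarray(absorption_np_m, dtype=float)
    if a.ndim and a.shape != I.shape:
        raise ValueError("absorption grid does not match the intensity grid")
    return HeatSource(Q=2.0 * a * I * 1e4)


def stable_dt(tissue: ThermalTissue, voxel_mm: float, safety: float = 0.9) -> float:
    """Largest stable explicit step: dt ≤ ρ c_p / (6 k/dx² + w_b c_b)."""
    dx = voxel_mm * 1e-3
    denom = 6.0 * np.asarray(tissue.k) / dx**2 + np.asarray(tissue.w_b) * tissue.c_b
    return float(safety * np.min(np.asarray(tissue.rho) * np.asarray(tissue.c_p) / denom))


def _laplacian(T: np.ndarray, dx_m: float) -> np.ndarray:
    lap = np.zeros_like(T)
    core = lap[1:-1, 1:-1, 1:-1]
    core += T[2:, 1:-1, 1:-1] + T[:-2, 1:-1, 1:-1]
    core += T[1:-1, 2:, 1:-1] + T[1:-1, :-2, 1:-1]
    core += T[1:-1, 1:-1, 2:] + T[1:-1, 1:-1, :-2]
    core -= 6.0 * T[1:-1, 1:-1, 1:-1]
    return lap / dx_m**2


def pennes_step(
    T: np.ndarray,
    Q: np.ndarray | float,
    tissue: ThermalTissue,
    voxel_mm: float,
    dt_s: float,
) -> np.ndarray:
    """One explicit FTCS step; domain faces clamped at T_a."""
    dx = voxel_mm * 1e-3
    rhs = (
        np.asarray(tissue.k) * _laplacian(T, dx)
        + Q
        - np.asarray(tissue.w_b) * tissue.c_b * (T - tissue.T_a)
    )
    Tn = T + dt_s * rhs / (np.asarray(tissue.rho) * np.asarray(tissue.c_p))
    for ax in range(3):
        idx0 = [slice(None)] * 3
        idx1 = [slice(None)] * 3
        idx0[ax], idx1[ax] = 0, -1
        Tn[tuple(idx0)] = tissue.T_a
        Tn[tuple(idx1)] = tissue.T_a
    return Tn


def pennes_solve(
    T0: np.ndarray | float,
    source: HeatSource | None,
    tissue: ThermalTissue,
    voxel_mm: float,
    dt_s: float,
    duration_s: float,
    shape: tuple[int, int, int] | None = None,
    record_stride: int = 1,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integrate the Pennes equation for ``duration_s``.

    Returns ``(times, snapshots)``: snapshot temperatures every
    ``record_stride`` steps (always including the initial state).  Raises
    :class:`StabilityError` with a suggested dt if the step is unstable.
    """
    dt_max = stable_dt(tissue, voxel_mm, safety=1.0)
    if dt_s > dt_max:
        raise StabilityError(
            f"dt = {dt_s:g} s unstable for this grid; use dt <= {0.9 * dt_max:.4g} s"
        )
    if np.isscalar(T0):
        if shape is None:
            raise ValueError("shape required for a scalar initial temperature")
        T = np.full(shape, float(T0))
    else:
        T = np.array(T0, dtype=float)
    Q = source.Q if source is not None else 0.0

    n_steps = int(round(duration_s / dt_s))
    times = [0.0]
    snaps = [T.copy()]
    for n in range(1, n_steps + 1):
        T = pennes_step(T, Q, tissue, voxel_mm, dt_s)
        if n % record_stride == 0 or n == n_steps:
            times.append(n * dt_s)
            snaps.append(T.copy())
    return np.asarray(times), snaps


def cem43_increment(T: np.ndarray, dt_s: float) -> np.ndarray:
    """CEM43 accrued in ``dt_s`` seconds at temperature grid ``T`` [min]."""
    R = np.where(np.asarray(T) >= 43.0, R_ABOVE, R_BELOW)
    return R ** (43.0 - np.asarray(T)) * (dt_s / 60.0)


def cem43_accumulate(
    snapshots: list[np.ndarray],
    dt_s: float | np.ndarray,
    dose: DoseField | None = None,
) -> DoseField:
    """Accumulate dose over a temperature history with uniform spacing.

    ``dt_s`` may be a scalar (uniform spacing) or per-interval array; the
    temperature of each interval is the snapshot at its start.  Additive
    over concatenated histories.
    """
    if dose is None:
        dose = DoseField(cem43=np.zeros_like(np.asarray(snapshots[0], dtype=float)))
    steps = np.atleast_1d(np.asarray(dt_s, dtype=float))
    n_int = len(snapshots) - 1
    if len(steps) == 1:
        steps = np.full(n_int, steps[0])
    elif len(steps) != n_int:
        raise ValueError(
            "non-uniform history: supply one dt per snapshot interval"
        )
    acc = dose.cem43.copy()
    for T, dt in zip(snapshots[:-1], steps):
        acc += cem43_increment(T, dt)
    return DoseField(cem43=acc, threshold_min=dose.threshold_min)


def ablated_volume(
    dose: DoseField | np.ndarray,
    voxel_volume_mm3: float,
    threshold_min: float | None = None,
) -> float:
    """Volume [cm³] with CEM43 ≥ threshold (inclusive)."""
    if isinstance(dose, DoseField):
        grid = dose.cem43
        thr = threshold_min if threshold_min is not None else dose.threshold_min
    else:
        grid = np.asarray(dose)
        thr = threshold_min if threshold_min is not None else ABLATION_THRESHOLD_MIN
    if thr <= 0:
        raise ValueError("ablation threshold must be positive")
    return float(np.count_nonzero(grid >= thr) * voxel_volume_mm3 * 1e-3)
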