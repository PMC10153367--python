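"""Finite-difference solver for the Pennes bioheat equation.

The temperature field T(x, t) in liver tissue obeys

    rho * Cp_eff(T) * dT/dt = div(lambda grad T)
                              + omega_eff * rho_b * c_b * (T_b - T) + Q_appl

with
* an evaporation-effective heat capacity Cp_eff(T) (Gaussian enthalpy bump
  around 100 C representing tissue water vaporization),
* a perfusion sink whose coefficient omega_eff rises sub-lethally with
  temperature, collapses with accumulated Arrhenius damage, and is elevated
  on the segmented-vessel subdomain (heat-sink effect), and
* the applicator heat source Q_appl (see :mod:`mwaplan.source`).

Time integration is backward (implicit) Euler on a 7-point Laplacian with all
nonlinear coefficients lagged one step; the linear system is solved matrix-free
with Jacobi-preconditioned conjugate gradients. Dirichlet T_b is imposed on a
ghost layer outside the domain faces; an insulated (zero-flux) mode and
diffusion/perfusion toggles exist for verification against closed-form
solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from . import constants
from .volumes import LabelVolume, VoxelGrid


@dataclass(frozen=True)
class TissueProperties:
    """Thermal, perfusion and damage-kinetics constants (SI; temperatures in C)."""

    rho: float = constants.LIVER_DENSITY                  # kg/m^3
    cp_baseline: float = constants.LIVER_SPECIFIC_HEAT    # J/(kg K)
    conductivity: float = constants.LIVER_CONDUCTIVITY    # W/(m K)
    omega_b: float = constants.LIVER_PERFUSION            # 1/s
    rho_b: float = constants.BLOOD_DENSITY                # kg/m^3
    c_b: float = constants.BLOOD_SPECIFIC_HEAT            # J/(kg K)
    t_b: float = constants.BODY_TEMPERATURE_C             # C
    water_content: float = constants.LIVER_WATER_CONTENT  # mass fraction
    latent_heat: float = constants.LATENT_HEAT_VAPORIZATION  # J/kg
    evap_center: float = constants.EVAPORATION_CENTER_C   # C
    evap_width: float = constants.EVAPORATION_WIDTH_C     # C
    omega_vessel: float = constants.VESSEL_PERFUSION      # 1/s
    valvano_slope: float = constants.VALVANO_SLOPE        # 1/K
    arrhenius_a: float = constants.ARRHENIUS_A            # 1/s
    arrhenius_ea: float = constants.ARRHENIUS_EA          # J/mol
    gas_constant: float = constants.GAS_CONSTANT          # J/(mol K)
    # Some published Pennes variants write the sink as omega_b*rho_b*(T_b - T)
    # without the blood specific heat; that form is dimensionally inconsistent,
    # so c_b is included by default. This flag sets c_b = 1 numerically to
    # reproduce the c_b-less variant for comparison.
    omit_sink_blood_heat: bool = False

    def __post_init__(self):
        positive = (
            "rho", "cp_baseline", "conductivity", "omega_b", "rho_b", "c_b",
            "water_content", "latent_heat", "evap_width", "omega_vessel",
            "arrhenius_a", "arrhenius_ea", "gas_constant",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (30.0 <= self.t_b <= 42.0):
            raise ValueError("t_b must lie in [30, 42] C")
        if self.omega_vessel < self.omega_b:
            raise ValueError("omega_vessel must be >= omega_b")

    @property
    def sink_c_b(self) -> float:
        """Blood specific heat actually used in the perfusion sink."""
        return 1.0 if self.omit_sink_blood_heat else self.c_b

    def replace(self, **kwargs) -> "TissueProperties":
        return replace(self, **kwargs)


@dataclass
class TemperatureField:
    """Temperature snapshot (C) on a grid at a simulation time (s)."""

    grid: VoxelGrid
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite temperature values")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the implicit-Euler bioheat solver."""

    dt: float = 1.0                    # s
    snapshot_interval: float = 30.0    # s
    boundary: str = "dirichlet"        # "dirichlet" (T_b ghost layer) | "insulated"
    enable_diffusion: bool = True
    enable_perfusion: bool = True
    track_damage: bool = True
    cg_tol: float = 1e-7
    cg_maxiter: int = 500

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.snapshot_interval < self.dt:
            raise ValueError("snapshot_interval must be >= dt")
        if self.boundary not in ("dirichlet", "insulated"):
            raise ValueError("boundary must be 'dirichlet' or 'insulated'")


def perfusion_rate(
    temperature: np.ndarray,
    omega_damage: np.ndarray | float,
    props: TissueProperties,
    vessel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Effective perfusion coefficient omega_eff (1/s) per voxel.

    omega_eff = omega * max(0, 1 + s*(T - T_b)) * exp(-Omega), where omega is
    omega_b on tissue and omega_vessel on segmented-vessel voxels: sub-lethal
    hyperaemia rises linearly with temperature and perfusion ceases as
    coagulation damage Omega accumulates.
    """
    t = np.asarray(temperature, dtype=float)
    omega = np.full(t.shape, props.omega_b)
    if vessel_mask is not None:
        omega[np.asarray(vessel_mask, dtype=bool)] = props.omega_vessel
    thermal = np.maximum(0.0, 1.0 + props.valvano_slope * (t - props.t_b))
    return omega * thermal * np.exp(-np.asarray(omega_damage, dtype=float))


def effective_cp(temperature: np.ndarray | float, props: TissueProperties) -> np.ndarray:
    """Evaporation-effective specific heat Cp_eff(T), J/(kg K).

    The latent heat of the tissue water content is spread as a normalized
    Gaussian bump centered at ``evap_center`` so that the bump integrates
    over temperature to ``water_content * latent_heat``.
    """
    t = np.asarray(temperature, dtype=float)
    w = props.evap_width
    bump = np.exp(-0.5 * ((t - props.evap_center) / w) ** 2) / (w * np.sqrt(2 * np.pi))
    return props.cp_baseline + props.water_content * props.latent_heat * bump


def enthalpy_density(temperature: np.ndarray | float, props: TissueProperties) -> np.ndarray:
    """Volumetric enthalpy rho * int_0^T Cp_eff dT' (J/m^3); for energy audits."""
    t = np.asarray(temperature, dtype=float)
    bump_cdf = ndtr((t - props.evap_center) / props.evap_width)
    return props.rho * (
        props.cp_baseline * t + props.water_content * props.latent_heat * bump_cdf
    )


def damage_rate(temperature: np.ndarray | float, props: TissueProperties) -> np.ndarray:
    """Arrhenius damage rate dOmega/dt = A * exp(-Ea / (R T_K)) at T in C."""
    t_k = np.asarray(temperature, dtype=float) + 273.15
    return props.arrhenius_a * np.exp(-props.arrhenius_ea / (props.gas_constant * t_k))


class UniformSource:
    """Spatially uniform volumetric heat source (verification mode)."""

    def __init__(self, power_density: float):
        self.q = float(power_density)  # W/m^3

    def power_density(self, temperature: np.ndarray) -> np.ndarray | float:
        return self.q

    def total_power(self, voxel_volume_m3: float, n_voxels: int) -> float:
        return self.q * voxel_volume_m3 * n_voxels


try:  # fused-stencil fast path; the numpy implementation below is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _apply_operator_jit(diag, v, lam, hx2i, hy2i, hz2i, insulated, out):  # pragma: no cover
        nx, ny, nz = v.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    c = v[i, j, k]
                    if insulated:
                        xm = v[i - 1, j, k] if i > 0 else c
                        xp = v[i + 1, j, k] if i < nx - 1 else c
                        ym = v[i, j - 1, k] if j > 0 else c
                        yp = v[i, j + 1, k] if j < ny - 1 else c
                        zm = v[i, j, k - 1] if k > 0 else c
                        zp = v[i, j, k + 1] if k < nz - 1 else c
                    else:
                        xm = v[i - 1, j, k] if i > 0 else 0.0
                        xp = v[i + 1, j, k] if i < nx - 1 else 0.0
                        ym = v[i, j - 1, k] if j > 0 else 0.0
                        yp = v[i, j + 1, k] if j < ny - 1 else 0.0
                        zm = v[i, j, k - 1] if k > 0 else 0.0
                        zp = v[i, j, k + 1] if k < nz - 1 else 0.0
                    lap = (
                        (xm - 2.0 * c + xp) * hx2i
                        + (ym - 2.0 * c + yp) * hy2i
                        + (zm - 2.0 * c + zp) * hz2i
                    )
                    out[i, j, k] = diag[i, j, k] * c - lam * lap

    @_njit(cache=True)
    def _pcg_jit(diag, lam, hx2i, hy2i, hz2i, insulated, b, x, inv_diag, tol, maxiter):  # pragma: no cover
        nx, ny, nz = b.shape
        r = np.empty_like(b)
        _apply_operator_jit(diag, x, lam, hx2i, hy2i, hz2i, insulated, r)
        bnorm = 0.0
        rz = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    r[i, j, k] = b[i, j, k] - r[i, j, k]
                    bnorm += b[i, j, k] * b[i, j, k]
        if bnorm == 0.0:
            x[:] = 0.0
            return 0
        z = r * inv_diag
        p = z.copy()
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    rz += r[i, j, k] * z[i, j, k]
        ap = np.empty_like(b)
        tol2 = tol * tol * bnorm
        for it in range(1, maxiter + 1):
            _apply_operator_jit(diag, p, lam, hx2i, hy2i, hz2i, insulated, ap)
            pap = 0.0
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        pap += p[i, j, k] * ap[i, j, k]
            alpha = rz / pap
            rnorm2 = 0.0
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        x[i, j, k] += alpha * p[i, j, k]
                        r[i, j, k] -= alpha * ap[i, j, k]
                        rnorm2 += r[i, j, k] * r[i, j, k]
            if rnorm2 <= tol2:
                return it
            rz_new = 0.0
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        z[i, j, k] = r[i, j, k] * inv_diag[i, j, k]
                        rz_new += r[i, j, k] * z[i, j, k]
            beta = rz_new / rz
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        p[i, j, k] = z[i, j, k] + beta * p[i, j, k]
            rz = rz_new
        return -1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _laplacian(v: np.ndarray, spacing_m: tuple[float, float, float], boundary: str) -> np.ndarray:
    mode = "edge" if boundary == "insulated" else "constant"
    p = np.pad(v, 1, mode=mode)
    hx2, hy2, hz2 = (s * s for s in spacing_m)
    out = (p[2:, 1:-1, 1:-1] - 2.0 * v + p[:-2, 1:-1, 1:-1]) / hx2
    out += (p[1:-1, 2:, 1:-1] - 2.0 * v + p[1:-1, :-2, 1:-1]) / hy2
    out += (p[1:-1, 1:-1, 2:] - 2.0 * v + p[1:-1, 1:-1, :-2]) / hz2
    return out


def _pcg(apply_a, b, x0, inv_diag, tol, maxiter):
    """Jacobi-preconditioned conjugate gradients on 3D arrays."""
    x = x0.copy()
    r = b - apply_a(x)
    z = r * inv_diag
    p = z.copy()
    rz = float(np.vdot(r, z).real)
    bnorm = float(np.linalg.norm(b.ravel()))
    if bnorm == 0.0:
        return np.zeros_like(b), 0
    for it in range(1, maxiter + 1):
        ap = apply_a(p)
        alpha = rz / float(np.vdot(p, ap).real)
        x += alpha * p
        r -= alpha * ap
        if float(np.linalg.norm(r.ravel())) <= tol * bnorm:
            return x, it
        z = r * inv_diag
        rz_new = float(np.vdot(r, z).real)
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise RuntimeError(f"CG failed to converge in {maxiter} iterations")


@dataclass
class SimulationResult:
    """Output bundle of one ablation simulation."""

    snapshots: list[TemperatureField]
    peak: TemperatureField
    damage_omega: np.ndarray
    grid: VoxelGrid
    cg_iterations: list[int] = field(default_factory=list)

    @property
    def final(self) -> TemperatureField:
        return self.snapshots[-1]


def simulate(
    grid: VoxelGrid,
    duration: float,
    props: TissueProperties,
    source,
    config: SolverConfig = SolverConfig(),
    initial: TemperatureField | float | None = None,
    vessel_mask: np.ndarray | LabelVolume | None = None,
) -> SimulationResult:
    """Advance the bioheat equation for ``duration`` seconds on ``grid``.

    ``source`` is any object with ``power_density(T) -> W/m^3`` (an
    :class:`mwaplan.source.ApplicatorSource`, a :class:`UniformSource`, or
    ``None`` for no heating). The initial field defaults to uniform T_b.
    Arrhenius damage is co-integrated (trapezoidal) so the perfusion sink can
    respond to coagulation; the accumulated field is returned.
    """
    if isinstance(vessel_mask, LabelVolume):
        vessel_mask = vessel_mask.voxels
    if initial is None:
        t_now = np.full(grid.shape, props.t_b, dtype=float)
    elif isinstance(initial, TemperatureField):
        if initial.grid.shape != grid.shape:
            raise ValueError("initial field grid mismatch")
        t_now = initial.values.astype(float).copy()
    else:
        t_now = np.full(grid.shape, float(initial), dtype=float)

    dt = config.dt
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(duration, 1.0):
        n_steps = int(np.ceil(duration / dt))
    spacing_m = tuple(s * 1e-3 for s in grid.spacing)
    lam = props.conductivity
    lap_diag = 2.0 * lam * sum(1.0 / (s * s) for s in spacing_m)
    sink_cb = props.sink_c_b

    omega_dmg = np.zeros(grid.shape, dtype=float)
    rate_now = damage_rate(t_now, props) if config.track_damage else None
    peak = t_now.copy()
    snapshots = [TemperatureField(grid=grid, values=t_now.copy(), time=0.0)]
    cg_iters: list[int] = []
    next_snap = config.snapshot_interval

    v = t_now - props.t_b  # deviation from body temperature (Dirichlet datum)
    for step in range(1, n_steps + 1):
        step_dt = dt if step * dt <= duration + 1e-12 else duration - (step - 1) * dt
        cp = effective_cp(t_now, props)
        a = props.rho * cp / step_dt  # J/(m^3 K s)
        if config.enable_perfusion:
            s = perfusion_rate(t_now, omega_dmg, props, vessel_mask) * props.rho_b * sink_cb
        else:
            s = 0.0
        q = 0.0 if source is None else source.power_density(t_now)
        diag = a + s
        rhs = a * v + q

        if config.enable_diffusion:
            diag_arr = np.ascontiguousarray(
                np.broadcast_to(np.asarray(diag, dtype=float), grid.shape)
            )
            inv_diag = np.ascontiguousarray(
                np.broadcast_to(1.0 / (diag + lap_diag), grid.shape)
            )
            if _HAVE_NUMBA:
                hx2i, hy2i, hz2i = (1.0 / (sm * sm) for sm in spacing_m)
                insulated = config.boundary == "insulated"
                rhs_c = np.ascontiguousarray(np.broadcast_to(rhs, grid.shape))
                it = _pcg_jit(
                    diag_arr, lam, hx2i, hy2i, hz2i, insulated,
                    rhs_c, v, inv_diag, config.cg_tol, config.cg_maxiter,
                )
                if it < 0:
                    raise RuntimeError(
                        f"CG failed to converge in {config.cg_maxiter} iterations"
                    )
            else:
                def apply_a(x):
                    return diag_arr * x - lam * _laplacian(x, spacing_m, config.boundary)

                v, it = _pcg(apply_a, rhs, v, inv_diag, config.cg_tol, config.cg_maxiter)
        else:
            v = rhs / diag
            it = 0
        cg_iters.append(it)

        t_now = v + props.t_b
        if not np.isfinite(t_now).all():
            raise RuntimeError(
                f"non-finite temperature at t = {step * dt:.1f} s "
                f"(max |T| = {np.nanmax(np.abs(t_now))})"
            )
        np.maximum(peak, t_now, out=peak)
        t_sim = min(step * dt, duration)
        if config.track_damage:
            rate_new = damage_rate(t_now, props)
            omega_dmg += 0.5 * (rate_now + rate_new) * step_dt
            rate_now = rate_new
        if t_sim + 1e-9 >= next_snap or step == n_steps:
            snapshots.append(TemperatureField(grid=grid, values=t_now.copy(), time=t_sim))
            while next_snap <= t_sim + 1e-9:
                next_snap += config.snapshot_interval

    return SimulationResult(
        snapshots=snapshots,
        peak=TemperatureField(grid=grid, values=peak, time=duration),
        damage_omega=omega_dmg,
        grid=grid,
        cg_iterations=cg_iters,
    )
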