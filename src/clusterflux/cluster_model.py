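"""Steady-state reaction-diffusion model of enzyme clustering in spherical basins.

The model describes an enzyme E (isocitrate dehydrogenase in the motivating
system) confined to a droplet of radius ``R2`` sitting inside a spherical
basin of radius ``R0``.  Interaction with a partner protein condenses a
fraction of the enzyme into a central cluster of radius ``R1``.  The degree of
clustering is the excess ratio ``gamma = n1/n2`` between clustered and
dispersed enzyme copies.  Substrate ``c0`` and product ``c1`` obey coupled
linear reaction-diffusion equations,

    D lap(c0) - k n(r) c0 - alpha0 (c0 - c0*) = 0
    D lap(c1) + k n(r) c0 - beta c1          = 0

with ``n(r)`` piecewise constant over cluster / droplet / bulk.  Because the
removal rates are constant per region, each region admits a closed-form
solution in the modified-Helmholtz basis {sinh(kr)/r, cosh(kr)/r} plus a
particular constant; the global solution is assembled from regularity at the
origin, continuity of value and diffusive flux at ``R1`` and ``R2``, and the
outer boundary condition (zero flux by default).

Internal unit system: micrometres, seconds, micromolar, enzyme copies.
A catalytic efficiency supplied as uM^-1 s^-1 converts to um^3 copies^-1 s^-1
through :data:`UM_TO_COPIES_PER_UM3`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AVOGADRO",
    "UM_TO_COPIES_PER_UM3",
    "ValidationError",
    "SolverError",
    "BasinGeometry",
    "KineticParams",
    "EnzymePartition",
    "RegionPiece",
    "RadialField",
    "SteadyStateSolution",
    "PhaseAverages",
    "GammaSweepResult",
    "OnsetPlateau",
    "partition_enzymes",
    "effective_activities",
    "enzyme_density",
    "solve_steady_state",
    "evaluate_profile",
    "phase_averages",
    "total_production_rate",
    "substrate_balance_residual",
    "product_balance_residual",
    "gamma_sweep",
    "find_onset_and_plateau",
    "fit_gamma",
    "preset",
    "profile_frame",
    "sweep_frame",
    "solution_summary",
    "catalytic_efficiency_to_internal",
]

AVOGADRO = 6.02214076e23
#: copies per um^3 corresponding to a 1 uM concentration
UM_TO_COPIES_PER_UM3 = AVOGADRO * 1e-6 / 1e15

#: relative window around beta = D*kappa0^2 treated as resonant (see solver)
RESONANCE_RTOL = 1e-9


class ValidationError(ValueError):
    """Invalid model input; the message names the offending field."""


class SolverError(RuntimeError):
    """The linear system for the matching coefficients could not be solved."""


def catalytic_efficiency_to_internal(k_per_uM_per_s: float) -> float:
    """Convert k = kcat/KM from uM^-1 s^-1 to um^3 copies^-1 s^-1."""
    return float(k_per_uM_per_s) / UM_TO_COPIES_PER_UM3


def _require_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return v


def _require_nonneg(name: str, value: float) -> float:
    v = _require_finite(name, value)
    if v < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")
    return v


def _sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


@dataclass(frozen=True)
class BasinGeometry:
    """Nested spherical geometry: cluster R1 < droplet R2 < basin R0 (um)."""

    R1: float
    R2: float
    R0: float

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R0"):
            _require_finite(name, getattr(self, name))
        if not (0.0 < self.R1 < self.R2 < self.R0):
            raise ValidationError(
                f"radii must satisfy 0 < R1 < R2 < R0, got "
                f"R1={self.R1}, R2={self.R2}, R0={self.R0}"
            )

    @property
    def v_cluster(self) -> float:
        return _sphere_volume(self.R1)

    @property
    def v_drop(self) -> float:
        return _sphere_volume(self.R2)

    @property
    def v_basin(self) -> float:
        return _sphere_volume(self.R0)

    @property
    def breakpoints(self) -> tuple[float, float, float, float]:
        return (0.0, self.R1, self.R2, self.R0)


@dataclass(frozen=True)
class KineticParams:
    """First-order kinetic and transport parameters.

    k : catalytic efficiency kcat/KM, um^3 copies^-1 s^-1
    D : metabolite diffusion coefficient, um^2/s
    alpha0 : substrate relaxation rate toward homeostatic level, 1/s
    beta : product removal/decay rate, 1/s
    c0_star : homeostatic substrate concentration, uM
    N_total : total enzyme copies in the droplet
    """

    k: float
    D: float
    alpha0: float
    beta: float
    c0_star: float
    N_total: float

    def __post_init__(self) -> None:
        for name in ("k", "D", "alpha0", "beta", "c0_star", "N_total"):
            _require_nonneg(name, getattr(self, name))
        if self.D <= 0:
            raise ValidationError(f"D must be > 0, got {self.D}")


@dataclass(frozen=True)
class EnzymePartition:
    """Split of N_total enzyme copies into clustered (n1) and dispersed (n2)."""

    gamma: float
    n1: float
    n2: float

    @property
    def N_total(self) -> float:
        return self.n1 + self.n2


def partition_enzymes(N_total: float, gamma: float) -> EnzymePartition:
    """Partition enzymes between cluster and droplet at excess ratio gamma.

    n1 = N_total * gamma/(gamma+1), n2 = N_total/(gamma+1); gamma = 0 means
    no cluster, gamma -> inf puts every copy in the cluster.
    """
    N_total = _require_nonneg("N_total", N_total)
    gamma = _require_nonneg("gamma", gamma)
    n2 = N_total / (gamma + 1.0)
    n1 = N_total * gamma / (gamma + 1.0)
    return EnzymePartition(gamma=gamma, n1=n1, n2=n2)


def effective_activities(
    partition: EnzymePartition, geometry: BasinGeometry, k: float
) -> tuple[float, float]:
    """Effective volumetric activities (a_drop, a_cluster).

    a_drop spreads the dispersed copies over the droplet volume; a_cluster
    adds the clustered copies concentrated in the cluster volume on top of the
    dispersed background (the dispersed pool permeates the cluster region).
    """
    k = _require_nonneg("k", k)
    a_drop = k * partition.n2 / geometry.v_drop
    a_cluster = a_drop + k * partition.n1 / geometry.v_cluster
    return a_drop, a_cluster


@dataclass(frozen=True)
class EnzymeDensity:
    """Piecewise-constant enzyme number density (copies/um^3) per region."""

    rho_cluster: float
    rho_droplet: float
    rho_bulk: float
    geometry: BasinGeometry

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        out = np.full(r.shape, self.rho_bulk)
        out = np.where(r < self.geometry.R2, self.rho_droplet, out)
        out = np.where(r < self.geometry.R1, self.rho_cluster, out)
        return out if out.shape else float(out)

    @property
    def per_region(self) -> tuple[float, float, float]:
        return (self.rho_cluster, self.rho_droplet, self.rho_bulk)


def enzyme_density(
    partition: EnzymePartition, geometry: BasinGeometry
) -> EnzymeDensity:
    """Number density n(r): dispersed background plus clustered excess."""
    rho_drop = partition.n2 / geometry.v_drop
    rho_cluster = rho_drop + partition.n1 / geometry.v_cluster
    return EnzymeDensity(
        rho_cluster=rho_cluster,
        rho_droplet=rho_drop,
        rho_bulk=0.0,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# region basis: {sinh(kr)/r, cosh(kr)/r} for k > 0, {1, 1/r} for k = 0


def _basis(kappa: float, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float)
    if kappa == 0.0:
        with np.errstate(divide="ignore"):
            return np.ones_like(r), np.where(r > 0, 1.0 / np.maximum(r, 1e-300), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(r > 0, np.sinh(kappa * r) / np.maximum(r, 1e-300), kappa)
        f2 = np.where(r > 0, np.cosh(kappa * r) / np.maximum(r, 1e-300), np.inf)
    return f1, f2


def _dbasis(kappa: float, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float)
    if kappa == 0.0:
        with np.errstate(divide="ignore"):
            return np.zeros_like(r), np.where(
                r > 0, -1.0 / np.maximum(r, 1e-300) ** 2, -np.inf
            )
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rr = np.maximum(r, 1e-300)
        df1 = np.where(
            r > 0,
            (kappa * rr * np.cosh(kappa * rr) - np.sinh(kappa * rr)) / rr**2,
            0.0,
        )
        df2 = np.where(
            r > 0,
            (kappa * rr * np.sinh(kappa * rr) - np.cosh(kappa * rr)) / rr**2,
            -np.inf,
        )
    return df1, df2


def _basis_shell_integral(kappa: float, a: float, b: float) -> tuple[float, float]:
    """Integrals of the two basis functions against 4*pi*r^2 dr over [a, b]."""
    if kappa == 0.0:
        return 4.0 * math.pi * (b**3 - a**3) / 3.0, 2.0 * math.pi * (b**2 - a**2)

    def anti1(r: float) -> float:
        return 4.0 * math.pi * (r * math.cosh(kappa * r) / kappa - math.sinh(kappa * r) / kappa**2)

    def anti2(r: float) -> float:
        return 4.0 * math.pi * (r * math.sinh(kappa * r) / kappa - math.cosh(kappa * r) / kappa**2)

    return anti1(b) - anti1(a), anti2(b) - anti2(a)


@dataclass(frozen=True)
class RegionPiece:
    """Closed-form solution over one radial region.

    value(r) = particular + coefA*f1(kappa, r) + coefB*f2(kappa, r)
               + sum_j a_j*f1(kappa_j, r) + b_j*f2(kappa_j, r)

    where the extra ``source_modes`` [(kappa_j, a_j, b_j), ...] carry the
    particular response of the product equation to the substrate's
    homogeneous modes.
    """

    kappa: float
    coefA: float
    coefB: float
    particular: float
    source_modes: tuple[tuple[float, float, float], ...] = ()

    def value(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        f1, f2 = _basis(self.kappa, r)
        out = self.particular + self.coefA * f1 + (self.coefB * f2 if self.coefB != 0.0 else 0.0)
        for k0, a, b in self.source_modes:
            g1, g2 = _basis(k0, r)
            out = out + a * g1 + (b * g2 if b != 0.0 else 0.0)
        return out

    def deriv(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        d1, d2 = _dbasis(self.kappa, r)
        out = self.coefA * d1 + (self.coefB * d2 if self.coefB != 0.0 else np.zeros_like(d1))
        for k0, a, b in self.source_modes:
            g1, g2 = _dbasis(k0, r)
            out = out + a * g1 + (b * g2 if b != 0.0 else 0.0)
        return out

    def shell_integral(self, a: float, b: float) -> float:
        i1, i2 = _basis_shell_integral(self.kappa, a, b)
        vol = 4.0 * math.pi * (b**3 - a**3) / 3.0
        total = self.particular * vol + self.coefA * i1 + self.coefB * i2
        for k0, aa, bb in self.source_modes:
            j1, j2 = _basis_shell_integral(k0, a, b)
            total += aa * j1 + bb * j2
        return total


@dataclass(frozen=True)
class RadialField:
    """Piecewise-analytic radial concentration field over the three regions."""

    species: str
    pieces: tuple[RegionPiece, RegionPiece, RegionPiece]
    geometry: BasinGeometry

    def _region_index(self, r: np.ndarray) -> np.ndarray:
        edges = (self.geometry.R1, self.geometry.R2)
        return np.searchsorted(edges, r, side="left")

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        if np.any(r < 0) or np.any(r > self.geometry.R0 * (1 + 1e-12)):
            raise ValidationError(
                f"radius outside basin [0, {self.geometry.R0}]"
            )
        idx = self._region_index(r)
        out = np.empty_like(r)
        for i, piece in enumerate(self.pieces):
            m = idx == i
            if np.any(m):
                out[m] = piece.value(r[m])
        return float(out[0]) if scalar else out

    def deriv(self, r) -> np.ndarray:
        r = np.atleast_1d(np.asarray(r, dtype=float))
        idx = self._region_index(r)
        out = np.empty_like(r)
        for i, piece in enumerate(self.pieces):
            m = idx == i
            if np.any(m):
                out[m] = piece.deriv(r[m])
        return out

    def shell_integral(self, a: float, b: float) -> float:
        """Integral of the field against 4*pi*r^2 dr over [a, b] <= [0, R0]."""
        bp = self.geometry.breakpoints
        total = 0.0
        for i, piece in enumerate(self.pieces):
            lo, hi = max(a, bp[i]), min(b, bp[i + 1])
            if hi > lo:
                total += piece.shell_integral(lo, hi)
        return total

    def region_mean(self, a: float, b: float) -> float:
        return self.shell_integral(a, b) / (4.0 / 3.0 * math.pi * (b**3 - a**3))


@dataclass(frozen=True)
class SteadyStateSolution:
    substrate: RadialField
    product: RadialField
    geometry: BasinGeometry
    params: KineticParams
    partition: EnzymePartition
    boundary_mode: str
    substrate_mode: str

    @property
    def gamma(self) -> float:
        return self.partition.gamma


@dataclass(frozen=True)
class PhaseAverages:
    """Volume-weighted mean concentrations per phase and the droplet/bulk ratio."""

    mean_cluster: float
    mean_droplet: float
    mean_bulk: float
    droplet_bulk_ratio: float
    ratio_defined: bool = True


def _solve_species(
    geometry: BasinGeometry,
    kappas: Sequence[float],
    particulars: Sequence[float],
    source_modes: Sequence[tuple[tuple[float, float, float], ...]],
    boundary_mode: str,
    clamp_value: float,
) -> tuple[RegionPiece, RegionPiece, RegionPiece]:
    """Assemble and solve the 5x5 matching system for one species.

    Unknowns: [A1, A2, B2, A3, B3] with B1 = 0 enforced by regularity at the
    origin.  Columns are rescaled by their largest magnitude to keep the
    system well conditioned when sinh/cosh spans many orders of magnitude.
    """
    R1, R2, R0 = geometry.R1, geometry.R2, geometry.R0

    draft = [
        RegionPiece(kappas[i], 0.0, 0.0, particulars[i], tuple(source_modes[i]))
        for i in range(3)
    ]

    def part_val(i: int, r: float) -> float:
        return float(draft[i].value(r))

    def part_drv(i: int, r: float) -> float:
        return float(draft[i].deriv(r))

    M = np.zeros((5, 5))
    b = np.zeros(5)

    f1_1, _ = (float(v) for v in _basis(kappas[0], np.array(R1)))
    d1_1, _ = (float(v) for v in _dbasis(kappas[0], np.array(R1)))
    f1_2a, f2_2a = (float(v) for v in _basis(kappas[1], np.array(R1)))
    d1_2a, d2_2a = (float(v) for v in _dbasis(kappas[1], np.array(R1)))
    f1_2b, f2_2b = (float(v) for v in _basis(kappas[1], np.array(R2)))
    d1_2b, d2_2b = (float(v) for v in _dbasis(kappas[1], np.array(R2)))
    f1_3a, f2_3a = (float(v) for v in _basis(kappas[2], np.array(R2)))
    d1_3a, d2_3a = (float(v) for v in _dbasis(kappas[2], np.array(R2)))
    f1_3b, f2_3b = (float(v) for v in _basis(kappas[2], np.array(R0)))
    d1_3b, d2_3b = (float(v) for v in _dbasis(kappas[2], np.array(R0)))

    # value continuity at R1
    M[0] = [f1_1, -f1_2a, -f2_2a, 0.0, 0.0]
    b[0] = part_val(1, R1) - part_val(0, R1)
    # flux continuity at R1 (common D cancels)
    M[1] = [d1_1, -d1_2a, -d2_2a, 0.0, 0.0]
    b[1] = part_drv(1, R1) - part_drv(0, R1)
    # value continuity at R2
    M[2] = [0.0, f1_2b, f2_2b, -f1_3a, -f2_3a]
    b[2] = part_val(2, R2) - part_val(1, R2)
    # flux continuity at R2
    M[3] = [0.0, d1_2b, d2_2b, -d1_3a, -d2_3a]
    b[3] = part_drv(2, R2) - part_drv(1, R2)
    # outer boundary at R0
    if boundary_mode == "zero_flux":
        M[4] = [0.0, 0.0, 0.0, d1_3b, d2_3b]
        b[4] = -part_drv(2, R0)
    elif boundary_mode == "clamped":
        M[4] = [0.0, 0.0, 0.0, f1_3b, f2_3b]
        b[4] = clamp_value - part_val(2, R0)
    else:
        raise ValidationError(f"unknown boundary mode {boundary_mode!r}")

    scale = np.max(np.abs(M), axis=0)
    scale[scale == 0] = 1.0
    Ms = M / scale
    try:
        x = np.linalg.solve(Ms, b) / scale
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(Ms)
        raise SolverError(
            f"singular matching system (condition number {cond:.3e})"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("non-finite matching coefficients")

    A1, A2, B2, A3, B3 = x
    return (
        RegionPiece(kappas[0], A1, 0.0, particulars[0], tuple(source_modes[0])),
        RegionPiece(kappas[1], A2, B2, particulars[1], tuple(source_modes[1])),
        RegionPiece(kappas[2], A3, B3, particulars[2], tuple(source_modes[2])),
    )


def solve_steady_state(
    geometry: BasinGeometry,
    params: KineticParams,
    gamma: float,
    boundary: str = "zero_flux",
    substrate_mode: str = "full",
    clamp_substrate: float | None = None,
    clamp_product: float = 0.0,
) -> SteadyStateSolution:
    """Solve the coupled steady-state equations exactly.

    The substrate equation is linear and independent of the product, so it is
    solved first; its per-region solution then enters the product equation as
    a source whose particular response is available in closed form (constant
    term k*n*P/beta plus modes proportional to the substrate basis with
    coefficient k*n*A/(beta - D*kappa0^2)).

    ``substrate_mode='excess'`` clamps the substrate at its homeostatic level
    c0* everywhere (substrate in excess), making the product equation a pure
    constant-source problem.
    """
    if boundary not in ("zero_flux", "clamped"):
        raise ValidationError(f"unknown boundary mode {boundary!r}")
    if substrate_mode not in ("full", "excess"):
        raise ValidationError(f"unknown substrate mode {substrate_mode!r}")
    if params.beta <= 0.0 and boundary == "zero_flux":
        raise ValidationError(
            "beta must be > 0 under a zero-flux outer boundary: with no "
            "product decay and no outflux there is no steady state"
        )
    gamma = _require_nonneg("gamma", gamma)

    partition = partition_enzymes(params.N_total, gamma)
    density = enzyme_density(partition, geometry)
    rho = density.per_region
    k, D, alpha0, beta, c0s = params.k, params.D, params.alpha0, params.beta, params.c0_star

    # --- substrate ---
    if substrate_mode == "excess":
        sub_pieces = tuple(
            RegionPiece(0.0, 0.0, 0.0, c0s, ()) for _ in range(3)
        )
    else:
        kappas_s, parts_s = [], []
        for rho_i in rho:
            lam = k * rho_i + alpha0
            kappas_s.append(math.sqrt(lam / D))
            parts_s.append(alpha0 * c0s / lam if lam > 0 else 0.0)
        sub_pieces = _solve_species(
            geometry,
            kappas_s,
            parts_s,
            [(), (), ()],
            boundary,
            c0s if clamp_substrate is None else clamp_substrate,
        )

    substrate = RadialField("substrate", sub_pieces, geometry)

    # --- product ---
    beta_eff = beta
    for i, rho_i in enumerate(rho):
        if rho_i > 0 and abs(D * sub_pieces[i].kappa**2 - beta) < RESONANCE_RTOL * beta:
            beta_eff = beta * (1.0 + 1e-8)
            warnings.warn(
                "substrate screening rate resonant with beta; perturbing beta "
                "by 1e-8 relative to sidestep the degenerate particular solution",
                RuntimeWarning,
                stacklevel=2,
            )
            break

    kappa_p = math.sqrt(beta_eff / D)
    prod_parts: list[float] = []
    prod_sources: list[tuple[tuple[float, float, float], ...]] = []
    for i, rho_i in enumerate(rho):
        sp = sub_pieces[i]
        const = k * rho_i * sp.particular / beta_eff
        modes: list[tuple[float, float, float]] = []
        if rho_i > 0 and (sp.coefA != 0.0 or sp.coefB != 0.0):
            denom = beta_eff - D * sp.kappa**2
            modes.append((sp.kappa, k * rho_i * sp.coefA / denom, k * rho_i * sp.coefB / denom))
        prod_parts.append(const)
        prod_sources.append(tuple(modes))

    prod_pieces = _solve_species(
        geometry,
        [kappa_p, kappa_p, kappa_p],
        prod_parts,
        prod_sources,
        boundary,
        clamp_product,
    )
    product = RadialField("product", prod_pieces, geometry)

    return SteadyStateSolution(
        substrate=substrate,
        product=product,
        geometry=geometry,
        params=params,
        partition=partition,
        boundary_mode=boundary,
        substrate_mode=substrate_mode,
    )


def evaluate_profile(
    solution: SteadyStateSolution, radii: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (substrate, product) concentrations at the given radii (um)."""
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 0) or np.any(radii > solution.geometry.R0 * (1 + 1e-12)):
        raise ValidationError(f"radii must lie within [0, {solution.geometry.R0}]")
    return solution.substrate(radii), solution.product(radii)


def phase_averages(
    solution: SteadyStateSolution, species: str = "product"
) -> PhaseAverages:
    """Volume-weighted phase means and the droplet/bulk partition ratio.

    Means are exact shell integrals of the analytic basis; the droplet mean is
    taken over the whole droplet [0, R2] and the bulk mean over [R2, R0].
    """
    fld = solution.product if species == "product" else solution.substrate
    g = solution.geometry
    mean_cluster = fld.region_mean(0.0, g.R1)
    mean_droplet = fld.region_mean(0.0, g.R2)
    mean_bulk = fld.region_mean(g.R2, g.R0)
    if mean_bulk == 0.0:
        return PhaseAverages(mean_cluster, mean_droplet, mean_bulk, math.nan, False)
    return PhaseAverages(
        mean_cluster, mean_droplet, mean_bulk, mean_droplet / mean_bulk, True
    )


def total_production_rate(solution: SteadyStateSolution) -> float:
    """Whole-basin production integral  int k n(r) c0(r) dV  (copies-normalised)."""
    g = solution.geometry
    rho = enzyme_density(solution.partition, g).per_region
    k = solution.params.k
    bp = g.breakpoints
    return sum(
        k * rho[i] * solution.substrate.pieces[i].shell_integral(bp[i], bp[i + 1])
        for i in range(3)
    )


def product_balance_residual(solution: SteadyStateSolution) -> float:
    """Relative residual of the steady product balance beta*int c1 = int k n c0."""
    g = solution.geometry
    decay = solution.params.beta * solution.product.shell_integral(0.0, g.R0)
    prod = total_production_rate(solution)
    scale = max(abs(decay), abs(prod), 1e-300)
    return abs(decay - prod) / scale


def substrate_balance_residual(solution: SteadyStateSolution) -> float:
    """Relative residual of alpha0*int(c0* - c0) = int k n c0 (zero-flux only)."""
    g = solution.geometry
    p = solution.params
    relax = p.alpha0 * (
        p.c0_star * g.v_basin - solution.substrate.shell_integral(0.0, g.R0)
    )
    prod = total_production_rate(solution)
    scale = max(abs(relax), abs(prod), 1e-300)
    return abs(relax - prod) / scale


@dataclass(frozen=True)
class GammaSweepResult:
    """Per-gamma steady-state summaries at fixed geometry and kinetics."""

    gammas: np.ndarray
    cluster_center_c1: np.ndarray
    droplet_bulk_ratio: np.ndarray
    mean_cluster: np.ndarray
    mean_droplet: np.ndarray
    mean_bulk: np.ndarray
    production_rate: np.ndarray

    def response(self, which: str = "cluster_center") -> np.ndarray:
        if which == "cluster_center":
            return self.cluster_center_c1
        if which == "ratio":
            return self.droplet_bulk_ratio
        raise ValidationError(f"unknown sweep response {which!r}")


def gamma_sweep(
    geometry: BasinGeometry,
    params: KineticParams,
    gammas: Sequence[float],
    **solve_options,
) -> GammaSweepResult:
    """Solve the steady state for each gamma in a strictly increasing grid."""
    gammas = np.asarray(gammas, dtype=float)
    if gammas.ndim != 1 or len(gammas) == 0:
        raise ValidationError("gammas must be a non-empty 1-D sequence")
    if np.any(gammas < 0) or np.any(np.diff(gammas) <= 0):
        raise ValidationError("gammas must be strictly increasing and >= 0")

    cols = {name: [] for name in (
        "cluster_center_c1", "droplet_bulk_ratio", "mean_cluster",
        "mean_droplet", "mean_bulk", "production_rate")}
    for gma in gammas:
        try:
            sol = solve_steady_state(geometry, params, float(gma), **solve_options)
        except (ValidationError, SolverError) as exc:
            raise SolverError(f"steady-state solve failed at gamma={gma}: {exc}") from exc
        pa = phase_averages(sol)
        cols["cluster_center_c1"].append(float(sol.product(0.0)))
        cols["droplet_bulk_ratio"].append(pa.droplet_bulk_ratio)
        cols["mean_cluster"].append(pa.mean_cluster)
        cols["mean_droplet"].append(pa.mean_droplet)
        cols["mean_bulk"].append(pa.mean_bulk)
        cols["production_rate"].append(total_production_rate(sol))
    return GammaSweepResult(
        gammas=gammas, **{kk: np.asarray(vv) for kk, vv in cols.items()}
    )


def default_gamma_grid(
    g_min: float = 0.1, g_max: float = 1000.0, n: int = 60
) -> np.ndarray:
    """Log-spaced gamma grid with gamma = 0 prepended."""
    return np.concatenate([[0.0], np.geomspace(g_min, g_max, n)])


@dataclass(frozen=True)
class OnsetPlateau:
    """Gamma values at which a monotone sweep response starts rising and levels off."""

    gamma_onset: float
    gamma_plateau: float
    baseline: float
    asymptote: float
    f_on: float
    f_pl: float
    degenerate: bool = False


def find_onset_and_plateau(
    sweep: GammaSweepResult,
    f_on: float = 0.05,
    f_pl: float = 0.95,
    response: str = "cluster_center",
) -> OnsetPlateau:
    """Locate onset/plateau of a monotone sweep response by threshold crossing.

    Onset is the smallest gamma at which the response exceeds the baseline by
    f_on of the full baseline-to-asymptote rise; plateau uses f_pl.  Crossings
    are located by linear interpolation between sweep points.
    """
    if not (0.0 < f_on < f_pl < 1.0):
        raise ValidationError("thresholds must satisfy 0 < f_on < f_pl < 1")
    if len(sweep.gammas) < 4:
        raise ValidationError("need at least 4 sweep points")
    resp = sweep.response(response)
    rise = resp[-1] - resp[0]
    tol = 1e-9 * max(abs(resp[0]), abs(resp[-1]), 1e-300)
    if np.any(np.diff(resp) < -tol):
        raise ValidationError("sweep response is not monotone non-decreasing")
    if rise <= tol:
        return OnsetPlateau(
            float(sweep.gammas[0]), float(sweep.gammas[0]),
            float(resp[0]), float(resp[-1]), f_on, f_pl, degenerate=True,
        )

    def crossing(frac: float) -> float:
        level = resp[0] + frac * rise
        idx = int(np.argmax(resp >= level))
        if idx == 0:
            return float(sweep.gammas[0])
        g0, g1 = sweep.gammas[idx - 1], sweep.gammas[idx]
        r0, r1 = resp[idx - 1], resp[idx]
        if r1 == r0:
            return float(g1)
        return float(g0 + (level - r0) / (r1 - r0) * (g1 - g0))

    return OnsetPlateau(
        gamma_onset=crossing(f_on),
        gamma_plateau=crossing(f_pl),
        baseline=float(resp[0]),
        asymptote=float(resp[-1]),
        f_on=f_on,
        f_pl=f_pl,
    )


def fit_gamma(
    observed_ratio: float,
    geometry: BasinGeometry,
    params: KineticParams,
    bracket: tuple[float, float] = (0.0, 1000.0),
    **solve_options,
) -> float:
    """Invert the droplet/bulk product ratio for gamma by monotone root finding."""
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0.0 <= lo < hi):
        raise ValidationError("bracket must satisfy 0 <= lo < hi")

    def ratio_at(g: float) -> float:
        sol = solve_steady_state(geometry, params, g, **solve_options)
        return phase_averages(sol).droplet_bulk_ratio

    r_lo, r_hi = ratio_at(lo), ratio_at(hi)
    r_min, r_max = min(r_lo, r_hi), max(r_lo, r_hi)
    if not (r_min <= observed_ratio <= r_max):
        raise ValidationError(
            f"observed ratio {observed_ratio} outside achievable range "
            f"[{r_min:.6g}, {r_max:.6g}] on bracket {bracket}"
        )
    if observed_ratio == r_lo:
        return lo
    if observed_ratio == r_hi:
        return hi
    gamma = brentq(
        lambda g: ratio_at(g) - observed_ratio, lo, hi,
        xtol=1e-12, rtol=1e-12, maxiter=200,
    )
    return float(gamma)


def preset(name: str):
    """Bundled (geometry, kinetics) parameterization; see presets.yaml."""
    from .config import load_preset

    return load_preset(name)


def profile_frame(solution: SteadyStateSolution, radii: Sequence[float]):
    """Radial profile as a tidy table with columns r, c0, c1."""
    import pandas as pd

    c0, c1 = evaluate_profile(solution, radii)
    return pd.DataFrame({"r": np.asarray(radii, dtype=float), "c0": c0, "c1": c1})


def sweep_frame(sweep: GammaSweepResult):
    """Gamma sweep as a tidy table (one row per gamma)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gamma": sweep.gammas,
            "cluster_center_c1": sweep.cluster_center_c1,
            "droplet_bulk_ratio": sweep.droplet_bulk_ratio,
            "mean_cluster": sweep.mean_cluster,
            "mean_droplet": sweep.mean_droplet,
            "mean_bulk": sweep.mean_bulk,
            "production_rate": sweep.production_rate,
        }
    )


def solution_summary(solution: SteadyStateSolution) -> dict:
    """JSON-serializable record of a solve: inputs, balances, phase summary."""
    pa = phase_averages(solution)
    g = solution.geometry
    p = solution.params
    return {
        "geometry": {"R1": g.R1, "R2": g.R2, "R0": g.R0},
        "kinetics": {
            "k": p.k, "D": p.D, "alpha0": p.alpha0, "beta": p.beta,
            "c0_star": p.c0_star, "N_total": p.N_total,
        },
        "gamma": solution.gamma,
        "boundary_mode": solution.boundary_mode,
        "substrate_mode": solution.substrate_mode,
        "cluster_center_product": float(solution.product(0.0)),
        "phase_means_product": {
            "cluster": pa.mean_cluster,
            "droplet": pa.mean_droplet,
            "bulk": pa.mean_bulk,
        },
        "droplet_bulk_ratio": pa.droplet_bulk_ratio,
        "product_balance_residual": product_balance_residual(solution),
        "substrate_balance_residual": substrate_balance_residual(solution),
    }
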