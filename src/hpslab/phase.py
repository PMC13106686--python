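"""Density profiles, binodals and critical-temperature analysis.

A slab direct-coexistence run yields a z-density profile with a dense
plateau and a dilute background.  The profile is fitted with the
symmetric two-interface hyperbolic-tangent form

    rho(z) = rho_dil + (rho_den - rho_dil)/2 * [1 - tanh((|z - zc| - z0)/w)]

which, after re-centering the slab at the box mid-plane, is equivalent to
the single-interface tanh form fitted per interface: z0 is the distance
from the slab center to the interface midpoint and w the interfacial
width.  Coexistence densities over a temperature grid are then fitted
with the critical scaling law

    rho_dense - rho_dilute = A * (T_C - T)^beta,   beta = 0.365

(3D Heisenberg universality class) to estimate the upper critical
solution temperature T_C.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as student_t

from .constants import AMU_PER_NM3_TO_MG_PER_CM3
from .params import SystemTopology

HEISENBERG_BETA = 0.365


@dataclass
class DensityProfile:
    """Binned mass-density profile along z (mg/cm^3 per bin)."""

    z_centers: np.ndarray  # nm
    density: np.ndarray  # mg/cm^3
    box: np.ndarray  # (3,) nm
    species: str | None = None
    n_frames: int = 1
    total_mass: float = 0.0  # amu of the profiled species

    def __post_init__(self):
        if np.any(self.density < -1e-12):
            raise ValueError("densities must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.z_centers[1] - self.z_centers[0])

    def integrated_mass(self) -> float:
        """Mass implied by the profile (amu); equals total_mass exactly."""
        bin_volume = self.box[0] * self.box[1] * self.bin_width
        return float(np.sum(self.density) * bin_volume / AMU_PER_NM3_TO_MG_PER_CM3)


@dataclass
class TanhFitResult:
    """Two-phase tanh fit of a slab density profile."""

    rho_dense: float  # mg/cm^3
    rho_dilute: float  # mg/cm^3
    z_half_width: float  # z0: slab-center -> interface midpoint distance, nm
    width: float  # w: interfacial width, nm
    center: float  # zc, nm
    ci_rho_dense: tuple[float, float] = (np.nan, np.nan)
    ci_rho_dilute: tuple[float, float] = (np.nan, np.nan)
    ci_z_half_width: tuple[float, float] = (np.nan, np.nan)
    ci_width: tuple[float, float] = (np.nan, np.nan)
    residual_norm: float = np.nan
    converged: bool = True
    degenerate: bool = False

    @property
    def density_ratio(self) -> float:
        return self.rho_dense / max(self.rho_dilute, 1e-12)


@dataclass
class CriticalFitResult:
    """Critical-scaling fit of the binodal: delta_rho = A (T_C - T)^beta."""

    t_c: float  # K
    amplitude: float
    beta: float
    ci_t_c: tuple[float, float]
    ci_amplitude: tuple[float, float]
    converged: bool


@dataclass
class PhaseDiagram:
    """Per-temperature coexistence points and the fitted critical point."""

    temperatures: np.ndarray  # contributing temperatures, K
    rho_dense: np.ndarray
    rho_dilute: np.ndarray
    fits: list  # TanhFitResult per contributing temperature
    critical: CriticalFitResult | None


def _profile_single_frame(positions, box, mass_w, n_bins, recenter=True):
    """Mass histogram along z, slab re-centered at the box mid-plane."""
    from .simulator import slab_center_z

    lz = box[2]
    z = positions[:, 2] % lz
    if recenter:
        zc = slab_center_z(positions, lz, mass_w)
        z = (z - zc + lz / 2.0) % lz
    hist, edges = np.histogram(z, bins=n_bins, range=(0.0, lz), weights=mass_w)
    return hist, edges


def density_profile_frame(
    positions: np.ndarray,
    box: np.ndarray,
    topology: SystemTopology,
    species: str | None = None,
    n_bins: int = 50,
    recenter: bool = True,
) -> DensityProfile:
    """Density profile of a single frame (see :func:`density_profile`)."""
    box = np.asarray(box, dtype=float)
    mask = topology.species_mask(species) if species else np.ones(
        topology.n_beads, dtype=bool)
    if not mask.any():
        raise ValueError("empty species selection")
    hist, edges = _profile_single_frame(
        positions[mask], box, topology.mass[mask], n_bins, recenter)
    bin_volume = box[0] * box[1] * (edges[1] - edges[0])
    density = hist / bin_volume * AMU_PER_NM3_TO_MG_PER_CM3
    return DensityProfile(
        z_centers=0.5 * (edges[1:] + edges[:-1]),
        density=density,
        box=box,
        species=species,
        n_frames=1,
        total_mass=float(topology.mass[mask].sum()),
    )


def density_profile(
    traj,
    species: str | None = None,
    n_bins: int = 50,
    window: tuple[float, float] | None = None,
    recenter: bool = True,
) -> DensityProfile:
    """Frame-averaged z-density profile of a trajectory (mg/cm^3).

    Each frame is re-centered on the (periodic) slab center of mass
    before binning, so interfaces line up across frames.  The integral of
    the averaged profile equals the profiled species mass per box
    cross-section exactly (mass conservation).
    """
    if n_bins < 20:
        raise ValueError("use at least 20 bins")
    topology = traj.topology
    mask = topology.species_mask(species) if species else np.ones(
        topology.n_beads, dtype=bool)
    if not mask.any():
        raise ValueError("empty species selection")
    if window is not None:
        traj = traj.window(*window)
    mass_w = topology.mass[mask]
    acc = np.zeros(n_bins)
    box = traj.boxes[-1]
    for f in range(traj.n_frames):
        hist, edges = _profile_single_frame(
            traj.positions[f][mask], traj.boxes[f], mass_w, n_bins, recenter)
        acc += hist
    acc /= traj.n_frames
    bin_volume = box[0] * box[1] * (box[2] / n_bins)
    density = acc / bin_volume * AMU_PER_NM3_TO_MG_PER_CM3
    z_centers = (np.arange(n_bins) + 0.5) * box[2] / n_bins
    return DensityProfile(
        z_centers=z_centers,
        density=density,
        box=np.asarray(box, dtype=float),
        species=species,
        n_frames=traj.n_frames,
        total_mass=float(mass_w.sum()),
    )


def _tanh_model(z, rho_den, rho_dil, z0, w, zc):
    return rho_dil + 0.5 * (rho_den - rho_dil) * (
        1.0 - np.tanh((np.abs(z - zc) - z0) / w))


def fit_density_tanh(profile: DensityProfile,
                     ratio_threshold: float = 3.0) -> TanhFitResult:
    """Nonlinear least-squares fit of the two-interface tanh profile.

    95% confidence intervals come from the parameter covariance.  The
    result is flagged ``degenerate`` when the profile shows no usable
    two-phase structure: fitted dense/dilute ratio below
    ``ratio_threshold`` or confidence intervals that do not exclude
    rho_dense = rho_dilute.
    """
    z = profile.z_centers
    rho = profile.density
    if z.size < 20:
        raise ValueError("profile needs at least 4x more bins than parameters")
    lz = profile.box[2]
    rho_max = float(rho.max())
    rho_min = float(max(rho.min(), 0.0))
    if rho_max <= 0:
        return TanhFitResult(0.0, 0.0, 0.0, 1.0, lz / 2, converged=False,
                             degenerate=True)
    # initial guesses: plateau from the top decile, background from the bottom
    p0_den = float(np.mean(rho[rho > 0.8 * rho_max])) if np.any(rho > 0.8 * rho_max) else rho_max
    p0_dil = float(np.mean(rho[rho < rho_min + 0.2 * (rho_max - rho_min) + 1e-30]))
    above = rho > 0.5 * (p0_den + p0_dil)
    p0_z0 = max(0.5 * np.sum(above) * profile.bin_width, profile.bin_width)
    p0 = [p0_den, p0_dil, p0_z0, 2.0 * profile.bin_width, lz / 2.0]
    bounds = ([0.0, 0.0, 0.0, 1e-3, 0.0], [np.inf, np.inf, lz, lz, lz])
    dof = max(z.size - 5, 1)
    try:
        popt, pcov = curve_fit(_tanh_model, z, rho, p0=p0, bounds=bounds,
                               maxfev=20000)
        # Profile noise is multiplicative (dense bins fluctuate more).
        # Estimate the relative noise scale from bins with appreciable
        # density, then recompute the covariance with per-bin GLS weights
        # so the CIs are honest; near-empty wings get a sigma floor and
        # cannot distort the fit.
        model = _tanh_model(z, *popt)
        mask = model > 0.1 * popt[0]
        if mask.sum() >= 10:
            rel = (rho[mask] - model[mask]) / model[mask]
            c = float(np.sqrt(np.sum(rel**2) / max(int(mask.sum()) - 5, 1)))
            if c > 1e-12:
                sigma_w = c * np.maximum(model, 0.05 * popt[0])
                popt, pcov = curve_fit(
                    _tanh_model, z, rho, p0=popt, bounds=bounds,
                    sigma=sigma_w, absolute_sigma=True, maxfev=20000)
                dof = max(int(mask.sum()) - 5, 1)
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(np.diag(pcov)))
    except RuntimeError:
        return TanhFitResult(rho_max, rho_min, 0.0, 1.0, lz / 2,
                             converged=False, degenerate=True)
    rho_den, rho_dil, z0, w, zc = popt
    if rho_den < rho_dil:  # enforce the dense >= dilute convention
        rho_den, rho_dil = rho_dil, rho_den
    se = np.sqrt(np.abs(np.diag(pcov)))
    tq = student_t.ppf(0.975, dof)
    ci = [(p - tq * s, p + tq * s) for p, s in zip(popt, se)]
    resid = rho - _tanh_model(z, *popt)
    ratio = rho_den / max(rho_dil, 1e-12)
    # equality excluded when the density difference is > tq joint SE
    diff_se = np.sqrt(se[0]**2 + se[1]**2)
    degenerate = (ratio < ratio_threshold) or (
        (rho_den - rho_dil) < tq * diff_se)
    # identifiability guard: if the fitted dense slab fills (nearly) the
    # whole box there is no dilute region and rho_dilute is meaningless
    if 2.0 * z0 + 2.0 * w > 0.9 * lz:
        degenerate = True
    return TanhFitResult(
        rho_dense=float(rho_den),
        rho_dilute=float(rho_dil),
        z_half_width=float(z0),
        width=float(w),
        center=float(zc),
        ci_rho_dense=ci[0],
        ci_rho_dilute=ci[1],
        ci_z_half_width=ci[2],
        ci_width=ci[3],
        residual_norm=float(np.linalg.norm(resid)),
        converged=bool(converged),
        degenerate=bool(degenerate),
    )


def fit_critical_point(
    temperatures,
    rho_dense,
    rho_dilute,
    beta: float = HEISENBERG_BETA,
) -> CriticalFitResult:
    """Fit the binodal width to A (T_C - T)^beta with beta frozen.

    In a UCST system the density gap closes as T rises toward T_C from
    below, so the scaling argument is (T_C - T).  95% confidence
    intervals for T_C and A come from the fit covariance.
    """
    t = np.asarray(temperatures, dtype=float)
    dense = np.asarray(rho_dense, dtype=float)
    dil = np.asarray(rho_dilute, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 coexistence points")
    gap = dense - dil
    if np.any(gap <= 0):
        raise ValueError("coexistence points must have rho_dense > rho_dilute")

    def model(tt, t_c, a):
        return a * np.power(np.maximum(t_c - tt, 1e-12), beta)

    t_max = float(t.max())
    # linearized start: gap^(1/beta) is linear in T
    y = gap ** (1.0 / beta)
    slope, intercept = np.polyfit(t, y, 1)
    t_c0 = -intercept / slope if slope < 0 else t_max + 10.0
    t_c0 = max(t_c0, t_max + 1e-3)
    a0 = float(np.mean(gap / np.maximum(t_c0 - t, 1e-9) ** beta))
    try:
        # relative weighting: binodal gaps carry multiplicative error
        popt, pcov = curve_fit(
            model, t, gap, p0=[t_c0, a0],
            bounds=([t_max + 1e-9, 0.0], [np.inf, np.inf]),
            sigma=gap, absolute_sigma=False,
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        return CriticalFitResult(np.nan, np.nan, beta, (np.nan, np.nan),
                                 (np.nan, np.nan), converged=False)
    se = np.sqrt(np.abs(np.diag(pcov)))
    tq = student_t.ppf(0.975, max(t.size - 2, 1))
    return CriticalFitResult(
        t_c=float(popt[0]),
        amplitude=float(popt[1]),
        beta=beta,
        ci_t_c=(float(popt[0] - tq * se[0]), float(popt[0] + tq * se[0])),
        ci_amplitude=(float(popt[1] - tq * se[1]), float(popt[1] + tq * se[1])),
        converged=bool(converged),
    )


def build_phase_diagram(
    temperatures,
    profiles,
    beta: float = HEISENBERG_BETA,
    ratio_threshold: float = 3.0,
) -> PhaseDiagram:
    """Fit each temperature's profile and the critical point.

    Only temperatures whose tanh fit detects coexistence (non-degenerate)
    contribute binodal points; T_C requires at least three of them.
    """
    contrib_t, dense, dil, fits = [], [], [], []
    for t, profile in zip(temperatures, profiles):
        fit = fit_density_tanh(profile, ratio_threshold=ratio_threshold)
        if fit.converged and not fit.degenerate:
            contrib_t.append(t)
            dense.append(fit.rho_dense)
            dil.append(fit.rho_dilute)
            fits.append(fit)
    critical = None
    if len(contrib_t) >= 3:
        critical = fit_critical_point(contrib_t, dense, dil, beta=beta)
    return PhaseDiagram(
        temperatures=np.array(contrib_t),
        rho_dense=np.array(dense),
        rho_dilute=np.array(dil),
        fits=fits,
        critical=critical,
    )


def saturation_concentration(
    profiles: list[DensityProfile],
    dense_interval: tuple[float, float] | None = None,
    buffer_widths: float = 3.0,
):
    """Mean dilute-phase concentration and its spread across profiles.

    For each profile the dilute region is the complement of the fitted
    dense slab extended by ``buffer_widths`` interfacial widths (or an
    explicit ``dense_interval`` in distance-from-center coordinates); the
    species density is averaged over that region.  Returns
    (mean, sd) across profiles (sd = 0 for a single profile).
    """
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    values = []
    for profile in profiles:
        z = profile.z_centers
        if dense_interval is not None:
            lo, hi = dense_interval
            dilute_bins = (z < lo) | (z > hi)
        else:
            fit = fit_density_tanh(profile)
            if fit.degenerate or not fit.converged:
                # single phase: the bulk is the dilute phase
                values.append(float(profile.density.mean()))
                continue
            half = fit.z_half_width + buffer_widths * fit.width
            dist = np.abs(z - fit.center)
            dist = np.minimum(dist, profile.box[2] - dist)
            dilute_bins = dist > half
        if not dilute_bins.any():
            raise ValueError("dilute region is empty")
        values.append(float(profile.density[dilute_bins].mean()))
    values = np.asarray(values)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd
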