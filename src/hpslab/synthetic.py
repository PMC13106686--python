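"""Seeded generators for every fixture the analysis stack consumes.

Each generator emulates the statistical structure its downstream fit
assumes — slab frames whose binned z-profile follows the two-phase tanh
form, Brownian and exact power-law displacement data, binodal point sets
drawn from the critical scaling law, FRAP recovery curves and paired
HSQC peak lists — and satisfies the round-trip property: at zero noise
the corresponding fit recovers the generator parameters to numerical
precision.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .constants import AMU_PER_NM3_TO_MG_PER_CM3
from .interactions import MSDResult
from .params import ChainSpec, SystemTopology, build_system, packaged_sequence
from .phase import DensityProfile
from .simulator import Trajectory, _chain_random_walk
from .wetlab import FrapCurve, PeakRecord


def toy_sequences() -> dict[str, str]:
    """Fixture sequences: the two study proteins plus designed toys.

    Includes Tau 2N4R (441 aa) and Abeta40 (40 aa) from the packaged
    FASTA files, the K18 four-repeat Tau fragment, and two designed
    50-residue polyampholytes: a charge-blocky diblock (strong phase
    separator) and a strictly alternating sequence (weak).
    """
    tau = packaged_sequence("tau_2n4r")
    return {
        "tau_2n4r": tau,
        "abeta40": packaged_sequence("abeta40"),
        "tau_k18": tau[243:372],  # Q244-E372 four-repeat fragment
        "polyampholyte_diblock": "E" * 25 + "K" * 25,
        "polyampholyte_alternating": "EK" * 25,
    }


def gen_tanh_profile(rho_dense, rho_dilute, half_width, width,
                     box=(15.0, 15.0, 150.0), n_bins=100,
                     noise=0.0, seed=0) -> DensityProfile:
    """Synthetic density profile following the two-interface tanh form.

    Multiplicative Gaussian noise of relative scale ``noise`` is applied
    per bin when requested.
    """
    box = np.asarray(box, dtype=float)
    z = (np.arange(n_bins) + 0.5) * box[2] / n_bins
    zc = box[2] / 2.0
    rho = rho_dilute + 0.5 * (rho_dense - rho_dilute) * (
        1.0 - np.tanh((np.abs(z - zc) - half_width) / width))
    if noise > 0:
        rng = np.random.default_rng(seed)
        rho = rho * (1.0 + noise * rng.standard_normal(n_bins))
        rho = np.maximum(rho, 0.0)
    bin_volume = box[0] * box[1] * (box[2] / n_bins)
    total_mass = float(np.sum(rho) * bin_volume / AMU_PER_NM3_TO_MG_PER_CM3)
    return DensityProfile(z_centers=z, density=rho, box=box,
                          total_mass=total_mass)


def gen_slab_frame(n_chains, chain_length, dense_density, dilute_density,
                   interface_width, box, seed, sequence: str | None = None,
                   walk_radius: float | None = None):
    """Slab frame whose expected z-profile follows the tanh form.

    Chain centroids are drawn from the normalized tanh density; chains
    are compact confined random walks, so the realized binned profile
    matches the requested parameters up to the centroid-to-bead smearing
    (kept small against the interface width).  Densities in mg/cm^3.

    Returns (SystemTopology, positions).  Raises if the requested
    densities are incompatible with the box volume.
    """
    if dense_density <= dilute_density:
        raise ValueError("dense_density must exceed dilute_density")
    box = np.asarray(box, dtype=float)
    if sequence is None:
        sequence = ("GS" * chain_length)[:chain_length]
    spec = ChainSpec("slab", sequence, n_chains)
    topology = build_system([spec], box)
    total_mass_conc = topology.total_mass() * AMU_PER_NM3_TO_MG_PER_CM3  # mg/cm^3 * nm^3
    area = box[0] * box[1]
    # mass balance fixes the dense-slab half width
    half_width = (total_mass_conc / area - dilute_density * box[2]) / (
        2.0 * (dense_density - dilute_density))
    if half_width <= 2.0 * interface_width or 2.0 * half_width > 0.9 * box[2]:
        raise ValueError(
            "requested densities are incompatible with the box volume "
            f"(implied dense half-width {half_width:.2f} nm)")

    rng = np.random.default_rng(seed)
    # inverse-CDF sampling of centroid z from the tanh profile
    zc = box[2] / 2.0
    zg = np.linspace(0.0, box[2], 4001)
    pdf = dilute_density + 0.5 * (dense_density - dilute_density) * (
        1.0 - np.tanh((np.abs(zg - zc) - half_width) / interface_width))
    cdf = np.cumsum(pdf)
    cdf = (cdf - cdf[0]) / (cdf[-1] - cdf[0])
    # stratified inverse-CDF sampling: the empirical centroid distribution
    # tracks the target profile to O(1/n) instead of O(1/sqrt(n))
    u = rng.permutation((np.arange(n_chains) + 0.5) / n_chains)
    z_centroids = np.interp(u, cdf, zg)

    if walk_radius is None:
        # compact but feasible: comfortably above the ideal-walk radius
        walk_radius = max(0.9, 0.38 * np.sqrt(chain_length) * 0.45)
    positions = np.empty((topology.n_beads, 3))
    for c in range(n_chains):
        sl = topology.chain_slice(c)
        walk = _chain_random_walk(chain_length, 0.38, walk_radius, rng)
        center = np.array([rng.random() * box[0], rng.random() * box[1],
                           z_centroids[c]])
        positions[sl] = walk + center
    return topology, positions


def gen_brownian_traj(n_particles, diffusion_coeff, dt, n_steps, seed,
                      box_size: float = 1000.0) -> Trajectory:
    """Brownian trajectory: Gaussian increments of variance 2 D dt per axis.

    ``dt`` in ns, ``diffusion_coeff`` in nm^2/ns.  Particles are
    independent single-bead chains; coordinates are unwrapped.
    """
    if diffusion_coeff < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    spec = ChainSpec("tracer", "G", n_particles)
    topology = build_system([spec], (box_size,) * 3)
    rng = np.random.default_rng(seed)
    start = rng.random((1, n_particles, 3)) * box_size
    if diffusion_coeff > 0:
        steps = rng.standard_normal((n_steps, n_particles, 3)) * np.sqrt(
            2.0 * diffusion_coeff * dt)
    else:
        steps = np.zeros((n_steps, n_particles, 3))
    positions = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    boxes = np.tile(np.array([box_size] * 3), (n_steps + 1, 1))
    times = np.arange(n_steps + 1, dtype=float) * dt
    if times.size > 1 and times[1] <= times[0]:
        raise ValueError("dt must be positive")
    return Trajectory(times=times, boxes=boxes, positions=positions,
                      topology=topology, unwrapped=True, seed=seed)


def gen_power_law_msd(k_alpha, alpha, lags, noise=0.0, seed=0) -> MSDResult:
    """Exact (optionally noisy) power-law MSD curve, MSD = K tau^alpha."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lags must be non-negative")
    if lags[0] != 0:
        lags = np.concatenate([[0.0], lags])
    msd = np.zeros_like(lags)
    pos = lags > 0
    msd[pos] = k_alpha * lags[pos] ** alpha
    if noise > 0:
        rng = np.random.default_rng(seed)
        msd[pos] *= 1.0 + noise * rng.standard_normal(pos.sum())
        msd = np.maximum(msd, 1e-30)
        msd[0] = 0.0
    return MSDResult(lag_times=lags, msd=msd)


def gen_binodal(t_c, amplitude, beta, temperatures, noise=0.0, seed=0,
                rho_mid: float = 300.0):
    """Binodal point set drawn from the critical scaling law.

    Returns (temperatures, rho_dense, rho_dilute) with
    rho_dense - rho_dilute = A (T_C - T)^beta and midline ``rho_mid``.
    Relative Gaussian noise is applied to the gap when requested.
    """
    t = np.asarray(temperatures, dtype=float)
    if np.any(t >= t_c):
        raise ValueError("all temperatures must lie below t_c")
    gap = amplitude * (t_c - t) ** beta
    if noise > 0:
        rng = np.random.default_rng(seed)
        gap = gap * (1.0 + noise * rng.standard_normal(t.size))
        gap = np.maximum(gap, 1e-9)
    rho_dense = rho_mid + gap / 2.0
    rho_dilute = np.maximum(rho_mid - gap / 2.0, 0.0)
    # keep the generated gap exact even after the floor at zero
    rho_dense = rho_dilute + gap
    return t, rho_dense, rho_dilute


def gen_frap_curve(bleach_floor=0.2, amplitude=0.6, tau=5.0,
                   times=None, n_prebleach=5, noise=0.0, seed=0) -> FrapCurve:
    """Synthetic FRAP recording with a single-exponential recovery.

    Pre-bleach samples sit at 1; the post-bleach signal follows
    I(t) = I0 + M (1 - exp(-t/tau)).  Additive Gaussian noise of scale
    ``noise`` is applied to both ROIs' raw intensities.
    """
    if times is None:
        times = np.arange(0.0, 60.0, 1.0)
    times = np.asarray(times, dtype=float)
    n_post = times.size - n_prebleach
    if n_post < 10:
        raise ValueError("need at least 10 post-bleach samples")
    signal = np.ones(times.size)
    t_post = times[n_prebleach:] - times[n_prebleach]
    signal[n_prebleach:] = bleach_floor + amplitude * (
        1.0 - np.exp(-t_post / tau))
    reference = np.ones(times.size)
    if noise > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise * rng.standard_normal(times.size)
        reference = reference + noise * rng.standard_normal(times.size)
    return FrapCurve(times=times, bleached=signal, reference=reference,
                     bleach_index=n_prebleach)


def gen_peak_tables(n_residues, shift_scale=0.02, intensity_factor=1.3,
                    n_missing=0, seed=0):
    """Paired HSQC peak lists (reference, perturbed).

    The perturbed spectrum scales intensities by ``intensity_factor``
    and shifts peaks by Gaussian perturbations of scale ``shift_scale``
    ppm (1H; 15N scaled by 5); ``n_missing`` peaks are dropped from the
    perturbed list to exercise the absent-peak bookkeeping.
    """
    rng = np.random.default_rng(seed)
    reference, perturbed = [], []
    missing = set(rng.choice(n_residues, size=n_missing, replace=False)
                  ) if n_missing else set()
    for i in range(n_residues):
        dh = 8.0 + 0.5 * rng.standard_normal()
        dn = 118.0 + 3.0 * rng.standard_normal()
        inten = 1.0 + 0.2 * rng.random()
        reference.append(PeakRecord(i + 1, dh, dn, inten))
        if i in missing:
            continue
        perturbed.append(PeakRecord(
            i + 1,
            dh + shift_scale * rng.standard_normal(),
            dn + 5.0 * shift_scale * rng.standard_normal(),
            inten * intensity_factor))
    return reference, perturbed


def gen_random_frame(n_beads, box, min_separation, seed,
                     charged_fraction: float = 0.3):
    """Random multi-chain frame with a minimum pair separation.

    Used as input for force-consistency checks; beads are grouped into
    short chains with a mix of charged and neutral residues.  Placement
    is rejection-sampled so no minimum-image pair distance falls below
    ``min_separation``.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    chain_len = 5
    n_chains = max(1, n_beads // chain_len)
    n_beads = n_chains * chain_len
    letters = np.array(list("GSAV"))
    charged = np.array(list("KEDR"))
    seqs = []
    for _ in range(n_chains):
        aa = [str(rng.choice(charged)) if rng.random() < charged_fraction
              else str(rng.choice(letters)) for _ in range(chain_len)]
        seqs.append("".join(aa))
    specs = [ChainSpec(f"rand{i}", s, 1) for i, s in enumerate(seqs)]
    topology = build_system(specs, box)

    positions = np.empty((n_beads, 3))
    placed = 0
    attempts = 0
    while placed < n_beads:
        cand = rng.random(3) * box
        ok = True
        for j in range(placed):
            d = cand - positions[j]
            d -= box * np.rint(d / box)
            if np.dot(d, d) < min_separation**2:
                ok = False
                break
        if ok:
            positions[placed] = cand
            placed += 1
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("could not place beads at the requested separation")
    return topology, positions
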