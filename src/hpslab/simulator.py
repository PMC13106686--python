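"""Langevin-dynamics engine and the slab direct-coexistence protocol.

The protocol mirrors the standard coarse-grained workflow for direct
phase-coexistence simulations of disordered proteins:

1. chains are grown as confined random walks and placed on an evenly
   spaced grid in a cuboid box (:func:`init_slab_configuration`);
2. the system is compressed by a short NPT relaxation at low temperature
   with a Berendsen barostat (:func:`relax_compress`);
3. the box is expanded along z by a fixed factor, producing a slab in an
   elongated periodic box (:func:`expand_z`);
4. the thermostat set point is ramped linearly to the target temperature
   (:func:`temperature_ramp`) and an NVT production run follows
   (:func:`run_langevin`).

Dynamics use a BAOAB Langevin integrator (velocity-Verlet limit at zero
friction).  Positions are integrated unwrapped — the force kernels apply
the minimum-image convention to pair differences — so center-of-mass
displacement analyses need no image bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import _run_md
from .constants import COULOMB, KB, KJ_PER_MOL_NM3_TO_BAR
from .forcefield import ForceFieldConfig
from .params import ChainSpec, SystemTopology, build_system


@dataclass
class SimProtocolConfig:
    """Integration and protocol parameters.

    Times follow the conventions of the printed protocol: femtosecond
    timestep, picosecond thermostat relaxation, nanosecond ramp rate.
    """

    timestep: float = 10.0  # fs
    langevin_relaxation: float = 5.0  # ps
    production_time: float = 3000.0  # ns (3 us full-scale default)
    ramp_rate: float = 0.2  # K/ns
    relax_temperature: float = 150.0  # K
    relax_pressure: float = 1.0  # bar
    z_expansion_factor: float = 10.0
    temperatures: tuple = tuple(range(280, 370, 10))  # nine-point grid, K
    seed: int = 2024
    frame_interval: float = 0.1  # ns between recorded frames
    diag_interval: float = 0.01  # ns between kinetic/pressure samples
    neighbor_skin: float = 0.4  # nm
    barostat_tau: float = 1.0  # ps
    compressibility: float = 1.0e-4  # 1/bar

    def __post_init__(self):
        if self.timestep <= 0 or self.ramp_rate <= 0:
            raise ValueError("timestep and ramp_rate must be positive")
        if self.langevin_relaxation <= 0:
            raise ValueError("thermostat relaxation must be positive")


@dataclass
class Trajectory:
    """Time-ordered frames of bead positions with box dimensions.

    Positions are stored unwrapped when ``unwrapped`` is true (the
    default for trajectories produced by this engine).
    """

    times: np.ndarray  # (n_frames,) ns, strictly increasing
    boxes: np.ndarray  # (n_frames, 3) nm
    positions: np.ndarray  # (n_frames, n_beads, 3) nm
    topology: SystemTopology
    unwrapped: bool = True
    seed: int | None = None
    kinetic_temperature: np.ndarray | None = None  # diagnostic series, K
    pressure: np.ndarray | None = None  # diagnostic series, bar

    def __post_init__(self):
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions in trajectory")
        if self.positions.shape[0] != self.times.size:
            raise ValueError("frame count mismatch")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def final_frame(self):
        return self.positions[-1].copy(), self.boxes[-1].copy()

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        """Sub-trajectory with t_min <= t <= t_max (ns)."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if not mask.any():
            raise ValueError("empty time window")
        return replace(self, times=self.times[mask], boxes=self.boxes[mask],
                       positions=self.positions[mask])


def maxwell_velocities(topology: SystemTopology, temperature: float,
                       seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities (nm/ps) at the given temperature."""
    rng = np.random.default_rng(seed)
    sd = np.sqrt(KB * temperature / topology.mass)[:, None]
    v = rng.standard_normal((topology.n_beads, 3)) * sd
    return v


def kinetic_temperature(velocities: np.ndarray, mass: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K) from velocities (nm/ps)."""
    mv2 = float(np.sum(mass[:, None] * velocities**2))
    return mv2 / (3.0 * mass.size * KB)


def _chain_random_walk(n: int, step: float, radius: float, rng,
                       max_retries: int = 2000) -> np.ndarray:
    """Fixed-step random walk re-drawn until it fits in a sphere."""
    for _ in range(max_retries):
        steps = rng.standard_normal((n - 1, 3))
        steps *= step / np.linalg.norm(steps, axis=1)[:, None]
        walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        walk -= walk.mean(axis=0)
        if n == 1 or np.linalg.norm(walk, axis=1).max() <= radius:
            return walk
    raise RuntimeError(
        f"could not fit a {n}-bead walk inside radius {radius} nm "
        f"after {max_retries} attempts"
    )


def init_slab_configuration(
    system: SystemTopology,
    grid_dims: tuple[int, int, int],
    confinement_radius: float,
    seed: int,
    bond_length: float = 0.38,
) -> np.ndarray:
    """Initial positions: confined random-walk chains on an even grid.

    Chain centroids occupy the first ``n_chains`` points of an evenly
    distributed ``grid_dims`` grid spanning the system box; each chain
    conformation is a fixed-step (bond-length) random walk, re-drawn
    until no bead lies farther than ``confinement_radius`` from the
    chain centroid.  Deterministic for a given seed.
    """
    nx, ny, nz = grid_dims
    n_chains = system.n_chains
    if nx * ny * nz < n_chains:
        raise ValueError("grid has fewer points than chains")
    rng = np.random.default_rng(seed)
    box = system.box
    # evenly distributed grid: cell centers
    xs = (np.arange(nx) + 0.5) * box[0] / nx
    ys = (np.arange(ny) + 0.5) * box[1] / ny
    zs = (np.arange(nz) + 0.5) * box[2] / nz
    grid = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    positions = np.empty((system.n_beads, 3))
    for c in range(n_chains):
        sl = system.chain_slice(c)
        n = sl.stop - sl.start
        walk = _chain_random_walk(n, bond_length, confinement_radius, rng)
        positions[sl] = walk + grid[c]
    return positions


def minimize_energy(
    positions: np.ndarray,
    topology: SystemTopology,
    ff: ForceFieldConfig,
    box: np.ndarray | None = None,
    max_steps: int = 500,
    max_displacement: float = 0.02,
    force_tol: float = 1e2,
) -> np.ndarray:
    """Displacement-capped steepest descent to remove steric overlaps.

    Freshly grown random-walk chains contain non-bonded overlaps whose
    forces would destabilize dynamics; a few hundred capped descent
    steps bring the maximum force below ``force_tol`` (kJ/mol/nm).
    """
    from ._kernels import (_bond_forces, _build_pairs, _nonbonded_forces,
                           _pair_params)

    if box is None:
        box = topology.box
    box = np.asarray(box, dtype=float)
    pos = np.ascontiguousarray(positions, dtype=float).copy()
    kappa = 1.0 / ff.electrostatics.debye_length
    fel = COULOMB / ff.electrostatics.rel_permittivity
    rlist = max(ff.lj_cutoff, ff.elec_cutoff) + 0.3
    bond_i = np.ascontiguousarray(topology.bonds[:, 0])
    bond_j = np.ascontiguousarray(topology.bonds[:, 1])
    for _ in range(max_steps):
        forces = np.zeros_like(pos)
        pi, pj = _build_pairs(pos, box, topology.chain_id, rlist)
        sig2, lamij, qq, eshift = _pair_params(
            pi, pj, topology.sigma, topology.lambda_hps, topology.charge,
            ff.epsilon, ff.lj_cutoff, ff.shift)
        _nonbonded_forces(pos, box, pi, pj, sig2, lamij, qq, eshift,
                          ff.epsilon, ff.lj_cutoff, ff.elec_cutoff,
                          kappa, fel, ff.shift, forces)
        _bond_forces(pos, box, bond_i, bond_j, ff.bond_k, ff.bond_r0, forces)
        fmax = np.linalg.norm(forces, axis=1).max()
        if fmax < force_tol:
            break
        step = forces * (max_displacement / max(fmax, 1e-30))
        norms = np.linalg.norm(step, axis=1)
        big = norms > max_displacement
        if big.any():
            step[big] *= (max_displacement / norms[big])[:, None]
        pos += step
    return pos


def _integrate(
    positions: np.ndarray,
    box: np.ndarray,
    topology: SystemTopology,
    ff: ForceFieldConfig,
    t_start: float,
    t_end: float,
    duration: float,  # ns
    config: SimProtocolConfig,
    seed: int,
    velocities: np.ndarray | None = None,
    npt: bool = False,
    pressure: float = 1.0,
) -> Trajectory:
    dt_ps = config.timestep * 1e-3
    nsteps = max(1, int(round(duration * 1000.0 / dt_ps)))
    frame_stride = max(1, int(round(config.frame_interval * 1000.0 / dt_ps)))
    diag_stride = max(1, int(round(config.diag_interval * 1000.0 / dt_ps)))
    n_frames = nsteps // frame_stride
    n_diag = nsteps // diag_stride
    if n_frames < 1:
        frame_stride = nsteps
        n_frames = 1

    pos = np.ascontiguousarray(positions, dtype=float).copy()
    box = np.asarray(box, dtype=float).copy()
    if velocities is None:
        velocities = maxwell_velocities(topology, max(t_start, 1.0), seed + 7)
    vel = np.ascontiguousarray(velocities, dtype=float).copy()

    out_pos = np.empty((n_frames, topology.n_beads, 3))
    out_box = np.empty((n_frames, 3))
    out_kin = np.empty(max(n_diag, 1))
    out_press = np.empty(max(n_diag, 1))

    kappa = 1.0 / ff.electrostatics.debye_length
    fel = COULOMB / ff.electrostatics.rel_permittivity
    status, bad_step, nframe, ndiag = _run_md(
        pos, vel, box, topology.mass, topology.sigma, topology.lambda_hps,
        topology.charge, topology.chain_id,
        np.ascontiguousarray(topology.bonds[:, 0]),
        np.ascontiguousarray(topology.bonds[:, 1]),
        ff.bond_k, ff.bond_r0,
        ff.epsilon, ff.lj_cutoff, ff.elec_cutoff, kappa, fel, ff.shift,
        dt_ps, config.langevin_relaxation, t_start, t_end, KB,
        nsteps, int(seed) % (2**31 - 1), config.neighbor_skin,
        npt, pressure, config.barostat_tau, config.compressibility,
        KJ_PER_MOL_NM3_TO_BAR,
        frame_stride, out_pos, out_box,
        diag_stride, out_kin, out_press)
    if status != 0:
        raise RuntimeError(f"integration blew up at step {bad_step}")
    times = (np.arange(1, nframe + 1) * frame_stride) * dt_ps * 1e-3  # ns
    traj = Trajectory(
        times=times,
        boxes=out_box[:nframe],
        positions=out_pos[:nframe],
        topology=topology,
        unwrapped=True,
        seed=seed,
        kinetic_temperature=out_kin[:ndiag].copy(),
        pressure=out_press[:ndiag].copy(),
    )
    # stash final state for protocol chaining
    traj.final_positions = pos
    traj.final_velocities = vel
    traj.final_box = box
    return traj


def run_langevin(
    positions: np.ndarray,
    topology: SystemTopology,
    ff: ForceFieldConfig,
    temperature: float,
    duration: float,
    config: SimProtocolConfig | None = None,
    box: np.ndarray | None = None,
    seed: int | None = None,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """NVT Langevin production run of ``duration`` ns at ``temperature`` K."""
    if config is None:
        config = SimProtocolConfig()
    if box is None:
        box = topology.box
    if seed is None:
        seed = config.seed
    return _integrate(positions, box, topology, ff, temperature, temperature,
                      duration, config, seed, velocities=velocities)


def relax_compress(
    positions: np.ndarray,
    topology: SystemTopology,
    ff: ForceFieldConfig,
    temperature: float = 150.0,
    pressure: float = 1.0,
    duration: float = 2.0,
    config: SimProtocolConfig | None = None,
    box: np.ndarray | None = None,
    seed: int | None = None,
):
    """NPT relaxation with a Berendsen barostat; returns (positions, box, traj).

    Starting from a sparse configuration the barostat compresses the box;
    an error is raised if the run fails to reduce the volume or stretches
    any bond beyond twice its equilibrium length.
    """
    if config is None:
        config = SimProtocolConfig()
    if box is None:
        box = topology.box
    if seed is None:
        seed = config.seed
    traj = _integrate(positions, box, topology, ff, temperature, temperature,
                      duration, config, seed, npt=True, pressure=pressure)
    final_pos, final_box = traj.final_positions, traj.final_box
    if len(topology.bonds):
        d = final_pos[topology.bonds[:, 1]] - final_pos[topology.bonds[:, 0]]
        d -= final_box * np.rint(d / final_box)
        max_bond = float(np.linalg.norm(d, axis=1).max())
        if max_bond > 2.0 * ff.bond_r0:
            raise RuntimeError(
                f"bond stretched to {max_bond:.3f} nm during relaxation")
    return final_pos, final_box, traj


def slab_center_z(positions: np.ndarray, box_z: float,
                  mass: np.ndarray | None = None) -> float:
    """Center of mass along z of a periodic system via the circular mean."""
    theta = positions[:, 2] / box_z * 2.0 * np.pi
    w = mass if mass is not None else np.ones(positions.shape[0])
    zc = math.atan2(np.average(np.sin(theta), weights=w),
                    np.average(np.cos(theta), weights=w))
    return (zc % (2.0 * np.pi)) / (2.0 * np.pi) * box_z


def make_chains_whole(positions: np.ndarray, box: np.ndarray,
                      topology: SystemTopology) -> np.ndarray:
    """Remove periodic jumps within each chain (walk along the bonds)."""
    box = np.asarray(box, dtype=float)
    pos = positions.copy()
    steps = pos[1:] - pos[:-1]
    steps -= box * np.rint(steps / box)
    # accumulate per chain: restart the walk at each chain head
    out = pos.copy()
    for c in range(topology.n_chains):
        sl = topology.chain_slice(c)
        if sl.stop - sl.start > 1:
            out[sl.start + 1:sl.stop] = out[sl.start] + np.cumsum(
                steps[sl.start:sl.stop - 1], axis=0)
    return out


def expand_z(positions: np.ndarray, box: np.ndarray, factor: float = 10.0,
             mass: np.ndarray | None = None,
             topology: SystemTopology | None = None):
    """Expand the box along z, re-centering the slab at the box mid-plane.

    The slab is shifted so its (periodic) center of mass sits at the new
    mid-plane and otherwise preserved rigidly: intra-slab distances are
    unchanged.  With a topology, chains are kept whole across the old
    periodic z-boundary (a molecule must never be cut when the boundary
    becomes real vacuum); without one, coordinates are unwrapped bead by
    bead around the slab center.
    """
    if factor <= 1:
        raise ValueError("expansion factor must exceed 1")
    box = np.asarray(box, dtype=float)
    new_box = box.copy()
    new_box[2] = box[2] * factor
    pos = positions.copy()
    pos -= box * np.floor(pos / box)  # wrap into old box
    zc = slab_center_z(pos, box[2], mass)
    if topology is not None:
        pos = make_chains_whole(pos, box, topology)
        # shift whole chains by the minimum-image offset of their center
        for c in range(topology.n_chains):
            sl = topology.chain_slice(c)
            m = topology.mass[sl] if mass is not None else None
            zcm = float(np.average(pos[sl, 2], weights=m))
            dz = zcm - zc
            dz -= box[2] * np.rint(dz / box[2])
            pos[sl, 2] += (dz + new_box[2] / 2.0) - zcm
    else:
        dz = pos[:, 2] - zc
        dz -= box[2] * np.rint(dz / box[2])
        pos[:, 2] = dz + new_box[2] / 2.0
    return pos, new_box


def temperature_ramp(
    positions: np.ndarray,
    topology: SystemTopology,
    ff: ForceFieldConfig,
    t_start: float,
    t_target: float,
    rate: float | None = None,
    config: SimProtocolConfig | None = None,
    box: np.ndarray | None = None,
    seed: int | None = None,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """NVT run whose thermostat set point moves linearly at ``rate`` K/ns."""
    if config is None:
        config = SimProtocolConfig()
    if rate is None:
        rate = config.ramp_rate
    if t_target == t_start:
        raise ValueError("t_target must differ from t_start")
    if box is None:
        box = topology.box
    if seed is None:
        seed = config.seed
    duration = abs(t_target - t_start) / rate  # ns
    return _integrate(positions, box, topology, ff, t_start, t_target,
                      duration, config, seed, velocities=velocities)


def extract_dense_phase(
    positions: np.ndarray,
    box: np.ndarray,
    topology: SystemTopology,
    n_bins: int = 100,
    buffer_widths: float = 0.0,
):
    """Carve the dense slab out into a cubic box of matching density.

    A z-density profile of the frame is fitted with the two-interface
    tanh form; chains whose centroids fall inside the dense interval
    (half-width reduced by ``buffer_widths`` interfacial widths) are kept
    and re-boxed into a cube whose volume preserves the fitted
    dense-phase density.  Raises if no dense phase is detected.
    """
    from .phase import density_profile_frame, fit_density_tanh

    profile = density_profile_frame(positions, box, topology, n_bins=n_bins)
    fit = fit_density_tanh(profile)
    if not fit.converged or fit.degenerate:
        raise RuntimeError("no dense phase detected in the final frame")

    box = np.asarray(box, dtype=float)
    pos = positions.copy()
    pos -= box * np.floor(pos / box)
    zc = slab_center_z(pos, box[2], topology.mass)
    half = max(fit.z_half_width - buffer_widths * fit.width, 0.25 * fit.z_half_width)

    keep = []
    for c in range(topology.n_chains):
        sl = topology.chain_slice(c)
        m = topology.mass[sl]
        # chain centroid z relative to the slab center, minimum image
        dz = pos[sl, 2] - zc
        dz -= box[2] * np.rint(dz / box[2])
        zcm = float(np.average(dz, weights=m))
        if abs(zcm) <= half:
            keep.append(c)
    if not keep:
        raise RuntimeError("dense interval contains no chains")

    # rebuild topology with kept chains, preserving species identities
    first_bead = np.searchsorted(topology.chain_id, np.arange(topology.n_chains))
    counts: dict[int, int] = {}
    for c in keep:
        si = int(topology.species_index[first_bead[c]])
        counts[si] = counts.get(si, 0) + 1
    kept_mass = 0.0
    bead_idx = []
    for c in keep:
        sl = topology.chain_slice(c)
        bead_idx.extend(range(sl.start, sl.stop))
        kept_mass += float(topology.mass[sl].sum())
    # cubic box preserving the fitted dense density (mg/cm^3 -> amu/nm^3)
    from .constants import AMU_PER_NM3_TO_MG_PER_CM3

    volume = kept_mass * AMU_PER_NM3_TO_MG_PER_CM3 / fit.rho_dense
    side = volume ** (1.0 / 3.0)
    new_specs = []
    order = []
    for si, spec in enumerate(topology.chain_specs):
        if si in counts:
            new_specs.append(ChainSpec(spec.name, spec.sequence, counts[si]))
            order.extend([c for c in keep
                          if int(topology.species_index[first_bead[c]]) == si])
    new_topology = build_system(new_specs, (side, side, side))

    # positions: chains grouped by species in the new bead order
    new_pos = np.empty((new_topology.n_beads, 3))
    cursor = 0
    for c in order:
        sl = topology.chain_slice(c)
        n = sl.stop - sl.start
        chain_pos = pos[sl].copy()
        # make the chain whole around its first bead, then center on slab
        ref = chain_pos[0]
        d = chain_pos - ref
        d -= box * np.rint(d / box)
        chain_pos = ref + d
        chain_pos[:, 2] -= zc
        chain_pos[:, 2] -= box[2] * np.rint(chain_pos[:, 2] / box[2])
        new_pos[cursor:cursor + n] = chain_pos
        cursor += n
    # shift into the cube
    new_pos[:, 0] -= new_pos[:, 0].mean() - side / 2.0
    new_pos[:, 1] -= new_pos[:, 1].mean() - side / 2.0
    new_pos[:, 2] += side / 2.0
    return new_topology, new_pos
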