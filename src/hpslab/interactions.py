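"""Residue-contact statistics and molecular-mobility (MSD) analysis.

Two beads form a contact when their minimum-image distance is below
1.2 * (sigma_i + sigma_j) / 2.  Intermolecular contacts are counted
between beads of different chains; intramolecular contacts within a
chain exclude directly bonded neighbors (|i - j| >= 2 along the chain),
which would otherwise sit inside the cutoff by construction.

Mobility is quantified by the mean square displacement of per-chain
centers of mass over multiple time origins, fitted either with the
power law MSD = K_alpha tau^alpha (sub-diffusion when alpha < 1) or the
Einstein relation MSD = 6 D tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import TYPE_CLASSES, SystemTopology

CONTACT_FACTOR = 1.2


def contact_cutoff(sigma_i: float, sigma_j: float) -> float:
    """Contact distance cutoff: 1.2 * (sigma_i + sigma_j) / 2 (nm)."""
    if sigma_i <= 0 or sigma_j <= 0:
        raise ValueError("sigma must be positive")
    return CONTACT_FACTOR * 0.5 * (sigma_i + sigma_j)


@njit(cache=True)
def _contact_pairs(pos, box, sigma, chain_id, factor):
    """All bead pairs within the contact cutoff, excluding bonded neighbors.

    Brute-force double loop over pairs (exact); returns index arrays.
    """
    n = pos.shape[0]
    cap = 64 * n
    out_i = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            rc = factor * 0.5 * (sigma[i] + sigma[j])
            if dx * dx + dy * dy + dz * dz < rc * rc:
                if cnt >= cap:
                    # grow
                    new_i = np.empty(cap * 2, dtype=np.int64)
                    new_j = np.empty(cap * 2, dtype=np.int64)
                    new_i[:cap] = out_i
                    new_j[:cap] = out_j
                    out_i = new_i
                    out_j = new_j
                    cap *= 2
                out_i[cnt] = i
                out_j[cnt] = j
                cnt += 1
    return out_i[:cnt], out_j[:cnt]


@dataclass
class ContactResult:
    """Frame-averaged contact statistics of a (multi-species) system.

    ``pair_matrices[(a, b)]`` holds the intermolecular residue-position
    contact matrix between species a and b, normalized per the molecule
    count recorded in ``normalization[(a, b)]`` (the count of the
    first-named species).  ``intra``/``inter`` are species-level totals
    under the same normalization; ``type_matrix`` aggregates all
    intermolecular contacts into the 4x4 charged/hydrophobic/polar/other
    classes.
    """

    pair_matrices: dict
    per_residue: dict
    type_matrix: np.ndarray
    intra: dict
    inter: dict
    normalization: dict
    n_frames: int
    type_classes: tuple = TYPE_CLASSES

    def total_inter(self) -> float:
        return float(sum(self.inter.values()))


def count_contacts(traj_or_frames, topology: SystemTopology | None = None,
                   normalize: bool = True) -> ContactResult:
    """Count residue-residue contacts, averaged over frames.

    Accepts a :class:`~hpslab.simulator.Trajectory` or a list of
    ``(positions, box)`` tuples plus an explicit topology.  Species-pair
    contact totals are divided by the molecule count of the first
    species of the pair (the Tau-Tau / Tau-Ab / Ab-Ab normalization
    convention) when ``normalize`` is set.
    """
    if topology is None:
        topology = traj_or_frames.topology
        frames = [(traj_or_frames.positions[f], traj_or_frames.boxes[f])
                  for f in range(traj_or_frames.n_frames)]
    elif hasattr(traj_or_frames, "positions"):
        frames = [(traj_or_frames.positions[f], traj_or_frames.boxes[f])
                  for f in range(traj_or_frames.n_frames)]
    else:
        frames = list(traj_or_frames)
    if not frames:
        raise ValueError("no frames to analyze")

    specs = topology.chain_specs
    names = [s.name for s in specs]
    spec_count = {s.name: 0 for s in specs}
    first_bead = np.searchsorted(topology.chain_id, np.arange(topology.n_chains))
    for c in range(topology.n_chains):
        spec_count[specs[int(topology.species_index[first_bead[c]])].name] += 1

    pair_keys = []
    for ai in range(len(names)):
        for bi in range(ai, len(names)):
            pair_keys.append((names[ai], names[bi]))
    pair_mat = {(a, b): np.zeros((len(specs[names.index(a)].sequence),
                                  len(specs[names.index(b)].sequence)))
                for a, b in pair_keys}
    intra = {n: 0.0 for n in names}
    inter = {k: 0.0 for k in pair_keys}
    n_types = len(TYPE_CLASSES)
    type_matrix = np.zeros((n_types, n_types))

    spi = topology.species_index
    rix = topology.residue_index
    tcode = topology.type_code
    for positions, box in frames:
        ci, cj = _contact_pairs(
            np.ascontiguousarray(positions, dtype=float),
            np.asarray(box, dtype=float),
            topology.sigma, topology.chain_id, CONTACT_FACTOR)
        same_chain = topology.chain_id[ci] == topology.chain_id[cj]
        # intramolecular: same chain, |i-j| >= 2 (bonded already excluded)
        for a, b in zip(ci[same_chain], cj[same_chain]):
            intra[names[spi[a]]] += 1.0
        ii, jj = ci[~same_chain], cj[~same_chain]
        for a, b in zip(ii, jj):
            sa, sb = int(spi[a]), int(spi[b])
            if sa <= sb:
                key = (names[sa], names[sb])
                pair_mat[key][rix[a], rix[b]] += 1.0
            else:
                key = (names[sb], names[sa])
                pair_mat[key][rix[b], rix[a]] += 1.0
            inter[key] += 1.0
            # each contact counted once, in the upper triangle of the
            # type matrix, so the grand total is conserved
            ta, tb = tcode[a], tcode[b]
            type_matrix[min(ta, tb), max(ta, tb)] += 1.0

    nf = len(frames)
    norm = {}
    for key in pair_keys:
        denom = spec_count[key[0]] if normalize else 1
        norm[key] = denom
        pair_mat[key] /= nf * denom
        inter[key] /= nf * denom
    for n in names:
        intra[n] /= nf * (spec_count[n] if normalize else 1)
    type_matrix /= nf

    per_residue = {}
    for name in names:
        seq_len = len(specs[names.index(name)].sequence)
        acc = np.zeros(seq_len)
        for (a, b), mat in pair_mat.items():
            if a == name:
                acc += mat.sum(axis=1)
            if b == name and a != name:
                acc += mat.sum(axis=0)
            elif b == name and a == name:
                acc += mat.sum(axis=0)
        per_residue[name] = acc
    return ContactResult(
        pair_matrices=pair_mat,
        per_residue=per_residue,
        type_matrix=type_matrix,
        intra=intra,
        inter=inter,
        normalization=norm,
        n_frames=nf,
    )


def aggregate_contacts(result: ContactResult, topology: SystemTopology):
    """Aggregate intermolecular residue-pair contacts into type classes.

    Returns (type_matrix, per_residue dict).  The 4x4 matrix entries are
    sums of the underlying residue-pair entries (computed from the
    un-normalized pair matrices re-scaled back by their normalization),
    so the grand total is conserved.
    """
    specs = {s.name: s for s in topology.chain_specs}
    n_types = len(TYPE_CLASSES)
    from .params import TYPE_CODES, load_residue_params

    table = load_residue_params()
    tm = np.zeros((n_types, n_types))
    for (a, b), mat in result.pair_matrices.items():
        ta = np.array([TYPE_CODES[table.lookup(aa).type_class]
                       for aa in specs[a].sequence])
        tb = np.array([TYPE_CODES[table.lookup(aa).type_class]
                       for aa in specs[b].sequence])
        raw = mat * result.normalization[(a, b)]
        for x in range(n_types):
            for y in range(n_types):
                block = raw[np.ix_(ta == x, tb == y)].sum()
                tm[min(x, y), max(x, y)] += block
    return tm, result.per_residue


def segment_errors(traj, analysis_fn, n_segments: int = 4,
                   window: tuple[float, float] | None = None):
    """(mean, min, max) of an analysis over equal trajectory segments.

    ``analysis_fn`` maps a trajectory to a scalar.  The window (default:
    the whole trajectory) is partitioned into ``n_segments`` contiguous
    segments; the spread [min, max] over segments estimates the
    statistical error, and the mean is computed over the full window.
    """
    if window is not None:
        traj = traj.window(*window)
    nf = traj.n_frames
    if nf < n_segments:
        raise ValueError(f"window has {nf} frames < {n_segments} segments")
    bounds = np.array_split(np.arange(nf), n_segments)
    values = []
    for seg in bounds:
        sub = traj.window(traj.times[seg[0]], traj.times[seg[-1]])
        values.append(analysis_fn(sub))
    mean = analysis_fn(traj)
    return float(mean), float(np.min(values)), float(np.max(values))


@dataclass
class MSDResult:
    """Center-of-mass mean square displacement versus lag time."""

    lag_times: np.ndarray  # ns, starting at 0
    msd: np.ndarray  # nm^2
    species: str | None = None
    n_chains: int = 0

    def __post_init__(self):
        if self.lag_times[0] != 0 or abs(self.msd[0]) > 1e-12:
            raise ValueError("MSD must start at lag 0 with value 0")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag grid must be increasing")
        if np.any(self.msd < -1e-12):
            raise ValueError("MSD must be non-negative")


def compute_msd(traj, species: str | None = None,
                window: tuple[float, float] | None = None,
                max_lag: float | None = None,
                origin_stride: int = 10,
                per_bead: bool = False) -> MSDResult:
    """Per-chain center-of-mass MSD averaged over chains and time origins.

    Requires unwrapped coordinates.  ``origin_stride`` sets the spacing
    (in frames) between time origins to bound their correlation;
    ``max_lag`` truncates the lag grid (ns).  With ``per_bead`` the MSD
    is computed over bead positions rather than chain centers of mass.
    """
    if not traj.unwrapped:
        raise ValueError("MSD requires unwrapped coordinates")
    if window is not None:
        traj = traj.window(*window)
    topology = traj.topology
    if species is not None:
        chains = topology.chains_of_species(species)
    else:
        chains = np.arange(topology.n_chains)
    if chains.size == 0:
        raise ValueError("no chains selected")

    if per_bead:
        mask = np.isin(topology.chain_id, chains)
        coords = traj.positions[:, mask, :]
    else:
        coords = np.empty((traj.n_frames, chains.size, 3))
        for k, c in enumerate(chains):
            sl = topology.chain_slice(c)
            m = topology.mass[sl]
            coords[:, k, :] = np.einsum(
                "fij,i->fj", traj.positions[:, sl, :], m) / m.sum()

    nf = traj.n_frames
    dt = float(traj.times[1] - traj.times[0]) if nf > 1 else 0.0
    max_lag_frames = nf - 1
    if max_lag is not None and dt > 0:
        max_lag_frames = min(max_lag_frames, int(round(max_lag / dt)))
    origins = np.arange(0, nf - 1, origin_stride)
    lags = np.arange(0, max_lag_frames + 1)
    msd = np.zeros(lags.size)
    counts = np.zeros(lags.size)
    for o in origins:
        upto = min(nf - o, max_lag_frames + 1)
        disp = coords[o:o + upto] - coords[o]
        msd[:upto] += np.sum(disp**2, axis=(1, 2))
        counts[:upto] += coords.shape[1]
    valid = counts > 0
    msd[valid] /= counts[valid]
    return MSDResult(
        lag_times=lags[valid] * dt,
        msd=msd[valid],
        species=species,
        n_chains=int(chains.size),
    )


def fit_msd_power_law(msd: MSDResult,
                      lag_range: tuple[float, float] | None = None):
    """Fit MSD = K_alpha * tau^alpha by least squares in log-log space.

    Returns (k_alpha, alpha, se_k_alpha, se_alpha).  Only positive lags
    are used; non-positive MSD values in the window are an error.
    """
    tau = msd.lag_times
    y = msd.msd
    sel = tau > 0
    if lag_range is not None:
        sel &= (tau >= lag_range[0]) & (tau <= lag_range[1])
    tau, y = tau[sel], y[sel]
    if tau.size < 5:
        raise ValueError("need at least 5 positive-lag points")
    if np.any(y <= 0):
        raise ValueError("non-positive MSD values in the fit window")
    x = np.log(tau)
    ly = np.log(y)
    n = x.size
    xm, ym = x.mean(), ly.mean()
    sxx = np.sum((x - xm) ** 2)
    alpha = float(np.sum((x - xm) * (ly - ym)) / sxx)
    logk = float(ym - alpha * xm)
    resid = ly - (logk + alpha * x)
    s2 = float(np.sum(resid**2) / max(n - 2, 1))
    se_alpha = float(np.sqrt(s2 / sxx))
    se_logk = float(np.sqrt(s2 * (1.0 / n + xm**2 / sxx)))
    k_alpha = float(np.exp(logk))
    return k_alpha, alpha, k_alpha * se_logk, se_alpha


def fit_msd_linear(msd: MSDResult,
                   lag_range: tuple[float, float] | None = None):
    """Zero-intercept fit of MSD = 6 D tau (Einstein relation).

    Returns (diffusion_coeff nm^2/ns, standard error).
    """
    tau = msd.lag_times
    y = msd.msd
    sel = tau > 0
    if lag_range is not None:
        sel &= (tau >= lag_range[0]) & (tau <= lag_range[1])
    tau, y = tau[sel], y[sel]
    if tau.size < 3:
        raise ValueError("need at least 3 points")
    x = 6.0 * tau
    sxx = float(np.sum(x * x))
    d = float(np.sum(x * y) / sxx)
    resid = y - d * x
    s2 = float(np.sum(resid**2) / max(tau.size - 1, 1))
    return d, float(np.sqrt(s2 / sxx))
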