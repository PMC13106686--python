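"""Plain-text import/export: trajectories, profiles, contacts, curves.

Trajectories are written as extended XYZ (one block per frame, a
``Lattice=...`` comment line carrying the box and time) with a JSON
sidecar recording the topology summary, seed and flags — both are
human-readable text. Analysis products go to CSV/TSV with ``#`` header
metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .interactions import ContactResult, MSDResult
from .params import ChainSpec, SystemTopology, build_system
from .phase import DensityProfile, PhaseDiagram
from .simulator import Trajectory
from .wetlab import FrapCurve


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as extended XYZ plus a ``<path>.json`` sidecar."""
    path = Path(path)
    top = traj.topology
    letters = top.letters
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            box = traj.boxes[f]
            fh.write(f"{top.n_beads}\n")
            fh.write(
                f'Lattice="{box[0]} 0 0 0 {box[1]} 0 0 0 {box[2]}" '
                f"Time={traj.times[f]} Properties=species:S:1:pos:R:3\n")
            frame = traj.positions[f]
            for i in range(top.n_beads):
                fh.write(f"{letters[i]} {frame[i, 0]:.8f} "
                         f"{frame[i, 1]:.8f} {frame[i, 2]:.8f}\n")
    sidecar = {
        "n_frames": int(traj.n_frames),
        "n_beads": int(top.n_beads),
        "unwrapped": bool(traj.unwrapped),
        "seed": traj.seed,
        "chain_specs": [
            {"name": s.name, "sequence": s.sequence, "count": s.count}
            for s in top.chain_specs],
        "box": [float(x) for x in top.box],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`save_trajectory`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    topology = build_system(
        [ChainSpec(s["name"], s["sequence"], s["count"])
         for s in sidecar["chain_specs"]],
        sidecar["box"])
    times, boxes, frames = [], [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            n = int(header)
            comment = fh.readline()
            lattice = comment.split('"')[1].split()
            box = [float(lattice[0]), float(lattice[4]), float(lattice[8])]
            time = float(comment.split("Time=")[1].split()[0])
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            times.append(time)
            boxes.append(box)
            frames.append(pos)
    return Trajectory(
        times=np.array(times),
        boxes=np.array(boxes),
        positions=np.array(frames),
        topology=topology,
        unwrapped=sidecar["unwrapped"],
        seed=sidecar["seed"],
    )


def export_profile_csv(profile: DensityProfile, path: str | Path) -> None:
    """Density profile as CSV with ``#`` header metadata."""
    with open(path, "w") as fh:
        fh.write(f"# species: {profile.species or 'all'}\n")
        fh.write(f"# box_nm: {profile.box[0]} {profile.box[1]} {profile.box[2]}\n")
        fh.write(f"# n_frames: {profile.n_frames}\n")
        fh.write(f"# total_mass_amu: {profile.total_mass}\n")
        fh.write("z_nm,density_mg_cm3\n")
        for z, d in zip(profile.z_centers, profile.density):
            fh.write(f"{z},{d}\n")


def read_profile_csv(path: str | Path) -> DensityProfile:
    """Read a profile written by :func:`export_profile_csv`."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    species = meta.get("species")
    return DensityProfile(
        z_centers=df["z_nm"].to_numpy(),
        density=df["density_mg_cm3"].to_numpy(),
        box=np.array([float(x) for x in meta["box_nm"].split()]),
        species=None if species == "all" else species,
        n_frames=int(meta.get("n_frames", 1)),
        total_mass=float(meta.get("total_mass_amu", 0.0)),
    )


def export_phase_diagram_json(diagram: PhaseDiagram, path: str | Path) -> None:
    """Phase diagram (binodal points + critical fit) as a JSON report."""
    report = {
        "points": [
            {"temperature_K": float(t),
             "rho_dense_mg_cm3": float(d),
             "rho_dilute_mg_cm3": float(l),
             "ci_rho_dense": [float(x) for x in fit.ci_rho_dense],
             "ci_rho_dilute": [float(x) for x in fit.ci_rho_dilute]}
            for t, d, l, fit in zip(diagram.temperatures, diagram.rho_dense,
                                    diagram.rho_dilute, diagram.fits)],
        "critical": None,
    }
    if diagram.critical is not None:
        c = diagram.critical
        report["critical"] = {
            "t_c_K": c.t_c, "amplitude": c.amplitude, "beta": c.beta,
            "ci_t_c": [float(x) for x in c.ci_t_c],
            "converged": c.converged,
        }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def export_contacts(result: ContactResult, directory: str | Path) -> None:
    """Contact matrices as dense CSV plus a long-format TSV.

    One ``contacts_<a>_<b>.csv`` per species pair and a combined
    ``contacts_long.tsv`` with columns res_i, res_j, species_pair, count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for (a, b), mat in result.pair_matrices.items():
        pd.DataFrame(mat).to_csv(directory / f"contacts_{a}_{b}.csv",
                                 index=False)
        nz = np.argwhere(mat > 0)
        for i, j in nz:
            rows.append((int(i), int(j), f"{a}-{b}", float(mat[i, j])))
    pd.DataFrame(rows, columns=["res_i", "res_j", "species_pair", "count"]) \
        .to_csv(directory / "contacts_long.tsv", sep="\t", index=False)


def export_msd_csv(result: MSDResult, path: str | Path) -> None:
    """MSD curve as CSV."""
    with open(path, "w") as fh:
        fh.write(f"# species: {result.species or 'all'}\n")
        fh.write(f"# n_chains: {result.n_chains}\n")
        fh.write("lag_ns,msd_nm2\n")
        for t, m in zip(result.lag_times, result.msd):
            fh.write(f"{t},{m}\n")


def read_frap_csv(path: str | Path) -> FrapCurve:
    """FRAP recording from CSV with columns time_s, bleached, reference."""
    df = pd.read_csv(path, comment="#")
    return FrapCurve(times=df["time_s"].to_numpy(),
                     bleached=df["bleached"].to_numpy(),
                     reference=df["reference"].to_numpy())


def write_fixture_tree(directory: str | Path, seed: int = 0) -> dict:
    """Write the standard synthetic-fixture set into a directory.

    FASTA sequences, a slab-profile CSV, a FRAP curve CSV and a peak
    table — the file-based counterparts of the in-memory generators.
    Returns the mapping of fixture name to path.
    """
    from .synthetic import (gen_frap_curve, gen_peak_tables, gen_tanh_profile,
                            toy_sequences)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, seq in toy_sequences().items():
        p = directory / f"{name}.fasta"
        with open(p, "w") as fh:
            fh.write(f">{name} synthetic fixture sequence\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
        written[name] = p
    prof = gen_tanh_profile(600.0, 10.0, 15.0, 2.0, noise=0.02, seed=seed)
    export_profile_csv(prof, directory / "slab_profile.csv")
    written["slab_profile"] = directory / "slab_profile.csv"
    curve = gen_frap_curve(noise=0.01, seed=seed)
    with open(directory / "frap_curve.csv", "w") as fh:
        fh.write("time_s,bleached,reference\n")
        for t, b, r in zip(curve.times, curve.bleached, curve.reference):
            fh.write(f"{t},{b},{r}\n")
    written["frap_curve"] = directory / "frap_curve.csv"
    ref, per = gen_peak_tables(40, seed=seed)
    for tag, peaks in [("reference", ref), ("perturbed", per)]:
        p = directory / f"peaks_{tag}.csv"
        with open(p, "w") as fh:
            fh.write("residue,delta_h,delta_n,intensity\n")
            for pk in peaks:
                fh.write(f"{pk.residue},{pk.delta_h},{pk.delta_n},{pk.intensity}\n")
        written[f"peaks_{tag}"] = p
    return written
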