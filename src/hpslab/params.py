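"""Residue-level parameterization, sequence utilities and system topology.

The coarse-grained model represents each residue as a single bead with a
van der Waals diameter sigma, a hydropathy weight lambda in [0, 1], a
fixed charge and a mass.  The packaged table follows the HPS model on the
Kapcha-Rossky hydrophobicity scale; it ships as a versioned TSV with a
provenance header and is loaded with :func:`load_residue_params`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import (
    AVOGADRO,
    BOLTZMANN_SI,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

TYPE_CLASSES = ("charged", "hydrophobic", "polar", "other")
TYPE_CODES = {name: i for i, name in enumerate(TYPE_CLASSES)}

_ALLOWED_CHARGES = (-1.0, 0.0, 0.5, 1.0)


@dataclass(frozen=True)
class ResidueParams:
    """Parameters of a single amino-acid bead."""

    residue: str
    mass: float  # amu
    charge: float  # elementary charges
    sigma: float  # nm
    lambda_hps: float  # dimensionless, in [0, 1]
    type_class: str  # one of TYPE_CLASSES


class ResidueParamTable:
    """Per-residue coarse-grained parameters for the 20 standard amino acids.

    Lookup is by one-letter code; unknown letters raise ``KeyError``.
    """

    def __init__(self, rows: dict[str, ResidueParams], provenance: str = ""):
        self._rows = dict(rows)
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        missing = sorted(set(STANDARD_AA) - set(self._rows))
        if missing:
            raise ValueError(
                f"parameter table incomplete: missing residues {missing}"
            )
        for aa, p in self._rows.items():
            if p.sigma <= 0:
                raise ValueError(f"non-positive sigma for residue {aa}")
            if not 0.0 <= p.lambda_hps <= 1.0:
                raise ValueError(f"lambda outside [0, 1] for residue {aa}")
            if p.charge not in _ALLOWED_CHARGES:
                raise ValueError(f"disallowed charge {p.charge} for {aa}")
            if p.type_class not in TYPE_CLASSES:
                raise ValueError(f"unknown type class for {aa}")
        for aa in "DE":
            if self._rows[aa].charge != -1.0:
                raise ValueError(f"{aa} must carry charge -1")
        for aa in "KR":
            if self._rows[aa].charge != +1.0:
                raise ValueError(f"{aa} must carry charge +1")
        for aa in "FWY":
            if self._rows[aa].type_class != "hydrophobic":
                raise ValueError(f"aromatic {aa} must be classed hydrophobic")

    def lookup(self, residue: str) -> ResidueParams:
        try:
            return self._rows[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} not in parameter table"
            ) from None

    def __getitem__(self, residue: str) -> ResidueParams:
        return self.lookup(residue)

    def __contains__(self, residue: str) -> bool:
        return residue in self._rows

    def residues(self) -> list[str]:
        return sorted(self._rows)

    def arrays_for(self, sequence: str):
        """Vectorized (sigma, lambda, charge, mass, type_code) for a sequence."""
        rows = [self.lookup(aa) for aa in sequence]
        sigma = np.array([r.sigma for r in rows])
        lam = np.array([r.lambda_hps for r in rows])
        charge = np.array([r.charge for r in rows])
        mass = np.array([r.mass for r in rows])
        tcode = np.array([TYPE_CODES[r.type_class] for r in rows], dtype=np.int64)
        return sigma, lam, charge, mass, tcode

    def charges_for(self, sequence: str) -> np.ndarray:
        return np.array([self.lookup(aa).charge for aa in sequence])


def load_residue_params(source: str | Path | None = None) -> ResidueParamTable:
    """Load the residue parameter table from a TSV file.

    Parameters
    ----------
    source
        Path to a tab-separated file with a ``#`` comment header and columns
        residue, name3, mass, charge, sigma, lambda_hps, type_class.
        When omitted, the packaged HPS (Kapcha-Rossky) table is used.
    """
    if source is None:
        ref = resources.files("hpslab.data").joinpath("hps_kr_params.tsv")
        with resources.as_file(ref) as path:
            return load_residue_params(path)
    source = Path(source)
    header_lines = []
    with open(source) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line.lstrip("# ").rstrip())
            else:
                break
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"residue", "mass", "charge", "sigma", "lambda_hps", "type_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"parameter file missing columns {required - set(df.columns)}")
    rows = {}
    for rec in df.itertuples(index=False):
        rows[rec.residue] = ResidueParams(
            residue=rec.residue,
            mass=float(rec.mass),
            charge=float(rec.charge),
            sigma=float(rec.sigma),
            lambda_hps=float(rec.lambda_hps),
            type_class=str(rec.type_class),
        )
    return ResidueParamTable(rows, provenance=" ".join(header_lines))


def read_fasta_sequence(path: str | Path) -> str:
    """Read the first record of a FASTA file and return its sequence."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def packaged_sequence(name: str) -> str:
    """Return a packaged fixture sequence: ``"tau_2n4r"`` or ``"abeta40"``."""
    ref = resources.files("hpslab.data").joinpath(f"{name}.fasta")
    with resources.as_file(ref) as path:
        return read_fasta_sequence(path)


def debye_length(
    temperature: float, ionic_strength: float, rel_permittivity: float
) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte.

    ``lambda_D = sqrt(eps_r eps_0 k_B T / (2 e^2 I))`` with the ionic
    strength ``I`` (molar) converted to a number density.

    Parameters
    ----------
    temperature : K
    ionic_strength : molar
    rel_permittivity : dimensionless
    """
    if temperature <= 0 or ionic_strength <= 0 or rel_permittivity <= 0:
        raise ValueError("temperature, ionic strength and permittivity must be > 0")
    number_density = ionic_strength * 1000.0 * AVOGADRO  # 1/m^3
    lam_sq = (
        rel_permittivity
        * VACUUM_PERMITTIVITY
        * BOLTZMANN_SI
        * temperature
        / (2.0 * ELEMENTARY_CHARGE**2 * number_density)
    )
    return math.sqrt(lam_sq) * 1e9  # m -> nm


@dataclass
class ElectrostaticsParams:
    """Solvent/electrolyte parameters of the screened Coulomb term."""

    ionic_strength: float = 0.150  # molar
    rel_permittivity: float = 80.0
    temperature: float = 300.0  # K
    debye_length: float = field(default=None)  # nm; derived when omitted

    def __post_init__(self):
        if self.ionic_strength <= 0 or self.rel_permittivity <= 0 or self.temperature <= 0:
            raise ValueError("all electrostatics parameters must be positive")
        expected = debye_length(
            self.temperature, self.ionic_strength, self.rel_permittivity
        )
        if self.debye_length is None:
            self.debye_length = expected
        else:
            if self.debye_length <= 0:
                raise ValueError("debye_length must be positive")
            if abs(self.debye_length - expected) > 1e-10 * expected:
                raise ValueError(
                    f"debye_length {self.debye_length} inconsistent with the "
                    f"Debye-Hueckel closed form {expected}"
                )


def ncpr_profile(sequence: str, window: int = 5,
                 table: ResidueParamTable | None = None) -> np.ndarray:
    """Net charge per residue in a sliding window.

    The value at position ``i`` is the mean bead charge over the window of
    ``window`` residues centered at ``i``; at the termini the window is
    truncated to the residues that exist.  Values lie in [-1, +1].

    Parameters
    ----------
    sequence
        Amino-acid string (one-letter codes).
    window
        Odd window length, at most ``len(sequence)``.
    """
    if window % 2 == 0 or window <= 0:
        raise ValueError("window must be a positive odd integer")
    if window > len(sequence):
        raise ValueError("window larger than sequence")
    if table is None:
        table = load_residue_params()
    charges = table.charges_for(sequence)
    half = window // 2
    n = len(sequence)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = charges[lo:hi].mean()
    return out


@dataclass(frozen=True)
class ChainSpec:
    """A molecular species: name, sequence and copy number."""

    name: str
    sequence: str
    count: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.count < 1:
            raise ValueError("count must be a positive integer")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SystemTopology:
    """Bead-level topology of a multi-chain coarse-grained system.

    Beads are numbered consecutively chain by chain.  ``bonds`` connects
    consecutive beads within each chain only.  Per-bead parameter arrays
    are precomputed from the residue table for the force kernels.
    """

    chain_specs: list[ChainSpec]
    box: np.ndarray  # (3,) nm
    chain_id: np.ndarray  # (n_beads,) int
    residue_index: np.ndarray  # (n_beads,) position within chain
    species_index: np.ndarray  # (n_beads,) index into chain_specs
    letters: np.ndarray  # (n_beads,) unicode residue letters
    bonds: np.ndarray  # (n_bonds, 2) int
    sigma: np.ndarray
    lambda_hps: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    type_code: np.ndarray

    @property
    def n_beads(self) -> int:
        return self.chain_id.size

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0

    def chain_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.chain_id == c)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chains_of_species(self, name: str) -> np.ndarray:
        """Chain indices belonging to the named species."""
        spec_idx = [i for i, s in enumerate(self.chain_specs) if s.name == name]
        if not spec_idx:
            raise ValueError(f"no species named {name!r}")
        first_bead = np.searchsorted(self.chain_id, np.arange(self.n_chains))
        return np.flatnonzero(np.isin(self.species_index[first_bead], spec_idx))

    def species_mask(self, name: str) -> np.ndarray:
        """Boolean bead mask for the named species."""
        spec_idx = [i for i, s in enumerate(self.chain_specs) if s.name == name]
        if not spec_idx:
            raise ValueError(f"no species named {name!r}")
        return np.isin(self.species_index, spec_idx)

    def total_mass(self) -> float:
        return float(self.mass.sum())


def build_system(
    chain_specs: Sequence[ChainSpec],
    box: Sequence[float],
    table: ResidueParamTable | None = None,
) -> SystemTopology:
    """Assemble a :class:`SystemTopology` from chain specifications.

    The bead count is ``sum(count * len(sequence))`` over species and the
    bond list connects consecutive beads within each chain only.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive lengths")
    if table is None:
        table = load_residue_params()
    chain_specs = list(chain_specs)

    chain_id, residue_index, species_index, letters = [], [], [], []
    bonds = []
    sigma, lam, charge, mass, tcode = [], [], [], [], []
    bead = 0
    chain = 0
    for si, spec in enumerate(chain_specs):
        s, l, q, m, t = table.arrays_for(spec.sequence)  # raises on unknown letter
        n = len(spec.sequence)
        for _ in range(spec.count):
            chain_id.append(np.full(n, chain))
            residue_index.append(np.arange(n))
            species_index.append(np.full(n, si))
            letters.append(np.array(list(spec.sequence)))
            sigma.append(s)
            lam.append(l)
            charge.append(q)
            mass.append(m)
            tcode.append(t)
            bonds.append(np.column_stack([np.arange(bead, bead + n - 1),
                                          np.arange(bead + 1, bead + n)]))
            bead += n
            chain += 1
    return SystemTopology(
        chain_specs=chain_specs,
        box=box,
        chain_id=np.concatenate(chain_id),
        residue_index=np.concatenate(residue_index),
        species_index=np.concatenate(species_index),
        letters=np.concatenate(letters),
        bonds=(np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=int)).astype(np.int64),
        sigma=np.concatenate(sigma),
        lambda_hps=np.concatenate(lam),
        charge=np.concatenate(charge),
        mass=np.concatenate(mass),
        type_code=np.concatenate(tcode),
    )
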