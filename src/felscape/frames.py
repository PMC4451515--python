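"""In-memory containers for conformations and collective-variable series.

Units follow simulation-package convention throughout: coordinates in nm,
energies in kJ/mol, times in ps.  Nucleotide indices are the (1-based) PDB
residue numbers within a chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083145

#: Residue names recognised as monatomic cations / anions in PDB input.
CATION_RESNAMES = {"NA", "K", "MG", "NA+", "K+", "MG2", "SOD", "POT", "LI", "CA"}
ANION_RESNAMES = {"CL", "CL-", "CLA"}

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "K": 39.098, "MG": 24.305, "CL": 35.45,
}


def element_mass(element: str) -> float:
    """Atomic mass for an element symbol; unknown symbols get unit mass."""
    return _MASSES.get(element.upper(), 1.0)


@dataclass
class StructureFrame:
    """One conformation: polymer atoms grouped into nucleotides, plus ions.

    Attributes
    ----------
    atom_names, residue_ids, residue_names, chain_ids, elements :
        Per-atom annotation arrays (length N) for the polymer (RNA) atoms.
    coords :
        (N, 3) polymer atom coordinates in nm.
    cation_names / cation_coords :
        Monatomic cations stored separately from the polymer.
    anion_names / anion_coords :
        Anions; kept for bookkeeping but excluded from all cation analyses.
    """

    atom_names: np.ndarray
    residue_ids: np.ndarray
    coords: np.ndarray
    residue_names: np.ndarray | None = None
    chain_ids: np.ndarray | None = None
    elements: np.ndarray | None = None
    cation_names: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    cation_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    anion_names: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    anion_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.residue_names is None:
            self.residue_names = np.full(len(self.atom_names), "UNK", dtype=object)
        if self.chain_ids is None:
            self.chain_ids = np.full(len(self.atom_names), "A", dtype=object)
        if self.elements is None:
            self.elements = np.array(
                [_guess_element(n) for n in self.atom_names], dtype=object
            )
        self.cation_coords = np.asarray(self.cation_coords, dtype=float).reshape(-1, 3)
        self.anion_coords = np.asarray(self.anion_coords, dtype=float).reshape(-1, 3)
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom annotation and coordinate lengths differ")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_cations(self) -> int:
        return len(self.cation_names)

    @property
    def residue_index(self) -> np.ndarray:
        """Sorted unique residue numbers present in the frame."""
        return np.unique(self.residue_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    def masses(self) -> np.ndarray:
        return np.array([element_mass(e) for e in self.elements], dtype=float)

    def atoms_of_residue(self, resid: int) -> np.ndarray:
        """Indices of the polymer atoms belonging to residue ``resid``."""
        return np.nonzero(self.residue_ids == resid)[0]

    def select(self, names: set[str]) -> np.ndarray:
        """Indices of polymer atoms whose atom name is in ``names``."""
        return np.nonzero(np.isin(self.atom_names, list(names)))[0]

    def with_coords(self, coords: np.ndarray) -> "StructureFrame":
        """Copy of the frame with replaced polymer coordinates."""
        return StructureFrame(
            atom_names=self.atom_names,
            residue_ids=self.residue_ids,
            coords=np.asarray(coords, dtype=float),
            residue_names=self.residue_names,
            chain_ids=self.chain_ids,
            elements=self.elements,
            cation_names=self.cation_names,
            cation_coords=self.cation_coords,
            anion_names=self.anion_names,
            anion_coords=self.anion_coords,
        )


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    if name.upper() in _MASSES:
        return name.upper()
    lead = name.lstrip("0123456789")
    return lead[:1].upper() if lead else "X"


@dataclass
class CVSeries:
    """Time-indexed values of named collective variables.

    ``data`` holds one column per CV; ``time`` is in ps and strictly
    increasing unless the series was assembled frame-by-frame (index order).
    """

    time: np.ndarray
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if len(self.time) != len(self.data):
            raise FormatError("time vector and CV table lengths differ")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate CV column name")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.time)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def values(self, names: list[str]) -> np.ndarray:
        """(n, k) array of the requested CV columns."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown CV column(s): {missing}")
        return self.data[list(names)].to_numpy(dtype=float)

    def window(self, start_frac: float, end_frac: float) -> "CVSeries":
        """Contiguous sub-series spanning the [start, end) fraction of rows."""
        n = len(self)
        i0, i1 = int(round(start_frac * n)), int(round(end_frac * n))
        if i1 <= i0:
            raise EmptyInputError("requested window contains no samples")
        return CVSeries(self.time[i0:i1], self.data.iloc[i0:i1].reset_index(drop=True))

    @classmethod
    def from_columns(cls, time: np.ndarray, **columns: np.ndarray) -> "CVSeries":
        return cls(np.asarray(time, dtype=float), pd.DataFrame(columns))
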