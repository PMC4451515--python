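"""Bound/bridging cation statistics and the ion-mediation ratio R_p.

Definitions (all configurable):

* bound ion -- a cation within 0.4 nm of any nucleotide, the residue-ion
  distance being the minimum over the residue's atoms (the most inclusive
  literal reading; a phosphate-only mode is available);
* bridging ion -- a bound cation simultaneously within the cutoff of two or
  more nucleotides separated by at least 4 nucleotides along the sequence
  (|i - j| >= 4 on residue numbering);
* ion-mediated structure -- a frame containing >= 1 bridging ion;
* R_p -- the population ratio (# ion-mediated frames) / (# non-mediated
  frames) of an ensemble.  R_p > 1 means most conformations are ion-bridged.
  An all-mediated ensemble yields the +inf sentinel; the mediated /
  non-mediated counts are always reported alongside.

Anions are excluded from every statistic; the analysis concerns cation
(Na+) binding only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyInputError
from .frames import StructureFrame

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P", "O3'", "O5'", "BB"}


@dataclass
class CationContact:
    residues: np.ndarray  # residue numbers within cutoff
    bound: bool
    bridging: bool


@dataclass
class IonFrameStats:
    cations: list[CationContact]
    n_bound: int
    n_bridging: int
    ion_mediated: bool


@dataclass
class EnsembleIonStats:
    frame_stats: list[IonFrameStats]
    mean_n_bound: float
    rp: float
    n_mediated: int
    n_non_mediated: int
    residue_ids: np.ndarray
    binding_probability: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frame_stats)


def ion_frame_stats(
    frame: StructureFrame,
    cutoff: float = 0.4,
    min_sep: int = 4,
    mode: str = "min_atom",
) -> IonFrameStats:
    """Per-frame bound/bridging classification of every cation."""
    atoms = _atom_mask(frame, mode)
    contacts: list[CationContact] = []
    n_bound = n_bridging = 0
    if frame.n_cations and atoms.any():
        dist = cdist(frame.cation_coords, frame.coords[atoms])
        resids = frame.residue_ids[atoms]
        for k in range(frame.n_cations):
            near = np.unique(resids[dist[k] <= cutoff])
            bound = len(near) > 0
            bridging = bound and (near.max() - near.min() >= min_sep)
            contacts.append(CationContact(near, bound, bridging))
            n_bound += bound
            n_bridging += bridging
    else:
        contacts = [
            CationContact(np.empty(0, dtype=int), False, False)
            for _ in range(frame.n_cations)
        ]
    return IonFrameStats(contacts, n_bound, n_bridging, n_bridging >= 1)


def _atom_mask(frame: StructureFrame, mode: str) -> np.ndarray:
    if mode == "min_atom":
        return np.ones(frame.n_atoms, dtype=bool)
    if mode == "phosphate":
        return np.isin(frame.atom_names, list(PHOSPHATE_ATOMS))
    raise ValueError(f"unknown residue-ion distance mode {mode!r}")


def compute_rp(frame_stats: list[IonFrameStats]) -> tuple[float, int, int]:
    """R_p = (# mediated frames) / (# non-mediated frames), with counts.

    Returns (rp, n_mediated, n_non_mediated); rp is +inf when every frame is
    ion-mediated and 0.0 when none is.
    """
    if not frame_stats:
        raise EmptyInputError("empty ensemble")
    n_med = sum(1 for s in frame_stats if s.ion_mediated)
    n_non = len(frame_stats) - n_med
    rp = np.inf if n_non == 0 else n_med / n_non
    return float(rp), n_med, n_non


def binding_probability_per_nucleotide(
    frames: list[StructureFrame],
    cutoff: float = 0.4,
    mode: str = "min_atom",
) -> tuple[np.ndarray, np.ndarray]:
    """Per residue: fraction of frames with >= 1 cation within the cutoff."""
    if not frames:
        raise EmptyInputError("empty ensemble")
    residue_ids = frames[0].residue_index
    pos = {r: k for k, r in enumerate(residue_ids)}
    hits = np.zeros(len(residue_ids))
    for frame in frames:
        stats = ion_frame_stats(frame, cutoff=cutoff, mode=mode)
        contacted = set()
        for c in stats.cations:
            contacted.update(int(r) for r in c.residues)
        for r in contacted:
            hits[pos[r]] += 1
    return residue_ids, hits / len(frames)


def ensemble_ion_stats(
    frames: list[StructureFrame],
    cutoff: float = 0.4,
    min_sep: int = 4,
    mode: str = "min_atom",
) -> EnsembleIonStats:
    """All ion statistics of an ensemble in one pass."""
    if not frames:
        raise EmptyInputError("empty ensemble")
    stats = [ion_frame_stats(f, cutoff, min_sep, mode) for f in frames]
    rp, n_med, n_non = compute_rp(stats)
    residue_ids = frames[0].residue_index
    pos = {r: k for k, r in enumerate(residue_ids)}
    hits = np.zeros(len(residue_ids))
    for s in stats:
        contacted = set()
        for c in s.cations:
            contacted.update(int(r) for r in c.residues)
        for r in contacted:
            hits[pos[r]] += 1
    return EnsembleIonStats(
        frame_stats=stats,
        mean_n_bound=float(np.mean([s.n_bound for s in stats])),
        rp=rp,
        n_mediated=n_med,
        n_non_mediated=n_non,
        residue_ids=residue_ids,
        binding_probability=hits / len(frames),
    )


def binding_vs_variable(
    frames: list[StructureFrame] | list[IonFrameStats],
    variable: np.ndarray,
    bin_edges: np.ndarray,
    cutoff: float = 0.4,
    min_sep: int = 4,
    mode: str = "min_atom",
) -> pd.DataFrame:
    """Mean bound-ion count and R_p binned along an auxiliary variable (Rg).

    Empty bins are omitted.  ``variable`` must be aligned with ``frames``.
    """
    variable = np.asarray(variable, dtype=float)
    if len(variable) != len(frames):
        raise ValueError("variable series and ensemble lengths differ")
    if frames and isinstance(frames[0], IonFrameStats):
        stats = list(frames)
    else:
        stats = [ion_frame_stats(f, cutoff, min_sep, mode) for f in frames]
    edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(variable, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        members = [stats[i] for i in np.nonzero(which == b)[0]]
        if not members:
            continue
        rp, n_med, n_non = compute_rp(members)
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n_frames": len(members),
                "mean_n_bound": float(np.mean([s.n_bound for s in members])),
                "rp": rp,
                "n_mediated": n_med,
                "n_non_mediated": n_non,
            }
        )
    return pd.DataFrame(rows)
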