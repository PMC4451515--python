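"""Per-frame and ensemble structural observables.

Hydrogen bonds are detected with the community-standard geometric criterion:
donor-acceptor heavy-atom distance <= 0.35 nm, with a D-H...A angle test
(>= 150 deg) applied only when the donor carries hydrogens; structures
without hydrogens (NMR-style heavy-atom models, toy ensembles) fall back to
the distance-only test.  The criterion the source trajectories used is not
recoverable, so every threshold here is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .config import AnalysisConfig, CVDefinition, HBondId
from .errors import ConfigError, EmptyInputError
from .frames import CVSeries, StructureFrame

#: Default donor / acceptor heavy-atom names: RNA nucleobase + ribose donors
#: and acceptors, plus the pseudo-atom names used by the toy generator.
RNA_DONOR_ATOMS = {"N1", "N2", "N3", "N4", "N6", "O2'", "DON"}
RNA_ACCEPTOR_ATOMS = {
    "N1", "N3", "N7", "O2", "O4", "O6",
    "O2'", "O3'", "O4'", "O5'", "OP1", "OP2", "O1P", "O2P",
    "ACC",
}


@dataclass(frozen=True)
class HBond:
    donor_res: int
    acceptor_res: int
    donor_atom: str
    acceptor_atom: str
    native: bool = False
    distance: float = np.nan

    @property
    def pair(self) -> tuple[int, int]:
        return (self.donor_res, self.acceptor_res)


@dataclass
class HBondCriterion:
    distance_cutoff: float = 0.35  # nm, donor-acceptor heavy atoms
    angle_min_deg: float = 150.0  # D-H...A
    donor_atoms: frozenset = frozenset(RNA_DONOR_ATOMS)
    acceptor_atoms: frozenset = frozenset(RNA_ACCEPTOR_ATOMS)
    min_residue_separation: int = 1  # |i - j| >= this

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "HBondCriterion":
        return cls(
            distance_cutoff=config.hb_distance_cutoff,
            angle_min_deg=config.hb_angle_min_deg,
        )


@dataclass
class HBMap:
    """Pairwise HB formation probabilities over an ensemble (symmetric)."""

    probabilities: np.ndarray
    residue_ids: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("HB map must be square")
        if ((p < -1e-12) | (p > 1 + 1e-12)).any():
            raise ValueError("HB map entries must lie in [0, 1]")
        self.probabilities = p
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)

    def entry(self, res_i: int, res_j: int) -> float:
        idx = {r: k for k, r in enumerate(self.residue_ids)}
        return float(self.probabilities[idx[res_i], idx[res_j]])


# ----------------------------------------------------------------------
def detect_hbonds(
    frame: StructureFrame,
    criterion: HBondCriterion | None = None,
    native_list: list[HBondId] | None = None,
) -> list[HBond]:
    """Detect hydrogen bonds in one frame.

    Returns one HBond per (donor atom, acceptor atom) pair satisfying the
    geometric criterion, tagged native if it appears in ``native_list``.
    """
    criterion = criterion or HBondCriterion()
    don_idx = frame.select(set(criterion.donor_atoms))
    acc_idx = frame.select(set(criterion.acceptor_atoms))
    if len(don_idx) == 0 or len(acc_idx) == 0:
        warnings.warn("frame has no donor/acceptor-capable atoms", stacklevel=2)
        return []

    native4 = set()
    native2 = set()
    for hb in native_list or []:
        hb = HBondId(*hb) if not isinstance(hb, HBondId) else hb
        native4.add(tuple(hb))
        native2.add(hb.pair)

    dist = cdist(frame.coords[don_idx], frame.coords[acc_idx])
    res_d = frame.residue_ids[don_idx]
    res_a = frame.residue_ids[acc_idx]
    sep = np.abs(res_d[:, None] - res_a[None, :])
    cand = (dist <= criterion.distance_cutoff) & (
        sep >= criterion.min_residue_separation
    )

    hydrogens = _donor_hydrogens(frame, don_idx)
    out: list[HBond] = []
    for di, ai in zip(*np.nonzero(cand)):
        d_at, a_at = don_idx[di], acc_idx[ai]
        if hydrogens.get(d_at) is not None and not _angle_ok(
            frame, d_at, hydrogens[d_at], a_at, criterion.angle_min_deg
        ):
            continue
        ident = (
            int(res_d[di]), int(res_a[ai]),
            str(frame.atom_names[d_at]), str(frame.atom_names[a_at]),
        )
        out.append(
            HBond(
                *ident,
                native=(ident in native4) or (ident[:2] in native2 and not native4),
                distance=float(dist[di, ai]),
            )
        )
    return out


def _donor_hydrogens(frame: StructureFrame, don_idx: np.ndarray) -> dict:
    """Map donor atom index -> indices of attached hydrogens (None if none)."""
    h_idx = np.nonzero(np.asarray(frame.elements, dtype=object) == "H")[0]
    if len(h_idx) == 0:
        return {int(d): None for d in don_idx}
    d_h = cdist(frame.coords[don_idx], frame.coords[h_idx])
    out = {}
    for k, d in enumerate(don_idx):
        attached = h_idx[d_h[k] <= 0.12]
        out[int(d)] = attached if len(attached) else None
    return out


def _angle_ok(frame, d_at, h_atoms, a_at, angle_min_deg) -> bool:
    for h in h_atoms:
        v1 = frame.coords[d_at] - frame.coords[h]
        v2 = frame.coords[a_at] - frame.coords[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min_deg:
            return True
    return False


def native_hb_fraction(
    frame: StructureFrame,
    native_list: list[HBondId],
    criterion: HBondCriterion | None = None,
) -> float:
    """Fraction Q of the native hydrogen-bond list formed in this frame."""
    if not native_list:
        raise ConfigError("native_hb_list is empty")
    native_list = [HBondId(*hb) for hb in native_list]
    detected = detect_hbonds(frame, criterion, native_list)
    found = {(h.donor_res, h.acceptor_res, h.donor_atom, h.acceptor_atom)
             for h in detected}
    formed = sum(1 for hb in native_list if tuple(hb) in found)
    return formed / len(native_list)


def hb_probability_map(
    frames: list[StructureFrame],
    criterion: HBondCriterion | None = None,
) -> HBMap:
    """Formation probability of a residue-residue HB over the ensemble.

    entry(i, j) = fraction of frames in which ANY hydrogen bond links
    residues i and j (symmetric).
    """
    if not frames:
        raise EmptyInputError("hb_probability_map needs >= 1 frame")
    residue_ids = frames[0].residue_index
    pos = {r: k for k, r in enumerate(residue_ids)}
    counts = np.zeros((len(residue_ids), len(residue_ids)))
    for frame in frames:
        pairs = {
            tuple(sorted((h.donor_res, h.acceptor_res)))
            for h in detect_hbonds(frame, criterion)
        }
        for i, j in pairs:
            counts[pos[i], pos[j]] += 1
            counts[pos[j], pos[i]] += 1
    return HBMap(counts / len(frames), residue_ids, len(frames))


# ----------------------------------------------------------------------
def radius_of_gyration(frame: StructureFrame, mass_weighted: bool = True) -> float:
    """Rg of the polymer atoms (cations excluded), in nm."""
    if frame.n_atoms == 0:
        raise EmptyInputError("frame has no polymer atoms")
    w = frame.masses() if mass_weighted else np.ones(frame.n_atoms)
    com = np.average(frame.coords, axis=0, weights=w)
    sq = np.sum((frame.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def rmsd(
    frame_a: StructureFrame | np.ndarray,
    frame_b: StructureFrame | np.ndarray,
    superpose: bool = True,
    heavy_only: bool = True,
) -> float:
    """RMSD between two frames with identical atom correspondence, in nm.

    With ``superpose`` the minimum over rigid rotations + translations is
    returned (Kabsch optimal rotation); otherwise the raw coordinate RMSD.
    """
    a = _rmsd_coords(frame_a, heavy_only)
    b = _rmsd_coords(frame_b, heavy_only)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(a, b)
    # recompute from coordinates: the reported rssd loses precision near 0
    diff = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def _rmsd_coords(frame, heavy_only: bool) -> np.ndarray:
    if isinstance(frame, np.ndarray):
        return np.asarray(frame, dtype=float)
    if heavy_only:
        keep = np.asarray(frame.elements, dtype=object) != "H"
        return frame.coords[keep]
    return frame.coords


# ----------------------------------------------------------------------
def evaluate_cvs(
    frames: list[StructureFrame],
    config: AnalysisConfig,
    dt: float = 1.0,
) -> CVSeries:
    """Evaluate the configured CVs (native-HB subset counts, Rg) per frame."""
    if not frames:
        raise EmptyInputError("no frames")
    criterion = HBondCriterion.from_config(config)
    columns: dict[str, list[float]] = {cv.name: [] for cv in config.cv_definitions}
    native = config.native_hb_list
    for frame in frames:
        detected = None
        for cv in config.cv_definitions:
            if cv.rg:
                columns[cv.name].append(radius_of_gyration(frame))
            else:
                if detected is None:
                    detected = {
                        h.pair for h in detect_hbonds(frame, criterion, native)
                        if h.native
                    }
                columns[cv.name].append(
                    float(sum(1 for p in cv.hb_subset if p in detected))
                )
    time = np.arange(len(frames), dtype=float) * dt
    return CVSeries.from_columns(time, **columns)
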