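"""Readers and writers for the external formats the pipeline touches.

Formats: multi-model PDB (MODEL/ENDMDL) for conformational ensembles,
COLVAR-style ``#! FIELDS`` whitespace tables for CV time series, and TSV for
surfaces, tables and HB maps.  PDB coordinates (angstrom) are converted to nm
exactly once, here; everything downstream works in nm.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import EmptyInputError, FormatError, StructureParseError
from .frames import ANION_RESNAMES, CATION_RESNAMES, CVSeries, StructureFrame

_A_TO_NM = 0.1


# ----------------------------------------------------------------------
# multi-model PDB
# ----------------------------------------------------------------------
def _prescan_pdb(path: Path) -> None:
    """Reject malformed ATOM/HETATM records, naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}: line {lineno}: truncated ATOM record"
                )
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}: line {lineno}: unreadable coordinates"
                ) from exc


def read_structure_ensemble(path: str | Path) -> list[StructureFrame]:
    """Read a (multi-model) PDB file into one StructureFrame per model.

    Monatomic ions are recognised by residue name (NA, K, MG -> cations;
    CL -> anions) and stored separately from the polymer atoms.  A file
    without MODEL/ENDMDL keywords yields a single frame.
    """
    path = Path(path)
    _prescan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("ens", str(path))
    frames = []
    for model in structure:
        names, resids, resnames, chains, coords = [], [], [], [], []
        cat_names, cat_coords, an_names, an_coords = [], [], [], []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip().upper()
                for atom in residue:
                    xyz = atom.coord * _A_TO_NM
                    if resname in CATION_RESNAMES:
                        cat_names.append(resname)
                        cat_coords.append(xyz)
                    elif resname in ANION_RESNAMES:
                        an_names.append(resname)
                        an_coords.append(xyz)
                    else:
                        names.append(atom.get_name())
                        resids.append(residue.id[1])
                        resnames.append(resname)
                        chains.append(chain.id)
                        coords.append(xyz)
        if not names and not cat_names and not an_names:
            continue
        frames.append(
            StructureFrame(
                atom_names=np.array(names, dtype=object),
                residue_ids=np.array(resids, dtype=int),
                coords=np.array(coords, dtype=float).reshape(-1, 3),
                residue_names=np.array(resnames, dtype=object),
                chain_ids=np.array(chains, dtype=object),
                cation_names=np.array(cat_names, dtype=object),
                cation_coords=np.array(cat_coords, dtype=float).reshape(-1, 3),
                anion_names=np.array(an_names, dtype=object),
                anion_coords=np.array(an_coords, dtype=float).reshape(-1, 3),
            )
        )
    if not frames:
        raise EmptyInputError(f"{path}: no models found")
    return frames


def write_structure_ensemble(frames: list[StructureFrame], path: str | Path) -> None:
    """Write frames as a multi-model PDB (coordinates converted nm -> angstrom)."""
    if not frames:
        raise EmptyInputError("no frames to write")
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            serial = 1
            for i in range(frame.n_atoms):
                serial = _write_atom(
                    fh, "ATOM", serial, str(frame.atom_names[i]),
                    str(frame.residue_names[i]), str(frame.chain_ids[i]),
                    int(frame.residue_ids[i]), frame.coords[i],
                    str(frame.elements[i]),
                )
            ion_res = frame.n_residues
            for kind, names, coords in (
                ("cat", frame.cation_names, frame.cation_coords),
                ("an", frame.anion_names, frame.anion_coords),
            ):
                for j in range(len(names)):
                    ion_res += 1
                    name = str(names[j])
                    serial = _write_atom(
                        fh, "HETATM", serial, name, name, "I", ion_res,
                        coords[j], name,
                    )
            fh.write("ENDMDL\n" if multi else "END\n")


def _write_atom(fh, record, serial, name, resname, chain, resid, xyz, element) -> int:
    pdb_name = name if len(name) >= 4 else f" {name:<3s}"
    x, y, z = np.asarray(xyz) / _A_TO_NM
    fh.write(
        f"{record:<6s}{serial:5d} {pdb_name:<4s} {resname:<3s} {chain:1s}"
        f"{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element[:2]:>2s}\n"
    )
    return serial + 1


# ----------------------------------------------------------------------
# COLVAR-style tables
# ----------------------------------------------------------------------
def read_cv_table(path: str | Path) -> CVSeries:
    """Read a COLVAR-style whitespace table with a ``#! FIELDS`` header.

    Rows with non-numeric entries or a wrong field count are dropped with a
    warning; the first column must be named ``time``.
    """
    path = Path(path)
    header = None
    with open(path) as fh:
        for line in fh:
            if line.strip():
                header = line.rstrip("\n")
                break
    if header is None or not header.startswith("#! FIELDS"):
        raise FormatError(f"{path}: missing '#! FIELDS' header")
    columns = header.split()[2:]
    if not columns or columns[0] != "time":
        raise FormatError(f"{path}: first FIELDS column must be 'time'")
    if len(set(columns)) != len(columns):
        raise FormatError(f"{path}: duplicate column name in FIELDS header")

    raw = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=columns,
        on_bad_lines="skip", engine="python",
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    kept = numeric.dropna()
    dropped = len(raw) - len(kept)
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} malformed row(s)", stacklevel=2)
    if kept.empty:
        warnings.warn(f"{path}: table has a header but no data rows", stacklevel=2)
        return CVSeries(np.empty(0), pd.DataFrame(columns=columns[1:]))
    kept = kept.reset_index(drop=True)
    return CVSeries(kept["time"].to_numpy(), kept.drop(columns="time"))


def write_cv_table(series: CVSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(series.names) + "\n")
        values = np.column_stack([series.time, series.data.to_numpy()])
        for row in values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# ----------------------------------------------------------------------
# surfaces, tables, HB maps
# ----------------------------------------------------------------------
def write_surface(surface, path: str | Path) -> None:
    """Serialize a FreeEnergySurface to TSV (empty bins written as 'inf')."""
    with open(path, "w") as fh:
        fh.write("# felscape free-energy surface\n")
        fh.write("# cv_names:\t" + "\t".join(surface.cv_names) + "\n")
        fh.write(f"# temperature_K:\t{surface.temperature:.17g}\n")
        for name, edges in zip(surface.cv_names, surface.edges):
            fh.write(
                f"# edges[{name}]:\t" + "\t".join(f"{e:.17g}" for e in edges) + "\n"
            )
        fh.write("\t".join([f"i_{n}" for n in surface.cv_names] + ["F_kJ_mol", "count"]) + "\n")
        counts = surface.counts
        for idx in np.ndindex(surface.F.shape):
            f = surface.F[idx]
            c = 0 if counts is None else int(counts[idx])
            fval = "inf" if np.isinf(f) else f"{f:.12g}"
            fh.write("\t".join(str(i) for i in idx) + f"\t{fval}\t{c}\n")


def read_surface(path: str | Path):
    from .fel import FreeEnergySurface  # local import avoids a cycle

    path = Path(path)
    cv_names, temperature, edges = None, None, {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# cv_names:"):
                cv_names = line.split("\t")[1:]
                cv_names = [c.strip() for c in cv_names]
            elif line.startswith("# temperature_K:"):
                temperature = float(line.split("\t")[1])
            elif line.startswith("# edges["):
                name = line[len("# edges[") : line.index("]")]
                edges[name] = np.array(
                    [float(v) for v in line.split("\t")[1:]], dtype=float
                )
            elif line.startswith("#") or line.startswith("i_"):
                continue
            elif line.strip():
                body_lines.append(line)
    if cv_names is None or temperature is None or not edges:
        raise FormatError(f"{path}: not a felscape surface file")
    edge_list = [edges[n] for n in cv_names]
    shape = tuple(len(e) - 1 for e in edge_list)
    F = np.full(shape, np.inf)
    counts = np.zeros(shape, dtype=int)
    for line in body_lines:
        parts = line.split("\t")
        idx = tuple(int(p) for p in parts[: len(shape)])
        F[idx] = float(parts[len(shape)])
        counts[idx] = int(parts[len(shape) + 1])
    return FreeEnergySurface(
        cv_names=cv_names, edges=edge_list, F=F, counts=counts,
        temperature=temperature,
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    try:
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    except OSError as exc:
        raise FelscapeIOError(str(exc)) from exc


class FelscapeIOError(FormatError):
    """Unwritable/unreadable path."""


def write_hb_map(hbmap, path: str | Path) -> None:
    """HB probability map as TSV with nucleotide-pair row/column headers."""
    df = pd.DataFrame(
        hbmap.probabilities, index=hbmap.residue_ids, columns=hbmap.residue_ids
    )
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_hb_map(path: str | Path):
    from .structure import HBMap

    df = pd.read_csv(path, sep="\t", index_col=0)
    return HBMap(
        probabilities=df.to_numpy(dtype=float),
        residue_ids=np.array([int(c) for c in df.columns]),
        n_frames=0,
    )
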