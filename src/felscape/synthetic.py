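"""Synthetic inputs with known ground truth.

The real study analysed enhanced-sampling MD trajectories that were never
deposited; everything the pipeline consumes can instead be generated here
with exactly known answers:

* CV time series sampled by Metropolis Monte Carlo from analytic multi-well
  potentials -- the stand-in for unbiased (neutral-replica-like) sampling of
  a known landscape, used to validate the Boltzmann-inversion estimator;
* toy structure/ion ensembles with controllable native-HB content,
  compactness and deliberately placed bridging / bound / free cations;
* rate models with exactly prescribed transition rates for validating the
  kinetic Monte Carlo and mean-first-passage machinery.

All generators are pure functions of (spec, seed): the same seed gives
bit-identical output.  Ground-truth labels are returned as a sidecar object
(and serialised to JSON, never embedded in the PDB), so the analysis path
cannot accidentally read them.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import HBondId
from .errors import ConfigError, EmptyInputError, FelscapeError
from .frames import KB, CVSeries, StructureFrame


# ----------------------------------------------------------------------
# analytic potentials + Metropolis sampling
# ----------------------------------------------------------------------
@dataclass
class AnalyticPotential:
    """Sum of Gaussian wells U(s) = -sum_k A_k exp(-|s-mu_k|^2 / (2 sigma_k^2)).

    amplitudes are in kJ/mol; centers/widths in CV units; ``domain`` is the
    sampling box, one (lo, hi) per dimension.
    """

    amplitudes: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    domain: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] != len(self.amplitudes):
            self.centers = self.centers.T
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        self.domain = np.atleast_2d(np.asarray(self.domain, dtype=float))
        if len(self.amplitudes) < 1:
            raise ConfigError("potential needs >= 1 well")
        if (self.sigmas <= 0).any():
            raise ConfigError("well widths must be > 0")
        if self.dimension not in (1, 2):
            raise ConfigError("potential dimension must be 1 or 2")

    @property
    def dimension(self) -> int:
        return self.domain.shape[0]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """U at an (n, d) or (n,) array of points, in kJ/mol."""
        x = np.asarray(points, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        d2 = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return -(self.amplitudes[None, :]
                 * np.exp(-d2 / (2.0 * self.sigmas[None, :] ** 2))).sum(axis=1)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)


def double_well_1d(
    depth_a: float = 6.0,
    depth_b: float = 5.0,
    separation: float = 1.6,
    sigma: float = 0.35,
    domain: tuple[float, float] = (-2.0, 2.0),
) -> AnalyticPotential:
    """Convenience 1D double well with wells at +-separation/2."""
    h = separation / 2.0
    return AnalyticPotential(
        amplitudes=[depth_a, depth_b],
        centers=[[-h], [h]],
        sigmas=[sigma, sigma],
        domain=[domain],
    )


def sample_metropolis(
    potential: AnalyticPotential,
    temperature: float,
    n_steps: int,
    step_size: float,
    seed: int,
    x0: np.ndarray | None = None,
    cv_names: list[str] | None = None,
) -> CVSeries:
    """Metropolis Monte Carlo chain with stationary density exp(-U / k_B T).

    Proposals are uniform displacements of +-step_size per dimension;
    proposals outside the domain box are rejected (the chain stays put),
    which preserves detailed balance w.r.t. the density restricted to the
    box.  Time is the step index (one "ps" per step by convention).
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    if step_size <= 0:
        raise ConfigError("step_size must be > 0")
    dim = potential.dimension
    lo, hi = potential.domain[:, 0], potential.domain[:, 1]
    x = np.asarray(x0, dtype=float) if x0 is not None else 0.5 * (lo + hi)
    x = np.atleast_1d(x)
    u = float(potential.evaluate(x[None, :])[0])
    if not np.isfinite(u):
        raise FelscapeError("potential is not finite at the start point")

    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    out = np.empty((n_steps, dim))

    if dim == 1:
        # scalar fast path: the chain is inherently sequential, so avoid
        # per-step numpy overhead
        amps = [float(a) for a in potential.amplitudes]
        mus = [float(m) for m in potential.centers[:, 0]]
        inv2s2 = [1.0 / (2.0 * float(s) ** 2) for s in potential.sigmas]

        def u_of(z: float) -> float:
            return -sum(a * math.exp(-((z - m) ** 2) * c)
                        for a, m, c in zip(amps, mus, inv2s2))

        xi = float(x[0])
        ui = u_of(xi)
        props = rng.uniform(-step_size, step_size, size=n_steps)
        accs = rng.random(n_steps)
        lo0, hi0 = float(lo[0]), float(hi[0])
        col = out[:, 0]
        for i in range(n_steps):
            z = xi + props[i]
            if lo0 <= z <= hi0:
                uz = u_of(z)
                if uz <= ui or accs[i] < math.exp(-beta * (uz - ui)):
                    xi, ui = z, uz
            col[i] = xi
    else:
        props = rng.uniform(-step_size, step_size, size=(n_steps, dim))
        accs = rng.random(n_steps)
        for i in range(n_steps):
            z = x + props[i]
            if ((z >= lo) & (z <= hi)).all():
                uz = float(potential.evaluate(z[None, :])[0])
                if uz <= u or accs[i] < math.exp(-beta * (uz - u)):
                    x, u = z, uz
            out[i] = x

    names = cv_names or [f"s{i + 1}" for i in range(dim)]
    data = pd.DataFrame({n: out[:, i] for i, n in enumerate(names)})
    return CVSeries(np.arange(n_steps, dtype=float), data)


# ----------------------------------------------------------------------
# toy structure/ion ensembles
# ----------------------------------------------------------------------
@dataclass
class CationPlacement:
    """One cation per frame: 'bridging' (i, j), 'bound' (i,), or 'free'.

    With probability < 1 the placement is realised per frame by a Bernoulli
    draw and the cation floats free otherwise.
    """

    kind: str
    residues: tuple[int, ...] = ()
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("bridging", "bound", "free"):
            raise ConfigError(f"unknown cation placement kind {self.kind!r}")
        need = {"bridging": 2, "bound": 1, "free": 0}[self.kind]
        if len(self.residues) != need:
            raise ConfigError(f"{self.kind} placement needs {need} residue(s)")
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigError("placement probability must be in [0, 1]")


@dataclass
class ToyEnsembleSpec:
    """Specification of a toy nucleotide ensemble with known ground truth.

    Each nucleotide is a 3-pseudo-atom residue (backbone bead BB, donor DON,
    acceptor ACC) laid out on a ring of circumference n * spacing *
    compactness -- the minimum structure that exercises HB detection, Rg,
    RMSD and the ion logic.  An HB pair (i, j) listed with probability p is
    geometrically formed (donor moved to 0.28 nm of the acceptor) in an
    independent Bernoulli(p) draw per frame.
    """

    n_nucleotides: int
    n_frames: int
    hb_probabilities: dict[tuple[int, int], float] = field(default_factory=dict)
    compactness: float = 1.0
    spacing: float = 1.0  # nm between adjacent backbone beads
    noise: float = 0.0  # per-atom Gaussian jitter, nm
    cations: list[CationPlacement] = field(default_factory=list)
    seed: int = 0
    frozen_geometry: bool = False
    ion_cutoff: float = 0.4  # nm; bridging geometry is built against this
    min_bridge_separation: int = 4

    def __post_init__(self) -> None:
        self.hb_probabilities = {
            (int(i), int(j)): float(p)
            for (i, j), p in self.hb_probabilities.items()
        }
        for (i, j), p in self.hb_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"HB probability for {(i, j)} outside [0, 1]")
            if not (1 <= i <= self.n_nucleotides and 1 <= j <= self.n_nucleotides):
                raise ConfigError(f"HB pair {(i, j)} outside sequence range")
        self.cations = [
            c if isinstance(c, CationPlacement) else CationPlacement(**c)
            for c in self.cations
        ]
        for c in self.cations:
            if c.kind == "bridging":
                i, j = c.residues
                if abs(i - j) < self.min_bridge_separation:
                    raise ConfigError(
                        f"bridging pair {c.residues} closer than "
                        f"{self.min_bridge_separation} nucleotides in sequence"
                    )

    @property
    def native_hb_list(self) -> list[HBondId]:
        return [HBondId(i, j, "DON", "ACC") for (i, j) in self.hb_probabilities]


@dataclass
class ToyGroundTruth:
    """Sidecar ground-truth labels for a generated toy ensemble."""

    formed_pairs: list[list[tuple[int, int]]]
    cation_roles: list[list[dict]]
    moved_residues: list[tuple[int, int]]  # (bridging anchor, moved residue)

    @property
    def n_bridging(self) -> np.ndarray:
        return np.array(
            [sum(1 for c in roles if c["kind"] == "bridging" and c["active"])
             for roles in self.cation_roles]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "formed_pairs": [[list(p) for p in fp] for fp in self.formed_pairs],
            "cation_roles": self.cation_roles,
            "moved_residues": [list(m) for m in self.moved_residues],
        }
        Path(path).write_text(json.dumps(payload))


def generate_toy_ensemble(
    spec: ToyEnsembleSpec, seed: int | None = None
) -> tuple[list[StructureFrame], ToyGroundTruth]:
    """Generate frames plus ground-truth labels for a ToyEnsembleSpec."""
    if spec.n_frames < 1 or spec.n_nucleotides < 1:
        raise EmptyInputError("spec requests an empty ensemble")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_nucleotides
    radius = spec.spacing * n / (2.0 * np.pi) * spec.compactness
    theta = 2.0 * np.pi * np.arange(n) / n
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    tangent = np.stack([-np.sin(theta), np.cos(theta), np.zeros(n)], axis=1)
    bb0 = radius * radial
    don0 = bb0 - 0.12 * radial
    acc0 = bb0 + 0.12 * tangent

    # residues relocated once so that a bridging midpoint ion can reach both
    moved: list[tuple[int, int]] = []
    bb = bb0.copy()
    offsets_used = 0
    for c in spec.cations:
        if c.kind != "bridging":
            continue
        i, j = c.residues
        gap = np.linalg.norm(bb[i - 1] - bb[j - 1])
        if gap > 2.0 * spec.ion_cutoff - 0.05:
            if spec.frozen_geometry:
                raise FelscapeError(
                    f"bridging residues {i},{j} are {gap:.2f} nm apart; a "
                    f"midpoint ion cannot reach both within "
                    f"{spec.ion_cutoff} nm (frozen geometry)"
                )
            phi = 2.399963 * offsets_used  # golden angle decollision
            offsets_used += 1
            direction = np.array([np.cos(phi), np.sin(phi), 1.0])
            direction /= np.linalg.norm(direction)
            shift = bb[i - 1] + 0.7 * direction - bb[j - 1]
            bb[j - 1] += shift
            don0[j - 1] += shift
            acc0[j - 1] += shift
            moved.append((i, j))

    atom_names = np.array(["BB", "DON", "ACC"] * n, dtype=object)
    residue_ids = np.repeat(np.arange(1, n + 1), 3)
    residue_names = np.array(["TOY"] * (3 * n), dtype=object)

    pairs = list(spec.hb_probabilities)
    probs = np.array([spec.hb_probabilities[p] for p in pairs])

    frames: list[StructureFrame] = []
    formed_all: list[list[tuple[int, int]]] = []
    roles_all: list[list[dict]] = []
    for _ in range(spec.n_frames):
        bbf, donf, accf = bb.copy(), don0.copy(), acc0.copy()
        draws = rng.random(len(pairs)) < probs if pairs else np.empty(0, bool)
        formed = []
        for (pair, on) in zip(pairs, draws):
            if not on:
                continue
            i, j = pair
            direction = bbf[i - 1] - accf[j - 1]
            direction /= np.linalg.norm(direction)
            donf[i - 1] = accf[j - 1] + 0.28 * direction
            formed.append(pair)

        cat_coords, roles = [], []
        free_slot = 0
        for c in spec.cations:
            placed = c.kind != "free" and bool(rng.random() < c.probability)
            roles.append(
                {"kind": c.kind, "residues": list(c.residues), "active": placed}
            )
            if not placed:  # floats far (> 2x cutoff) above the ring plane
                cat_coords.append(np.array([0.0, 0.0, 2.0 + 0.5 * free_slot]))
                free_slot += 1
            elif c.kind == "bound":
                (i,) = c.residues
                cat_coords.append(bbf[i - 1] + np.array([0.0, 0.0, 0.3]))
            else:  # bridging: midpoint reaches both residues within cutoff
                i, j = c.residues
                cat_coords.append(0.5 * (bbf[i - 1] + bbf[j - 1]))

        coords = np.empty((3 * n, 3))
        coords[0::3], coords[1::3], coords[2::3] = bbf, donf, accf
        if spec.noise > 0:
            coords = coords + rng.normal(0.0, spec.noise, size=coords.shape)
        frames.append(
            StructureFrame(
                atom_names=atom_names,
                residue_ids=residue_ids,
                coords=coords,
                residue_names=residue_names,
                cation_names=np.array(["NA"] * len(cat_coords), dtype=object),
                cation_coords=(np.array(cat_coords).reshape(-1, 3)
                               if cat_coords else np.empty((0, 3))),
            )
        )
        formed_all.append(formed)
        roles_all.append(roles)

    return frames, ToyGroundTruth(formed_all, roles_all, moved)


# ----------------------------------------------------------------------
# rate models with known rates
# ----------------------------------------------------------------------
def generate_known_rate_model(
    n_states: int,
    rates: dict[tuple[int, int], float],
    seed: int = 0,
    require_connected: bool = False,
):
    """RateModel with exactly the given pairwise rates (ps^-1, 0-based states).

    ``seed`` is stored for downstream KMC defaults; the construction itself
    is deterministic.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    from .kinetics import RateModel

    rows, cols, vals = [], [], []
    for (i, j), k in rates.items():
        if i == j:
            raise ConfigError("self-rates are not allowed")
        if k < 0:
            raise ConfigError("rates must be >= 0")
        if not (0 <= i < n_states and 0 <= j < n_states):
            raise ConfigError(f"state pair {(i, j)} outside range")
        if k > 0:
            rows.append(i), cols.append(j), vals.append(float(k))
    mat = csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    n_comp, _ = connected_components(mat, directed=True, connection="weak")
    if n_comp > 1 and require_connected:
        warnings.warn(
            f"rate model has {n_comp} disconnected components", stacklevel=2
        )
    return RateModel(rates=mat, temperature=300.0, seed=seed)
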