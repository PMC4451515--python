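"""Free-energy surfaces from CV histograms, convergence checks, basins.

The landscape estimator is the Boltzmann inversion of the sampled CV
histogram,

    F(s) = -k_B T ln P(s),

with P the normalised occupancy of each bin and the surface shifted so the
lowest occupied bin sits at F = 0.  Bins with zero samples carry F = +inf
(the logarithm is undefined there) and are excluded from every norm.  The
statistical error of a bin with n samples is roughly k_B T / sqrt(n), which
motivates the default >= 100-sample occupancy threshold used whenever an
estimated surface is compared against a reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyInputError
from .frames import KB, CVSeries


@dataclass
class FreeEnergySurface:
    """Binned grid over 1-2 CVs holding F(s) in kJ/mol at temperature T."""

    cv_names: list[str]
    edges: list[np.ndarray]
    F: np.ndarray
    temperature: float
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        self.F = np.asarray(self.F, dtype=float)
        if len(self.cv_names) not in (1, 2):
            raise ConfigError("surfaces are defined over 1 or 2 CVs")
        expected = tuple(len(e) - 1 for e in self.edges)
        if self.F.shape != expected:
            raise ValueError(f"F shape {self.F.shape} != grid shape {expected}")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - self.F[finite].min()  # min-shift gauge

    @property
    def ndim(self) -> int:
        return len(self.cv_names)

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.F)

    def center_grid(self) -> np.ndarray:
        """(n_bins, ndim) array of all bin-center coordinates."""
        mesh = np.meshgrid(*self.centers, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    @classmethod
    def from_potential(
        cls,
        potential,
        edges: list[np.ndarray],
        temperature: float,
        cv_names: list[str] | None = None,
    ) -> "FreeEnergySurface":
        """Exact surface of an analytic potential, evaluated at bin centers."""
        edges = [np.asarray(e, dtype=float) for e in edges]
        names = cv_names or [f"s{i + 1}" for i in range(len(edges))]
        centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
        mesh = np.meshgrid(*centers, indexing="ij")
        points = np.stack([m.ravel() for m in mesh], axis=1)
        U = np.asarray(potential(points) if callable(potential)
                       else potential.evaluate(points), dtype=float)
        F = U.reshape(tuple(len(c) for c in centers))
        return cls(names, edges, F - F.min(), temperature,
                   counts=np.ones_like(F, dtype=int))


def estimate_fel(
    series: CVSeries,
    cv_names: list[str],
    bin_edges: dict[str, np.ndarray] | list[np.ndarray],
    temperature: float = 300.0,
) -> FreeEnergySurface:
    """Histogram free-energy estimate F = -k_B T ln P over 1-2 CVs."""
    if isinstance(bin_edges, dict):
        edges = [np.asarray(bin_edges[n], dtype=float) for n in cv_names]
    else:
        edges = [np.asarray(e, dtype=float) for e in bin_edges]
    values = series.values(cv_names)
    counts, _ = np.histogramdd(values, bins=edges)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("all samples fall outside the binned domain")
    with np.errstate(divide="ignore"):
        F = -KB * temperature * np.log(counts / total)
    return FreeEnergySurface(list(cv_names), edges, F, temperature,
                             counts=counts.astype(int))


def auto_edges(
    series: CVSeries, cv_names: list[str], widths: dict[str, float]
) -> dict[str, np.ndarray]:
    """Uniform bin edges covering each CV's sampled range at the given width.

    Integer-count CVs conventionally get width 1 (one bin per HB count);
    lengths like Rg get 0.05 nm.
    """
    out = {}
    for name in cv_names:
        v = series[name]
        w = widths[name]
        lo = np.floor(v.min() / w) * w - 0.5 * w
        hi = np.ceil(v.max() / w) * w + 0.5 * w
        out[name] = np.arange(lo, hi + 0.5 * w, w)
    return out


# ----------------------------------------------------------------------
@dataclass
class ConvergenceWindow:
    fraction_range: tuple[float, float]
    rms_divergence: float
    surface: FreeEnergySurface


@dataclass
class ConvergenceResult:
    divergence: float  # max over windows of RMS |F_window - F_full|
    windows: list[ConvergenceWindow] = field(default_factory=list)


def fel_convergence(
    series: CVSeries,
    split_fractions: list[float],
    cv_names: list[str],
    bin_edges: dict[str, np.ndarray] | list[np.ndarray],
    temperature: float = 300.0,
    f_cap: float = np.inf,
    min_count: int = 100,
) -> ConvergenceResult:
    """Compare per-window surfaces against the full-series surface.

    ``split_fractions`` are interior cut points in (0, 1); windows are the
    intervals between consecutive cuts (0 and 1 included).  The divergence of
    a window is the RMS |F_window - F_full| over bins occupied by at least
    ``min_count`` samples in both and with F_full below ``f_cap``.  A
    monotone decrease is reported, never assumed.
    """
    cuts = sorted(set([0.0, 1.0] + [float(f) for f in split_fractions]))
    if len(cuts) < 3:
        raise ConfigError("need >= 1 interior split fraction")
    full = estimate_fel(series, cv_names, bin_edges, temperature)
    result = ConvergenceResult(divergence=0.0)
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        try:
            sub = series.window(lo, hi)
            surf = estimate_fel(sub, cv_names, bin_edges, temperature)
        except EmptyInputError:
            warnings.warn(f"window [{lo}, {hi}) has no samples; skipped",
                          stacklevel=2)
            continue
        mask = (
            (full.counts >= min_count)
            & (surf.counts >= min_count)
            & (full.F < f_cap)
        )
        if not mask.any():
            warnings.warn(
                f"window [{lo}, {hi}): no co-occupied bins above threshold",
                stacklevel=2,
            )
            continue
        rms = float(np.sqrt(np.mean((surf.F[mask] - full.F[mask]) ** 2)))
        result.windows.append(ConvergenceWindow((lo, hi), rms, surf))
        result.divergence = max(result.divergence, rms)
    return result


def rms_vs_reference(
    surface: FreeEnergySurface,
    reference: np.ndarray,
    min_count: int = 100,
) -> float:
    """RMS |F_est - (U_ref - min U_ref)| over bins with >= min_count samples.

    ``reference`` is the reference potential evaluated on the surface's bin
    centers (same shape as ``surface.F``), e.g. the ground-truth well the
    samples were drawn from.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != surface.F.shape:
        raise ValueError("reference grid shape mismatch")
    ref = ref - ref.min()
    if surface.counts is None:
        raise ValueError("surface carries no sample counts")
    mask = surface.counts >= min_count
    if not mask.any():
        raise EmptyInputError("no bins above the occupancy threshold")
    return float(np.sqrt(np.mean((surface.F[mask] - ref[mask]) ** 2)))


# ----------------------------------------------------------------------
@dataclass
class BasinSet:
    """Named axis-aligned rectangles in CV space (pairwise disjoint)."""

    basins: dict[str, dict[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        from .config import _check_disjoint

        _check_disjoint(self.basins)

    @property
    def labels(self) -> list[str]:
        return list(self.basins)

    def contains(self, name: str, point: dict[str, float]) -> bool:
        rect = self.basins[name]
        return all(lo <= point[cv] < hi for cv, (lo, hi) in rect.items())


TRANSITION_LABEL = "transition"


def assign_basins(series: CVSeries, basins: BasinSet | dict) -> np.ndarray:
    """Label each frame with its containing basin, or 'transition' if none."""
    if not isinstance(basins, BasinSet):
        basins = BasinSet(basins)
    labels = np.full(len(series), TRANSITION_LABEL, dtype=object)
    for name, rect in basins.basins.items():
        inside = np.ones(len(series), dtype=bool)
        for cv, (lo, hi) in rect.items():
            v = series[cv]
            inside &= (v >= lo) & (v < hi)
        labels[inside] = name
    return labels
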