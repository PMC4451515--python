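"""FEL-discretized Markov state model, kinetic Monte Carlo, folding kinetics.

The kinetic model lives on the occupied bins of a free-energy surface.  With
a position-independent diffusion constant D along each CV (a deliberate,
rough approximation carried over from the source analysis), grid neighbours
i -> j are connected with the discretized-Smoluchowski rate

    k_ij = (D / ds^2) * exp(-(F_j - F_i) / (2 k_B T)),

which satisfies detailed balance w.r.t. the Boltzmann weights of the surface
exactly (a Metropolis-type convention min(1, exp(-dF/kT)) is available).
Kinetics are then obtained by Gillespie simulation of the jump process
(kinetic Monte Carlo), by direct linear-algebra mean-first-passage-time
solves, and by single-exponential fits to the fraction of folded
trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.sparse import csr_matrix, csc_matrix, diags
from scipy.sparse.csgraph import breadth_first_order, connected_components
from scipy.sparse.linalg import spsolve

from .errors import ConfigError, EmptyInputError, FelscapeError
from .frames import KB, CVSeries
from .fel import FreeEnergySurface


# ----------------------------------------------------------------------
# rate model
# ----------------------------------------------------------------------
@dataclass
class RateModel:
    """Discrete states with pairwise rates (ps^-1).

    ``free_energies`` (kJ/mol) are carried when the model was built from a
    surface; the stationary distribution is then the Boltzmann distribution
    exp(-F/kT)/Z.  For models given by raw rates the stationary distribution
    is computed from the generator's null space.
    """

    rates: csr_matrix
    temperature: float = 300.0
    free_energies: np.ndarray | None = None
    state_coords: np.ndarray | None = None
    state_labels: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.rates = csr_matrix(self.rates)
        if (self.rates.data < 0).any():
            raise ConfigError("rates must be >= 0")
        if self.free_energies is not None:
            self.free_energies = np.asarray(self.free_energies, dtype=float)

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def exit_rates(self) -> np.ndarray:
        return np.asarray(self.rates.sum(axis=1)).ravel()

    def generator(self) -> csr_matrix:
        """Infinitesimal generator Q (rows sum to zero)."""
        return (self.rates - diags(self.exit_rates)).tocsr()

    def stationary_distribution(self) -> np.ndarray:
        if self.free_energies is not None:
            w = np.exp(-(self.free_energies - self.free_energies.min())
                       / (KB * self.temperature))
            return w / w.sum()
        q = self.generator().toarray()
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()

    def detailed_balance_violation(self) -> float:
        """Max relative pairwise flux imbalance |pi_i k_ij - pi_j k_ji|."""
        pi = self.stationary_distribution()
        coo = self.rates.tocoo()
        worst = 0.0
        rates_dense = {}
        for i, j, k in zip(coo.row, coo.col, coo.data):
            rates_dense[(int(i), int(j))] = float(k)
        for (i, j), k in rates_dense.items():
            if i >= j:
                continue
            f_ij = pi[i] * k
            f_ji = pi[j] * rates_dense.get((j, i), 0.0)
            scale = max(f_ij, f_ji)
            if scale > 0:
                worst = max(worst, abs(f_ij - f_ji) / scale)
        return worst

    def components(self) -> tuple[int, np.ndarray]:
        return connected_components(self.rates, directed=True, connection="weak")


def build_rate_model(
    surface: FreeEnergySurface,
    D: float | dict[str, float],
    convention: str = "half",
    folded_states: np.ndarray | None = None,
    unfolded_states: np.ndarray | None = None,
) -> RateModel:
    """Rate model on the occupied bins of a surface with diffusive rates.

    ``D`` is the diffusion constant in (CV unit)^2/ps, either one scalar or
    one value per CV name (the axes of a 2D surface generally carry
    different units).  Neighbours are von-Neumann (4-neighbour in 2D).
    ``folded_states``/``unfolded_states`` (state-index arrays) trigger a
    connectivity check between the two regions.
    """
    occupied = surface.occupied
    if surface.counts is not None:
        occupied = occupied & (np.asarray(surface.counts) > 0)
    n_occ = int(occupied.sum())
    if n_occ < 2:
        raise EmptyInputError("surface has fewer than 2 occupied bins")

    widths = []
    for name, e in zip(surface.cv_names, surface.edges):
        w = np.diff(e)
        if not np.allclose(w, w[0], rtol=1e-9):
            raise ConfigError(f"non-uniform bin widths on axis {name!r}")
        widths.append(float(w[0]))
    if np.isscalar(D):
        d_axis = [float(D)] * surface.ndim
    else:
        d_axis = [float(D[name]) for name in surface.cv_names]

    grid_to_state = np.full(surface.F.shape, -1, dtype=int)
    grid_idx = np.argwhere(occupied)
    for s, idx in enumerate(grid_idx):
        grid_to_state[tuple(idx)] = s
    F_states = surface.F[occupied]
    beta = 1.0 / (KB * surface.temperature)

    rows, cols, vals = [], [], []
    for axis in range(surface.ndim):
        base = d_axis[axis] / widths[axis] ** 2
        for s, idx in enumerate(grid_idx):
            nb = idx.copy()
            nb[axis] += 1
            if nb[axis] >= surface.F.shape[axis]:
                continue
            t = grid_to_state[tuple(nb)]
            if t < 0:
                continue
            df = F_states[t] - F_states[s]
            if convention == "half":
                k_fwd = base * np.exp(-0.5 * beta * df)
                k_bwd = base * np.exp(+0.5 * beta * df)
            elif convention == "metropolis":
                k_fwd = base * min(1.0, np.exp(-beta * df))
                k_bwd = base * min(1.0, np.exp(+beta * df))
            else:
                raise ConfigError(f"unknown rate convention {convention!r}")
            rows += [s, t]
            cols += [t, s]
            vals += [k_fwd, k_bwd]

    centers = surface.center_grid()[occupied.ravel()]
    model = RateModel(
        rates=csr_matrix((vals, (rows, cols)), shape=(n_occ, n_occ)),
        temperature=surface.temperature,
        free_energies=F_states,
        state_coords=centers,
        state_labels=[tuple(int(i) for i in idx) for idx in grid_idx],
    )
    n_comp, comp = model.components()
    if n_comp > 1:
        warnings.warn(
            f"occupied bins form {n_comp} disconnected components",
            stacklevel=2,
        )
    if folded_states is not None and unfolded_states is not None:
        cf = set(comp[np.asarray(folded_states, dtype=int)])
        cu = set(comp[np.asarray(unfolded_states, dtype=int)])
        if not cf & cu:
            raise FelscapeError(
                f"folded and unfolded regions are disconnected: "
                f"components {sorted(cf)} vs {sorted(cu)}"
            )
    return model


# ----------------------------------------------------------------------
# diffusion constant from CV series
# ----------------------------------------------------------------------
@dataclass
class DiffusionResult:
    table: pd.DataFrame  # columns: lag_ps, D_<cv> ...
    plateau: dict[str, float]  # mean D over the plateau window, per CV
    plateau_ok: dict[str, bool]  # False when D(tau) keeps drifting (no plateau)


def estimate_diffusion(
    series: CVSeries,
    lag_times: list[int],
    plateau_window: tuple[int, int] | None = None,
    spread_tolerance: float = 0.25,
) -> DiffusionResult:
    """D(tau) = <(s(t+tau) - s(t))^2> / (2 tau) per CV, plus a plateau mean.

    ``lag_times`` are in frames; the conversion to ps uses the series' time
    step.  The plateau estimate averages D over ``plateau_window`` (defaults
    to the second half of the lag ladder); a relative spread above
    ``spread_tolerance`` within the window flags the absence of a plateau
    (e.g. deterministic drift, where D(tau) grows linearly).
    """
    lags = sorted(int(l) for l in lag_times)
    if not lags or lags[0] < 1:
        raise ConfigError("lag times must be >= 1 frame")
    if lags[-1] >= len(series):
        raise ConfigError("largest lag reaches beyond the series length")
    dt = float(np.median(np.diff(series.time))) if len(series) > 1 else 1.0
    rows = {"lag_ps": [l * dt for l in lags]}
    for name in series.names:
        s = series[name]
        rows[f"D_{name}"] = [
            float(np.mean((s[l:] - s[:-l]) ** 2) / (2.0 * l * dt)) for l in lags
        ]
    table = pd.DataFrame(rows)
    if plateau_window is None:
        start = len(lags) // 2
        window = np.arange(start, len(lags))
    else:
        window = np.nonzero(
            (np.array(lags) >= plateau_window[0])
            & (np.array(lags) <= plateau_window[1])
        )[0]
        if len(window) == 0:
            raise ConfigError("plateau window contains no lags")
    plateau, ok = {}, {}
    for name in series.names:
        d = np.array(rows[f"D_{name}"])[window]
        mean = float(d.mean())
        plateau[name] = mean
        spread = float((d.max() - d.min()) / mean) if mean > 0 else 0.0
        ok[name] = spread <= spread_tolerance
    return DiffusionResult(table, plateau, ok)


# ----------------------------------------------------------------------
# kinetic Monte Carlo (Gillespie)
# ----------------------------------------------------------------------
@dataclass
class Trajectory:
    states: np.ndarray  # visited states, states[0] at t = 0
    times: np.ndarray  # arrival times (ps), times[0] = 0
    t_max: float


def _start_chooser(start_states, rng, size):
    start = np.atleast_1d(np.asarray(start_states))
    if start.ndim == 1 and start.dtype.kind in "iu":
        return rng.choice(start, size=size)
    raise ConfigError("start_states must be an int or an array of state indices")


def kmc_simulate(
    model: RateModel,
    start_states,
    n_traj: int,
    t_max: float,
    seed: int | None = None,
) -> list[Trajectory]:
    """Gillespie simulation: dwell ~ Exp(sum_j k_ij), next state ~ k_ij.

    One global seed spawns independent per-trajectory substreams, so
    enlarging ``n_traj`` never reshuffles earlier trajectories.
    """
    if n_traj < 1:
        raise ConfigError("n_traj must be >= 1")
    if not np.isfinite(t_max) or t_max <= 0:
        raise ConfigError("t_max must be finite and > 0")
    seed = model.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(n_traj)
    exit_rates = model.exit_rates
    rates = model.rates
    out = []
    for k in range(n_traj):
        rng = np.random.default_rng(streams[k])
        s = int(_start_chooser(start_states, rng, 1)[0])
        states, times = [s], [0.0]
        t = 0.0
        while True:
            kout = exit_rates[s]
            if kout <= 0:  # absorbing: dwell until t_max
                break
            t += rng.standard_exponential() / kout
            if t > t_max:
                break
            row = rates.getrow(s)
            s = int(rng.choice(row.indices, p=row.data / kout))
            states.append(s)
            times.append(t)
        out.append(Trajectory(np.array(states), np.array(times), t_max))
    return out


def _padded_transition_tables(model: RateModel):
    """Per-state cumulative jump probabilities, padded to equal row length."""
    rates = model.rates
    exit_rates = model.exit_rates
    n = model.n_states
    nnz = np.diff(rates.indptr)
    m = max(1, int(nnz.max()))
    cum = np.ones((n, m))
    idx = np.zeros((n, m), dtype=int)
    for s in range(n):
        lo, hi = rates.indptr[s], rates.indptr[s + 1]
        if hi == lo:
            continue
        p = rates.data[lo:hi] / exit_rates[s]
        cum[s, : hi - lo] = np.cumsum(p)
        cum[s, hi - lo - 1] = 1.0 + 1e-12  # guard against rounding
        idx[s, : hi - lo] = rates.indices[lo:hi]
        idx[s, hi - lo :] = rates.indices[hi - 1]
    return cum, idx


def kmc_first_passage_times(
    model: RateModel,
    start_states,
    target_states,
    n_traj: int,
    seed: int,
    t_max: float = np.inf,
    max_jumps: int = 2_000_000,
) -> np.ndarray:
    """First-passage times into the target set for an ensemble of walkers.

    Vectorized synchronous stepping of all walkers (statistically identical
    to per-trajectory Gillespie); trajectories that never arrive within
    ``t_max``/``max_jumps`` report +inf.
    """
    rng = np.random.default_rng(seed)
    targets = np.zeros(model.n_states, dtype=bool)
    targets[np.asarray(target_states, dtype=int)] = True
    exit_rates = model.exit_rates
    cum, idx = _padded_transition_tables(model)

    state = _start_chooser(start_states, rng, n_traj).astype(int)
    t = np.zeros(n_traj)
    fpt = np.full(n_traj, np.inf)
    fpt[targets[state]] = 0.0
    active = ~targets[state]

    for _ in range(max_jumps):
        if not active.any():
            break
        s = state[active]
        stuck = exit_rates[s] <= 0
        if stuck.any():  # absorbing non-target states never arrive
            act_idx = np.nonzero(active)[0]
            active[act_idx[stuck]] = False
            s = state[active]
            if s.size == 0:
                break
        dwell = rng.standard_exponential(s.size) / exit_rates[s]
        u = rng.random(s.size)
        col = (u[:, None] >= cum[s]).sum(axis=1)
        nxt = idx[s, col]
        act_idx = np.nonzero(active)[0]
        t[act_idx] += dwell
        state[act_idx] = nxt
        arrived = targets[nxt] & (t[act_idx] <= t_max)
        fpt[act_idx[arrived]] = t[act_idx[arrived]]
        done = arrived | (t[act_idx] > t_max)
        active[act_idx[done]] = False
    else:
        warnings.warn("max_jumps exhausted before all walkers finished",
                      stacklevel=2)
    return fpt


def kmc_occupancy(
    model: RateModel,
    start_state: int,
    n_jumps: int,
    seed: int,
) -> np.ndarray:
    """Time-weighted state occupancy of one long KMC trajectory.

    Converges to the model's stationary (Boltzmann) distribution as the jump
    count grows.
    """
    rng = np.random.default_rng(seed)
    cum, idx = _padded_transition_tables(model)
    exit_rates = model.exit_rates
    seq = np.empty(n_jumps + 1, dtype=int)
    seq[0] = int(start_state)
    uniforms = rng.random(n_jumps)
    s = int(start_state)
    for i in range(n_jumps):
        if exit_rates[s] <= 0:
            seq[i + 1 :] = s
            break
        col = int(np.searchsorted(cum[s], uniforms[i], side="right"))
        s = int(idx[s, min(col, idx.shape[1] - 1)])
        seq[i + 1] = s
    dwells = rng.standard_exponential(n_jumps + 1) / np.maximum(
        exit_rates[seq], 1e-300
    )
    occ = np.bincount(seq, weights=dwells, minlength=model.n_states)
    return occ / occ.sum()


# ----------------------------------------------------------------------
# folding kinetics
# ----------------------------------------------------------------------
@dataclass
class FoldingKinetics:
    times: np.ndarray
    fraction_folded: np.ndarray
    rate: float | None  # per ps; None when no trajectory ever folds
    residual: float | None  # RMS of the single-exponential fit
    n_folded: int
    n_traj: int
    first_passage_times: np.ndarray = field(repr=False, default=None)


def first_passage_time(traj: Trajectory, folded_states) -> float:
    folded = np.isin(traj.states, np.asarray(folded_states, dtype=int))
    hits = np.nonzero(folded)[0]
    return float(traj.times[hits[0]]) if hits.size else np.inf


def fit_single_exponential(
    times: np.ndarray, fraction: np.ndarray
) -> tuple[float, float]:
    """Least-squares fit of f(t) = 1 - exp(-k t); returns (k, RMS residual)."""
    times = np.asarray(times, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    pos = fraction[(fraction > 0) & (fraction < 1)]
    k0 = 1.0 / np.median(times[times > 0]) if (times > 0).any() else 1.0
    (k,), _ = curve_fit(
        lambda t, k: 1.0 - np.exp(-k * t), times, fraction,
        p0=[k0], bounds=(0.0, np.inf), maxfev=10000,
    )
    resid = float(np.sqrt(np.mean((1.0 - np.exp(-k * times) - fraction) ** 2)))
    return float(k), resid


def folding_kinetics(
    trajectories,
    folded_states=None,
    time_grid: np.ndarray | None = None,
    n_grid: int = 200,
) -> FoldingKinetics:
    """Ensemble folding curve and single-exponential rate.

    ``trajectories`` is either a list of KMC trajectories (then
    ``folded_states`` designates the folded basin and the first entry into
    it defines folding -- first-passage accounting, so the curve is
    non-decreasing) or a precomputed array of first-passage times.  The
    fitted rate is reported with its RMS residual; a visibly larger residual
    than the two-state case is the multi-exponential signature and is
    reported, not hidden.
    """
    if isinstance(trajectories, np.ndarray):
        fpts = np.asarray(trajectories, dtype=float)
    else:
        if folded_states is None:
            raise ConfigError("folded_states required with trajectory input")
        fpts = np.array(
            [first_passage_time(tr, folded_states) for tr in trajectories]
        )
    n_traj = len(fpts)
    finite = fpts[np.isfinite(fpts)]
    if finite.size == 0:
        warnings.warn("no trajectory ever folded; rate undefined", stacklevel=2)
        return FoldingKinetics(
            np.empty(0), np.empty(0), None, None, 0, n_traj, fpts
        )
    if time_grid is None:
        horizon = float(np.quantile(finite, 0.98)) * 1.2
        time_grid = np.linspace(0.0, horizon, n_grid)[1:]
    fraction = (fpts[None, :] <= time_grid[:, None]).mean(axis=1)
    rate, resid = fit_single_exponential(time_grid, fraction)
    return FoldingKinetics(
        time_grid, fraction, rate, resid, int(finite.size), n_traj, fpts
    )


# ----------------------------------------------------------------------
# mean first-passage times
# ----------------------------------------------------------------------
def transition_times(
    model: RateModel,
    state_basins: np.ndarray,
    kmc_check: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Basin-to-basin mean first-passage times (ps).

    MFPT(A -> B) is the expected first-passage time into any state of B,
    started from A's equilibrium-weighted states, from the linear system
    Q tau = -1 (tau = 0 on B).  Unreachable targets report +inf with a
    warning.  With ``kmc_check`` > 0 a KMC estimate over that many
    trajectories is computed alongside (columns suffixed ``_kmc``).
    """
    labels = np.asarray(state_basins, dtype=object)
    if len(labels) != model.n_states:
        raise ValueError("state_basins must label every state")
    basins = [b for b in pd.unique(labels) if b is not None]
    pi = model.stationary_distribution()
    q = model.generator().tocsc()

    tau_to = {}
    for b in basins:
        target = labels == b
        tau = np.zeros(model.n_states)
        rest = np.nonzero(~target)[0]
        if rest.size:
            reachable = _reaches(model.rates, target)
            solvable = rest[reachable[rest]]
            unreachable = rest[~reachable[rest]]
            if unreachable.size:
                warnings.warn(
                    f"{unreachable.size} state(s) cannot reach basin {b!r}",
                    stacklevel=2,
                )
                tau[unreachable] = np.inf
            if solvable.size:
                sub = q[np.ix_(solvable, solvable)]
                tau[solvable] = spsolve(csc_matrix(sub), -np.ones(solvable.size))
        tau_to[b] = tau

    rows = []
    for a in basins:
        src = labels == a
        mass = pi[src].sum()
        if mass > 0:
            w = pi[src] / mass
        else:  # zero-equilibrium-weight basin: weight its states uniformly
            w = np.full(int(src.sum()), 1.0 / src.sum())
        row = {"from": a}
        for b in basins:
            row[b] = 0.0 if a == b else float(w @ tau_to[b][src])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("from")

    if kmc_check > 0:
        for a in basins:
            src = np.nonzero(labels == a)[0]
            for b in basins:
                if a == b:
                    continue
                tgt = np.nonzero(labels == b)[0]
                fpts = kmc_first_passage_times(
                    model, src, tgt, kmc_check, seed=seed
                )
                out.loc[a, f"{b}_kmc"] = float(
                    np.mean(fpts[np.isfinite(fpts)])
                ) if np.isfinite(fpts).any() else np.inf
    return out


def _reaches(rates: csr_matrix, target: np.ndarray) -> np.ndarray:
    """Boolean mask of states from which the target set is reachable."""
    rt = rates.T.tocsr()
    seen = target.copy()
    frontier = list(np.nonzero(target)[0])
    while frontier:
        nxt = []
        for s in frontier:
            for j in rt.getrow(s).indices:
                if not seen[j]:
                    seen[j] = True
                    nxt.append(j)
        frontier = nxt
    return seen


def birth_death_mfpt(
    k_up: np.ndarray, k_down: np.ndarray, start: int, end: int
) -> float:
    """Closed-form MFPT for a 1D birth-death chain (nested-sum formula).

    ``k_up[i]`` is the rate i -> i+1, ``k_down[i]`` the rate i+1 -> i.
    """
    k_up = np.asarray(k_up, dtype=float)
    k_down = np.asarray(k_down, dtype=float)
    n = len(k_up) + 1
    if not (0 <= start < n and 0 <= end < n):
        raise ValueError("states outside chain")
    if start == end:
        return 0.0
    if start > end:  # mirror the chain
        return birth_death_mfpt(k_down[::-1], k_up[::-1], n - 1 - start,
                                n - 1 - end)
    pi = np.ones(n)
    for i in range(n - 1):
        pi[i + 1] = pi[i] * k_up[i] / k_down[i]
    total = 0.0
    for j in range(start, end):
        total += pi[: j + 1].sum() / (k_up[j] * pi[j])
    return float(total)
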