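"""Forward Wright–Fisher simulation of the burst-upon-drift (BUD) model.

The model follows a haploid, asexual population of cells.  Each of
``G`` genes in a cell is in one of three viable states —

* ``M``: functional mitochondrial copy only (ancestral),
* ``D``: functional copies in both compartments (intercompartmental
  duplication),
* ``N``: functional nuclear copy only (transfer complete),

— or the gene has no functional copy left, which renders the whole
cell inviable (fitness 0).  Per generation, mutation acts first:

* a mitochondrial gene gains a functional nuclear copy with
  probability ``mu_dup`` (duplication, ``M→D``),
* every functional mitochondrial copy is inactivated with probability
  ``mu_mt`` (``D→N``; ``M→`` inviable),
* every functional nuclear copy is inactivated with probability
  ``mu_nuc`` (``D→M``; ``N→`` inviable).

The three per-copy events are independent within a generation and are
composed (e.g. duplication immediately followed by loss of the
mitochondrial copy yields ``N``), which reproduces the first-order
transitions above exactly for small rates.  Reproduction then draws
the next generation by fitness-weighted multinomial resampling of
whole parental genotypes: mitochondrial and nuclear loci are
co-transmitted, with multiplicative fitness across genes
(``w_M = 1``, ``w_D = 1 − s_dup``, ``w_N = 1 − s_nuc``, clamped at 0).

A *bottleneck* window multiplies ``mu_mt`` by ``bottleneck_mu_factor``
and shrinks the offspring generation to ``N_b`` cells for its
duration — the regime in which slightly deleterious transfers
(``s_nuc > 0`` small) can drift to fixation, several genes at a time.
Setting ``s_nuc < 0`` recovers the adaptive (sweep) path with no
separate code.

Fixation of a gene is recorded the first generation at which every
living cell carries only the nuclear copy; with ``mu_nuc = 0`` this is
absorbing.  Extinction (no living cell) terminates a replicate and is
a recorded outcome, not an error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .rng import RngLike, as_rng

_STATE_CODE = {"M": 0, "D": 1, "N": 2}
_M, _D, _N, _X = 0, 1, 2, 3  # X = inviable (no functional copy)


class BUDError(ValueError):
    pass


@dataclass(frozen=True)
class Bottleneck:
    """Population contraction with optionally elevated mitochondrial
    mutation rate.

    ``start`` is the first offspring generation produced under
    bottleneck conditions; generations ``start .. start+duration-1``
    have size ``n_b`` and use ``mu_mt * mu_factor`` in their mutation
    phase.
    """

    n_b: int
    start: int
    duration: int
    mu_factor: float = 1.0

    def active(self, gen: int) -> bool:
        return self.start <= gen < self.start + self.duration

    def window(self) -> tuple[int, int]:
        return self.start, self.start + self.duration


@dataclass(frozen=True)
class BUDParams:
    """Parameters of one BUD simulation.

    ``initial_counts`` seeds the starting population: a mapping from
    state letter to number of cells whose genes all start in that
    state; remaining cells start in ``initial_state``.
    """

    n_pop: int = 100
    bottleneck: Optional[Bottleneck] = None
    mu_mt: float = 0.0
    mu_nuc: float = 0.0
    mu_dup: float = 0.0
    s_dup: float = 0.0
    s_nuc: float = 0.0
    n_genes: int = 1
    t_max: int = 100
    replicates: int = 1
    seed: int = 0
    initial_state: str = "M"
    initial_counts: Optional[Mapping[str, int]] = None
    record_trajectories: bool = False
    trajectory_thin: int = 1

    def __post_init__(self):
        if self.n_pop < 1:
            raise BUDError("n_pop must be >= 1")
        for name in ("mu_mt", "mu_nuc", "mu_dup"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BUDError(f"{name} must be in [0, 1]")
        if self.bottleneck is not None:
            b = self.bottleneck
            if not 0 < b.n_b <= self.n_pop:
                raise BUDError("bottleneck size must satisfy 0 < N_b <= N")
            if b.duration < 1 or b.start < 0 or b.mu_factor < 0:
                raise BUDError("invalid bottleneck window")
            if not 0.0 <= min(1.0, self.mu_mt * b.mu_factor) <= 1.0:
                raise BUDError("bottleneck-elevated mu_mt out of range")
        if min(self.t_max, self.n_genes, self.replicates) < 1:
            raise BUDError("t_max, n_genes and replicates must be >= 1")
        if self.initial_state not in _STATE_CODE:
            raise BUDError("initial_state must be one of M, D, N")
        if self.initial_counts:
            tot = sum(self.initial_counts.values())
            if tot > self.n_pop:
                raise BUDError("initial_counts exceed population size")
            for s in self.initial_counts:
                if s not in _STATE_CODE:
                    raise BUDError(f"unknown initial state {s!r}")

    @property
    def fitness_by_state(self) -> np.ndarray:
        return np.array(
            [1.0, max(1.0 - self.s_dup, 0.0), max(1.0 - self.s_nuc, 0.0), 0.0]
        )

    def mu_mt_at(self, gen: int) -> float:
        mu = self.mu_mt
        if self.bottleneck is not None and self.bottleneck.active(gen):
            mu = min(mu * self.bottleneck.mu_factor, 1.0)
        return mu

    def size_at(self, gen: int) -> int:
        if gen == 0:
            return self.n_pop
        if self.bottleneck is not None and self.bottleneck.active(gen):
            return self.bottleneck.n_b
        return self.n_pop


@dataclass
class SimulationResult:
    """Outcome of a replicated BUD run."""

    params: BUDParams
    #: first generation at which gene g was fixed N in replicate r; -1 = never
    fixation_gen: np.ndarray  # (replicates, n_genes) int
    #: generation of population extinction per replicate; -1 = survived
    extinct_gen: np.ndarray  # (replicates,) int
    #: optional thinned state-frequency trajectories
    #: shape (replicates, n_records, n_genes, 4); NaN once a replicate ends
    trajectories: Optional[np.ndarray] = None
    trajectory_gens: Optional[np.ndarray] = None

    @property
    def fixed(self) -> np.ndarray:
        return self.fixation_gen >= 0

    def fixation_fraction(self) -> float:
        """Fraction of (replicate, gene) pairs that reached N-fixation."""
        return float(self.fixed.mean())

    def mean_fixation_time(self) -> float:
        times = self.fixation_gen[self.fixed]
        return float(times.mean()) if times.size else math.nan

    def fixation_times(self) -> np.ndarray:
        return self.fixation_gen[self.fixed]


# ----------------------------------------------------------------------
# transition probabilities of the per-gene mutation phase
def _mutation_pvals(mu_dup: float, a: float, b: float) -> np.ndarray:
    """Rows: source state M/D/N/X; columns: destination M/D/N/X."""
    q = mu_dup
    return np.array(
        [
            # from M: optional duplication, then per-copy inactivation
            [
                q * (1 - a) * b + (1 - q) * (1 - a),
                q * (1 - a) * (1 - b),
                q * a * (1 - b),
                q * a * b + (1 - q) * a,
            ],
            # from D
            [(1 - a) * b, (1 - a) * (1 - b), a * (1 - b), a * b],
            # from N
            [0.0, 0.0, 1 - b, b],
            # from X (inert; cell already inviable)
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def _initial_states(params: BUDParams) -> np.ndarray:
    """Initial per-cell state codes, shape (n_pop,)."""
    cells = np.full(params.n_pop, _STATE_CODE[params.initial_state], dtype=np.int8)
    i = 0
    if params.initial_counts:
        for state, count in params.initial_counts.items():
            cells[i : i + count] = _STATE_CODE[state]
            i += count
    return cells


def simulate(
    params: BUDParams, rng: RngLike = None, engine: str = "auto"
) -> SimulationResult:
    """Run the BUD Wright–Fisher simulation.

    ``engine`` selects the internal representation: ``counts`` tracks
    per-state cell counts (exact and fast, single-gene only),
    ``agents`` tracks every cell's genotype (any number of genes);
    ``auto`` picks ``counts`` when ``n_genes == 1``.  Both engines
    implement the identical model.
    """
    rng = as_rng(rng if rng is not None else params.seed)
    if engine == "auto":
        engine = "counts" if params.n_genes == 1 else "agents"
    if engine == "counts":
        if params.n_genes != 1:
            raise BUDError("counts engine supports a single gene")
        return _simulate_counts(params, rng)
    if engine == "agents":
        return _simulate_agents(params, rng)
    raise BUDError(f"unknown engine {engine!r}")


# ----------------------------------------------------------------------
# counts engine: single gene, fully vectorised over replicates
def _simulate_counts(params: BUDParams, rng) -> SimulationResult:
    R = params.replicates
    w = params.fitness_by_state
    init_cells = _initial_states(params)
    init_counts = np.bincount(init_cells, minlength=4)
    c = np.tile(init_counts, (R, 1)).astype(np.int64)

    fixation_gen = np.full((R, 1), -1, dtype=np.int64)
    extinct_gen = np.full(R, -1, dtype=np.int64)
    record = params.record_trajectories
    traj, traj_gens = [], []

    def check_fixation(counts, gen, active):
        living = counts[:, :3].sum(axis=1)
        newly = (
            active
            & (fixation_gen[:, 0] < 0)
            & (living > 0)
            & (counts[:, _M] == 0)
            & (counts[:, _D] == 0)
        )
        fixation_gen[newly, 0] = gen
        return newly

    active = np.ones(R, dtype=bool)
    check_fixation(c, 0, active)
    if record:
        traj.append(c / c.sum(axis=1, keepdims=True))
        traj_gens.append(0)

    # with no duplication and no mitochondrial decay, a replicate whose
    # N and D cells are gone can neither fix N nor go extinct
    frozen_without_n = params.mu_dup == 0.0 and params.mu_mt == 0.0
    for gen in range(1, params.t_max + 1):
        # replicates needing no further work: extinct, or fixed in an
        # absorbing N state, or N unreachable with nothing left to happen
        settled = (extinct_gen >= 0) | (
            (fixation_gen[:, 0] >= 0) & (params.mu_nuc == 0.0)
        )
        if frozen_without_n:
            settled |= (c[:, _D] == 0) & (c[:, _N] == 0) & (
                fixation_gen[:, 0] < 0
            )
        active = ~settled
        if not active.any():
            break

        a = params.mu_mt_at(gen)
        size_next = params.size_at(gen)
        pv = _mutation_pvals(params.mu_dup, a, params.mu_nuc)

        ca = c[active]
        mutated = np.zeros_like(ca)
        for s in range(4):
            if pv[s].max() == 1.0 and pv[s, s] == 1.0:
                mutated[:, s] += ca[:, s]
                continue
            mutated += rng.multinomial(ca[:, s], pv[s])

        weights = mutated * w  # (r, 4)
        totals = weights.sum(axis=1)
        dead = totals <= 0
        pvals = np.empty_like(weights, dtype=float)
        pvals[~dead] = weights[~dead] / totals[~dead, None]
        pvals[dead] = [1.0, 0.0, 0.0, 0.0]
        n_next = np.where(dead, 0, size_next)
        offspring = rng.multinomial(n_next, pvals)

        idx = np.flatnonzero(active)
        c[idx] = offspring
        extinct_gen[idx[dead]] = gen
        check_fixation(c, gen, active)

        if record and gen % params.trajectory_thin == 0:
            tot = c.sum(axis=1, keepdims=True).astype(float)
            freq = np.where(tot > 0, c / np.maximum(tot, 1), np.nan)
            traj.append(freq)
            traj_gens.append(gen)

    trajectories = None
    tg = None
    if record:
        trajectories = np.stack(traj, axis=1)[:, :, None, :]
        tg = np.array(traj_gens)
    return SimulationResult(
        params=params,
        fixation_gen=fixation_gen,
        extinct_gen=extinct_gen,
        trajectories=trajectories,
        trajectory_gens=tg,
    )


# ----------------------------------------------------------------------
# agents engine: per-cell genotypes, any number of genes
def _simulate_agents(params: BUDParams, rng) -> SimulationResult:
    R, G = params.replicates, params.n_genes
    w_state = params.fitness_by_state
    init_cells = _initial_states(params)
    pop = np.tile(init_cells[None, :, None], (R, 1, G)).astype(np.int8)

    fixation_gen = np.full((R, G), -1, dtype=np.int64)
    extinct_gen = np.full(R, -1, dtype=np.int64)
    record = params.record_trajectories
    traj, traj_gens = [], []

    def check_fixation(pop_arr, gen, rep_idx):
        living = ~(pop_arr == _X).any(axis=2)  # (r, n)
        for j, r in enumerate(rep_idx):
            if not living[j].any():
                continue
            allN = (pop_arr[j][living[j]] == _N).all(axis=0)  # (G,)
            newly = allN & (fixation_gen[r] < 0)
            fixation_gen[r, newly] = gen

    def freqs(pop_arr):
        n = pop_arr.shape[1]
        out = np.empty((pop_arr.shape[0], G, 4))
        for s in range(4):
            out[:, :, s] = (pop_arr == s).sum(axis=1) / n
        return out

    check_fixation(pop, 0, np.arange(R))
    if record:
        traj.append(freqs(pop))
        traj_gens.append(0)

    alive = np.ones(R, dtype=bool)
    pops = {r: pop[r] for r in range(R)}  # per-replicate arrays (size may vary)

    for gen in range(1, params.t_max + 1):
        rep_idx = np.flatnonzero(alive)
        if rep_idx.size == 0:
            break
        a = params.mu_mt_at(gen)
        size_next = params.size_at(gen)
        pv = _mutation_pvals(params.mu_dup, a, params.mu_nuc)
        cum = pv.cumsum(axis=1)

        new_pops = {}
        for r in rep_idx:
            cells = pops[r]
            # mutation phase: redraw the state of every cell-gene
            u = rng.random(cells.shape)
            mutated = (u[..., None] >= cum[cells]).sum(axis=-1).astype(np.int8)
            # selection + resampling
            w = w_state[mutated].prod(axis=1)  # (n,)
            total = w.sum()
            if total <= 0:
                extinct_gen[r] = gen
                alive[r] = False
                continue
            cw = np.cumsum(w)
            draws = rng.random(size_next) * total
            parents = np.searchsorted(cw, draws, side="right")
            new_pops[r] = mutated[parents]
        for r, arr in new_pops.items():
            pops[r] = arr

        live_idx = np.flatnonzero(alive)
        if live_idx.size:
            # all live replicates share the same size this generation
            batch = np.stack([pops[r] for r in live_idx])
            check_fixation(batch, gen, live_idx)
            if record and gen % params.trajectory_thin == 0:
                f = np.full((R, G, 4), np.nan)
                f[live_idx] = freqs(batch)
                traj.append(f)
                traj_gens.append(gen)

    trajectories = None
    tg = None
    if record:
        trajectories = np.stack(traj, axis=1)
        tg = np.array(traj_gens)
    return SimulationResult(
        params=params,
        fixation_gen=fixation_gen,
        extinct_gen=extinct_gen,
        trajectories=trajectories,
        trajectory_gens=tg,
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FixationEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


def fixation_probability(
    params: BUDParams, replicates: Optional[int] = None, rng: RngLike = None
) -> FixationEstimate:
    """Monte-Carlo per-gene N-fixation probability with a Wilson interval."""
    if replicates is not None:
        params = replace(params, replicates=replicates)
    if params.replicates < 100:
        raise BUDError("need at least 100 replicates for a fixation estimate")
    res = simulate(params, rng=rng)
    n = int(res.fixed.size)
    k = int(res.fixed.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return FixationEstimate(k / n, float(lo), float(hi), n)


@dataclass(frozen=True)
class BurstStatistics:
    """Timing statistics of N-fixations.

    ``window_fraction``: share of fixations inside the bottleneck
    window; ``burst_index``: that share divided by the window's share
    of total time (1 under time-homogeneous fixation); ``dispersion``:
    variance/mean of fixation counts per time bin (index of
    dispersion, > 1 = bursty).  Undefined values are ``None``.
    """

    burst_index: Optional[float]
    window_fraction: Optional[float]
    dispersion: Optional[float]
    n_fixations: int = 0


def burst_statistics(
    result: SimulationResult,
    params: Optional[BUDParams] = None,
    n_bins: int = 10,
) -> BurstStatistics:
    params = params or result.params
    times = result.fixation_times()
    if times.size == 0:
        return BurstStatistics(None, None, None, 0)
    bins = np.linspace(0, params.t_max, n_bins + 1)
    counts, _ = np.histogram(times, bins=bins)
    dispersion = float(counts.var() / counts.mean()) if counts.mean() > 0 else None
    if params.bottleneck is None:
        return BurstStatistics(None, None, dispersion, int(times.size))
    lo, hi = params.bottleneck.window()
    wf = float(((times >= lo) & (times < hi)).mean())
    share = params.bottleneck.duration / params.t_max
    return BurstStatistics(wf / share, wf, dispersion, int(times.size))


def sweep(
    base: BUDParams,
    grid: Mapping[str, Sequence],
    replicates: Optional[int] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run ``fixation_probability`` over a parameter grid.

    Each grid point overrides fields of ``base``; randomness derives
    from one seed plus the point index, so points are comparable
    across sweeps with the same seed.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise BUDError("empty parameter grid")
    keys = list(grid)
    rows = []
    seed = base.seed if seed is None else seed
    for i, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        p = replace(base, **dict(zip(keys, values)))
        rng = as_rng([int(seed), i])
        if replicates is not None:
            p = replace(p, replicates=replicates)
        res = simulate(p, rng=rng)
        n = int(res.fixed.size)
        k = int(res.fixed.sum())
        row = {
            "n_pop": p.n_pop,
            "mu_mt": p.mu_mt,
            "s_nuc": p.s_nuc,
            "fixation_fraction": k / n,
            "mean_fixation_time": res.mean_fixation_time(),
            "n": n,
        }
        row.update(dict(zip(keys, values)))
        rows.append(row)
    return pd.DataFrame(rows)
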