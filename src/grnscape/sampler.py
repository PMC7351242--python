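"""Multicanonical sampling of networks across the fitness range.

High-fitness networks are exponentially rare under uniform random
generation, so the landscape is measured by entropic sampling: a
Markov chain over valid genotypes whose per-bin sampling weight is
inversely proportional to the (estimated) number of networks in that
fitness bin, yielding near-uniform visits across bins.  The weights are
learned with the Wang-Landau scheme; a subsequent fixed-weight
measurement run produces the sample histogram from which the relative
number of states Omega(f) per bin — the "fitness landscape" — is
estimated.  On tiny systems the estimate is validated against exhaustive
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from ._kernels import entropic_kernel, wl_learn_kernel
from .dynamics import DynamicsParams, evaluate_fitness, fast_fitness
from .network import (
    RegulatoryNetwork,
    enumerate_all_networks,
    make_random_network,
    structural_check,
)

__all__ = [
    "FitnessBins",
    "WLConfig",
    "MeasureConfig",
    "WeightTable",
    "EntropicResult",
    "DensityOfStates",
    "random_valid_network",
    "wang_landau",
    "entropic_run",
    "estimate_density",
    "exact_density_small",
    "landscape",
]


@dataclass(frozen=True)
class FitnessBins:
    """Uniform binning of the fitness range [0, 1].

    Bins are half-open [lo, hi) with the last bin closed at 1.
    """

    n_bins: int = 100

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def index(self, f: float) -> int:
        return min(int(f * self.n_bins), self.n_bins - 1)


@dataclass(frozen=True)
class WLConfig:
    """Wang-Landau schedule.

    The modification factor starts at ``ln_f0`` and halves whenever the
    stage histogram is flat (minimum >= ``flatness`` x mean over the
    bins visited in the stage); learning stops below ``ln_f_final`` or
    at the move budget.  These are standard Wang-Landau defaults.
    """

    ln_f0: float = 1.0
    ln_f_final: float = 1e-8
    flatness: float = 0.8
    check_interval: int = 10_000
    max_moves: int = 50_000_000
    init_retries: int = 10_000


@dataclass(frozen=True)
class MeasureConfig:
    """Measurement-run sizes: total MCS, sampling cadence, archive window.

    One MCS is K attempted edge relocations; a sample is recorded every
    ``sample_interval`` MCS to thin out chain correlations.  Genotypes
    with fitness in ``store_range`` are archived up to ``store_cap``.
    """

    n_mcs: int = 100_000
    sample_interval: int = 10
    store_range: Tuple[float, float] = (2.0, 2.0)  # store nothing by default
    store_cap: int = 10_000


@dataclass
class WeightTable:
    """Learned per-bin sampling weights plus the chain's final state."""

    bins: FitnessBins
    log_weight: np.ndarray  # log sampling weight, = -(ln Omega estimate)
    visit_histogram: np.ndarray
    visited: np.ndarray  # bins the learning walk ever reached
    converged: bool
    final_mod_factor: float
    moves_used: int
    state: RegulatoryNetwork  # chain endpoint, reusable as a start
    state_fitness: float

    @property
    def log_density(self) -> np.ndarray:
        return -self.log_weight


@dataclass
class EntropicResult:
    """Recorded samples of one fixed-weight measurement run."""

    fitness_values: np.ndarray
    output_nodes: np.ndarray
    histogram: np.ndarray
    stored_networks: List[RegulatoryNetwork]
    state: RegulatoryNetwork
    state_fitness: float


@dataclass
class DensityOfStates:
    """Relative number of networks per fitness bin, normalized to sum 1."""

    bins: FitnessBins
    log_rel_states: np.ndarray  # -inf on unresolved (empty) bins
    histogram: np.ndarray
    n_runs: int

    @property
    def probability(self) -> np.ndarray:
        return np.exp(self.log_rel_states)

    @property
    def resolved(self) -> np.ndarray:
        return np.isfinite(self.log_rel_states)


def _child_seed(rng: np.random.Generator) -> int:
    # numba kernels take a plain 32-bit seed
    return int(rng.integers(2**31 - 1))


def random_valid_network(
    n_genes: int,
    n_edges: int,
    rng: np.random.Generator,
    params: DynamicsParams = DynamicsParams(),
    max_retries: int = 10_000,
) -> Tuple[RegulatoryNetwork, float]:
    """Rejection-sample a structurally valid genotype with its fitness.

    Draws random networks until the input reaches all genes and all
    genes reach the fitness-selected output gene.
    """
    for _ in range(max_retries):
        net = make_random_network(n_genes, n_edges, rng)
        res = evaluate_fitness(net, params)
        if res.valid:
            net.output_node = res.output_node
            return net, res.fitness
    raise RuntimeError(
        f"no valid network found in {max_retries} draws at "
        f"N={n_genes}, K={n_edges}"
    )


def wang_landau(
    n_genes: int,
    n_edges: int,
    bins: FitnessBins,
    wl_config: WLConfig,
    rng: np.random.Generator,
    params: DynamicsParams = DynamicsParams(),
    initial: Optional[RegulatoryNetwork] = None,
) -> WeightTable:
    """Learn multicanonical weights over the fitness bins."""
    if initial is None:
        net, f0 = random_valid_network(
            n_genes, n_edges, rng, params, wl_config.init_retries
        )
    else:
        net = initial.copy()
        f0, out, valid = fast_fitness(net.interactions, params)
        if not valid:
            raise ValueError("initial network fails the structural validity rule")
        net.output_node = out
    J = net.interactions.copy()
    lng, hist, ever, ln_f, moves, converged = wl_learn_kernel(
        J,
        f0,
        bins.n_bins,
        wl_config.ln_f0,
        wl_config.ln_f_final,
        wl_config.flatness,
        wl_config.check_interval,
        wl_config.max_moves,
        _child_seed(rng),
        params.a,
        params.b,
        params.convergence_tol,
        params.max_steps,
        params.average_window,
    )
    f_end, out_end, _ = fast_fitness(J, params)
    state = RegulatoryNetwork(n_genes=n_genes, interactions=J, output_node=out_end)
    return WeightTable(
        bins=bins,
        log_weight=-lng,
        visit_histogram=hist,
        visited=ever.astype(bool),
        converged=bool(converged),
        final_mod_factor=float(ln_f),
        moves_used=int(moves),
        state=state,
        state_fitness=f_end,
    )


def entropic_run(
    weights: WeightTable,
    run_config: MeasureConfig,
    rng: np.random.Generator,
    params: DynamicsParams = DynamicsParams(),
    initial: Optional[RegulatoryNetwork] = None,
) -> EntropicResult:
    """Fixed-weight Metropolis measurement run.

    Starts from the weight table's chain endpoint (or ``initial``),
    records (fitness, output) every ``sample_interval`` MCS and archives
    genotypes falling in the configured fitness window.
    """
    net = (initial or weights.state).copy()
    f0, out0, valid = fast_fitness(net.interactions, params)
    if not valid:
        raise ValueError("starting network fails the structural validity rule")
    J = net.interactions.copy()
    lo, hi = run_config.store_range
    fs, outs, hist, store, n_stored = entropic_kernel(
        J,
        f0,
        -weights.log_weight,
        weights.bins.n_bins,
        run_config.n_mcs,
        run_config.sample_interval,
        _child_seed(rng),
        lo,
        hi,
        run_config.store_cap,
        params.a,
        params.b,
        params.convergence_tol,
        params.max_steps,
        params.average_window,
    )
    stored = []
    for k in range(n_stored):
        m = store[k].copy()
        f, out, _ = fast_fitness(m, params)
        stored.append(
            RegulatoryNetwork(n_genes=net.n_genes, interactions=m, output_node=out)
        )
    f_end, out_end, _ = fast_fitness(J, params)
    return EntropicResult(
        fitness_values=fs,
        output_nodes=outs,
        histogram=hist,
        stored_networks=stored,
        state=RegulatoryNetwork(
            n_genes=net.n_genes, interactions=J, output_node=out_end
        ),
        state_fitness=f_end,
    )


def estimate_density(
    histogram: np.ndarray, weights: WeightTable, n_runs: int = 1
) -> DensityOfStates:
    """Reweight the measured histogram into a normalized density of states.

    ln Omega(bin) = ln hist(bin) - log_weight(bin), normalized so the
    probabilities over resolved (nonempty) bins sum to one.  Empty bins
    are unresolved and carry -inf.
    """
    hist = np.asarray(histogram, dtype=float)
    if not (hist > 0).any():
        raise ValueError("cannot estimate a density from an all-empty histogram")
    log_omega = np.full(weights.bins.n_bins, -np.inf)
    nz = hist > 0
    with np.errstate(divide="ignore"):
        log_omega[nz] = np.log(hist[nz]) - weights.log_weight[nz]
    log_omega[nz] -= logsumexp(log_omega[nz])
    return DensityOfStates(
        bins=weights.bins,
        log_rel_states=log_omega,
        histogram=np.asarray(histogram).astype(np.int64),
        n_runs=n_runs,
    )


def exact_density_small(
    n_genes: int,
    n_edges: int,
    bins: FitnessBins = FitnessBins(),
    params: DynamicsParams = DynamicsParams(),
    cap: int = 10_000_000,
) -> DensityOfStates:
    """Exhaustive-enumeration oracle for the density of states.

    Every constrained network is generated, the sampler's validity rule
    applied, and the exact fitness values binned.  Only feasible for
    toy sizes.
    """
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    for net in enumerate_all_networks(n_genes, n_edges, cap=cap):
        f, out, valid = fast_fitness(net.interactions, params)
        if valid:
            counts[bins.index(f)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no structurally valid networks at this size")
    log_omega = np.full(bins.n_bins, -np.inf)
    nz = counts > 0
    log_omega[nz] = np.log(counts[nz] / total)
    return DensityOfStates(
        bins=bins, log_rel_states=log_omega, histogram=counts, n_runs=1
    )


def landscape(
    n_genes: int,
    n_edges: int,
    rng: np.random.Generator,
    bins: FitnessBins = FitnessBins(),
    wl_config: WLConfig = WLConfig(),
    run_config: MeasureConfig = MeasureConfig(),
    n_runs: int = 5,
    params: DynamicsParams = DynamicsParams(),
):
    """Learn weights, measure with ``n_runs`` independent runs, estimate.

    Returns ``(weights, density, runs)``; the runs' histograms are
    pooled for the density estimate, and each run continues from the
    previous chain endpoint with its own seed.
    """
    weights = wang_landau(n_genes, n_edges, bins, wl_config, rng, params)
    hist = np.zeros(bins.n_bins, dtype=np.int64)
    runs = []
    state = weights.state
    for _ in range(n_runs):
        res = entropic_run(weights, run_config, rng, params, initial=state)
        hist += res.histogram
        runs.append(res)
        state = res.state
    density = estimate_density(hist, weights, n_runs=n_runs)
    return weights, density, runs
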