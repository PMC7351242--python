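"""Discrete-time expression dynamics, steady states and fitness.

Each gene carries a continuous expression level x_i in [0, 1] updated
synchronously through a sigmoidal response

    x_i(t+1) = R( I(t) [i = input] + sum_{j != i} J_ij x_j(t) ),
    R(x) = 1 / (1 + exp(-a (x - b))),

with steepness a = 1 and threshold b = 0 by default, so an unregulated
gene sits at the spontaneous level R(0) = 0.5.  The response of a gene
to a constant input I is its steady-state expression (fixed point, or
temporal average on a limit cycle) reached from the uniform 0.5 start.
The sensitivity s_i = |x̄_i(1) - x̄_i(0)| measures how strongly gene i
discriminates input off from input on; the output gene is the non-input
gene maximizing it and its sensitivity is the network's fitness f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import (
    all_reach_kernel,
    fitness_kernel,
    input_reaches_all_kernel,
    relax_kernel,
    sensitivities_kernel,
)
from .network import RegulatoryNetwork

__all__ = [
    "DynamicsParams",
    "SteadyStateResult",
    "FitnessResult",
    "response_function",
    "step",
    "relax",
    "evaluate_fitness",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the expression map and the steady-state criterion.

    ``a`` and ``b`` are the sigmoid steepness and threshold (dimensionless).
    Iteration stops when successive states differ by less than
    ``convergence_tol`` in max norm; after ``max_steps`` without
    convergence the response is the mean over the final
    ``average_window`` iterations (limit-cycle averaging).
    """

    a: float = 1.0
    b: float = 0.0
    convergence_tol: float = 1e-10
    max_steps: int = 5000
    average_window: int = 1000

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("steepness a must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.average_window > self.max_steps:
            raise ValueError("average_window cannot exceed max_steps")


@dataclass
class SteadyStateResult:
    response: np.ndarray  # per-gene steady expression in [0, 1]
    fixed_point: bool
    steps_used: int


@dataclass
class FitnessResult:
    sensitivities: np.ndarray
    output_node: int
    fitness: float
    valid: bool
    invalid_reason: Optional[str] = None


def response_function(x, params: DynamicsParams = DynamicsParams()):
    """Sigmoid regulation response R(x) = 1 / (1 + exp(-a (x - b)))."""
    return 1.0 / (1.0 + np.exp(-params.a * (np.asarray(x, dtype=float) - params.b)))


def _clamp_mask(n: int, clamped) -> np.ndarray:
    mask = np.zeros(n, dtype=np.uint8)
    if clamped:
        for k in clamped:
            mask[k] = 1
    return mask


def step(
    net: RegulatoryNetwork,
    state: np.ndarray,
    input_level: float,
    params: DynamicsParams = DynamicsParams(),
    internal_noise: Optional[np.ndarray] = None,
    clamped=None,
) -> np.ndarray:
    """One synchronous update of all expression levels.

    ``internal_noise``, if given, is the per-(i, j) matrix xi_ij added to
    the regulator's expression as seen by each target (a zero matrix
    reproduces the noiseless map exactly).  Genes in ``clamped`` are
    silenced: their expression is pinned to 0.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_genes,):
        raise ValueError("state length must equal the number of genes")
    J = net.interactions.astype(float)
    if internal_noise is not None:
        x_eff = state[None, :] + np.asarray(internal_noise, dtype=float)
        h = np.sum(J * x_eff, axis=1)
    else:
        h = J @ state
    h[net.input_node] += input_level
    nxt = response_function(h, params)
    if clamped:
        nxt[list(clamped)] = 0.0
    return nxt


def relax(
    net: RegulatoryNetwork,
    input_level: float,
    initial_state: Optional[np.ndarray] = None,
    params: DynamicsParams = DynamicsParams(),
    clamped=None,
) -> SteadyStateResult:
    """Iterate the noiseless map to a steady state.

    Non-convergence within ``max_steps`` is an ordinary outcome: the
    response is then the tail average and ``fixed_point`` is False.
    """
    n = net.n_genes
    mask = _clamp_mask(n, clamped)
    if initial_state is None:
        x0 = np.full(n, 0.5)
        x0[mask != 0] = 0.0
    else:
        x0 = np.asarray(initial_state, dtype=float).copy()
    resp, fp, steps = relax_kernel(
        net.interactions,
        float(input_level),
        x0,
        params.a,
        params.b,
        params.convergence_tol,
        params.max_steps,
        params.average_window,
        mask,
    )
    return SteadyStateResult(response=resp, fixed_point=bool(fp), steps_used=int(steps))


def evaluate_fitness(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    output_node: Optional[int] = None,
    clamped=None,
) -> FitnessResult:
    """Sensitivities, output-gene selection and fitness of a genotype.

    Relaxes at I = 0 and I = 1 from the uniform 0.5 start and takes
    s_i = |x̄_i(1) - x̄_i(0)|.  With ``output_node=None`` the output is
    the non-input gene of largest sensitivity (ties to the lowest
    index) and validity additionally requires the input to reach every
    gene and every gene to reach that output.  Passing ``output_node``
    (mutational scans keep the parent's output) skips the selection and
    the validity verdict refers to the given output.
    """
    n = net.n_genes
    mask = _clamp_mask(n, clamped)
    s = sensitivities_kernel(
        net.interactions,
        params.a,
        params.b,
        params.convergence_tol,
        params.max_steps,
        params.average_window,
        mask,
    )
    if output_node is None:
        non_input = np.arange(n) != net.input_node
        out = int(np.flatnonzero(non_input)[np.argmax(s[non_input])])
    else:
        out = int(output_node)
    reason = None
    if not input_reaches_all_kernel(net.interactions):
        reason = "input_unreachable"
    elif not all_reach_kernel(net.interactions, out).all():
        reason = "output_not_reached"
    return FitnessResult(
        sensitivities=s,
        output_node=out,
        fitness=float(s[out]),
        valid=reason is None,
        invalid_reason=reason,
    )


def fast_fitness(J: np.ndarray, params: DynamicsParams = DynamicsParams()):
    """Kernel-level fitness for hot loops: returns (f, output, valid)."""
    f, out, valid = fitness_kernel(
        J,
        params.a,
        params.b,
        params.convergence_tol,
        params.max_steps,
        params.average_window,
    )
    return float(f), int(out), bool(valid)
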