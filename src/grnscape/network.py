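"""Constrained signed directed regulatory networks.

A genotype is an N-gene network with K signed edges.  Entry ``J[i, j]``
of the interaction matrix is the regulation exerted *by gene j on gene i*
(+1 activation, -1 repression, 0 none).  Three hard structural constraints
apply to every genotype: no self-regulation (zero diagonal), no mutual
regulation (never both ``J[i, j]`` and ``J[j, i]`` nonzero), and exactly K
nonzero entries.  Gene 0 is always the input gene; the output gene is
chosen downstream from the dynamics (the most input-sensitive gene).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

import numpy as np

__all__ = [
    "RegulatoryNetwork",
    "StructuralReport",
    "Mutation",
    "max_edges",
    "make_random_network",
    "structural_check",
    "propose_edge_move",
    "apply_mutation",
    "enumerate_all_networks",
]


class NetworkParameterError(ValueError):
    """Raised for inadmissible network parameters or mutation sites."""


def max_edges(n_genes: int) -> int:
    """Largest K compatible with the no-mutual-regulation constraint.

    Each unordered gene pair can carry at most one directed edge, so the
    capacity is N(N-1)/2.
    """
    return n_genes * (n_genes - 1) // 2


@dataclass
class RegulatoryNetwork:
    """A signed-digraph genotype with designated input (gene 0) and output.

    Parameters
    ----------
    n_genes
        Number of genes N (>= 2).
    interactions
        N x N integer matrix J with entries in {-1, 0, +1};
        ``J[i, j]`` is the regulation from gene j onto gene i.
    input_node
        Index of the gene receiving the external input; fixed to 0.
    output_node
        Index of the readout gene, or ``None`` before fitness evaluation.
    """

    n_genes: int
    interactions: np.ndarray
    input_node: int = 0
    output_node: Optional[int] = None

    def __post_init__(self) -> None:
        self.interactions = np.asarray(self.interactions, dtype=np.int8)
        if self.interactions.shape != (self.n_genes, self.n_genes):
            raise NetworkParameterError(
                f"interaction matrix shape {self.interactions.shape} does not "
                f"match n_genes={self.n_genes}"
            )

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.interactions))

    def copy(self) -> "RegulatoryNetwork":
        return replace(self, interactions=self.interactions.copy())

    def validate(self) -> None:
        """Raise ``NetworkParameterError`` on any structural-invariant breach."""
        J = self.interactions
        bad = np.argwhere((J < -1) | (J > 1))
        if bad.size:
            i, j = bad[0]
            raise NetworkParameterError(
                f"entry ({i},{j}) = {J[i, j]} outside {{-1,0,+1}}"
            )
        diag = np.flatnonzero(np.diag(J))
        if diag.size:
            raise NetworkParameterError(f"self-regulation at gene {diag[0]}")
        mutual = np.argwhere((J != 0) & (J.T != 0))
        if mutual.size:
            i, j = mutual[0]
            raise NetworkParameterError(f"mutual regulation between genes {i} and {j}")
        if self.output_node is not None and self.output_node == self.input_node:
            raise NetworkParameterError("output gene coincides with input gene")

    def edge_list(self) -> np.ndarray:
        """Return the (n_edges, 2) array of (target i, regulator j) pairs."""
        return np.argwhere(self.interactions != 0)


@dataclass
class StructuralReport:
    """Reachability diagnosis for the sampler's validity rule.

    A genotype is usable only if the input gene has a directed path to
    every other gene and every gene has a directed path to the output
    gene; genes outside those paths could not participate in the response.
    """

    input_reaches_all: bool
    nodes_reaching: np.ndarray  # per-gene: has a directed path to the target
    violation: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.violation is None


MutationKind = Literal["delete_edge", "add_edge", "knockout_node"]


@dataclass(frozen=True)
class Mutation:
    """A single genetic perturbation applied to a genotype.

    ``delete_edge`` removes the interaction at ``site=(i, j)``;
    ``add_edge`` writes ``sign`` there; ``knockout_node`` silences gene
    ``site=k`` (its row and column are zeroed and its expression clamps
    to 0 in the dynamics).
    """

    kind: MutationKind
    site: tuple
    sign: int = 0


def make_random_network(
    n_genes: int, n_edges: int, rng: np.random.Generator
) -> RegulatoryNetwork:
    """Draw a uniform random constrained network with exactly K edges.

    K unordered gene pairs are chosen uniformly without replacement; each
    chosen pair receives one directed edge with uniform orientation and a
    uniform +/-1 sign.  Reachability of the input to all genes is *not*
    enforced here: validity is a property of the (network, output) pair
    and is checked downstream via :func:`structural_check`.
    """
    if n_genes < 2:
        raise NetworkParameterError("need at least 2 genes")
    cap = max_edges(n_genes)
    if n_edges > cap:
        raise NetworkParameterError(
            f"n_edges={n_edges} exceeds capacity {cap} for n_genes={n_genes} "
            "(one edge per unordered pair)"
        )
    pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    J = np.zeros((n_genes, n_genes), dtype=np.int8)
    for idx in chosen:
        i, j = pairs[idx]
        sign = 1 if rng.random() < 0.5 else -1
        if rng.random() < 0.5:
            J[i, j] = sign  # j regulates i
        else:
            J[j, i] = sign  # i regulates j
    return RegulatoryNetwork(n_genes=n_genes, interactions=J)


def _reachable_from(adj_out: np.ndarray, start: int) -> np.ndarray:
    """Boolean reachability from ``start`` following ``adj_out[u] -> v`` edges."""
    n = adj_out.shape[0]
    seen = np.zeros(n, dtype=bool)
    seen[start] = True
    stack = [start]
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(adj_out[u]):
            if not seen[v]:
                seen[v] = True
                stack.append(int(v))
    return seen


def structural_check(
    net: RegulatoryNetwork, candidate_output: int
) -> StructuralReport:
    """Check the two path conditions for a candidate output gene.

    ``J[i, j] != 0`` is the graph edge j -> i.  The input must reach every
    gene going forward; every gene must reach ``candidate_output`` (a gene
    trivially reaches itself).
    """
    if candidate_output == net.input_node:
        raise NetworkParameterError("candidate output must differ from the input gene")
    J = net.interactions
    # forward adjacency: out-neighbours of u are the nonzeros of column u
    forward = (J != 0).T
    from_input = _reachable_from(forward, net.input_node)
    input_reaches_all = bool(from_input.all())
    # genes reaching the output = reverse reachability from the output
    nodes_reaching = _reachable_from(J != 0, candidate_output)
    violation = None
    if not input_reaches_all:
        violation = "input_unreachable"
    elif not nodes_reaching.all():
        violation = "output_not_reached"
    return StructuralReport(
        input_reaches_all=input_reaches_all,
        nodes_reaching=nodes_reaching,
        violation=violation,
    )


def propose_edge_move(
    net: RegulatoryNetwork,
    rng: np.random.Generator,
    rerandomize_sign: bool = True,
) -> RegulatoryNetwork:
    """Relocate one uniformly chosen edge to a uniformly chosen legal slot.

    The elementary Monte Carlo move: an existing edge is removed and a new
    edge is placed at a position drawn uniformly among the admissible empty
    positions (off-diagonal, reverse also empty, computed after removal),
    so K is conserved.  By default the relocated edge gets a fresh uniform
    +/-1 sign; set ``rerandomize_sign=False`` to carry the old sign.

    The proposal is symmetric (the removal-intermediate network is shared
    by the forward and reverse moves), so plain Metropolis acceptance on
    the sampling weights preserves detailed balance.  Structural validity
    of the proposal is *not* checked here.
    """
    edges = net.edge_list()
    if len(edges) == 0:
        raise NetworkParameterError("network has no edges to move")
    k = rng.integers(len(edges))
    i, j = map(int, edges[k])
    old_sign = int(net.interactions[i, j])
    J = net.interactions.copy()
    J[i, j] = 0
    occupied = (J != 0) | (J.T != 0)
    np.fill_diagonal(occupied, True)
    free = np.argwhere(~occupied)
    if len(free) == 0:  # cannot happen for K >= 1: the vacated slot is free
        raise NetworkParameterError("no admissible target position")
    ti, tj = map(int, free[rng.integers(len(free))])
    if rerandomize_sign:
        sign = 1 if rng.random() < 0.5 else -1
    else:
        sign = old_sign
    J[ti, tj] = sign
    return replace(net, interactions=J)


def apply_mutation(net: RegulatoryNetwork, mut: Mutation) -> RegulatoryNetwork:
    """Return the mutant genotype; input/output designations are preserved.

    Mutants are deliberately *not* re-validated structurally: mutational
    scans re-evaluate fitness with the original input and output genes
    fixed, whatever the mutant's connectivity.
    """
    J = net.interactions.copy()
    if mut.kind == "delete_edge":
        i, j = mut.site
        if J[i, j] == 0:
            raise NetworkParameterError(f"no edge at ({i},{j}) to delete")
        J[i, j] = 0
    elif mut.kind == "add_edge":
        i, j = mut.site
        if i == j:
            raise NetworkParameterError("cannot add a self-regulation")
        if J[i, j] != 0:
            raise NetworkParameterError(f"position ({i},{j}) already occupied")
        if J[j, i] != 0:
            raise NetworkParameterError(
                f"adding ({i},{j}) would create mutual regulation with ({j},{i})"
            )
        if mut.sign not in (1, -1):
            raise NetworkParameterError("add_edge needs sign +1 or -1")
        J[i, j] = mut.sign
    elif mut.kind == "knockout_node":
        (k,) = mut.site if isinstance(mut.site, tuple) else (mut.site,)
        if k == net.input_node or (net.output_node is not None and k == net.output_node):
            raise NetworkParameterError("cannot knock out the input or output gene")
        J[k, :] = 0
        J[:, k] = 0
    else:  # pragma: no cover - exhaustive kinds
        raise NetworkParameterError(f"unknown mutation kind {mut.kind!r}")
    return replace(net, interactions=J)


def enumerate_all_networks(
    n_genes: int, n_edges: int, cap: int = 10_000_000
) -> Iterator[RegulatoryNetwork]:
    """Yield every distinct constrained network exactly once (brute force).

    Used as an exhaustive oracle for validating the Monte Carlo sampler on
    tiny systems.  The count is C(P, K) * 4^K with P = N(N-1)/2: choose the
    K occupied unordered pairs, then an orientation and a sign for each.
    """
    n_pairs = max_edges(n_genes)
    if n_edges > n_pairs:
        raise NetworkParameterError("n_edges exceeds pair capacity")
    from math import comb

    total = comb(n_pairs, n_edges) * 4**n_edges
    if total > cap:
        raise NetworkParameterError(
            f"enumeration would visit {total} networks (> cap {cap})"
        )
    pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    for combo in itertools.combinations(range(n_pairs), n_edges):
        for options in itertools.product(range(4), repeat=n_edges):
            J = np.zeros((n_genes, n_genes), dtype=np.int8)
            for idx, opt in zip(combo, options):
                i, j = pairs[idx]
                sign = 1 if opt & 1 else -1
                if opt & 2:
                    J[i, j] = sign
                else:
                    J[j, i] = sign
            yield RegulatoryNetwork(n_genes=n_genes, interactions=J)
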