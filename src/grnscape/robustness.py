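"""Noise robustness and mutational robustness of sampled genotypes.

Noise protocols rerun the abrupt 0 -> 1 -> 0 input schedule with either
input noise (a uniform [-0.3, 0.3] draw added to I each step, modelling
input-molecule number fluctuations) or internal noise (independent
uniform [-0.1, 0.1] draws added to each transmitted expression level
per regulating pair per step, modelling transcription-factor number
fluctuations).  A network that fails to track the input deterministically
but succeeds under noise exhibits a *noise-induced response* (NIR): the
noise kicks it off the wrong fixed point.

Mutational scans perturb one site at a time — deleting an existing
edge, knocking out a gene, or adding an edge at an admissible empty
position — and re-evaluate the fitness f' with the parent's input and
output genes held fixed.  A deletion or knockout with f' < 0.9 is
*lethal*.  Toggle switches with no lethal edge (TSwoLE) are the
distinguished, doubly-robust class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .bistability import StepProtocolResult, step_protocol
from .dynamics import DynamicsParams, evaluate_fitness
from .network import Mutation, RegulatoryNetwork, apply_mutation

__all__ = [
    "NoiseSpec",
    "NoiseProtocolResult",
    "MutationScanResult",
    "noise_protocol",
    "edge_deletion_scan",
    "node_knockout_scan",
    "edge_addition_scan",
    "tswole_filter",
    "INPUT_NOISE_AMPLITUDE",
    "INTERNAL_NOISE_AMPLITUDE",
    "LETHAL_THRESHOLD",
]

INPUT_NOISE_AMPLITUDE = 0.3
INTERNAL_NOISE_AMPLITUDE = 0.1
LETHAL_THRESHOLD = 0.9


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform noise description: where it enters and its half-width."""

    kind: str  # "input" | "internal"
    amplitude: float = -1.0  # <0 -> the kind's canonical default

    def __post_init__(self):
        if self.kind not in ("input", "internal"):
            raise ValueError("noise kind must be 'input' or 'internal'")
        if self.amplitude < 0:
            object.__setattr__(
                self,
                "amplitude",
                INPUT_NOISE_AMPLITUDE
                if self.kind == "input"
                else INTERNAL_NOISE_AMPLITUDE,
            )


@dataclass
class NoiseProtocolResult:
    follows_without_noise: bool
    follows_with_noise: bool
    nir: bool
    noiseless: StepProtocolResult
    noisy: StepProtocolResult


@dataclass
class MutationScanResult:
    """Per-site mutant fitness map of a single-perturbation scan.

    ``n_lethal`` counts deletion/knockout sites with f' below the
    lethal threshold; for addition scans ``robust_fraction`` is the
    share of admissible additions keeping f' at or above the high
    threshold (``None`` when no addition is admissible).
    """

    kind: str
    per_site_fitness: Dict[tuple, float]
    threshold: float
    lethal_sites: List[tuple]
    n_lethal: int
    robust_fraction: Optional[float] = None


def noise_protocol(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    spec: NoiseSpec = NoiseSpec("input"),
    rng: Optional[np.random.Generator] = None,
    **protocol_kwargs,
) -> NoiseProtocolResult:
    """Compare input tracking with and without noise; detect NIR."""
    if rng is None:
        raise ValueError("noise protocols need a seeded rng")
    base = step_protocol(net, params, **protocol_kwargs)
    if spec.kind == "input":
        noisy = step_protocol(
            net, params, input_noise_amp=spec.amplitude, rng=rng, **protocol_kwargs
        )
    else:
        noisy = step_protocol(
            net, params, internal_noise_amp=spec.amplitude, rng=rng, **protocol_kwargs
        )
    return NoiseProtocolResult(
        follows_without_noise=base.follows,
        follows_with_noise=noisy.follows,
        nir=(not base.follows) and noisy.follows,
        noiseless=base,
        noisy=noisy,
    )


def _require_output(net: RegulatoryNetwork) -> int:
    if net.output_node is None:
        raise ValueError("network needs a designated output gene")
    return net.output_node


def edge_deletion_scan(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    lethal_threshold: float = LETHAL_THRESHOLD,
) -> MutationScanResult:
    """Delete each edge in turn and record the mutant fitness f'.

    The input and output genes stay those of the parent; mutants are
    not re-validated structurally.  The scan leaves the parent matrix
    untouched.
    """
    out = _require_output(net)
    per_site: Dict[tuple, float] = {}
    for i, j in net.edge_list():
        mutant = apply_mutation(net, Mutation("delete_edge", (int(i), int(j))))
        res = evaluate_fitness(mutant, params, output_node=out)
        per_site[(int(i), int(j))] = res.fitness
    lethal = [site for site, f in per_site.items() if f < lethal_threshold]
    return MutationScanResult(
        kind="delete_edge",
        per_site_fitness=per_site,
        threshold=lethal_threshold,
        lethal_sites=lethal,
        n_lethal=len(lethal),
    )


def node_knockout_scan(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    lethal_threshold: float = LETHAL_THRESHOLD,
) -> MutationScanResult:
    """Knock out each non-input, non-output gene and record f'.

    A knockout silences the gene: its row and column are zeroed and its
    expression is clamped to 0 during the mutant's dynamics.
    """
    out = _require_output(net)
    per_site: Dict[tuple, float] = {}
    for k in range(net.n_genes):
        if k == net.input_node or k == out:
            continue
        mutant = apply_mutation(net, Mutation("knockout_node", (k,)))
        res = evaluate_fitness(mutant, params, output_node=out, clamped=(k,))
        per_site[(k,)] = res.fitness
    lethal = [site for site, f in per_site.items() if f < lethal_threshold]
    return MutationScanResult(
        kind="knockout_node",
        per_site_fitness=per_site,
        threshold=lethal_threshold,
        lethal_sites=lethal,
        n_lethal=len(lethal),
    )


def edge_addition_scan(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    high_threshold: float = LETHAL_THRESHOLD,
    signs: Tuple[int, ...] = (1, -1),
) -> MutationScanResult:
    """Add one edge of each sign at every admissible empty position.

    Admissible means off-diagonal with both directions currently empty.
    ``robust_fraction`` is the share of additions with f' >=
    ``high_threshold`` (None for a full-capacity parent).
    """
    out = _require_output(net)
    J = net.interactions
    per_site: Dict[tuple, float] = {}
    n = net.n_genes
    for i in range(n):
        for j in range(n):
            if i == j or J[i, j] != 0 or J[j, i] != 0:
                continue
            for sign in signs:
                mutant = apply_mutation(net, Mutation("add_edge", (i, j), sign))
                res = evaluate_fitness(mutant, params, output_node=out)
                per_site[(i, j, sign)] = res.fitness
    lethal = [site for site, f in per_site.items() if f < high_threshold]
    robust = None
    if per_site:
        robust = 1.0 - len(lethal) / len(per_site)
    return MutationScanResult(
        kind="add_edge",
        per_site_fitness=per_site,
        threshold=high_threshold,
        lethal_sites=lethal,
        n_lethal=len(lethal),
        robust_fraction=robust,
    )


def tswole_filter(
    ensemble: List[RegulatoryNetwork],
    switch_classes: List[str],
    deletion_scans: List[MutationScanResult],
) -> List[RegulatoryNetwork]:
    """Toggle switches without a lethal edge (TSwoLE)."""
    if not (len(ensemble) == len(switch_classes) == len(deletion_scans)):
        raise ValueError("ensemble, classes and scans must align")
    return [
        net
        for net, cls, scan in zip(ensemble, switch_classes, deletion_scans)
        if cls == "toggle" and scan.n_lethal == 0
    ]
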