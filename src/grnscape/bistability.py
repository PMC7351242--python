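"""Bistability detection via quasistatic hysteresis and input following.

Highly-fit networks respond to the input through a pair of saddle-node
bifurcations: two stable fixed points coexist over a window of input
values.  Tracking the unstable branch directly is impractical for many
genes, so bistability is detected heuristically by hysteresis: the
input is swept up 0 -> 1 and back down in small steps, fully relaxing
at each value and carrying the steady state forward; a discrepancy
between the branches larger than a small threshold flags bistability
(a lower bound — weak bistability below the threshold is missed).

Bistable networks split into three switch classes by where the bistable
window sits: a *toggle switch* is monostable at both I = 0 and 1 with
the window strictly between, a *one-way switch* has the window touching
one endpoint, and the *unswitchable* window covers both endpoints.
Only toggle switches track an abrupt 0 -> 1 -> 0 input step; the others
get trapped on the wrong fixed point in at least one direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._kernels import hysteresis_kernel, step_protocol_kernel
from .dynamics import DynamicsParams
from .network import RegulatoryNetwork

__all__ = [
    "HysteresisScan",
    "StepProtocolResult",
    "hysteresis_scan",
    "classify_switch",
    "step_protocol",
]

SWITCH_CLASSES = ("toggle", "one_way", "unswitchable", "monostable")


@dataclass
class HysteresisScan:
    input_grid: np.ndarray
    up_branch: np.ndarray
    down_branch: np.ndarray
    threshold: float
    bistable: bool
    bistable_interval: Optional[Tuple[float, float]]
    switch_class: str


@dataclass
class StepProtocolResult:
    """Output trajectory over a piecewise-constant input schedule.

    ``follows`` demands a large excursion during the on-phase
    (|mean2 - mean1| >= excursion_min) and a return to the initial
    branch afterwards (|mean3 - mean1| <= return_max), with phase means
    taken over each phase's final tail steps.
    """

    trajectory: np.ndarray
    phase_means: np.ndarray
    follows: bool


def hysteresis_scan(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    delta_i: float = 0.001,
    threshold: float = 0.01,
) -> HysteresisScan:
    """Quasistatic up/down input sweep with bistability classification.

    The upward branch starts from the steady state at I = 0 (relaxed
    from the all-0.5 state) and each grid point reuses the previous
    steady state; the downward branch continues from the I = 1
    endpoint.  The bistable interval is the closure of grid points
    where the branches differ by more than ``threshold``.
    """
    if net.output_node is None:
        raise ValueError("network needs a designated output gene")
    n_grid = int(round(1.0 / delta_i)) + 1
    up, down = hysteresis_kernel(
        net.interactions,
        net.output_node,
        n_grid,
        params.a,
        params.b,
        params.convergence_tol,
        params.max_steps,
        params.average_window,
    )
    grid = np.linspace(0.0, 1.0, n_grid)
    gap = np.abs(up - down)
    exceed = np.flatnonzero(gap > threshold)
    if exceed.size:
        interval = (float(grid[exceed[0]]), float(grid[exceed[-1]]))
        bistable = True
    else:
        interval = None
        bistable = False
    scan = HysteresisScan(
        input_grid=grid,
        up_branch=up,
        down_branch=down,
        threshold=threshold,
        bistable=bistable,
        bistable_interval=interval,
        switch_class="",
    )
    scan.switch_class = classify_switch(scan)
    return scan


def classify_switch(scan: HysteresisScan) -> str:
    """Map a scan to {toggle, one_way, unswitchable, monostable}."""
    if not scan.bistable or scan.bistable_interval is None:
        return "monostable"
    lo, hi = scan.bistable_interval
    at_zero = lo <= scan.input_grid[0]
    at_one = hi >= scan.input_grid[-1]
    if at_zero and at_one:
        return "unswitchable"
    if at_zero or at_one:
        return "one_way"
    return "toggle"


def step_protocol(
    net: RegulatoryNetwork,
    params: DynamicsParams = DynamicsParams(),
    schedule: Tuple[float, ...] = (0.0, 1.0, 0.0),
    phase_len: int = 1000,
    input_noise_amp: float = 0.0,
    internal_noise_amp: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    tail: int = 200,
    excursion_min: float = 0.5,
    return_max: float = 0.1,
    clamped=None,
) -> StepProtocolResult:
    """Drive the network through an abrupt input schedule from 0.5 start.

    The canonical schedule holds I = 0, then 1, then 0 for
    ``phase_len`` steps each.  Optional uniform input noise (added to I
    each step) or internal noise (added per regulating pair per step)
    use a stream derived from ``rng``; zero amplitudes reproduce the
    noiseless trajectory exactly.
    """
    if net.output_node is None:
        raise ValueError("network needs a designated output gene")
    if (input_noise_amp > 0 or internal_noise_amp > 0) and rng is None:
        raise ValueError("noisy protocols need an rng")
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    clamp = np.zeros(net.n_genes, dtype=np.uint8)
    if clamped:
        for k in clamped:
            clamp[k] = 1
    traj = step_protocol_kernel(
        net.interactions,
        net.output_node,
        np.asarray(schedule, dtype=float),
        phase_len,
        float(input_noise_amp),
        float(internal_noise_amp),
        seed,
        params.a,
        params.b,
        clamp,
    )
    n_phases = len(schedule)
    means = np.empty(n_phases)
    window = min(tail, phase_len) if phase_len > 0 else 0
    for p in range(n_phases):
        if window == 0:
            means[p] = np.nan
        else:
            end = (p + 1) * phase_len
            means[p] = traj[end - window : end].mean()
    follows = (
        n_phases >= 3
        and window > 0
        and abs(means[1] - means[0]) >= excursion_min
        and abs(means[2] - means[0]) <= return_max
    )
    return StepProtocolResult(trajectory=traj, phase_means=means, follows=bool(follows))
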