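"""File formats, run configuration and seed derivation.

Interaction matrices travel as plain CSV (N rows x N columns of
-1/0/+1; entry (i, j) is the regulation of gene i by gene j; gene 0 is
the input; an optional ``g0..g{N-1}`` header row is accepted).
Ensembles are JSON-Lines archives, densities and weight checkpoints are
TSV.  All stochastic stages derive their streams from one master seed
through fixed labels, so adding an analysis never perturbs the
randomness of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .dynamics import DynamicsParams
from .network import NetworkParameterError, RegulatoryNetwork
from .sampler import (
    DensityOfStates,
    FitnessBins,
    MeasureConfig,
    WeightTable,
    WLConfig,
)

__all__ = [
    "RunConfig",
    "read_network_csv",
    "write_network_csv",
    "write_ensemble_jsonl",
    "read_ensemble_jsonl",
    "write_density_tsv",
    "read_density_tsv",
    "write_weights_tsv",
    "read_weights_tsv",
    "derive_seed",
    "load_config",
    "save_config",
]


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from a master seed."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def stage_rng(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, label))


@dataclass
class RunConfig:
    """Complete configuration of a sampling-and-analysis run.

    Connectivity may be given as C (mean degree, K = C N / 2) or as an
    explicit edge count; C N must then be even.  All thresholds carry
    their canonical defaults: bistability detection 0.01 at input step
    0.001, lethality 0.9, input/internal noise amplitudes 0.3/0.1.
    """

    n_genes: int = 16
    connectivity: Optional[float] = 5.0
    n_edges: Optional[int] = None
    a: float = 1.0
    b: float = 0.0
    convergence_tol: float = 1e-10
    max_steps: int = 5000
    average_window: int = 1000
    n_bins: int = 100
    wl_ln_f0: float = 1.0
    wl_ln_f_final: float = 1e-8
    wl_flatness: float = 0.8
    wl_check_interval: int = 10_000
    wl_max_moves: int = 50_000_000
    n_mcs: int = 100_000
    sample_interval: int = 10
    n_runs: int = 5
    fittest_bin: Tuple[float, float] = (0.99, 1.0)
    store_cap: int = 10_000
    sweep_step: float = 0.001
    bistability_threshold: float = 0.01
    lethal_threshold: float = 0.9
    input_noise_amplitude: float = 0.3
    internal_noise_amplitude: float = 0.1
    phase_len: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges is None:
            if self.connectivity is None:
                raise ValueError("give either connectivity C or n_edges K")
            k2 = self.connectivity * self.n_genes
            if abs(k2 / 2 - round(k2 / 2)) > 1e-9:
                raise ValueError("C*N must be even so that K = C*N/2 is integral")
            self.n_edges = int(round(k2 / 2))
        elif self.connectivity is None:
            self.connectivity = 2 * self.n_edges / self.n_genes
        for name in ("sweep_step", "bistability_threshold", "lethal_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(
            a=self.a,
            b=self.b,
            convergence_tol=self.convergence_tol,
            max_steps=self.max_steps,
            average_window=self.average_window,
        )

    def bins(self) -> FitnessBins:
        return FitnessBins(self.n_bins)

    def wl_config(self) -> WLConfig:
        return WLConfig(
            ln_f0=self.wl_ln_f0,
            ln_f_final=self.wl_ln_f_final,
            flatness=self.wl_flatness,
            check_interval=self.wl_check_interval,
            max_moves=self.wl_max_moves,
        )

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            n_mcs=self.n_mcs,
            sample_interval=self.sample_interval,
            store_range=tuple(self.fittest_bin),
            store_cap=self.store_cap,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a flat key: value (YAML) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "fittest_bin" in data:
        data["fittest_bin"] = tuple(data["fittest_bin"])
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    data["fittest_bin"] = list(data["fittest_bin"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_network_csv(path, output_node: Optional[int] = None) -> RegulatoryNetwork:
    """Parse and validate an interaction-matrix CSV.

    Violations are reported with the offending cell's coordinates.
    """
    rows: List[List[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([c.strip() for c in line.split(",")])
    if rows and any(not _is_int(c) for c in rows[0]):
        rows = rows[1:]  # optional g0..g{N-1} header
    n = len(rows)
    if n < 2:
        raise NetworkParameterError(f"{path}: need at least a 2x2 matrix")
    J = np.zeros((n, n), dtype=np.int8)
    for i, row in enumerate(rows):
        if len(row) != n:
            raise NetworkParameterError(
                f"{path}: row {i} has {len(row)} columns, expected {n}"
            )
        for j, cell in enumerate(row):
            if not _is_int(cell) or int(cell) not in (-1, 0, 1):
                raise NetworkParameterError(
                    f"{path}: entry at row {i}, column {j} is {cell!r}, "
                    "expected -1, 0 or +1"
                )
            J[i, j] = int(cell)
    net = RegulatoryNetwork(n_genes=n, interactions=J, output_node=output_node)
    net.validate()
    return net


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_network_csv(net: RegulatoryNetwork, path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(f"g{j}" for j in range(net.n_genes)) + "\n")
        for i in range(net.n_genes):
            fh.write(",".join(str(int(v)) for v in net.interactions[i]) + "\n")


def write_ensemble_jsonl(
    nets: List[RegulatoryNetwork],
    fitness_values,
    path,
    meta: Optional[dict] = None,
) -> None:
    """One JSON record per network: fitness, output gene, matrix, meta."""
    with open(path, "w") as fh:
        for net, f in zip(nets, fitness_values):
            rec = {
                "f": float(f),
                "output_node": int(net.output_node)
                if net.output_node is not None
                else None,
                "matrix": net.interactions.astype(int).tolist(),
                "meta": meta or {},
            }
            fh.write(json.dumps(rec) + "\n")


def read_ensemble_jsonl(path) -> Tuple[List[RegulatoryNetwork], np.ndarray]:
    nets: List[RegulatoryNetwork] = []
    fs: List[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            J = np.asarray(rec["matrix"], dtype=np.int8)
            nets.append(
                RegulatoryNetwork(
                    n_genes=J.shape[0],
                    interactions=J,
                    output_node=rec.get("output_node"),
                )
            )
            fs.append(rec["f"])
    return nets, np.asarray(fs)


def write_density_tsv(density: DensityOfStates, path) -> None:
    edges = density.bins.edges
    df = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "ln_rel_states": density.log_rel_states,
            "probability": density.probability,
            "histogram_count": density.histogram,
            "n_runs": density.n_runs,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_density_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_weights_tsv(weights: WeightTable, path) -> None:
    """Checkpoint the learned weights (and chain endpoint) for reuse."""
    edges = weights.bins.edges
    df = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "log_weight": weights.log_weight,
            "visit_histogram": weights.visit_histogram,
            "visited": weights.visited.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# converged={weights.converged}\n")
        fh.write(f"# final_mod_factor={weights.final_mod_factor!r}\n")
        fh.write(f"# moves_used={weights.moves_used}\n")
        fh.write(f"# state={json.dumps(weights.state.interactions.astype(int).tolist())}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_weights_tsv(path) -> WeightTable:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            body_start = k + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    J = np.asarray(json.loads(meta["state"]), dtype=np.int8)
    state = RegulatoryNetwork(n_genes=J.shape[0], interactions=J)
    return WeightTable(
        bins=FitnessBins(len(df)),
        log_weight=df["log_weight"].to_numpy(),
        visit_histogram=df["visit_histogram"].to_numpy(),
        visited=df["visited"].to_numpy().astype(bool),
        converged=meta.get("converged") == "True",
        final_mod_factor=float(meta.get("final_mod_factor", "nan")),
        moves_used=int(meta.get("moves_used", 0)),
        state=state,
        state_fitness=float("nan"),
    )
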