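"""End-to-end run: landscape -> fittest ensemble -> downstream analyses.

``run_pipeline`` executes the whole study for one configuration and
writes every artifact (density TSV, weight checkpoint, ensemble JSONL,
per-network analysis report JSONL, motif TSV) plus a manifest recording
the configuration, its hash, the master seed and package versions, so
a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .bistability import hysteresis_scan, step_protocol
from .dynamics import evaluate_fitness
from .io import (
    RunConfig,
    stage_rng,
    write_density_tsv,
    write_ensemble_jsonl,
    write_weights_tsv,
)
from .motifs import MOTIF_CLASSES, count_motifs, ensemble_motif_histogram
from .network import RegulatoryNetwork
from .robustness import (
    NoiseSpec,
    edge_addition_scan,
    edge_deletion_scan,
    node_knockout_scan,
    noise_protocol,
)
from .sampler import (
    WeightTable,
    entropic_run,
    estimate_density,
    wang_landau,
)

__all__ = ["run_pipeline", "analyze_ensemble"]

log = logging.getLogger("grnscape")


def analyze_ensemble(
    nets: List[RegulatoryNetwork],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bistability, noise and mutation report for each network.

    One row per network: fitness, switch class, input following with
    and without each noise kind, NIR flags, lethal-edge and lethal-node
    counts, addition robustness and motif counts.
    """
    params = cfg.dynamics_params()
    rows = []
    for net in nets:
        scan = hysteresis_scan(
            net, params, delta_i=cfg.sweep_step, threshold=cfg.bistability_threshold
        )
        base = step_protocol(net, params, phase_len=cfg.phase_len)
        noisy_in = noise_protocol(
            net,
            params,
            NoiseSpec("input", cfg.input_noise_amplitude),
            rng=rng,
            phase_len=cfg.phase_len,
        )
        noisy_int = noise_protocol(
            net,
            params,
            NoiseSpec("internal", cfg.internal_noise_amplitude),
            rng=rng,
            phase_len=cfg.phase_len,
        )
        deletions = edge_deletion_scan(net, params, cfg.lethal_threshold)
        knockouts = node_knockout_scan(net, params, cfg.lethal_threshold)
        additions = edge_addition_scan(net, params, cfg.lethal_threshold)
        motifs = count_motifs(net)
        f = evaluate_fitness(net, params).fitness
        rows.append(
            {
                "f": f,
                "output_node": net.output_node,
                "switch_class": scan.switch_class,
                "bistable": scan.bistable,
                "follows": base.follows,
                "follows_noisy_input": noisy_in.follows_with_noise,
                "follows_internal_noise": noisy_int.follows_with_noise,
                "nir_input": noisy_in.nir,
                "nir_internal": noisy_int.nir,
                "n_L": deletions.n_lethal,
                "n_LN": knockouts.n_lethal,
                "addition_robust_fraction": additions.robust_fraction,
                **{c: getattr(motifs, c) for c in MOTIF_CLASSES},
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: RunConfig,
    out_dir,
    weights: Optional[WeightTable] = None,
) -> dict:
    """Run learning, measurement, estimation and all analyses.

    Passing a pre-learned ``weights`` table (e.g. from a checkpoint)
    skips the Wang-Landau stage.  Returns a manifest dict; all
    artifacts are written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "wang_landau"
    try:
        if weights is None:
            log.info("learning Wang-Landau weights (N=%d, K=%d)", cfg.n_genes, cfg.n_edges)
            weights = wang_landau(
                cfg.n_genes,
                cfg.n_edges,
                cfg.bins(),
                cfg.wl_config(),
                stage_rng(cfg.master_seed, "wang_landau"),
                cfg.dynamics_params(),
            )
            log.info(
                "WL done: %d moves, converged=%s, final factor %.3g",
                weights.moves_used,
                weights.converged,
                weights.final_mod_factor,
            )
        write_weights_tsv(weights, out / "weights.tsv")

        stage = "entropic_sampling"
        hist = np.zeros(cfg.n_bins, dtype=np.int64)
        ensemble: List[RegulatoryNetwork] = []
        state = weights.state
        for r in range(cfg.n_runs):
            res = entropic_run(
                weights,
                cfg.measure_config(),
                stage_rng(cfg.master_seed, f"entropic_{r}"),
                cfg.dynamics_params(),
                initial=state,
            )
            hist += res.histogram
            ensemble.extend(res.stored_networks)
            state = res.state
            log.info("run %d: %d samples, %d archived", r, len(res.fitness_values), len(res.stored_networks))

        stage = "density_estimate"
        density = estimate_density(hist, weights, n_runs=cfg.n_runs)
        write_density_tsv(density, out / "density.tsv")

        stage = "ensemble_archive"
        fs = [
            evaluate_fitness(net, cfg.dynamics_params()).fitness for net in ensemble
        ]
        write_ensemble_jsonl(
            ensemble,
            fs,
            out / "ensemble.jsonl",
            meta={"fittest_bin": list(cfg.fittest_bin), "seed": cfg.master_seed},
        )

        stage = "analysis"
        if ensemble:
            report = analyze_ensemble(
                ensemble, cfg, stage_rng(cfg.master_seed, "analysis")
            )
            report.to_json(out / "report.jsonl", orient="records", lines=True)
            motif_hist = ensemble_motif_histogram(ensemble)
            motif_rows = []
            for cls, counts in motif_hist.items():
                for count, n_nets in enumerate(counts):
                    motif_rows.append(
                        {"class": cls, "count": count, "n_networks": int(n_nets)}
                    )
            pd.DataFrame(motif_rows).to_csv(out / "motifs.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    from importlib.metadata import version as pkg_version

    try:
        own_version = pkg_version("grnscape")
    except Exception:
        own_version = "unknown"
    manifest = {
        "config": {**asdict(cfg), "fittest_bin": list(cfg.fittest_bin)},
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "n_archived": len(ensemble),
        "versions": {
            "grnscape": own_version,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
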