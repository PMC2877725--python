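"""End-to-end orchestration with seeds, manifests and file outputs.

``run_pipeline`` drives: read network -> null ensemble -> filtered
partnership network -> scaling analyses (degree distribution,
power-law diagnostic, partners-vs-targets scatter, linear and
saturation fits, randomized-network comparison, optional operon
recalibration and down-sampling robustness), writing TSV/JSON outputs
plus a run manifest.  A single master seed fans out to per-stage
sub-seeds (recorded in the manifest) so any stage can be re-run in
isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from . import fits as _fits
from .growth import GrowthConfig, simulate_growth
from .model import PartnershipModel
from .network import (OperonMap, RegulatoryNetwork, read_edge_list,
                      read_operon_map, write_edge_list)
from .nullmodel import DEFAULT_ENSEMBLE_SIZE, DEFAULT_SWAP_FACTOR

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline",
           "run_growth_experiment"]

_STAGE_NAMES = ("read", "null_ensemble", "coregulation", "randomized",
                "operon", "downsample")


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Counter-based sub-seed derivation (each child < 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] & 0x7FFF_FFFF)
            for child in ss.spawn(n)]


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    input_path: str | Path | None = None
    network: RegulatoryNetwork | None = None
    operon_map_path: str | Path | None = None
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE
    swap_factor: float = DEFAULT_SWAP_FACTOR
    filter: str = "cc"
    threshold: float | None = None
    compare_randomized: bool = True
    downsample_fractions: Sequence[float] = ()
    downsample_modes: Sequence[str] = ("nodes", "edges")
    downsample_trials: int = 3
    out_dir: str | Path = "coregnet_run"
    seed: int = 0

    def validate(self) -> None:
        if self.network is None and self.input_path is None:
            raise ValueError("config needs input_path or an in-memory network")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(str(self.input_path))
        if (self.operon_map_path is not None
                and not Path(self.operon_map_path).exists()):
            raise FileNotFoundError(str(self.operon_map_path))


@dataclass
class PipelineReport:
    """Where a run wrote its outputs, plus the manifest dict."""

    out_dir: Path
    manifest: dict
    results: object = None  # PartnershipResults of the main analysis


def _fit_dict(comparison) -> dict | None:
    return comparison.to_dict() if comparison is not None else None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full partnership analysis per ``config``.

    Structural stages (reading inputs, the null ensemble, partnership
    construction) abort the run on error; per-analysis fit failures on
    degenerate data are recorded in the manifest with a message so a
    toy network still completes end-to-end.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = dict(zip(_STAGE_NAMES, derive_seeds(config.seed,
                                                      len(_STAGE_NAMES))))
    manifest: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": {
            "input_path": str(config.input_path) if config.input_path else None,
            "operon_map_path": (str(config.operon_map_path)
                                if config.operon_map_path else None),
            "ensemble_size": config.ensemble_size,
            "swap_factor": config.swap_factor,
            "filter": config.filter,
            "threshold": config.threshold,
            "downsample_fractions": list(config.downsample_fractions),
            "downsample_modes": list(config.downsample_modes),
            "downsample_trials": config.downsample_trials,
        },
        "stages": {},
    }

    # -- read -------------------------------------------------------------
    net = config.network if config.network is not None \
        else read_edge_list(config.input_path)
    s = net.summary()
    logger.info("read network: %s", s)
    manifest["stages"]["read"] = {
        "num_regulators": s.num_regulators, "num_targets": s.num_targets,
        "num_interactions": s.num_interactions,
    }

    operon_map = None
    if config.operon_map_path is not None:
        operon_map = read_operon_map(config.operon_map_path)

    # -- null ensemble + partnership + fits (via the model object) --------
    model = PartnershipModel(net, ensemble_size=config.ensemble_size,
                             swap_factor=config.swap_factor,
                             filter=config.filter, threshold=config.threshold,
                             operon_map=operon_map)
    results = model.fit(seed=stage_seeds["null_ensemble"])
    results.null_stats.to_tsv(out_dir / "null_stats.tsv")
    results.coregulation.to_tsv(out_dir / "partnership.tsv",
                                out_dir / "partnership_provenance.json")
    results.series.to_tsv(out_dir / "partners_vs_targets.tsv")
    manifest["stages"]["null_ensemble"] = {
        "ensemble_size": config.ensemble_size,
        "pairs_tracked": len(results.null_stats.pair_mean),
    }
    manifest["stages"]["coregulation"] = {
        "filter": results.coregulation.filter_applied,
        "threshold": results.coregulation.threshold,
        "edges_retained": results.coregulation.num_edges,
    }
    manifest["stages"]["fits"] = {
        "comparison": _fit_dict(results.comparison),
        "powerlaw": results.powerlaw.to_dict() if results.powerlaw else None,
    }
    if results.comparison is None:
        manifest["stages"]["fits"]["error"] = \
            "degenerate partners-vs-targets scatter; scaling fits skipped"
    with open(out_dir / "fits.json", "w", encoding="utf-8") as fh:
        json.dump(manifest["stages"]["fits"], fh, indent=2, sort_keys=True)
        fh.write("\n")

    # -- randomized-network comparison ------------------------------------
    if config.compare_randomized:
        from .nullmodel import shuffle_preserving_degrees

        rand_net = shuffle_preserving_degrees(
            net, config.swap_factor, stage_seeds["randomized"])
        rand_model = PartnershipModel(
            rand_net, ensemble_size=config.ensemble_size,
            swap_factor=config.swap_factor, filter=config.filter,
            threshold=config.threshold)
        rand_results = rand_model.fit(seed=stage_seeds["randomized"])
        rand_results.series.to_tsv(out_dir / "partners_vs_targets_random.tsv")
        manifest["stages"]["randomized"] = {
            "comparison": _fit_dict(rand_results.comparison)}

    # -- operon recalibration ---------------------------------------------
    if operon_map is not None:
        results.operon_series.to_tsv(out_dir / "partners_vs_operons.tsv")
        manifest["stages"]["operon"] = {
            "comparison": _fit_dict(results.operon_comparison)}

    # -- down-sampling robustness -----------------------------------------
    if config.downsample_fractions:
        ds_report = []
        ds_seeds = derive_seeds(stage_seeds["downsample"],
                                len(config.downsample_fractions)
                                * len(config.downsample_modes))
        i = 0
        for fraction in config.downsample_fractions:
            for mode in config.downsample_modes:
                subs = _fits.downsample(net, fraction, mode,
                                        config.downsample_trials, ds_seeds[i])
                i += 1
                for trial, sub in enumerate(subs):
                    entry = {"fraction": fraction, "mode": mode, "trial": trial,
                             "num_edges": len(sub.edges)}
                    try:
                        sub_model = PartnershipModel(
                            sub, ensemble_size=config.ensemble_size,
                            swap_factor=config.swap_factor,
                            filter=config.filter, threshold=config.threshold)
                        sub_res = sub_model.fit(seed=ds_seeds[i - 1] + trial)
                        entry["comparison"] = _fit_dict(sub_res.comparison)
                    except ValueError as exc:  # e.g. empty down-sampled net
                        entry["error"] = str(exc)
                    ds_report.append(entry)
        manifest["stages"]["downsample"] = ds_report

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineReport(out_dir, manifest, results)


def run_growth_experiment(growth_config: GrowthConfig,
                          pipeline_config: PipelineConfig) -> PipelineReport:
    """Grow a network, then run the full partnership analysis on it."""
    grown = simulate_growth(growth_config)
    out_dir = Path(pipeline_config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_edge_list(grown.network, out_dir / "grown_network.tsv")
    pipeline_config.network = grown.network
    pipeline_config.input_path = None
    report = run_pipeline(pipeline_config)
    report.manifest["growth"] = {
        "iterations": growth_config.iterations,
        "inheritance_rate": growth_config.inheritance_rate,
        "seed": growth_config.seed,
        "audit": grown.audit,
        "num_tfs": grown.num_tfs,
        "num_tgs": grown.num_tgs,
        "preferred_family": (report.results.preferred_family
                             if report.results else None),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
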