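"""Model/results interface over the partnership-analysis pipeline.

``PartnershipModel`` bundles a regulatory network with the analysis
settings (null-ensemble size, edge filter, optional operon map);
``fit()`` runs the null ensemble, builds the filtered partnership
network, extracts the partners-vs-targets scatter and fits the
competing scaling laws, returning a ``PartnershipResults`` object with
a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fits as _fits
from .network import OperonMap, RegulatoryNetwork, read_edge_list
from .nullmodel import (DEFAULT_ENSEMBLE_SIZE, DEFAULT_SWAP_FACTOR,
                        NullEnsembleStats, null_cotarget_stats)
from .partnership import CoRegulationNetwork, build_coregulation

__all__ = ["PartnershipModel", "PartnershipResults"]


class PartnershipModel:
    """Co-regulation partnership analysis of one regulatory network.

    Parameters
    ----------
    network :
        The directed regulator -> target network to analyse.
    ensemble_size :
        Number of degree-preserving randomizations behind the null
        statistics (study-grade default 1,000; smaller values trade
        null precision for speed).
    swap_factor :
        Attempted edge swaps per randomization, as a multiple of the
        edge count.
    filter, threshold :
        Partnership edge retention rule ('cc' keeps CC > 1 by default;
        'z' and 'none' are the robustness variants).
    operon_map :
        Optional gene -> operon map; when given, results also carry the
        operon-recalibrated partners-vs-operons fits.
    """

    def __init__(self, network: RegulatoryNetwork, *,
                 ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
                 swap_factor: float = DEFAULT_SWAP_FACTOR,
                 filter: str = "cc", threshold: float | None = None,
                 operon_map: OperonMap | None = None):
        self.network = network
        self.ensemble_size = ensemble_size
        self.swap_factor = swap_factor
        self.filter = filter
        self.threshold = threshold
        self.operon_map = operon_map

    @classmethod
    def from_edge_list(cls, path, *, delimiter=None, header=False, **kwargs
                       ) -> "PartnershipModel":
        return cls(read_edge_list(path, delimiter=delimiter, header=header),
                   **kwargs)

    def fit(self, seed: int = 0) -> "PartnershipResults":
        """Run the full analysis; all randomness derives from ``seed``."""
        stats = null_cotarget_stats(self.network, self.ensemble_size,
                                    self.swap_factor, seed)
        coreg = build_coregulation(self.network, stats, self.filter,
                                   self.threshold)
        series = _fits.partners_vs_targets(self.network, coreg)

        def _try(fn, *args):
            try:
                return fn(*args)
            except (_fits.FitError, ValueError):
                return None

        comparison = _try(_fits.compare_fits, series)
        powerlaw = None
        dist = _try(_fits.degree_distribution, coreg, False)
        if dist is not None:
            powerlaw = _try(_fits.fit_powerlaw, dist)

        operon_series = operon_comparison = None
        if self.operon_map is not None:
            collapsed = _fits.collapse_operons(self.network, self.operon_map)
            operon_series = _fits.partners_vs_targets(collapsed, coreg)
            operon_comparison = _try(_fits.compare_fits, operon_series)

        return PartnershipResults(
            model=self, seed=seed, null_stats=stats, coregulation=coreg,
            series=series, comparison=comparison, powerlaw=powerlaw,
            operon_series=operon_series, operon_comparison=operon_comparison)


@dataclass
class PartnershipResults:
    """Fitted partnership analysis: networks, scatter and scaling fits.

    ``comparison`` / ``operon_comparison`` are None when the scatter is
    degenerate (e.g. an empty partnership network); ``powerlaw`` is the
    log-log diagnostic on the partnership degree distribution.
    """

    model: PartnershipModel
    seed: int
    null_stats: NullEnsembleStats
    coregulation: CoRegulationNetwork
    series: "_fits.PartnerTargetSeries"
    comparison: "_fits.FitComparison | None"
    powerlaw: "_fits.SaturationFit | None"
    operon_series: "_fits.PartnerTargetSeries | None" = None
    operon_comparison: "_fits.FitComparison | None" = None

    @property
    def preferred_family(self) -> str | None:
        return self.comparison.preferred if self.comparison else None

    def summary(self) -> str:
        """Human-readable report of sizes, filter and fitted laws."""
        net = self.model.network
        s = net.summary()
        lines = [
            "Partnership network analysis",
            "=" * 60,
            f"Network: {net.name or '(unnamed)'}",
            f"  regulators={s.num_regulators}  targets={s.num_targets}  "
            f"interactions={s.num_interactions}",
            f"Null ensemble: size={self.null_stats.ensemble_size}  "
            f"swap_factor={self.null_stats.swap_factor:g}  seed={self.seed}",
            f"Edge filter: {self.coregulation.filter_applied} "
            f"(threshold {self.coregulation.threshold:g}); "
            f"{self.coregulation.num_edges} partnership edges retained",
        ]
        if self.comparison is not None:
            lin, sat = self.comparison.linear, self.comparison.exp_saturation
            lines += [
                "-" * 60,
                "Partners f vs targets k (one point per regulator):",
                f"  linear:         f = {lin.params['slope']:.4g} k + "
                f"{lin.params['intercept']:.4g}   R^2 = {lin.r_squared:.4f}",
                f"  exp saturation: f = {sat.params['a']:.4g} "
                f"(1 - exp(-{sat.params['b']:.4g} k))   "
                f"R^2 = {sat.r_squared:.4f}",
                f"  preferred: {self.comparison.preferred} "
                f"(delta R^2 = {self.comparison.delta_r_squared:+.4f})",
            ]
        else:
            lines += ["-" * 60, "Partners-vs-targets fits: not available "
                      "(degenerate scatter)"]
        if self.powerlaw is not None:
            lines.append(
                f"Degree-distribution power-law diagnostic: gamma = "
                f"{self.powerlaw.params['gamma']:.3f}, "
                f"R^2 = {self.powerlaw.r_squared:.3f}")
        if self.operon_comparison is not None:
            sat = self.operon_comparison.exp_saturation
            lines += [
                "-" * 60,
                "Operon-recalibrated (partners vs regulated operons):",
                f"  preferred: {self.operon_comparison.preferred} "
                f"(delta R^2 = {self.operon_comparison.delta_r_squared:+.4f})",
                f"  exp saturation: a = {sat.params['a']:.4g}, "
                f"b = {sat.params['b']:.4g}, R^2 = {sat.r_squared:.4f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of partners vs targets with both fitted curves."""
        import matplotlib.pyplot as plt  # optional dependency

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.series.k, self.series.f, s=12, alpha=0.6,
                   label="regulators")
        if self.comparison is not None:
            grid = np.linspace(0, self.series.k.max(), 200)
            ax.plot(grid, self.comparison.linear.predict(grid), "k-",
                    label=f"linear (R^2={self.comparison.linear.r_squared:.3f})")
            ax.plot(grid, self.comparison.exp_saturation.predict(grid), "r-",
                    label="a(1-e^{-bk}) "
                    f"(R^2={self.comparison.exp_saturation.r_squared:.3f})")
        ax.set_xlabel("targets k")
        ax.set_ylabel("partners f")
        ax.legend()
        return ax
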