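"""Scaling analyses: degree distributions, power-law diagnostics, and
linear vs exponential-saturation fits of partners against targets.

The central object is the per-regulator scatter of (k, f) points, where
k is a regulator's number of targets (out-degree in the regulatory
network) and f its number of partners (degree in the filtered
co-regulation network).  The competing descriptions are

    linear:           f(x) = slope * x + intercept
    exp. saturation:  f(x) = a * (1 - exp(-b x)),   a, b >= 0

with a the plateau (limiting partner count) and b the approach rate.
Model preference is by coefficient of determination R^2; in the
small-b*x regime the saturation curve is indistinguishable from a line
(its first-order expansion), which is the operon-driven behaviour seen
in bacterial networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network import OperonMap, RegulatoryNetwork
from .partnership import CoRegulationNetwork, partner_counts

logger = logging.getLogger(__name__)

__all__ = [
    "PartnerTargetSeries",
    "SaturationFit",
    "FitComparison",
    "FitError",
    "degree_distribution",
    "fit_powerlaw",
    "partners_vs_targets",
    "fit_linear",
    "fit_exp_saturation",
    "compare_fits",
    "collapse_operons",
    "downsample",
]

FitFamily = Literal["linear", "exp_saturation", "powerlaw"]


class FitError(RuntimeError):
    """A fit that could not be performed or did not converge.

    ``last_params`` carries the final iterate when the optimizer ran.
    """

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class PartnerTargetSeries:
    """One (k, f) point per regulator: targets vs partners.

    ``f`` is integer-valued for real partnership degrees but may be real
    for synthetic scatter or replicate means; ``f_se`` optionally holds
    standard errors for simulated means.
    """

    regulators: tuple[str, ...]
    k: np.ndarray
    f: np.ndarray
    f_se: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        if len(self.regulators) != len(self.k) or len(self.k) != len(self.f):
            raise ValueError("regulators, k and f must have equal length")
        if np.any(self.k < 0) or np.any(self.f < 0):
            raise ValueError("k and f must be nonnegative")

    def __len__(self) -> int:
        return len(self.k)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"regulator": self.regulators, "k": self.k, "f": self.f})
        if self.f_se is not None:
            df["f_se"] = self.f_se
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SaturationFit:
    """A fitted scaling law and its goodness of fit.

    params holds ``slope``/``intercept`` (linear), ``a``/``b``
    (exp_saturation) or ``gamma``/``log10_c`` (powerlaw).  R^2 is
    1 - SS_res/SS_tot about the mean response; for nonlinear families it
    can be negative and is reported as-is.
    """

    family: FitFamily
    params: dict[str, float]
    r_squared: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "linear":
            return self.params["slope"] * x + self.params["intercept"]
        if self.family == "exp_saturation":
            return self.params["a"] * (1.0 - np.exp(-self.params["b"] * x))
        if self.family == "powerlaw":
            return 10.0 ** self.params["log10_c"] * x ** (-self.params["gamma"])
        raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params),
                "r_squared": self.r_squared, "n_points": self.n_points}


@dataclass(frozen=True)
class FitComparison:
    """Linear vs exponential-saturation comparison on one series."""

    linear: SaturationFit
    exp_saturation: SaturationFit
    preferred: FitFamily
    delta_r_squared: float  # R^2(exp) - R^2(linear)

    def to_dict(self) -> dict:
        return {"linear": self.linear.to_dict(),
                "exp_saturation": self.exp_saturation.to_dict(),
                "preferred": self.preferred,
                "delta_r_squared": self.delta_r_squared}


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        # constant response: the model explains nothing beyond the mean
        return 0.0
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# degree distribution and power-law diagnostic


def degree_distribution(coreg: CoRegulationNetwork,
                        include_zero: bool = True) -> dict[int, float]:
    """Empirical P(k) over partnership degrees; sums to 1.

    With ``include_zero=False`` partner-less regulators are dropped from
    the support (an empty partnership network is then an error).
    """
    degrees = list(partner_counts(coreg).values())
    if not include_zero:
        degrees = [d for d in degrees if d > 0]
    if not degrees:
        raise ValueError("no qualifying degrees (empty partnership network "
                         "with include_zero=False)")
    values, counts = np.unique(np.asarray(degrees), return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(values, counts)}


def fit_powerlaw(dist: Mapping[int, float]) -> SaturationFit:
    """Log-log OLS diagnostic for P(k) ~ k^-gamma.

    Regresses log10 P(k) on log10 k over support points with k >= 1 and
    P(k) > 0; returns gamma (the negated slope) and the regression R^2.
    A flat distribution (zero variance in log P) is the slope-zero
    degenerate: gamma = 0, R^2 = 0.
    """
    pts = [(k, p) for k, p in dist.items() if k >= 1 and p > 0]
    if len(pts) < 3:
        raise FitError(f"power-law fit needs >= 3 support points, got {len(pts)}")
    logk = np.log10([k for k, _ in pts])
    logp = np.log10([p for _, p in pts])
    if np.ptp(logk) == 0:
        raise FitError("degenerate support: all k identical")
    if np.allclose(logp, logp[0]):
        intercept = float(logp[0])
        return SaturationFit("powerlaw", {"gamma": 0.0, "log10_c": intercept},
                             0.0, len(pts))
    res = stats.linregress(logk, logp)
    return SaturationFit("powerlaw",
                         {"gamma": -float(res.slope), "log10_c": float(res.intercept)},
                         float(res.rvalue) ** 2, len(pts))


# ---------------------------------------------------------------------------
# partners vs targets


def partners_vs_targets(net: RegulatoryNetwork,
                        coreg: CoRegulationNetwork) -> PartnerTargetSeries:
    """Per-regulator (out-degree, partnership-degree) scatter.

    ``coreg`` must derive from ``net``: their regulator sets must match.
    Regulators without partners contribute f = 0.
    """
    if set(coreg.regulators) != set(net.regulators):
        raise ValueError("co-regulation network regulators do not match the "
                         "regulatory network (provenance mismatch)")
    pc = partner_counts(coreg)
    regs = sorted(net.regulators)
    k = np.array([net.out_degree(r) for r in regs], dtype=float)
    f = np.array([pc[r] for r in regs], dtype=float)
    return PartnerTargetSeries(tuple(regs), k, f)


def fit_linear(series: PartnerTargetSeries) -> SaturationFit:
    """OLS of f on k; slope, intercept and R^2."""
    if len(series) < 3:
        raise FitError(f"linear fit needs >= 3 points, got {len(series)}")
    if np.ptp(series.k) == 0:
        raise FitError("degenerate series: zero variance in k")
    if np.ptp(series.f) == 0:
        # constant response: OLS slope 0, no variance explained
        return SaturationFit("linear",
                             {"slope": 0.0, "intercept": float(series.f[0])},
                             0.0, len(series))
    res = stats.linregress(series.k, series.f)
    fit = SaturationFit("linear",
                        {"slope": float(res.slope), "intercept": float(res.intercept)},
                        float(res.rvalue) ** 2, len(series))
    return fit


def fit_exp_saturation(series: PartnerTargetSeries, *, xtol: float = 1e-8,
                       max_iter: int = 500) -> SaturationFit:
    """Nonlinear least squares of f = a(1 - exp(-b k)), a, b >= 0.

    Initialization: a0 = 1.05 * max(f); b0 from the through-origin
    regression of -ln(1 - f/a0) on k (the linearization of the curve for
    known plateau), with a positive fallback of 1/mean(k).  Convergence
    tolerance 1e-8 on relative parameter change, at most ``max_iter``
    residual evaluations.

    The plateau search is bounded above at 10 * max(f): in the
    near-linear regime (b k << 1 over the observed range) a and b are
    not separately identifiable — only their product is — and the
    unbounded likelihood ridge runs to a = infinity.  The bound makes
    the fit well-posed there without affecting interior optima or the
    fitted curve's quality (b compensates along the ridge).
    """
    if len(series) < 3:
        raise FitError(f"saturation fit needs >= 3 points, got {len(series)}")
    k, f = series.k, series.f
    fmax = float(np.max(f))
    if fmax <= 0:
        raise FitError("saturation fit undefined: all partner counts are zero")
    a0 = 1.05 * fmax
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log1p(-f / a0)
    mask = np.isfinite(y) & (k > 0)
    denom = float(np.sum(k[mask] ** 2)) if np.any(mask) else 0.0
    b0 = float(np.sum(k[mask] * y[mask]) / denom) if denom > 0 else 0.0
    if not np.isfinite(b0) or b0 <= 0:
        b0 = 1.0 / max(float(np.mean(k)), 1e-12)

    def residual(p):
        a, b = p
        return a * (1.0 - np.exp(-b * k)) - f

    sol = optimize.least_squares(residual, x0=[a0, b0],
                                 bounds=([0.0, 0.0], [10.0 * fmax, np.inf]),
                                 xtol=xtol, ftol=xtol, gtol=None,
                                 max_nfev=max_iter)
    if not sol.success:
        raise FitError(f"saturation fit did not converge: {sol.message}",
                       last_params=tuple(sol.x))
    a, b = (float(v) for v in sol.x)
    r2 = _r_squared(f, a * (1.0 - np.exp(-b * k)))
    return SaturationFit("exp_saturation", {"a": a, "b": b}, r2, len(series))


def compare_fits(series: PartnerTargetSeries) -> FitComparison:
    """Fit both families and prefer the larger R^2.

    Ties within 1e-12 go to the linear family (fewer effective shape
    parameters).
    """
    lin = fit_linear(series)
    sat = fit_exp_saturation(series)
    delta = sat.r_squared - lin.r_squared
    preferred: FitFamily = "exp_saturation" if delta > 1e-12 else "linear"
    return FitComparison(lin, sat, preferred, delta)


# ---------------------------------------------------------------------------
# operon recalibration and down-sampling controls


def collapse_operons(net: RegulatoryNetwork, operons: OperonMap) -> RegulatoryNetwork:
    """Recount targets at the operon level.

    Every target endpoint is replaced by its operon (unmapped genes are
    singleton operons); parallel edges produced by the merge collapse to
    one.  Regulator identifiers are untouched, so a regulator's
    out-degree after collapse is its number of distinct regulated
    operons and never exceeds its gene-level out-degree.
    """
    edges = {(r, operons.operon_of(t)) for r, t in net.edges}
    isolated = net.nodes - {u for e in net.edges for u in e}
    return RegulatoryNetwork(edges, nodes=isolated,
                             name=f"{net.name}|operon-collapsed" if net.name
                             else "operon-collapsed")


def downsample(net: RegulatoryNetwork, fraction: float,
               mode: Literal["nodes", "edges"], trials: int = 3,
               seed: int = 0) -> list[RegulatoryNetwork]:
    """Random node or edge removal, one network per independent trial.

    Removes ``round(fraction * |nodes|)`` nodes (with incident edges) or
    ``round(fraction * |edges|)`` edges, uniformly without replacement.
    Nodes are drawn from the full node set, regulators and targets
    alike; per-role removal counts are logged for auditing.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if mode not in ("nodes", "edges"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[RegulatoryNetwork] = []
    seeds = np.random.SeedSequence(seed).spawn(trials)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if mode == "nodes":
            nodes = sorted(net.nodes)
            n_remove = int(round(fraction * len(nodes)))
            removed = set(rng.choice(nodes, size=n_remove, replace=False)) \
                if n_remove else set()
            logger.info("trial %d: removed %d nodes (%d regulator-role, "
                        "%d target-role)", i, len(removed),
                        sum(1 for v in removed if v in net.regulators),
                        sum(1 for v in removed if v in net.targets))
            edges = {e for e in net.edges
                     if e[0] not in removed and e[1] not in removed}
            sub = RegulatoryNetwork(edges, nodes=net.nodes - removed,
                                    name=f"{net.name}|nodes-{fraction:g}-t{i}")
        else:
            edges_sorted = sorted(net.edges)
            n_remove = int(round(fraction * len(edges_sorted)))
            idx = rng.choice(len(edges_sorted), size=n_remove, replace=False) \
                if n_remove else np.array([], dtype=int)
            drop = {edges_sorted[j] for j in idx}
            sub = RegulatoryNetwork(set(net.edges) - drop, nodes=net.nodes,
                                    name=f"{net.name}|edges-{fraction:g}-t{i}")
        if not sub.edges:
            logger.warning("trial %d: down-sampled network has no edges", i)
        out.append(sub)
    return out
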