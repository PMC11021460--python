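"""In-silico optimization of enzyme loadings (one-at-a-time Vmax scans).

The procedure mirrors systematic enzyme-loading optimization of a
multi-enzyme one-pot system: each enzyme's Vmax is scanned over a grid
while all others are held fixed, the bifunctional activities move as
coupled groups (phosphoketolase XPK:FPK at 1:0.12, transketolase
TK1:TK2 at 1:1), and the accepted optimum is the *minimal* Vmax whose
metric reaches at least 99% of the best metric on the grid — loading
more enzyme than that buys less than 1% of performance.

A full round runs in two phases: first the PHB synthase is scanned on
final titer over a long horizon (it controls how far the reaction can
run before product binding silences it), its optimum is applied, and
then every other enzyme/group is scanned on the initial PHB production
rate (PHB formed in the first hour) over a short horizon.  Vmax in
mM/min converts 1:1 to loading in U/mL (1 U/mL = 1 umol/(mL*min)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParameters, ScenarioSpec, SimulationError, initial_phb_rate, simulate
from .network import Network

__all__ = [
    "COUPLED_GROUPS",
    "ScanSpec",
    "ScanResult",
    "RoundSpec",
    "scan_enzyme",
    "optimal_vmax",
    "run_round",
    "vmax_to_loading",
]

log = logging.getLogger(__name__)

#: Coupled bifunctional groups: lead reaction -> {member: ratio to lead}.
COUPLED_GROUPS: dict[str, dict[str, float]] = {
    "PKL": {"XPK": 1.0, "FPK": 0.12},
    "TK": {"TK1": 1.0, "TK2": 1.0},
}


@dataclass(frozen=True)
class ScanSpec:
    """One enzyme (or coupled group) scan."""

    target: str  # reaction id, or group label "PKL"/"TK"
    grid: tuple[float, ...]
    timescale: float  # min
    metric: str = "final_PHB"  # or "initial_rate"

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in self.grid)
        object.__setattr__(self, "grid", g)
        if not g or any(v <= 0 for v in g) or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("grid must be strictly increasing and positive")
        if self.timescale <= 0:
            raise ValueError("timescale must be > 0")
        if self.metric not in ("final_PHB", "initial_rate"):
            raise ValueError("metric must be final_PHB|initial_rate")

    def vmax_updates(self, value: float) -> dict[str, float]:
        if self.target in COUPLED_GROUPS:
            return {rid: ratio * value for rid, ratio in COUPLED_GROUPS[self.target].items()}
        return {self.target: value}


@dataclass(frozen=True)
class ScanResult:
    target: str
    grid: tuple[float, ...]
    metrics: tuple[float, ...]  # NaN where simulation failed
    optimal: float
    peak: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"vmax_mM_per_min": self.grid, "metric": self.metrics,
                             "target": self.target})


def _metric(result, which: str, product: str = "PHB") -> float:
    if which == "final_PHB":
        return result.final(product)
    return initial_phb_rate(result)


def scan_enzyme(
    network: Network,
    params: KineticParameters,
    scenario: ScenarioSpec,
    spec: ScanSpec,
    threshold: float = 0.99,
) -> ScanResult:
    """Simulate once per grid point and apply the minimal-Vmax-at-99% rule.

    Grid points where the integration fails are recorded as missing and
    logged; the scan continues.  The shared parameter set is never
    mutated.
    """
    members = spec.vmax_updates(1.0)
    unknown = set(members) - set(network.reaction_ids)
    if unknown:
        raise KeyError(f"scan target reactions not in network: {sorted(unknown)}")
    scenario = ScenarioSpec(
        initial=scenario.initial, additions=scenario.additions,
        t_end=max(spec.timescale, 60.0 if spec.metric == "initial_rate" else spec.timescale),
        residual_fraction=scenario.residual_fraction,
        grid_dt=scenario.grid_dt, label=scenario.label,
    )
    values = []
    for v in spec.grid:
        try:
            res = simulate(network, params.with_vmax(spec.vmax_updates(v)), scenario)
            values.append(_metric(res, spec.metric))
        except SimulationError as err:
            log.warning("scan %s at Vmax=%g failed: %s", spec.target, v, err)
            values.append(float("nan"))
    opt = optimal_vmax_from_curve(spec.grid, values, threshold)
    peak = float(np.nanmax(values))
    return ScanResult(target=spec.target, grid=spec.grid, metrics=tuple(values),
                      optimal=opt, peak=peak)


def optimal_vmax_from_curve(grid, metrics, threshold: float = 0.99) -> float:
    """Smallest grid value whose metric is >= threshold x grid maximum."""
    arr = np.asarray(metrics, dtype=float)
    if np.all(np.isnan(arr)):
        raise ValueError("no valid metric values in scan")
    peak = np.nanmax(arr)
    for v, m in zip(grid, arr):
        if not np.isnan(m) and m >= threshold * peak:
            return float(v)
    raise AssertionError("unreachable: peak itself satisfies the rule")


def optimal_vmax(scan: ScanResult, threshold: float = 0.99) -> float:
    """Re-apply the minimal-Vmax rule to an existing scan at a threshold."""
    return optimal_vmax_from_curve(scan.grid, scan.metrics, threshold)


@dataclass(frozen=True)
class RoundSpec:
    """One optimization round (two-phase)."""

    start_vmax: dict[str, float] = field(default_factory=dict)  # per reaction id
    yield_grid: tuple[float, ...] = tuple(float(v) for v in range(1, 11))
    yield_timescale: float = 240.0  # min; PhaC phase, metric final_PHB
    rate_grid: tuple[float, ...] = tuple(float(v) for v in range(1, 6))
    rate_timescale: float = 60.0  # min; all others, metric initial_rate
    label: str = "round1"


def run_round(
    network: Network,
    params: KineticParameters,
    scenario: ScenarioSpec,
    round_spec: RoundSpec,
) -> tuple[pd.DataFrame, dict[str, ScanResult]]:
    """Execute one two-phase optimization round.

    Phase 1 scans PhaC on final titer and fixes its optimum; phase 2
    scans every remaining enzyme (coupled groups together) on initial
    PHB production rate at the already-fixed PhaC.  Returns the loading
    table (Vmax in mM/min and the 1:1 U/mL loading) plus all scan curves.
    Deterministic given its inputs.
    """
    params = params.with_vmax(round_spec.start_vmax) if round_spec.start_vmax else params
    scans: dict[str, ScanResult] = {}

    phac_scan = scan_enzyme(network, params, scenario,
                            ScanSpec("PhaC", round_spec.yield_grid,
                                     round_spec.yield_timescale, "final_PHB"))
    scans["PhaC"] = phac_scan
    params = params.with_vmax({"PhaC": phac_scan.optimal})

    grouped = {rid for members in COUPLED_GROUPS.values() for rid in members}
    targets = [g for g in COUPLED_GROUPS] + [
        r.id for r in network.reactions if r.id not in grouped and r.id != "PhaC"
    ]
    optima: dict[str, float] = {"PhaC": phac_scan.optimal}
    for target in targets:
        sc = scan_enzyme(network, params, scenario,
                         ScanSpec(target, round_spec.rate_grid,
                                  round_spec.rate_timescale, "initial_rate"))
        scans[target] = sc
        optima[target] = sc.optimal

    rows = []
    for r in network.reactions:
        if r.id == "PhaC":
            v = optima["PhaC"]
        elif r.id in grouped:
            group = next(g for g, m in COUPLED_GROUPS.items() if r.id in m)
            v = COUPLED_GROUPS[group][r.id] * optima[group]
        else:
            v = optima[r.id]
        rows.append({"reaction": r.id, "vmax_mM_per_min": v, "loading_U_per_mL": vmax_to_loading(v)})
    return pd.DataFrame(rows), scans


def vmax_to_loading(vmax: float) -> float:
    """mM/min -> U/mL at the 1:1 numerical ratio (1 U/mL = 1 umol/(mL*min))."""
    if vmax < 0:
        raise ValueError("Vmax must be >= 0")
    return float(vmax)
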