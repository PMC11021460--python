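"""Calibration of the kinetic model against time-course data.

The study's calibration was manual ("adjust until the curves agree");
here it is formalized as bounded least squares over exactly the
parameter families that were adjusted per round (Km entries, keq
entries, the PhaC binding coefficient and exponent), with the
bifunctional XPK:FPK Vmax constraint held fixed.  Replicate means are
fitted; replicate SDs are carried for reporting only.  The loss is

    sum over datasets, time points, observables of
        ((model - replicate mean) / scale)^2

with ``scale`` the largest observed mean of that observable in that
dataset, so PHB and residual-substrate curves weigh comparably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import KineticParameters, ScenarioSpec, SimulationError, simulate
from .network import Network

__all__ = [
    "TimeCourseDataset",
    "FitSpec",
    "FitResult",
    "read_dataset",
    "write_dataset",
    "objective",
    "residuals",
    "fit",
    "compare",
]

#: observable name -> species id in the kinetic state
OBSERVABLES = {"PHB": "PHB", "maltodextrin": "MD"}


@dataclass(frozen=True)
class TimeCourseDataset:
    """Triplicate-style time-course measurements of one reaction scenario.

    ``measurements`` is a long-format frame with columns
    ``time_h, observable, replicate, value_mM``; observables are ``PHB``
    (monomer equivalents) and ``maltodextrin`` (residual glucose
    equivalents).
    """

    label: str
    scenario: ScenarioSpec
    measurements: pd.DataFrame
    provenance: Mapping[str, object] = field(default_factory=dict)
    #: enzyme loading (Vmax per reaction) the dataset was measured at; an
    #: experimental given, applied over the candidate parameters when the
    #: dataset is simulated (None = use the candidate Vmax as is)
    vmax_overrides: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        df = self.measurements
        required = {"time_h", "observable", "replicate", "value_mM"}
        if not required <= set(df.columns):
            raise ValueError(f"measurements need columns {sorted(required)}")
        if (df["value_mM"] < 0).any():
            raise ValueError("measurements must be >= 0")
        if (df["time_h"] < 0).any():
            raise ValueError("times must be >= 0")

    @property
    def replicate_count(self) -> int:
        return int(self.measurements["replicate"].nunique())

    def means(self) -> pd.DataFrame:
        """Replicate means: columns time_h, observable, mean_mM, sd_mM."""
        g = self.measurements.groupby(["observable", "time_h"])["value_mM"]
        out = g.agg(mean_mM="mean", sd_mM="std").reset_index()
        out["sd_mM"] = out["sd_mM"].fillna(0.0)
        return out.sort_values(["observable", "time_h"], ignore_index=True)


def write_dataset(ds: TimeCourseDataset, path) -> None:
    ds.measurements.to_csv(path, index=False)


def read_dataset(path, label: str, scenario: ScenarioSpec) -> TimeCourseDataset:
    df = pd.read_csv(path)
    return TimeCourseDataset(label=label, scenario=scenario, measurements=df,
                             provenance={"source": str(path)})


@dataclass(frozen=True)
class FitSpec:
    """Free parameters and bounds for a calibration round.

    ``free`` maps a parameter address to (lower, upper) bounds.  An
    address is ``("km", reaction, species)``, ``("keq", reaction)``,
    ``("c_bind", "PhaC")`` or ``("n", "PhaC")``.
    """

    free: dict[tuple, tuple[float, float]]
    pkl_ratio: float = 0.12  # fixed XPK:FPK Vmax coupling

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter set must be non-empty")
        for addr, (lo, hi) in self.free.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {addr} must satisfy 0 < lo < hi")

    def get(self, params: KineticParameters, addr: tuple) -> float:
        kind = addr[0]
        p = params[addr[1]]
        if kind == "km":
            return p.km[addr[2]]
        return getattr(p, {"keq": "keq", "c_bind": "c_bind", "n": "n"}[kind])

    def apply(self, params: KineticParameters, values: Sequence[float]) -> KineticParameters:
        recs = dict(params.reactions)
        for addr, v in zip(self.free, values):
            kind, rid = addr[0], addr[1]
            p = recs[rid]
            if kind == "km":
                recs[rid] = replace(p, km={**p.km, addr[2]: float(v)})
            else:
                recs[rid] = replace(p, **{kind: float(v)})
        out = KineticParameters(recs)
        return out.with_vmax({"FPK": self.pkl_ratio * out["XPK"].vmax}) if "XPK" in out and "FPK" in out else out


@dataclass
class FitResult:
    params: KineticParameters
    values: dict[tuple, float]
    loss: float
    start_loss: float
    converged: bool
    n_starts: int
    per_dataset_rmse: pd.DataFrame | None = None


def residuals(
    network: Network,
    params: KineticParameters,
    datasets: Sequence[TimeCourseDataset],
) -> np.ndarray:
    """Scaled model-vs-mean residual vector over all datasets."""
    res: list[float] = []
    for ds in datasets:
        means = ds.means()
        t_end = max(float(means["time_h"].max()) * 60.0, ds.scenario.t_end)
        scenario = replace(ds.scenario, t_end=t_end)
        p = params.with_vmax(dict(ds.vmax_overrides)) if ds.vmax_overrides else params
        try:
            sim = simulate(network, p, scenario)
        except SimulationError:
            return np.full(1, np.inf)
        for obs, sid in OBSERVABLES.items():
            sub = means[means["observable"] == obs]
            if sub.empty:
                continue
            scale = max(float(sub["mean_mM"].max()), 1e-12)
            for _, row in sub.iterrows():
                model = sim.at(sid, float(row["time_h"]) * 60.0)
                res.append((model - float(row["mean_mM"])) / scale)
    return np.asarray(res)


def objective(
    network: Network,
    params: KineticParameters,
    datasets: Sequence[TimeCourseDataset],
) -> float:
    """Weighted sum of squared residuals (infinite on simulation failure)."""
    r = residuals(network, params, datasets)
    if not np.all(np.isfinite(r)):
        return math.inf
    return float(np.dot(r, r))


def fit(
    network: Network,
    datasets: Sequence[TimeCourseDataset],
    spec: FitSpec,
    start: KineticParameters,
    n_starts: int = 5,
    seed: int = 0,
    max_nfev: int | None = None,
) -> FitResult:
    """Bounded multistart least squares over the free parameter set.

    Parameters are optimized in log space (all are positive scale
    parameters).  Start points are the given start plus ``n_starts - 1``
    seeded log-uniform draws within bounds.  Never returns a point worse
    than the start.
    """
    addrs = list(spec.free)
    lo = np.log([spec.free[a][0] for a in addrs])
    hi = np.log([spec.free[a][1] for a in addrs])
    x0 = np.log(np.clip([spec.get(start, a) for a in addrs], np.exp(lo), np.exp(hi)))

    def fun(x):
        p = spec.apply(start, np.exp(x))
        r = residuals(network, p, datasets)
        if not np.all(np.isfinite(r)):
            return np.full(max(r.size, len(addrs) + 1), 1e6)
        return r

    start_loss = objective(network, spec.apply(start, np.exp(x0)), datasets)
    rng = np.random.default_rng(seed)
    starts = [x0] + [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    best_x, best_loss, any_ok = x0, start_loss, False
    diagnostics = []
    for xs in starts:
        try:
            sol = least_squares(fun, xs, bounds=(lo, hi), max_nfev=max_nfev,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as err:  # pragma: no cover - scipy internal failures
            diagnostics.append(str(err))
            continue
        any_ok = True
        loss = float(2 * sol.cost)
        if loss < best_loss:
            best_x, best_loss = sol.x, loss
    if not any_ok:
        raise RuntimeError(f"all fit starts failed: {diagnostics}")

    values = dict(zip(addrs, np.exp(best_x)))
    fitted = spec.apply(start, np.exp(best_x))
    result = FitResult(params=fitted, values=values, loss=best_loss,
                       start_loss=start_loss, converged=True, n_starts=len(starts))
    result.per_dataset_rmse = compare(result, network, datasets)
    return result


def compare(
    fit_result: FitResult,
    network: Network,
    datasets: Sequence[TimeCourseDataset],
) -> pd.DataFrame:
    """Per-dataset, per-observable RMSE of the fitted model (mM)."""
    rows = []
    for ds in datasets:
        means = ds.means()
        t_end = max(float(means["time_h"].max()) * 60.0, ds.scenario.t_end)
        p = fit_result.params
        if ds.vmax_overrides:
            p = p.with_vmax(dict(ds.vmax_overrides))
        sim = simulate(network, p, replace(ds.scenario, t_end=t_end))
        for obs, sid in OBSERVABLES.items():
            sub = means[means["observable"] == obs]
            if sub.empty:
                continue
            err = [sim.at(sid, float(r["time_h"]) * 60.0) - float(r["mean_mM"])
                   for _, r in sub.iterrows()]
            rows.append({"dataset": ds.label, "observable": obs,
                         "rmse_mM": float(np.sqrt(np.mean(np.square(err)))),
                         "n_points": len(err)})
    return pd.DataFrame(rows)
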