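"""Kinetic rate laws and event-aware ODE simulation of the cascade.

Rate-law families
-----------------
* irreversible Michaelis-Menten (any number of substrates)::

      v = Vmax * prod_s (S / (Km_s + S))^|a_s|

* reversible Michaelis-Menten (rapid-equilibrium random, any arity)::

      v = Vmax / prod_s Km_s^|a_s|
          * (prod_s S^|a_s| - prod_p P^b_p / keq)
          / (prod_s (1 + S/Km_s)^|a_s| + prod_p (1 + P/Km_p)^b_p - 1)

  which returns exactly zero at thermodynamic equilibrium (mass-action
  ratio = keq) and reduces to the familiar uni-uni and bi-bi forms.

* the PHB-synthase law: Michaelis-Menten damped by a product-binding
  factor ``C_bind / (C_bind + PHB^n)`` modelling the progressive loss of
  PhaC activity as it binds the insoluble PHB granules it produces.  At
  ``PHB = 0`` (or ``C_bind`` large) it is plain Michaelis-Menten.

Water is excluded from the kinetic state (constant solvent); CO2 is a
dynamic product with no consumer.  Internal time unit is minutes,
matching Vmax in mM/min; user-facing reports are per hour.

The simulation stops *consuming substrate* when maltodextrin falls to a
configurable fraction (default 40%) of its initial concentration — the
empirical limit of alpha-glucan phosphorylase on shortening dextrin
chains.  Downstream reactions keep draining the intermediate pools to
``t_end``, so the final titer approaches the stoichiometric expectation
for the consumed substrate; both the titer at the event and at ``t_end``
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .network import Network, Reaction
from .util import round_half_up

__all__ = [
    "ReactionParams",
    "KineticParameters",
    "ScenarioSpec",
    "SimulationResult",
    "load_params_yaml",
    "shipped_params",
    "evaluate_rate",
    "simulate",
    "initial_phb_rate",
    "derived_metrics",
    "metrics_from_result",
    "conservation_series",
]

_EXCLUDED = ("H2O",)  # constant solvent, not part of the kinetic state


@dataclass(frozen=True)
class ReactionParams:
    """Kinetic constants of one reaction."""

    vmax: float  # mM/min
    km: Mapping[str, float] = field(default_factory=dict)  # mM
    keq: float | None = None  # reversible laws only
    c_bind: float | None = None  # PhaC only, mM^n
    n: float | None = None  # PhaC only, exponent of PHB

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("Vmax must be >= 0")
        if any(k <= 0 for k in self.km.values()):
            raise ValueError("Km values must be > 0")
        if self.keq is not None and self.keq <= 0:
            raise ValueError("keq must be > 0")
        if self.c_bind is not None and self.c_bind <= 0:
            raise ValueError("C_bind must be > 0")
        if self.n is not None and self.n < 0:
            raise ValueError("n must be >= 0")


class KineticParameters:
    """Per-reaction kinetic constants for a network."""

    def __init__(self, reactions: Mapping[str, ReactionParams]):
        self.reactions = dict(reactions)

    def __getitem__(self, rid: str) -> ReactionParams:
        return self.reactions[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.reactions

    def with_vmax(self, updates: Mapping[str, float]) -> "KineticParameters":
        """Copy with some Vmax values replaced (scan/optimization helper)."""
        new = dict(self.reactions)
        for rid, v in updates.items():
            new[rid] = replace(new[rid], vmax=float(v))
        return KineticParameters(new)

    def vmax_map(self) -> dict[str, float]:
        return {rid: p.vmax for rid, p in self.reactions.items()}

    def to_dict(self) -> dict:
        out = {}
        for rid, p in self.reactions.items():
            rec: dict = {"vmax": p.vmax, "km": dict(p.km)}
            if p.keq is not None:
                rec["keq"] = p.keq
            if p.c_bind is not None:
                rec["c_bind"] = p.c_bind
            if p.n is not None:
                rec["n"] = p.n
            out[rid] = rec
        return {"reactions": out}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KineticParameters":
        reactions = {}
        for rid, rec in doc["reactions"].items():
            reactions[str(rid)] = ReactionParams(
                vmax=float(rec["vmax"]),
                km={str(s): float(v) for s, v in (rec.get("km") or {}).items()},
                keq=None if rec.get("keq") is None else float(rec["keq"]),
                c_bind=None if rec.get("c_bind") is None else float(rec["c_bind"]),
                n=None if rec.get("n") is None else float(rec["n"]),
            )
        return cls(reactions)


def load_params_yaml(path_or_stream) -> KineticParameters:
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    return KineticParameters.from_dict(doc)


def shipped_params(model: str) -> KineticParameters:
    """Load one of the shipped parameter sets: ``model0``/``model1``/``model2``.

    These are synthetic stand-ins constructed from the study narrative
    (see the parameter files and docs/methods.md), not transcriptions of
    a published table.
    """
    import importlib.resources

    ref = importlib.resources.files("phbcascade.data.params") / f"{model}.yaml"
    with ref.open("r") as fh:
        return load_params_yaml(fh)


@dataclass(frozen=True)
class ScenarioSpec:
    """Initial conditions, timed additions and stop-event settings."""

    initial: Mapping[str, float] = field(
        default_factory=lambda: {"MD": 100.0, "Pi": 10.0, "NADP": 2.0, "CoA": 0.5}
    )
    additions: tuple[tuple[float, str, float], ...] = ()  # (time min, species, mM)
    t_end: float = 480.0  # min
    residual_fraction: float = 0.40  # stop-event threshold on MD/MD0
    grid_dt: float = 1.0  # min, dense-output grid
    label: str = "std100"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.initial.values()):
            raise ValueError("initial concentrations must be >= 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if not (0 < self.residual_fraction <= 1):
            raise ValueError("residual_fraction must be in (0, 1]")


@dataclass
class SimulationResult:
    """Time grid (min), per-species trajectories (mM) and the event time."""

    time: np.ndarray
    conc: np.ndarray  # shape (len(time), n_species)
    species: tuple[str, ...]
    event_time: float | None
    scenario: ScenarioSpec

    def series(self, sid: str) -> np.ndarray:
        return self.conc[:, self.species.index(sid)]

    def at(self, sid: str, t: float) -> float:
        return float(np.interp(t, self.time, self.series(sid)))

    def final(self, sid: str) -> float:
        return float(self.series(sid)[-1])

    def consumed_substrate(self) -> float:
        md = self.series("MD")
        added = sum(a for _, sid, a in self.scenario.additions if sid == "MD")
        return float(md[0] + added - md[-1])

    def dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.conc, columns=list(self.species))
        df.insert(0, "time_min", self.time)
        return df


# ---------------------------------------------------------------------------
# rate evaluation


def _law_terms(reaction: Reaction):
    subs = [(s, float(c)) for s, c in reaction.substrates.items() if s not in _EXCLUDED]
    prods = [(s, float(c)) for s, c in reaction.products.items() if s not in _EXCLUDED]
    return subs, prods


def _check_params(reaction: Reaction, p: ReactionParams) -> None:
    subs, prods = _law_terms(reaction)
    need = [s for s, _ in subs] + ([s for s, _ in prods] if reaction.reversible else [])
    missing = [s for s in need if s not in p.km]
    if missing:
        raise ValueError(f"reaction {reaction.id!r}: missing Km for {missing}")
    if reaction.reversible and p.keq is None:
        raise ValueError(f"reaction {reaction.id!r}: reversible law requires keq")
    if reaction.id == "PhaC" and (p.c_bind is None or p.n is None):
        raise ValueError("PhaC law requires c_bind and n")


def _rate_fn(reaction: Reaction, p: ReactionParams) -> Callable[[Mapping[str, float]], float]:
    _check_params(reaction, p)
    subs, prods = _law_terms(reaction)

    if reaction.id == "PhaC":
        (s_id, _), = subs
        km = p.km[s_id]

        def phac(state: Mapping[str, float]) -> float:
            s = max(state.get(s_id, 0.0), 0.0)
            phb = max(state.get("PHB", 0.0), 0.0)
            binding = p.c_bind / (p.c_bind + phb ** p.n)
            return p.vmax * s / (km + s) * binding

        return phac

    if not reaction.reversible:

        def irrev(state: Mapping[str, float]) -> float:
            v = p.vmax
            for sid, a in subs:
                s = max(state.get(sid, 0.0), 0.0)
                v *= (s / (p.km[sid] + s)) ** a
            return v

        return irrev

    def rev(state: Mapping[str, float]) -> float:
        num_fwd = 1.0
        denom_s = 1.0
        km_prod = 1.0
        for sid, a in subs:
            s = max(state.get(sid, 0.0), 0.0)
            num_fwd *= s ** a
            denom_s *= (1.0 + s / p.km[sid]) ** a
            km_prod *= p.km[sid] ** a
        num_rev = 1.0
        denom_p = 1.0
        for sid, b in prods:
            c = max(state.get(sid, 0.0), 0.0)
            num_rev *= c ** b
            denom_p *= (1.0 + c / p.km[sid]) ** b
        return (p.vmax / km_prod) * (num_fwd - num_rev / p.keq) / (denom_s + denom_p - 1.0)

    return rev


def evaluate_rate(reaction: Reaction, state: Mapping[str, float], params: KineticParameters | ReactionParams) -> float:
    """Signed reaction rate (mM/min) at the given concentrations."""
    p = params[reaction.id] if isinstance(params, KineticParameters) else params
    return _rate_fn(reaction, p)(state)


# ---------------------------------------------------------------------------
# simulation


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the failing time/state."""

    def __init__(self, message: str, t: float, state: Mapping[str, float]):
        super().__init__(message)
        self.t = t
        self.state = dict(state)


def _assemble(network: Network, params: KineticParameters, disabled: frozenset[str] = frozenset()):
    species = tuple(s.id for s in network.species if s.id not in _EXCLUDED)
    index = {sid: i for i, sid in enumerate(species)}
    terms = []  # (rate_fn over vector state, [(species index, coeff)])
    for r in network.reactions:
        if r.id in disabled:
            continue
        fn = _rate_fn(r, params[r.id])
        touch = [(index[s], float(c)) for s, c in r.stoich.items() if s not in _EXCLUDED]
        ids = [sid for sid in r.stoich if sid not in _EXCLUDED]
        terms.append((fn, touch, ids))

    def rhs(t, y):
        state = {sid: y[i] for sid, i in index.items()}
        dy = np.zeros_like(y)
        for fn, touch, _ids in terms:
            v = fn(state)
            for i, c in touch:
                dy[i] += c * v
        return dy

    return species, index, rhs


def simulate(
    network: Network,
    params: KineticParameters,
    scenario: ScenarioSpec,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the cascade ODEs under ``scenario``.

    Stiff-capable (LSODA); the substrate-exhaustion event is located by
    root-finding, after which alpha-glucan phosphorylase is switched off
    (no further substrate consumption) while the downstream cascade keeps
    running to ``t_end``.  Timed additions are applied as concentration
    discontinuities.  Raises :class:`SimulationError` on integrator
    failure rather than returning a partial trajectory.
    """
    for rid in params.reactions:
        if rid not in set(network.reaction_ids):
            pass  # extra parameter entries are tolerated (variant subsets)
    for r in network.reactions:
        if r.id not in params:
            raise ValueError(f"no kinetic parameters for reaction {r.id!r}")

    species, index, rhs = _assemble(network, params)
    y0 = np.zeros(len(species))
    for sid, c in scenario.initial.items():
        if sid in index:
            y0[index[sid]] = c
    md_i = index["MD"]
    md0 = y0[md_i]
    threshold = scenario.residual_fraction * md0

    def md_event(t, y):
        return y[md_i] - threshold

    md_event.terminal = True
    md_event.direction = -1.0

    breakpoints = sorted({t for t, _, _ in scenario.additions if 0 < t < scenario.t_end})
    segment_edges = [0.0] + breakpoints + [scenario.t_end]

    times: list[np.ndarray] = []
    concs: list[np.ndarray] = []
    event_time: float | None = None
    y = y0.copy()
    stopped = False

    for t0, t1 in zip(segment_edges[:-1], segment_edges[1:]):
        for at, sid, amount in scenario.additions:
            if at == t0 and sid in index:
                y[index[sid]] += amount
        grid = np.arange(t0, t1, scenario.grid_dt)
        if grid.size == 0 or grid[-1] < t1:
            grid = np.append(grid, t1)
        if not stopped and md0 > 0 and scenario.residual_fraction < 1.0:
            sol = solve_ivp(
                rhs, (t0, t1), y, method="LSODA", t_eval=grid,
                events=md_event, rtol=rtol, atol=atol, dense_output=True,
            )
            if not sol.success:
                raise SimulationError(sol.message, float(sol.t[-1]) if sol.t.size else t0,
                                      {sid: y[i] for sid, i in index.items()})
            times.append(sol.t)
            concs.append(sol.y.T)
            if sol.t_events[0].size:
                event_time = float(sol.t_events[0][0])
                stopped = True
                y = sol.y_events[0][0].copy()
                # substrate consumption ceases: aGP off, clamp MD exactly
                species2, index2, rhs2 = _assemble(network, params, disabled=frozenset({"aGP"}))
                grid2 = np.arange(event_time, t1, scenario.grid_dt)
                if grid2.size == 0 or grid2[-1] < t1:
                    grid2 = np.append(grid2, t1)
                sol2 = solve_ivp(rhs2, (event_time, t1), y, method="LSODA",
                                 t_eval=grid2, rtol=rtol, atol=atol)
                if not sol2.success:
                    raise SimulationError(sol2.message, float(sol2.t[-1]),
                                          {sid: y[i] for sid, i in index2.items()})
                times.append(sol2.t)
                concs.append(sol2.y.T)
                y = sol2.y[:, -1].copy()
            else:
                y = sol.y[:, -1].copy()
        else:
            rhs_used = _assemble(network, params, disabled=frozenset({"aGP"}))[2] if stopped else rhs
            sol = solve_ivp(rhs_used, (t0, t1), y, method="LSODA", t_eval=grid,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise SimulationError(sol.message, float(sol.t[-1]),
                                      {sid: y[i] for sid, i in index.items()})
            times.append(sol.t)
            concs.append(sol.y.T)
            y = sol.y[:, -1].copy()

    time = np.concatenate(times)
    conc = np.vstack(concs)
    # deduplicate segment joints (keeping the post-discontinuity state),
    # clip integration noise below zero
    keep = np.concatenate([np.diff(time) > 0, [True]])
    time, conc = time[keep], conc[keep]
    conc = np.where(conc < 0, np.where(conc < -1e-9, conc, 0.0), conc)
    if conc.min() < -1e-6:
        raise SimulationError("negative concentrations beyond tolerance",
                              float(time[conc.min(axis=1).argmin()]), {})
    return SimulationResult(time=time, conc=conc, species=species,
                            event_time=event_time, scenario=scenario)


# ---------------------------------------------------------------------------
# derived observables


def initial_phb_rate(result: SimulationResult) -> float:
    """PHB produced in the first hour of reaction, in mM/h."""
    if result.time[-1] < 60.0:
        raise ValueError("trajectory must cover at least 60 min")
    return result.at("PHB", 60.0) - result.at("PHB", 0.0)


def derived_metrics(phb_mM: float, consumed_mM: float, duration_h: float) -> dict[str, float]:
    """Yield/rate arithmetic from a (titer, consumption, duration) triple.

    molar yield = 100 x titer / consumed (one decimal, half-up);
    overall rate = titer / duration in mM/h (one decimal, half-up).
    """
    if consumed_mM <= 0:
        raise ValueError("molar yield undefined: no substrate consumed")
    if duration_h <= 0:
        raise ValueError("rate undefined: non-positive duration")
    return {
        "final_titer_mM": phb_mM,
        "consumed_mM": consumed_mM,
        "molar_yield_percent": round_half_up(100.0 * phb_mM / consumed_mM, 1),
        "rate_mM_per_h": round_half_up(phb_mM / duration_h, 1),
    }


def metrics_from_result(result: SimulationResult) -> dict[str, float]:
    """Summary of a simulation: titers at event and end, consumption, yield, rate."""
    phb_end = result.final("PHB")
    consumed = result.consumed_substrate()
    duration_h = float(result.time[-1]) / 60.0
    out = derived_metrics(phb_end, consumed, duration_h) if consumed > 0 else {
        "final_titer_mM": phb_end, "consumed_mM": consumed,
    }
    out["event_time_min"] = result.event_time if result.event_time is not None else float("nan")
    out["phb_at_event_mM"] = (
        result.at("PHB", result.event_time) if result.event_time is not None else float("nan")
    )
    return out


def conservation_series(result: SimulationResult, network: Network) -> pd.DataFrame:
    """Totals that must stay constant along a trajectory.

    Columns: total carbon (mM C, including boundary pools and CO2), the
    NADP and CoA moiety totals, and total explicit phosphate.
    """
    cols = {}
    for label, token in (("carbon", "C"), ("NADP_moiety", "NADPm"),
                         ("CoA_moiety", "CoAm"), ("phosphate", "P")):
        weights = np.array([
            network.species_by_id(sid).composition.get(token, 0) for sid in result.species
        ], dtype=float)
        cols[label] = result.conc @ weights
    df = pd.DataFrame(cols)
    df.insert(0, "time_min", result.time)
    return df
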