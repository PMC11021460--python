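"""End-to-end orchestration: build -> EFM -> simulate -> fit -> optimize.

Each stage writes delimited-text artifacts into the output directory and
the pipeline records a machine-readable manifest (stage, files, sha256
checksums, seed, package version) so a run is reproducible bit-for-bit
from its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import __version__
from .calibrate import FitSpec, fit
from .efm import cofactor_closure, mode_yields, normalize_mode, pathway_modes
from .kinetics import (KineticParameters, ScenarioSpec, load_params_yaml,
                       metrics_from_result, shipped_params, simulate)
from .network import VARIANTS, build_network, net_equation
from .optimize import RoundSpec, run_round
from .synth import DesignSpec, NoiseModel, generate_timecourse
from .util import round_half_up

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_STAGES"]

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("efm", "simulate", "gen-data", "fit", "optimize")

#: calibration free set emulating the first fitting round: Km of the
#: phosphoketolase/transketolase substrates, then PTA and PhaB, plus the
#: PhaC binding parameters.
ROUND1_FREE: dict[tuple, tuple[float, float]] = {
    ("km", "XPK", "Xu5P"): (1e-3, 10.0),
    ("km", "TK1", "Xu5P"): (1e-3, 10.0),
    ("km", "PTA", "AcP"): (1e-3, 10.0),
    ("km", "PhaB", "AcAcCoA"): (1e-4, 10.0),
    ("c_bind", "PhaC"): (1.0, 1e6),
    ("n", "PhaC"): (0.1, 4.0),
}

#: round 2 additionally frees the alpha-glucan phosphorylase keq.
ROUND2_FREE: dict[tuple, tuple[float, float]] = {
    **ROUND1_FREE,
    ("keq", "aGP"): (1e-3, 10.0),
}


@dataclass(frozen=True)
class RunConfig:
    variant: str = "full"
    model: str = "model1"  # shipped name or a YAML path
    scenario: ScenarioSpec = field(default_factory=lambda: ScenarioSpec(t_end=240.0))
    stages: tuple[str, ...] = DEFAULT_STAGES
    outdir: str | Path = "pipeline_out"
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    fit_round: int = 1
    fit_max_nfev: int | None = 40

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        bad = [s for s in self.stages if s not in DEFAULT_STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {DEFAULT_STAGES}")
        order = {s: i for i, s in enumerate(DEFAULT_STAGES)}
        idx = [order[s] for s in self.stages]
        if idx != sorted(idx):
            raise ValueError("stages must respect the pipeline order "
                             f"{DEFAULT_STAGES}")


def _load_model(model: str) -> KineticParameters:
    path = Path(model)
    if path.suffix in (".yaml", ".yml") and path.exists():
        return load_params_yaml(path)
    return shipped_params(model)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network = build_network(config.variant)
    params = _load_model(config.model)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "variant": config.variant, "model": str(config.model),
                      "stages": {}}
    produced: dict[str, list[str]] = {}
    datasets = None
    fitted = None

    for stage in config.stages:
        try:
            files: list[Path] = []
            if stage == "efm":
                rows = []
                for mode in pathway_modes(network):
                    mode = normalize_mode(mode, "aGP", 3)
                    y = mode_yields(mode, network)
                    closure = cofactor_closure(mode, network)
                    rows.append({
                        "support": "+".join(mode.support),
                        "fluxes": {k: str(v) for k, v in mode.fluxes.items()},
                        "net_equation": {k: str(v) for k, v in net_equation(mode, network).items()},
                        "molar_yield_percent": y.molar_percent,
                        "carbon_yield_percent": y.carbon_percent,
                        "closure": {k: str(v) for k, v in closure.items()},
                    })
                out = outdir / "efm_report.json"
                out.write_text(json.dumps(rows, indent=2) + "\n")
                files.append(out)
            elif stage == "simulate":
                res = simulate(network, params, config.scenario,
                               rtol=config.rtol, atol=config.atol)
                traj = outdir / "trajectory.tsv"
                res.dataframe().round(9).to_csv(traj, sep="\t", index=False)
                met = outdir / "simulation_metrics.json"
                met.write_text(json.dumps(metrics_from_result(res), indent=2) + "\n")
                files += [traj, met]
            elif stage == "gen-data":
                datasets = []
                for label, level in (("1x", 1.0), ("5x", 5.0)):
                    vm = {rid: level for rid in params.reactions}
                    vm["FPK"] = 0.12 * level
                    ds = generate_timecourse(
                        network, params.with_vmax(vm),
                        replace(config.scenario, label=label),
                        DesignSpec(label=label), NoiseModel(), seed=config.seed,
                    )
                    out = outdir / f"timecourse_{label}.csv"
                    ds.measurements.round(6).to_csv(out, index=False)
                    files.append(out)
                    datasets.append(ds)
            elif stage == "fit":
                if datasets is None:
                    raise RuntimeError("fit requires the gen-data stage")
                free = ROUND1_FREE if config.fit_round == 1 else ROUND2_FREE
                start = _load_model("model0") if config.fit_round == 1 else params
                fitted = fit(network, datasets, FitSpec(free=free), start,
                             n_starts=1, seed=config.seed, max_nfev=config.fit_max_nfev)
                out = outdir / f"fit_round{config.fit_round}.json"
                out.write_text(json.dumps({
                    "loss": fitted.loss, "start_loss": fitted.start_loss,
                    "values": {"/".join(a): v for a, v in fitted.values.items()},
                }, indent=2) + "\n")
                files.append(out)
            elif stage == "optimize":
                p = fitted.params if fitted is not None else params
                table, scans = run_round(network, p, config.scenario, RoundSpec())
                out = outdir / "loading_table.tsv"
                table.to_csv(out, sep="\t", index=False)
                files.append(out)
                curves = outdir / "scan_curves.tsv"
                import pandas as pd
                pd.concat([s.to_frame() for s in scans.values()]).to_csv(
                    curves, sep="\t", index=False)
                files.append(curves)
            produced[stage] = [f.name for f in files]
            manifest["stages"][stage] = {
                "files": {f.name: _sha256(f) for f in files},
            }
            log.info("stage %s: wrote %s", stage, [f.name for f in files])
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
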