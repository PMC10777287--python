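"""End-to-end orchestration: umbrella data → PMFs → ΔG°(T) → ΔH°/ΔS°/Tm.

A run is a pure function of (inputs, config, seed).  Per temperature the
pipeline builds histograms, checks adjacent-window overlap (warning below
20 % by default, error under strict mode), solves WHAM, optionally
bootstraps, writes the PMF table and extracts ΔG°(T); the series is then
fitted by the van't Hoff relation and reported.  A manifest records the
config, seed, package version and per-output checksums so an identical run
can be reproduced from it alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .io import (
    MetadataIndex,
    WindowTimeSeries,
    read_metadata,
    read_timeseries,
    write_pmf_table,
    write_thermo_report,
)
from .synthetic import GroundTruth, SimulationPlan, simulate_windows
from .thermo import ThermoSeries, fit_gibbs_temperature
from .wham import WHAM

log = logging.getLogger("whamtherm")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and temperature."""


@dataclass
class RunConfig:
    """Validated settings of one pipeline run.

    Either ``metadata_files`` (real or pre-generated data) or ``simulate``
    (a SimulationPlan plus GroundTruth) must be given.  Defaults follow the
    standard protocol: 150 bins, 10⁻⁶ kcal/mol tolerance, Ct = 10 μM,
    temperatures 273–333 K.
    """

    out_dir: Path
    metadata_files: list[Path] = field(default_factory=list)
    default_temperature: float | None = None
    simulate: SimulationPlan | None = None
    truth: GroundTruth | None = None
    duplex_id: str = "synthetic-duplex"
    n_bins: int = 150
    tol: float = 1e-6
    max_iter: int = 100_000
    n_boot: int = 0
    seed: int = 0
    ct: float = 1e-5
    self_complementary: bool = False
    burn_in: float = 0.0
    half_factor: bool = True
    strict_overlap: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.metadata_files and self.simulate is None:
            raise ValueError("give metadata_files or a simulation plan")
        if self.simulate is not None and self.truth is None:
            self.truth = GroundTruth()
        if self.n_bins < 2 or self.tol <= 0 or not 0 <= self.burn_in < 1:
            raise ValueError("invalid numeric settings")

    def to_jsonable(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "out_dir": str(self.out_dir),
            "metadata_files": [str(p) for p in self.metadata_files],
            "default_temperature": self.default_temperature,
            "duplex_id": self.duplex_id,
            "n_bins": self.n_bins,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "ct": self.ct,
            "self_complementary": self.self_complementary,
            "burn_in": self.burn_in,
            "half_factor": self.half_factor,
            "strict_overlap": self.strict_overlap,
        }
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["truth"] = dataclasses.asdict(self.truth)
        return d


def _load_real_windows(config: RunConfig) -> dict[float, list[WindowTimeSeries]]:
    by_temp: dict[float, list[WindowTimeSeries]] = {}
    for meta_file in config.metadata_files:
        index: MetadataIndex = read_metadata(meta_file, config.default_temperature)
        for meta in index.windows:
            by_temp.setdefault(meta.temperature, []).append(read_timeseries(meta))
    return by_temp


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and return the run report.

    Writes per-temperature PMF tables, the thermodynamic report, and a
    manifest into ``config.out_dir``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    if config.simulate is not None:
        temps = list(config.simulate.temperatures)
        windows_by_temp = {
            t: simulate_windows(config.simulate, config.truth, t) for t in temps
        }
    else:
        windows_by_temp = _load_real_windows(config)
        temps = sorted(windows_by_temp)

    per_temp: list[dict[str, Any]] = []
    temperatures, delta_gs, delta_g_errs = [], [], []
    for t in temps:
        log.info("temperature %.1f K: %d windows", t, len(windows_by_temp[t]))
        est = WHAM(
            n_bins=config.n_bins,
            tol=config.tol,
            max_iter=config.max_iter,
            half_factor=config.half_factor,
            burn_in=config.burn_in,
            n_boot=config.n_boot,
            random_state=config.seed,
        )
        try:
            est.fit(windows_by_temp[t])
        except Exception as exc:
            raise PipelineError(f"WHAM stage failed at {t} K: {exc}") from exc
        if est.overlap_ is not None and not est.overlap_.passed:
            msg = (
                f"minimum adjacent histogram overlap {est.overlap_.minimum:.3f} "
                f"< {est.overlap_.threshold:.2f} at {t} K"
            )
            if config.strict_overlap:
                raise PipelineError(f"overlap stage failed: {msg}")
            warnings.warn(msg, stacklevel=2)
        pmf_path = out / f"pmf_{t:g}K.tsv"
        write_pmf_table(est.profile_, pmf_path)
        outputs.append(pmf_path)
        from .thermo import extract_delta_g

        try:
            dg, xi_min, xi_max = extract_delta_g(est.profile_)
        except Exception as exc:
            raise PipelineError(f"dG extraction failed at {t} K: {exc}") from exc
        dg_err = float("nan")
        if est.profile_.err is not None:
            i = int(np.nanargmin(np.where(np.isfinite(est.profile_.pmf), est.profile_.pmf, np.nan)))
            dg_err = float(est.profile_.err[i])
        temperatures.append(t)
        delta_gs.append(dg)
        delta_g_errs.append(dg_err)
        per_temp.append(
            {
                "temperature_K": t,
                "delta_g_kcal_per_mol": dg,
                "xi_min_A": xi_min,
                "xi_max_A": xi_max,
                "iterations": est.n_iter_,
                "converged": est.converged_,
                "min_overlap": None if est.overlap_ is None else est.overlap_.minimum,
            }
        )

    series = ThermoSeries(
        duplex_id=config.duplex_id,
        temperatures=np.array(temperatures),
        delta_g=np.array(delta_gs),
        delta_g_err=np.array(delta_g_errs),
    )
    try:
        params = fit_gibbs_temperature(
            series, ct=config.ct, self_complementary=config.self_complementary
        )
    except Exception as exc:
        raise PipelineError(f"van't Hoff fit failed: {exc}") from exc
    report_path = out / "thermo.json"
    write_thermo_report(params, series, report_path)
    outputs.append(report_path)

    manifest = {
        "package": "whamtherm",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "params": params,
        "series": series,
        "per_temperature": per_temp,
        "outputs": [str(p) for p in outputs + [manifest_path]],
        "manifest": manifest,
    }
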