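"""Text I/O for umbrella-sampling inputs and pipeline outputs.

The metadata dialect is the one used by Grossfield-style WHAM drivers: one
window per line, ``path  bias_center  spring_constant  [temperature]``, with
``#`` comments.  Window time series are one- or two-column numeric text
(``time  value`` or just ``value``).  PMF tables are TSV with a ``#`` header;
thermodynamic reports are JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .thermo import ThermoParams, ThermoSeries
    from .wham import PMFProfile


class MetadataError(ValueError):
    """A metadata or time-series file could not be parsed."""


@dataclass(frozen=True)
class WindowMeta:
    """One umbrella window: where it is biased to, how hard, and how hot.

    Parameters
    ----------
    series_path
        Location of the reaction-coordinate time series, or None for
        in-memory windows.
    bias_center
        Restraint center ξᵢ in Å.
    bias_constant
        Harmonic spring constant K in kcal/(mol·Å²).  The bias energy
        convention (with or without the ½ factor) is decided by the solver,
        not stored here.
    temperature
        Simulation temperature in K.
    """

    series_path: Path | None
    bias_center: float
    bias_constant: float
    temperature: float

    def __post_init__(self) -> None:
        if self.bias_center < 0:
            raise ValueError(f"bias_center must be >= 0, got {self.bias_center}")
        if self.bias_constant <= 0:
            raise ValueError(f"bias_constant must be > 0, got {self.bias_constant}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass
class WindowTimeSeries:
    """Sampled reaction-coordinate values of one umbrella window."""

    meta: WindowMeta
    values: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("reaction-coordinate values must be >= 0")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.values.shape:
                raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class MetadataIndex:
    """Ordered collection of umbrella windows, grouped by temperature."""

    windows: list[WindowMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        for temp, group in self.by_temperature().items():
            centers = [w.bias_center for w in group]
            if any(b <= a for a, b in zip(centers, centers[1:])):
                raise ValueError(
                    f"bias centers must be strictly increasing within the "
                    f"{temp} K group"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def by_temperature(self) -> dict[float, list[WindowMeta]]:
        groups: dict[float, list[WindowMeta]] = {}
        for w in self.windows:
            groups.setdefault(w.temperature, []).append(w)
        return groups

    def temperatures(self) -> list[float]:
        return sorted(self.by_temperature())


def read_metadata(path: str | Path, default_temperature: float | None = None) -> MetadataIndex:
    """Parse a window metadata file.

    Each non-comment line holds ``series_path bias_center bias_constant
    [temperature]``; a missing temperature falls back to
    ``default_temperature``.  Relative series paths are resolved against the
    metadata file's directory.  Missing series files are *not* an error here —
    they fail at :func:`read_timeseries` time.
    """
    path = Path(path)
    base = path.parent
    windows: list[WindowMeta] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise MetadataError(
                    f"{path}:{lineno}: expected at least 3 fields "
                    f"(path center spring_const [temperature]), got {len(fields)}"
                )
            series = Path(fields[0])
            if not series.is_absolute():
                series = base / series
            try:
                center = float(fields[1])
                spring = float(fields[2])
                temp = float(fields[3]) if len(fields) >= 4 else default_temperature
            except ValueError as exc:
                raise MetadataError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if temp is None:
                raise MetadataError(
                    f"{path}:{lineno}: no temperature column and no default given"
                )
            windows.append(WindowMeta(series, center, spring, temp))
    return MetadataIndex(windows)


def write_metadata(index: MetadataIndex, path: str | Path, relative_to: str | Path | None = None) -> None:
    """Write a metadata index in the same dialect :func:`read_metadata` reads."""
    path = Path(path)
    lines = ["# series_path  bias_center(A)  bias_constant(kcal/mol/A^2)  temperature(K)"]
    for w in index.windows:
        if w.series_path is None:
            raise ValueError("cannot write a window without a series_path")
        p = w.series_path
        if relative_to is not None:
            p = Path(p).relative_to(relative_to)
        lines.append(f"{p}\t{w.bias_center:.6f}\t{w.bias_constant:.6f}\t{w.temperature:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_timeseries(meta: WindowMeta) -> WindowTimeSeries:
    """Load one window's reaction-coordinate series.

    Two-column files are read as ``time value``; one-column files as values
    only.  ``#`` comments and blank lines are skipped.
    """
    if meta.series_path is None:
        raise ValueError("window has no series_path")
    path = Path(meta.series_path)
    times: list[float] = []
    values: list[float] = []
    two_col: bool | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if two_col is None:
                    two_col = len(fields) >= 2
                if two_col and len(fields) >= 2:
                    times.append(float(fields[0]))
                    values.append(float(fields[1]))
                else:
                    values.append(float(fields[0]))
            except ValueError:
                raise MetadataError(f"{path}:{lineno}: non-numeric token in {fields!r}") from None
    if not values:
        raise MetadataError(f"{path}: no data lines")
    return WindowTimeSeries(
        meta=meta,
        values=np.array(values),
        times=np.array(times) if two_col else None,
    )


def write_timeseries(series: WindowTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# time(ps)\tdistance(A)\n")
        times = series.times
        if times is None:
            times = np.arange(len(series), dtype=float)
        for t, v in zip(times, series.values):
            fh.write(f"{t:.3f}\t{v:.6f}\n")


def write_pmf_table(profile: "PMFProfile", path: str | Path) -> None:
    """Write a PMF profile as TSV: bin center, PMF, bootstrap error, probability."""
    grid = profile.grid
    n = grid.n_bins
    arrays = [profile.pmf, profile.prob]
    if profile.err is not None:
        arrays.append(profile.err)
    if any(np.asarray(a).shape != (n,) for a in arrays):
        raise ValueError("profile arrays inconsistent with grid length")
    if n == 0:
        raise ValueError("refusing to write an empty profile")
    path = Path(path)
    err = profile.err if profile.err is not None else np.full(n, math.nan)
    with open(path, "w") as fh:
        fh.write(f"# temperature_K: {profile.temperature:.6f}\n")
        fh.write(f"# n_bins: {n}\n")
        fh.write(f"# tol_kcal_mol: {profile.tol:.3e}\n")
        fh.write(f"# iterations: {profile.iterations}\n")
        fh.write(f"# converged: {profile.converged}\n")
        fh.write("# bin_center_A\tpmf_kcal_mol\terr_kcal_mol\tprobability\n")
        for c, g, e, p in zip(grid.bin_centers, profile.pmf, err, profile.prob):
            fh.write(f"{c:.6f}\t{g:.6f}\t{e:.6f}\t{p:.10e}\n")


def read_pmf_table(path: str | Path) -> "PMFProfile":
    """Round-trip reader for :func:`write_pmf_table` output."""
    from .wham import HistogramGrid, PMFProfile

    path = Path(path)
    header: dict[str, str] = {}
    centers: list[float] = []
    pmf: list[float] = []
    err: list[float] = []
    prob: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    header[key.strip()] = val.strip()
                continue
            c, g, e, p = line.split("\t")
            centers.append(float(c))
            pmf.append(float(g))
            err.append(float(e))
            prob.append(float(p))
    centers_arr = np.array(centers)
    width = centers_arr[1] - centers_arr[0] if len(centers_arr) > 1 else 1.0
    grid = HistogramGrid(
        xi_min=float(centers_arr[0] - width / 2),
        xi_max=float(centers_arr[-1] + width / 2),
        n_bins=len(centers_arr),
    )
    err_arr = np.array(err)
    return PMFProfile(
        grid=grid,
        pmf=np.array(pmf),
        prob=np.array(prob),
        err=None if np.all(np.isnan(err_arr)) else err_arr,
        temperature=float(header.get("temperature_K", "nan")),
        shifts=None,
        iterations=int(header.get("iterations", "0")),
        converged=header.get("converged", "True") == "True",
        tol=float(header.get("tol_kcal_mol", "nan")),
    )


def write_thermo_report(params: "ThermoParams", series: "ThermoSeries", path: str | Path) -> None:
    """Write the thermodynamic summary as JSON.

    Units follow the reporting convention for duplex thermodynamics:
    ΔH° and ΔG°37 in kcal/mol, ΔS° in cal/(mol·K), Tm in °C.
    """
    payload = {
        "duplex_id": series.duplex_id,
        "dH_kcal_per_mol": params.dh,
        "dS_cal_per_mol_K": params.ds,
        "dG37_kcal_per_mol": params.dg37,
        "Tm_C": params.tm,
        "R2": params.r2,
        "se_dH_kcal_per_mol": params.se_dh,
        "se_dS_cal_per_mol_K": params.se_ds,
        "corrected": params.corrected,
        "ct_mol_per_L": params.ct,
        "self_complementary": params.self_complementary,
        "delta_g_by_temperature": [
            {"T_K": float(t), "dG_kcal_per_mol": float(g), "dG_err_kcal_per_mol": (None if e is None or not np.isfinite(e) else float(e))}
            for t, g, e in series.iter_entries()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_thermo_report(path: str | Path) -> tuple["ThermoParams", "ThermoSeries"]:
    """Round-trip reader for :func:`write_thermo_report` output."""
    from .thermo import ThermoParams, ThermoSeries

    payload = json.loads(Path(path).read_text())
    entries = payload["delta_g_by_temperature"]
    series = ThermoSeries(
        duplex_id=payload["duplex_id"],
        temperatures=np.array([e["T_K"] for e in entries]),
        delta_g=np.array([e["dG_kcal_per_mol"] for e in entries]),
        delta_g_err=np.array(
            [math.nan if e["dG_err_kcal_per_mol"] is None else e["dG_err_kcal_per_mol"] for e in entries]
        ),
    )
    params = ThermoParams(
        dh=payload["dH_kcal_per_mol"],
        ds=payload["dS_cal_per_mol_K"],
        dg37=payload["dG37_kcal_per_mol"],
        tm=payload["Tm_C"],
        r2=payload["R2"],
        se_dh=payload["se_dH_kcal_per_mol"],
        se_ds=payload["se_dS_cal_per_mol_K"],
        corrected=payload["corrected"],
        ct=payload["ct_mol_per_L"],
        self_complementary=payload["self_complementary"],
        duplex_id=payload["duplex_id"],
    )
    return params, series
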