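"""Synthetic umbrella-sampling data from analytic model free-energy surfaces.

The model PMF reproduces the canonical shape of a strand-separation profile:
a steep repulsive wall at near-contact distances, a single duplex well near
6 Å, a rise to a dissociation barrier, and a gently declining plateau beyond
it.  The closed form is a sum of compactly supported pieces,

    G(ξ) = wall(ξ) + well(ξ) + rise(ξ)/plateau(ξ)

    wall(ξ)   = A_wall · ((ξ_wall − ξ)/ξ_wall)³            for ξ < ξ_wall
    well(ξ)   = V_well · (1 − u²)³ ,  u = (ξ − ξ_w)/σ_w     for |u| < 1
    rise(ξ)   = H_b · s((ξ − ξ_r)/(ξ_b − ξ_r)) ,  s(u)=u²(3−2u)
    plateau(ξ)= H_b + m_p·(ξ − ξ_b)                          for ξ > ξ_b

whose supports do not overlap, so the global minimum is exactly V_well at the
well center and the post-well maximum is exactly H_b at the barrier position
ξ_b.  Setting V_well = ΔG_true(T) + H_b therefore makes the well-to-barrier
difference equal the configured ΔG_true(T) = ΔH_true − T·ΔS_true/1000
identically — every downstream stage can be checked by parameter recovery.

Window sampling is direct: the biased density p(ξ) ∝ exp(−[G(ξ)+w(ξ)]/RT) is
tabulated on a fine grid and drawn from by inverse-CDF transform (exact
marginal, no dynamics).  An AR(1) mode imposes lag-1 autocorrelation through
a Gaussian copula while preserving the marginal, to exercise error
estimation under correlated samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .constants import R_KCAL
from .io import (
    MetadataIndex,
    WindowMeta,
    WindowTimeSeries,
    write_metadata,
    write_timeseries,
)


@dataclass(frozen=True)
class ModelPMF:
    """Analytic ground-truth free-energy surface (kcal/mol vs Å).

    ``well_value`` is the PMF at the well center (negative for a stable
    duplex); the well-to-barrier difference is ``well_value − barrier_height``.
    """

    well_value: float
    well_center: float = 6.0
    well_width: float = 3.0          # half-width of the well's support, Å
    wall_height: float = 20.0        # PMF at contact (ξ=0)
    wall_cutoff: float = 3.0         # wall support [0, wall_cutoff)
    barrier_height: float = 2.0      # PMF at the barrier crest
    barrier_position: float = 30.0
    plateau_slope: float = -0.02     # kcal/mol/Å beyond the crest

    def __post_init__(self) -> None:
        if self.well_width <= 0:
            raise ValueError("well_width must be > 0")
        if self.wall_cutoff > self.well_center - self.well_width + 1e-12:
            raise ValueError("wall support must end before the well support begins")
        if self.barrier_position <= self.well_center + self.well_width:
            raise ValueError("barrier must lie beyond the well support")
        if self.well_value >= 0:
            warnings.warn(
                "well_value >= 0: the modeled duplex is unstable", stacklevel=2
            )

    @property
    def rise_start(self) -> float:
        return self.well_center + self.well_width

    @property
    def delta_g(self) -> float:
        """Exact well-to-barrier free-energy difference, kcal/mol."""
        return self.well_value - self.barrier_height

    def value(self, xi) -> np.ndarray | float:
        """Evaluate G(ξ) for ξ ≥ 0 (vectorized)."""
        x = np.asarray(xi, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        if np.any(x < 0):
            raise ValueError("xi must be >= 0")
        g = np.zeros_like(x)
        if self.wall_cutoff > 0 and self.wall_height != 0:
            m = x < self.wall_cutoff
            g[m] += self.wall_height * ((self.wall_cutoff - x[m]) / self.wall_cutoff) ** 3
        u = (x - self.well_center) / self.well_width
        m = np.abs(u) < 1
        g[m] += self.well_value * (1 - u[m] ** 2) ** 3
        span = self.barrier_position - self.rise_start
        m = (x >= self.rise_start) & (x <= self.barrier_position)
        s = (x[m] - self.rise_start) / span
        g[m] += self.barrier_height * s**2 * (3 - 2 * s)
        m = x > self.barrier_position
        g[m] += self.barrier_height + self.plateau_slope * (x[m] - self.barrier_position)
        return float(g[0]) if scalar else g


def model_pmf_value(model: ModelPMF, xi) -> np.ndarray | float:
    """Functional alias for :meth:`ModelPMF.value`."""
    return model.value(xi)


def flat_model() -> ModelPMF:
    """A model whose PMF is identically zero (null surface for solver checks)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ModelPMF(well_value=0.0, wall_height=0.0, barrier_height=0.0,
                        plateau_slope=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Target thermodynamics encoded in the model family.

    ΔG_true(T) = ΔH_true − T·ΔS_true/1000 exactly; all shape parameters other
    than the well depth are held fixed across temperature.  The defaults are
    synthetic values typical of a short (~8-mer) DNA duplex, not measurements.
    """

    dh_true: float = -60.0           # kcal/mol
    ds_true: float = -160.0          # cal/(mol·K)
    shape: dict = field(default_factory=dict)  # ModelPMF overrides (no well_value)

    def delta_g(self, temperature: float) -> float:
        return self.dh_true - temperature * self.ds_true / 1000.0


def thermo_model_pmf(truth: GroundTruth, temperature: float) -> ModelPMF:
    """Model PMF at one temperature, well depth pinned to ΔG_true(T)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    barrier = truth.shape.get("barrier_height", ModelPMF.barrier_height)
    return ModelPMF(
        well_value=truth.delta_g(temperature) + barrier, **truth.shape
    )


@dataclass(frozen=True)
class SimulationPlan:
    """Umbrella-sampling layout: window centers, bias, temperatures, sampling.

    Defaults follow the standard short-duplex protocol: windows every 0.5 Å
    from 0 to 45 Å (91 windows), a 10 kcal/(mol·Å²) harmonic bias, and seven
    temperatures from 273 to 333 K in 10 K steps.
    """

    centers: tuple[float, ...] = tuple(np.round(np.arange(0.0, 45.0 + 1e-9, 0.5), 6))
    bias_constant: float = 10.0
    temperatures: tuple[float, ...] = tuple(float(t) for t in range(273, 334, 10))
    n_per_window: int = 10_000
    seed: int = 0
    sampling_mode: str = "iid"       # "iid" | "ar1"
    ar1_corr: float = 0.9
    half_factor: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.centers)
        if np.any(np.diff(c) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.n_per_window < 1:
            raise ValueError("n_per_window must be >= 1")
        if self.sampling_mode not in ("iid", "ar1"):
            raise ValueError("sampling_mode must be 'iid' or 'ar1'")
        if self.sampling_mode == "ar1" and not 0.0 < self.ar1_corr < 1.0:
            raise ValueError("ar1_corr must be in (0, 1)")


def _tabulate_biased_density(
    model: ModelPMF, meta: WindowMeta, half_factor: bool,
    span: float, n_grid: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fine-grid CDF of p(ξ) ∝ exp(−[G(ξ)+w(ξ)]/RT) around the window center."""
    lo = max(0.0, meta.bias_center - span)
    hi = meta.bias_center + span
    xs = np.linspace(lo, hi, n_grid)
    rt = R_KCAL * meta.temperature
    factor = 0.5 if half_factor else 1.0
    u = model.value(xs) + factor * meta.bias_constant * (xs - meta.bias_center) ** 2
    p = np.exp(-(u - u.min()) / rt)
    if np.count_nonzero(p > 1e-15 * p.max()) < 2:
        raise ValueError("degenerate biased density: all mass in one grid cell")
    cdf = np.concatenate([[0.0], cumulative_trapezoid(p, xs)])
    cdf /= cdf[-1]
    return xs, cdf


def sample_window(
    model: ModelPMF,
    meta: WindowMeta,
    n: int,
    seed: int | np.random.Generator | None = None,
    mode: str = "iid",
    ar1_corr: float = 0.9,
    half_factor: bool = True,
    span: float = 4.0,
    n_grid: int = 10_001,
) -> WindowTimeSeries:
    """Draw ``n`` reaction-coordinate samples from one biased window.

    iid mode: exact inverse-CDF draws from the tabulated biased density.
    ar1 mode: a stationary Gaussian AR(1) chain with lag-1 autocorrelation
    ``ar1_corr`` is pushed through the Gaussian copula onto the same marginal.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, cdf = _tabulate_biased_density(model, meta, half_factor, span, n_grid)
    if mode == "iid":
        u = rng.random(n)
    elif mode == "ar1":
        eps = rng.standard_normal(n)
        z = np.empty(n)
        z[0] = eps[0]
        scale = np.sqrt(1.0 - ar1_corr**2)
        for t in range(1, n):
            z[t] = ar1_corr * z[t - 1] + scale * eps[t]
        u = stats.norm.cdf(z)
    else:
        raise ValueError("mode must be 'iid' or 'ar1'")
    values = np.interp(u, cdf, xs)
    return WindowTimeSeries(meta=meta, values=values)


def simulate_windows(
    plan: SimulationPlan, truth: GroundTruth, temperature: float
) -> list[WindowTimeSeries]:
    """All windows of one temperature, in memory, reproducible from the plan.

    Window seeds derive from (plan.seed, temperature, window index), so any
    temperature — in the plan's list or not — regenerates identically.
    """
    model = thermo_model_pmf(truth, temperature)
    t_key = int(round(temperature * 1000.0))
    out = []
    for c_idx, center in enumerate(plan.centers):
        meta = WindowMeta(
            series_path=None,
            bias_center=float(center),
            bias_constant=plan.bias_constant,
            temperature=float(temperature),
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([plan.seed, t_key, c_idx])
        )
        out.append(
            sample_window(
                model, meta, plan.n_per_window, seed=rng,
                mode=plan.sampling_mode, ar1_corr=plan.ar1_corr,
                half_factor=plan.half_factor,
            )
        )
    return out


def generate_dataset(
    plan: SimulationPlan, truth: GroundTruth, out_dir: str | Path
) -> dict[float, MetadataIndex]:
    """Write a full umbrella-sampling dataset plus its ground-truth record.

    One metadata file and one series file per window per temperature, plus
    ``ground_truth.json``.  Regeneration with the same plan and seed is
    byte-identical.  Returns the per-temperature metadata indices.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    indices: dict[float, MetadataIndex] = {}
    for temperature in plan.temperatures:
        windows = simulate_windows(plan, truth, temperature)
        metas = []
        for w in windows:
            name = f"win_{temperature:g}K_{w.meta.bias_center:06.2f}A.dat"
            path = out_dir / name
            meta = WindowMeta(
                series_path=path,
                bias_center=w.meta.bias_center,
                bias_constant=w.meta.bias_constant,
                temperature=w.meta.temperature,
            )
            write_timeseries(WindowTimeSeries(meta=meta, values=w.values), path)
            metas.append(meta)
        index = MetadataIndex(metas)
        write_metadata(index, out_dir / f"meta_{temperature:g}K.txt", relative_to=out_dir)
        indices[float(temperature)] = index
    record = {
        "dh_true_kcal_per_mol": truth.dh_true,
        "ds_true_cal_per_mol_K": truth.ds_true,
        "delta_g_true_by_T": {
            f"{t:g}": truth.delta_g(t) for t in plan.temperatures
        },
        "model_shape": truth.shape,
        "plan": {
            "centers": list(plan.centers),
            "bias_constant": plan.bias_constant,
            "temperatures": list(plan.temperatures),
            "n_per_window": plan.n_per_window,
            "seed": plan.seed,
            "sampling_mode": plan.sampling_mode,
            "ar1_corr": plan.ar1_corr,
            "half_factor": plan.half_factor,
        },
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(record, indent=2) + "\n")
    return indices
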