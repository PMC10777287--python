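"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Given reaction-coordinate histograms from a series of harmonically biased
windows at one temperature, the WHAM self-consistent equations recover the
unbiased probability distribution p(ξ) and hence the potential of mean force
PMF(ξ) = −RT ln p(ξ):

    p(b)  =  Σ_i n_i(b)  /  Σ_i N_i exp[(f_i − w_i(ξ_b)) / RT]
    f_i   =  −RT ln Σ_b p(b) exp[−w_i(ξ_b) / RT]

where n_i(b) are per-window bin counts, N_i in-grid totals, w_i the bias
energy of window i at the bin center, and f_i the per-window free-energy
shifts.  The equations are iterated plainly (no acceleration) until the
largest change in any f_i falls below a tolerance, by default 10⁻⁶ kcal/mol.

The bias convention is w_i(ξ) = ½K(ξ−ξᵢ)² by default (the convention of the
widely used WHAM command-line program, whose metadata dialect the io module
mirrors); ``half_factor=False`` switches to the AMBER restraint convention
w_i(ξ) = K(ξ−ξᵢ)².

Uncertainties come from a Monte-Carlo bootstrap: each window's samples are
resampled with replacement, the equations re-solved, and the per-bin standard
deviation across replicates reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .constants import OVERLAP_THRESHOLD, R_KCAL
from .io import WindowMeta, WindowTimeSeries


class WHAMError(RuntimeError):
    """WHAM could not be set up or solved on the given histograms."""


@dataclass(frozen=True)
class HistogramGrid:
    """Uniform binning of the reaction coordinate.

    Bins are half-open [edge_k, edge_{k+1}); the last bin is closed, so a
    sample exactly at ``xi_max`` is kept.
    """

    xi_min: float
    xi_max: float
    n_bins: int

    def __post_init__(self) -> None:
        if not self.xi_min < self.xi_max:
            raise ValueError("xi_min must be < xi_max")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.xi_min, self.xi_max, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_width(self) -> float:
        return (self.xi_max - self.xi_min) / self.n_bins


def default_grid(
    metas: Sequence[WindowMeta], n_bins: int = 150, half_factor: bool = True
) -> HistogramGrid:
    """Grid spanning [0, highest bias center + 3 bias standard deviations].

    The bias standard deviation √(RT / (2·factor·K)) is the width a window's
    histogram would have on a locally flat free-energy surface, so the grid
    covers essentially all samples of the outermost window.
    """
    factor = 0.5 if half_factor else 1.0
    t_max = max(m.temperature for m in metas)
    k_min = min(m.bias_constant for m in metas)
    sigma = float(np.sqrt(R_KCAL * t_max / (2.0 * factor * k_min)))
    hi = max(m.bias_center for m in metas) + 3.0 * sigma
    return HistogramGrid(xi_min=0.0, xi_max=hi, n_bins=n_bins)


@dataclass
class BiasedHistogramSet:
    """Per-window, per-bin counts on a shared grid, ordered by bias center."""

    grid: HistogramGrid
    counts: np.ndarray          # (n_windows, n_bins) integers
    totals: np.ndarray          # raw sample counts per window (incl. dropped)
    metas: list[WindowMeta]
    n_dropped: np.ndarray = field(default=None)  # out-of-grid samples per window

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.metas):
            raise ValueError("counts shape inconsistent with window list")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")
        if self.n_dropped is None:
            self.n_dropped = np.asarray(self.totals) - self.counts.sum(axis=1)

    @property
    def in_grid_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def temperature(self) -> float:
        return self.metas[0].temperature


@dataclass
class PMFProfile:
    """A potential of mean force at one temperature, with provenance.

    ``pmf`` is −RT ln p(ξ) shifted so the mean over the outer 5 % of (finite)
    bins — the dissociated plateau — is zero; bins with zero probability carry
    +inf.  ``shifts`` are the converged per-window free-energy offsets f_i.
    """

    grid: HistogramGrid
    pmf: np.ndarray
    prob: np.ndarray
    temperature: float
    shifts: np.ndarray | None = None
    err: np.ndarray | None = None
    iterations: int = 0
    converged: bool = True
    tol: float = float("nan")

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.pmf.shape != (self.grid.n_bins,) or self.prob.shape != (self.grid.n_bins,):
            raise ValueError("array lengths inconsistent with grid")


def build_histograms(
    windows: Sequence[WindowTimeSeries],
    grid: HistogramGrid,
    burn_in: float = 0.0,
    stride: int = 1,
) -> BiasedHistogramSet:
    """Histogram each window on the shared grid.

    The first ``burn_in`` fraction of every series is discarded (equilibration
    portion) and every ``stride``-th remaining sample kept (crude decorrelation
    for serially correlated input); samples outside the grid are dropped and
    counted.  All windows must share one temperature.
    """
    if not windows:
        raise WHAMError("no windows given")
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    temps = {w.meta.temperature for w in windows}
    if len(temps) > 1:
        raise WHAMError(f"windows span several temperatures: {sorted(temps)}")
    order = np.argsort([w.meta.bias_center for w in windows], kind="stable")
    windows = [windows[i] for i in order]
    edges = grid.edges
    counts = np.zeros((len(windows), grid.n_bins), dtype=np.int64)
    totals = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        keep = w.values[int(np.floor(burn_in * len(w)))::stride]
        if keep.size == 0:
            raise WHAMError(
                f"window at {w.meta.bias_center} Å is empty after burn-in"
            )
        totals[i] = keep.size
        counts[i], _ = np.histogram(keep, bins=edges)
    return BiasedHistogramSet(
        grid=grid, counts=counts, totals=totals, metas=[w.meta for w in windows]
    )


@dataclass
class OverlapReport:
    """Adjacent-window histogram overlaps and the 20 % design check."""

    fractions: np.ndarray
    minimum: float
    threshold: float
    passed: bool


def adjacent_overlap(
    hists: BiasedHistogramSet, threshold: float = OVERLAP_THRESHOLD
) -> OverlapReport:
    """Overlap Σ_b min(p_i(b), p_{i+1}(b)) for each adjacent window pair.

    Windows must be ordered by bias center (build_histograms guarantees it);
    every window needs at least one in-grid sample.
    """
    if len(hists.metas) < 2:
        raise WHAMError("need at least 2 windows for overlap")
    totals = hists.in_grid_totals
    if np.any(totals == 0):
        bad = hists.metas[int(np.argmin(totals))].bias_center
        raise WHAMError(f"window at {bad} Å has no in-grid samples")
    p = hists.counts / totals[:, None]
    fractions = np.minimum(p[:-1], p[1:]).sum(axis=1)
    minimum = float(fractions.min())
    return OverlapReport(
        fractions=fractions,
        minimum=minimum,
        threshold=threshold,
        passed=minimum >= threshold,
    )


def _bias_matrix(hists: BiasedHistogramSet, half_factor: bool) -> np.ndarray:
    factor = 0.5 if half_factor else 1.0
    centers = hists.grid.bin_centers
    c = np.array([m.bias_center for m in hists.metas])
    k = np.array([m.bias_constant for m in hists.metas])
    return factor * k[:, None] * (centers[None, :] - c[:, None]) ** 2


def _reference_shift(pmf: np.ndarray, n_bins: int) -> np.ndarray:
    """Shift so the outer 5 % of bins (the dissociated plateau) average zero."""
    tail = max(1, int(np.ceil(0.05 * n_bins)))
    tail_vals = pmf[-tail:]
    finite = tail_vals[np.isfinite(tail_vals)]
    ref = finite.mean() if finite.size else np.nanmin(pmf[np.isfinite(pmf)])
    return pmf - ref


def solve_wham(
    hists: BiasedHistogramSet,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    half_factor: bool = True,
    f_init: np.ndarray | None = None,
) -> PMFProfile:
    """Solve the WHAM equations by plain self-consistent iteration.

    Convergence is declared when the largest per-iteration change in any
    window shift f_i drops below ``tol`` (kcal/mol).  Non-convergence at
    ``max_iter`` returns the current state with ``converged=False`` and a
    warning.  ``f_init`` warm-starts the shifts (used by the bootstrap).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    grid = hists.grid
    rt = R_KCAL * hists.temperature
    m_b = hists.counts.sum(axis=0).astype(float)
    if not np.any(m_b > 0):
        raise WHAMError("all bins are empty")
    n_i = hists.in_grid_totals.astype(float)
    if np.any(n_i == 0):
        raise WHAMError("a window has no in-grid samples")
    w = _bias_matrix(hists, half_factor)
    # exp(-w/RT) underflows harmlessly to 0 far from each window's center
    c = np.exp(-w / rt)
    occupied = m_b > 0
    f = np.zeros(len(n_i)) if f_init is None else np.array(f_init, dtype=float)
    converged = False
    iterations = 0
    p = np.zeros_like(m_b)
    for iterations in range(1, max_iter + 1):
        denom = (n_i * np.exp(f / rt)) @ c
        bad = occupied & (denom <= 0.0)
        if np.any(bad):
            raise WHAMError(
                f"populated bin at {grid.bin_centers[bad][0]:.3f} Å is "
                "unreachable by every window bias"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, m_b / np.where(denom > 0, denom, 1.0), 0.0)
        p /= p.sum()
        f_new = -rt * np.log(c @ p)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max |Δf| = {delta:.3e} kcal/mol)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        pmf = np.where(p > 0, -rt * np.log(np.where(p > 0, p, 1.0)), np.inf)
    pmf = _reference_shift(pmf, grid.n_bins)
    return PMFProfile(
        grid=grid,
        pmf=pmf,
        prob=p,
        temperature=hists.temperature,
        shifts=f,
        iterations=iterations,
        converged=converged,
        tol=tol,
    )


def bootstrap_pmf(
    windows: Sequence[WindowTimeSeries],
    grid: HistogramGrid | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    n_boot: int = 100,
    seed: int | None = None,
    burn_in: float = 0.0,
    stride: int = 1,
    half_factor: bool = True,
    n_bins: int = 150,
) -> tuple[PMFProfile, np.ndarray | None]:
    """Central WHAM solution plus bootstrap per-bin uncertainties.

    Each replicate resamples every window's in-grid samples with replacement
    (same size), re-solves WHAM warm-started from the central shifts, and
    aligns to the common plateau-zero reference.  ``err`` is the per-bin
    standard deviation across replicates; the second return value is the
    relative error err(b)/|ΔG| when a well-to-barrier ΔG can be extracted,
    else None.  Replicates that fail are dropped; more than 10 % failures is
    an error.  Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    metas = [w.meta for w in windows]
    if grid is None:
        grid = default_grid(metas, n_bins=n_bins, half_factor=half_factor)
    central_hists = build_histograms(windows, grid, burn_in=burn_in, stride=stride)
    central = solve_wham(central_hists, tol=tol, max_iter=max_iter, half_factor=half_factor)

    # in-grid, post-burn-in samples per window, in the solver's center order
    order = np.argsort([w.meta.bias_center for w in windows], kind="stable")
    kept: list[np.ndarray] = []
    for i in order:
        w = windows[i]
        v = w.values[int(np.floor(burn_in * len(w)))::stride]
        v = v[(v >= grid.xi_min) & (v <= grid.xi_max)]
        kept.append(v)

    rng = np.random.default_rng(seed)
    replicates = []
    n_failed = 0
    for _ in range(n_boot):
        counts = np.zeros((len(kept), grid.n_bins), dtype=np.int64)
        totals = np.zeros(len(kept), dtype=np.int64)
        for i, v in enumerate(kept):
            resampled = v[rng.integers(0, v.size, size=v.size)]
            counts[i], _ = np.histogram(resampled, bins=grid.edges)
            totals[i] = v.size
        hists = BiasedHistogramSet(
            grid=grid, counts=counts, totals=totals, metas=central_hists.metas
        )
        try:
            prof = solve_wham(
                hists, tol=tol, max_iter=max_iter, half_factor=half_factor,
                f_init=central.shifts,
            )
        except WHAMError:
            n_failed += 1
            continue
        replicates.append(np.where(np.isfinite(prof.pmf), prof.pmf, np.nan))
    if n_failed > 0.1 * n_boot:
        raise WHAMError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    stack = np.array(replicates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        err = np.nanstd(stack, axis=0, ddof=1)
    central.err = err

    rel_err: np.ndarray | None = None
    from .thermo import ThermoError, extract_delta_g

    try:
        dg, _, _ = extract_delta_g(central)
        rel_err = err / abs(dg)
    except ThermoError:
        pass
    return central, rel_err


def bin_convergence_scan(
    windows: Sequence[WindowTimeSeries],
    bin_counts: Sequence[int],
    tol: float = 1e-6,
    max_iter: int = 100_000,
    burn_in: float = 0.0,
    half_factor: bool = True,
    plateau_floor: int = 100,
) -> tuple[pd.DataFrame, float]:
    """ΔG as a function of the bin count M, with the spread over M ≥ 100.

    Mirrors the standard check that the extracted free energy plateaus once
    the reaction coordinate is resolved by ~100 bins or more.  Returns the
    (M, ΔG) table — with a flag for M below the plateau region — and the
    max−min ΔG spread over M ≥ ``plateau_floor``.
    """
    from .thermo import ThermoError, extract_delta_g

    metas = [w.meta for w in windows]
    rows = []
    for m in bin_counts:
        if m < 2:
            raise ValueError("bin counts must be >= 2")
        grid = default_grid(metas, n_bins=int(m), half_factor=half_factor)
        hists = build_histograms(windows, grid, burn_in=burn_in)
        try:
            profile = solve_wham(hists, tol=tol, max_iter=max_iter, half_factor=half_factor)
        except WHAMError as exc:
            raise WHAMError(f"M={m}: {exc}") from exc
        try:
            dg, _, _ = extract_delta_g(profile)
        except ThermoError:
            # too few bins to resolve well and barrier; keep the row
            dg = float("nan")
        rows.append({"n_bins": int(m), "delta_g": dg, "below_plateau": m < plateau_floor})
    table = pd.DataFrame(rows)
    plateau = table.loc[~table["below_plateau"], "delta_g"]
    spread = float(plateau.max() - plateau.min()) if len(plateau) else float("nan")
    return table, spread


class WHAM(BaseEstimator):
    """WHAM potential-of-mean-force estimator for one temperature.

    Scikit-learn-style: construct with hyperparameters, call :meth:`fit` on a
    list of :class:`~whamtherm.io.WindowTimeSeries`, read fitted attributes.

    Parameters
    ----------
    n_bins : int, default 150
        Number of reaction-coordinate bins.
    tol : float, default 1e-6
        Convergence threshold on the per-iteration change of the window
        shifts, kcal/mol.
    max_iter : int, default 100000
        Iteration cap for the self-consistent loop.
    half_factor : bool, default True
        Bias convention; True means w(ξ)=½K(ξ−ξc)².
    burn_in : float, default 0.0
        Fraction of each window discarded as equilibration.
    stride : int, default 1
        Keep every stride-th sample (crude decorrelation).
    grid : HistogramGrid or None
        Explicit grid; None derives one from the window layout.
    n_boot : int, default 0
        Bootstrap replicates for per-bin errors (0 disables).
    random_state : int or None
        Bootstrap seed.

    Attributes
    ----------
    profile_ : PMFProfile
    pmf_, prob_, shifts_ : ndarray
    overlap_ : OverlapReport
    rel_err_ : ndarray or None
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_bins: int = 150,
        tol: float = 1e-6,
        max_iter: int = 100_000,
        half_factor: bool = True,
        burn_in: float = 0.0,
        stride: int = 1,
        grid: HistogramGrid | None = None,
        n_boot: int = 0,
        random_state: int | None = None,
    ):
        self.n_bins = n_bins
        self.tol = tol
        self.max_iter = max_iter
        self.half_factor = half_factor
        self.burn_in = burn_in
        self.stride = stride
        self.grid = grid
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X: Sequence[WindowTimeSeries], y=None) -> "WHAM":
        """Estimate the PMF from umbrella windows (all at one temperature)."""
        windows = list(X)
        metas = [w.meta for w in windows]
        grid = self.grid or default_grid(
            metas, n_bins=self.n_bins, half_factor=self.half_factor
        )
        self.histograms_ = build_histograms(
            windows, grid, burn_in=self.burn_in, stride=self.stride
        )
        self.overlap_ = (
            adjacent_overlap(self.histograms_) if len(windows) >= 2 else None
        )
        if self.n_boot:
            profile, rel_err = bootstrap_pmf(
                windows,
                grid=grid,
                tol=self.tol,
                max_iter=self.max_iter,
                n_boot=self.n_boot,
                seed=self.random_state,
                burn_in=self.burn_in,
                stride=self.stride,
                half_factor=self.half_factor,
            )
        else:
            profile = solve_wham(
                self.histograms_,
                tol=self.tol,
                max_iter=self.max_iter,
                half_factor=self.half_factor,
            )
            rel_err = None
        self.profile_ = profile
        self.rel_err_ = rel_err
        self.pmf_ = profile.pmf
        self.prob_ = profile.prob
        self.shifts_ = profile.shifts
        self.n_iter_ = profile.iterations
        self.converged_ = profile.converged
        return self

    def transform(self, X=None) -> PMFProfile:
        """Return the fitted PMF profile."""
        if not hasattr(self, "profile_"):
            raise RuntimeError("WHAM estimator is not fitted")
        return self.profile_
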