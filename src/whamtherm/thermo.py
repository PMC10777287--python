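"""Duplex-formation thermodynamics from potential-of-mean-force profiles.

The hybridization free energy at one temperature is read off a PMF profile as
ΔG°(T) = PMF(ξ_min) − PMF(ξ_max), the difference between the duplex well and
the dissociation barrier.  Across temperatures, the two-state van't Hoff
relation ΔG°(T) = ΔH° − T·ΔS° is fitted by ordinary least squares, giving the
enthalpy (intercept) and entropy (−slope) of duplex formation, the
conventional ΔG°37 at 310.15 K, and the melting temperature of a bimolecular
two-state transition at total strand concentration Ct:

    Tm(K) = 1000·ΔH° / (ΔS° + R·ln(Ct/m)),   m = 4 (non-self-complementary)
                                             m = 1 (self-complementary)

with ΔH° in kcal/mol, ΔS° in cal/(mol·K), R = 1.987204 cal/(mol·K).

Computed parameters can be calibrated against experimental ones by
independent linear regressions on ΔH° and ΔS° (experimental = a·computed + b);
ΔG°37 and Tm are then recomputed from the corrected ΔH°/ΔS°, never corrected
on their own.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import KELVIN_OFFSET, R_CAL, T_37C
from .wham import PMFProfile


class ThermoError(ValueError):
    """A thermodynamic quantity could not be computed from the given input."""


@dataclass
class ThermoSeries:
    """ΔG°(T) with uncertainties across simulated temperatures for one duplex."""

    duplex_id: str
    temperatures: np.ndarray    # K
    delta_g: np.ndarray         # kcal/mol
    delta_g_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.delta_g = np.asarray(self.delta_g, dtype=float)
        if self.temperatures.shape != self.delta_g.shape:
            raise ValueError("temperatures and delta_g must have equal length")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if self.delta_g_err is None:
            self.delta_g_err = np.full_like(self.delta_g, math.nan)
        else:
            self.delta_g_err = np.asarray(self.delta_g_err, dtype=float)

    def iter_entries(self) -> Iterator[tuple[float, float, float]]:
        yield from zip(self.temperatures, self.delta_g, self.delta_g_err)


@dataclass
class ThermoParams:
    """Fitted duplex-formation parameters in the field's reporting units.

    dh: ΔH° kcal/mol · ds: ΔS° cal/(mol·K) · dg37: ΔG°37 kcal/mol ·
    tm: Tm °C · r2: squared Pearson correlation of the ΔG°(T) fit.
    """

    dh: float
    ds: float
    dg37: float
    tm: float
    r2: float
    se_dh: float = math.nan
    se_ds: float = math.nan
    corrected: bool = False
    ct: float = 1e-5
    self_complementary: bool = False
    duplex_id: str | None = None

    def __post_init__(self) -> None:
        if abs(self.dg37 - (self.dh - T_37C * self.ds / 1000.0)) > 1e-9:
            raise ValueError(
                "inconsistent parameters: dG37 must equal dH - 310.15*dS/1000"
            )
        if not (math.isnan(self.r2) or 0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")


def extract_delta_g(profile: PMFProfile) -> tuple[float, float, float]:
    """ΔG°(T) = PMF(ξ_min) − PMF(ξ_max) from one PMF profile.

    ξ_min is the global finite minimum (the duplex well); ξ_max the global
    finite maximum restricted to ξ > ξ_min (the dissociation barrier — the
    profile rises out of the well, peaks, then declines slightly).  The
    near-contact repulsive wall below the well is deliberately excluded.
    Returns (ΔG in kcal/mol, ξ_min in Å, ξ_max in Å); ΔG < 0 for a stable
    duplex.
    """
    finite = np.isfinite(profile.pmf)
    if finite.sum() < 2:
        raise ThermoError("profile has fewer than 2 finite bins")
    centers = profile.grid.bin_centers
    idx = np.flatnonzero(finite)
    i_min = idx[np.argmin(profile.pmf[idx])]
    after = idx[idx > i_min]
    if after.size == 0:
        raise ThermoError(
            "no finite bins beyond the minimum; the reaction-coordinate "
            "range is too short to resolve dissociation"
        )
    i_max = after[np.argmax(profile.pmf[after])]
    if i_max == after[-1]:
        raise ThermoError(
            "PMF is still rising at the end of the grid (no barrier crest); "
            "extend the reaction-coordinate range (45 Å suffices for short "
            "duplexes, 60 Å for 14-16 bp)"
        )
    dg = float(profile.pmf[i_min] - profile.pmf[i_max])
    return dg, float(centers[i_min]), float(centers[i_max])


def melting_temperature(
    dh: float,
    ds: float,
    ct: float = 1e-5,
    self_complementary: bool = False,
) -> float:
    """Two-state bimolecular melting temperature, °C.

    Tm is the temperature at which half of the strands are duplexed, at total
    oligonucleotide concentration ``ct`` (mol/L, default 10 μM).  ``dh`` in
    kcal/mol, ``ds`` in cal/(mol·K); molecularity factor m = 1 for a
    self-complementary duplex, else 4.
    """
    if ct <= 0:
        raise ValueError("ct must be positive")
    if dh > 0 and ds < 0:
        raise ThermoError("dH > 0 with dS < 0: the duplex never melts in the two-state model")
    m = 1.0 if self_complementary else 4.0
    denom = ds + R_CAL * math.log(ct / m)
    if abs(denom) < 1e-12:
        raise ThermoError("dS + R ln(Ct/m) is ~0; Tm undefined")
    tm_k = 1000.0 * dh / denom
    return tm_k - KELVIN_OFFSET


class VantHoffModel(BaseEstimator, RegressorMixin):
    """Van't Hoff decomposition of ΔG°(T) into ΔH° and ΔS° by linear OLS.

    fit(T, ΔG) regresses ΔG on T; the intercept is ΔH° (kcal/mol) and the
    negated slope, ×1000, is ΔS° (cal/(mol·K)).  ΔG°37 is the fitted line at
    310.15 K and Tm comes from :func:`melting_temperature` with the
    configured strand concentration.

    Attributes: ``dh_``, ``ds_``, ``dg37_``, ``tm_``, ``r2_``, ``se_dh_``,
    ``se_ds_``, and ``params_`` (a :class:`ThermoParams`).
    """

    def __init__(self, ct: float = 1e-5, self_complementary: bool = False):
        self.ct = ct
        self.self_complementary = self_complementary

    def fit(self, X, y=None, duplex_id: str | None = None) -> "VantHoffModel":
        T = np.asarray(X, dtype=float).ravel()
        dg = np.asarray(y, dtype=float).ravel()
        if T.shape != dg.shape:
            raise ValueError("T and dG must have equal length")
        if np.unique(T).size < 2:
            raise ThermoError("need at least 2 distinct temperatures")
        res = stats.linregress(T, dg)
        self.dh_ = float(res.intercept)
        self.ds_ = float(-res.slope * 1000.0)
        self.r2_ = float(res.rvalue**2)
        self.se_dh_ = float(res.intercept_stderr)
        self.se_ds_ = float(res.stderr * 1000.0)
        self.dg37_ = self.dh_ - T_37C * self.ds_ / 1000.0
        self.tm_ = melting_temperature(
            self.dh_, self.ds_, ct=self.ct, self_complementary=self.self_complementary
        )
        self.params_ = ThermoParams(
            dh=self.dh_,
            ds=self.ds_,
            dg37=self.dg37_,
            tm=self.tm_,
            r2=self.r2_,
            se_dh=self.se_dh_,
            se_ds=self.se_ds_,
            ct=self.ct,
            self_complementary=self.self_complementary,
            duplex_id=duplex_id,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """ΔG°(T) from the fitted line, kcal/mol."""
        T = np.asarray(X, dtype=float)
        return self.dh_ - T * self.ds_ / 1000.0


def fit_gibbs_temperature(
    series: ThermoSeries,
    ct: float = 1e-5,
    self_complementary: bool = False,
) -> ThermoParams:
    """ΔH°/ΔS°/ΔG°37/Tm from a ΔG°(T) series (thin wrapper over VantHoffModel)."""
    model = VantHoffModel(ct=ct, self_complementary=self_complementary)
    model.fit(series.temperatures, series.delta_g, duplex_id=series.duplex_id)
    return model.params_


@dataclass
class CorrectionModel:
    """Independent linear maps experimental = a·computed + b for ΔH° and ΔS°."""

    slope_dh: float
    intercept_dh: float
    r2_dh: float
    slope_ds: float
    intercept_ds: float
    r2_ds: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 pairs")
        for s in (self.slope_dh, self.slope_ds):
            if not math.isfinite(s) or s == 0:
                raise ValueError("calibration slope must be finite and nonzero")


class LinearCorrection(BaseEstimator):
    """Calibration of computed ΔH°/ΔS° against experimental values.

    fit(computed, experimental) regresses the experimental parameter on the
    computed one, separately for ΔH° and ΔS°; transform(params) applies the
    maps and recomputes ΔG°37 and Tm from the corrected ΔH°/ΔS°.
    """

    def fit(
        self,
        X: Sequence[ThermoParams],
        y: Sequence[ThermoParams],
    ) -> "LinearCorrection":
        calc, exp = list(X), list(y)
        if len(calc) != len(exp):
            raise ValueError("computed and experimental lists differ in length")
        if len(calc) < 3:
            raise ValueError("calibration needs at least 3 pairs")
        for c, e in zip(calc, exp):
            if c.duplex_id is not None and e.duplex_id is not None and c.duplex_id != e.duplex_id:
                raise ValueError(
                    f"unmatched duplex ids: {c.duplex_id!r} vs {e.duplex_id!r}"
                )
        dh_res = stats.linregress([c.dh for c in calc], [e.dh for e in exp])
        ds_res = stats.linregress([c.ds for c in calc], [e.ds for e in exp])
        self.model_ = CorrectionModel(
            slope_dh=float(dh_res.slope),
            intercept_dh=float(dh_res.intercept),
            r2_dh=float(dh_res.rvalue**2),
            slope_ds=float(ds_res.slope),
            intercept_ds=float(ds_res.intercept),
            r2_ds=float(ds_res.rvalue**2),
            n_points=len(calc),
        )
        return self

    def transform(self, X: Sequence[ThermoParams] | ThermoParams):
        if isinstance(X, ThermoParams):
            return apply_correction(X, self.model_)
        return [apply_correction(p, self.model_) for p in X]


def calibrate_linear_correction(
    calc: Sequence[ThermoParams], exp: Sequence[ThermoParams]
) -> CorrectionModel:
    """Fit the experimental-on-computed linear maps for ΔH° and ΔS°."""
    return LinearCorrection().fit(calc, exp).model_


def apply_correction(params: ThermoParams, model: CorrectionModel) -> ThermoParams:
    """Map ΔH°/ΔS° through the calibration; ΔG°37 and Tm are re-derived.

    Refuses to correct twice.
    """
    if params.corrected:
        raise ThermoError("parameters are already corrected")
    dh = model.slope_dh * params.dh + model.intercept_dh
    ds = model.slope_ds * params.ds + model.intercept_ds
    dg37 = dh - T_37C * ds / 1000.0
    tm = melting_temperature(dh, ds, ct=params.ct, self_complementary=params.self_complementary)
    return replace(params, dh=dh, ds=ds, dg37=dg37, tm=tm, corrected=True)


@dataclass
class ErrorSummary:
    """Agreement of predicted vs experimental thermodynamic parameters.

    Mean absolute percentage errors for ΔH°, ΔS°, ΔG°37; mean absolute error
    in °C for Tm; per-parameter squared Pearson correlations.
    """

    mape_dh: float
    mape_ds: float
    mape_dg37: float
    mae_tm: float
    r2_dh: float
    r2_ds: float
    r2_dg37: float
    r2_tm: float
    n: int


def _mape(pred: np.ndarray, exp: np.ndarray, label: str) -> float:
    nonzero = exp != 0
    if not np.all(nonzero):
        warnings.warn(
            f"{int((~nonzero).sum())} pair(s) with zero experimental {label} "
            "excluded from the percentage error",
            stacklevel=3,
        )
    if not np.any(nonzero):
        return math.nan
    return float(np.mean(np.abs((pred[nonzero] - exp[nonzero]) / exp[nonzero])) * 100.0)


def _r2(pred: np.ndarray, exp: np.ndarray) -> float:
    if np.unique(exp).size < 2 or np.unique(pred).size < 2:
        return math.nan
    return float(stats.pearsonr(pred, exp).statistic ** 2)


def summarize_errors(
    pred: Sequence[ThermoParams], exp: Sequence[ThermoParams]
) -> ErrorSummary:
    """Cohort-level error statistics of predicted vs experimental parameters."""
    if len(pred) != len(exp):
        raise ValueError("paired lists differ in length")
    if not pred:
        raise ValueError("empty input")
    p_dh = np.array([p.dh for p in pred]); e_dh = np.array([e.dh for e in exp])
    p_ds = np.array([p.ds for p in pred]); e_ds = np.array([e.ds for e in exp])
    p_dg = np.array([p.dg37 for p in pred]); e_dg = np.array([e.dg37 for e in exp])
    p_tm = np.array([p.tm for p in pred]); e_tm = np.array([e.tm for e in exp])
    return ErrorSummary(
        mape_dh=_mape(p_dh, e_dh, "dH"),
        mape_ds=_mape(p_ds, e_ds, "dS"),
        mape_dg37=_mape(p_dg, e_dg, "dG37"),
        mae_tm=float(np.mean(np.abs(p_tm - e_tm))),
        r2_dh=_r2(p_dh, e_dh),
        r2_ds=_r2(p_ds, e_ds),
        r2_dg37=_r2(p_dg, e_dg),
        r2_tm=_r2(p_tm, e_tm),
        n=len(pred),
    )
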