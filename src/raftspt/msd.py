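"""Time-averaged MSD, length-weighted ensemble MSD, and the anomalous
diffusion model ``MSD(dt) = 4*Gamma*dt^alpha + offset``.

For a track r(t) sampled every ``dt`` the time-averaged MSD at lag ``k*dt``
is the mean of ``|r(t + k*dt) - r(t)|^2`` over all N-k overlapping start
times. Ensembles are averaged with weights proportional to each track's step
count, so long tracks dominate in proportion to the data they carry.

The anomalous model has three free parameters: the transport coefficient
Gamma (um^2 s^-alpha), the anomalous exponent alpha (1 = Brownian, < 1
subdiffusion), and a constant offset that absorbs the dynamic localization
error (static noise inflates the MSD by 4*sigma^2, motion blur over the
exposure deflates it by 4*D*dt/3; the net offset may be negative, which is
why it is fitted as a free parameter). The microscopic diffusion rate is the
two-point slope D = [MSD(2dt) - MSD(dt)] / (4*dt), which cancels any
lag-independent offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trajectory import Trajectory

DEFAULT_FIT_RANGE_S = (2.0e-5, 2.0e-2)  # 20 us - 20 ms
BROWNIAN_ALPHA_BAND = 0.1
MAX_FIT_LAGS = 30
MIN_PAIRS_PER_LAG = 10


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track (or a weighted ensemble)."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    n_steps: int

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if not (self.lag_s.size == self.msd_um2.size == self.n_pairs.size):
            raise ValueError("lag/msd/n_pairs lengths differ")
        if self.lag_s.size == 0:
            raise ValueError("empty MSD curve")
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be >= 0")

    @property
    def dt_s(self) -> float:
        return float(self.lag_s[0])

    def restrict(self, fit_range_s: tuple[float, float]) -> "MSDCurve":
        lo, hi = fit_range_s
        m = (self.lag_s >= lo * (1 - 1e-9)) & (self.lag_s <= hi * (1 + 1e-9))
        if not np.any(m):
            raise ValueError("no lags inside the requested range")
        return MSDCurve(self.lag_s[m], self.msd_um2[m], self.n_pairs[m], self.n_steps)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"lag_s": self.lag_s, "msd_um2": self.msd_um2, "n_pairs": self.n_pairs}
        ).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path, n_steps: int = 0) -> "MSDCurve":
        df = pd.read_csv(path)
        return cls(
            df["lag_s"].to_numpy(), df["msd_um2"].to_numpy(), df["n_pairs"].to_numpy(), n_steps
        )


def pseudo_log_lags(max_k: int, n_points: int = MAX_FIT_LAGS) -> np.ndarray:
    """<= n_points unique integer lags, roughly log-spaced on [1, max_k].

    Log spacing avoids overweighting the long-lag points, whose overlapping
    displacement pairs are strongly correlated.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    ks = np.unique(np.round(np.logspace(0, np.log10(max_k), n_points)).astype(int))
    return ks[(ks >= 1) & (ks <= max_k)]


def time_averaged_msd(
    traj: Trajectory,
    max_lag_s: float | None = None,
    lags: np.ndarray | None = None,
    use_truth: bool = False,
) -> MSDCurve:
    """Overlapping-pair time-averaged MSD on a pseudo-log lag grid.

    Lags with fewer than 10 displacement pairs are dropped with a warning.
    """
    dt = traj.frame_interval_s
    n = traj.n_steps
    xy = traj.true_xy if use_truth else traj.xy
    explicit = lags is not None
    if lags is None:
        if max_lag_s is None:
            max_lag_s = DEFAULT_FIT_RANGE_S[1]
        max_k = int(np.floor(max_lag_s / dt + 1e-9))
        if max_k < 1:
            raise ValueError("max_lag_s below one frame interval")
        # canonical grid over the requested range (not the track length), so
        # tracks of different lengths share lag values and can be ensembled;
        # lags the track cannot support are silently capped
        lags = pseudo_log_lags(max_k)
        lags = lags[lags <= n - MIN_PAIRS_PER_LAG]
    lags = np.asarray(lags, dtype=int)
    if lags.size == 0:
        raise ValueError("no lag has enough displacement pairs")
    msd = np.empty(lags.size)
    n_pairs = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        d = xy[k:] - xy[:-k]
        msd[i] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
        n_pairs[i] = n - k
    keep = n_pairs >= MIN_PAIRS_PER_LAG
    if not np.all(keep):
        if explicit:
            warnings.warn(
                f"dropped {np.sum(~keep)} lag(s) with fewer than {MIN_PAIRS_PER_LAG} pairs"
            )
        lags, msd, n_pairs = lags[keep], msd[keep], n_pairs[keep]
    if lags.size == 0:
        raise ValueError("no lag has enough displacement pairs")
    return MSDCurve(lag_s=lags * dt, msd_um2=msd, n_pairs=n_pairs, n_steps=n)


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Length-weighted ensemble MSD: weights ``N_i / sum_j N_j``.

    Curves must be computed on the same canonical lag grid (same frame
    interval and requested range). At lags that only the longer tracks reach,
    the weights are renormalized over the curves that carry the lag, so an
    ensemble of unequal-length tracks spans the full requested range instead
    of truncating at the shortest track.
    """
    if not curves:
        raise ValueError("ensemble_msd requires at least one curve")
    steps = np.array([float(c.n_steps) for c in curves])
    if np.any(steps <= 0):
        raise ValueError("curves must carry positive step counts")
    all_lags = np.unique(np.concatenate([c.lag_s for c in curves]))
    num = np.zeros(all_lags.size)
    den = np.zeros(all_lags.size)
    pairs = np.zeros(all_lags.size, dtype=int)
    for w, c in zip(steps, curves):
        idx = np.searchsorted(all_lags, c.lag_s)
        num[idx] += w * c.msd_um2
        den[idx] += w
        pairs[idx] += c.n_pairs
    return MSDCurve(all_lags, num / den, pairs, n_steps=int(steps.sum()))


def microscopic_d(curve: MSDCurve) -> float:
    """Two-point microscopic diffusion rate at the frame interval.

    ``D = [MSD(2*dt) - MSD(dt)] / (4*dt)`` — the finite difference between
    the first two MSD points, which cancels any lag-independent offset. A
    negative value (noise-dominated track) is returned as-is with a warning.
    """
    dt = curve.lag_s[0]
    i2 = np.flatnonzero(np.isclose(curve.lag_s, 2 * dt, rtol=1e-6))
    if i2.size == 0:
        raise ValueError("curve must contain lags dt and 2*dt")
    d = float((curve.msd_um2[i2[0]] - curve.msd_um2[0]) / (4 * dt))
    if d < 0:
        warnings.warn("negative microscopic D (noise-dominated); not clipped")
    return d


def transient_d(traj: Trajectory, segment_len: int = 146) -> pd.DataFrame:
    """Microscopic D over non-overlapping fixed-length segments.

    Returns a frame with segment center times and per-segment two-point D;
    the trailing remainder is dropped. A track shorter than two segments
    yields a single-segment result with a warning.
    """
    n = traj.n_steps
    n_seg = n // segment_len
    if n_seg < 2:
        warnings.warn("trajectory shorter than two segments; single-segment result")
        n_seg = 1
        segment_len = n
    t_c = np.empty(n_seg)
    d = np.empty(n_seg)
    for i in range(n_seg):
        seg = traj.slice(i * segment_len, (i + 1) * segment_len)
        curve = time_averaged_msd(seg, max_lag_s=2.5 * seg.frame_interval_s)
        d[i] = microscopic_d(curve)
        t_c[i] = 0.5 * (seg.t[0] + seg.t[-1])
    return pd.DataFrame({"t_center_s": t_c, "d_um2_s": d})


# ----------------------------------------------------------------------
# anomalous-diffusion model
# ----------------------------------------------------------------------


def _anomalous(lag, gamma, alpha, offset):
    return 4.0 * gamma * lag**alpha + offset


@dataclass
class AnomalousFitResults:
    """Results of the anomalous-diffusion MSD fit.

    Attributes
    ----------
    gamma : float
        Anomalous transport coefficient, um^2 s^-alpha.
    alpha : float
        Anomalous exponent (1 = Brownian).
    offset_um2 : float
        Fitted lag-independent offset (dynamic localization error), um^2.
    d_micro_um2_s : float
        Two-point microscopic diffusion rate of the fitted curve.
    bse : ndarray
        Approximate standard errors of (gamma, alpha, offset).
    fit_rms : float
        RMS residual of the fit, um^2.
    alpha_loglog : float or nan
        Cross-check exponent: slope of log(MSD - offset) vs log(lag).
    classification : str
        'BROWNIAN' if |alpha - 1| <= 0.1, else 'SUB'/'SUPER'; 'DEGENERATE'
        for offset-only fits.
    """

    gamma: float
    alpha: float
    offset_um2: float
    d_micro_um2_s: float
    bse: np.ndarray
    fit_rms: float
    alpha_loglog: float
    classification: str
    curve: MSDCurve = field(repr=False)
    fit_range_s: tuple[float, float] = DEFAULT_FIT_RANGE_S

    @property
    def params(self) -> np.ndarray:
        return np.array([self.gamma, self.alpha, self.offset_um2])

    def predict(self, lag_s: np.ndarray | None = None) -> np.ndarray:
        if lag_s is None:
            lag_s = self.curve.lag_s
        return _anomalous(np.asarray(lag_s, dtype=float), *self.params)

    def summary(self) -> str:
        lines = [
            "Anomalous diffusion MSD fit",
            "    MSD(dt) = 4*Gamma*dt^alpha + offset",
            f"  lags fitted     : {self.curve.lag_s.size} "
            f"({self.fit_range_s[0]:.3g}-{self.fit_range_s[1]:.3g} s)",
            f"  Gamma           : {self.gamma:.4g} +/- {self.bse[0]:.2g} um^2 s^-alpha",
            f"  alpha           : {self.alpha:.4f} +/- {self.bse[1]:.2g}",
            f"  offset          : {self.offset_um2:.4g} +/- {self.bse[2]:.2g} um^2",
            f"  D (2-point)     : {self.d_micro_um2_s:.4g} um^2/s",
            f"  alpha (log-log) : {self.alpha_loglog:.4f}",
            f"  fit RMS         : {self.fit_rms:.3g} um^2",
            f"  classification  : {self.classification}",
        ]
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {
            "gamma": self.gamma,
            "alpha": self.alpha,
            "offset_um2": self.offset_um2,
            "d_micro_um2_s": self.d_micro_um2_s,
            "classification": self.classification,
            "fit_range_s": list(self.fit_range_s),
        }


class AnomalousDiffusionModel:
    """Nonlinear least-squares fit of the anomalous MSD model to a curve.

    Parameters
    ----------
    curve : MSDCurve
        Time-averaged (or ensemble) MSD.
    fit_range_s : (float, float)
        Lag range used for fitting, default 20 us - 20 ms.
    weights : {'statistical', 'pairs', 'none'}
        Residual weighting. The default 'statistical' uses the standard
        error model of the overlapping time-averaged MSD of a Brownian
        track, ``sigma_k ~ MSD_k * sqrt(2k / (3 n_pairs_k))`` with k the lag
        in frames: the relative error of the time average grows with lag, so
        unweighted linear least squares lets the noisy long-lag tail dominate
        and roughly sextuples the spread of the fitted exponent on
        few-thousand-step tracks. 'pairs' weights by sqrt(n_pairs) only;
        'none' is plain least squares.
    brownian_band : float
        Half-width of the |alpha - 1| band classified as Brownian.
    """

    def __init__(
        self,
        curve: MSDCurve,
        fit_range_s: tuple[float, float] = DEFAULT_FIT_RANGE_S,
        weights: str = "statistical",
        brownian_band: float = BROWNIAN_ALPHA_BAND,
    ):
        self.curve = curve.restrict(fit_range_s)
        if self.curve.lag_s.size < 5:
            raise ValueError("need at least 5 lags inside fit_range_s")
        if weights not in ("statistical", "pairs", "none"):
            raise ValueError("weights must be 'statistical', 'pairs' or 'none'")
        self.fit_range_s = fit_range_s
        self.weights = weights
        self.brownian_band = brownian_band

    def _classify(self, alpha: float) -> str:
        if abs(alpha - 1.0) <= self.brownian_band:
            return "BROWNIAN"
        return "SUB" if alpha < 1.0 else "SUPER"

    def fit(self) -> AnomalousFitResults:
        lag = self.curve.lag_s
        msd = self.curve.msd_um2
        spread = msd[-1] - msd[0]
        if spread <= 0 or spread < 1e-9 * max(msd[-1], 1e-30):
            # curve consistent with a constant: offset-only degenerate fit
            offset = float(np.mean(msd))
            return AnomalousFitResults(
                gamma=0.0,
                alpha=1.0,
                offset_um2=offset,
                d_micro_um2_s=0.0,
                bse=np.full(3, np.nan),
                fit_rms=float(np.sqrt(np.mean((msd - offset) ** 2))),
                alpha_loglog=np.nan,
                classification="DEGENERATE",
                curve=self.curve,
                fit_range_s=self.fit_range_s,
            )
        # initial values: Brownian slope through the first points, offset from
        # a linear extrapolation of the first two points to lag 0
        offset0 = msd[0] - (msd[1] - msd[0]) * lag[0] / (lag[1] - lag[0])
        gamma0 = max(spread / (4.0 * (lag[-1] - lag[0])), 1e-12)
        p0 = [gamma0, 1.0, offset0]
        if self.weights == "statistical":
            k = lag / lag[0]
            npairs = self.curve.n_pairs.astype(float)
            sigma = msd * np.sqrt(2.0 * k / (3.0 * npairs))
            sigma = np.maximum(sigma, 1e-12 * max(msd.max(), 1e-30))
        elif self.weights == "pairs":
            sigma = 1.0 / np.sqrt(self.curve.n_pairs.astype(float))
        else:
            sigma = None
        popt, pcov = curve_fit(
            _anomalous,
            lag,
            msd,
            p0=p0,
            sigma=sigma,
            bounds=([0.0, 1e-3, -np.inf], [np.inf, 2.0, np.inf]),
            maxfev=20000,
        )
        gamma, alpha, offset = (float(v) for v in popt)
        resid = msd - _anomalous(lag, *popt)
        fit_rms = float(np.sqrt(np.mean(resid**2)))
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        # log-log cross-check after offset subtraction
        corrected = msd - offset
        if np.all(corrected > 0):
            slope = np.polyfit(np.log(lag), np.log(corrected), 1)[0]
            alpha_loglog = float(slope)
        else:
            warnings.warn("negative offset-corrected MSD; log-log cross-check skipped")
            alpha_loglog = np.nan
        pred = _anomalous(np.array([lag[0], 2 * lag[0]]), *popt)
        d_micro = float((pred[1] - pred[0]) / (4 * lag[0]))
        return AnomalousFitResults(
            gamma=gamma,
            alpha=alpha,
            offset_um2=offset,
            d_micro_um2_s=d_micro,
            bse=bse,
            fit_rms=fit_rms,
            alpha_loglog=alpha_loglog,
            classification=self._classify(alpha),
            curve=self.curve,
            fit_range_s=self.fit_range_s,
        )


def fit_anomalous(
    curve: MSDCurve,
    fit_range_s: tuple[float, float] = DEFAULT_FIT_RANGE_S,
    **kwargs,
) -> AnomalousFitResults:
    """Convenience wrapper: fit the anomalous model over ``fit_range_s``."""
    return AnomalousDiffusionModel(curve, fit_range_s=fit_range_s, **kwargs).fit()
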