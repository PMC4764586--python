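"""Displacement statistics: MSD, apparent D, and displacement-CDF fits.

For 2-D free diffusion with apparent coefficient D, the radial
displacement r over a lag Δt has the cumulative distribution

    P(r, Δt) = 1 − exp(−r² / 4·D·Δt)                      (one component)

and a two-population mixture (slow fraction A) follows

    P(r, Δt) = 1 − [A·exp(−r²/4·D_slow·Δt) + (1−A)·exp(−r²/4·D_fast·Δt)].

Fitting these forms to the empirical CDF of pooled single-lag
displacements ("CDF deconvolution") estimates the apparent diffusion
coefficient, or the slow/fast subpopulation split.  All fits here use
lag-1 displacements supplied by :func:`collect_displacements`, least
squares on the empirical CDF evaluated at 200 quantile points of the
data.  Diffusion coefficients are *apparent*: localization error is not
subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.distributions.empirical_distribution import ECDF

from sptmap.errors import ConfigurationError, FitError

__all__ = [
    "DisplacementSet",
    "CdfFit",
    "MsdCurve",
    "ExplorationArea",
    "collect_displacements",
    "empirical_cdf",
    "cdf_one_model",
    "cdf_two_model",
    "fit_cdf_one",
    "fit_cdf_two",
    "msd_ensemble",
    "apparent_D_per_track",
    "apparent_D_table",
    "exploration_area",
    "track_lifetimes",
]

D_BOUNDS = (1e-4, 10.0)  # μm²/s search interval for all CDF fits
N_QUANTILES = 200


@dataclass
class DisplacementSet:
    """Pooled radial displacements at one fixed lag.

    ``values`` are the radial displacements r (μm); ``origin_x/origin_y``
    the start point of each displacement; ``track_ids`` and ``frames``
    identify the source localization.
    """

    lag: float  # seconds
    values: np.ndarray
    origin_x: np.ndarray
    origin_y: np.ndarray
    track_ids: np.ndarray
    frames: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CdfFit:
    """Result of a one- or two-component displacement-CDF fit."""

    n_components: int
    lag: float
    n_displacements: int
    residual_ss: float
    D_app: Optional[float] = None
    A: Optional[float] = None
    D_slow: Optional[float] = None
    D_fast: Optional[float] = None
    flagged: bool = False

    @property
    def fast_fraction(self) -> Optional[float]:
        return None if self.A is None else 1.0 - self.A

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "lag_s": self.lag,
            "n_displacements": self.n_displacements,
            "residual_ss": self.residual_ss,
            "D_app": self.D_app,
            "A": self.A,
            "D_slow": self.D_slow,
            "D_fast": self.D_fast,
            "flagged": self.flagged,
        }


@dataclass
class MsdCurve:
    """Ensemble MSD per lag with SEM over per-track means."""

    lags: np.ndarray  # seconds, strictly increasing
    msd: np.ndarray  # μm²
    sem: np.ndarray  # μm²
    n: np.ndarray  # displacement count per lag

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags, "msd_um2": self.msd, "sem_um2": self.sem, "n": self.n}
        )


@dataclass
class ExplorationArea:
    """MSD plateau estimate, reported as the explored area (μm²)."""

    area: float
    plateau: bool  # False ⇒ MSD still rising over the window ("no plateau")
    window_slope: float
    initial_slope: float


def _iter_tracks(tracks: pd.DataFrame):
    keys = [c for c in ("channel", "track_id") if c in tracks.columns]
    return tracks.groupby(keys, sort=True)


def collect_displacements(
    tracks: pd.DataFrame, lag_frames: int = 1, frame_interval: float = 0.035
) -> DisplacementSet:
    """Pool radial displacements at one lag over all tracks.

    Emits one displacement per (track, frame) pair that has a
    localization at both ``t`` and ``t + lag_frames`` (overlapping
    windows).
    """
    if lag_frames < 1:
        raise ConfigurationError("lag_frames must be >= 1")
    vals, oxs, oys, tids, frs = [], [], [], [], []
    for key, grp in _iter_tracks(tracks):
        grp = grp.sort_values("frame")
        frames = grp.frame.to_numpy()
        x = grp.x_um.to_numpy()
        y = grp.y_um.to_numpy()
        pos = {int(f): i for i, f in enumerate(frames)}
        idx0, idx1 = [], []
        for i, f in enumerate(frames):
            j = pos.get(int(f) + lag_frames)
            if j is not None:
                idx0.append(i)
                idx1.append(j)
        if not idx0:
            continue
        i0 = np.asarray(idx0)
        i1 = np.asarray(idx1)
        vals.append(np.hypot(x[i1] - x[i0], y[i1] - y[i0]))
        oxs.append(x[i0])
        oys.append(y[i0])
        tid = key[-1] if isinstance(key, tuple) else key
        tids.append(np.full(len(i0), tid))
        frs.append(frames[i0])

    def cat(parts, dtype=float):
        return (
            np.concatenate(parts) if parts else np.array([], dtype=dtype)
        )

    return DisplacementSet(
        lag=lag_frames * frame_interval,
        values=cat(vals),
        origin_x=cat(oxs),
        origin_y=cat(oys),
        track_ids=cat(tids, dtype=object),
        frames=cat(frs, dtype=np.int64),
    )


def empirical_cdf(d: DisplacementSet | np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Right-continuous empirical CDF of the pooled displacements."""
    values = d.values if isinstance(d, DisplacementSet) else np.asarray(d, dtype=float)
    if len(values) == 0:
        raise ValueError("empty displacement set")
    return ECDF(values, side="right")


def cdf_one_model(r: np.ndarray, D: float, dt: float) -> np.ndarray:
    """One-component model CDF P(r, Δt) = 1 − exp(−r²/4DΔt)."""
    return 1.0 - np.exp(-np.square(r) / (4.0 * D * dt))


def cdf_two_model(
    r: np.ndarray, A: float, D_slow: float, D_fast: float, dt: float
) -> np.ndarray:
    """Two-component mixture CDF with slow fraction A."""
    return 1.0 - (
        A * np.exp(-np.square(r) / (4.0 * D_slow * dt))
        + (1.0 - A) * np.exp(-np.square(r) / (4.0 * D_fast * dt))
    )


def _fit_grid(d: DisplacementSet) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation grid (r at 200 evenly spaced quantiles) and ECDF values."""
    q = (np.arange(N_QUANTILES) + 0.5) / N_QUANTILES
    r_grid = np.quantile(d.values, q)
    return r_grid, empirical_cdf(d)(r_grid)


def fit_cdf_one(d: DisplacementSet, min_n: int = 100) -> CdfFit:
    """Fit the one-component CDF model; returns the apparent D.

    Least squares between the model and the empirical CDF on a fixed
    grid of 200 quantile points; D bounded in [1e-4, 10] μm²/s.
    """
    if len(d) < min_n:
        raise ConfigurationError(f"need >= {min_n} displacements, got {len(d)}")
    r_grid, y = _fit_grid(d)

    def ss(logD: float) -> float:
        return float(np.sum((cdf_one_model(r_grid, 10.0**logD, d.lag) - y) ** 2))

    res = optimize.minimize_scalar(
        ss, bounds=np.log10(D_BOUNDS), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise FitError(f"one-component CDF fit failed: {res.message}")
    return CdfFit(
        n_components=1, lag=d.lag, n_displacements=len(d),
        residual_ss=float(res.fun), D_app=float(10.0**res.x),
    )


def _fit_A_only(
    r_grid: np.ndarray, y: np.ndarray, dt: float, D_slow: float, D_fast: float
) -> tuple[float, float]:
    def ss(A: float) -> float:
        return float(np.sum((cdf_two_model(r_grid, A, D_slow, D_fast, dt) - y) ** 2))

    res = optimize.minimize_scalar(
        ss, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-10}
    )
    return float(res.x), float(res.fun)


def fit_cdf_two(
    d: DisplacementSet,
    fix_D: Optional[tuple[float, float]] = None,
    fix_A: Optional[float] = None,
    min_n: int = 1000,
) -> CdfFit:
    """Fit the two-component CDF mixture (A, D_slow, D_fast).

    ``fix_D=(D_slow, D_fast)`` holds both coefficients and fits only the
    slow fraction A — the shared-coefficient convention (0.1/0.4 μm²/s)
    for comparing conditions.  ``fix_A`` holds A instead (0 or 1 reduces
    the model to one component).  A fit with A stuck at a boundary is
    returned flagged rather than raising.
    """
    if len(d) < min_n:
        raise ConfigurationError(f"need >= {min_n} displacements, got {len(d)}")
    if fix_D is not None and fix_A is not None:
        raise ConfigurationError("fix_D and fix_A are mutually exclusive")
    r_grid, y = _fit_grid(d)
    dt = d.lag

    if fix_D is not None:
        D_slow, D_fast = sorted(fix_D)
        if D_slow >= D_fast:
            raise ConfigurationError("fix_D requires two distinct coefficients")
        A, rss = _fit_A_only(r_grid, y, dt, D_slow, D_fast)
        return CdfFit(
            n_components=2, lag=dt, n_displacements=len(d), residual_ss=rss,
            A=A, D_slow=D_slow, D_fast=D_fast,
            flagged=bool(A < 1e-3 or A > 1.0 - 1e-3),
        )

    if fix_A is not None:
        if not 0.0 <= fix_A <= 1.0:
            raise ConfigurationError("fix_A must be in [0, 1]")
        if fix_A in (0.0, 1.0):
            # degenerate one-component problem in the surviving coefficient
            one = fit_cdf_one(d, min_n=min_n)
            D = one.D_app
            Ds, Df = (D, D_BOUNDS[1]) if fix_A == 1.0 else (D_BOUNDS[0], D)
            return CdfFit(
                n_components=2, lag=dt, n_displacements=len(d),
                residual_ss=one.residual_ss, A=fix_A, D_slow=Ds, D_fast=Df,
            )

        def resid_fixA(p: np.ndarray) -> np.ndarray:
            return cdf_two_model(r_grid, fix_A, 10.0 ** p[0], 10.0 ** p[1], dt) - y

        lo, hi = np.log10(D_BOUNDS)
        res = optimize.least_squares(
            resid_fixA, x0=[lo / 2 + hi / 2 - 1.0, lo / 2 + hi / 2 + 0.5],
            bounds=([lo, lo], [hi, hi]),
        )
        Ds, Df = sorted(10.0**res.x)
        return CdfFit(
            n_components=2, lag=dt, n_displacements=len(d),
            residual_ss=float(np.sum(res.fun**2)), A=fix_A, D_slow=Ds, D_fast=Df,
        )

    # free fit: A, log10 D_slow, log10 D_fast, several starts
    lo, hi = np.log10(D_BOUNDS)

    def resid(p: np.ndarray) -> np.ndarray:
        return cdf_two_model(r_grid, p[0], 10.0 ** p[1], 10.0 ** p[2], dt) - y

    one = fit_cdf_one(d, min_n=min_n)
    base = np.log10(one.D_app)
    starts = [
        [0.5, base - 0.5, base + 0.5],
        [0.3, base - 1.0, base + 0.3],
        [0.7, base - 0.3, base + 1.0],
    ]
    best = None
    for x0 in starts:
        x0 = [np.clip(x0[0], 0, 1), np.clip(x0[1], lo, hi), np.clip(x0[2], lo, hi)]
        res = optimize.least_squares(
            resid, x0=x0, bounds=([0.0, lo, lo], [1.0, hi, hi])
        )
        if best is None or res.cost < best.cost:
            best = res
    A = float(best.x[0])
    Ds, Df = float(10.0 ** best.x[1]), float(10.0 ** best.x[2])
    if Ds > Df:  # enforce D_slow < D_fast by relabeling
        Ds, Df = Df, Ds
        A = 1.0 - A
    return CdfFit(
        n_components=2, lag=dt, n_displacements=len(d),
        residual_ss=float(np.sum(best.fun**2)), A=A, D_slow=Ds, D_fast=Df,
        flagged=bool(A < 1e-3 or A > 1.0 - 1e-3),
    )


def msd_ensemble(
    tracks: pd.DataFrame, max_lag_frames: int, frame_interval: float = 0.035
) -> MsdCurve:
    """Ensemble MSD over lags 1..max_lag_frames (overlapping windows).

    The MSD value at each lag pools all displacements; the error bar is
    the standard error over per-track mean squared displacements (tracks
    are the independent units).  Lags no track supports are omitted.
    """
    if max_lag_frames < 1:
        raise ConfigurationError("max_lag_frames must be >= 1")
    lags, msds, sems, ns = [], [], [], []
    per_track: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for _, grp in _iter_tracks(tracks):
        grp = grp.sort_values("frame")
        per_track.append(
            (grp.frame.to_numpy(), grp.x_um.to_numpy(), grp.y_um.to_numpy())
        )
    for lag in range(1, max_lag_frames + 1):
        all_sq: list[np.ndarray] = []
        track_means: list[float] = []
        for frames, x, y in per_track:
            pos = {int(f): i for i, f in enumerate(frames)}
            pairs = [
                (i, pos[int(f) + lag]) for i, f in enumerate(frames)
                if int(f) + lag in pos
            ]
            if not pairs:
                continue
            i0 = np.array([p[0] for p in pairs])
            i1 = np.array([p[1] for p in pairs])
            sq = (x[i1] - x[i0]) ** 2 + (y[i1] - y[i0]) ** 2
            all_sq.append(sq)
            track_means.append(float(sq.mean()))
        if not all_sq:
            continue
        pooled = np.concatenate(all_sq)
        tm = np.asarray(track_means)
        sem = float(tm.std(ddof=1) / np.sqrt(len(tm))) if len(tm) > 1 else np.nan
        lags.append(lag * frame_interval)
        msds.append(float(pooled.mean()))
        sems.append(sem)
        ns.append(len(pooled))
    return MsdCurve(
        lags=np.asarray(lags), msd=np.asarray(msds),
        sem=np.asarray(sems), n=np.asarray(ns, dtype=np.int64),
    )


def apparent_D_per_track(track: pd.DataFrame, frame_interval: float = 0.035) -> float:
    """Apparent D of one track: mean lag-1 squared displacement / 4Δt."""
    if len(track) < 2:
        raise ValueError("track must have at least 2 localizations")
    grp = track.sort_values("frame")
    frames = grp.frame.to_numpy()
    x, y = grp.x_um.to_numpy(), grp.y_um.to_numpy()
    step = np.flatnonzero(np.diff(frames) == 1)
    if len(step) == 0:
        raise ValueError("track has no consecutive-frame displacement")
    sq = (x[step + 1] - x[step]) ** 2 + (y[step + 1] - y[step]) ** 2
    return float(sq.mean() / (4.0 * frame_interval))


def apparent_D_table(
    tracks: pd.DataFrame, frame_interval: float = 0.035
) -> pd.Series:
    """Per-track apparent D for a whole trajectory table."""
    out = {}
    for key, grp in _iter_tracks(tracks):
        if len(grp) < 2:
            continue
        tid = key[-1] if isinstance(key, tuple) else key
        out[tid] = apparent_D_per_track(grp, frame_interval)
    return pd.Series(out, name="D_app")


def exploration_area(
    msd: MsdCurve, plateau_window: float = 1.0 / 3.0
) -> ExplorationArea:
    """Estimate the MSD plateau and report it as the exploration area.

    The plateau is the mean MSD over the last ``plateau_window`` fraction
    of lags.  If the MSD is still rising there (window slope above 10% of
    the initial slope) the result is flagged ``plateau=False``.
    """
    if len(msd.lags) < 10:
        raise ConfigurationError("MSD curve must have >= 10 lags")
    k = max(int(np.ceil(plateau_window * len(msd.lags))), 2)
    tail_l, tail_m = msd.lags[-k:], msd.msd[-k:]
    area = float(tail_m.mean())
    window_slope = float(np.polyfit(tail_l, tail_m, 1)[0])
    initial_slope = float(msd.msd[0] / msd.lags[0])
    plateau = window_slope <= 0.10 * initial_slope
    return ExplorationArea(
        area=area, plateau=plateau,
        window_slope=window_slope, initial_slope=initial_slope,
    )


def track_lifetimes(
    tracks: pd.DataFrame, frame_interval: float = 0.035
) -> pd.Series:
    """Lifetime per track, as n_localizations × Δt (3 frames ⇒ 105 ms)."""
    keys = [c for c in ("channel", "track_id") if c in tracks.columns]
    return tracks.groupby(keys, sort=True).size() * frame_interval
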