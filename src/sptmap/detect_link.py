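"""Sub-pixel spot detection and nearest-neighbour track linking.

Detection: frames are background-subtracted (median), smoothed with a
Gaussian filter specified by its half-width-at-half-maximum (1.3 px
default; sd = HWHM/√(2 ln 2)), thresholded at a multiple of the robust
(MAD-based) background noise, and candidate maxima are refined by local
least-squares 2-D Gaussian fits.  Detections closer than twice the
filter HWHM are merged to the brighter one.

Linking: globally greedy nearest neighbour — all frame-to-frame
candidate pairs within ``max_disp`` (5 px ≈ 533 nm default) are sorted
by distance (ties broken by detection index) and accepted when both
endpoints are still unused.  No gap closing: a particle lost for one
frame starts a new track.  Tracks shorter than ``min_track_len``
(3 frames default) are dropped on export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from sptmap.io import TRACK_COLUMNS, empty_tracks

__all__ = ["Detection", "LinkConfig", "detect_spots", "detect_stack", "link_tracks"]

HWHM_TO_SD = 1.0 / np.sqrt(2.0 * np.log(2.0))


@dataclass
class Detection:
    """One fitted spot: sub-pixel position in pixel units."""

    frame: int
    x: float
    y: float
    amplitude: float
    fit_sd: float
    background: float
    saturated: bool = False


@dataclass(frozen=True)
class LinkConfig:
    filter_hwhm: float = 1.3  # px
    detect_threshold: float = 5.0  # multiples of robust background sd
    max_disp: float = 5.0  # px
    min_track_len: int = 3  # localizations

    def validate(self) -> "LinkConfig":
        if self.max_disp <= 0:
            raise ValueError("max_disp must be > 0")
        if self.min_track_len < 1:
            raise ValueError("min_track_len must be >= 1")
        return self


def _gaussian2d(params, xx, yy):
    x0, y0, amp, sd, off = params
    return off + amp * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sd**2)
    )


def _fit_spot(img: np.ndarray, cx: int, cy: int, sd0: float, win: int = 3):
    """Least-squares Gaussian refinement in a (2·win+1)² window.

    Returns (x, y, amplitude, sd, offset) or None if the fit is
    unusable; positions are clamped to the window.
    """
    nrow, ncol = img.shape
    r0, r1 = max(cy - win, 0), min(cy + win + 1, nrow)
    c0, c1 = max(cx - win, 0), min(cx + win + 1, ncol)
    patch = img[r0:r1, c0:c1].astype(float)
    if patch.size < 9:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]

    def resid(p):
        return (_gaussian2d(p, xx, yy) - patch).ravel()

    amp0 = max(float(patch.max() - patch.min()), 1e-3)
    p0 = [cx, cy, amp0, sd0, float(patch.min())]
    bounds = (
        [c0 - 0.5, r0 - 0.5, 1e-6, 0.3, -np.inf],
        [c1 - 0.5, r1 - 0.5, np.inf, 2.0 * win, np.inf],
    )
    try:
        res = optimize.least_squares(resid, p0, bounds=bounds, max_nfev=200)
    except Exception:
        return None
    if not np.isfinite(res.x).all():
        return None
    return tuple(float(v) for v in res.x)


def detect_spots(
    frame: np.ndarray, cfg: LinkConfig, frame_index: int = 0
) -> list[Detection]:
    """Detect sub-pixel spots in one frame.

    Saturated fit windows (any raw pixel at the 16-bit ceiling) are kept
    but flagged.
    """
    cfg.validate()
    img = np.asarray(frame, dtype=float)
    if img.min() < 0:
        raise ValueError("frame must be non-negative")
    bg = float(np.median(img))
    sub = img - bg
    sd_filter = cfg.filter_hwhm * HWHM_TO_SD
    sm = gaussian_filter(sub, sd_filter)
    noise = 1.4826 * float(np.median(np.abs(sm - np.median(sm))))
    if noise == 0.0:
        # noiseless frame: any real signal still stands out; use a tiny floor
        noise = 1e-12
    thr = cfg.detect_threshold * noise
    peaks = peak_local_max(
        sm, min_distance=max(int(round(sd_filter)), 1), threshold_abs=thr
    )
    dets: list[Detection] = []
    for py, px in peaks:
        fit = _fit_spot(sub, int(px), int(py), sd_filter)
        if fit is None:
            continue
        x, y, amp, sd, off = fit
        if amp <= 0:
            continue
        win = img[max(py - 3, 0) : py + 4, max(px - 3, 0) : px + 4]
        dets.append(
            Detection(
                frame=frame_index, x=x, y=y, amplitude=amp, fit_sd=sd,
                background=bg + off, saturated=bool((win >= 65535).any()),
            )
        )
    # merge detections closer than 2×HWHM: keep the brighter one
    dets.sort(key=lambda d: -d.amplitude)
    kept: list[Detection] = []
    merge_r = 2.0 * cfg.filter_hwhm
    for d in dets:
        if all(np.hypot(d.x - k.x, d.y - k.y) >= merge_r for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


def detect_stack(stack: np.ndarray, cfg: LinkConfig) -> list[list[Detection]]:
    """Run :func:`detect_spots` on every frame of a stack."""
    return [
        detect_spots(stack[i], cfg, frame_index=i) for i in range(len(stack))
    ]


def link_tracks(
    detections: list[list[Detection]],
    cfg: LinkConfig,
    pixel_size: float = 1.0,
    channel: str = "ch0",
) -> pd.DataFrame:
    """Link per-frame detections into trajectories (greedy nearest neighbour).

    ``detections`` is one list per frame, in frame order.  Output is a
    trajectory table with positions converted to μm via ``pixel_size``
    (leave at 1.0 for pixel units); tracks shorter than
    ``cfg.min_track_len`` are discarded.
    """
    cfg.validate()
    if not detections:
        return empty_tracks()

    next_id = 0
    # active: detection index in previous frame -> track id
    prev_dets: list[Detection] = []
    prev_ids: list[int] = []
    rows: list[tuple[int, int, float, float]] = []

    for frame_idx, dets in enumerate(detections):
        cur_ids = [-1] * len(dets)
        if prev_dets and dets:
            cand = []
            for i, p in enumerate(prev_dets):
                for j, c in enumerate(dets):
                    dist = float(np.hypot(c.x - p.x, c.y - p.y))
                    if dist <= cfg.max_disp:
                        cand.append((dist, i, j))
            cand.sort()
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for dist, i, j in cand:
                if i in used_prev or j in used_cur:
                    continue
                used_prev.add(i)
                used_cur.add(j)
                cur_ids[j] = prev_ids[i]
        for j, det in enumerate(dets):
            if cur_ids[j] < 0:
                cur_ids[j] = next_id
                next_id += 1
            rows.append((cur_ids[j], frame_idx, det.x, det.y))
        prev_dets, prev_ids = list(dets), cur_ids

    if not rows:
        return empty_tracks()
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px"])
    sizes = df.groupby("track_id").size()
    keep = sizes[sizes >= cfg.min_track_len].index
    df = df[df.track_id.isin(keep)].copy()
    df["x_um"] = df.x_px * pixel_size
    df["y_um"] = df.y_px * pixel_size
    df["channel"] = channel
    # renumber exported tracks densely
    remap = {tid: k for k, tid in enumerate(sorted(df.track_id.unique()))}
    df["track_id"] = df.track_id.map(remap)
    return df[TRACK_COLUMNS].sort_values(["track_id", "frame"]).reset_index(drop=True)
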