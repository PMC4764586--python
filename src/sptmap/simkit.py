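"""Synthetic single-particle-tracking data with retained ground truth.

Generates trajectory populations with the statistical structure that the
downstream analyses assume: free Brownian motion, two-state switching
diffusion, confined (corralled) diffusion in reflecting square corrals,
tethered (jittering) particles, adhesion-shaped slow zones, dual-channel
co-moving particle pairs, and rendered camera movies.  Every simulation
returns a :class:`GroundTruth` record so recovery can be scored exactly.

Conventions
-----------
* Positions are in μm; the field origin is the top-left corner, x grows
  rightward and y downward (image convention).
* One displacement step per frame interval; a Brownian step has variance
  ``2·D·Δt`` per coordinate.
* Localization noise is added to the *reported* positions only; the
  underlying walk stays Markovian.
* Track lengths (in localizations) are geometric with the configured
  mean — memoryless photobleaching — with a minimum of one frame.
* Free tracks are simulated in an unbounded plane; only movie rendering
  clips to the field, so no artificial confinement is introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import erf

from sptmap.errors import ConfigurationError
from sptmap.io import TRACK_COLUMNS

__all__ = [
    "SimConfig",
    "MotionSpec",
    "GroundTruth",
    "simulate_tracks",
    "simulate_adhesion_field",
    "simulate_comoving_channels",
    "expected_pair_count",
    "render_movie",
    "render_marker_image",
]


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and noise model shared by all simulations.

    Defaults follow a streaming TIRF acquisition: 35 ms frame interval,
    107 nm pixels, 500 frames.  ``localization_sd`` is the per-coordinate
    standard deviation of the localization error in μm (25 nm default, a
    typical single-molecule localization precision); ``mean_track_length``
    is the mean of the geometric track-length (bleaching) distribution in
    frames (6.2 frames ≈ 200 ms mean lifetime).
    """

    frame_interval: float = 0.035
    pixel_size: float = 0.107
    field_size: tuple[float, float] = (20.0, 20.0)
    n_frames: int = 500
    localization_sd: float = 0.025
    mean_track_length: float = 6.2
    rng_seed: int = 0

    def validate(self) -> "SimConfig":
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.localization_sd < 0:
            raise ConfigurationError("localization_sd must be non-negative")
        if self.mean_track_length < 1:
            raise ConfigurationError("mean_track_length must be >= 1 frame")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if min(self.field_size) <= 0:
            raise ConfigurationError("field_size must be positive")
        return self

    def field_shape_px(self) -> tuple[int, int]:
        """(rows, cols) of the pixel grid covering the field."""
        w, h = self.field_size
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))


@dataclass(frozen=True)
class MotionSpec:
    """Per-track motion model.

    ``kind`` selects the model:

    * ``brownian`` — free diffusion with coefficient ``D``;
    * ``two_state`` — Markov switching between a fast state 1 (``D1``)
      and a slow state 2 (``D2``), with rates ``k12`` (1→2) and ``k21``
      (2→1) in s⁻¹;
    * ``confined`` — diffusion with ``D_in`` inside a reflecting square
      corral of side ``corral_side`` μm;
    * ``tethered`` — a stationary anchor plus i.i.d. Gaussian jitter of
      sd ``tether_sd`` per coordinate.
    """

    kind: str = "brownian"
    D: float = 0.2
    D1: float = 0.4
    D2: float = 0.1
    k12: float = 1.0
    k21: float = 1.0
    D_in: float = 0.4
    corral_side: float = 0.5
    tether_sd: float = 0.02

    def validate(self) -> "MotionSpec":
        if self.kind not in {"brownian", "two_state", "confined", "tethered"}:
            raise ConfigurationError(f"unknown motion kind {self.kind!r}")
        if self.kind == "brownian" and self.D < 0:
            raise ConfigurationError("D must be >= 0")
        if self.kind == "two_state":
            if self.D1 < 0 or self.D2 < 0:
                raise ConfigurationError("D1, D2 must be >= 0")
            if self.D1 <= self.D2:
                raise ConfigurationError("two_state requires D1 > D2")
            if self.k12 < 0 or self.k21 < 0:
                raise ConfigurationError("switching rates must be >= 0")
        if self.kind == "confined":
            if self.D_in < 0:
                raise ConfigurationError("D_in must be >= 0")
            if self.corral_side <= 0:
                raise ConfigurationError("corral_side must be > 0")
        if self.kind == "tethered" and self.tether_sd < 0:
            raise ConfigurationError("tether_sd must be >= 0")
        return self


@dataclass
class GroundTruth:
    """What the simulator actually did, keyed by track id.

    ``tracks`` has one row per track (motion kind and parameters);
    ``steps`` (two-state and adhesion-field runs) has one row per
    displacement step with its true state / zone flag; ``pairs``
    (dual-channel runs) lists true co-moving partners and their overlap
    window.
    """

    tracks: pd.DataFrame
    steps: Optional[pd.DataFrame] = None
    pairs: Optional[pd.DataFrame] = None

    def write(self, prefix) -> None:
        """Write ground-truth CSV sidecars ``<prefix>_{tracks,steps,pairs}.csv``."""
        self.tracks.to_csv(f"{prefix}_tracks.csv", index=False)
        if self.steps is not None:
            self.steps.to_csv(f"{prefix}_steps.csv", index=False)
        if self.pairs is not None:
            self.pairs.to_csv(f"{prefix}_pairs.csv", index=False)


def _track_lengths(
    rng: np.random.Generator, config: SimConfig, n: int, track_length: Optional[int]
) -> np.ndarray:
    if track_length is not None:
        if track_length < 1:
            raise ConfigurationError("track_length must be >= 1")
        return np.full(n, track_length, dtype=np.int64)
    if config.mean_track_length <= 1.0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 / config.mean_track_length, size=n).astype(np.int64)


def _fold(x: np.ndarray, side: float) -> np.ndarray:
    """Fold unconstrained coordinates into [0, side] by mirror reflection.

    Folding the free-diffusion proposal reproduces the exact transition
    density of reflected Brownian motion in an interval (method of
    images), so no sub-stepping is needed for the corral walls.
    """
    x = np.mod(x, 2.0 * side)
    return np.where(x > side, 2.0 * side - x, x)


def _two_state_chain(
    rng: np.random.Generator, n_steps: int, k12: float, k21: float, dt: float
) -> np.ndarray:
    """Sample a state sequence (values 1/2) of length ``n_steps``."""
    p12 = 1.0 - np.exp(-k12 * dt)
    p21 = 1.0 - np.exp(-k21 * dt)
    if p12 + p21 == 0.0:
        return np.ones(n_steps, dtype=np.int8)
    states = np.empty(n_steps, dtype=np.int8)
    # start from the stationary distribution of the discretized chain
    state = 2 if rng.random() < p12 / (p12 + p21) else 1
    u = rng.random(n_steps)
    for i in range(n_steps):
        states[i] = state
        if state == 1:
            if u[i] < p12:
                state = 2
        else:
            if u[i] < p21:
                state = 1
    return states


def simulate_tracks(
    config: SimConfig,
    motion: MotionSpec,
    n_tracks: int,
    *,
    track_length: Optional[int] = None,
    channel: str = "ch0",
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate ``n_tracks`` trajectories under one motion model.

    Track lengths are geometric with mean ``config.mean_track_length``
    (minimum one localization) unless ``track_length`` pins them; start
    frames are uniform over the acquisition and tracks are truncated at
    the last frame.  Reported positions carry additive Gaussian
    localization noise of sd ``config.localization_sd`` per coordinate.

    Returns the trajectory table and a :class:`GroundTruth` with one
    record per track (plus per-step state labels for two-state motion).
    """
    config.validate()
    motion.validate()
    if n_tracks < 1:
        raise ConfigurationError("n_tracks must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval
    w, h = config.field_size

    lengths = _track_lengths(rng, config, n_tracks, track_length)
    if track_length is not None:
        starts = np.zeros(n_tracks, dtype=np.int64)
    else:
        starts = rng.integers(0, config.n_frames, size=n_tracks)
        lengths = np.minimum(lengths, config.n_frames - starts)

    rows: list[pd.DataFrame] = []
    gt_rows: list[dict] = []
    step_rows: list[pd.DataFrame] = []
    for tid in range(n_tracks):
        n = int(lengths[tid])
        if motion.kind == "tethered":
            anchor = rng.uniform((0.0, 0.0), (w, h))
            true = anchor + rng.normal(0.0, motion.tether_sd, size=(n, 2))
            gt_rows.append(
                {"track_id": tid, "kind": "tethered", "tether_sd": motion.tether_sd,
                 "anchor_x": anchor[0], "anchor_y": anchor[1]}
            )
        elif motion.kind == "confined":
            L = motion.corral_side
            cx = rng.uniform(0.0, max(w - L, 0.0))
            cy = rng.uniform(0.0, max(h - L, 0.0))
            sd = np.sqrt(2.0 * motion.D_in * dt)
            rel = np.empty((n, 2))
            rel[0] = rng.uniform(0.0, L, size=2)
            if n > 1:
                steps = rng.normal(0.0, sd, size=(n - 1, 2))
                for i in range(1, n):
                    rel[i] = _fold(rel[i - 1] + steps[i - 1], L)
            true = rel + (cx, cy)
            gt_rows.append(
                {"track_id": tid, "kind": "confined", "D_in": motion.D_in,
                 "corral_side": L, "corral_x": cx, "corral_y": cy}
            )
        elif motion.kind == "two_state":
            start = rng.uniform((0.0, 0.0), (w, h))
            states = _two_state_chain(rng, max(n - 1, 0), motion.k12, motion.k21, dt)
            sd_by_state = np.sqrt(
                2.0 * np.where(states == 1, motion.D1, motion.D2) * dt
            )
            steps = rng.normal(0.0, 1.0, size=(max(n - 1, 0), 2)) * sd_by_state[:, None]
            true = start + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
            gt_rows.append(
                {"track_id": tid, "kind": "two_state", "D1": motion.D1,
                 "D2": motion.D2, "k12": motion.k12, "k21": motion.k21}
            )
            if n > 1:
                step_rows.append(
                    pd.DataFrame(
                        {"track_id": tid, "step": np.arange(n - 1),
                         "state": states.astype(np.int64)}
                    )
                )
        else:  # brownian
            start = rng.uniform((0.0, 0.0), (w, h))
            sd = np.sqrt(2.0 * motion.D * dt)
            steps = rng.normal(0.0, sd, size=(max(n - 1, 0), 2))
            true = start + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
            gt_rows.append({"track_id": tid, "kind": "brownian", "D": motion.D})

        reported = true
        if config.localization_sd > 0:
            reported = true + rng.normal(0.0, config.localization_sd, size=true.shape)
        frames = starts[tid] + np.arange(n)
        rows.append(
            pd.DataFrame(
                {"track_id": tid, "frame": frames, "x_um": reported[:, 0],
                 "y_um": reported[:, 1], "channel": channel}
            )
        )

    tracks = pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]
    steps_df = pd.concat(step_rows, ignore_index=True) if step_rows else None
    gt = GroundTruth(tracks=pd.DataFrame(gt_rows), steps=steps_df)
    return tracks, gt


# ---------------------------------------------------------------------------
# adhesion-shaped slow zones


@dataclass(frozen=True)
class _Ellipse:
    cx: float
    cy: float
    a: float  # semi-major, μm
    b: float  # semi-minor, μm
    theta: float

    def contains(self, x: np.ndarray, y: np.ndarray, margin: float = 0.0) -> np.ndarray:
        ct, st = np.cos(self.theta), np.sin(self.theta)
        dx, dy = x - self.cx, y - self.cy
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / (self.a + margin)) ** 2 + (v / (self.b + margin)) ** 2 <= 1.0


def _place_ellipses(
    rng: np.random.Generator, config: SimConfig, n: int, size: float
) -> list[_Ellipse]:
    w, h = config.field_size
    a, b = size / 2.0, size / 4.0
    out: list[_Ellipse] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ConfigurationError(
                f"cannot place {n} non-overlapping adhesions of size {size} μm "
                f"in a {w}x{h} μm field"
            )
        cand = _Ellipse(
            cx=rng.uniform(a, w - a),
            cy=rng.uniform(a, h - a),
            a=a,
            b=b,
            theta=rng.uniform(0.0, np.pi),
        )
        # conservative non-overlap: centre distance beyond summed semi-majors
        if all(np.hypot(cand.cx - e.cx, cand.cy - e.cy) > cand.a + e.a for e in out):
            out.append(cand)
    return out


def _ellipse_mask(config: SimConfig, ellipses: list[_Ellipse]) -> np.ndarray:
    shape = config.field_shape_px()
    mask = np.zeros(shape, dtype=bool)
    if not ellipses:
        return mask
    px = config.pixel_size
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    xum = (xx + 0.5) * px
    yum = (yy + 0.5) * px
    for e in ellipses:
        mask |= e.contains(xum, yum)
    return mask


def simulate_adhesion_field(
    config: SimConfig,
    n_adhesions: int,
    adhesion_size: float,
    D_near: float,
    D_far: float,
    *,
    n_tracks: int = 500,
    inside_fraction: Optional[float] = None,
    dilation_margin: float = 0.0,
    track_length: Optional[int] = None,
    channel: str = "ch0",
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Simulate tracks in a field of elliptical adhesion-shaped slow zones.

    Elliptical zones (major axis ``adhesion_size`` μm, axis ratio 2:1,
    random orientation) are placed without overlap.  A particle's step
    variance uses ``D_near`` while its true position lies inside a zone
    (dilated by ``dilation_margin``) and ``D_far`` otherwise.  If
    ``inside_fraction`` is given, that fraction of tracks start inside a
    zone; otherwise starts are uniform over the field.

    Returns (tracks, mask, ground truth); the mask is a boolean pixel
    image of the zones.
    """
    config.validate()
    if D_near > D_far:
        raise ConfigurationError("require D_near <= D_far")
    if D_near < 0:
        raise ConfigurationError("diffusion coefficients must be >= 0")
    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval
    w, h = config.field_size

    ellipses = _place_ellipses(rng, config, n_adhesions, adhesion_size)
    mask = _ellipse_mask(config, ellipses)

    def inside(p: np.ndarray) -> bool:
        return any(
            bool(e.contains(np.array(p[0]), np.array(p[1]), margin=dilation_margin))
            for e in ellipses
        )

    lengths = _track_lengths(rng, config, n_tracks, track_length)
    if track_length is not None:
        starts = np.zeros(n_tracks, dtype=np.int64)
    else:
        starts = rng.integers(0, config.n_frames, size=n_tracks)
        lengths = np.minimum(lengths, config.n_frames - starts)

    rows, gt_rows, step_rows = [], [], []
    for tid in range(n_tracks):
        n = int(lengths[tid])
        start_inside = False
        if inside_fraction is not None and ellipses and rng.random() < inside_fraction:
            e = ellipses[rng.integers(len(ellipses))]
            while True:
                u = rng.uniform(-e.a, e.a)
                v = rng.uniform(-e.b, e.b)
                if (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0:
                    break
            ct, st = np.cos(e.theta), np.sin(e.theta)
            pos = np.array([e.cx + u * ct - v * st, e.cy + u * st + v * ct])
            start_inside = True
        else:
            pos = rng.uniform((0.0, 0.0), (w, h))
            start_inside = inside(pos)

        true = np.empty((n, 2))
        true[0] = pos
        in_zone = np.empty(max(n - 1, 0), dtype=bool)
        for i in range(1, n):
            here = inside(true[i - 1])
            in_zone[i - 1] = here
            D = D_near if here else D_far
            true[i] = true[i - 1] + rng.normal(0.0, np.sqrt(2.0 * D * dt), size=2)

        reported = true
        if config.localization_sd > 0:
            reported = true + rng.normal(0.0, config.localization_sd, size=true.shape)
        frames = starts[tid] + np.arange(n)
        rows.append(
            pd.DataFrame(
                {"track_id": tid, "frame": frames, "x_um": reported[:, 0],
                 "y_um": reported[:, 1], "channel": channel}
            )
        )
        gt_rows.append(
            {"track_id": tid, "kind": "adhesion_field", "D_near": D_near,
             "D_far": D_far, "start_inside": start_inside,
             "fraction_inside": float(in_zone.mean()) if n > 1 else float(start_inside)}
        )
        if n > 1:
            step_rows.append(
                pd.DataFrame(
                    {"track_id": tid, "step": np.arange(n - 1), "in_zone": in_zone}
                )
            )

    tracks = pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]
    steps_df = pd.concat(step_rows, ignore_index=True) if step_rows else None
    gt = GroundTruth(tracks=pd.DataFrame(gt_rows), steps=steps_df)
    return tracks, mask, gt


# ---------------------------------------------------------------------------
# dual-channel co-moving pairs


def expected_pair_count(n_mrna: int, comoving_fraction: float) -> float:
    """Binomial-mean number of true co-moving pairs."""
    return n_mrna * comoving_fraction


def simulate_comoving_channels(
    config: SimConfig,
    n_mrna: int,
    n_ribo: int,
    comoving_fraction: float,
    pair_offset_sd: float,
    motion_comoving: MotionSpec,
    motion_free: MotionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a dual-channel acquisition with a co-moving subpopulation.

    Each mRNA track is independently co-moving with probability
    ``comoving_fraction``.  A co-moving mRNA moves under
    ``motion_comoving`` and is shadowed by a partner ribosome whose
    position is the mRNA's reported position plus i.i.d. Gaussian jitter
    of sd ``pair_offset_sd`` per coordinate over the full track window.
    All other tracks (free mRNA and the remaining ribosomes) move
    independently under ``motion_free``.
    """
    config.validate()
    motion_comoving.validate()
    motion_free.validate()
    if not 0.0 <= comoving_fraction <= 1.0:
        raise ConfigurationError("comoving_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.rng_seed)

    comover = rng.random(n_mrna) < comoving_fraction
    n_pairs = int(comover.sum())
    if n_ribo < n_pairs:
        raise ConfigurationError(
            f"n_ribo={n_ribo} smaller than required partners ({n_pairs})"
        )

    mrna_parts, gt_tracks, pair_rows = [], [], []
    for tid in range(n_mrna):
        spec = motion_comoving if comover[tid] else motion_free
        t, g = simulate_tracks(
            config, spec, 1, channel="mrna", rng=rng
        )
        t = t.assign(track_id=tid)
        rec = g.tracks.iloc[0].to_dict()
        rec.update(track_id=tid, channel="mrna", comoving=bool(comover[tid]))
        mrna_parts.append(t)
        gt_tracks.append(rec)
    mrna = pd.concat(mrna_parts, ignore_index=True)

    ribo_parts = []
    rid = 0
    for tid in np.flatnonzero(comover):
        base = mrna[mrna.track_id == tid]
        jitter = (
            rng.normal(0.0, pair_offset_sd, size=(len(base), 2))
            if pair_offset_sd > 0
            else np.zeros((len(base), 2))
        )
        ribo_parts.append(
            pd.DataFrame(
                {"track_id": rid, "frame": base.frame.to_numpy(),
                 "x_um": base.x_um.to_numpy() + jitter[:, 0],
                 "y_um": base.y_um.to_numpy() + jitter[:, 1], "channel": "ribo"}
            )
        )
        gt_tracks.append(
            {"track_id": rid, "channel": "ribo", "kind": "partner",
             "comoving": True, "partner_mrna": int(tid)}
        )
        pair_rows.append(
            {"mrna_id": int(tid), "ribo_id": rid,
             "start_frame": int(base.frame.min()), "end_frame": int(base.frame.max())}
        )
        rid += 1
    for _ in range(n_ribo - n_pairs):
        t, g = simulate_tracks(config, motion_free, 1, channel="ribo", rng=rng)
        ribo_parts.append(t.assign(track_id=rid))
        rec = g.tracks.iloc[0].to_dict()
        rec.update(track_id=rid, channel="ribo", comoving=False)
        gt_tracks.append(rec)
        rid += 1
    ribo = (
        pd.concat(ribo_parts, ignore_index=True)[TRACK_COLUMNS]
        if ribo_parts
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )

    pairs = pd.DataFrame(
        pair_rows, columns=["mrna_id", "ribo_id", "start_frame", "end_frame"]
    )
    gt = GroundTruth(tracks=pd.DataFrame(gt_tracks), pairs=pairs)
    return mrna, ribo, gt


# ---------------------------------------------------------------------------
# movie rendering


def _render_spot(
    frame: np.ndarray, x_px: float, y_px: float, psf_sd: float, photons: float
) -> None:
    """Add an integrated 2-D Gaussian spot (in place) to ``frame``."""
    nrow, ncol = frame.shape
    r = int(np.ceil(4.0 * psf_sd)) + 1
    c0, c1 = int(np.floor(x_px)) - r, int(np.floor(x_px)) + r + 1
    r0, r1 = int(np.floor(y_px)) - r, int(np.floor(y_px)) + r + 1
    c0, c1 = max(c0, 0), min(c1, ncol)
    r0, r1 = max(r0, 0), min(r1, nrow)
    if c0 >= c1 or r0 >= r1:
        return
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    s = psf_sd * np.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - x_px) / s) - erf((cols - 0.5 - x_px) / s))
    fy = 0.5 * (erf((rows + 0.5 - y_px) / s) - erf((rows - 0.5 - y_px) / s))
    frame[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def render_movie(
    tracks: pd.DataFrame,
    psf_sd: float,
    photons_per_spot: float,
    background: float,
    config: SimConfig,
    *,
    noise: bool = True,
) -> np.ndarray:
    """Render trajectories into a 16-bit camera movie.

    Each localization becomes an integrated 2-D Gaussian of total
    intensity ``photons_per_spot`` on the pixel grid (pixel centres at
    integer pixel coordinates; μm → px via ``config.pixel_size``).
    Poisson shot noise is applied to signal + background unless
    ``noise=False``.  Localizations outside the field are clipped with a
    warning.
    """
    config.validate()
    if psf_sd <= 0:
        raise ConfigurationError("psf_sd must be > 0")
    if photons_per_spot <= 0:
        raise ConfigurationError("photons_per_spot must be > 0")
    shape = config.field_shape_px()
    stack = np.full((config.n_frames,) + shape, float(background))
    px = config.pixel_size
    n_clipped = 0
    for frame_idx, grp in tracks.groupby("frame"):
        if frame_idx < 0 or frame_idx >= config.n_frames:
            continue
        for x_um, y_um in zip(grp.x_um.to_numpy(), grp.y_um.to_numpy()):
            x_px, y_px = x_um / px, y_um / px
            if not (0 <= x_px < shape[1] and 0 <= y_px < shape[0]):
                n_clipped += 1
                x_px = np.clip(x_px, 0, shape[1] - 1)
                y_px = np.clip(y_px, 0, shape[0] - 1)
            _render_spot(stack[frame_idx], x_px, y_px, psf_sd, photons_per_spot)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} localizations outside the field were clipped to its edge"
        )
    if noise:
        rng = np.random.default_rng(config.rng_seed)
        stack = rng.poisson(stack).astype(float)
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


def render_marker_image(
    mask: np.ndarray,
    signal: float = 200.0,
    background: float = 20.0,
    *,
    seed: int = 0,
    noise: bool = True,
) -> np.ndarray:
    """Render a compartment mask as a noisy marker-channel image.

    Zones are rendered at ``background + signal`` counts, the rest at
    ``background``, with Poisson noise — a stand-in for a focal-adhesion
    marker channel (e.g. paxillin) used to exercise segmentation.
    """
    img = background + signal * np.asarray(mask, dtype=float)
    if noise:
        img = np.random.default_rng(seed).poisson(img).astype(float)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)
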