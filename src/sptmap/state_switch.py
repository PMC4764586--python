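"""Pooled K-state diffusion HMM over trajectory ensembles.

The emission model treats each per-frame radial displacement r as
Rayleigh-distributed given the hidden diffusive state k:

    p(r | D_k) = r / (2·D_k·Δt) · exp(−r² / (4·D_k·Δt)),

the magnitude law of an isotropic 2-D Gaussian step of per-coordinate
variance 2·D_k·Δt.  Parameters (D_k, transition matrix T, initial
distribution π) are shared across all tracks and estimated by
Baum–Welch EM over the pooled set of sequences; state sequences are then
annotated per track by Viterbi decoding.  Model order (K = 1 vs 2) is
chosen by BIC — a deliberately simple, documented selection criterion
with the same decision behaviour as Bayesian evidence on well-separated
states.  States are labelled in order of decreasing D: state 1 is the
fast state (D1), state 2 the slow one (D2).  Mean state lifetimes are
reported as Δt/(1 − T_kk), the mean of the geometric holding time.
Localization error is not modelled: coefficients are apparent, matching
the CDF-fit convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sptmap.errors import ConfigurationError, FitError

__all__ = [
    "HmmModel",
    "StateAnnotation",
    "DurationHistogram",
    "step_likelihood",
    "fit_hmm",
    "select_model",
    "annotate",
    "annotate_tracks",
    "duration_histograms",
]

_EPS = 1e-300


@dataclass
class HmmModel:
    """Fitted pooled diffusion HMM (states sorted by decreasing D)."""

    K: int
    D: np.ndarray  # μm²/s, descending: D[0] = fast state 1
    T: np.ndarray  # row-stochastic per-frame transition matrix
    pi: np.ndarray  # initial state distribution
    log_likelihood: float
    n_steps: int
    frame_interval: float
    converged: bool = True
    degenerate: bool = False  # some state occupies < 1% of steps

    @property
    def n_parameters(self) -> int:
        return self.K + self.K * (self.K - 1) + (self.K - 1)

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * np.log(self.n_steps)

    def state_lifetimes(self) -> np.ndarray:
        """Mean dwell time per state, Δt/(1 − T_kk), seconds."""
        stay = np.clip(np.diag(self.T), None, 1.0 - 1e-12)
        return self.frame_interval / (1.0 - stay)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "D_um2_s": self.D.tolist(),
            "T": self.T.tolist(),
            "pi": self.pi.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_steps": self.n_steps,
            "frame_interval_s": self.frame_interval,
            "state_lifetimes_s": self.state_lifetimes().tolist(),
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


@dataclass
class StateAnnotation:
    """Viterbi state labels for one track, with state-visit records.

    ``states`` holds one 1-based label per displacement step.  ``visits``
    is a DataFrame (state, start_step, n_steps, duration_s, at_start,
    at_end); visits touching the first or last step of the track are
    boundary visits (censored durations).
    """

    track_id: object
    states: np.ndarray
    visits: pd.DataFrame


@dataclass
class DurationHistogram:
    """Pooled state-visit durations for one state."""

    state: int
    durations: np.ndarray  # seconds
    internal_only: bool

    @property
    def n_visits(self) -> int:
        return len(self.durations)

    @property
    def mean_duration(self) -> float:
        return float(self.durations.mean()) if len(self.durations) else np.nan


def step_likelihood(r, D: float, dt: float):
    """Rayleigh density of a radial displacement given diffusive state D."""
    if D <= 0:
        raise ConfigurationError("D must be > 0")
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    r = np.asarray(r, dtype=float)
    return r / (2.0 * D * dt) * np.exp(-np.square(r) / (4.0 * D * dt))


def _step_sequences(tracks: pd.DataFrame) -> list[tuple[object, np.ndarray]]:
    """Per-track consecutive-frame displacement magnitudes."""
    out = []
    keys = [c for c in ("channel", "track_id") if c in tracks.columns]
    for key, grp in tracks.groupby(keys, sort=True):
        grp = grp.sort_values("frame")
        frames = grp.frame.to_numpy()
        x, y = grp.x_um.to_numpy(), grp.y_um.to_numpy()
        step = np.flatnonzero(np.diff(frames) == 1)
        if len(step) == 0:
            continue
        r = np.hypot(x[step + 1] - x[step], y[step + 1] - y[step])
        tid = key[-1] if isinstance(key, tuple) else key
        out.append((tid, r))
    return out


def _emissions(r: np.ndarray, D: np.ndarray, dt: float) -> np.ndarray:
    B = np.empty((len(r), len(D)))
    for k, Dk in enumerate(D):
        B[:, k] = step_likelihood(r, Dk, dt)
    return np.maximum(B, _EPS)


def _forward_backward(B: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward. Returns (gamma, xi_sum, logL)."""
    n, K = B.shape
    alpha = np.empty((n, K))
    c = np.empty(n)
    alpha[0] = pi * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ T) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((n, K))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (T @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(n - 1):
        xi = (alpha[t][:, None] * T) * (B[t + 1] * beta[t + 1])[None, :]
        xi_sum += xi / c[t + 1]
    return gamma, xi_sum, float(np.log(c).sum())


def _fb_batch(B: np.ndarray, T: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward over a batch of equal-length sequences.

    ``B``: (n_seq, L, K) emission probabilities.  Returns
    (gamma (n_seq, L, K), xi_sum (K, K) pooled over batch and time, logL).
    """
    n_seq, L, K = B.shape
    alpha = np.empty_like(B)
    c = np.empty((n_seq, L))
    a = pi[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, L):
        a = (alpha[:, t - 1] @ T) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty_like(B)
    beta[:, -1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[:, t] = ((B[:, t + 1] * beta[:, t + 1]) @ T.T) / c[:, t + 1, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(L - 1):
        w = (B[:, t + 1] * beta[:, t + 1]) / c[:, t + 1, None]
        xi_sum += (alpha[:, t].T @ w)
    xi_sum *= T
    return gamma, xi_sum, float(np.log(c).sum())


def _em(
    seqs: list[np.ndarray], D0: np.ndarray, T0: np.ndarray, pi0: np.ndarray,
    dt: float, max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, list[float]]:
    D, T, pi = D0.copy(), T0.copy(), pi0.copy()
    K = len(D)
    # batch sequences of equal length for vectorized forward-backward
    by_len: dict[int, np.ndarray] = {}
    for L in sorted({len(r) for r in seqs}):
        by_len[L] = np.stack([r for r in seqs if len(r) == L])
    prev = -np.inf
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        logL = 0.0
        g_sum = np.zeros(K)
        gr2_sum = np.zeros(K)
        xi_tot = np.zeros((K, K))
        pi_acc = np.zeros(K)
        for L, R in by_len.items():
            B = np.maximum(
                np.stack([step_likelihood(R, Dk, dt) for Dk in D], axis=-1), _EPS
            )
            gamma, xi, ll = _fb_batch(B, T, pi)
            logL += ll
            g_sum += gamma.sum(axis=(0, 1))
            gr2_sum += np.einsum("nlk,nl->k", gamma, np.square(R))
            xi_tot += xi
            pi_acc += gamma[:, 0].sum(axis=0)
        history.append(logL)
        if np.isfinite(prev) and abs(logL - prev) <= tol * abs(prev):
            converged = True
            break
        prev = logL
        # M-step
        D = np.maximum(gr2_sum / (4.0 * dt * np.maximum(g_sum, 1e-12)), 1e-6)
        if K > 1:
            rowsum = xi_tot.sum(axis=1, keepdims=True)
            T = np.where(rowsum > 0, xi_tot / np.maximum(rowsum, 1e-300), T)
            T /= T.sum(axis=1, keepdims=True)
        pi = pi_acc / pi_acc.sum()
    return D, T, pi, history[-1], converged, history


def fit_hmm(
    tracks: pd.DataFrame,
    K: int,
    frame_interval: float = 0.035,
    n_restarts: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    return_history: bool = False,
):
    """Fit a pooled K-state diffusion HMM by Baum–Welch EM.

    Each track is an independent sequence; parameters are shared across
    the pool.  The best of ``n_restarts`` randomized initializations (by
    log-likelihood) is returned.  Convergence: relative log-likelihood
    change below ``tol`` or ``max_iter`` iterations.  A state holding
    under 1% of the posterior step mass marks the model degenerate.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    seqs = [r for _, r in _step_sequences(tracks)]
    n_steps = int(sum(len(r) for r in seqs))
    if n_steps < 50 * K:
        raise ConfigurationError(
            f"need >= {50 * K} pooled steps for K={K}, got {n_steps}"
        )
    dt = frame_interval
    pooled_r2 = np.concatenate([np.square(r) for r in seqs])
    D_scale = pooled_r2.mean() / (4.0 * dt)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        if K == 1:
            D0 = np.array([D_scale]) * (1.0 if restart == 0 else rng.uniform(0.5, 2.0))
        else:
            q = np.quantile(pooled_r2, np.linspace(0.25, 0.9, K)) / (4.0 * dt)
            D0 = np.sort(q * rng.uniform(0.5, 1.5, size=K))
        if K == 1:
            T0 = np.ones((1, 1))
        else:
            T0 = np.full((K, K), 0.1 / (K - 1))
            np.fill_diagonal(T0, 0.9)
        pi0 = np.full(K, 1.0 / K)
        D, T, pi, logL, converged, history = _em(
            seqs, D0, T0, pi0, dt, max_iter, tol
        )
        if best is None or history[-1] > best[3]:
            best = (D, T, pi, history[-1], converged, history)
    D, T, pi, logL, converged, history = best

    # relabel states by decreasing D (state 1 = fast)
    order = np.argsort(-D)
    D, pi = D[order], pi[order]
    T = T[np.ix_(order, order)]

    # occupancy check via one posterior pass
    occ = np.zeros(K)
    for r in seqs:
        gamma, _, _ = _forward_backward(_emissions(r, D, dt), T, pi)
        occ += gamma.sum(axis=0)
    occ /= occ.sum()
    model = HmmModel(
        K=K, D=D, T=T, pi=pi, log_likelihood=logL, n_steps=n_steps,
        frame_interval=dt, converged=converged, degenerate=bool((occ < 0.01).any()),
    )
    if return_history:
        return model, history
    return model


def select_model(
    tracks: pd.DataFrame,
    frame_interval: float = 0.035,
    K_candidates: Sequence[int] = (1, 2),
    n_restarts: int = 3,
    seed: int = 0,
) -> HmmModel:
    """Fit each candidate K and return the model minimizing BIC."""
    if not K_candidates:
        raise ConfigurationError("K_candidates must be nonempty")
    models = [
        fit_hmm(tracks, K, frame_interval, n_restarts=n_restarts, seed=seed)
        for K in K_candidates
    ]
    return min(models, key=lambda m: m.bic)


def _viterbi(B: np.ndarray, T: np.ndarray, pi: np.ndarray) -> np.ndarray:
    n, K = B.shape
    logB = np.log(B)
    logT = np.log(np.maximum(T, _EPS))
    delta = np.log(np.maximum(pi, _EPS)) + logB[0]
    back = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + logT
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _visits(states: np.ndarray, dt: float) -> pd.DataFrame:
    """Run-length encode a label sequence into state visits."""
    n = len(states)
    breaks = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [n - 1]])
    return pd.DataFrame(
        {
            "state": states[starts],
            "start_step": starts,
            "n_steps": ends - starts + 1,
            "duration_s": (ends - starts + 1) * dt,
            "at_start": starts == 0,
            "at_end": ends == n - 1,
        }
    )


def annotate(
    track: pd.DataFrame, model: HmmModel, track_id: object = None
) -> StateAnnotation:
    """Viterbi-annotate one track's steps with 1-based state labels."""
    seqs = _step_sequences(track)
    if not seqs:
        raise ValueError("track has no displacement step to annotate")
    tid, r = seqs[0]
    B = _emissions(r, model.D, model.frame_interval)
    states = _viterbi(B, model.T, model.pi) + 1
    return StateAnnotation(
        track_id=track_id if track_id is not None else tid,
        states=states,
        visits=_visits(states, model.frame_interval),
    )


def annotate_tracks(tracks: pd.DataFrame, model: HmmModel) -> list[StateAnnotation]:
    """Annotate every track in a trajectory table."""
    out = []
    for tid, r in _step_sequences(tracks):
        B = _emissions(r, model.D, model.frame_interval)
        states = _viterbi(B, model.T, model.pi) + 1
        out.append(
            StateAnnotation(
                track_id=tid, states=states,
                visits=_visits(states, model.frame_interval),
            )
        )
    return out


def duration_histograms(
    annotations: list[StateAnnotation], internal_only: bool = False
) -> dict[int, DurationHistogram]:
    """Pool state-visit durations across tracks, per state.

    ``internal_only`` drops visits touching a track's first or last step
    (their durations are censored by the finite track lifetime).
    """
    if not annotations:
        raise ConfigurationError("annotations must be nonempty")
    all_visits = pd.concat([a.visits for a in annotations], ignore_index=True)
    if internal_only:
        all_visits = all_visits[~(all_visits.at_start | all_visits.at_end)]
    out = {}
    states = sorted(pd.unique(pd.concat([a.visits for a in annotations]).state))
    for s in states:
        durs = all_visits[all_visits.state == s].duration_s.to_numpy()
        out[int(s)] = DurationHistogram(
            state=int(s), durations=durs, internal_only=internal_only
        )
    return out
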