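"""Synthetic trajectory generators and track-based estimators.

These emulate the two camera experiments the physics estimators assume:

* cuvette settling assays -- near-straight downward drift of passive
  settlers observed at a fixed frame rate with pixel-scale position noise;
* run-and-tumble swimming -- constant-speed self-propulsion whose heading
  is resampled uniformly on the sphere at random (exponential-waiting, by
  default) or fixed intervals.

Everything is seed-deterministic and parameter-stamped, so generator ->
estimator round trips can be tested without any recorded data.  The
generators deliberately omit several features of real recordings: worm
shape and undulation, camera calibration drift, tracking dropouts, and
wall effects near the cuvette boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidInputError

#: default camera frame rate, Hz
DEFAULT_RATE = 16.0


@dataclass
class TrajectorySet:
    """A set of sampled tracks.

    ``frame`` columns: track_id, t (s), x, y, z (m) and, when headings are
    stored, hx, hy, hz (unit vector).  Within a track, t is strictly
    increasing with a uniform interval.
    """

    frame: pd.DataFrame
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def has_headings(self) -> bool:
        return "hx" in self.frame.columns

    def track_ids(self) -> np.ndarray:
        return self.frame["track_id"].unique()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def generate_settling_tracks(
    n: int = 30,
    u_mean: float = 0.52e-3,
    u_sd: float = 0.02e-3 * np.sqrt(30),
    position_noise_sd: float = 0.05e-3,
    duration: float = 60.0,
    rate: float = DEFAULT_RATE,
    seed: int | None = 0,
) -> TrajectorySet:
    """Straight downward drift tracks with Gaussian observation noise.

    Per-track settling speed is drawn from Normal(u_mean, u_sd); the
    defaults emulate a 30-worm passive-settler cohort whose published
    0.02 mm/s uncertainty is read as the standard error of the mean of
    N = 30, hence a per-worm spread of 0.02*sqrt(30) mm/s.
    """
    if n < 1:
        raise InvalidInputError("need at least one track")
    if not rate > 0:
        raise InvalidInputError("sampling rate must be > 0")
    if u_sd < 0 or position_noise_sd < 0:
        raise InvalidInputError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / rate)
    frames = []
    speeds = rng.normal(u_mean, u_sd, size=n)
    for i in range(n):
        start = rng.uniform(-5e-3, 5e-3, size=3)
        pos = np.empty((t.size, 3))
        pos[:, 0] = start[0]
        pos[:, 1] = start[1]
        pos[:, 2] = start[2] - speeds[i] * t
        pos += rng.normal(0.0, position_noise_sd, size=pos.shape)
        frames.append(
            pd.DataFrame(
                {"track_id": i, "t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]}
            )
        )
    meta = dict(
        kind="settling",
        n=n,
        u_mean=u_mean,
        u_sd=u_sd,
        position_noise_sd=position_noise_sd,
        duration=duration,
        rate=rate,
        seed=seed,
    )
    return TrajectorySet(pd.concat(frames, ignore_index=True), rate, meta)


def generate_run_tumble_tracks(
    speed: float = 2.43e-5,
    tau_r: float = 4.65,
    scheme: str = "exponential",
    duration: float = 60.0,
    rate: float = DEFAULT_RATE,
    seed: int | None = 0,
    n_tracks: int = 32,
    position_noise_sd: float = 0.0,
) -> TrajectorySet:
    """Constant-speed run-and-tumble tracks with stored headings.

    ``scheme='exponential'`` draws exponential waiting times with mean
    tau_r (Poisson tumbling, directional autocorrelation exp(-t/tau_r));
    ``'fixed_interval'`` resamples exactly every tau_r seconds.
    """
    if not (speed > 0 and tau_r > 0):
        raise InvalidInputError("speed and tau_r must be > 0")
    if scheme not in ("exponential", "fixed_interval"):
        raise InvalidInputError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate
    t = np.arange(0.0, duration, dt)
    frames = []
    for i in range(n_tracks):
        if scheme == "exponential":
            # draw enough events to cover the duration
            n_ev = max(8, int(3 * duration / tau_r) + 8)
            ev = np.cumsum(rng.exponential(tau_r, size=n_ev))
            while ev[-1] < duration:
                ev = np.concatenate([ev, ev[-1] + np.cumsum(rng.exponential(tau_r, size=n_ev))])
        else:
            ev = np.arange(tau_r, duration + 2 * tau_r, tau_r)
        seg = np.searchsorted(ev, t, side="right")
        headings = _uniform_sphere(rng, seg.max() + 1)[seg]
        pos = np.vstack([np.zeros(3), np.cumsum(speed * headings[:-1] * dt, axis=0)])
        if position_noise_sd > 0:
            pos = pos + rng.normal(0.0, position_noise_sd, size=pos.shape)
        frames.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "t": t,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                    "hx": headings[:, 0],
                    "hy": headings[:, 1],
                    "hz": headings[:, 2],
                }
            )
        )
    meta = dict(
        kind="run_tumble",
        speed=speed,
        tau_r=tau_r,
        scheme=scheme,
        duration=duration,
        rate=rate,
        seed=seed,
        n_tracks=n_tracks,
        position_noise_sd=position_noise_sd,
    )
    return TrajectorySet(pd.concat(frames, ignore_index=True), rate, meta)


def estimate_settling_velocity(tracks: TrajectorySet) -> tuple[float, float, int]:
    """Per-track settling speed (positive downward), population mean/sd/n.

    Each track's speed is its vertical displacement over its elapsed time;
    single-point tracks are excluded with a warning in the return count.
    """
    speeds = []
    for tid, g in tracks.frame.groupby("track_id"):
        if len(g) < 2:
            continue
        dt = g["t"].iloc[-1] - g["t"].iloc[0]
        speeds.append(-(g["z"].iloc[-1] - g["z"].iloc[0]) / dt)
    if not speeds:
        raise InvalidInputError("no track has two or more samples")
    arr = np.asarray(speeds)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def heading_autocorrelation(tracks: TrajectorySet, max_lag_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged directional autocorrelation <n(t).n(t+lag)>."""
    if not tracks.has_headings:
        raise InvalidInputError("tracks have no stored headings")
    dt = 1.0 / tracks.sampling_rate
    max_lag = max(1, int(round(max_lag_s / dt)))
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for tid, g in tracks.frame.groupby("track_id"):
        h = g[["hx", "hy", "hz"]].to_numpy()
        m = min(max_lag, len(h) - 1)
        for k in range(m + 1):
            dots = np.einsum("ij,ij->i", h[: len(h) - k], h[k:])
            sums[k] += dots.sum()
            counts[k] += dots.size
    valid = counts > 0
    lags = np.arange(max_lag + 1)[valid] * dt
    return lags, sums[valid] / counts[valid]


def estimate_tau_r(tracks: TrajectorySet, initial_guess: float | None = None) -> float:
    """Directional persistence time from the heading autocorrelation decay.

    Fits ``A exp(-lag/tau)`` over lags <= 3*tau, iterating the lag window
    once on the fitted value.  Returns ``inf`` when the autocorrelation
    does not decay (ballistic tracks).
    """
    dt = 1.0 / tracks.sampling_rate
    duration = float(tracks.frame.groupby("track_id")["t"].max().min())

    def _fit(window: float) -> float:
        lags, corr = heading_autocorrelation(tracks, min(window, duration / 2))
        if corr[-1] > 0.9:  # no visible decay over the window
            return np.inf
        # initial tau from the 1/e crossing
        below = np.nonzero(corr < np.exp(-1.0))[0]
        tau0 = lags[below[0]] if below.size else window / 3.0

        def model(p):
            return p[0] * np.exp(-lags / p[1]) - corr

        res = optimize.least_squares(model, x0=[1.0, max(tau0, dt)], method="lm")
        return float(res.x[1])

    guess = initial_guess if initial_guess is not None else duration / 6.0
    tau1 = _fit(3.0 * guess)
    if not np.isfinite(tau1):
        return np.inf
    tau2 = _fit(3.0 * tau1)
    return tau2 if np.isfinite(tau2) else np.inf


def run_tumble_msd(tracks: TrajectorySet, lags_s) -> np.ndarray:
    """Ensemble mean-squared displacement at the given lags (s)."""
    dt = 1.0 / tracks.sampling_rate
    lags_s = np.atleast_1d(np.asarray(lags_s, dtype=float))
    out = np.zeros(lags_s.size)
    counts = np.zeros(lags_s.size)
    for tid, g in tracks.frame.groupby("track_id"):
        p = g[["x", "y", "z"]].to_numpy()
        for j, lag in enumerate(lags_s):
            k = int(round(lag / dt))
            if k < 1 or k >= len(p):
                continue
            d = p[k:] - p[:-k]
            out[j] += np.sum(np.einsum("ij,ij->i", d, d))
            counts[j] += len(d)
    with np.errstate(invalid="ignore"):
        return out / counts
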