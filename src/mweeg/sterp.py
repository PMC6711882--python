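"""Single-trial ERP extraction by Mexican-hat template matching.

Instead of averaging across trials, each epoch is cross-covaried with a family
of Mexican-hat templates

    psi(u) = (1 - 16 u^2) exp(-8 u^2)

over a grid of time lags ``t`` (template peak position, ms) and scales ``s``
(template breadth, approximately the wavelength, ms):

    W(s, t) = s^(-1/2) * sum_tau f(tau) * psi((tau - t)/s) * dtau

``W`` at the polarity-appropriate extreme inside a component's search window is
the single-trial amplitude estimate; the extreme's coordinates give the
component's latency and breadth. Search windows follow the standard visual
components: P1 (positive, 50-150 ms, occipital A10/B7), N1 (negative,
100-200 ms, same sites) and P3 (positive, 250-600 ms, parietal A19).

A traditional trial-averaged ERP path (:func:`traditional_erp`) is included so
single-trial and averaged amplitude estimates can be compared on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .containers import EpochSet

__all__ = [
    "mexican_hat", "WaveletMap", "wavelet_cross_covariance", "riemann_cross_covariance",
    "SterpFeature", "detect_component", "ComponentSpec", "DEFAULT_COMPONENTS",
    "extract_erp_features", "traditional_erp", "TRADITIONAL_WINDOWS",
]


def mexican_hat(u):
    """Mexican-hat template, ``(1 - 16 u^2) exp(-8 u^2)``.

    Unit peak at ``u = 0``, zero crossings at ``u = +/- 1/4``, even symmetric,
    effectively zero beyond ``|u| ~ 1``.
    """
    u = np.asarray(u, dtype=float)
    return (1.0 - 16.0 * u ** 2) * np.exp(-8.0 * u ** 2)


@dataclass
class WaveletMap:
    """Cross-covariance values over a (scale x lag) grid for one epoch channel."""

    W: np.ndarray          # shape (n_scales, n_lags)
    s_grid: np.ndarray     # scales, ms
    t_grid: np.ndarray     # lags, ms

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.W.shape != (self.s_grid.size, self.t_grid.size):
            raise ValueError("W shape does not match grids")


def wavelet_cross_covariance(signal, time_ms, s_grid, t_grid=None) -> WaveletMap:
    """Template match one epoch channel against Mexican hats over a (s, t) grid.

    Evaluates ``W(s, t) = s^(-1/2) sum_tau f(tau) psi((tau-t)/s) dtau`` as a
    Riemann sum over the epoch support (zero outside), with ``dtau = 1000/fs``
    ms. Because psi is even, the lag scan is a convolution and is computed with
    an FFT per scale; :func:`riemann_cross_covariance` is the literal-sum
    reference route used to verify this one.

    Parameters
    ----------
    signal : (n_samples,) array
        One channel of one epoch, microvolts.
    time_ms : (n_samples,) array
        Sample times in ms (uniform spacing).
    s_grid : array of scales in ms, all > 0.
    t_grid : array of lags in ms, or None for every sample time.
    """
    f = np.asarray(signal, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if f.size == 0:
        raise ValueError("empty signal")
    if f.shape != time_ms.shape:
        raise ValueError("signal/time axis mismatch")
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    if np.any(s_grid <= 0):
        raise ValueError("scales must be positive")
    if t_grid is None:
        t_grid = time_ms.copy()
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))

    dtau = time_ms[1] - time_ms[0]
    n = f.size
    # lags of the full cross-correlation, in ms relative to time_ms[0]
    full = _full_lag_maps(f, s_grid, dtau)
    # W at arbitrary t via interpolation on the sample-aligned lag axis; for
    # t on the sample grid this is exact.
    lag_axis = time_ms[0] + np.arange(n) * dtau
    W = np.empty((s_grid.size, t_grid.size))
    for i in range(s_grid.size):
        W[i] = np.interp(t_grid, lag_axis, full[i])
    return WaveletMap(W, s_grid, t_grid)


def _full_lag_maps(f: np.ndarray, s_grid: np.ndarray, dtau: float) -> np.ndarray:
    """W for every sample-aligned lag, one row per scale (FFT convolution)."""
    n = f.size
    k = np.arange(-(n - 1), n)  # kernel support covers every in-epoch offset
    out = np.empty((s_grid.size, n))
    for i, s in enumerate(s_grid):
        g = mexican_hat(k * dtau / s)
        # psi even => correlation == convolution with the same kernel
        out[i] = fftconvolve(f, g, mode="full")[n - 1:2 * n - 1] * (dtau / np.sqrt(s))
    return out


def riemann_cross_covariance(signal, time_ms, s_grid, t_grid) -> WaveletMap:
    """Literal Riemann-sum evaluation of the template match (oracle route)."""
    f = np.asarray(signal, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    dtau = time_ms[1] - time_ms[0]
    W = np.empty((s_grid.size, t_grid.size))
    for i, s in enumerate(s_grid):
        for j, t in enumerate(t_grid):
            W[i, j] = np.sum(f * mexican_hat((time_ms - t) / s)) * dtau / np.sqrt(s)
    return WaveletMap(W, s_grid, t_grid)


@dataclass
class SterpFeature:
    """One detected single-trial component.

    ``amplitude`` is the signed W at the selected extreme (negative for N1
    when properly found); ``found`` is ``"ok"`` for a correctly signed interior
    extreme and ``"degraded"`` when the extreme sits on the search-grid
    boundary or has the wrong sign (the value is still reported).
    """

    component: str
    channel: str
    amplitude: float
    lag_ms: float
    scale_ms: float
    found: str  # "ok" | "degraded"


def detect_component(wmap: WaveletMap, window_ms: tuple[float, float],
                     polarity: int, component: str = "", channel: str = "") -> SterpFeature:
    """Locate the polarity-signed grid extreme of W inside a lag window.

    Ties are broken toward the earliest lag, then the smallest scale. The
    extreme is flagged ``degraded`` when it lies on the boundary of the search
    region (any edge of the window or of the scale grid), when its sign
    contradicts the requested polarity, or when W is identically zero.
    """
    lo, hi = window_ms
    in_win = np.nonzero((wmap.t_grid >= lo) & (wmap.t_grid <= hi))[0]
    if in_win.size == 0:
        raise ValueError(f"window {window_ms} outside lag grid "
                         f"[{wmap.t_grid[0]}, {wmap.t_grid[-1]}] ms")
    sub = wmap.W[:, in_win] * np.sign(polarity)
    best = sub.max()
    # earliest lag, then smallest scale, among exact ties
    ties = np.argwhere(np.isclose(sub, best, rtol=0.0, atol=0.0))
    order = np.lexsort((ties[:, 0], ties[:, 1]))  # lag first, then scale
    si, tj = ties[order[0]]
    tj_full = in_win[tj]
    amplitude = float(wmap.W[si, tj_full])
    on_boundary = (tj == 0 or tj == in_win.size - 1
                   or si == 0 or si == wmap.s_grid.size - 1)
    wrong_sign = amplitude * np.sign(polarity) <= 0.0
    found = "degraded" if (on_boundary or wrong_sign) else "ok"
    return SterpFeature(component=component, channel=channel, amplitude=amplitude,
                        lag_ms=float(wmap.t_grid[tj_full]),
                        scale_ms=float(wmap.s_grid[si]), found=found)


@dataclass(frozen=True)
class ComponentSpec:
    """Search definition for one ERP component on one set of channels."""

    name: str
    channels: tuple[str, ...]
    window_ms: tuple[float, float]
    polarity: int                      # +1 or -1
    scale_range_ms: tuple[float, float]
    n_scales: int = 32

    def scale_grid(self) -> np.ndarray:
        return np.geomspace(self.scale_range_ms[0], self.scale_range_ms[1],
                            self.n_scales)


#: default component set: occipital P1/N1, parietal P3. Scale grids are
#: logarithmic and bracket each component's plausible breadth.
DEFAULT_COMPONENTS = (
    ComponentSpec("P1", ("A10", "B7"), (50.0, 150.0), +1, (50.0, 400.0)),
    ComponentSpec("N1", ("A10", "B7"), (100.0, 200.0), -1, (50.0, 400.0)),
    ComponentSpec("P3", ("A19",), (250.0, 600.0), +1, (200.0, 1400.0)),
)


def with_n1_window(components=DEFAULT_COMPONENTS,
                   window_ms=(100.0, 230.0)) -> tuple[ComponentSpec, ...]:
    """Component set with a widened N1 search window (default 100-230 ms).

    The canonical 100-200 ms window clips the N1, whose averaged peak sits
    near 200 ms; widening the upper bound lets the template center there.
    """
    return tuple(replace(c, window_ms=window_ms) if c.name == "N1" else c
                 for c in components)


def extract_erp_features(epochs: EpochSet,
                         components: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS
                         ) -> pd.DataFrame:
    """Single-trial component features for every trial in an EpochSet.

    Returns a long-format frame with one row per trial x component x channel
    (5 rows per trial for the default set: P1@A10, P1@B7, N1@A10, N1@B7,
    P3@A19) and columns ``trial_id, component, channel, W, t_ms, s_ms, found``.
    """
    dtau = 1000.0 / epochs.fs
    rows = []
    for comp in components:
        s_grid = comp.scale_grid()
        lo, hi = comp.window_ms
        # lag grid: every sample inside the window
        t_grid = epochs.time_ms[(epochs.time_ms >= lo) & (epochs.time_ms <= hi)]
        for ch in comp.channels:
            sig = epochs.get_channel(ch).astype(float)   # (n_trials, n_samples)
            maps = _batch_lag_maps(sig, s_grid, dtau)     # (n_scales, n_trials, n)
            lag_axis = epochs.time_ms
            keep = np.nonzero((lag_axis >= lo) & (lag_axis <= hi))[0]
            sub = maps[:, :, keep]                        # (n_scales, n_trials, n_win)
            # vectorized detect_component with the same tie-break: flatten in
            # (lag, scale) order so argmax prefers earliest lag then smallest
            # scale among exact ties
            signed = np.transpose(sub, (1, 2, 0)) * np.sign(comp.polarity)
            flat = signed.reshape(epochs.n_trials, -1)
            best = flat.argmax(axis=1)
            tj = best // s_grid.size
            si = best % s_grid.size
            amps = sub[si, np.arange(epochs.n_trials), tj]
            boundary = ((tj == 0) | (tj == keep.size - 1)
                        | (si == 0) | (si == s_grid.size - 1))
            wrong_sign = amps * np.sign(comp.polarity) <= 0.0
            found = np.where(boundary | wrong_sign, "degraded", "ok")
            rows.append(pd.DataFrame({
                "trial_id": epochs.trials["trial_id"].to_numpy(),
                "component": comp.name, "channel": ch,
                "W": amps, "t_ms": lag_axis[keep][tj],
                "s_ms": s_grid[si], "found": found,
            }))
    return pd.concat(rows, ignore_index=True)


def _batch_lag_maps(signals: np.ndarray, s_grid: np.ndarray, dtau: float) -> np.ndarray:
    """Vectorized _full_lag_maps over trials: (n_scales, n_trials, n_samples)."""
    n = signals.shape[1]
    k = np.arange(-(n - 1), n)
    out = np.empty((s_grid.size, signals.shape[0], n))
    for i, s in enumerate(s_grid):
        g = mexican_hat(k * dtau / s)[None, :]
        out[i] = fftconvolve(signals, g, mode="full", axes=1)[:, n - 1:2 * n - 1] \
            * (dtau / np.sqrt(s))
    return out


#: averaging-method measurement windows (ms) for the per-trial window means
TRADITIONAL_WINDOWS = {"P1": (120.0, 130.0), "N1": (195.0, 205.0), "P3": (400.0, 500.0)}

#: channel each traditional component is measured at
TRADITIONAL_CHANNELS = {"P1": ("A10", "B7"), "N1": ("A10", "B7"), "P3": ("A19",)}


def traditional_erp(epochs: EpochSet, labels: pd.Series | np.ndarray,
                    component_windows: dict[str, tuple[float, float]] | None = None):
    """Trial-averaged ERP waveforms per state plus per-trial window means.

    Parameters
    ----------
    epochs : EpochSet
    labels : per-trial state labels aligned with ``epochs.trials``
    component_windows : component -> (lo_ms, hi_ms); defaults to the 10-ms
        (P1/N1) and 100-ms (P3) windows used for the averaged-ERP comparison.

    Returns
    -------
    waveforms : DataFrame with columns (state, channel, time_ms, mean_uv)
    amplitudes : DataFrame with per-trial mean amplitude in each component
        window, columns (trial_id, state, component, channel, amplitude)
    """
    if component_windows is None:
        component_windows = TRADITIONAL_WINDOWS
    labels = np.asarray(labels)
    if labels.size != epochs.n_trials:
        raise ValueError("labels length mismatch")
    states = [s for s in pd.unique(labels)]
    if any((labels == s).sum() < 1 for s in states):
        raise ValueError("empty state class")

    wf_rows = []
    for state in states:
        mask = labels == state
        mean_wave = epochs.data[mask].mean(axis=0)  # (n_channels, n_samples)
        for ci, ch in enumerate(epochs.channels):
            wf_rows.append(pd.DataFrame({
                "state": state, "channel": ch,
                "time_ms": epochs.time_ms, "mean_uv": mean_wave[ci],
            }))
    waveforms = pd.concat(wf_rows, ignore_index=True)

    amp_rows = []
    for comp, (lo, hi) in component_windows.items():
        sl = epochs.sample_slice(lo, hi + 1e-9)  # inclusive upper edge
        for ch in TRADITIONAL_CHANNELS.get(comp, tuple(epochs.channels)):
            if ch not in epochs.channels:
                continue
            vals = epochs.get_channel(ch)[:, sl].mean(axis=1)
            amp_rows.append(pd.DataFrame({
                "trial_id": epochs.trials["trial_id"].to_numpy(),
                "state": labels, "component": comp, "channel": ch,
                "amplitude": vals,
            }))
    amplitudes = pd.concat(amp_rows, ignore_index=True)
    return waveforms, amplitudes
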