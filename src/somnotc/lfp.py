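"""LFP forward models and spectral analysis of simulation output.

Two forward models:

* **summed-voltage LFP** — the population mean of PY dendritic membrane
  voltages (mV): a useful first approximation that tracks network state but
  has no extracellular physics in it;
* **biophysical LFP** — the extracellular potential of a point-source volume
  conductor: each compartment k contributes R_k·I_k(t), where I_k is its
  total transmembrane current (ionic + synaptic + capacitive; for a
  two-compartment cell this equals the axial current entering the
  compartment, making each cell a current dipole) and
  R_k = 1/(4π·σ·r_k) is the transfer resistance to the electrode.

Spectral analysis (short-time spectrogram, band power) is built on
scipy.signal.  Default bands: slow oscillation 0.1–1 Hz, spindle 7–14 Hz,
alpha 8–13 Hz.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .engine import RunResult

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "slow_oscillation": (0.1, 1.0),
    "spindle": (7.0, 14.0),
    "alpha": (8.0, 13.0),
}


class GeometryError(ValueError):
    """Electrode placed too close to (or inside) a compartment."""


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def transfer_resistance(r_um: float, sigma_s_per_m: float = 0.3,
                        min_distance_um: float = 10.0) -> float:
    """Point-source transfer resistance R = 1/(4π·σ·r) in ohms (r in µm).

    At σ = 0.3 S/m and r = 100 µm this is ≈ 2652.6 Ω, i.e. 1 nA of
    transmembrane current contributes ≈ 2.65 µV at the electrode.
    """
    if r_um < min_distance_um:
        raise GeometryError(
            f"electrode–compartment distance {r_um} µm below minimum {min_distance_um} µm")
    return 1.0 / (4.0 * math.pi * sigma_s_per_m * r_um * 1e-6)


def transfer_resistance_array(electrode_um: np.ndarray, points_um: np.ndarray,
                              sigma_s_per_m: float = 0.3,
                              min_distance_um: float = 10.0) -> np.ndarray:
    """Transfer resistances (Ω) from an electrode to an (n, 3) set of points."""
    r = np.linalg.norm(points_um - np.asarray(electrode_um, dtype=float), axis=1)
    if np.any(r < min_distance_um):
        bad = float(r.min())
        raise GeometryError(
            f"electrode–compartment distance {bad:.1f} µm below minimum {min_distance_um} µm")
    return 1.0 / (4.0 * math.pi * sigma_s_per_m * r * 1e-6)


def electrode_position(cfg, net) -> np.ndarray:
    """Configured electrode position, or the default: centred over the PY
    layer, 100 µm above the dendritic plane (EEG-like, closer to the
    dendrites than the somata so the vertical cell dipoles do not cancel)."""
    if cfg.lfp.electrode_um is not None:
        return np.asarray(cfg.lfp.electrode_um, dtype=float)
    soma = net.soma_xyz["PY"]
    y = soma[:, 1].mean() + cfg.lfp.dend_offset_um + 100.0
    return np.array([soma[:, 0].mean(), y, 0.0])


def summed_voltage_lfp(v_traces: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted mean of intracellular voltage traces, shape (n_t, n_cells) → (n_t,).

    The mean (not the raw sum) keeps the amplitude population-size invariant.
    """
    v = np.atleast_2d(np.asarray(v_traces, dtype=float))
    if v.shape[1] == 0:
        raise ValueError("summed-voltage LFP needs at least one trace")
    if weights is None:
        return v.mean(axis=1)
    w = np.asarray(weights, dtype=float)
    if w.size != v.shape[1]:
        raise ValueError("weights length must match number of traces")
    return v @ (w / w.sum())


def biophysical_lfp(currents_nA: np.ndarray, resistances_ohm: np.ndarray) -> np.ndarray:
    """φ(t) = Σ_k R_k·I_k(t) in µV; linear in the currents (superposition).

    ``currents_nA`` is (n_t, n_compartments) of *total* transmembrane
    currents (their capacitive components included, so each cell's
    compartment currents sum to zero and form a dipole).
    """
    i = np.atleast_2d(np.asarray(currents_nA, dtype=float))
    r = np.asarray(resistances_ohm, dtype=float)
    if i.shape[1] != r.size:
        raise ValueError(
            f"current columns ({i.shape[1]}) != number of resistances ({r.size})")
    return (i @ r) * 1e-3  # nA·Ω = nV → µV


# --------------------------------------------------------------------------
# spectral analysis
# --------------------------------------------------------------------------

def spectrogram(lfp: np.ndarray, fs_hz: float, window_s: float = 2.0,
                overlap: float = 0.75):
    """Short-time power spectral density (single Hann taper).

    Returns (freqs_hz, times_s, Sxx) with Sxx in power density units
    (signal²/Hz) on the stated window/overlap grid.
    """
    lfp = np.asarray(lfp, dtype=float)
    nperseg = int(round(window_s * fs_hz))
    if nperseg > lfp.size:
        raise ValueError(f"window ({nperseg} samples) longer than trace ({lfp.size})")
    noverlap = int(round(overlap * nperseg))
    f, t, sxx = signal.spectrogram(lfp, fs=fs_hz, window="hann", nperseg=nperseg,
                                   noverlap=noverlap, detrend="constant",
                                   scaling="density", mode="psd")
    return f, t, sxx


def band_power(freqs_hz: np.ndarray, sxx: np.ndarray,
               band: tuple[float, float]) -> np.ndarray:
    """Integral of the PSD over ``band`` per window (trapezoid in frequency)."""
    lo, hi = band
    if not hi > lo:
        raise ValueError(f"empty band {band}")
    m = (freqs_hz >= lo) & (freqs_hz <= hi)
    if not np.any(m):
        raise ValueError(f"band {band} contains no frequency bins")
    sxx = np.atleast_2d(sxx)
    if m.sum() == 1:
        df = freqs_hz[1] - freqs_hz[0] if freqs_hz.size > 1 else 1.0
        return sxx[m, :].ravel() * df
    return np.trapezoid(sxx[m, :], freqs_hz[m], axis=0)


def welch_psd(lfp: np.ndarray, fs_hz: float, window_s: float = 4.0):
    lfp = np.asarray(lfp, dtype=float)
    nperseg = min(int(round(window_s * fs_hz)), lfp.size)
    return signal.welch(lfp, fs=fs_hz, nperseg=nperseg, detrend="constant")


def dominant_frequency(lfp: np.ndarray, fs_hz: float,
                       fmin: float = 0.5, fmax: float = 30.0,
                       window_s: float = 4.0) -> float:
    """Frequency (Hz) of the PSD maximum within [fmin, fmax]."""
    f, p = welch_psd(lfp, fs_hz, window_s)
    m = (f >= fmin) & (f <= fmax)
    if not np.any(m):
        raise ValueError("no frequency bins in the requested range")
    return float(f[m][np.argmax(p[m])])


# --------------------------------------------------------------------------
# run-level summaries
# --------------------------------------------------------------------------

def silent_fraction(spike_times_ms: np.ndarray, t0_ms: float, t1_ms: float,
                    bin_ms: float = 10.0) -> float:
    """Fraction of ``bin_ms`` bins in [t0, t1) with no spikes network-wide.

    The signature of the slow oscillation: alternating network-wide active
    (Up) and silent (Down) periods give a substantial silent fraction,
    whereas tonic activity gives ≈ 0.
    """
    if not t1_ms > t0_ms:
        raise ValueError("t1 must exceed t0")
    edges = np.arange(t0_ms, t1_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(spike_times_ms, bins=edges)
    return float(np.mean(counts == 0))


def stage_windows(result: "RunResult", exclude_ramp: bool = True,
                  min_t_ms: float | None = None):
    """(stage label, t_start_ms, t_end_ms) plateau windows of a run's schedule."""
    from .config import loads_config

    cfg = loads_config(result.config_yaml)
    sched = cfg.schedule
    half = sched.ramp_ms / 2.0 if exclude_ramp else 0.0
    if min_t_ms is None:
        min_t_ms = result.settle_ms
    out = []
    start = 0.0
    ends = sched.boundaries()
    for i, stage in enumerate(sched.stages):
        end = float(ends[i])
        lo = max(start + (half if i > 0 else 0.0), min_t_ms)
        hi = min(end - (half if i < len(sched.stages) - 1 else 0.0),
                 result.duration_ms)
        if hi > lo:
            out.append((stage.stage, lo, hi))
        start = end
    return out


def stage_band_powers(result: "RunResult", bands: dict[str, tuple[float, float]]
                      | None = None, window_s: float = 4.0, overlap: float = 0.75,
                      source: str = "summed") -> dict[str, dict[str, float]]:
    """Median per-window band power of the LFP within each stage plateau.

    The default 4-s window is the shortest that resolves the slow-oscillation
    band (0.1–1 Hz needs Δf ≤ 0.25 Hz); the display spectrogram keeps its own
    2-s default.  Returns {occurrence label: {band: median power}} with
    occurrence labels ``stage#k`` for repeated stages plus an aggregated
    plain ``stage`` key.
    """
    bands = bands or DEFAULT_BANDS
    lfp = result.lfp_summed if source == "summed" else result.lfp_bio
    fs = result.fs_hz
    f, tw, sxx = spectrogram(lfp, fs, window_s=window_s, overlap=overlap)
    tw_ms = tw * 1000.0 + result.t_ms[0]
    powers = {name: band_power(f, sxx, band) for name, band in bands.items()}
    per_stage: dict[str, dict[str, list[np.ndarray]]] = {}
    out: dict[str, dict[str, float]] = {}
    for k, (stage, lo, hi) in enumerate(stage_windows(result)):
        m = (tw_ms >= lo) & (tw_ms <= hi)
        key = f"{stage}#{k}"
        out[key] = {}
        for name in bands:
            vals = powers[name][m]
            out[key][name] = float(np.median(vals)) if vals.size else float("nan")
            per_stage.setdefault(stage, {}).setdefault(name, []).append(vals)
    for stage, d in per_stage.items():
        out[stage] = {}
        for name, parts in d.items():
            allv = np.concatenate(parts) if parts else np.empty(0)
            out[stage][name] = float(np.median(allv)) if allv.size else float("nan")
    return out


def burst_isi_fraction(result: "RunResult", pop: str = "TC",
                       thresh_ms: float = 10.0, min_t_ms: float = 0.0) -> float:
    """Mean per-cell fraction of inter-spike intervals shorter than ``thresh_ms``.

    Burst-mode (spindling) thalamic firing packs spikes into < 10 ms
    intervals riding each rebound; tonic relay-mode firing does not, so this
    index discriminates the two regimes independently of the mean rate.
    """
    ids, ts = result.spikes_of(pop)
    keep = ts >= min_t_ms
    ids, ts = ids[keep], ts[keep]
    fractions = []
    for i in range(result.pop_counts[pop]):
        tt = ts[ids == i]
        if tt.size > 3:
            isi = np.diff(tt)
            fractions.append(float(np.mean(isi < thresh_ms)))
    return float(np.mean(fractions)) if fractions else 0.0


def firing_rate_trace(result: "RunResult", pop: str, bin_ms: float = 10.0):
    """(bin centres ms, population rate in Hz/cell) for one population."""
    _, times = result.spikes_of(pop)
    edges = np.arange(0.0, result.duration_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(times, bins=edges)
    n = result.pop_counts[pop]
    rate = counts / (n * bin_ms / 1000.0)
    return (edges[:-1] + edges[1:]) / 2.0, rate
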