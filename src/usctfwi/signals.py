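"""Source wavelets and band operators.

Three source signatures drive the data generation:

* a narrowband Gaussian tone burst standing in for the transmission pulse
  of a P4-1-class cardiac probe (−40 dB low-frequency limit around
  0.5 MHz at the default 2 MHz centre frequency);
* an ideal 3-cycle broadband pulse with substantial content below the
  probe band;
* a hybrid broadband splice that keeps the narrowband pulse's spectrum
  above a 1.00 MHz split point and substitutes the ideal pulse's spectrum
  below it, crossfaded and amplitude-matched at the seam so the inverse
  FFT yields a clean real-valued time signal. The hybrid pulse lowers the
  −40 dB limit to well below 0.1 MHz, which is the property frequency-
  stepped inversion needs to avoid cycle skipping.

All filters are linear and applied zero-phase (forward–backward) so that
band limiting never shifts first-arrival times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps


@dataclass
class Wavelet:
    """Time-sampled source signature."""

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite wavelet samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.samples))

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def spectrum(self, n_fft: int | None = None):
        """(freqs, complex one-sided spectrum)."""
        n = n_fft or len(self.samples)
        return np.fft.rfftfreq(n, self.dt), np.fft.rfft(self.samples, n)

    def copy(self) -> "Wavelet":
        return replace(self, samples=self.samples.copy())

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_s,amplitude", comments="")

    @classmethod
    def from_csv(cls, path) -> "Wavelet":
        arr = np.loadtxt(Path(path), delimiter=",", skiprows=1)
        t, a = arr[:, 0], arr[:, 1]
        return cls(samples=a, dt=float(t[1] - t[0]), t0=float(t[0]))


@dataclass
class BandSpec:
    """A frequency band given by centre and width, with a relative
    threshold (dB below spectral peak) for limit detection."""

    center_f: float
    width: float
    threshold_db: float = -40.0

    def __post_init__(self) -> None:
        if not (self.center_f > self.width / 2 >= 0):
            raise ValueError("require center_f > width/2 >= 0")
        if self.threshold_db >= 0:
            raise ValueError("threshold_db must be negative")


def narrowband_wavelet(
    fc: float = 2.0e6,
    fractional_bandwidth: float = 0.6,
    dt: float = 1.0 / 20e6,
    n: int = 512,
) -> Wavelet:
    """Gaussian-enveloped tone burst emulating a band-limited probe pulse.

    ``fractional_bandwidth`` is the two-sided −6 dB bandwidth divided by
    ``fc``. The default settings put the −40 dB low-side limit near
    0.5 MHz, mimicking a P4-1 transmission.
    """
    if not (0 < fc < 0.5 / dt):
        raise ValueError(f"fc={fc} must lie in (0, Nyquist={0.5 / dt:.3g})")
    if not (0 < fractional_bandwidth < 2):
        raise ValueError("fractional_bandwidth must be in (0, 2)")
    # -6 dB half-width = 1.1774 sigma_f for a Gaussian amplitude spectrum
    sigma_f = fractional_bandwidth * fc / (2 * 1.1774)
    sigma_t = 1.0 / (2 * np.pi * sigma_f)
    t = dt * np.arange(n)
    t_center = 4 * sigma_t
    env = np.exp(-0.5 * ((t - t_center) / sigma_t) ** 2)
    return Wavelet(env * np.sin(2 * np.pi * fc * (t - t_center)), dt)


def ideal_pulse(
    fc: float = 0.25e6, n_cycles: int = 3, dt: float = 1.0 / 20e6, n: int = 512
) -> Wavelet:
    """Ideal ``n_cycles``-cycle broadband pulse: Hann-windowed sinusoid.

    The −40 dB low-side limit of a 3-cycle Hann burst sits near 0.35·fc,
    so the 0.25 MHz default places the limit of the spliced hybrid pulse
    below 0.1 MHz — the band a 2 MHz imaging probe cannot reach.
    """
    if not (0 < fc < 0.5 / dt):
        raise ValueError(f"fc={fc} must lie in (0, Nyquist={0.5 / dt:.3g})")
    t = dt * np.arange(n)
    dur = n_cycles / fc
    if dur > t[-1]:
        raise ValueError("pulse duration exceeds the sampled window; increase n")
    mask = t <= dur
    w = np.zeros(n)
    w[mask] = np.sin(2 * np.pi * fc * t[mask]) * np.hanning(mask.sum())
    w -= w.mean()  # enforce zero mean (no DC in a propagating pulse)
    return Wavelet(w, dt)


def hybrid_broadband(
    narrow: Wavelet,
    ideal: Wavelet,
    splice_f: float = 1.0e6,
    taper_width: float = 0.1e6,
) -> Wavelet:
    """Frequency-domain splice: narrowband spectrum above ``splice_f``,
    ideal-pulse spectrum below, cosine-crossfaded over ``taper_width``.

    The ideal pulse's low band is amplitude-matched to the narrowband
    spectrum at the splice so the seam is continuous; the inverse FFT of
    the conjugate-symmetric hybrid spectrum gives a real time signal.
    """
    if abs(narrow.dt - ideal.dt) > 1e-15:
        raise ValueError(f"dt mismatch: {narrow.dt} vs {ideal.dt}; resample first")
    if splice_f >= narrow.nyquist:
        raise ValueError("splice frequency above Nyquist")
    n = max(len(narrow), len(ideal))
    f, spec_n = narrow.spectrum(n)
    _, spec_i = ideal.spectrum(n)

    # match the ideal pulse's amplitude to the narrowband one at the seam
    seam = (f >= splice_f - taper_width / 2) & (f <= splice_f + taper_width / 2)
    if seam.any():
        a_n = np.mean(np.abs(spec_n[seam]))
        a_i = np.mean(np.abs(spec_i[seam]))
        if a_i > 0:
            spec_i = spec_i * (a_n / a_i)

    # cosine crossfade: weight of the narrowband spectrum rises 0 -> 1
    # across [splice - taper/2, splice + taper/2]
    w = np.zeros_like(f)
    lo, hi = splice_f - taper_width / 2, splice_f + taper_width / 2
    w[f >= hi] = 1.0
    ramp = (f > lo) & (f < hi)
    w[ramp] = 0.5 * (1 - np.cos(np.pi * (f[ramp] - lo) / (hi - lo)))

    hybrid_spec = w * spec_n + (1 - w) * spec_i
    samples = np.fft.irfft(hybrid_spec, n)
    return Wavelet(samples, narrow.dt, narrow.t0)


def bandwidth_limit_db(
    w: Wavelet, threshold_db: float = -40.0, side: str = "low", n_fft: int | None = None
) -> tuple[float, bool]:
    """Frequency where the amplitude spectrum crosses ``peak + threshold_db``.

    Returns ``(frequency_Hz, found)``. ``side='low'`` scans downward from
    the spectral peak for the last frequency still above the threshold;
    ``side='high'`` scans upward. Crossings are located by linear
    interpolation between FFT bins on the dB scale. When the spectrum
    never falls to the threshold on the requested side, returns 0 (low) or
    Nyquist (high) with ``found=False``.
    """
    if side not in ("low", "high"):
        raise ValueError("side must be 'low' or 'high'")
    n = n_fft or max(len(w) * 8, 4096)  # zero-pad for fine frequency sampling
    f, spec = w.spectrum(n)
    amp = np.abs(spec)
    peak = amp.max()
    if peak == 0:
        raise ValueError("zero signal has no bandwidth")
    with np.errstate(divide="ignore"):
        db = 20 * np.log10(amp / peak)
    k_peak = int(np.argmax(amp))
    if side == "low":
        below = np.nonzero(db[: k_peak + 1] < threshold_db)[0]
        if len(below) == 0:
            return 0.0, False
        k = below[-1]  # last bin below threshold before the peak
        d0, d1 = db[k], db[k + 1]
        frac = (threshold_db - d0) / (d1 - d0)
        return float(f[k] + frac * (f[k + 1] - f[k])), True
    else:
        above_idx = np.nonzero(db[k_peak:] < threshold_db)[0]
        if len(above_idx) == 0:
            return float(f[-1]), False
        k = k_peak + above_idx[0] - 1  # last bin above threshold after peak
        d0, d1 = db[k], db[k + 1]
        frac = (threshold_db - d0) / (d1 - d0)
        return float(f[k] + frac * (f[k + 1] - f[k])), True


def _apply_filtfilt_rows(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Zero-phase FIR application along the last axis."""
    return sps.filtfilt(taps, [1.0], data, axis=-1, padtype="odd")


def highpass_filter(
    traces: np.ndarray, dt: float, cutoff: float = 0.55e6, order: int = 40
) -> np.ndarray:
    """Zero-phase FIR high-pass per trace (length preserved).

    Defaults reproduce the band-limiting used to strip sub-0.5 MHz content
    from a broadband acquisition: order-40 FIR, 0.55 MHz cutoff.
    """
    nyq = 0.5 / dt
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff {cutoff} outside (0, Nyquist={nyq:.3g})")
    traces = np.asarray(traces, dtype=np.float64)
    if traces.shape[-1] < 3 * order:
        raise ValueError(
            f"trace length {traces.shape[-1]} too short for order-{order} "
            f"zero-phase filtering (need >= {3 * order})"
        )
    taps = sps.firwin(order + 1, cutoff / nyq, pass_zero=False)
    return _apply_filtfilt_rows(taps, traces)


def lowpass_filter(
    traces: np.ndarray, dt: float, cutoff: float, order: int = 40
) -> np.ndarray:
    """Zero-phase FIR low-pass per trace; companion of highpass_filter used
    by the frequency-stepping loop."""
    nyq = 0.5 / dt
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff {cutoff} outside (0, Nyquist={nyq:.3g})")
    traces = np.asarray(traces, dtype=np.float64)
    if traces.shape[-1] < 3 * order:
        raise ValueError(f"trace too short for order-{order} filtering")
    taps = sps.firwin(order + 1, cutoff / nyq, pass_zero=True)
    return _apply_filtfilt_rows(taps, traces)


def bandpass_window(
    trace: np.ndarray, dt: float, center_f: float, width: float = 50e3,
    order: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass [center − width/2, center + width/2].

    The 50 kHz default width matches the sliding window used for the
    band-resolved RMS error curves. With ``order=None`` the filter order
    adapts to the trace length (capped at 512); narrow bands need high
    orders, so callers measuring short traces should zero-pad first.
    """
    nyq = 0.5 / dt
    lo, hi = center_f - width / 2, center_f + width / 2
    if not (0 < lo and hi < nyq):
        raise ValueError(f"band [{lo:.3g}, {hi:.3g}] Hz outside (0, {nyq:.3g})")
    trace = np.asarray(trace, dtype=np.float64)
    if order is None:
        order = min(512, (trace.shape[-1] - 1) // 3)
        order -= order % 2  # even order: symmetric, odd tap count
    if trace.shape[-1] < 3 * order or order < 16:
        raise ValueError(f"trace too short for order-{order} filtering")
    taps = sps.firwin(order + 1, [lo / nyq, hi / nyq], pass_zero=False)
    return _apply_filtfilt_rows(taps, trace)


def add_noise(
    traces: np.ndarray,
    dt: float,
    rms_level: float,
    band: tuple[float, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Add band-limited Gaussian noise at ``rms_level`` × the signal RMS.

    A parametric surrogate for measured probe noise: white Gaussian noise,
    optionally band-passed to ``band = (f_lo, f_hi)``, rescaled so its RMS
    equals ``rms_level`` times the RMS of ``traces``. Deterministic per
    seed; ``rms_level=0`` returns the input unchanged.
    """
    if rms_level < 0:
        raise ValueError("rms_level must be >= 0")
    traces = np.asarray(traces, dtype=np.float64)
    if rms_level == 0:
        return traces.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(traces.shape)
    if band is not None:
        f_lo, f_hi = band
        center, width = (f_lo + f_hi) / 2, (f_hi - f_lo)
        noise = bandpass_window(noise, dt, center, width)
    sig_rms = np.sqrt(np.mean(traces**2))
    noise_rms = np.sqrt(np.mean(noise**2))
    if noise_rms == 0:
        return traces.copy()
    return traces + noise * (rms_level * sig_rms / noise_rms)


def resample_wavelet(w: Wavelet, dt_new: float, n_new: int) -> Wavelet:
    """Band-limited resampling onto a new time grid via Fourier
    interpolation (scipy.signal.resample semantics, then crop/pad)."""
    if abs(dt_new - w.dt) < 1e-18:
        s = w.samples
    else:
        n_res = int(round(len(w) * w.dt / dt_new))
        s = sps.resample(w.samples, n_res)
    out = np.zeros(n_new)
    m = min(len(s), n_new)
    out[:m] = s[:m]
    return Wavelet(out, dt_new, w.t0)
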