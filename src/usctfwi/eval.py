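"""Quantitative evaluation of datasets and reconstructions.

Two complementary error measures drive the analysis:

* model-space RMS between a reconstruction and the true SoS phantom
  (``phantom.phantom_rms``), and
* data-space RMS between two datasets resolved per frequency band: both
  datasets are band-passed through a sliding window (50 kHz wide by
  default) and the pooled RMS of the trace difference is reported per
  centre frequency. The resulting curve shows exactly where a
  band-limited or extrapolated dataset stops matching the broadband
  reference, and its low-error plateau is how the usable FWI band is
  chosen.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .phantom import VelocityModel, phantom_rms
from .signals import bandpass_window
from .wavesim import USCTDataset

DEFAULT_CENTERS = np.arange(0.03e6, 1.50e6 + 1, 10e3)  # full-scale sweep


@dataclass
class BandRMSCurve:
    centers: np.ndarray   # Hz, strictly increasing
    values: np.ndarray    # RMS error per band, trace units
    width: float = 50e3
    reference_label: str = ""
    data_label: str = ""

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("RMS values cannot be negative")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["center_hz", "rms"])
            for c, v in zip(self.centers, self.values):
                w.writerow([c, v])

    def value_in(self, f_lo: float, f_hi: float) -> float:
        """Quadratic-mean curve level over centers within [f_lo, f_hi]."""
        m = (self.centers >= f_lo) & (self.centers <= f_hi)
        if not m.any():
            raise ValueError("no band centers in the requested range")
        return float(np.sqrt(np.mean(self.values[m] ** 2)))


def band_rms_curve(
    data: USCTDataset,
    reference: USCTDataset,
    centers: np.ndarray | None = None,
    width: float = 50e3,
) -> BandRMSCurve:
    """Pooled per-band RMS of (data - reference) over all shared traces.

    Both datasets are band-passed identically, so by linearity the
    difference is filtered once. Symmetric in (data, reference).
    """
    keys = sorted(set(data.gathers) & set(reference.gathers))
    if not keys:
        raise ValueError("datasets share no gathers")
    if abs(data.dt - reference.dt) > 1e-15:
        raise ValueError("dt mismatch")
    dt = data.dt
    if centers is None:
        centers = DEFAULT_CENTERS
    centers = np.asarray(centers, dtype=np.float64)
    nyq = 0.5 / dt
    if centers[-1] + width / 2 >= nyq or centers[0] - width / 2 <= 0:
        raise ValueError(
            f"band sweep [{centers[0]:.3g}, {centers[-1]:.3g}] +/- {width / 2:.3g} Hz "
            f"outside (0, Nyquist={nyq:.3g})"
        )
    diff = np.concatenate(
        [
            (np.asarray(data.gathers[k].traces, np.float64)
             - np.asarray(reference.gathers[k].traces, np.float64)).T
            for k in keys
        ]
    )
    # zero-pad so short traces still admit a sharp FIR band; the RMS is
    # normalized by the original sample count (energy is conserved)
    n0 = diff.shape[-1]
    n_pad = max(n0, 2048)
    if n_pad > n0:
        diff = np.pad(diff, ((0, 0), (0, n_pad - n0)))
    values = np.empty(len(centers))
    for i, c in enumerate(centers):
        band = bandpass_window(diff, dt, c, width)
        values[i] = np.sqrt(np.sum(band**2) / (diff.shape[0] * n0))
    return BandRMSCurve(centers, values, width, reference.label, data.label)


def select_fwi_band(
    curve: BandRMSCurve, threshold: float | None = None
) -> tuple[float, float] | None:
    """Widest contiguous run of band centers with curve values at or
    below ``threshold``; returns its (f_start, f_stop) endpoints.

    ``threshold`` defaults to twice the 10th-percentile curve level (the
    low-error plateau). Returns None when no center qualifies.
    """
    if len(curve.values) == 0:
        raise ValueError("empty curve")
    if threshold is None:
        threshold = 2.0 * float(np.percentile(curve.values, 10))
    ok = curve.values <= threshold
    if not ok.any():
        return None
    runs = []
    start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])
    return float(curve.centers[i0]), float(curve.centers[i1])


@dataclass
class CycleSkipReport:
    """Per-label model RMS against the ground truth, with the expected
    ordering (broadband <= extrapolated < band-limited) evaluated."""

    rms: dict[str, float] = field(default_factory=dict)
    ordering_expected: bool | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"rms_m_per_s": self.rms, "ordering_expected": self.ordering_expected},
                fh, indent=1,
            )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "rms_m_per_s"])
            for k, v in self.rms.items():
                w.writerow([k, v])


def cycle_skip_report(
    truth: VelocityModel,
    reconstructions: dict[str, VelocityModel],
    mask: np.ndarray | None = None,
) -> CycleSkipReport:
    """Model RMS per labelled reconstruction, plus the cycle-skipping
    ordering check where the standard labels are present."""
    report = CycleSkipReport()
    for label, model in reconstructions.items():
        report.rms[label] = phantom_rms(truth, model, mask)
    r = report.rms
    if {"broadband", "extrapolated", "bandlimited"} <= set(r):
        report.ordering_expected = (
            r["broadband"] <= r["extrapolated"] < r["bandlimited"]
        )
    return report
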