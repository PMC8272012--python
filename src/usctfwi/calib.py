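"""Travel-time calibration of the dual-probe ring system.

On hardware, neither the exact probe poses nor the transmitted wavelet
are known: both are estimated from a water-only calibration acquisition.

* Probe localization: with only water in the ring, the predicted first
  arrival between two elements is the straight-ray time
  ``distance / c_water``. Element positions are tied to rigid probe
  poses (centre x, centre y, orientation) with the known element pitch;
  minimizing the squared TOF misfit over all source-receiver pairs is a
  nonlinear least-squares problem solved by Gauss-Newton (with a
  Levenberg fallback when the normal equations are ill-conditioned).
  Probe 0 is held at its nominal pose to fix the global translation /
  rotation gauge.

* Wavelet estimation: for one source, every receiver sees the same
  pulse delayed by its distance; a normal move-out (NMO) correction
  removes the per-trace delay, after which the coherent stack average
  is an estimate of the source signature. Sub-sample shifts use
  Fourier-domain fractional delays.

Elements are treated as 2D points; a guard warns when the element width
approaches the minimum wavelength, where the point-source approximation
starts to fail.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import AcquisitionGeometry
from .signals import Wavelet
from .wavesim import ShotGather


@dataclass
class TOFTable:
    """Picked (or predicted) first-arrival times per element pair."""

    entries: dict[tuple[int, int, int, int], float]  # (sp, se, rp, re) -> t(s)
    c_water: float = 1484.0

    def __post_init__(self):
        if not (1400.0 <= self.c_water <= 1550.0):
            raise ValueError(f"c_water={self.c_water} outside [1400, 1550] m/s")
        if any(t <= 0 for t in self.entries.values()):
            raise ValueError("travel times must be positive")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source_probe", "source_elem", "recv_probe", "recv_elem", "t_s"])
            for (sp, se, rp, re), t in sorted(self.entries.items()):
                w.writerow([sp, se, rp, re, repr(t)])

    @classmethod
    def from_csv(cls, path, c_water: float = 1484.0) -> "TOFTable":
        entries = {}
        with open(path, newline="") as fh:
            rd = csv.reader(fh)
            next(rd)
            for row in rd:
                entries[(int(row[0]), int(row[1]), int(row[2]), int(row[3]))] = float(row[4])
        return cls(entries, c_water)


@dataclass
class ProbePose:
    center: np.ndarray  # (2,)
    angle: float        # orientation of the element axis, rad

    def element_positions(self, n_elements: int, pitch: float) -> np.ndarray:
        u = np.array([np.cos(self.angle), np.sin(self.angle)])
        offs = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
        return self.center[None, :] + offs[:, None] * u[None, :]


@dataclass
class CalibrationResult:
    poses: list[ProbePose]
    residual_rms: float
    iterations: int
    residual_history: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        data = {
            "residual_rms_s": self.residual_rms,
            "iterations": self.iterations,
            "residual_history_s": self.residual_history,
            "poses": [
                {"cx_m": float(p.center[0]), "cy_m": float(p.center[1]),
                 "angle_rad": float(p.angle)}
                for p in self.poses
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1))


def nominal_poses(geometry: AcquisitionGeometry) -> list[ProbePose]:
    """Rigid poses recovered from a geometry's element coordinates."""
    poses = []
    for p in range(geometry.n_probe_positions):
        coords = geometry.element_coords[p]
        center = coords.mean(axis=0)
        if len(coords) > 1:
            d = coords[-1] - coords[0]
            angle = float(np.arctan2(d[1], d[0]))
        else:
            angle = 0.0
        poses.append(ProbePose(center, angle))
    return poses


def point_source_guard(element_width: float, c_water: float, f_max: float) -> bool:
    """Warn when the element width reaches the minimum wavelength; the
    2D point-element model then stops being justified. Returns True when
    the approximation holds."""
    lam_min = c_water / f_max
    if element_width >= lam_min:
        warnings.warn(
            f"element width {element_width:.3e} m >= minimum wavelength "
            f"{lam_min:.3e} m: point-source approximation questionable",
            stacklevel=2,
        )
        return False
    return True


def predict_tof(
    geometry: AcquisitionGeometry, c_water: float = 1484.0,
    pairs=None,
) -> TOFTable:
    """Straight-ray water times for every pair in the receive map (or an
    explicit pair list)."""
    entries = {}
    if pairs is None:
        pairs = [
            (sp, se, rp, re)
            for sp in range(geometry.n_probe_positions)
            for se in range(geometry.n_elements)
            for rp in geometry.receive_map[sp]
            for re in range(geometry.n_elements)
        ]
    for (sp, se, rp, re) in pairs:
        d = np.linalg.norm(
            geometry.element_coords[rp, re] - geometry.element_coords[sp, se]
        )
        entries[(sp, se, rp, re)] = float(d / c_water)
    return TOFTable(entries, c_water)


def _tof_residuals_jacobian(poses, pairs, times, n_elements, pitch, c):
    """Residual vector and Jacobian w.r.t. the free pose parameters
    (probes 1..P-1, 3 DOF each; probe 0 gauge-fixed)."""
    P = len(poses)
    el = np.stack([p.element_positions(n_elements, pitch) for p in poses])
    offs = (np.arange(n_elements) - (n_elements - 1) / 2.0) * pitch
    r = np.empty(len(pairs))
    J = np.zeros((len(pairs), 3 * (P - 1)))
    for row, (sp, se, rp, re) in enumerate(pairs):
        xs, xr = el[sp, se], el[rp, re]
        diff = xr - xs
        dist = np.linalg.norm(diff)
        r[row] = dist / c - times[row]
        e = diff / (dist * c)  # d t / d xr
        for probe, sign, elem in ((rp, 1.0, re), (sp, -1.0, se)):
            if probe == 0:
                continue
            k = 3 * (probe - 1)
            J[row, k:k + 2] += sign * e
            a = poses[probe].angle
            du = np.array([-np.sin(a), np.cos(a)]) * offs[elem]
            J[row, k + 2] += sign * float(e @ du)
    return r, J


def localize_probes(
    measured: TOFTable,
    initial_geometry: AcquisitionGeometry,
    max_iter: int = 20,
    tol: float = 1e-12,
    damping: float = 0.0,
) -> CalibrationResult:
    """Gauss-Newton refinement of rigid probe poses from picked TOFs.

    Iterates until the residual RMS change falls below ``tol`` seconds or
    ``max_iter`` is reached. When the normal system is ill-conditioned a
    Levenberg-damped step is used; a rank-deficient system that stays
    unsolvable raises with the number of unconstrained degrees of
    freedom.
    """
    geom = initial_geometry
    poses = nominal_poses(geom)
    pairs = sorted(measured.entries)
    times = np.array([measured.entries[k] for k in pairs])
    c = measured.c_water
    n_par = 3 * (len(poses) - 1)
    if len(pairs) < n_par:
        raise ValueError(
            f"{len(pairs)} TOF pairs cannot constrain {n_par} pose parameters"
        )
    history = []
    rms_prev = None
    it = 0
    for it in range(1, max_iter + 1):
        r, J = _tof_residuals_jacobian(
            poses, pairs, times, geom.n_elements, geom.element_pitch, c
        )
        rms = float(np.sqrt(np.mean(r**2)))
        history.append(rms)
        if rms_prev is not None and abs(rms_prev - rms) < tol:
            break
        rms_prev = rms
        JtJ = J.T @ J
        rhs = -J.T @ r
        lam = damping
        for attempt in range(6):
            try:
                A = JtJ + lam * np.eye(n_par) if lam > 0 else JtJ
                cond = np.linalg.cond(A)
                if cond > 1e12:
                    raise np.linalg.LinAlgError(f"condition number {cond:.2e}")
                delta = np.linalg.solve(A, rhs)
                break
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, np.trace(JtJ) / n_par * 1e-8)
        else:
            ev = np.linalg.eigvalsh(JtJ)
            n_null = int(np.sum(ev < 1e-12 * ev.max()))
            raise np.linalg.LinAlgError(
                f"normal system rank-deficient even after damping: "
                f"{n_null} unconstrained degrees of freedom"
            )
        for p in range(1, len(poses)):
            k = 3 * (p - 1)
            poses[p].center = poses[p].center + delta[k:k + 2]
            poses[p].angle += delta[k + 2]
    r, _ = _tof_residuals_jacobian(
        poses, pairs, times, geom.n_elements, geom.element_pitch, c
    )
    final_rms = float(np.sqrt(np.mean(r**2)))
    history.append(final_rms)
    return CalibrationResult(poses, final_rms, it, history)


def geometry_from_poses(
    poses: list[ProbePose], template: AcquisitionGeometry
) -> AcquisitionGeometry:
    """Geometry with element coordinates rebuilt from rigid poses."""
    from dataclasses import replace

    coords = np.stack(
        [p.element_positions(template.n_elements, template.element_pitch)
         for p in poses]
    )
    return replace(template, element_coords=coords)


# ---------------------------------------------------------------------
# wavelet estimation


def fractional_delay(traces: np.ndarray, shift_samples: np.ndarray) -> np.ndarray:
    """Delay each column of (n_t, n_traces) by a (possibly fractional)
    number of samples via Fourier phase shifts; positive shifts delay.

    Traces are zero-padded before the FFT so energy shifted past the
    edge is discarded rather than wrapped."""
    traces = np.asarray(traces, dtype=np.float64)
    n_t, n_tr = traces.shape
    shift_samples = np.broadcast_to(np.asarray(shift_samples, float), (n_tr,))
    margin = int(np.ceil(np.abs(shift_samples).max())) + 8
    n_fft = int(2 ** np.ceil(np.log2(n_t + margin)))
    spec = np.fft.rfft(traces, n_fft, axis=0)
    freqs = np.fft.rfftfreq(n_fft)
    spec *= np.exp(-2j * np.pi * freqs[:, None] * shift_samples[None, :])
    return np.fft.irfft(spec, n_fft, axis=0)[:n_t]


def nmo_correct(
    gather: ShotGather, geometry: AcquisitionGeometry, c_water: float = 1484.0
) -> ShotGather:
    """Remove the water-path delay from each trace so that direct
    arrivals align at the wavelet onset time (offset zero)."""
    from dataclasses import replace

    sp, se = gather.source_id
    src = geometry.element_coords[sp, se]
    rec = np.stack([geometry.element_coords[rp, re] for rp, re in gather.receiver_ids])
    dist = np.linalg.norm(rec - src[None, :], axis=1)
    shifts = -dist / c_water / gather.dt  # advance by the travel time
    big = np.abs(shifts) >= gather.traces.shape[0]
    if big.any():
        warnings.warn(
            f"{big.sum()} traces shifted beyond their length; zero-padded",
            stacklevel=2,
        )
    out = fractional_delay(np.asarray(gather.traces, np.float64), shifts)
    return replace(gather, traces=out.astype(gather.traces.dtype))


def half_derivative(trace: np.ndarray, dt: float) -> np.ndarray:
    """Fractional half-derivative via the spectrum factor sqrt(2*pi*i*f).

    A cylindrical (2D) wavefield reaches a far-field receiver as the
    half-*integral* of the source signature (the sqrt(f) roll-off and
    -45 deg phase of the 2D Green's function); applying the
    half-derivative to an NMO stack therefore maps the received waveform
    back onto the injected source."""
    trace = np.asarray(trace, dtype=np.float64)
    n = len(trace)
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfftfreq(n_fft, dt)
    spec = np.fft.rfft(trace, n_fft) * np.sqrt(2j * np.pi * f)
    return np.fft.irfft(spec, n_fft)[:n]


def estimate_wavelet(
    gathers: list[ShotGather],
    geometry: AcquisitionGeometry,
    c_water: float = 1484.0,
    trim_threshold: float = 1e-3,
    correct_2d_response: bool = True,
) -> Wavelet:
    """NMO-corrected stack average over all traces of all gathers,
    trimmed to the energetic support and peak-normalized.

    With ``correct_2d_response`` the stack is half-differentiated so the
    estimate matches the *injected* source signature rather than the
    received (half-integrated) waveform; disable it to obtain the raw
    received-pulse estimate."""
    if not gathers:
        raise ValueError("no gathers to stack")
    dt = gathers[0].dt
    stacks = []
    for g in gathers:
        if abs(g.dt - dt) > 1e-15:
            raise ValueError("gathers have inconsistent dt")
        aligned = nmo_correct(g, geometry, c_water)
        stacks.append(np.asarray(aligned.traces, np.float64))
    stack = np.concatenate(stacks, axis=1)
    mean = stack.mean(axis=1)
    if correct_2d_response:
        mean = half_derivative(mean, dt)
    peak = np.abs(mean).max()
    if peak == 0:
        raise ValueError("stacked mean is identically zero")
    # trim to support where the envelope exceeds the threshold
    keep = np.nonzero(np.abs(mean) >= trim_threshold * peak)[0]
    lo = max(0, keep[0] - 2)
    hi = min(len(mean), keep[-1] + 3)
    trimmed = mean[lo:hi] / peak
    return Wavelet(trimmed, dt, t0=lo * dt)
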