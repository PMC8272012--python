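"""2D constant-density acoustic finite-difference simulation.

The forward engine behind both data generation and inversion: a scalar
wave equation ``m p_tt = lap(p) + s`` (``m`` = slowness squared) solved
with a 4th-order-in-space, 2nd-order-in-time explicit scheme, an
exponential-damping sponge layer, bilinear off-grid source injection and
receiver sampling, and exact linear-interpolation resampling of receiver
traces onto a coarser output time grid.

The receiver operator and the time stepping are linear in the wavefield,
and the solver exposes their exact discrete transposes
(:meth:`WaveSolver.adjoint_gradient`, :meth:`WaveSolver.born`), so the
adjoint-state gradient passes dot-product tests to near machine
precision at any output sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from . import _kernels
from .geometry import AcquisitionGeometry
from .phantom import VelocityModel
from .signals import Wavelet, resample_wavelet

# 4th-order 2D leapfrog stability: dt <= CFL4 * h / c_max
CFL4 = 2.0 / np.sqrt(2 * (16.0 / 3.0))  # ~0.612


@dataclass
class SimParams:
    """Discretization settings for the acoustic solver.

    ``dt``/``n_steps`` are derived from the CFL limit and ``t_max`` when
    left as None. ``output_dt`` sets the receiver-trace sampling interval
    (defaults to the simulation step). ``f_max`` enables the
    points-per-wavelength check against the model's slowest speed.
    """

    t_max: float = 170e-6
    dt: float | None = None
    n_steps: int | None = None
    output_dt: float | None = None
    spatial_order: int = 4
    boundary_width: int = 16
    sponge_coef: float = 0.03
    cfl_safety: float = 0.8
    ppw_min: float = 5.0
    f_max: float | None = None

    def resolve(self, model: VelocityModel) -> "SimParams":
        """Fill in dt / n_steps for a given model and validate stability."""
        if self.spatial_order != 4:
            raise ValueError("only 4th-order spatial stencils are implemented")
        c_max = float(model.grid.max())
        dt_limit = CFL4 * model.spacing / c_max
        dt = self.dt if self.dt is not None else self.cfl_safety * dt_limit
        if dt > dt_limit * (1 + 1e-12):
            raise ValueError(
                f"dt={dt:.3e} violates the CFL limit {dt_limit:.3e} "
                f"for c_max={c_max:.0f} m/s at h={model.spacing:.3e} m"
            )
        n_steps = self.n_steps if self.n_steps is not None else int(np.ceil(self.t_max / dt))
        if self.f_max is not None:
            c_min = float(model.grid.min())
            ppw = c_min / (self.f_max * model.spacing)
            if ppw < self.ppw_min:
                raise ValueError(
                    f"only {ppw:.1f} points per wavelength at f_max="
                    f"{self.f_max:.3g} Hz (minimum {self.ppw_min})"
                )
        out_dt = self.output_dt if self.output_dt is not None else dt
        return replace(self, dt=dt, n_steps=n_steps, output_dt=out_dt)


@dataclass
class ShotGather:
    """Traces recorded by one receiving probe for one source element."""

    traces: np.ndarray  # (n_t, n_receivers)
    dt: float
    source_id: tuple[int, int]
    receiver_probe: int
    receiver_ids: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("non-finite trace values")

    @property
    def n_t(self) -> int:
        return self.traces.shape[0]


@dataclass
class USCTDataset:
    """Full acquisition: shot gathers keyed by (src_probe, src_elem,
    receiving_probe), plus the geometry and source wavelet that produced
    them. ``label`` distinguishes band-limited / broadband / extrapolated
    variants of the same acquisition."""

    gathers: dict[tuple[int, int, int], ShotGather]
    geometry: AcquisitionGeometry
    wavelet: Wavelet
    label: str = "broadband"

    @property
    def dt(self) -> float:
        return next(iter(self.gathers.values())).dt

    @property
    def source_ids(self) -> list[tuple[int, int]]:
        return sorted({(sp, se) for (sp, se, _) in self.gathers})

    def gathers_for_source(self, source_id) -> dict[int, ShotGather]:
        sp, se = source_id
        return {
            rp: g for (p, e, rp), g in self.gathers.items() if (p, e) == (sp, se)
        }

    def n_traces(self) -> int:
        return sum(g.traces.shape[1] for g in self.gathers.values())

    def map_traces(self, fn) -> "USCTDataset":
        """New dataset with ``fn(traces, dt) -> traces`` applied per gather."""
        new = {
            k: replace(g, traces=np.asarray(fn(g.traces.T, g.dt)).T)
            for k, g in self.gathers.items()
        }
        return USCTDataset(new, self.geometry, self.wavelet, self.label)


def _bilinear(model: VelocityModel, pos: np.ndarray, pad: int = 2):
    """Row/column indices (4, n) into the padded grid and weights (4, n)
    for bilinear interpolation at physical positions (n, 2)."""
    pos = np.atleast_2d(pos)
    ny, nx = model.grid.shape
    x0, y0 = model.origin
    fx = (pos[:, 0] - x0) / model.spacing
    fy = (pos[:, 1] - y0) / model.spacing
    if np.any(fx < 0) or np.any(fx > nx - 1) or np.any(fy < 0) or np.any(fy > ny - 1):
        raise ValueError("source/receiver position outside the model grid")
    ix, iy = np.floor(fx).astype(np.int64), np.floor(fy).astype(np.int64)
    ix = np.minimum(ix, nx - 2)
    iy = np.minimum(iy, ny - 2)
    ax, ay = fx - ix, fy - iy
    riy = np.stack([iy, iy, iy + 1, iy + 1]) + pad
    rix = np.stack([ix, ix + 1, ix, ix + 1]) + pad
    w = np.stack([(1 - ax) * (1 - ay), ax * (1 - ay), (1 - ax) * ay, ax * ay])
    return riy, rix, w


def _sponge_profile(shape, width: int, coef: float) -> np.ndarray:
    """Multiplicative per-step damping factor over the (unpadded) grid."""
    ny, nx = shape
    sigma = np.ones((ny, nx))
    if width <= 0:
        return sigma
    d_edge = np.minimum.outer(
        np.minimum(np.arange(ny), np.arange(ny)[::-1]),
        np.full(nx, np.iinfo(np.int64).max),
    )
    dx = np.minimum(np.arange(nx), np.arange(nx)[::-1])
    d = np.minimum(d_edge, dx[None, :])
    in_sponge = d < width
    sigma[in_sponge] = np.exp(-((coef * (width - d[in_sponge])) ** 2))
    return sigma


class WaveSolver:
    """Stateful solver bound to one (model, params) pair.

    Holds the padded sponge/coefficient fields and provides forward
    modelling, Born (linearized) modelling and the adjoint-state gradient
    with exact discrete transposition.
    """

    def __init__(
        self, model: VelocityModel, params: SimParams, dtype=np.float64
    ):
        self.model = model
        self.params = params.resolve(model)
        self.dtype = np.dtype(dtype)
        ny, nx = model.grid.shape
        self.pad = 2
        self.pshape = (ny + 4, nx + 4)
        c = model.grid
        self.m = 1.0 / c**2  # slowness squared
        self.b = np.zeros(self.pshape, dtype=self.dtype)
        self.b[2:-2, 2:-2] = self.params.dt**2 / self.m
        self.sigma = np.ones(self.pshape, dtype=self.dtype)
        self.sigma[2:-2, 2:-2] = _sponge_profile(
            (ny, nx), self.params.boundary_width, self.params.sponge_coef
        )
        self.inv_h2 = 1.0 / model.spacing**2
        # output-time bookkeeping: t_j = j * output_dt -> frames (n0, n0+1)
        dt, N = self.params.dt, self.params.n_steps
        self.n_out = int(np.floor(N * dt / self.params.output_dt)) + 1
        t_out = self.params.output_dt * np.arange(self.n_out)
        frame0 = np.minimum((t_out / dt).astype(np.int64), N - 1)
        self.alpha = (t_out / dt - frame0).astype(self.dtype)
        # outputs with frame0 == n occupy range(ostart[n], ostart[n+1])
        self.ostart = np.searchsorted(frame0, np.arange(N + 2)).astype(np.int64)

    # -- internal helpers ---------------------------------------------

    def _prep_source(self, src_pos, wavelet: Wavelet):
        w = resample_wavelet(wavelet, self.params.dt, self.params.n_steps)
        iy, ix, wt = _bilinear(self.model, np.atleast_2d(src_pos))
        return (
            iy[:, 0], ix[:, 0], wt[:, 0].astype(self.dtype),
            w.samples.astype(self.dtype),
        )

    def _prep_receivers(self, rec_pos):
        riy, rix, rwt = _bilinear(self.model, rec_pos)
        return riy, rix, rwt.astype(self.dtype)

    # -- forward ------------------------------------------------------

    def forward(
        self,
        src_pos,
        wavelet: Wavelet,
        rec_pos: np.ndarray,
        store: bool = False,
    ):
        """Simulate one shot; returns (data, stored_wavefield_or_None).

        ``data`` is (n_out, n_receivers) sampled at ``params.output_dt``.
        With ``store=True`` the full padded wavefield history is returned
        for use by :meth:`adjoint_gradient` / :meth:`born`.
        """
        N = self.params.n_steps
        siy, six, swt, wsamp = self._prep_source(src_pos, wavelet)
        riy, rix, rwt = self._prep_receivers(rec_pos)
        out = np.zeros((self.n_out, riy.shape[1]), dtype=self.dtype)
        if store:
            W = np.zeros((N + 1,) + self.pshape, dtype=self.dtype)
        else:
            W = np.zeros((1, 1, 1), dtype=self.dtype)
        illum = np.zeros(self.pshape if store else (1, 1), dtype=self.dtype)
        _kernels.run_forward(
            self.sigma, self.b, self.inv_h2, wsamp,
            siy, six, swt, riy, rix, rwt,
            self.ostart, self.alpha, N, out, W, illum, store,
        )
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("solver produced non-finite receiver data")
        if store:
            self._last_illum = illum[2:-2, 2:-2].astype(np.float64)
            return out, W
        return out, None

    # -- adjoint ------------------------------------------------------

    def adjoint_gradient(
        self, W: np.ndarray, residual: np.ndarray, src_pos, wavelet: Wavelet,
        rec_pos: np.ndarray,
    ) -> np.ndarray:
        """Gradient of 1/2 sum(residual^2) w.r.t. slowness-squared ``m``.

        ``residual`` (n_out, n_rec) is (synthetic - observed) on the output
        time grid; ``W`` is the stored source-side history returned by
        ``forward(..., store=True)`` for the same shot. Returns a
        model-shaped array (dJ/dm).
        """
        N = self.params.n_steps
        siy, six, swt, wsamp = self._prep_source(src_pos, wavelet)
        riy, rix, rwt = self._prep_receivers(rec_pos)
        acc = np.zeros(self.pshape, dtype=self.dtype)
        _kernels.run_adjoint(
            self.sigma, self.b, self.inv_h2, wsamp,
            siy, six, swt, riy, rix, rwt,
            self.ostart, self.alpha, N,
            np.ascontiguousarray(residual, dtype=self.dtype), W, acc,
        )
        return acc[2:-2, 2:-2].astype(np.float64) * (
            -(self.params.dt**2) / self.m**2
        )

    def gradient_sos(self, grad_m: np.ndarray) -> np.ndarray:
        """Map a slowness-squared gradient to the SoS convention:
        dJ/dc = dJ/dm * dm/dc with m = 1/c^2."""
        return grad_m * (-2.0 / self.model.grid**3)

    def born(
        self, W: np.ndarray, dm: np.ndarray, src_pos, wavelet: Wavelet,
        rec_pos: np.ndarray,
    ) -> np.ndarray:
        """Linearized (Born) data perturbation for a slowness-squared
        perturbation ``dm``, using the stored source-side history ``W``.
        Exact Jacobian action of the discrete scheme; the transpose of
        :meth:`adjoint_gradient`'s residual-to-gradient map."""
        N = self.params.n_steps
        siy, six, swt, wsamp = self._prep_source(src_pos, wavelet)
        riy, rix, rwt = self._prep_receivers(rec_pos)
        db = np.zeros(self.pshape, dtype=self.dtype)
        db[2:-2, 2:-2] = -(self.params.dt**2) / self.m**2 * dm
        dp = np.zeros(self.pshape, dtype=self.dtype)
        dpm = np.zeros(self.pshape, dtype=self.dtype)
        nxt = np.zeros(self.pshape, dtype=self.dtype)
        out = np.zeros((self.n_out, riy.shape[1]), dtype=self.dtype)
        for n in range(N + 1):
            if n > 0:
                nxt[...] = 0.0
                _kernels.step_forward(dp, dpm, nxt, self.sigma, self.b, self.inv_h2)
                # perturbation source: sigma*db*(A p[n-1] + s[n-1]) = db*W[n]
                nxt[2:-2, 2:-2] += db[2:-2, 2:-2] * W[n][2:-2, 2:-2]
                dpm, dp, nxt = dp, nxt, dpm
            lo1, hi1 = self.ostart[n], self.ostart[n + 1]
            lo2, hi2 = (self.ostart[n - 1], self.ostart[n]) if n >= 1 else (0, 0)
            if hi1 > lo1 or hi2 > lo2:
                vals = (dp[riy, rix] * rwt).sum(axis=0)
                for jo in range(lo1, hi1):
                    out[jo] += (1.0 - self.alpha[jo]) * vals
                for jo in range(lo2, hi2):
                    out[jo] += self.alpha[jo] * vals
        return out

    @property
    def last_illumination(self) -> np.ndarray:
        """Source illumination sum_t p^2 of the most recent stored
        forward run, model-shaped (used as a gradient preconditioner)."""
        if not hasattr(self, "_last_illum"):
            raise RuntimeError("no stored forward run yet")
        return self._last_illum


# ---------------------------------------------------------------------
# acquisition-level drivers


def simulate_shot(
    model: VelocityModel,
    geometry: AcquisitionGeometry,
    source_id: tuple[int, int],
    wavelet: Wavelet,
    params: SimParams,
    receiving_probes: Sequence[int] | None = None,
) -> list[ShotGather]:
    """One source element, one gather per receiving probe."""
    sp, se = source_id
    if receiving_probes is None:
        receiving_probes = geometry.receive_map[sp]
    solver = WaveSolver(model, params)
    rec_pos = np.concatenate([geometry.element_coords[rp] for rp in receiving_probes])
    src_pos = geometry.element_coords[sp, se]
    data, _ = solver.forward(src_pos, wavelet, rec_pos, store=False)
    ne = geometry.n_elements
    gathers = []
    for k, rp in enumerate(receiving_probes):
        gathers.append(
            ShotGather(
                traces=data[:, k * ne:(k + 1) * ne].astype(np.float32),
                dt=solver.params.output_dt,
                source_id=(sp, se),
                receiver_probe=rp,
                receiver_ids=[(rp, e) for e in range(ne)],
            )
        )
    return gathers


def simulate_dataset(
    model: VelocityModel,
    geometry: AcquisitionGeometry,
    wavelet: Wavelet,
    params: SimParams,
    sources: Sequence[tuple[int, int]] | None = None,
    label: str = "broadband",
    noise_rms: float = 0.0,
    noise_band: tuple[float, float] | None = None,
    noise_seed: int = 0,
) -> USCTDataset:
    """Loop all (or a subset of) source elements over the receive map.

    One solver instance is reused across sources (the model does not
    change between shots). Optional band-limited Gaussian noise is added
    per gather at ``noise_rms`` times the gather RMS.
    """
    from .signals import add_noise

    if sources is None:
        sources = [
            (sp, se)
            for sp in range(geometry.n_probe_positions)
            for se in range(geometry.n_elements)
        ]
    solver = WaveSolver(model, params)
    ne = geometry.n_elements
    gathers: dict[tuple[int, int, int], ShotGather] = {}
    nz = 0
    for (sp, se) in sources:
        rps = geometry.receive_map[sp]
        rec_pos = np.concatenate([geometry.element_coords[rp] for rp in rps])
        data, _ = solver.forward(
            geometry.element_coords[sp, se], wavelet, rec_pos, store=False
        )
        for k, rp in enumerate(rps):
            tr = data[:, k * ne:(k + 1) * ne]
            if noise_rms > 0:
                tr = add_noise(
                    tr.T, solver.params.output_dt, noise_rms, noise_band,
                    seed=noise_seed + nz,
                ).T
                nz += 1
            gathers[(sp, se, rp)] = ShotGather(
                traces=tr.astype(np.float32),
                dt=solver.params.output_dt,
                source_id=(sp, se),
                receiver_probe=rp,
                receiver_ids=[(rp, e) for e in range(ne)],
            )
    return USCTDataset(gathers, geometry, wavelet, label)


def first_arrival_pick(
    trace: np.ndarray, dt: float, threshold_frac: float = 0.2
) -> float:
    """First time the trace envelope exceeds ``threshold_frac`` of its
    maximum, with sub-sample linear refinement of the crossing.

    Returns NaN when the trace carries no energy (no arrival).
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must lie in (0, 1)")
    trace = np.asarray(trace, dtype=np.float64)
    if np.max(np.abs(trace)) == 0:
        return float("nan")
    # zero-pad before the Hilbert transform: the analytic signal is
    # computed circularly, and a pulse near the record end would
    # otherwise leak envelope energy to t = 0
    n = len(trace)
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    env = np.abs(hilbert(trace, N=n_fft))[:n]
    thr = threshold_frac * env.max()
    above = np.nonzero(env >= thr)[0]
    k = above[0]
    if k == 0:
        return 0.0
    frac = (thr - env[k - 1]) / (env[k] - env[k - 1])
    return float((k - 1 + frac) * dt)
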