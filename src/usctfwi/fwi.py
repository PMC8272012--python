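"""Frequency-stepped adjoint-state full-waveform inversion of SoS.

The inversion minimises the L2 waveform misfit between observed and
simulated shot gathers, stepping through a sequence of low-pass bands
from ``f_start`` to ``f_stop`` (multiscale continuation): early bands see
only the smooth, low-wavenumber structure, which keeps the data within
half a cycle of the water starting model and avoids cycle skipping —
provided the data actually contain energy at ``f_start``.

Band limiting is applied by zero-phase low-passing both the observed and
the synthetic gathers at each band cutoff, so the two sides of the
misfit pass through the identical record-truncation and filter-edge
path. The band-limited misfit gradient uses the adjoint-state method
with the filtered residual passed back through the (zero-phase, hence
nearly self-transpose) filter. The model update variable is slowness squared
(linear in the wave operator); results are reported as SoS and clipped
to the physiological range inside the inversion mask.

Optimizer: steepest descent preconditioned by source illumination, with
a backtracking line search. The optimizer is deliberately simple — the
scientific content is in the frequency continuation, not the descent
rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
import numpy as np
from scipy.signal import butter, sosfiltfilt

from .phantom import VelocityModel, interior_mask
from .signals import Wavelet
from .wavesim import SimParams, USCTDataset, WaveSolver


def _lowpass(traces: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    nyq = 0.5 / dt
    if cutoff >= nyq:
        return np.asarray(traces, dtype=np.float64)
    sos = butter(6, cutoff / nyq, output="sos")
    return sosfiltfilt(sos, np.asarray(traces, dtype=np.float64), axis=-1)


@dataclass
class FWIConfig:
    """Inversion settings.

    ``total_iterations`` are split evenly across ``n_bands`` low-pass
    cutoffs spaced linearly from ``f_start`` to ``f_stop`` (remainder to
    the last band). The default iteration budget matches the full-scale
    protocol; desk-scale runs use far fewer.
    """

    f_start: float
    f_stop: float
    n_bands: int = 8
    total_iterations: int = 208
    start_model: VelocityModel | None = None  # default: homogeneous water
    water_sos: float = 1484.0
    sim_params: SimParams = field(default_factory=SimParams)
    mask_radius: float | None = None  # inversion mask; None -> whole grid
    water_mask_update: bool = False   # True: update outside the mask too
    clip: tuple[float, float] = (1300.0, 1800.0)
    optimizer: str = "pcg"            # "pcg" (preconditioned CG) or "sd"
    step_init_dc: float = 25.0        # first-trial max SoS change, m/s
    step_grow: float = 1.5
    step_shrink: float = 0.5
    max_backtracks: int = 4
    precond_eps: float = 1e-3
    normalize_traces: bool = False    # flag only; raw L2 is the default
    dtype: str = "float32"

    def band_cutoffs(self) -> np.ndarray:
        if not (0 < self.f_start < self.f_stop):
            raise ValueError("require 0 < f_start < f_stop")
        if self.total_iterations < self.n_bands:
            raise ValueError("need at least one iteration per band")
        return np.linspace(self.f_start, self.f_stop, self.n_bands)

    def iters_per_band(self) -> list[int]:
        base = self.total_iterations // self.n_bands
        out = [base] * self.n_bands
        out[-1] += self.total_iterations - base * self.n_bands
        return out


@dataclass
class LogRow:
    band_cutoff: float
    iteration: int
    misfit: float
    step: float
    update_rms: float
    note: str = ""


@dataclass
class InversionLog:
    rows: list[LogRow] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.rows.append(LogRow(**kw))

    def misfits(self) -> np.ndarray:
        return np.array([r.misfit for r in self.rows])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["band_cutoff_hz", "iteration", "misfit", "step",
                        "update_rms", "note"])
            for r in self.rows:
                w.writerow([r.band_cutoff, r.iteration, r.misfit, r.step,
                            r.update_rms, r.note])


def _check_compatible(a: USCTDataset, b: USCTDataset) -> None:
    if set(a.gathers) != set(b.gathers):
        raise ValueError("datasets cover different (source, probe) sets")
    if abs(a.dt - b.dt) > 1e-15:
        raise ValueError(f"dt mismatch: {a.dt} vs {b.dt}")


def misfit(
    observed: USCTDataset, synthetic: USCTDataset, band_cutoff: float | None = None
) -> float:
    """1/2 sum of squared sample differences over all traces, after
    low-passing both datasets at ``band_cutoff`` (None: no filtering)."""
    _check_compatible(observed, synthetic)
    total = 0.0
    for key, g_obs in observed.gathers.items():
        a = np.asarray(g_obs.traces, dtype=np.float64)
        b = np.asarray(synthetic.gathers[key].traces, dtype=np.float64)
        if band_cutoff is not None:
            a = _lowpass(a.T, g_obs.dt, band_cutoff).T
            b = _lowpass(b.T, g_obs.dt, band_cutoff).T
        total += 0.5 * np.sum((b - a) ** 2)
    return float(total)


class _ShotTable:
    """Per-source receiver layout and observed-trace blocks."""

    def __init__(self, observed: USCTDataset):
        geom = observed.geometry
        self.entries = []
        for sid in observed.source_ids:
            gs = observed.gathers_for_source(sid)
            rps = sorted(gs)
            rec_pos = np.concatenate([geom.element_coords[rp] for rp in rps])
            obs = np.concatenate([gs[rp].traces for rp in rps], axis=1)
            self.entries.append(
                (sid, geom.element_coords[sid[0], sid[1]], rec_pos,
                 np.asarray(obs, dtype=np.float64))
            )


def gradient(
    model: VelocityModel,
    observed: USCTDataset,
    wavelet: Wavelet,
    band_cutoff: float | None = None,
    sim_params: SimParams | None = None,
    mask: np.ndarray | None = None,
    dtype=np.float64,
    return_parts: bool = False,
):
    """Adjoint-state gradient of the band-limited misfit w.r.t.
    slowness-squared, summed over all sources in ``observed``.

    With ``return_parts`` also returns (misfit value, illumination).
    The wavelet and the observed traces are low-passed at ``band_cutoff``;
    the synthetic data inherit the band limit through the source.
    """
    sim_params = sim_params or SimParams()
    solver = WaveSolver(model, sim_params, dtype=dtype)
    table = _ShotTable(observed)
    grad = np.zeros(model.grid.shape)
    illum = np.zeros(model.grid.shape)
    total = 0.0
    for sid, src_pos, rec_pos, obs in table.entries:
        if band_cutoff is not None:
            obs = _lowpass(obs.T, observed.dt, band_cutoff).T
        syn, W = solver.forward(src_pos, wavelet, rec_pos, store=True)
        syn = np.asarray(syn, dtype=np.float64)
        if band_cutoff is not None:
            syn = _lowpass(syn.T, observed.dt, band_cutoff).T
        res = syn - obs
        total += 0.5 * float(np.sum(res**2))
        if band_cutoff is not None:
            # adjoint of the zero-phase filter approximated by the filter
            # itself (symmetric impulse response)
            res = _lowpass(res.T, observed.dt, band_cutoff).T
        grad += solver.adjoint_gradient(W, res, src_pos, wavelet, rec_pos)
        illum += solver.last_illumination
    if mask is not None:
        grad = grad * mask
    if return_parts:
        return grad, total, illum
    return grad


def _data_misfit(
    model: VelocityModel, table: _ShotTable, wavelet: Wavelet,
    obs_band: list[np.ndarray], cutoff: float, sim_params: SimParams, dtype,
) -> float:
    solver = WaveSolver(model, sim_params, dtype=dtype)
    total = 0.0
    for (sid, src_pos, rec_pos, _), obs in zip(table.entries, obs_band):
        syn, _ = solver.forward(src_pos, wavelet, rec_pos, store=False)
        syn = _lowpass(np.asarray(syn, np.float64).T, solver.params.output_dt,
                       cutoff).T
        total += 0.5 * float(np.sum((syn - obs) ** 2))
    return total


def invert(
    observed: USCTDataset, config: FWIConfig
) -> tuple[VelocityModel, InversionLog]:
    """Frequency-stepped FWI; returns the final model and iteration log.

    Deterministic given inputs. A failed line search (no decrease after
    ``max_backtracks`` halvings) ends the current band early with a
    logged warning and moves on to the next band.
    """
    geom = observed.geometry
    wavelet = observed.wavelet
    cutoffs = config.band_cutoffs()
    iters = config.iters_per_band()

    if config.start_model is not None:
        start = config.start_model.copy()
    else:
        # homogeneous water on a grid that must be supplied via start_model
        raise ValueError("config.start_model is required (grid/spacing source)")
    model = start.copy()
    sim_params = config.sim_params
    if sim_params.dt is None:
        # pin the time step to the SoS clip ceiling so every model the
        # line search visits shares one discretization (otherwise the
        # misfit would depend on the model through dt as well)
        from .wavesim import CFL4

        sim_params = replace(
            sim_params,
            dt=sim_params.cfl_safety * CFL4 * start.spacing / config.clip[1],
        )
    config = replace(config, sim_params=sim_params)
    if config.mask_radius is not None and not config.water_mask_update:
        mask = interior_mask(model, config.mask_radius)
    else:
        mask = np.ones(model.grid.shape, dtype=bool)
    dtype = np.dtype(config.dtype)
    table = _ShotTable(observed)
    log = InversionLog()

    def clip_project(c: np.ndarray) -> np.ndarray:
        c = np.clip(c, config.clip[0], config.clip[1])
        c[~mask] = start.grid[~mask]
        return c

    step = None
    for cutoff, n_it in zip(cutoffs, iters):
        obs_band = [
            _lowpass(obs.T, observed.dt, cutoff).T for (_, _, _, obs) in table.entries
        ]
        band_energy = sum(float(np.sum(o**2)) for o in obs_band)
        prev_g = prev_d = None  # CG memory, reset at each band
        for it in range(n_it):
            solver = WaveSolver(model, config.sim_params, dtype=dtype)
            grad = np.zeros(model.grid.shape)
            illum = np.zeros(model.grid.shape)
            j0 = 0.0
            for (sid, src_pos, rec_pos, _), obs in zip(table.entries, obs_band):
                syn, Wst = solver.forward(src_pos, wavelet, rec_pos, store=True)
                syn = _lowpass(np.asarray(syn, np.float64).T, observed.dt,
                               cutoff).T
                res = syn - obs
                j0 += 0.5 * float(np.sum(res**2))
                res = _lowpass(res.T, observed.dt, cutoff).T  # filter transpose
                grad += solver.adjoint_gradient(Wst, res, src_pos, wavelet,
                                                rec_pos)
                illum += solver.last_illumination
            if j0 <= 1e-9 * band_energy:
                # residual at rounding level relative to the data in this
                # band: nothing meaningful left to fit
                log.append(band_cutoff=cutoff, iteration=it, misfit=j0,
                           step=0.0, update_rms=0.0, note="band converged")
                break
            g = grad / (illum + config.precond_eps * illum.max())
            g[~mask] = 0.0
            if np.abs(g).max() == 0:
                log.append(band_cutoff=cutoff, iteration=it, misfit=j0,
                           step=0.0, update_rms=0.0, note="zero gradient")
                break
            if step is None:
                c0 = config.water_sos
                step = 2.0 * config.step_init_dc / c0**3  # |dm| for dc at water

            def try_direction(d, trial):
                """Backtracking + one-point quadratic refinement.

                Returns (accepted, step, best SoS grid, best misfit)."""
                dn = d / np.abs(d).max()  # unit-max direction in m-units
                m0 = 1.0 / model.grid**2
                gdot = float(np.sum(grad * dn))  # directional derivative

                def evaluate(alpha):
                    c = clip_project(
                        1.0 / np.sqrt(np.maximum(m0 - alpha * dn, 1e-12))
                    )
                    j = _data_misfit(
                        replace(model, grid=c), table, wavelet, obs_band,
                        cutoff, config.sim_params, dtype,
                    )
                    return c, j

                for bt in range(config.max_backtracks + 1):
                    c1, j1 = evaluate(trial)
                    if j1 < j0 * (1.0 - 1e-4):  # relative sufficient decrease
                        # quadratic model through (0, j0), slope -gdot, (trial, j1)
                        denom = j1 - j0 + gdot * trial
                        if denom > 0:
                            a_star = 0.5 * gdot * trial**2 / denom
                            a_star = float(np.clip(a_star, 0.25 * trial, 3.0 * trial))
                            if abs(a_star - trial) > 0.05 * trial:
                                c2, j2 = evaluate(a_star)
                                if j2 < j1:
                                    return True, a_star, c2, j2
                        return True, trial, c1, j1
                    trial *= config.step_shrink
                return False, trial, None, None

            use_cg = config.optimizer == "pcg" and prev_g is not None
            if use_cg:
                beta = max(
                    0.0, float(np.sum(g * (g - prev_g)) / np.sum(prev_g * prev_g))
                )
                d = g + beta * prev_d
            else:
                d = g
            accepted, used, c_new, j_new = try_direction(d, step)
            if not accepted and use_cg:
                # CG direction failed: restart with steepest descent
                d = g
                accepted, used, c_new, j_new = try_direction(d, step)
            if not accepted:
                log.append(band_cutoff=cutoff, iteration=it, misfit=j0,
                           step=0.0, update_rms=0.0,
                           note="line search failed; band stopped")
                break
            prev_g, prev_d = g, d
            upd_rms = float(np.sqrt(np.mean((c_new - model.grid) ** 2)))
            model = replace(model, grid=c_new)
            log.append(band_cutoff=cutoff, iteration=it, misfit=j0,
                       step=used, update_rms=upd_rms)
            step = used * config.step_grow
    return model, log
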