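"""Experiment presets.

``desk`` is the scale every test and example runs at: a 128x128 grid,
an 8-probe x 16-element ring, and frequencies scaled so that the whole
band-limited-fails / broadband-succeeds contrast plays out in seconds
per shot on one CPU core. The scaling preserves the dimensionless
cycle-skip number N = f_min * dTOF (lowest usable data frequency times
the water-vs-tissue travel-time error): the band-limited start band has
N ~ 0.7 (skipped), the broadband start band N ~ 0.25 (safe), mirroring
the full-scale situation where a 0.5 MHz start frequency on probe-band
data skips while a 0.2 MHz start on broadband data does not.

``paper`` records the printed full-scale protocol (16 x 96 geometry,
0.20/0.50 -> 1.20 MHz stepping, 208 iterations, 256 x 96 windows,
+/-144-step shifts). It is a documented configuration, not something the
test suite runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ring_geometry
from .phantom import PhantomSpec
from .signals import Wavelet, hybrid_broadband, ideal_pulse, narrowband_wavelet
from .wavesim import SimParams


@dataclass(frozen=True)
class DeskScale:
    """Constants of the desk-scale study."""

    grid_shape: tuple[int, int] = (128, 128)
    spacing: float = 1.2e-3
    n_probes: int = 8
    n_elements: int = 16
    ring_diameter: float = 0.104
    element_pitch: float = 1.2e-3
    # wavelets (sampled at the output rate)
    trace_dt: float = 1e-6
    n_t: int = 136
    narrow_fc: float = 185e3
    narrow_fbw: float = 0.20
    ideal_fc: float = 80e3
    splice_f: float = 150e3
    splice_taper: float = 20e3
    # inversion bands
    fwi_f_start_broadband: float = 45e3
    fwi_f_start_bandlimited: float = 135e3
    fwi_f_stop: float = 210e3
    fwi_n_bands: int = 4
    fwi_iterations: int = 20
    mask_radius: float = 0.046
    # acquisition / noise
    fwi_source_elements: tuple[int, ...] = (4, 11)
    train_source_elements: tuple[int, ...] = (2, 6, 9, 13)
    noise_rms: float = 0.02
    # bandext windows
    window_t: int = 96
    window_x: int = 16
    shift: int = 16

    def sim_params(self) -> SimParams:
        # dt fixed from the SoS clip ceiling so every simulation in the
        # study shares one discretization regardless of the model
        dt = 0.85 * (2.0 / np.sqrt(32.0 / 3.0)) * self.spacing / 1800.0
        return SimParams(
            t_max=self.n_t * self.trace_dt - self.trace_dt / 2,
            dt=dt,
            output_dt=self.trace_dt,
            boundary_width=16,
            sponge_coef=0.03,
        )

    def geometry(self):
        return ring_geometry(
            self.n_probes, self.n_elements, self.ring_diameter, self.element_pitch
        )

    def phantom_spec(self, seed: int) -> PhantomSpec:
        return PhantomSpec(
            outer_radius=0.038,
            fat_layer_thickness=6e-3,
            fat_sos=1450.0,
            glandular_sos_mean=1700.0,
            glandular_sos_texture_amplitude=25.0,
            # texture features scaled with the inversion wavelength so the
            # stop-band (~210 kHz, lambda/2 ~ 3.5 mm) can resolve them,
            # mirroring the full-scale relation of 5 mm texture to a
            # 1.2 MHz stop band
            texture_correlation_length=7e-3,
            inclusions=(((0.012, 0.008), 0.007, 1600.0),
                        ((-0.012, -0.009), 0.005, 1760.0)),
            scatterer_density=2e3,
            scatterer_amplitude=40.0,
            boundary_wobble=0.05,
            seed=seed,
        )

    def narrow_wavelet(self) -> Wavelet:
        return narrowband_wavelet(
            fc=self.narrow_fc, fractional_bandwidth=self.narrow_fbw,
            dt=self.trace_dt, n=self.n_t,
        )

    def broadband_wavelet(self) -> Wavelet:
        narrow = self.narrow_wavelet()
        ideal = ideal_pulse(fc=self.ideal_fc, dt=self.trace_dt, n=self.n_t)
        return hybrid_broadband(
            narrow, ideal, splice_f=self.splice_f, taper_width=self.splice_taper
        )

    def fwi_sources(self) -> list[tuple[int, int]]:
        return [(p, e) for p in range(self.n_probes)
                for e in self.fwi_source_elements]

    def train_sources(self) -> list[tuple[int, int]]:
        return [(p, e) for p in range(self.n_probes)
                for e in self.train_source_elements]


DESK = DeskScale()


@dataclass(frozen=True)
class PaperScale:
    """The printed full-scale protocol, for documentation and for users
    with the compute to run it; not exercised by the test suite."""

    grid_spacing: float = 0.25e-3
    n_probes: int = 16
    n_elements: int = 96
    ring_diameter: float = 0.200
    trace_dt: float = 1.0 / 12.5e6
    narrow_fc: float = 2.0e6
    ideal_fc: float = 0.5e6
    splice_f: float = 1.0e6
    highpass_cutoff: float = 0.55e6
    highpass_order: int = 40
    fwi_f_start_broadband: float = 0.20e6
    fwi_f_start_bandlimited: float = 0.50e6
    fwi_f_stop: float = 1.20e6
    fwi_iterations: int = 208
    window_t: int = 256
    window_x: int = 96
    shift: int = 144


PAPER = PaperScale()
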