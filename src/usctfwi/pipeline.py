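"""Configuration-driven experiment orchestration.

``run_experiment`` executes the full desk-scale study:

    phantoms -> paired band-limited / broadband simulation -> network
    training -> extrapolation -> frequency-stepped FWI on every dataset
    variant -> evaluation,

writing content-addressed artifacts (skip-if-exists) plus a manifest of
inputs, seeds and output hashes, and returning the headline numbers in
memory. Tests and the acceptance script drive this entry point so the
whole chain stays reproducible from one config and one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as uio
from .bandext import (CNN1dConfig, UNetConfig, build_cnn1d, build_unet,
                      extrapolate, make_pairs, train)
from .eval import band_rms_curve, cycle_skip_report
from .fwi import FWIConfig, invert
from .phantom import (homogeneous_model, interior_mask, make_breast_phantom,
                      phantom_rms)
from .presets import DESK
from .signals import bandwidth_limit_db
from .wavesim import simulate_dataset


@dataclass
class ExperimentConfig:
    """Seeds and sizes of one desk-scale experiment run.

    Geometry, wavelets, phantom statistics, and FWI bands come from the
    desk preset (the study conditions); this config selects the seeds,
    training effort and output location.
    """

    seed: int = 0
    n_test_phantoms: int = 3
    n_train_phantoms: int = 2
    n_pairs_per_phantom: int = 192
    unet: UNetConfig = field(default_factory=UNetConfig)
    cnn1d: CNN1dConfig = field(default_factory=CNN1dConfig)
    unet_epochs: int = 15
    cnn1d_epochs: int = 6
    cnn1d_max_pairs: int = 256
    lr: float = 1.5e-3
    run_cnn1d: bool = True
    outdir: str | None = None

    @property
    def test_seeds(self) -> list[int]:
        return [self.seed + k for k in range(self.n_test_phantoms)]

    @property
    def train_seeds(self) -> list[int]:
        return [self.seed + 101 + k for k in range(self.n_train_phantoms)]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "unet" in d:
            d["unet"] = UNetConfig(**d["unet"])
        if "cnn1d" in d:
            c = d["cnn1d"]
            c["channels"] = tuple(c["channels"])
            d["cnn1d"] = CNN1dConfig(**c)
        return cls(**d)

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path | None, config: ExperimentConfig):
        self.outdir = outdir
        self.data = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {},
        }

    def record(self, stage: str, outputs: dict[str, Path] | None, error=None):
        entry = {"status": "error" if error else "ok"}
        if error:
            entry["error"] = repr(error)
        if outputs:
            entry["outputs"] = {k: {"path": str(p), "sha256": _sha256(p)}
                                for k, p in outputs.items()}
        self.data["stages"][stage] = entry
        if self.outdir is not None:
            (self.outdir / "manifest.json").write_text(
                json.dumps(self.data, indent=1)
            )


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the staged desk-scale study; returns the results dict.

    Heavy intermediate artifacts (datasets, models, reconstructions) are
    written under ``config.outdir`` when given, keyed by the config
    hash so a rerun with an identical config skips completed stages.
    Any stage failure is recorded in the manifest before the exception
    propagates; prior outputs stay on disk.
    """
    desk = DESK
    geom = desk.geometry()
    sp = desk.sim_params()
    wn, wb = desk.narrow_wavelet(), desk.broadband_wavelet()
    outdir = None
    if config.outdir:
        outdir = Path(config.outdir) / config.content_hash()
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    def stage(name, fn, *files):
        """Run ``fn`` (which may itself load a cached artifact) and
        record its outputs in the manifest."""
        try:
            result = fn()
        except Exception as exc:
            manifest.record(name, None, error=exc)
            raise
        if outdir is not None and files:
            manifest.record(name, {f: outdir / f for f in files
                                   if (outdir / f).exists()})
        else:
            manifest.record(name, None)
        return result

    results: dict = {"seed": config.seed, "labels": {}, "start_rms": {},
                     "rms": {}, "band_reduction": {}}

    # -- training data + models ---------------------------------------
    def build_pairs():
        pairs = []
        for k, tseed in enumerate(config.train_seeds):
            ph = make_breast_phantom(desk.phantom_spec(tseed), desk.grid_shape,
                                     desk.spacing)
            bl = simulate_dataset(ph, geom, wn, sp, sources=desk.train_sources(),
                                  label="bandlimited", noise_rms=desk.noise_rms,
                                  noise_seed=tseed)
            bb = simulate_dataset(ph, geom, wb, sp, sources=desk.train_sources(),
                                  label="broadband")
            pairs += make_pairs(bl, bb, config.n_pairs_per_phantom, seed=tseed,
                                window_t=desk.window_t, window_x=desk.window_x,
                                shift=desk.shift)
        return pairs

    pairs = stage("training_pairs", build_pairs)

    def train_unet():
        from .bandext import BandextModel

        if outdir is not None and (outdir / "unet2d.npz").exists():
            return BandextModel.load(outdir / "unet2d")
        m = build_unet(config.unet)
        train(m, pairs, epochs=config.unet_epochs, lr=config.lr, batch=12,
              seed=config.seed)
        if outdir is not None:
            m.save(outdir / "unet2d")
        return m

    def train_cnn():
        from .bandext import BandextModel

        if outdir is not None and (outdir / "cnn1d.npz").exists():
            return BandextModel.load(outdir / "cnn1d")
        m = build_cnn1d(config.cnn1d)
        train(m, pairs[:config.cnn1d_max_pairs], epochs=config.cnn1d_epochs,
              lr=config.lr, batch=192, seed=config.seed)
        if outdir is not None:
            m.save(outdir / "cnn1d")
        return m

    unet = stage("train_unet2d", train_unet)
    cnn = stage("train_cnn1d", train_cnn) if config.run_cnn1d else None

    # -- per-test-phantom datasets, extrapolation, inversion ----------
    start = homogeneous_model(desk.grid_shape, desk.spacing)
    f_lo40, _ = bandwidth_limit_db(wn)
    low_band = (40e3, np.floor(f_lo40 / 10e3) * 10e3)
    centers = np.arange(40e3, 241e3, 10e3)
    red_acc: dict[str, list] = {"unet2d": [], "cnn1d": []}

    for tseed in config.test_seeds:
        truth = make_breast_phantom(desk.phantom_spec(tseed), desk.grid_shape,
                                    desk.spacing)
        mask = interior_mask(truth, desk.mask_radius)
        obs_bl = simulate_dataset(truth, geom, wn, sp, sources=desk.fwi_sources(),
                                  label="bandlimited", noise_rms=desk.noise_rms,
                                  noise_seed=7 + tseed)
        obs_bb = simulate_dataset(truth, geom, wb, sp, sources=desk.fwi_sources(),
                                  label="broadband")
        variants = {"bandlimited": obs_bl, "broadband": obs_bb}
        ext_u = extrapolate(unet, obs_bl, window_t=desk.window_t, wavelet=wb)
        variants["extrapolated"] = ext_u
        if cnn is not None:
            variants["extrapolated_cnn1d"] = extrapolate(
                cnn, obs_bl, window_t=desk.window_t, wavelet=wb
            )

        # data-space error in the band below the input's -40 dB limit
        c_in = band_rms_curve(obs_bl, obs_bb, centers, width=20e3)
        c_u = band_rms_curve(ext_u, obs_bb, centers, width=20e3)
        red_acc["unet2d"].append(
            1.0 - c_u.value_in(*low_band) / c_in.value_in(*low_band)
        )
        if cnn is not None:
            c_c = band_rms_curve(variants["extrapolated_cnn1d"], obs_bb,
                                 centers, width=20e3)
            red_acc["cnn1d"].append(
                1.0 - c_c.value_in(*low_band) / c_in.value_in(*low_band)
            )

        recon = {}
        for label, data in variants.items():
            f_start = (desk.fwi_f_start_bandlimited if label == "bandlimited"
                       else desk.fwi_f_start_broadband)
            cfg = FWIConfig(
                f_start=f_start, f_stop=desk.fwi_f_stop,
                n_bands=desk.fwi_n_bands, total_iterations=desk.fwi_iterations,
                start_model=start, sim_params=sp, mask_radius=desk.mask_radius,
            )

            def run_inv(data=data, cfg=cfg, label=label):
                path = (outdir / f"model_{tseed}_{label}.h5") if outdir else None
                if path is not None and path.exists():
                    return uio.load_model(path)
                model, log = invert(data, cfg)
                if path is not None:
                    uio.save_model(path, model)
                    log.to_csv(outdir / f"log_{tseed}_{label}.csv")
                return model

            recon[label] = stage(f"invert_{tseed}_{label}", run_inv)

        report = cycle_skip_report(truth, recon, mask)
        results["rms"][tseed] = report.rms
        results["start_rms"][tseed] = phantom_rms(truth, start, mask)
        results["labels"][tseed] = report.ordering_expected
        if outdir is not None:
            report.to_json(outdir / f"cycle_skip_{tseed}.json")

    results["band_reduction"] = {
        k: float(np.median(v)) for k, v in red_acc.items() if v
    }
    results["low_band_hz"] = [float(low_band[0]), float(low_band[1])]
    if outdir is not None:
        (outdir / "results.json").write_text(json.dumps(results, indent=1))
        manifest.record("results", {"results.json": outdir / "results.json"})
    return results


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the small reference artifacts the test suite and examples
    load: a phantom, the ring geometry, the three wavelets, and a mini
    two-source dataset. Deterministic per seed."""
    desk = DESK
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ph = make_breast_phantom(desk.phantom_spec(seed), desk.grid_shape, desk.spacing)
    paths["phantom"] = outdir / "phantom.h5"
    uio.save_model(paths["phantom"], ph)

    geom = desk.geometry()
    paths["geometry"] = outdir / "geometry.csv"
    geom.to_csv(paths["geometry"])

    for name, w in (("narrowband", desk.narrow_wavelet()),
                    ("broadband", desk.broadband_wavelet())):
        paths[f"wavelet_{name}"] = outdir / f"wavelet_{name}.csv"
        w.to_csv(paths[f"wavelet_{name}"])

    mini = simulate_dataset(ph, geom, desk.narrow_wavelet(), desk.sim_params(),
                            sources=[(0, 4), (4, 11)], label="bandlimited")
    paths["dataset"] = outdir / "mini_dataset.h5"
    uio.save_dataset(paths["dataset"], mini)
    return paths
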