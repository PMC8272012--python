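"""HDF5 containers for models, wavelets, and USCT datasets.

Layout of a dataset file:

    /gathers/s{probe}_{element}/r{probe}   float32 (n_t, n_receivers)
    /geometry/element_coords               float64 (n_probes, n_elem, 2)
    /wavelet/samples                       float64
    attributes: dt, label, ring metadata

Velocity models are stored as a single 2D float dataset with spacing /
origin / water_sos attributes. All writes are deterministic so identical
inputs produce byte-identical files (HDF5 metadata aside).
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .geometry import AcquisitionGeometry
from .phantom import VelocityModel
from .signals import Wavelet
from .wavesim import ShotGather, USCTDataset


def save_model(path, model: VelocityModel) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sos", data=model.grid)
        d.attrs["spacing"] = model.spacing
        d.attrs["origin"] = model.origin
        d.attrs["water_sos"] = model.water_sos


def load_model(path) -> VelocityModel:
    with h5py.File(path, "r") as f:
        d = f["sos"]
        return VelocityModel(
            grid=d[()],
            spacing=float(d.attrs["spacing"]),
            origin=tuple(d.attrs["origin"]),
            water_sos=float(d.attrs["water_sos"]),
        )


def model_png(path, model: VelocityModel, vmin=1400.0, vmax=1800.0) -> None:
    """Optional quick-look PNG of a SoS model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ext = model.extent
    im = ax.imshow(model.grid, origin="lower", extent=(ext[0], ext[1], ext[2], ext[3]),
                   vmin=vmin, vmax=vmax, cmap="viridis")
    fig.colorbar(im, ax=ax, label="SoS (m/s)")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_geometry(f: h5py.File, geom: AcquisitionGeometry) -> None:
    g = f.create_group("geometry")
    g.create_dataset("element_coords", data=geom.element_coords)
    g.create_dataset("probe_angles", data=geom.probe_angles)
    g.attrs["n_probe_positions"] = geom.n_probe_positions
    g.attrs["n_elements"] = geom.n_elements
    g.attrs["ring_diameter"] = geom.ring_diameter
    g.attrs["element_pitch"] = geom.element_pitch
    g.attrs["receive_map"] = json.dumps(
        {str(k): v for k, v in geom.receive_map.items()}
    )


def _read_geometry(f: h5py.File) -> AcquisitionGeometry:
    g = f["geometry"]
    return AcquisitionGeometry(
        n_probe_positions=int(g.attrs["n_probe_positions"]),
        n_elements=int(g.attrs["n_elements"]),
        ring_diameter=float(g.attrs["ring_diameter"]),
        element_pitch=float(g.attrs["element_pitch"]),
        probe_angles=g["probe_angles"][()],
        element_coords=g["element_coords"][()],
        receive_map={int(k): list(v)
                     for k, v in json.loads(g.attrs["receive_map"]).items()},
    )


def save_dataset(path, ds: USCTDataset) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = ds.dt
        f.attrs["label"] = ds.label
        _write_geometry(f, ds.geometry)
        w = f.create_group("wavelet")
        w.create_dataset("samples", data=ds.wavelet.samples)
        w.attrs["dt"] = ds.wavelet.dt
        w.attrs["t0"] = ds.wavelet.t0
        root = f.create_group("gathers")
        for (sp, se, rp) in sorted(ds.gathers):
            g = ds.gathers[(sp, se, rp)]
            grp = root.require_group(f"s{sp}_{se}")
            d = grp.create_dataset(f"r{rp}", data=g.traces.astype(np.float32))
            d.attrs["receiver_probe"] = rp


def load_dataset(path) -> USCTDataset:
    with h5py.File(path, "r") as f:
        geom = _read_geometry(f)
        w = f["wavelet"]
        wavelet = Wavelet(w["samples"][()], float(w.attrs["dt"]), float(w.attrs["t0"]))
        dt = float(f.attrs["dt"])
        gathers = {}
        for sname, grp in f["gathers"].items():
            sp, se = (int(v) for v in sname[1:].split("_"))
            for rname, d in grp.items():
                rp = int(rname[1:])
                gathers[(sp, se, rp)] = ShotGather(
                    traces=d[()],
                    dt=dt,
                    source_id=(sp, se),
                    receiver_probe=rp,
                    receiver_ids=[(rp, e) for e in range(geom.n_elements)],
                )
        return USCTDataset(gathers, geom, wavelet, label=str(f.attrs["label"]))
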