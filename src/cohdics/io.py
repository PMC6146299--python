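"""HDF5 serialization for the pipeline's artifacts.

Each container carries a ``format_version`` attribute; complex matrices
are stored as separate real and imaginary datasets.  Datasets are
written without modification timestamps so identical content yields
identical files.
"""

from __future__ import annotations

import numpy as np
import h5py

from .connectivity import ConnectivityEstimate, ConnectivityPairs
from .csd import CSDMatrix
from .geometry import ForwardModel, SensorArray, SourceSpace
from .simulate import EpochsData
from .stats import BundleResult

FORMAT_VERSION = 1

__all__ = [
    "save_forward", "load_forward",
    "save_epochs", "load_epochs",
    "save_csd_list", "load_csd_list",
    "save_connectivity", "load_connectivity",
    "save_bundle_result", "load_bundle_result",
]


def _ds(group, name, data):
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def save_forward(path, fwd: ForwardModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_orient"] = fwd.n_orient
        _ds(f, "leadfields", fwd.leadfields)
        _ds(f, "orientation_vectors", fwd.orientation_vectors)
        _ds(f, "source_points", fwd.source_space.points)
        _ds(f, "vertex_ids", fwd.source_space.vertex_ids)
        _ds(f, "sphere_origin", fwd.source_space.sphere_origin)
        _ds(f, "sensor_positions", fwd.sensor_array.positions)
        _ds(f, "sensor_orientations", fwd.sensor_array.orientations)
        f.attrs["sensor_names"] = list(fwd.sensor_array.names)


def load_forward(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        src = SourceSpace(
            points=f["source_points"][()],
            vertex_ids=f["vertex_ids"][()],
            sphere_origin=f["sphere_origin"][()],
        )
        sensors = SensorArray(
            positions=f["sensor_positions"][()],
            orientations=f["sensor_orientations"][()],
            names=list(f.attrs["sensor_names"]),
        )
        return ForwardModel(
            leadfields=f["leadfields"][()],
            n_orient=int(f.attrs["n_orient"]),
            orientation_vectors=f["orientation_vectors"][()],
            source_space=src,
            sensor_array=sensors,
        )


def save_epochs(path, epochs: EpochsData, condition: str = "",
                subject: str = "", ground_truth: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["fs"] = epochs.fs
        f.attrs["tmin"] = epochs.tmin
        f.attrs["condition"] = condition
        f.attrs["subject"] = subject
        _ds(f, "data", epochs.data)
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.attrs["coupling"] = np.atleast_1d(ground_truth["coupling"])
            g.attrs["noise_sigma"] = ground_truth["noise_sigma"]
            if ground_truth["active_sources"]:
                _ds(g, "active_sources",
                    np.array(ground_truth["active_sources"], dtype=float))


def load_epochs(path) -> tuple[EpochsData, dict]:
    with h5py.File(path, "r") as f:
        epochs = EpochsData(
            data=f["data"][()], fs=float(f.attrs["fs"]),
            tmin=float(f.attrs["tmin"]),
        )
        meta = {
            "condition": str(f.attrs["condition"]),
            "subject": str(f.attrs["subject"]),
        }
        if "ground_truth" in f:
            g = f["ground_truth"]
            meta["coupling"] = np.asarray(g.attrs["coupling"])
            meta["noise_sigma"] = float(g.attrs["noise_sigma"])
            if "active_sources" in g:
                meta["active_sources"] = g["active_sources"][()]
    return epochs, meta


def save_csd_list(path, csds: list[CSDMatrix]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        for k, csd in enumerate(csds):
            g = f.create_group(f"csd_{k:04d}")
            _ds(g, "real", csd.matrix.real)
            _ds(g, "imag", csd.matrix.imag)
            _ds(g, "frequencies", np.asarray(csd.frequencies))
            g.attrs["tmin"] = csd.tmin
            g.attrs["tmax"] = csd.tmax
            g.attrs["n_epochs"] = csd.n_epochs
            g.attrs["sensor_names"] = list(csd.sensor_names)


def load_csd_list(path) -> list[CSDMatrix]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(CSDMatrix(
                matrix=g["real"][()] + 1j * g["imag"][()],
                frequencies=tuple(g["frequencies"][()]),
                tmin=float(g.attrs["tmin"]), tmax=float(g.attrs["tmax"]),
                n_epochs=int(g.attrs["n_epochs"]),
                sensor_names=tuple(g.attrs["sensor_names"]),
            ))
    return out


def save_connectivity(path, con: ConnectivityEstimate) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        _ds(f, "pairs", con.pairs.pairs)
        _ds(f, "coherence", con.coherence)
        vids = sorted(con.pairs.positions.keys())
        _ds(f, "position_vertex_ids", np.asarray(vids, dtype=int))
        _ds(f, "positions", np.array([con.pairs.positions[v] for v in vids]))
        f.attrs["min_dist"] = con.pairs.min_dist
        f.attrs["band"] = np.asarray(con.band, dtype=float)
        f.attrs["window"] = np.asarray(con.window, dtype=float)
        f.attrs["condition"] = con.condition
        f.attrs["n_angles"] = con.n_angles
        f.attrs["is_contrast"] = con.is_contrast


def load_connectivity(path) -> ConnectivityEstimate:
    with h5py.File(path, "r") as f:
        vids = f["position_vertex_ids"][()]
        pos = f["positions"][()]
        pairs = ConnectivityPairs(
            pairs=f["pairs"][()], min_dist=float(f.attrs["min_dist"]),
            positions={int(v): p for v, p in zip(vids, pos)},
        )
        return ConnectivityEstimate(
            pairs=pairs, coherence=f["coherence"][()],
            band=tuple(f.attrs["band"]), window=tuple(f.attrs["window"]),
            condition=str(f.attrs["condition"]),
            n_angles=int(f.attrs["n_angles"]),
            is_contrast=bool(f.attrs["is_contrast"]),
        )


def save_bundle_result(path, res: BundleResult) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        _ds(f, "t_values", res.t_values)
        _ds(f, "surviving_idx", res.surviving_idx)
        _ds(f, "bundle_t", res.bundle_t)
        _ds(f, "null_max", res.null_max)
        _ds(f, "p_values", res.p_values)
        _ds(f, "significant_idx", res.significant_idx)
        g = f.create_group("bundles")
        for k, (members, sign) in enumerate(res.bundles):
            d = g.create_dataset(f"bundle_{k:04d}", data=np.asarray(members),
                                 track_times=False)
            d.attrs["sign"] = sign
        for name in ("cluster_threshold", "max_spread", "n_permutations",
                     "alpha", "seed"):
            f.attrs[name] = getattr(res, name)


def load_bundle_result(path) -> BundleResult:
    with h5py.File(path, "r") as f:
        bundles = []
        g = f["bundles"]
        for key in sorted(g.keys()):
            bundles.append((g[key][()], int(g[key].attrs["sign"])))
        return BundleResult(
            t_values=f["t_values"][()],
            surviving_idx=f["surviving_idx"][()],
            bundles=bundles,
            bundle_t=f["bundle_t"][()],
            null_max=f["null_max"][()],
            p_values=f["p_values"][()],
            significant_idx=f["significant_idx"][()],
            cluster_threshold=float(f.attrs["cluster_threshold"]),
            max_spread=float(f.attrs["max_spread"]),
            n_permutations=int(f.attrs["n_permutations"]),
            alpha=float(f.attrs["alpha"]),
            seed=int(f.attrs["seed"]),
        )
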