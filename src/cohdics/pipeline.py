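"""Config-driven end-to-end driver: simulate -> csd -> power ->
connectivity -> stats -> summarize.

Each stage reads its predecessors' artifacts from the run directory and
writes its own (HDF5 for arrays, CSV for tables).  A manifest records
every output file with the configuration and a SHA-256 content hash, so
a rerun with the same config can be checked for bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .connectivity import (
    all_to_all_connectivity_pairs,
    connectivity_grand_average,
    dics_connectivity,
)
from .csd import csd_band_mean, csd_morlet, make_morlet
from .dics import PowerMap, power_contrast, power_map
from .geometry import (
    compute_forward,
    forward_to_tangential,
    make_spherical_sensor_array,
    make_spherical_source_grid,
    restrict_forward_to_vertices,
    select_vertices_in_sensor_range,
)
from .simulate import SimulationConfig, simulate_group
from .stats import SubjectConnectivitySet, cluster_permutation_test
from .summarize import (
    degree_map,
    export_connectogram_table,
    make_synthetic_parcellation,
    parcellate_connectivity,
)

logger = logging.getLogger("cohdics")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "STAGES", "run_stage"]


@dataclass
class PipelineConfig:
    """All stage parameters of one end-to-end run (SI units throughout)."""

    seed: int = 0
    # geometry: a close-fitting, near-complete spherical array (3 cm
    # standoff) so the beamformer's point spread is narrower than the
    # 4 cm pair-distance threshold
    n_sensors: int = 96
    shell_radius: float = 0.10
    coverage: float = 0.85
    n_sources: int = 500
    source_radius: float = 0.07
    # simulation
    fs: float = 200.0
    epoch_tmin: float = -1.0
    epoch_tmax: float = 1.2
    n_epochs: int = 100
    carrier_band: tuple = (8.0, 12.0)
    active_sources: tuple = ((70, 0.4), (370, 1.2))
    conditions: dict = field(
        default_factory=lambda: {"face": 0.7, "scrambled": 0.2}
    )
    n_subjects: int = 12
    snr: float = 2.0
    angle_jitter: float = 0.1
    # csd
    bands: tuple = (("alpha", 7.0, 13.0),)
    n_cycles: float = 7.0
    decim: int = 20
    window: tuple = (0.0, 0.4)
    baseline: tuple = (-0.2, 0.0)
    # beamformer
    reg: float = 0.05
    power_mode: str = "max_power"
    # connectivity
    sensor_range_dist: float = 0.07
    min_dist: float = 0.04
    n_angles: int = 50
    analysis_band: str = "alpha"
    # stats
    cluster_threshold: float = 5.0
    max_spread: float = 0.01
    n_permutations: int = 1000
    alpha: float = 0.05
    # summarize
    n_parcels: int = 12
    weight_by_degree: bool = True

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = json.load(f)
        cfg = cls(**raw)
        cfg.carrier_band = tuple(cfg.carrier_band)
        cfg.active_sources = tuple(tuple(s) for s in cfg.active_sources)
        cfg.bands = tuple(tuple(b) for b in cfg.bands)
        cfg.window = tuple(cfg.window)
        cfg.baseline = tuple(cfg.baseline)
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True)

    def band_frequencies(self, name: str) -> np.ndarray:
        """1-Hz-spaced wavelet centre frequencies spanning the named band."""
        for bname, lo, hi in self.bands:
            if bname == name:
                return np.linspace(lo, hi, int(round(hi - lo)) + 1)
        raise KeyError(f"unknown band {name!r}")


def validate_config(cfg: PipelineConfig) -> tuple[list[str], list[str]]:
    """Check every config invariant; returns (errors, warnings)."""
    errors, warns = [], []
    bands = sorted(cfg.bands, key=lambda b: b[1])
    for (na, lo_a, hi_a), (nb, lo_b, hi_b) in zip(bands, bands[1:]):
        if hi_a > lo_b:
            errors.append(f"bands {na!r} and {nb!r} overlap")
    for name, lo, hi in cfg.bands:
        if lo >= hi:
            errors.append(f"band {name!r} has lo >= hi")
        if cfg.fs <= 2.0 * hi:
            errors.append(
                f"fs={cfg.fs} Hz aliases band {name!r} (upper edge {hi} Hz)"
            )
    if not any(b[0] == cfg.analysis_band for b in cfg.bands):
        errors.append(f"analysis_band {cfg.analysis_band!r} not in bands")
    for wname, (lo, hi) in (("window", cfg.window), ("baseline", cfg.baseline)):
        if lo >= hi:
            errors.append(f"{wname} has tmin >= tmax")
        if lo < cfg.epoch_tmin or hi > cfg.epoch_tmax:
            errors.append(f"{wname} lies outside the epoch extent")
    for name, value in (
        ("sensor_range_dist", cfg.sensor_range_dist),
        ("cluster_threshold", cfg.cluster_threshold),
        ("max_spread", cfg.max_spread),
        ("n_permutations", cfg.n_permutations),
        ("alpha", cfg.alpha),
        ("reg", cfg.reg),
    ):
        if value <= 0:
            errors.append(f"{name} must be positive")
    if cfg.min_dist < 0:
        errors.append("min_dist must be non-negative")
    if len(cfg.conditions) != 2:
        errors.append("exactly two conditions are required for the contrast")
    # edge-effect warnings: the slowest wavelet of each band
    if not errors:
        for name, lo, hi in cfg.bands:
            sigma_t = make_morlet(lo, cfg.n_cycles, cfg.fs).sigma_t
            for wname, (wlo, whi) in (
                ("window", cfg.window), ("baseline", cfg.baseline)
            ):
                if (wlo - cfg.epoch_tmin < 5 * sigma_t
                        or cfg.epoch_tmax - whi < 5 * sigma_t):
                    warns.append(
                        f"{wname} within 5 sigma_t of the epoch edge for "
                        f"band {name!r} (sigma_t={sigma_t:.3f} s)"
                    )
    return errors, warns


def _sim_configs(cfg: PipelineConfig) -> dict[str, SimulationConfig]:
    return {
        cond: SimulationConfig(
            fs=cfg.fs, tmin=cfg.epoch_tmin, tmax=cfg.epoch_tmax,
            n_epochs=cfg.n_epochs, carrier_band=tuple(cfg.carrier_band),
            active_sources=tuple(cfg.active_sources), coupling=coupling,
            snr=cfg.snr, n_subjects=cfg.n_subjects, seed=cfg.seed,
        )
        for cond, coupling in cfg.conditions.items()
    }


def stage_forward(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    sensors = make_spherical_sensor_array(
        cfg.n_sensors, cfg.shell_radius, cfg.coverage
    )
    src = make_spherical_source_grid(cfg.n_sources, cfg.source_radius)
    fwd = compute_forward(src, sensors)
    fwd_tan = forward_to_tangential(fwd)
    keep = select_vertices_in_sensor_range(src, sensors, cfg.sensor_range_dist)
    fwd_tan_restricted = restrict_forward_to_vertices(fwd_tan, keep)
    logger.info(
        "forward: %d sensors, %d sources, %d within %.3f m of a sensor",
        sensors.n_sensors, src.n_vertices, len(keep), cfg.sensor_range_dist,
    )
    paths = []
    for name, obj in (
        ("forward_full.h5", fwd),
        ("forward_tan.h5", fwd_tan),
        ("forward_tan_restricted.h5", fwd_tan_restricted),
    ):
        p = outdir / name
        _io.save_forward(p, obj)
        paths.append(p)
    return paths


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    """Write every subject's epochs to HDF5 (inspection / external use).

    The csd stage re-simulates from the same seeds instead of reading
    these files, so raw epochs never need to be persisted for a normal
    run; this stage exists for debugging and for consumers who want the
    sensor data itself.
    """
    fwd_tan = _io.load_forward(outdir / "forward_tan.h5")
    group = simulate_group(
        fwd_tan, _sim_configs(cfg), cfg.n_subjects, cfg.angle_jitter
    )
    epo_dir = outdir / "epochs"
    epo_dir.mkdir(exist_ok=True)
    paths = []
    for subj, entry in enumerate(group):
        for cond, (epochs, truth) in entry.items():
            p = epo_dir / f"sub{subj:03d}_{cond}.h5"
            _io.save_epochs(p, epochs, condition=cond,
                            subject=f"sub{subj:03d}", ground_truth=truth)
            paths.append(p)
    logger.info("simulate: wrote epochs for %d subjects", len(group))
    return paths


def stage_csd(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    fwd_tan = _io.load_forward(outdir / "forward_tan.h5")
    group = simulate_group(
        fwd_tan, _sim_configs(cfg), cfg.n_subjects, cfg.angle_jitter
    )
    freqs = np.unique(np.concatenate(
        [cfg.band_frequencies(b[0]) for b in cfg.bands]
    ))
    csd_dir = outdir / "csd"
    csd_dir.mkdir(exist_ok=True)
    paths = []
    for subj, entry in enumerate(group):
        for cond, (epochs, _) in entry.items():
            for wname, (lo, hi) in (
                ("active", cfg.window), ("baseline", cfg.baseline)
            ):
                csds = csd_morlet(
                    epochs, freqs, lo, hi, cfg.n_cycles, cfg.decim
                )
                p = csd_dir / f"sub{subj:03d}_{cond}_{wname}.h5"
                _io.save_csd_list(p, csds)
                paths.append(p)
        logger.info("csd: subject %d done", subj)
    return paths


def _band_csd(cfg, outdir, subj, cond, wname):
    csds = _io.load_csd_list(outdir / "csd" / f"sub{subj:03d}_{cond}_{wname}.h5")
    band = next(b for b in cfg.bands if b[0] == cfg.analysis_band)
    return csd_band_mean(csds, band[1], band[2])


def stage_power(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    fwd = _io.load_forward(outdir / "forward_full.h5")
    cond_a, cond_b = list(cfg.conditions)
    contrasts = []
    for subj in range(cfg.n_subjects):
        maps = {}
        for cond in (cond_a, cond_b):
            csd = _band_csd(cfg, outdir, subj, cond, "active")
            maps[cond] = power_map(fwd, csd, cfg.reg, cfg.power_mode)
        # baseline power pooled over both conditions' pre-stimulus windows
        base_maps = [
            power_map(fwd, _band_csd(cfg, outdir, subj, cond, "baseline"),
                      cfg.reg, cfg.power_mode)
            for cond in (cond_a, cond_b)
        ]
        baseline = PowerMap(
            values=np.mean([m.values for m in base_maps], axis=0),
            summary_mode=base_maps[0].summary_mode,
            vertex_ids=base_maps[0].vertex_ids,
            band=base_maps[0].band, window=base_maps[0].window,
        )
        contrasts.append(power_contrast(maps[cond_a], maps[cond_b], baseline))
    mean_contrast = np.mean([c.values for c in contrasts], axis=0)
    df = pd.DataFrame({
        "vertex_id": contrasts[0].vertex_ids, "value": mean_contrast,
    })
    p = outdir / "power_contrast.csv"
    df.to_csv(p, index=False)
    logger.info("power: grand-average contrast over %d subjects", len(contrasts))
    return [p]


def stage_connectivity(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    fwd_tan = _io.load_forward(outdir / "forward_tan_restricted.h5")
    pairs = all_to_all_connectivity_pairs(fwd_tan.source_space, cfg.min_dist)
    logger.info("connectivity: %d candidate pairs", pairs.n_pairs)
    con_dir = outdir / "con"
    con_dir.mkdir(exist_ok=True)
    paths = []
    for subj in range(cfg.n_subjects):
        for cond in cfg.conditions:
            csd = _band_csd(cfg, outdir, subj, cond, "active")
            con = dics_connectivity(
                pairs, fwd_tan, csd, cfg.reg, cfg.n_angles, condition=cond
            )
            p = con_dir / f"sub{subj:03d}_{cond}.h5"
            _io.save_connectivity(p, con)
            paths.append(p)
        logger.info("connectivity: subject %d done", subj)
    return paths


def stage_stats(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    cond_a, cond_b = list(cfg.conditions)
    cons_a, cons_b = [], []
    for subj in range(cfg.n_subjects):
        cons_a.append(_io.load_connectivity(outdir / "con" / f"sub{subj:03d}_{cond_a}.h5"))
        cons_b.append(_io.load_connectivity(outdir / "con" / f"sub{subj:03d}_{cond_b}.h5"))
    con_set = SubjectConnectivitySet(condition_a=cons_a, condition_b=cons_b)
    result = cluster_permutation_test(
        con_set, cfg.cluster_threshold, cfg.max_spread,
        cfg.n_permutations, cfg.alpha, seed=cfg.seed,
    )
    logger.info(
        "stats: %d of %d connections survive |t| >= %g; %d bundles, "
        "%d significant",
        len(result.surviving_idx), con_set.pairs.n_pairs,
        cfg.cluster_threshold, len(result.bundles),
        len(result.significant_bundles),
    )
    p_h5 = outdir / "stats.h5"
    _io.save_bundle_result(p_h5, result)
    pairs = con_set.pairs.pairs
    sig = result.significant_idx
    df = pd.DataFrame({
        "vertex_i": pairs[sig, 0] if len(sig) else [],
        "vertex_j": pairs[sig, 1] if len(sig) else [],
        "t_value": result.t_values[sig] if len(sig) else [],
    })
    p_csv = outdir / "significant_connections.csv"
    df.to_csv(p_csv, index=False)
    return [p_h5, p_csv]


def stage_summarize(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    cond_a, cond_b = list(cfg.conditions)
    result = _io.load_bundle_result(outdir / "stats.h5")
    cons_a, cons_b = [], []
    for subj in range(cfg.n_subjects):
        cons_a.append(_io.load_connectivity(outdir / "con" / f"sub{subj:03d}_{cond_a}.h5"))
        cons_b.append(_io.load_connectivity(outdir / "con" / f"sub{subj:03d}_{cond_b}.h5"))
    contrast = connectivity_grand_average(
        [a - b for a, b in zip(cons_a, cons_b)]
    )
    pairs = contrast.pairs
    sig = result.significant_idx
    from dataclasses import replace as _replace
    from .connectivity import ConnectivityPairs
    pruned_pairs = ConnectivityPairs(
        pairs=pairs.pairs[sig], min_dist=pairs.min_dist,
        positions=pairs.positions,
    )
    pruned = _replace(contrast, pairs=pruned_pairs,
                      coherence=contrast.coherence[sig])
    fwd_tan = _io.load_forward(outdir / "forward_tan_restricted.h5")
    src = fwd_tan.source_space
    deg = degree_map(pruned, src.vertex_ids, cfg.weight_by_degree, pairs)
    p_deg = outdir / "degree_map.csv"
    pd.DataFrame({"vertex_id": src.vertex_ids, "value": deg}).to_csv(
        p_deg, index=False
    )
    parc = make_synthetic_parcellation(
        src, min(cfg.n_parcels, src.n_vertices), seed=cfg.seed
    )
    pc = parcellate_connectivity(pruned, parc, cfg.weight_by_degree, pairs)
    p_tab = outdir / "connectogram.csv"
    export_connectogram_table(pc, p_tab)
    logger.info("summarize: %d significant connections summarized", len(sig))
    return [p_deg, p_tab]


# stages run (in order) by run_pipeline; raw epochs are re-simulated
# from their seeds inside stage_csd rather than persisted
STAGES = {
    "forward": stage_forward,
    "csd": stage_csd,
    "power": stage_power,
    "connectivity": stage_connectivity,
    "stats": stage_stats,
    "summarize": stage_summarize,
}

# additionally runnable on demand (CLI)
ALL_STAGES = {**STAGES, "simulate": stage_simulate}


def run_stage(name: str, cfg: PipelineConfig, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        paths = ALL_STAGES[name](cfg, outdir)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run every stage in order and write a manifest with content hashes.

    A rerun with the same config and seed produces bit-identical
    artifacts and therefore an identical manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        errors, warns = validate_config(cfg)
        for w in warns:
            warnings.warn(w, stacklevel=2)
            logger.warning(w)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        all_paths = []
        for name in STAGES:
            all_paths.extend(run_stage(name, cfg, outdir))
        manifest = {
            "config": asdict(cfg),
            "artifacts": {
                str(p.relative_to(outdir)): _sha256(p) for p in all_paths
            },
        }
        mpath = outdir / "manifest.json"
        with open(mpath, "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        return mpath
    finally:
        logger.removeHandler(handler)
        handler.close()
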