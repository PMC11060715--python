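"""End-to-end pipeline: simulate/load -> preprocess -> detect -> connect -> assemble.

A single :class:`PipelineConfig` carries every stage parameter (defaults
are the workflow's standard constants: alpha = 0.4, 30 s / 8th-percentile
baseline, 98% CI, tau = 1.8 s, 30 mm/s movement threshold with a 6-frame
debounce, 5000 bootstrap iterations with 23-frame mean blocks at the 99th
percentile, strong edges at r > 0.3, Promax power 4, merge dot 0.6,
p < 0.05, widefield k = 5) plus one integer seed that is expanded into
independent per-stage substreams.  ``run_pipeline`` writes tidy result
tables and a manifest with config hash, seed and per-file checksums so a
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblies as asm
from . import connectivity as conn
from . import events, io, traces
from .synthetic import GroundTruth, generate_population

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline", "load_config"]

_FLOAT_FMT = "%.10g"  # fixed CSV float format => byte-identical reruns


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the master seed."""

    # preprocessing
    alpha: float = 0.4
    group_k: int = 2
    baseline_window_s: float = 30.0
    baseline_percentile: float = 8.0
    # transient detection
    ci_level: float = 0.98
    tau_s: float = 1.8
    # movement
    speed_threshold_mms: float = 30.0
    min_bout_frames: int = 6
    # connectivity
    bootstrap_iterations: int = 5000
    mean_block_frames: float = 23.0
    bootstrap_quantile: float = 0.99
    strong_edge_threshold: float = 0.3
    # assemblies
    promax_power: int = 4
    overlap_threshold: float = 0.6
    synchrony_surrogates: int = 1000
    p_threshold: float = 0.05
    assembly_bootstrap_iterations: int = 1000
    z_max_override: float | None = None
    # widefield
    widefield_k: float = 5.0
    pixel_scale_mm: float = 0.01
    # inputs
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    input_raw: str | None = None
    input_neuropil: str | None = None
    input_speed: str | None = None
    input_centroids: str | None = None
    input_frame_rate_hz: float = 25.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) config file into a PipelineConfig."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    output_checksums: dict[str, str]
    summary: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    summary: dict
    manifest: RunManifest
    dff: traces.DffTraceSet
    raster: events.TransientRaster
    graph: conn.FunctionalGraph
    model: asm.AssemblyModel
    activation: asm.ActivationSeries | None


def _substreams(seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute the full analysis chain and write tidy outputs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_sim, seed_boot, seed_syn, seed_asm = _substreams(config.seed, 4)

    # --- inputs -----------------------------------------------------------
    if config.input_raw is not None:
        trace_set = io.load_trace_tables(
            config.input_raw,
            config.input_neuropil,
            config.input_frame_rate_hz,
            config.input_centroids,
        )
        speed = pd.read_csv(config.input_speed)["speed_mms"].to_numpy()
        recording = None
    else:
        gt = GroundTruth(**{**config.simulate, "seed": seed_sim})
        recording = generate_population(gt)
        trace_set = traces.RoiTraceSet(
            raw=recording.roi_fluorescence,
            neuropil=recording.neuropil_fluorescence,
            frame_rate_hz=gt.frame_rate_hz,
            centroids=recording.roi_centroids,
        )
        speed = recording.speed.speed

    # --- preprocess -------------------------------------------------------
    dff = traces.preprocess(
        trace_set,
        alpha=config.alpha,
        group_k=config.group_k,
        window_s=config.baseline_window_s,
        percentile=config.baseline_percentile,
    )
    z = traces.zscore_traces(dff.dff)

    # --- transients + movement -------------------------------------------
    noise = events.estimate_noise(dff.dff, ci_level=config.ci_level)
    raster = events.detect_transients(
        dff.dff, noise, dff.frame_rate_hz, tau_s=config.tau_s
    )
    seg_tracking = events.segment_movement(
        speed, config.speed_threshold_mms, config.min_bout_frames
    )
    seg = events.downsample_movement(seg_tracking, config.group_k)
    seg.moving = seg.moving[: raster.active.shape[1]]
    rates = events.firing_rates(raster, seg)

    # --- connectivity -----------------------------------------------------
    corr = conn.pairwise_correlation(z)
    null = conn.stationary_bootstrap_null(
        z,
        n_iterations=config.bootstrap_iterations,
        mean_block_frames=config.mean_block_frames,
        quantile=config.bootstrap_quantile,
        seed=seed_boot,
    )
    graph = conn.build_graph(
        corr, null, trace_set.centroids, strong_threshold=config.strong_edge_threshold
    )

    # --- assemblies -------------------------------------------------------
    model = asm.detect_assemblies(
        z,
        raster.active,
        promax_power=config.promax_power,
        z_max=config.z_max_override,
        overlap_threshold=config.overlap_threshold,
        n_surrogates=config.synchrony_surrogates,
        p_threshold=config.p_threshold,
        seed=seed_syn,
    )
    activation = None
    assembly_corr = None
    if model.n_assemblies:
        activation = asm.activation_significance(
            raster.active, model.memberships, p_threshold=config.p_threshold
        )
        if model.n_assemblies >= 2:
            assembly_corr = asm.assembly_assembly_correlation(
                activation,
                n_iterations=config.assembly_bootstrap_iterations,
                mean_block_frames=config.mean_block_frames,
                quantile=config.bootstrap_quantile,
                seed=seed_asm,
            )

    # --- summary ----------------------------------------------------------
    n = trace_set.raw.shape[0]
    summary = {
        "n_neurons": n,
        "n_frames_effective": int(dff.dff.shape[1]),
        "frame_rate_effective_hz": dff.frame_rate_hz,
        "fraction_moving": rates.fraction_moving,
        "population_rate_moving_per_min": rates.population_rate_moving,
        "population_rate_resting_per_min": rates.population_rate_resting,
        "connections_per_neuron": graph.connections_per_neuron,
        "mean_strong_connections_per_neuron": float(graph.strong_count.mean()),
        "density_percent": graph.density_percent,
        "n_assemblies": model.n_assemblies,
        "mean_neurons_per_assembly": float(model.sizes.mean()) if model.n_assemblies else np.nan,
        "percent_population_per_assembly": (
            100.0 * float(model.sizes.mean()) / n if model.n_assemblies else np.nan
        ),
        "assembly_assembly_mean_r": (
            assembly_corr.mean_significant_r if assembly_corr is not None else np.nan
        ),
    }

    # --- outputs ----------------------------------------------------------
    pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False, float_format=_FLOAT_FMT)
    per_neuron = pd.DataFrame(
        {
            "neuron": range(n),
            "noise_sd": noise.sd,
            "n_events": raster.n_events,
            "rate_per_min": raster.rate_per_min,
            "rate_moving_per_min": rates.rate_moving,
            "rate_resting_per_min": rates.rate_resting,
            "significant_connections": graph.significant_count,
            "strong_connections": graph.strong_count,
        }
    )
    per_neuron.to_csv(out / "neurons.csv", index=False, float_format=_FLOAT_FMT)
    io.raster_to_table(raster).to_csv(out / "events.csv", index=False)
    io.edges_to_table(graph, null).to_csv(out / "edges.csv", index=False, float_format=_FLOAT_FMT)
    atable, ameta = io.assemblies_to_tables(model)
    atable.to_csv(out / "assemblies.csv", index=False)
    (out / "assemblies.json").write_text(json.dumps(ameta, indent=2, sort_keys=True))
    if recording is not None:
        io.save_ground_truth_json(recording.ground_truth, out / "ground_truth.json")

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.csv"))
    }
    manifest = RunManifest(
        config_hash=config.hash(),
        seed=config.seed,
        package_version=_package_version(),
        output_checksums=checksums,
        summary=summary,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return PipelineResult(
        summary=summary,
        manifest=manifest,
        dff=dff,
        raster=raster,
        graph=graph,
        model=model,
        activation=activation,
    )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("caim")
    except PackageNotFoundError:
        return "0.0.0+local"
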