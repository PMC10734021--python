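"""End-to-end experiment runner: simulate -> localize -> track -> analyze.

An :class:`ExperimentConfig` bundles the phantom geometry, flow, acquisition,
pipeline and analysis parameters with a seed; :func:`run_experiment` executes
the full chain and (optionally) writes a reproducible output bundle — frame
stack, ground truth, localization and track tables, density/velocity maps,
saturation curves and a summary — together with a manifest recording every
parameter.  Named recipes reproduce the study designs: bifurcation angles
25/45/55 deg, channel-width pairs 300/100 and 500/200 um, trifurcating and
converging phantoms, and the bubble-concentration series.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .geometry import (
    ChannelNetwork,
    FlowConfig,
    build_bifurcation,
    build_trifurcation,
    expected_velocity,
    flow_split,
)
from .processing import UlmParams, localize_stack
from .saturation import SaturationCurve, TauEstimate, fit_exponential, saturation_curve
from .simulate import AcquisitionConfig, FrameStack, GroundTruth, generate_sequence
from .tracking import (
    DensityMap,
    Track,
    VelocityMap,
    accumulate_maps,
    compute_velocities,
    filter_tracks,
    link_tracks,
    tracks_to_frame,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ConfigError",
    "run_experiment",
    "make_fixtures",
    "recipe_config",
    "RECIPES",
    "mean_channel_speed",
    "default_link_gate_px",
]

log = logging.getLogger("ulmflow")


class ConfigError(ValueError):
    """An experiment configuration section or field is invalid."""


@dataclass
class AnalysisConfig:
    """Where and over how many frames the saturation analysis runs."""

    roi_size_px: int = 25
    roi_offset_mm: float = 0.3
    n_saturation_frames: int | None = None
    channels: list[str] = field(default_factory=list)
    min_track_frames: int = 10


@dataclass
class ExperimentConfig:
    """Full description of one simulated experiment."""

    phantom: dict
    flow: FlowConfig
    acquisition: AcquisitionConfig
    pipeline: UlmParams
    analysis: AnalysisConfig
    seed: int = 0
    name: str = "experiment"

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        for section in ("phantom", "flow", "acquisition"):
            if section not in d:
                raise ConfigError(f"missing config section {section!r}")
        phantom = dict(d["phantom"])
        kind = phantom.get("kind")
        if kind not in ("bifurcation", "trifurcation", "single"):
            raise ConfigError(
                f"phantom.kind must be bifurcation, trifurcation or single, got {kind!r}"
            )
        try:
            flow = FlowConfig(**d["flow"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid flow section: {exc}") from exc
        try:
            acq = AcquisitionConfig(**d["acquisition"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid acquisition section: {exc}") from exc
        try:
            pipeline = UlmParams(**d.get("pipeline", {}))
        except TypeError as exc:
            raise ConfigError(f"invalid pipeline section: {exc}") from exc
        try:
            analysis = AnalysisConfig(**d.get("analysis", {}))
        except TypeError as exc:
            raise ConfigError(f"invalid analysis section: {exc}") from exc
        seed = int(d.get("seed", 0))
        acq.rng_seed = seed
        return cls(
            phantom=phantom,
            flow=flow,
            acquisition=acq,
            pipeline=pipeline,
            analysis=analysis,
            seed=seed,
            name=d.get("name", "experiment"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "phantom": self.phantom,
            "flow": dataclasses.asdict(self.flow),
            "acquisition": self.acquisition.to_dict(),
            "pipeline": dataclasses.asdict(self.pipeline),
            "analysis": dataclasses.asdict(self.analysis),
        }

    def build_network(self) -> ChannelNetwork:
        p = self.phantom
        kind = p["kind"]
        if kind == "bifurcation":
            return build_bifurcation(
                main_width_um=p.get("main_width_um", 300.0),
                branch_width_um=p.get("branch_width_um", 300.0),
                angle_deg=p.get("angle_deg", 45.0),
                lengths_mm=tuple(p.get("lengths_mm", (1.2, 1.8, 1.8))),
                height_um=p.get("height_um", 300.0),
            )
        if kind == "trifurcation":
            return build_trifurcation(
                width_um=p.get("width_um", 300.0),
                angle_deg=p.get("angle_deg", 30.0),
                converging=p.get("converging", False),
                lengths_mm=tuple(p.get("lengths_mm", (1.0, 1.8))),
                height_um=p.get("height_um", 300.0),
            )
        from .geometry import build_single_channel

        return build_single_channel(
            width_um=p.get("width_um", 300.0),
            length_mm=p.get("length_mm", 3.0),
            height_um=p.get("height_um", 300.0),
        )


@dataclass
class ExperimentResult:
    """In-memory bundle produced by :func:`run_experiment`."""

    config: ExperimentConfig
    network: ChannelNetwork
    stack: FrameStack
    ground_truth: GroundTruth
    localizations: pd.DataFrame
    tracks: list[Track]
    density_map: DensityMap
    velocity_map: VelocityMap
    saturation: dict[str, SaturationCurve]
    taus: dict[str, TauEstimate]
    summary: pd.DataFrame


def default_link_gate_px(
    network: ChannelNetwork, acq: AcquisitionConfig, upsample_factor: int
) -> float:
    """Link gate: twice the largest expected per-frame displacement, in px."""
    v_max = 1.5 * max(s.mean_velocity_mm_s for s in network.segments)
    disp_mm = v_max / acq.frame_rate_hz
    pitch = acq.pixel_size_mm / upsample_factor
    return max(2.0 * disp_mm / pitch, 1.0)


def mean_channel_speed(
    tracks: list[Track],
    network: ChannelNetwork,
    segment_id: str,
    junction_margin_mm: float = 0.2,
    per_track: bool = True,
) -> float:
    """Mean track speed within one channel segment.

    Steps are assigned to the segment containing their midpoint; steps
    within ``junction_margin_mm`` of a junction end are discarded because
    channel footprints overlap there.  With ``per_track`` each track
    contributes its own mean once (so slow long-lived bubbles are not
    over-weighted by their many steps); otherwise all steps pool equally.
    """
    seg = network[segment_id]
    lo = junction_margin_mm if network.parents(segment_id) else 0.0
    hi = seg.length_mm - (junction_margin_mm if network.daughters(segment_id) else 0.0)
    per_track_means = []
    pooled = []
    for t in tracks:
        if t.step_speeds_mm_s is None:
            continue
        speeds = []
        for k, v in enumerate(t.step_speeds_mm_s):
            mx = (t.x_mm[k] + t.x_mm[k + 1]) / 2.0
            mz = (t.z_mm[k] + t.z_mm[k + 1]) / 2.0
            hit = network.locate((mx, mz))
            if hit is not None and hit[0] == segment_id and lo <= hit[1] <= hi:
                speeds.append(v)
        if speeds:
            per_track_means.append(float(np.mean(speeds)))
            pooled.extend(speeds)
    vals = per_track_means if per_track else pooled
    return float(np.mean(vals)) if vals else float("nan")


def _analysis_channels(network: ChannelNetwork, requested: list[str]) -> list[str]:
    if requested:
        for ch in requested:
            if ch not in [s.id for s in network.segments]:
                raise ConfigError(f"analysis.channels: unknown segment {ch!r}")
        return requested
    ids = [s.id for s in network.segments]
    picks = [c for c in ("main_out", "branch", "branch_mid") if c in ids]
    return picks or [network.outlets[0]]


def _roi_for_segment(
    network: ChannelNetwork,
    segment_id: str,
    acq: AcquisitionConfig,
    upsample_factor: int,
    roi_size: int,
    roi_offset_mm: float,
) -> tuple[int, int, int]:
    """25 x 25 (by default) upsampled-px ROI just downstream of a segment start."""
    seg = network[segment_id]
    center = np.asarray(seg.start, float) + seg.direction * min(
        roi_offset_mm, seg.length_mm / 2.0
    )
    pitch = acq.pixel_size_mm / upsample_factor
    x0, z0 = acq.origin_mm
    rc = (center[1] - z0) / pitch - 0.5
    cc = (center[0] - x0) / pitch - 0.5
    rows = acq.rows * upsample_factor
    cols = acq.cols * upsample_factor
    r0 = int(np.clip(round(rc - roi_size / 2.0), 0, rows - roi_size))
    c0 = int(np.clip(round(cc - roi_size / 2.0), 0, cols - roi_size))
    return (r0, c0, roi_size)


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentResult:
    """Simulate, process and analyze one experiment; optionally write outputs.

    The output bundle contains the frame stack (TIFF + JSON sidecar), ground
    truth and localization/track CSVs, density and velocity maps (TIFF and
    CSV), one saturation CSV per analyzed channel, a summary CSV and a
    manifest with every parameter and the seed.
    """
    acq = config.acquisition
    log.info("experiment %s: seed=%d", config.name, config.seed)
    network = flow_split(config.build_network(), config.flow)
    stack, truth = generate_sequence(network, config.flow, acq)
    log.info("simulated %d frames, %d true tracks", stack.n_frames,
             truth.positions["track_id"].nunique() if len(truth.positions) else 0)

    locs = localize_stack(stack, config.pipeline)
    log.info("localized %d events", len(locs))

    gate = default_link_gate_px(network, acq, config.pipeline.upsample_factor)
    tracks = link_tracks(locs, max_link_distance=gate)
    tracks = filter_tracks(tracks, config.analysis.min_track_frames)
    pitch = acq.pixel_size_mm / config.pipeline.upsample_factor
    for t in tracks:
        compute_velocities(t, acq.frame_rate_hz, pitch)
    log.info("kept %d tracks after the >%d-frame rule", len(tracks),
             config.analysis.min_track_frames)

    up_shape = (acq.rows * config.pipeline.upsample_factor,
                acq.cols * config.pipeline.upsample_factor)
    density, vmap = accumulate_maps(tracks, up_shape)

    vessel_mask_up = network.channel_mask(
        up_shape[0], up_shape[1], pitch, acq.origin_mm
    )
    n_sat = config.analysis.n_saturation_frames or min(3000, stack.n_frames)
    n_sat = min(n_sat, stack.n_frames)
    saturation: dict[str, SaturationCurve] = {}
    taus: dict[str, TauEstimate] = {}
    rows = []
    for ch in _analysis_channels(network, config.analysis.channels):
        roi = _roi_for_segment(
            network, ch, acq, config.pipeline.upsample_factor,
            config.analysis.roi_size_px, config.analysis.roi_offset_mm,
        )
        curve = saturation_curve(
            locs, roi, vessel_mask_up, acq.frame_rate_hz, n_frames=n_sat
        )
        saturation[ch] = curve
        seg = network[ch]
        v_expected = expected_velocity(seg.flow_rate_ml_min, seg.area_m2)
        row = {
            "channel": ch,
            "flow_rate_ml_min": seg.flow_rate_ml_min,
            "expected_mean_velocity_mm_s": v_expected,
            "measured_mean_speed_mm_s": mean_channel_speed(tracks, network, ch),
            "tau_s": float("nan"),
            "r_squared": float("nan"),
            "fit_flagged": True,
        }
        try:
            est = fit_exponential(curve)
            taus[ch] = est
            row.update(tau_s=est.tau_s, r_squared=est.r_squared,
                       fit_flagged=est.flagged)
            if est.flagged:
                log.warning("channel %s: fit R^2=%.3f below %.2f", ch,
                            est.r_squared, 0.98)
        except ValueError as exc:
            log.warning("channel %s: %s", ch, exc)
        rows.append(row)
    summary = pd.DataFrame(rows)

    result = ExperimentResult(
        config=config, network=network, stack=stack, ground_truth=truth,
        localizations=locs, tracks=tracks, density_map=density,
        velocity_map=vmap, saturation=saturation, taus=taus, summary=summary,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.stack.save(out_dir / "stack.tif")
    result.ground_truth.positions.to_csv(out_dir / "ground_truth.csv", index=False)
    result.localizations.to_csv(out_dir / "localizations.csv", index=False)
    tracks_to_frame(result.tracks).to_csv(out_dir / "tracks.csv", index=False)
    tifffile.imwrite(out_dir / "density_map.tif",
                     result.density_map.counts.astype(np.float32))
    tifffile.imwrite(out_dir / "velocity_map.tif",
                     result.velocity_map.speeds.astype(np.float32))
    vr, vc = np.nonzero(result.velocity_map.n_steps)
    pd.DataFrame(
        {"row": vr, "col": vc, "speed_mm_s": result.velocity_map.speeds[vr, vc]}
    ).to_csv(out_dir / "velocity_map.csv", index=False)
    for ch, curve in result.saturation.items():
        frame = curve.to_frame()
        if ch in result.taus:
            frame["fitted_fraction"] = result.taus[ch].evaluate(curve.times_s)
        frame.to_csv(out_dir / f"saturation_{ch}.csv", index=False)
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    manifest = {
        "ulmflow_version": __version__,
        "config": result.config.to_dict(),
        "network": result.network.to_dict(),
        "n_localizations": int(len(result.localizations)),
        "n_tracks": int(len(result.tracks)),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

def _scaled(scale: str) -> dict:
    """Grid/frames presets: ``tiny`` for fast test-size runs, ``full`` for
    full 9000-frame velocity / 3000-frame saturation acquisitions."""
    if scale == "tiny":
        return {
            "rows": 64, "cols": 64, "n_frames": 300, "block_size": 300,
            "lengths_bif": (0.5, 1.0, 1.0), "lengths_tri": (0.4, 0.9),
        }
    if scale == "full":
        return {
            "rows": 128, "cols": 128, "n_frames": 9000, "block_size": 1500,
            "lengths_bif": (1.2, 1.8, 1.8), "lengths_tri": (1.0, 1.8),
        }
    raise ConfigError(f"unknown scale {scale!r} (expected tiny or full)")


def recipe_config(name: str, seed: int = 0, scale: str = "tiny",
                  **overrides) -> ExperimentConfig:
    """Build the configuration for a named study recipe."""
    if name not in RECIPES:
        raise ConfigError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")
    s = _scaled(scale)
    d = RECIPES[name](s)
    d["seed"] = seed
    d["name"] = name
    acq = d.setdefault("acquisition", {})
    acq.setdefault("rows", s["rows"])
    acq.setdefault("cols", s["cols"])
    acq.setdefault("n_frames", s["n_frames"])
    acq.setdefault("block_size", s["block_size"])
    for key, val in overrides.items():
        section, _, fieldname = key.partition(".")
        if not fieldname:
            d[section] = val
        else:
            d.setdefault(section, {})[fieldname] = val
    return ExperimentConfig.from_dict(d)


def _bifurcation_recipe(s, main=300.0, branch=300.0, angle=45.0,
                        rule="symmetric", flow=0.02, **acq):
    return {
        "phantom": {
            "kind": "bifurcation", "main_width_um": main,
            "branch_width_um": branch, "angle_deg": angle,
            "lengths_mm": list(s["lengths_bif"]),
        },
        "flow": {"inlet_flow_rate_ml_min": flow, "split_rule": rule},
        "acquisition": dict(acq),
    }


RECIPES = {
    "bifurcation-25": lambda s: _bifurcation_recipe(s, angle=25.0),
    "bifurcation-45": lambda s: _bifurcation_recipe(s, angle=45.0),
    "bifurcation-55": lambda s: _bifurcation_recipe(s, angle=55.0),
    "width-300-100": lambda s: _bifurcation_recipe(
        s, main=300.0, branch=100.0, rule="resistance"
    ),
    "width-500-200": lambda s: _bifurcation_recipe(
        s, main=500.0, branch=200.0, rule="resistance"
    ),
    "concentration-low": lambda s: _bifurcation_recipe(
        s, concentration_per_ml=1.6e6
    ),
    "concentration-medium": lambda s: _bifurcation_recipe(
        s, concentration_per_ml=6.4e6
    ),
    "concentration-high": lambda s: _bifurcation_recipe(
        s, concentration_per_ml=6.4e7
    ),
    "bmode-scatterers": lambda s: _bifurcation_recipe(
        s, mode="BMODE", scatterer_density=0.005
    ),
    "trifurcation": lambda s: {
        "phantom": {"kind": "trifurcation", "width_um": 300.0,
                    "angle_deg": 30.0, "converging": False,
                    "lengths_mm": list(s["lengths_tri"])},
        "flow": {"inlet_flow_rate_ml_min": 0.02, "split_rule": "symmetric"},
        "acquisition": {},
    },
    "trifurcation-converging": lambda s: {
        "phantom": {"kind": "trifurcation", "width_um": 300.0,
                    "angle_deg": 30.0, "converging": True,
                    "lengths_mm": list(s["lengths_tri"])},
        "flow": {"inlet_flow_rate_ml_min": 0.02, "split_rule": "symmetric"},
        "acquisition": {},
    },
}


def make_fixtures(scale: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Generate a standard fixture set at ``tiny`` or ``full`` scale.

    Tiny runs (64 x 64 px, 300 frames) complete in seconds and drive the
    test suite; full-scale runs produce 9000-frame velocity acquisitions
    and 3000-frame saturation analyses.
    """
    out_dir = Path(out_dir)
    recipes = ["bifurcation-45", "width-300-100"]
    written = []
    for i, name in enumerate(recipes):
        cfg = recipe_config(name, seed=seed + i, scale=scale)
        if scale == "full":
            cfg.analysis.n_saturation_frames = 3000
        run_experiment(cfg, out_dir / name)
        written.append(out_dir / name)
    return written
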