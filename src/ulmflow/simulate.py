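"""Synthetic microbubble flow sequences through a channel-network phantom.

The simulator stands in for the contrast experiments: microbubbles arrive at
the phantom inlet as a Poisson stream with rate ``concentration x flow``,
ride the laminar profile through the network, and are rendered into
post-beamformed envelope frames with a Gaussian point spread function.

Two acquisition modes are emulated at the image level (no RF physics):

* ``CPS`` — contrast pulse sequencing with pulse weights (0.5, -1, 0.5):
  any linear scatterer's contributions cancel exactly, so only the bubbles'
  nonlinear residual appears.
* ``BMODE`` — plane-wave brightness mode: bubbles and the static scatterer
  field both contribute.

Only the *detectable* fraction of the arriving bubbles is rendered and
tracked: a real sequence images a thin elevation slab and localizes only the
bubbles returning a strong, isolated nonlinear echo, so the stream of usable
point sources is far sparser than the nominal dose.  The thinning fraction
is a configuration parameter (Poisson thinning keeps the arrival statistics
Poisson).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import ChannelNetwork, FlowConfig, flow_split, profile_factor

__all__ = [
    "Bubble",
    "AcquisitionConfig",
    "FrameStack",
    "GroundTruth",
    "RadiationForce",
    "seed_bubbles",
    "advect",
    "make_scatterer_field",
    "render_frame",
    "generate_sequence",
]

#: CPS transmit weights; they sum to zero so linear echoes cancel identically.
CPS_WEIGHTS = (0.5, -1.0, 0.5)


@dataclass
class Bubble:
    """One microbubble travelling through the network.

    ``segment``/``s_mm`` give the axial position along a channel segment and
    ``lateral_offset`` the signed cross-channel position as a fraction of the
    half width (walls at +-1); the planar position follows from those.
    """

    id: int
    segment: str
    s_mm: float
    lateral_offset: float
    birth_frame: int = 0
    amplitude: float = 1.0
    stuck: bool = False

    def position(self, network: ChannelNetwork) -> np.ndarray:
        seg = network[self.segment]
        half_w = seg.width_um * 1e-3 / 2.0
        return (
            np.asarray(seg.start, float)
            + seg.direction * self.s_mm
            + seg.normal * (self.lateral_offset * half_w)
        )


@dataclass(frozen=True)
class RadiationForce:
    """Optional acoustic radiation-force effect.

    A constant drift in +z (away from the transducer) pushes bubbles toward
    the far wall, where each step they may stick and become static.  The
    magnitudes are illustrative — the effect is qualitative, not calibrated.
    """

    drift_mm_s: float = 0.05
    stick_probability: float = 0.02


@dataclass
class AcquisitionConfig:
    """Acquisition and rendering parameters for a synthetic sequence.

    Defaults mirror the ultrafast contrast protocol the simulator emulates:
    250 Hz framing in 1500-frame blocks, 25 um pixels on a 128 x 128 grid,
    a medium bubble dose of 6.4e6 MB/mL, and CPS imaging.
    """

    frame_rate_hz: float = 250.0
    n_frames: int = 1500
    block_size: int = 1500
    rows: int = 128
    cols: int = 128
    pixel_size_mm: float = 0.025
    psf_sigma_px: float = 1.5
    mode: str = "CPS"
    noise_sd: float = 0.02
    scatterer_density: float = 0.0
    concentration_per_ml: float = 6.4e6
    detectable_fraction: float = 0.01
    cps_residual: float = 1.0
    origin_x_mm: float = 0.0
    origin_z_mm: float | None = None
    rng_seed: int = 0
    radiation_force: RadiationForce | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.scatterer_density <= 1):
            raise ValueError("scatterer_density must be in [0, 1]")
        if not (0 < self.detectable_fraction <= 1):
            raise ValueError("detectable_fraction must be in (0, 1]")
        if self.mode not in ("CPS", "BMODE"):
            raise ValueError(f"mode must be CPS or BMODE, got {self.mode!r}")
        if self.origin_z_mm is None:
            # centre the depth axis on z = 0 (the main channel axis)
            self.origin_z_mm = -self.rows * self.pixel_size_mm / 2.0

    @property
    def origin_mm(self) -> tuple[float, float]:
        return (self.origin_x_mm, float(self.origin_z_mm))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.radiation_force is not None:
            d["radiation_force"] = dataclasses.asdict(self.radiation_force)
        return d


@dataclass
class FrameStack:
    """An image sequence: ``data`` is (frames, rows, cols) non-negative."""

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be (frames, rows, cols) with >= 1 frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def save(self, path: str | Path) -> None:
        """Write a multi-page 32-bit float TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        meta = {
            "frame_rate_hz": self.frame_rate_hz,
            "pixel_size_mm": self.pixel_size_mm,
            "origin_mm": list(self.origin_mm),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            frame_rate_hz=meta["frame_rate_hz"],
            pixel_size_mm=meta["pixel_size_mm"],
            origin_mm=tuple(meta.get("origin_mm", (0.0, 0.0))),
        )


@dataclass
class GroundTruth:
    """True bubble positions and tracks recorded during simulation.

    ``positions`` has one row per rendered bubble per frame with columns
    ``frame, track_id, x_mm, z_mm, speed_mm_s, segment, stuck``;
    ``channel_mask`` is the channel footprint on the original pixel grid.
    """

    positions: pd.DataFrame
    channel_mask: np.ndarray
    network: ChannelNetwork

    def save(self, path: str | Path) -> None:
        self.positions.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stochastic building blocks
# ---------------------------------------------------------------------------

#: Bubble centres keep at least ~a bubble radius off the wall; entry offsets
#: are truncated to this fraction of the half width.
MAX_ENTRY_OFFSET = 0.95


def _sample_flux_weighted_offsets(
    n: int, rng: np.random.Generator, u_max: float = MAX_ENTRY_OFFSET
) -> np.ndarray:
    """Lateral entry offsets with density proportional to the local velocity.

    Faster streamlines carry proportionally more bubbles, so the entry
    density across the width is the parabolic profile itself (rejection
    sampling against 1 - u^2).  Offsets are truncated to ``|u| <= u_max``:
    a bubble of finite size cannot have its centre on the wall.
    """
    out = np.empty(0)
    while out.size < n:
        u = rng.uniform(-u_max, u_max, size=max(2 * (n - out.size), 16))
        keep = rng.uniform(0.0, 1.0, size=u.size) < (1.0 - u**2)
        out = np.concatenate([out, u[keep]])
    return out[:n]


def seed_bubbles(
    concentration_per_ml: float,
    flow_rate_ml_min: float,
    dt_s: float,
    rng: np.random.Generator,
    inlet_segment: str = "main_in",
    birth_frame: int = 0,
    start_id: int = 0,
) -> list[Bubble]:
    """Poisson bubble arrivals at the inlet over an interval of ``dt_s``.

    The arrival rate is ``concentration x flow rate`` (per second); each
    arrival enters at the inlet start with a flux-weighted lateral offset.
    """
    if concentration_per_ml < 0 or flow_rate_ml_min < 0 or dt_s < 0:
        raise ValueError("concentration, flow rate and dt must be non-negative")
    lam = concentration_per_ml * flow_rate_ml_min / 60.0 * dt_s
    n = int(rng.poisson(lam)) if lam > 0 else 0
    if n == 0:
        return []
    offsets = _sample_flux_weighted_offsets(n, rng)
    return [
        Bubble(
            id=start_id + i,
            segment=inlet_segment,
            s_mm=0.0,
            lateral_offset=float(offsets[i]),
            birth_frame=birth_frame,
        )
        for i in range(n)
    ]


def advect(
    bubbles: list[Bubble],
    network: ChannelNetwork,
    dt_s: float,
    rng: np.random.Generator,
    radiation_force: RadiationForce | None = None,
) -> list[Bubble]:
    """Move bubbles along the laminar flow for one time step.

    Each bubble advances by its local profile velocity; on reaching a
    junction it enters a daughter segment with probability proportional to
    the daughter's flow, keeping its lateral offset.  Bubbles leaving an
    outlet are dropped.  With radiation force enabled, a constant +z drift
    pushes bubbles toward the far wall where they may stick permanently.
    """
    if not network.flow_assigned:
        raise ValueError("assign flow rates with flow_split() first")
    if dt_s < 0:
        raise ValueError("dt must be non-negative")
    survivors: list[Bubble] = []
    for b in bubbles:
        if b.stuck:
            survivors.append(b)
            continue
        seg = network[b.segment]
        u = b.lateral_offset
        if radiation_force is not None:
            # drift acts along +z; project onto the segment's lateral normal
            nz = float(seg.normal[1])
            half_w = seg.width_um * 1e-3 / 2.0
            u = float(np.clip(u + radiation_force.drift_mm_s * dt_s * nz / half_w, -1.0, 1.0))
            far_wall = np.sign(nz) if nz != 0 else 0.0
            if far_wall != 0 and u * far_wall >= 0.98:
                if rng.uniform() < radiation_force.stick_probability:
                    survivors.append(
                        dataclasses.replace(b, lateral_offset=u, stuck=True)
                    )
                    continue
        speed = seg.mean_velocity_mm_s * float(profile_factor(u))
        s = b.s_mm + speed * dt_s
        seg_id = b.segment
        alive = True
        while s > network[seg_id].length_mm:
            daughters = network.daughters(seg_id)
            if not daughters:
                alive = False  # exited an outlet
                break
            flows = np.array([d.flow_rate_ml_min for d in daughters])
            if flows.sum() <= 0:
                alive = False
                break
            probs = flows / flows.sum()
            choice = int(rng.choice(len(daughters), p=probs))
            s -= network[seg_id].length_mm
            seg_id = daughters[choice].id
        if alive:
            survivors.append(
                dataclasses.replace(b, segment=seg_id, s_mm=s, lateral_offset=u)
            )
    return survivors


def make_scatterer_field(
    density: float,
    rows: int,
    cols: int,
    rng: np.random.Generator,
    channel_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Static linear point scatterers outside the channel footprint.

    Each pixel independently hosts a scatterer with probability ``density``
    (so the count is Binomial(rows*cols, density)); positions are uniform
    within their pixel and amplitudes uniform in [0.5, 1.5].  Returns
    ``(positions_px (n, 2) as (row, col), amplitudes (n,))``.
    """
    if not (0 <= density <= 1):
        raise ValueError("density must be in [0, 1]")
    n = int(rng.binomial(rows * cols, density))
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    pos = np.stack(
        [rng.uniform(0, rows, size=n), rng.uniform(0, cols, size=n)], axis=1
    )
    amp = rng.uniform(0.5, 1.5, size=n)
    if channel_mask is not None:
        r = np.clip(pos[:, 0].astype(int), 0, rows - 1)
        c = np.clip(pos[:, 1].astype(int), 0, cols - 1)
        keep = ~channel_mask[r, c]
        pos, amp = pos[keep], amp[keep]
    return pos, amp


def _splat_gaussians(
    frame: np.ndarray, pos_px: np.ndarray, amps: np.ndarray, sigma: float
) -> None:
    """Add Gaussian point spread functions at subpixel (row, col) positions."""
    rows, cols = frame.shape
    radius = int(np.ceil(4 * sigma))
    for (r, c), a in zip(pos_px, amps):
        if a == 0.0:
            continue
        r0, r1 = int(np.floor(r)) - radius, int(np.floor(r)) + radius + 1
        c0, c1 = int(np.floor(c)) - radius, int(np.floor(c)) + radius + 1
        r0c, r1c = max(r0, 0), min(r1, rows)
        c0c, c1c = max(c0, 0), min(c1, cols)
        if r0c >= r1c or c0c >= c1c:
            continue
        rr = np.arange(r0c, r1c)
        cc = np.arange(c0c, c1c)
        gr = np.exp(-((rr - r) ** 2) / (2 * sigma**2))
        gc = np.exp(-((cc - c) ** 2) / (2 * sigma**2))
        frame[r0c:r1c, c0c:c1c] += a * np.outer(gr, gc)


def _mm_to_px(pos_mm: np.ndarray, config: AcquisitionConfig) -> np.ndarray:
    """(x, z) mm -> (row, col) pixel coordinates (pixel centres at i + 0.5)."""
    x0, z0 = config.origin_mm
    px = config.pixel_size_mm
    out = np.empty_like(pos_mm)
    out[:, 0] = (pos_mm[:, 1] - z0) / px - 0.5
    out[:, 1] = (pos_mm[:, 0] - x0) / px - 0.5
    return out


def render_frame(
    bubble_positions_mm: np.ndarray,
    bubble_amplitudes: np.ndarray | None,
    scatterers: tuple[np.ndarray, np.ndarray] | None,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one envelope frame from bubbles and static scatterers.

    In CPS mode the pulse weights (0.5, -1, 0.5) are applied to the linear
    scatterer response, which therefore cancels to exactly zero; bubbles
    contribute their nonlinear residual scaled by ``cps_residual``.  In
    B-mode both populations contribute linearly.  Additive Gaussian noise of
    sd ``noise_sd`` is applied last and the frame clipped at zero.
    """
    frame = np.zeros((config.rows, config.cols), float)
    pos = np.asarray(bubble_positions_mm, float).reshape(-1, 2)
    if pos.shape[0]:
        amps = (
            np.ones(pos.shape[0])
            if bubble_amplitudes is None
            else np.asarray(bubble_amplitudes, float)
        )
        if config.mode == "CPS":
            amps = amps * config.cps_residual
        _splat_gaussians(frame, _mm_to_px(pos, config), amps, config.psf_sigma_px)
    if scatterers is not None and scatterers[0].shape[0]:
        s_pos, s_amp = scatterers
        linear_weight = sum(CPS_WEIGHTS) if config.mode == "CPS" else 1.0
        weighted = s_amp * linear_weight
        _splat_gaussians(frame, np.asarray(s_pos, float), weighted, config.psf_sigma_px)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        frame += rng.normal(0.0, config.noise_sd, size=frame.shape)
    return np.clip(frame, 0.0, None)


def generate_sequence(
    network: ChannelNetwork,
    flow_config: FlowConfig,
    acq: AcquisitionConfig,
) -> tuple[FrameStack, GroundTruth]:
    """Simulate a full acquisition: seed, advect and render every frame.

    Arrivals are thinned to the detectable fraction before simulation
    (thinning a Poisson stream keeps it Poisson), so the rendered bubbles
    are exactly the trackable point sources.  Fully reproducible from
    ``acq.rng_seed``.
    """
    if not network.flow_assigned:
        network = flow_split(network, flow_config)
    rng = np.random.default_rng(acq.rng_seed)
    dt = 1.0 / acq.frame_rate_hz
    mask = network.channel_mask(acq.rows, acq.cols, acq.pixel_size_mm, acq.origin_mm)
    scatterers = make_scatterer_field(
        acq.scatterer_density, acq.rows, acq.cols, rng, channel_mask=mask
    )
    eff_concentration = acq.concentration_per_ml * acq.detectable_fraction
    frames = np.empty((acq.n_frames, acq.rows, acq.cols), np.float32)
    bubbles: list[Bubble] = []
    next_id = 0
    records: list[tuple] = []
    for t in range(acq.n_frames):
        new = seed_bubbles(
            eff_concentration,
            flow_config.inlet_flow_rate_ml_min,
            dt,
            rng,
            inlet_segment=network.inlet,
            birth_frame=t,
            start_id=next_id,
        )
        next_id += len(new)
        bubbles = advect(bubbles, network, dt, rng, acq.radiation_force) + new
        if bubbles:
            pos = np.stack([b.position(network) for b in bubbles])
            amps = np.array([b.amplitude for b in bubbles])
        else:
            pos = np.empty((0, 2))
            amps = np.empty(0)
        frames[t] = render_frame(pos, amps, scatterers, acq, rng)
        for b, p in zip(bubbles, pos):
            seg = network[b.segment]
            speed = (
                0.0
                if b.stuck
                else seg.mean_velocity_mm_s * float(profile_factor(b.lateral_offset))
            )
            records.append((t, b.id, p[0], p[1], speed, b.segment, b.stuck))
    positions = pd.DataFrame(
        records,
        columns=["frame", "track_id", "x_mm", "z_mm", "speed_mm_s", "segment", "stuck"],
    )
    stack = FrameStack(
        data=frames,
        frame_rate_hz=acq.frame_rate_hz,
        pixel_size_mm=acq.pixel_size_mm,
        origin_mm=acq.origin_mm,
    )
    return stack, GroundTruth(positions=positions, channel_mask=mask, network=network)
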