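"""Planar channel-network phantoms and their steady laminar flow model.

A phantom is a graph of straight rectangular channels lying in a single
plane (the imaging plane).  Cross sections are ``width x height`` rectangles;
all widths and heights are given in micrometres while segment endpoints are
in millimetres with ``x`` the lateral axis and ``z`` depth (increasing away
from the transducer).  The flow model is the one-dimensional conservation of
mass: given the inlet volumetric rate ``Q`` (mL/min) the mean velocity in a
segment of cross-section area ``A`` is ``V = Q / A``, and at every junction
the volumetric rates of the daughters sum to the parent rate.

Across the imaged width each channel carries a plane-Poiseuille (parabolic)
profile with no-slip walls and a centreline peak of 1.5x the mean velocity;
the non-imaged height dimension is absorbed into the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelSegment",
    "ChannelNetwork",
    "FlowConfig",
    "InvalidGeometryError",
    "build_single_channel",
    "build_bifurcation",
    "build_trifurcation",
    "cross_section_area",
    "expected_velocity",
    "flow_split",
    "local_velocity",
    "PROFILE_PEAK_FACTOR",
    "FLUX_WEIGHTED_FACTOR",
]

#: Centreline / mean velocity ratio of the plane-Poiseuille profile.
PROFILE_PEAK_FACTOR = 1.5

#: Mean speed of flux-weighted (bubble-carrying) streamlines relative to the
#: sectional mean: E[v^2]/E[v] with v(u) = 1.5*(1-u^2) equals 1.2.
FLUX_WEIGHTED_FACTOR = 1.2

_NODE_TOL_MM = 1e-9


class InvalidGeometryError(ValueError):
    """Raised for degenerate or non-physical channel geometry."""


def cross_section_area(width_um: float, height_um: float) -> float:
    """Rectangular cross-section area in m^2 for a width x height channel (um)."""
    if width_um <= 0 or height_um <= 0:
        raise InvalidGeometryError(
            f"channel cross section must be positive, got {width_um} x {height_um} um"
        )
    return width_um * height_um * 1e-12


def expected_velocity(flow_rate_ml_min: float, area_m2: float) -> float:
    """Mean velocity ``Q/A`` in mm/s.

    Parameters
    ----------
    flow_rate_ml_min
        Volumetric flow rate in mL/min (1 mL/min = 1/60 * 1e-6 m^3/s).
    area_m2
        Cross-section area in m^2.
    """
    if area_m2 <= 0:
        raise InvalidGeometryError(f"cross-section area must be positive, got {area_m2}")
    if flow_rate_ml_min < 0:
        raise ValueError(f"flow rate must be non-negative, got {flow_rate_ml_min}")
    q_m3_s = flow_rate_ml_min * 1e-6 / 60.0
    return q_m3_s / area_m2 * 1e3


@dataclass(frozen=True)
class ChannelSegment:
    """A straight channel segment in the imaging plane.

    ``start``/``end`` are (x, z) in mm; ``width_um``/``height_um`` the
    rectangular cross section; ``flow_rate_ml_min`` is NaN until assigned by
    :func:`flow_split`.
    """

    id: str
    start: tuple[float, float]
    end: tuple[float, float]
    width_um: float
    height_um: float = 300.0
    flow_rate_ml_min: float = float("nan")

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise InvalidGeometryError(
                f"segment {self.id!r}: non-positive cross section "
                f"{self.width_um} x {self.height_um} um"
            )
        if self.length_mm <= _NODE_TOL_MM:
            raise InvalidGeometryError(f"segment {self.id!r}: start and end coincide")
        if not math.isnan(self.flow_rate_ml_min) and self.flow_rate_ml_min < 0:
            raise InvalidGeometryError(f"segment {self.id!r}: negative flow rate")

    @property
    def length_mm(self) -> float:
        dx = self.end[0] - self.start[0]
        dz = self.end[1] - self.start[1]
        return math.hypot(dx, dz)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from start to end."""
        d = np.asarray(self.end, float) - np.asarray(self.start, float)
        return d / np.linalg.norm(d)

    @property
    def normal(self) -> np.ndarray:
        """Unit lateral normal (direction rotated +90 deg: (dz, -dx) -> here (-dz, dx))."""
        dx, dz = self.direction
        return np.array([-dz, dx])

    @property
    def area_m2(self) -> float:
        return cross_section_area(self.width_um, self.height_um)

    @property
    def mean_velocity_mm_s(self) -> float:
        """Sectional mean velocity Q/A (mm/s); NaN until flow is assigned."""
        if math.isnan(self.flow_rate_ml_min):
            return float("nan")
        return expected_velocity(self.flow_rate_ml_min, self.area_m2)

    def hydraulic_resistance(self) -> float:
        """Relative viscous resistance of a rectangular slit, R ~ L / (w^3 h)."""
        return self.length_mm / (self.width_um**3 * self.height_um)


@dataclass(frozen=True)
class FlowConfig:
    """Inlet flow rate (mL/min) and the rule for dividing flow at junctions.

    ``split_rule`` is ``"symmetric"`` (equal division among daughters; the
    conservation-of-mass symmetry argument for equal cross sections) or
    ``"resistance"`` (division inversely proportional to the slit resistance
    ``L/(w^3 h)`` of each daughter).
    """

    inlet_flow_rate_ml_min: float = 0.02
    split_rule: str = "symmetric"

    def __post_init__(self) -> None:
        if self.inlet_flow_rate_ml_min < 0:
            raise ValueError("inlet flow rate must be non-negative")
        if self.split_rule not in ("symmetric", "resistance"):
            raise ValueError(f"unknown split rule {self.split_rule!r}")


@dataclass
class ChannelNetwork:
    """A connected planar network of :class:`ChannelSegment` objects.

    Connectivity is inferred from coincident endpoints: a junction is any
    point where one or more segment ends meet one or more segment starts.
    Exactly one segment must begin at a free node (the inlet); segments whose
    end is a free node are outlets.
    """

    segments: list[ChannelSegment]
    name: str = "network"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise InvalidGeometryError("duplicate segment ids")
        self._index = {s.id: s for s in self.segments}
        if len(self.inlet_candidates()) != 1:
            raise InvalidGeometryError(
                f"network must have exactly one inlet, found {self.inlet_candidates()}"
            )
        if not self.outlets:
            raise InvalidGeometryError("network has no outlet")

    # -- connectivity ------------------------------------------------------
    def __getitem__(self, seg_id: str) -> ChannelSegment:
        return self._index[seg_id]

    def _same_node(self, a: tuple[float, float], b: tuple[float, float]) -> bool:
        return math.hypot(a[0] - b[0], a[1] - b[1]) <= 1e-6

    def daughters(self, seg_id: str) -> list[ChannelSegment]:
        end = self[seg_id].end
        return [s for s in self.segments if self._same_node(s.start, end)]

    def parents(self, seg_id: str) -> list[ChannelSegment]:
        start = self[seg_id].start
        return [s for s in self.segments if self._same_node(s.end, start)]

    def inlet_candidates(self) -> list[str]:
        return [s.id for s in self.segments if not self.parents(s.id)]

    @property
    def inlet(self) -> str:
        return self.inlet_candidates()[0]

    @property
    def outlets(self) -> list[str]:
        return [s.id for s in self.segments if not self.daughters(s.id)]

    @property
    def flow_assigned(self) -> bool:
        return all(not math.isnan(s.flow_rate_ml_min) for s in self.segments)

    # -- geometry queries --------------------------------------------------
    def locate(self, point) -> tuple[str, float, float] | None:
        """Return ``(segment id, axial position mm, lateral offset fraction)``
        of the segment footprint containing *point*, or None.

        The lateral offset is signed, in units of the half width, so the
        walls sit at +-1.  When footprints overlap (near junctions) the
        segment whose axis is nearest wins.
        """
        p = np.asarray(point, float)
        best = None
        best_lat = np.inf
        for s in self.segments:
            a = np.asarray(s.start, float)
            d = s.direction
            t = float(np.dot(p - a, d))
            if t < -_NODE_TOL_MM or t > s.length_mm + _NODE_TOL_MM:
                continue
            lat = float(np.dot(p - a, s.normal))
            half_w = s.width_um * 1e-3 / 2.0
            if abs(lat) > half_w + _NODE_TOL_MM:
                continue
            if abs(lat) / half_w < best_lat:
                best_lat = abs(lat) / half_w
                best = (s.id, min(max(t, 0.0), s.length_mm), lat / half_w)
        return best

    def channel_mask(self, rows: int, cols: int, pixel_size_mm: float,
                     origin_mm: tuple[float, float]) -> np.ndarray:
        """Boolean pixel mask of the channel footprint.

        Pixel ``(r, c)`` has its centre at
        ``(origin_x + (c + 0.5) px, origin_z + (r + 0.5) px)``.
        """
        x0, z0 = origin_mm
        cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
        x = x0 + (cc + 0.5) * pixel_size_mm
        z = z0 + (rr + 0.5) * pixel_size_mm
        mask = np.zeros((rows, cols), bool)
        pts = np.stack([x.ravel(), z.ravel()], axis=1)
        for s in self.segments:
            a = np.asarray(s.start, float)
            d = s.direction
            rel = pts - a
            t = rel @ d
            lat = rel @ s.normal
            half_w = s.width_um * 1e-3 / 2.0
            inside = (t >= 0) & (t <= s.length_mm) & (np.abs(lat) <= half_w)
            mask |= inside.reshape(rows, cols)
        return mask

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segments": [
                {
                    "id": s.id,
                    "start": list(s.start),
                    "end": list(s.end),
                    "width_um": s.width_um,
                    "height_um": s.height_um,
                    **(
                        {"flow_rate_ml_min": s.flow_rate_ml_min}
                        if not math.isnan(s.flow_rate_ml_min)
                        else {}
                    ),
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelNetwork":
        segs = [
            ChannelSegment(
                id=s["id"],
                start=tuple(s["start"]),
                end=tuple(s["end"]),
                width_um=s["width_um"],
                height_um=s.get("height_um", 300.0),
                flow_rate_ml_min=s.get("flow_rate_ml_min", float("nan")),
            )
            for s in d["segments"]
        ]
        return cls(segments=segs, name=d.get("name", "network"))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _check_width(width_um: float, what: str) -> None:
    if not (0 < width_um <= 1000):
        raise InvalidGeometryError(f"{what} width must be in (0, 1000] um, got {width_um}")


def build_single_channel(width_um: float, length_mm: float = 3.0,
                         height_um: float = 300.0) -> ChannelNetwork:
    """A single straight channel along +x starting at the origin."""
    _check_width(width_um, "channel")
    if length_mm <= 0:
        raise InvalidGeometryError("length must be positive")
    seg = ChannelSegment("main", (0.0, 0.0), (length_mm, 0.0), width_um, height_um)
    return ChannelNetwork([seg], name=f"single-{width_um:.0f}um")


def build_bifurcation(
    main_width_um: float,
    branch_width_um: float,
    angle_deg: float,
    lengths_mm: tuple[float, float, float] = (1.2, 1.8, 1.8),
    height_um: float = 300.0,
) -> ChannelNetwork:
    """Main channel with a branch splitting off at ``angle_deg``.

    The main channel runs along +x from the origin; at the junction it
    continues straight (same width) while the branch leaves towards +z at the
    given angle.  ``lengths_mm`` are (inlet, main continuation, branch).
    """
    _check_width(main_width_um, "main")
    _check_width(branch_width_um, "branch")
    if not (0 < angle_deg < 90):
        raise InvalidGeometryError(f"bifurcation angle must be in (0, 90) deg, got {angle_deg}")
    l0, l1, l2 = lengths_mm
    if min(l0, l1, l2) <= 0:
        raise InvalidGeometryError(f"segment lengths must be positive, got {lengths_mm}")
    theta = math.radians(angle_deg)
    jx = l0
    segs = [
        ChannelSegment("main_in", (0.0, 0.0), (jx, 0.0), main_width_um, height_um),
        ChannelSegment("main_out", (jx, 0.0), (jx + l1, 0.0), main_width_um, height_um),
        ChannelSegment(
            "branch",
            (jx, 0.0),
            (jx + l2 * math.cos(theta), l2 * math.sin(theta)),
            branch_width_um,
            height_um,
        ),
    ]
    return ChannelNetwork(
        segs, name=f"bifurcation-{main_width_um:.0f}/{branch_width_um:.0f}um-{angle_deg:g}deg"
    )


def build_trifurcation(
    width_um: float,
    angle_deg: float = 30.0,
    converging: bool = False,
    lengths_mm: tuple[float, float] = (1.0, 1.8),
    height_um: float = 300.0,
) -> ChannelNetwork:
    """Main channel splitting into three equal-width branches at ``+-angle``/0.

    With ``converging=True`` the side branches fold back after half their
    length and all three rejoin into a single outlet channel, mimicking a
    classical microfluidic chip; otherwise each branch runs to its own
    outlet.  ``lengths_mm`` are (inlet length, branch path length).
    """
    _check_width(width_um, "channel")
    if not (0 < angle_deg < 90):
        raise InvalidGeometryError(f"trifurcation angle must be in (0, 90) deg, got {angle_deg}")
    l0, lb = lengths_mm
    if min(l0, lb) <= 0:
        raise InvalidGeometryError(f"segment lengths must be positive, got {lengths_mm}")
    theta = math.radians(angle_deg)
    jx = l0
    segs = [ChannelSegment("main_in", (0.0, 0.0), (jx, 0.0), width_um, height_um)]
    if not converging:
        for label, sign in (("branch_up", -1.0), ("branch_mid", 0.0), ("branch_dn", 1.0)):
            ang = sign * theta
            end = (jx + lb * math.cos(ang), lb * math.sin(ang))
            segs.append(ChannelSegment(label, (jx, 0.0), end, width_um, height_um))
        name = f"trifurcation-{width_um:.0f}um-{angle_deg:g}deg"
    else:
        half = lb / 2.0
        mx = jx + 2 * half * math.cos(theta)  # merge node x
        for label, sign in (("up", -1.0), ("dn", 1.0)):
            apex = (jx + half * math.cos(theta), sign * half * math.sin(theta))
            segs.append(ChannelSegment(f"branch_{label}_1", (jx, 0.0), apex, width_um, height_um))
            segs.append(ChannelSegment(f"branch_{label}_2", apex, (mx, 0.0), width_um, height_um))
        segs.append(
            ChannelSegment("branch_mid", (jx, 0.0), (mx, 0.0), width_um, height_um)
        )
        segs.append(
            ChannelSegment("main_out", (mx, 0.0), (mx + l0, 0.0), width_um, height_um)
        )
        name = f"trifurcation-converging-{width_um:.0f}um-{angle_deg:g}deg"
    return ChannelNetwork(segs, name=name)


# ---------------------------------------------------------------------------
# Flow assignment and the velocity field
# ---------------------------------------------------------------------------

def flow_split(network: ChannelNetwork, config: FlowConfig) -> ChannelNetwork:
    """Assign a volumetric flow rate to every segment by conservation of mass.

    Flow enters at the inlet segment and divides at each junction according
    to ``config.split_rule``; at merging junctions the daughter receives the
    sum of its parents.  Returns a new network; the input is untouched.
    """
    flows: dict[str, float] = {network.inlet: config.inlet_flow_rate_ml_min}
    # Process junctions in topological order (acyclic by construction); a
    # junction is identified by its daughter set and resolved exactly once,
    # after every parent flow is known.
    pending = [network.inlet]
    done_junctions: set[frozenset[str]] = set()
    while pending:
        seg_id = pending.pop(0)
        daughters = network.daughters(seg_id)
        if not daughters:
            continue
        key = frozenset(d.id for d in daughters)
        if key in done_junctions:
            continue
        junction_parents = network.parents(daughters[0].id)
        if any(p.id not in flows for p in junction_parents):
            pending.append(seg_id)
            continue
        done_junctions.add(key)
        q_in = sum(flows[p.id] for p in junction_parents)
        if len(daughters) == 1:
            shares = [1.0]
        elif config.split_rule == "symmetric":
            shares = [1.0 / len(daughters)] * len(daughters)
        else:
            conduct = np.array([1.0 / d.hydraulic_resistance() for d in daughters])
            shares = conduct / conduct.sum()
        for d, share in zip(daughters, shares):
            flows[d.id] = q_in * share
            pending.append(d.id)
    missing = [s.id for s in network.segments if s.id not in flows]
    if missing:
        raise InvalidGeometryError(f"segments unreachable from inlet: {missing}")
    segs = [replace(s, flow_rate_ml_min=flows[s.id]) for s in network.segments]
    return ChannelNetwork(segs, name=network.name)


def profile_factor(lateral_offset: float | np.ndarray) -> np.ndarray:
    """Plane-Poiseuille velocity factor ``1.5 (1 - u^2)`` at offset u in [-1, 1]."""
    u = np.asarray(lateral_offset, float)
    return PROFILE_PEAK_FACTOR * (1.0 - u**2)


def local_velocity(network: ChannelNetwork, point) -> np.ndarray | None:
    """Velocity vector (mm/s) of the laminar flow at a planar point, or None.

    Inside a segment the magnitude is the sectional mean velocity scaled by
    the parabolic profile at the point's lateral offset; the direction is
    the segment axis.  Outside every channel footprint returns None.
    """
    if not network.flow_assigned:
        raise ValueError("assign flow rates with flow_split() first")
    hit = network.locate(point)
    if hit is None:
        return None
    seg_id, _, u = hit
    seg = network[seg_id]
    speed = seg.mean_velocity_mm_s * float(profile_factor(u))
    return seg.direction * speed
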