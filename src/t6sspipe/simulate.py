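"""Synthetic fluorescence-microscopy fields of rod-shaped bacteria.

The generator produces seeded fields of spherocylindrical cells carrying
diffuse cytoplasmic signal, membrane signal and/or diffraction-limited foci,
renders them through a Gaussian-PSF + EMCCD forward model, and reports full
ground truth (cell geometries, true focus positions, time-lapse event log).

Channel archetypes mirror the fluorescence patterns of T6SS reporter
fusions: sheath-like channels form bright cytoplasmic foci over diffuse
background in a minority of cells; an unfoldase-like partner forms rarer foci
that preferentially co-localize with sheath foci; a membrane-complex-like
channel forms many foci of which only a subset is occupied by a sheath
focus; membrane channels show peripheral, patchy fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .containers import FieldTooCrowdedError, ImageStack

def _normalized(p: tuple[float, ...]) -> tuple[float, ...]:
    s = sum(p)
    return tuple(v / s for v in p)


# Per-cell focus-count distribution of the sheath channel: fractions of cells
# with 0, 1, 2 and 3 foci in a snapshot of the whole population (renormalized).
TSSB_POPULATION_PMF = _normalized((0.690, 0.277, 0.030, 0.002))
# Same distribution restricted to isolated single cells.
TSSB_ISOLATED_PMF = _normalized((0.54, 0.39, 0.07))

#: Distance below which two foci are unresolvable for the reference optics (um).
COLOC_THRESHOLD_UM = 0.272


def pmf_mean(pmf: Sequence[float]) -> float:
    p = np.asarray(pmf, dtype=float)
    p = p / p.sum()
    return float(np.sum(np.arange(len(p)) * p))


# ---------------------------------------------------------------------------
# configuration models
# ---------------------------------------------------------------------------


class FieldConfig(BaseModel):
    """Geometry of one simulated field of view."""

    model_config = ConfigDict(extra="forbid")

    n_cells: int = Field(80, ge=0)
    width_um: float = Field(40.96, gt=0)
    height_um: float = Field(40.96, gt=0)
    layout: Literal["isolated", "microcolony"] = "isolated"
    min_separation_um: float = Field(1.0, ge=0)
    overlap_tol_um: float = Field(0.2, ge=0)
    cell_length_um: tuple[float, float] = (2.0, 3.5)
    cell_width_um: float = Field(0.8, gt=0)
    margin_um: float = Field(0.6, ge=0)
    z_mid_um: float = Field(1.2, ge=0)
    max_retries: int = Field(5000, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "FieldConfig":
        lo, hi = self.cell_length_um
        if not (0 < lo <= hi):
            raise ValueError("cell_length_um must be an increasing positive range")
        if lo < self.cell_width_um:
            raise ValueError("cell length must be >= cell width (spherocylinder)")
        return self


class ChannelModel(BaseModel):
    """Fluorescence model for one channel.

    Focus counts per cell are i.i.d. draws from ``focus_count_pmf`` when
    given, else Poisson with ``focus_count_mean``. With a ``coloc_partner``:

    * each independently drawn focus is placed within ``coloc_radius_um`` of a
      randomly chosen partner focus of the same cell with probability
      ``p_coloc`` (uniform in the cell otherwise);
    * additionally, every partner focus in the cell receives one co-localized
      focus with probability ``p_partner_coloc``.

    Intensities are photon counts before gain: ``diffuse_intensity`` per voxel
    inside the cell body (or membrane shell), ``focus_intensity`` integrated
    over a focus.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    mode: Literal[
        "cytoplasmic_foci", "foci_only", "membrane_patchy", "membrane_foci"
    ] = "cytoplasmic_foci"
    focus_count_pmf: Optional[tuple[float, ...]] = None
    focus_count_mean: Optional[float] = Field(None, ge=0)
    diffuse_intensity: float = Field(50.0, ge=0)
    focus_intensity: float = Field(6000.0, ge=0)
    coloc_partner: Optional[str] = None
    p_coloc: float = Field(0.0, ge=0, le=1)
    p_partner_coloc: float = Field(0.0, ge=0, le=1)
    coloc_radius_um: float = Field(0.1, gt=0)
    # Printed per-cell focus counts are counts of resolved puncta, and the
    # resolution limit of the reference optics is 0.272 um: the generator
    # therefore keeps same-channel foci of one cell at least this far apart
    # (uniform placement conditional on resolvability; 0 disables).
    min_focus_separation_um: float = Field(COLOC_THRESHOLD_UM, ge=0)
    membrane_thickness_um: float = Field(0.15, gt=0)
    membrane_patchiness: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ChannelModel":
        if self.focus_count_pmf is not None:
            p = np.asarray(self.focus_count_pmf, dtype=float)
            if p.ndim != 1 or len(p) == 0 or np.any(p < 0):
                raise ValueError("focus_count_pmf must be a non-negative vector")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("focus_count_pmf must sum to 1 (+/- 1e-9)")
            if self.focus_count_mean is not None:
                raise ValueError("give focus_count_pmf or focus_count_mean, not both")
        if (self.p_coloc > 0 or self.p_partner_coloc > 0) and not self.coloc_partner:
            raise ValueError("co-localization probabilities require coloc_partner")
        return self

    def draw_count(self, rng: np.random.Generator) -> int:
        if self.focus_count_pmf is not None:
            p = np.asarray(self.focus_count_pmf, dtype=float)
            return int(rng.choice(len(p), p=p / p.sum()))
        if self.focus_count_mean is not None:
            return int(rng.poisson(self.focus_count_mean))
        return 0


class OpticsModel(BaseModel):
    """Wide-field acquisition model: sampling, Gaussian PSF and EMCCD noise."""

    model_config = ConfigDict(extra="forbid")

    pixel_size_um: float = Field(0.08, gt=0)
    z_spacing_um: float = Field(0.2, gt=0)
    n_z: int = Field(13, ge=1)
    psf_sigma_xy_um: float = Field(0.11, gt=0)
    psf_sigma_z_um: float = Field(0.30, gt=0)
    emccd_gain: float = Field(30.0, gt=0)
    read_noise_sd: float = Field(6.0, ge=0)
    offset: float = Field(100.0, ge=0)


class KineticsConfig(BaseModel):
    """Focus assembly / persistence / disassembly kinetics for time-lapse mode.

    Defaults follow sheath-cycle timescales reported for contractile T6SS
    machines: ~30 s assembly, minutes-scale persistence, 30-60 s disassembly.
    The per-cell event rate is chosen so the steady-state expected number of
    visible foci per cell matches ``target_mean_foci`` (rate = mean / mean
    event duration) unless an explicit rate is given.
    """

    model_config = ConfigDict(extra="forbid")

    t_assemble_s: float = Field(30.0, gt=0)
    persistence_mean_s: float = Field(60.0, gt=0)
    persistence: Literal["exponential", "fixed"] = "exponential"
    t_disassemble_s: float = Field(45.0, gt=0)
    event_rate_per_cell_per_s: Optional[float] = Field(None, ge=0)
    target_mean_foci: float = Field(pmf_mean(TSSB_POPULATION_PMF), ge=0)

    def mean_event_duration_s(self) -> float:
        return self.t_assemble_s + self.persistence_mean_s + self.t_disassemble_s

    def rate(self) -> float:
        if self.event_rate_per_cell_per_s is not None:
            return self.event_rate_per_cell_per_s
        return self.target_mean_foci / self.mean_event_duration_s()


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """A 2D spherocylinder (pole-to-pole ``length``, ``width`` = diameter)."""

    id: int
    center: tuple[float, float]  # um
    length: float  # um, pole to pole
    width: float  # um
    orientation: float  # radians

    @property
    def half_axis(self) -> float:
        """Half-length of the central axis segment."""
        return (self.length - self.width) / 2.0

    def axis_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        u = np.array([math.cos(self.orientation), math.sin(self.orientation)])
        c = np.asarray(self.center, dtype=float)
        return c - self.half_axis * u, c + self.half_axis * u

    def contains(self, x: float, y: float, dz: float = 0.0) -> bool:
        """Whether the 3D point (x, y, z_mid + dz) lies inside the cell body."""
        a, b = self.axis_endpoints()
        d2 = _point_segment_dist2(np.array([[x, y]]), a, b)[0]
        r = self.width / 2.0
        return d2 + dz * dz <= r * r + 1e-12


@dataclass
class TrueFocus:
    focus_id: int
    channel: str
    cell_id: Optional[int]
    x: float  # um
    y: float  # um
    z: float  # um (absolute stack coordinate)
    intensity_scale: float = 1.0
    partner_focus_id: Optional[int] = None  # focus this one was placed next to


@dataclass
class FocusEvent:
    focus_id: int
    cell_id: Optional[int]
    t_appear: float
    t_disappear: float


@dataclass
class FieldGroundTruth:
    field: FieldConfig
    cells: list[CellGeometry]
    foci: dict[str, list[TrueFocus]]
    events: list[FocusEvent] = dc_field(default_factory=list)

    def counts_per_cell(self, channel: str) -> dict[int, int]:
        counts = {c.id: 0 for c in self.cells}
        for f in self.foci.get(channel, []):
            if f.cell_id is not None:
                counts[f.cell_id] += 1
        return counts


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _point_segment_dist2(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared distances from points p (N, 2) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        d = p - a
        return np.einsum("ij,ij->i", d, d)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = p - proj
    return np.einsum("ij,ij->i", d, d)


def _segments_cross(a0, a1, b0, b1) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1 = orient(b0, b1, a0)
    d2 = orient(b0, b1, a1)
    d3 = orient(a0, a1, b0)
    d4 = orient(a0, a1, b1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _segment_segment_dist(a0, a1, b0, b1) -> float:
    if _segments_cross(a0, a1, b0, b1):
        return 0.0
    d2 = min(
        _point_segment_dist2(np.array([a0]), b0, b1)[0],
        _point_segment_dist2(np.array([a1]), b0, b1)[0],
        _point_segment_dist2(np.array([b0]), a0, a1)[0],
        _point_segment_dist2(np.array([b1]), a0, a1)[0],
    )
    return math.sqrt(d2)


def boundary_distance(c1: CellGeometry, c2: CellGeometry) -> float:
    """Gap between two capsule boundaries (negative when they overlap)."""
    a0, a1 = c1.axis_endpoints()
    b0, b1 = c2.axis_endpoints()
    return _segment_segment_dist(a0, a1, b0, b1) - (c1.width + c2.width) / 2.0


# ---------------------------------------------------------------------------
# field sampling
# ---------------------------------------------------------------------------


def _propose_cell(cfg: FieldConfig, cell_id: int, rng: np.random.Generator,
                  anchor: CellGeometry | None = None) -> CellGeometry:
    length = rng.uniform(*cfg.cell_length_um)
    if anchor is None:
        lo = cfg.margin_um + length / 2.0
        cx = rng.uniform(lo, cfg.width_um - lo)
        cy = rng.uniform(lo, cfg.height_um - lo)
        theta = rng.uniform(0, math.pi)
    else:
        # side-by-side or pole-to-pole neighbour with similar orientation
        theta = anchor.orientation + rng.normal(0, 0.25)
        gap = rng.uniform(0.0, 0.15)
        if rng.random() < 0.7:  # lateral neighbour
            off = (anchor.width + cfg.cell_width_um) / 2.0 + gap
            direction = anchor.orientation + math.pi / 2.0
            slide = rng.uniform(-anchor.half_axis, anchor.half_axis)
            cx = anchor.center[0] + off * math.cos(direction) + slide * math.cos(anchor.orientation)
            cy = anchor.center[1] + off * math.sin(direction) + slide * math.sin(anchor.orientation)
        else:  # pole neighbour
            off = (anchor.length + length) / 2.0 + gap
            sign = 1.0 if rng.random() < 0.5 else -1.0
            cx = anchor.center[0] + sign * off * math.cos(anchor.orientation)
            cy = anchor.center[1] + sign * off * math.sin(anchor.orientation)
    return CellGeometry(cell_id, (float(cx), float(cy)), float(length),
                        cfg.cell_width_um, float(theta) % math.pi)


def _inside_field(cell: CellGeometry, cfg: FieldConfig) -> bool:
    a, b = cell.axis_endpoints()
    r = cell.width / 2.0 + cfg.margin_um
    for p in (a, b):
        if not (r <= p[0] <= cfg.width_um - r and r <= p[1] <= cfg.height_um - r):
            return False
    return True


def _gaps_to_placed(cand: CellGeometry, a0: np.ndarray, a1: np.ndarray,
                    widths: np.ndarray) -> np.ndarray:
    """Boundary gaps between a candidate capsule and all placed capsules."""
    c0, c1 = cand.axis_endpoints()
    n = len(widths)
    # point-to-segment distances, all four endpoint/segment combinations
    d2 = np.full(n, np.inf)
    for p in (c0, c1):
        d2 = np.minimum(d2, _points_to_segments_dist2(p[None, :], a0, a1))
    for q0, q1 in ((a0, a1),):
        d2 = np.minimum(d2, _segment_to_points_dist2(c0, c1, q0))
        d2 = np.minimum(d2, _segment_to_points_dist2(c0, c1, q1))
    dist = np.sqrt(d2)
    # crossing segments have distance zero
    dist[_cross_mask(c0, c1, a0, a1)] = 0.0
    return dist - (cand.width + widths) / 2.0


def _points_to_segments_dist2(p: np.ndarray, a0: np.ndarray,
                              a1: np.ndarray) -> np.ndarray:
    """Squared distance from one point p (1,2) to each segment a0[i]-a1[i]."""
    ab = a1 - a0
    denom = np.einsum("ij,ij->i", ab, ab)
    ap = p - a0
    t = np.where(denom > 0, np.einsum("ij,ij->i", ap, ab) / np.maximum(denom, 1e-300), 0.0)
    t = np.clip(t, 0.0, 1.0)
    d = ap - t[:, None] * ab
    return np.einsum("ij,ij->i", d, d)


def _segment_to_points_dist2(c0: np.ndarray, c1: np.ndarray,
                             q: np.ndarray) -> np.ndarray:
    """Squared distance from each point q[i] to the segment c0-c1."""
    ab = c1 - c0
    denom = float(ab @ ab)
    if denom == 0.0:
        d = q - c0
        return np.einsum("ij,ij->i", d, d)
    t = np.clip((q - c0) @ ab / denom, 0.0, 1.0)
    d = q - (c0 + t[:, None] * ab)
    return np.einsum("ij,ij->i", d, d)


def _cross_mask(c0, c1, a0, a1) -> np.ndarray:
    def orient(p, q, r):
        return ((q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1])
                - (q[..., 1] - p[..., 1]) * (r[..., 0] - p[..., 0]))

    d1 = orient(a0, a1, c0[None, :])
    d2 = orient(a0, a1, c1[None, :])
    d3 = orient(c0[None, :], c1[None, :], a0)
    d4 = orient(c0[None, :], c1[None, :], a1)
    return ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0))


def place_cells(cfg: FieldConfig, rng: np.random.Generator) -> list[CellGeometry]:
    """Rejection-sample non-conflicting cell geometries for one field."""
    cells: list[CellGeometry] = []
    a0s: list[np.ndarray] = []
    a1s: list[np.ndarray] = []
    widths: list[float] = []
    retries = 0
    while len(cells) < cfg.n_cells:
        anchor = None
        if cfg.layout == "microcolony" and cells:
            anchor = cells[int(rng.integers(len(cells)))]
        cand = _propose_cell(cfg, len(cells) + 1, rng, anchor)
        ok = _inside_field(cand, cfg)
        if ok and cells:
            gaps = _gaps_to_placed(cand, np.asarray(a0s), np.asarray(a1s),
                                   np.asarray(widths))
            if cfg.layout == "isolated":
                ok = bool(gaps.min() >= cfg.min_separation_um)
            else:
                ok = bool(gaps.min() >= -cfg.overlap_tol_um)
        if ok:
            cells.append(cand)
            e0, e1 = cand.axis_endpoints()
            a0s.append(e0)
            a1s.append(e1)
            widths.append(cand.width)
            retries = 0
        else:
            retries += 1
            if retries > cfg.max_retries:
                raise FieldTooCrowdedError(
                    f"could not place cell {len(cells) + 1}/{cfg.n_cells} after "
                    f"{cfg.max_retries} retries; field too crowded"
                )
    return cells


def _sample_point_in_cell(cell: CellGeometry, rng: np.random.Generator,
                          on_membrane: bool = False) -> tuple[float, float, float]:
    """Uniform point inside (or on the surface of) the 3D spherocylinder.

    Returns (x, y, dz) with dz the offset from the cell mid-plane.
    """
    r = cell.width / 2.0
    h = cell.half_axis
    while True:
        s = rng.uniform(-(h + r), h + r)
        t = rng.uniform(-r, r)
        u = rng.uniform(-r, r)
        rad2 = t * t + u * u
        cap = max(abs(s) - h, 0.0)
        if cap * cap + rad2 <= r * r:
            break
    if on_membrane:
        # project the transverse/cap offset onto the surface
        vec = np.array([max(abs(s) - h, 0.0) * np.sign(s), t, u])
        nrm = np.linalg.norm(vec)
        if nrm < 1e-12:
            t, u = r, 0.0
            s = np.clip(s, -h, h)
        else:
            vec = vec * (r / nrm)
            s = np.clip(s, -h, h) + vec[0]
            t, u = vec[1], vec[2]
    ux, uy = math.cos(cell.orientation), math.sin(cell.orientation)
    x = cell.center[0] + s * ux - t * uy
    y = cell.center[1] + s * uy + t * ux
    return float(x), float(y), float(u)


def _place_channel_foci(truth: FieldGroundTruth, channel: ChannelModel,
                        cfg: FieldConfig, rng: np.random.Generator,
                        next_id: int) -> int:
    on_membrane = channel.mode == "membrane_foci"
    partner_foci_by_cell: dict[int, list[TrueFocus]] = {}
    all_partner_foci: list[TrueFocus] = []
    if channel.coloc_partner:
        if channel.coloc_partner not in truth.foci:
            raise ValueError(
                f"channel {channel.name!r} references partner "
                f"{channel.coloc_partner!r} which has not been sampled yet"
            )
        for f in truth.foci[channel.coloc_partner]:
            if f.cell_id is not None:
                partner_foci_by_cell.setdefault(f.cell_id, []).append(f)
                all_partner_foci.append(f)
        # each partner focus hosts at most one sought focus (a sheath is
        # serviced by a single disassembly focus): draw without replacement
        rng.shuffle(all_partner_foci)
    cells_by_id = {c.id: c for c in truth.cells}

    placed_xy: dict[int, list[tuple[float, float]]] = {}
    sep2 = channel.min_focus_separation_um ** 2

    def resolvable(cell_id: int, x: float, y: float) -> bool:
        return all((x - px) ** 2 + (y - py) ** 2 >= sep2
                   for px, py in placed_xy.get(cell_id, []))

    def record(cell_id: int, x: float, y: float) -> None:
        placed_xy.setdefault(cell_id, []).append((x, y))

    foci: list[TrueFocus] = []
    for cell in truth.cells:
        partners = partner_foci_by_cell.get(cell.id, [])
        # one focus per partner focus, with probability p_partner_coloc
        for pf in partners:
            if channel.p_partner_coloc > 0 and rng.random() < channel.p_partner_coloc:
                for _ in range(30):
                    x, y, dz = _offset_near(pf, cell, channel.coloc_radius_um,
                                            cfg.z_mid_um, rng)
                    if resolvable(cell.id, x, y):
                        break
                record(cell.id, x, y)
                foci.append(TrueFocus(next_id, channel.name, cell.id, x, y,
                                      cfg.z_mid_um + dz,
                                      partner_focus_id=pf.focus_id))
                next_id += 1
        # independent draws; with probability p_coloc a focus seeks a partner
        # focus anywhere in the field (the count per cell keeps its mean, but
        # sought foci concentrate in partner-bearing cells, as a disassembly
        # factor concentrates at sheaths)
        n = channel.draw_count(rng)
        for _ in range(n):
            if all_partner_foci and channel.p_coloc > 0 and rng.random() < channel.p_coloc:
                pf = all_partner_foci.pop()
                host = cells_by_id[pf.cell_id]
                for _ in range(30):
                    x, y, dz = _offset_near(pf, host, channel.coloc_radius_um,
                                            cfg.z_mid_um, rng)
                    if resolvable(host.id, x, y):
                        break
                pid = pf.focus_id
                host_id = host.id
            else:
                for _ in range(100):
                    x, y, dz = _sample_point_in_cell(cell, rng, on_membrane)
                    if resolvable(cell.id, x, y):
                        break
                pid = None
                host_id = cell.id
            record(host_id, x, y)
            foci.append(TrueFocus(next_id, channel.name, host_id, x, y,
                                  cfg.z_mid_um + dz, partner_focus_id=pid))
            next_id += 1
    truth.foci[channel.name] = foci
    return next_id


def _offset_near(pf: TrueFocus, cell: CellGeometry, radius: float,
                 z_mid: float, rng: np.random.Generator
                 ) -> tuple[float, float, float]:
    """Point uniform in a sphere of ``radius`` around a partner focus, inside the cell.

    Returns (x, y, dz) with dz relative to the field mid-plane.
    """
    dz_pf = pf.z - z_mid
    for _ in range(200):
        v = rng.normal(size=3)
        v *= radius * rng.random() ** (1.0 / 3.0) / np.linalg.norm(v)
        x, y, dz = pf.x + v[0], pf.y + v[1], dz_pf + v[2]
        if cell.contains(x, y, dz):
            return float(x), float(y), float(dz)
    return pf.x, pf.y, dz_pf


def sample_field(field: FieldConfig, channels: Sequence[ChannelModel],
                 seed: int | np.random.SeedSequence) -> FieldGroundTruth:
    """Sample one field: cell geometries plus true foci for every channel.

    Channels with a ``coloc_partner`` must come after their partner in
    ``channels`` (the partner's foci are sampled first).
    """
    rng = np.random.default_rng(seed)
    cells = place_cells(field, rng)
    truth = FieldGroundTruth(field=field, cells=cells, foci={})
    next_id = 0
    for ch in channels:
        next_id = _place_channel_foci(truth, ch, field, rng, next_id)
    return truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def stack_z_coords(field: FieldConfig, optics: OpticsModel) -> np.ndarray:
    """Absolute z positions of the stack planes, centred on the cell mid-plane.

    With the default 13 planes at 0.2 um spacing and z_mid 1.2 um the planes
    sit at 0, 0.2, ..., 2.4 um.
    """
    z0 = field.z_mid_um - (optics.n_z - 1) / 2.0 * optics.z_spacing_um
    return z0 + np.arange(optics.n_z) * optics.z_spacing_um


def _diffuse_volume(truth: FieldGroundTruth, channel: ChannelModel,
                    optics: OpticsModel, rng: np.random.Generator) -> np.ndarray:
    cfg = truth.field
    ps = optics.pixel_size_um
    ny = int(round(cfg.height_um / ps))
    nx = int(round(cfg.width_um / ps))
    nz = optics.n_z
    vol = np.zeros((ny, nx, nz), dtype=np.float32)
    if channel.diffuse_intensity <= 0 or not truth.cells:
        return vol
    z_coords = stack_z_coords(cfg, optics)
    membrane = channel.mode in ("membrane_patchy", "membrane_foci")
    for cell in truth.cells:
        r = cell.width / 2.0
        a, b = cell.axis_endpoints()
        lo_x = max(int((min(a[0], b[0]) - r) / ps) - 2, 0)
        hi_x = min(int((max(a[0], b[0]) + r) / ps) + 3, nx)
        lo_y = max(int((min(a[1], b[1]) - r) / ps) - 2, 0)
        hi_y = min(int((max(a[1], b[1]) + r) / ps) + 3, ny)
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        xs = np.arange(lo_x, hi_x) * ps
        ys = np.arange(lo_y, hi_y) * ps
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d2 = _point_segment_dist2(pts, a, b).reshape(gy.shape)
        patches = None
        if membrane and channel.membrane_patchiness > 0:
            patches = [_sample_point_in_cell(cell, rng, on_membrane=True)
                       for _ in range(6)]
        for k, zk in enumerate(z_coords):
            dz = zk - cfg.z_mid_um
            d3 = d2 + dz * dz
            if membrane:
                r_in = max(r - channel.membrane_thickness_um, 0.0)
                mask = (d3 <= r * r) & (d3 >= r_in * r_in)
            else:
                mask = d3 <= r * r
            if not mask.any():
                continue
            inten = np.where(mask, channel.diffuse_intensity, 0.0)
            if patches is not None:
                yy, xx = np.nonzero(mask)
                px_um = xs[xx]
                py_um = ys[yy]
                boost = np.zeros(len(xx))
                for (pxc, pyc, pdz) in patches:
                    dd = ((px_um - pxc) ** 2 + (py_um - pyc) ** 2
                          + (dz - pdz) ** 2)
                    boost += np.exp(-dd / (2 * 0.25 ** 2))
                inten_vals = channel.diffuse_intensity * (
                    0.5 + channel.membrane_patchiness * boost)
                inten = np.zeros(mask.shape)
                inten[yy, xx] = inten_vals
            vol[lo_y:hi_y, lo_x:hi_x, k] += inten.astype(np.float32)
    return vol


def _splat_focus(vol: np.ndarray, x_px: float, y_px: float, z_pl: float,
                 photons: float, sx_px: float, sz_pl: float) -> None:
    """Add a pixel-integrated 3D Gaussian (photon-conserving within the stack)."""
    ny, nx, nz = vol.shape

    def axis_weights(center: float, sigma: float, n: int, reach: float):
        lo = max(int(math.floor(center - reach)), 0)
        hi = min(int(math.ceil(center + reach)) + 1, n)
        if lo >= hi:
            return lo, np.zeros(0)
        edges = np.arange(lo, hi + 1) - 0.5
        cdf = 0.5 * (1.0 + erf((edges - center) / (sigma * math.sqrt(2.0))))
        return lo, np.diff(cdf)

    x0, wx = axis_weights(x_px, sx_px, nx, 4 * sx_px + 1)
    y0, wy = axis_weights(y_px, sx_px, ny, 4 * sx_px + 1)
    z0, wz = axis_weights(z_pl, sz_pl, nz, 4 * sz_pl + 1)
    if len(wx) == 0 or len(wy) == 0 or len(wz) == 0:
        return
    block = photons * wy[:, None, None] * wx[None, :, None] * wz[None, None, :]
    vol[y0:y0 + len(wy), x0:x0 + len(wx), z0:z0 + len(wz)] += block.astype(np.float32)


def expected_photons(truth: FieldGroundTruth, channel: ChannelModel,
                     optics: OpticsModel,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """PSF-blurred expected photon field (no gain, no offset, no noise)."""
    if rng is None:
        rng = np.random.default_rng(0)
    vol = _diffuse_volume(truth, channel, optics, rng)
    if vol.size and vol.any():
        vol = gaussian_filter(
            vol,
            sigma=(optics.psf_sigma_xy_um / optics.pixel_size_um,
                   optics.psf_sigma_xy_um / optics.pixel_size_um,
                   optics.psf_sigma_z_um / optics.z_spacing_um),
            mode="constant",
        )
    ps = optics.pixel_size_um
    z0 = truth.field.z_mid_um - (optics.n_z - 1) / 2.0 * optics.z_spacing_um
    for f in truth.foci.get(channel.name, []):
        photons = channel.focus_intensity * f.intensity_scale
        if photons <= 0:
            continue
        _splat_focus(vol, f.x / ps, f.y / ps, (f.z - z0) / optics.z_spacing_um,
                     photons, optics.psf_sigma_xy_um / ps,
                     optics.psf_sigma_z_um / optics.z_spacing_um)
    return vol


def render_channel(truth: FieldGroundTruth, channel: ChannelModel,
                   optics: OpticsModel, seed: int | np.random.SeedSequence,
                   noise: bool = True) -> ImageStack:
    """Render one channel of a field through the PSF + EMCCD forward model.

    Expected pixel value is ``offset + gain * blurred_photons``; with
    ``noise=True`` the photon field is Poisson-sampled and amplified by the
    gain, and Gaussian read noise is added.
    """
    rng = np.random.default_rng(seed)
    photons = expected_photons(truth, channel, optics, rng)
    if noise:
        img = optics.offset + optics.emccd_gain * rng.poisson(photons).astype(np.float32)
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd,
                                   size=img.shape).astype(np.float32)
    else:
        img = optics.offset + optics.emccd_gain * photons
    np.clip(img, 0.0, None, out=img)
    return ImageStack(img.astype(np.float32), optics.pixel_size_um,
                      optics.z_spacing_um, channel=channel.name)


# ---------------------------------------------------------------------------
# time-lapse simulation
# ---------------------------------------------------------------------------


def _event_amplitude(t: float, ev: FocusEvent, kin: KineticsConfig) -> float:
    """Triangular-plateau intensity profile of one assembly/disassembly cycle."""
    if t <= ev.t_appear or t >= ev.t_disappear:
        return 0.0
    rise_end = ev.t_appear + kin.t_assemble_s
    fall_start = ev.t_disappear - kin.t_disassemble_s
    if kin.t_assemble_s > 0 and t < rise_end:
        return (t - ev.t_appear) / kin.t_assemble_s
    if kin.t_disassemble_s > 0 and t > fall_start:
        return (ev.t_disappear - t) / kin.t_disassemble_s
    return 1.0


def simulate_timelapse(field: FieldConfig, channel: ChannelModel,
                       optics: OpticsModel, kinetics: KineticsConfig,
                       frame_interval_s: float, duration_s: float,
                       seed: int | np.random.SeedSequence,
                       noise: bool = True) -> tuple[list[ImageStack], FieldGroundTruth]:
    """Simulate a movie of focus assembly/disassembly cycles.

    Events arrive per cell as a Poisson process (warmed up before t=0 so the
    movie starts in steady state); each event ramps up over ``t_assemble_s``,
    persists for a drawn persistence time and ramps down over
    ``t_disassemble_s``. Frames are rendered at ``frame_interval_s``.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    if duration_s < frame_interval_s:
        raise ValueError("duration_s must be >= frame_interval_s")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_field, s_events, s_render = ss.spawn(3)
    rng = np.random.default_rng(s_events)

    truth = sample_field(field, [], s_field)
    rate = kinetics.rate()
    warmup = kinetics.mean_event_duration_s() + 5 * kinetics.persistence_mean_s
    events: list[FocusEvent] = []
    foci: list[TrueFocus] = []
    fid = 0
    for cell in truth.cells:
        n_ev = rng.poisson(rate * (warmup + duration_s)) if rate > 0 else 0
        starts = np.sort(rng.uniform(-warmup, duration_s, size=n_ev))
        for t0 in starts:
            if kinetics.persistence == "fixed":
                persist = kinetics.persistence_mean_s
            else:
                persist = rng.exponential(kinetics.persistence_mean_s)
            t1 = t0 + kinetics.t_assemble_s + persist + kinetics.t_disassemble_s
            if t1 <= 0:
                continue
            x, y, dz = _sample_point_in_cell(cell, rng)
            events.append(FocusEvent(fid, cell.id, float(t0), float(t1)))
            foci.append(TrueFocus(fid, channel.name, cell.id, x, y,
                                  field.z_mid_um + dz))
            fid += 1
    truth.events = events
    truth.foci[channel.name] = foci

    frames: list[ImageStack] = []
    n_frames = int(duration_s // frame_interval_s)
    frame_seeds = np.random.SeedSequence(entropy=s_render.entropy).spawn(n_frames)
    foci_by_id = {f.focus_id: f for f in foci}
    for k in range(n_frames):
        t = k * frame_interval_s
        active: list[TrueFocus] = []
        for ev in events:
            amp = _event_amplitude(t, ev, kinetics)
            if amp > 0:
                f = foci_by_id[ev.focus_id]
                active.append(TrueFocus(f.focus_id, f.channel, f.cell_id,
                                        f.x, f.y, f.z, intensity_scale=amp))
        frame_truth = FieldGroundTruth(field=field, cells=truth.cells,
                                       foci={channel.name: active})
        frames.append(render_channel(frame_truth, channel, optics,
                                     frame_seeds[k], noise=noise))
    return frames, truth


# ---------------------------------------------------------------------------
# default study-condition channel sets
# ---------------------------------------------------------------------------


def mask_channel(name: str = "gfp") -> ChannelModel:
    """Uniform cytoplasmic marker used for segmentation (no foci)."""
    return ChannelModel(name=name, mode="cytoplasmic_foci",
                        focus_count_pmf=(1.0,), diffuse_intensity=50.0,
                        focus_intensity=0.0)


def tssb_channel(name: str = "tssb", pmf: Sequence[float] = TSSB_POPULATION_PMF,
                 ) -> ChannelModel:
    """Sheath-reporter channel: bright foci over weak diffuse background."""
    return ChannelModel(name=name, mode="foci_only",
                        focus_count_pmf=tuple(pmf), diffuse_intensity=15.0,
                        focus_intensity=6000.0)


def tssb_gfp_channel(name: str = "tssb_gfp") -> ChannelModel:
    """Sheath reporter fused to the segmentation fluorophore (dual-reporter runs)."""
    return ChannelModel(name=name, mode="cytoplasmic_foci",
                        focus_count_pmf=TSSB_POPULATION_PMF,
                        diffuse_intensity=50.0, focus_intensity=6000.0)


def tssh_channel(partner: str, name: str = "tssh") -> ChannelModel:
    """Unfoldase-like channel: ~0.2 foci/cell, 80% placed at a partner focus."""
    return ChannelModel(name=name, mode="foci_only", focus_count_mean=0.2,
                        diffuse_intensity=15.0, focus_intensity=6000.0,
                        coloc_partner=partner, p_coloc=0.8)


def tssl_channel(partner: str, name: str = "tssl",
                 partner_pmf: Sequence[float] = TSSB_POPULATION_PMF) -> ChannelModel:
    """Membrane-complex-like channel: each partner focus is matched with
    probability 0.85; independent extra foci bring the total to 0.9 per cell."""
    extra = max(0.9 - 0.85 * pmf_mean(partner_pmf), 0.0)
    return ChannelModel(name=name, mode="membrane_foci", focus_count_mean=extra,
                        diffuse_intensity=10.0, focus_intensity=6000.0,
                        coloc_partner=partner, p_partner_coloc=0.85)
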