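"""Seeded generator of MADM-like two-fluorophore scenes with exact ground truth.

The generator emulates the image properties that make mosaic-labeled brain
sections hard for detectors: sparse bright neurons (compact somas with a few
thin processes), larger fuzzy low-contrast glial arborizations, dense glia
clusters built from overlapping glia whose summed signal can saturate the
detector ceiling, three reporter color classes (red = RFP-only, green =
GFP-only, yellow = both), and an optional DAPI channel with nuclei everywhere
independent of the reporter labels.

Every scene is a pure function of its :class:`SceneConfig` (including the
seed): the same config renders bit-identical images, and the returned
:class:`SceneTruth` is the exact generative record — per-cell footprint
boxes and areas, and per-cluster per-color member counts.

Geometry is parameterized in micrometres and converted through
``pixel_size``, so scenes generated at different resolutions have the same
physical content.  The glial arbor radius default is calibrated so that a
singleton glial cell's above-background footprint is close to the
2000 um^2 per-cell quantum used by area-based counting (see
:func:`calibrate_cell_area`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import BoundingBox, CellClass, GroundTruthRecord, COLORS

__all__ = [
    "GFP",
    "RFP",
    "DAPI",
    "PlacementError",
    "ClusterSpec",
    "SceneConfig",
    "SceneTruth",
    "make_scene",
    "calibrate_cell_area",
]

# channel indices of the rendered (H, W, 3) raster
GFP, RFP, DAPI = 0, 1, 2

# renderer constants (intensity units of an 8-bit acquisition)
_GLIA_AMP = 115.0
_NEURON_AMP = 215.0
_AMP_JITTER = 0.08
_GLIA_EDGE_UM = 1.2  # soft-edge width of the arbor profile
_CLUSTER_MARGIN_PX = 5  # loose-annotation margin around cluster footprints


class PlacementError(ValueError):
    """Raised when requested objects cannot be placed inside the image."""


@dataclass(frozen=True)
class ClusterSpec:
    """One glia cluster: per-color member counts and a saturation flag."""

    members: Mapping[str, int]
    saturated: bool = False

    def __post_init__(self) -> None:
        bad = [c for c in self.members if c not in COLORS]
        if bad:
            raise ValueError(f"unknown cluster member colors {bad}")
        if any(v < 0 for v in self.members.values()):
            raise ValueError("cluster member counts must be non-negative")
        if self.total < 2:
            raise ValueError("a glia cluster needs at least 2 members")

    @property
    def total(self) -> int:
        return sum(self.members.values())


@dataclass(frozen=True)
class SceneConfig:
    """Parameters and exact generative record for one synthetic scene.

    Counts are per color; geometry parameters are in micrometres so that the
    same config rendered at a different ``pixel_size`` describes the same
    physical scene.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 1.0  # um per pixel
    neurons: Mapping[str, int] = field(default_factory=dict)
    glia: Mapping[str, int] = field(default_factory=dict)
    clusters: tuple[ClusterSpec, ...] = ()
    background_level: float = 8.0
    background_noise: float = 3.0
    dapi_density: float = 1.5e-4  # nuclei per um^2
    ceiling: int = 255
    glia_radius: float = 25.4  # um, flat-top arbor radius (calibrated default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image extent must be positive")
        for counts in (self.neurons, self.glia):
            bad = [c for c in counts if c not in COLORS]
            if bad:
                raise ValueError(f"unknown colors {bad}")
            if any(v < 0 for v in counts.values()):
                raise ValueError("cell counts must be non-negative")
        if self.glia_radius <= 0:
            raise ValueError("glia_radius must be positive")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be positive")

    @property
    def footprint_level(self) -> float:
        """Intensity above which a rendered pixel counts as cell footprint."""
        return self.background_level + 2.0 * self.background_noise


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth for one rendered scene.

    ``records`` and ``footprint_areas_um2`` are aligned: entry *i* gives the
    above-background footprint area of record *i* (for clusters, the union
    footprint of all members).
    """

    records: tuple[GroundTruthRecord, ...]
    footprint_areas_um2: tuple[float, ...]
    config: SceneConfig

    def by_phenotype(self, phenotype: str) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.label.phenotype == phenotype]


# ---------------------------------------------------------------------------
# profile renderers (all local patches, centred grids in um)


def _soft_disk(r_um: np.ndarray, radius: float, edge: float, amp: float) -> np.ndarray:
    z = np.clip((r_um - radius) / edge, -50.0, 50.0)
    return amp / (1.0 + np.exp(z))


def _patch_grid(half_px: int, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-half_px, half_px + 1, dtype=np.float64) * pixel_size
    x, y = np.meshgrid(ax, ax)
    return x, y


def _render_glia_patch(
    rng: np.random.Generator, radius_um: float, pixel_size: float
) -> np.ndarray:
    """Bushy flat-top arbor: radially modulated soft-edged plateau."""
    half = int(np.ceil((radius_um * 1.35) / pixel_size)) + 5
    x, y = _patch_grid(half, pixel_size)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    mod = np.zeros_like(theta)
    for k in (2, 3, 5):
        mod += rng.uniform(-0.06, 0.06) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r_theta = radius_um * (1.0 + mod)
    amp = _GLIA_AMP * (1.0 + rng.uniform(-_AMP_JITTER, _AMP_JITTER))
    # soft edge at the angle-dependent radius
    return _soft_disk(r - (r_theta - radius_um), radius_um, _GLIA_EDGE_UM, amp)


def _render_neuron_patch(
    rng: np.random.Generator, pixel_size: float
) -> np.ndarray:
    """Compact bright soma plus 1-3 thin processes."""
    half = int(np.ceil(16.0 / pixel_size)) + 2
    x, y = _patch_grid(half, pixel_size)
    r = np.hypot(x, y)
    amp = _NEURON_AMP * (1.0 + rng.uniform(-_AMP_JITTER, _AMP_JITTER))
    soma_radius = rng.uniform(2.2, 3.0)
    patch = _soft_disk(r, soma_radius, 0.8, amp)
    n_proc = int(rng.integers(1, 4))
    for _ in range(n_proc):
        phi = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(6.0, 12.0)
        cos_p, sin_p = np.cos(phi), np.sin(phi)
        t = np.clip(x * cos_p + y * sin_p, 0.0, length)
        dist = np.hypot(x - t * cos_p, y - t * sin_p)
        patch = np.maximum(patch, _soft_disk(dist, 0.8, 0.5, 0.55 * amp))
    return patch


def _render_nucleus_patch(rng: np.random.Generator, pixel_size: float) -> np.ndarray:
    half = int(np.ceil(6.0 / pixel_size)) + 1
    x, y = _patch_grid(half, pixel_size)
    radius = rng.uniform(2.5, 4.0)
    amp = rng.uniform(60.0, 110.0)
    return _soft_disk(np.hypot(x, y), radius, 0.8, amp)


# ---------------------------------------------------------------------------
# placement


def _place_one(
    rng: np.random.Generator,
    config: SceneConfig,
    margin_px: float,
    r_excl_um: float,
    placed: list[tuple[float, float, float]],
    anchor: tuple[float, float, float, float] | None = None,
    max_tries: int = 3000,
) -> tuple[float, float]:
    """Find a center (pixel coords) respecting exclusion radii (um)."""
    w, h, ps = config.width, config.height, config.pixel_size
    if 2 * margin_px >= min(w, h):
        raise PlacementError(
            f"image extent ({w}x{h}) too small for an object needing "
            f"{margin_px:.0f} px margins"
        )
    gap = 3.0  # um clearance between footprints
    for _ in range(max_tries):
        if anchor is None:
            cx = rng.uniform(margin_px, w - margin_px)
            cy = rng.uniform(margin_px, h - margin_px)
        else:
            ax, ay, dmin, dmax = anchor
            phi = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(dmin, dmax) / ps
            cx, cy = ax + d * np.cos(phi), ay + d * np.sin(phi)
            if not (margin_px <= cx <= w - margin_px and margin_px <= cy <= h - margin_px):
                continue
        ok = True
        for px, py, pr in placed:
            if np.hypot(cx - px, cy - py) * ps < r_excl_um + pr + gap:
                ok = False
                break
        if ok:
            return cx, cy
    raise PlacementError(
        f"could not place an object with exclusion radius {r_excl_um:.0f} um "
        f"in a {w}x{h} image after {max_tries} attempts"
    )


def _add_patch(accum: np.ndarray, patch: np.ndarray, cx: float, cy: float) -> tuple[int, int]:
    """Add a centred patch into the accumulator; returns top-left offset."""
    half = patch.shape[0] // 2
    ix, iy = int(round(cx)), int(round(cy))
    x0, y0 = ix - half, iy - half
    h, w = accum.shape
    sx0, sy0 = max(0, -x0), max(0, -y0)
    ex0, ey0 = max(0, x0), max(0, y0)
    sw = min(patch.shape[1] - sx0, w - ex0)
    sh = min(patch.shape[0] - sy0, h - ey0)
    if sw > 0 and sh > 0:
        accum[ey0 : ey0 + sh, ex0 : ex0 + sw] += patch[sy0 : sy0 + sh, sx0 : sx0 + sw]
    return x0, y0


def _footprint_record(
    patch: np.ndarray, x0: int, y0: int, level: float, extent: tuple[int, int]
) -> tuple[BoundingBox, np.ndarray | None, float, int, int]:
    """Tight box + mask of the above-background footprint, in image coords."""
    mask = patch > level
    if not mask.any():
        raise PlacementError("rendered cell has an empty footprint")
    ys, xs = np.nonzero(mask)
    w, h = extent
    bx0 = max(0, x0 + xs.min())
    by0 = max(0, y0 + ys.min())
    bx1 = min(w, x0 + xs.max() + 1)
    by1 = min(h, y0 + ys.max() + 1)
    return BoundingBox(bx0, by0, bx1, by1), mask, float(mask.sum()), x0, y0


_COLOR_CHANNELS = {"red": (RFP,), "green": (GFP,), "yellow": (GFP, RFP)}


def make_scene(config: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; returns ``(image, truth)``.

    The image is an ``(H, W, 3)`` uint8-like integer raster with channels
    ``(GFP, RFP, DAPI)`` clipped at ``config.ceiling``.  Pixels reach the
    ceiling exactly when a cluster flagged ``saturated`` drove them there;
    unsaturated scenes contain no ceiling-valued pixel.
    """
    rng = np.random.default_rng(config.seed)
    w, h, ps = config.width, config.height, config.pixel_size
    fluor = np.zeros((h, w, 2), dtype=np.float64)  # GFP, RFP accumulators
    sat_mask = np.zeros((h, w, 2), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    level = config.footprint_level

    cell_records: list[tuple[GroundTruthRecord, float]] = []
    cluster_records: list[tuple[GroundTruthRecord, float]] = []

    glia_excl = config.glia_radius * 1.3
    glia_margin = glia_excl / ps + 5

    # clusters first (largest objects), then singles
    for spec in config.clusters:
        colors = [c for c in COLORS for _ in range(spec.members.get(c, 0))]
        rng.shuffle(colors)
        member_centers: list[tuple[float, float]] = []
        cluster_acc = np.zeros((h, w, 2), dtype=np.float64)
        member_patches: list[tuple[np.ndarray, int, int, str]] = []
        for i, color in enumerate(colors):
            if i == 0:
                cx, cy = _place_one(rng, config, glia_margin, glia_excl * 2.2, placed)
            else:
                for attempt in range(500):
                    ax, ay = member_centers[int(rng.integers(0, len(member_centers)))]
                    try:
                        cx, cy = _place_one(
                            rng,
                            config,
                            glia_margin,
                            glia_excl,
                            placed,
                            anchor=(
                                ax,
                                ay,
                                1.80 * config.glia_radius,
                                1.96 * config.glia_radius,
                            ),
                            max_tries=20,
                        )
                    except PlacementError:
                        continue
                    d_um = min(
                        np.hypot(cx - mx, cy - my) * ps for mx, my in member_centers
                    )
                    if d_um >= 1.6 * config.glia_radius:
                        break
                else:
                    raise PlacementError("could not place a cluster member")
            member_centers.append((cx, cy))
            patch = _render_glia_patch(rng, config.glia_radius, ps)
            for ch in _COLOR_CHANNELS[color]:
                x0, y0 = _add_patch(cluster_acc[:, :, ch], patch, cx, cy)
            member_patches.append((patch, x0, y0, color))
        # exclusion footprint for later singles: every member blocks its area
        for mx, my in member_centers:
            placed.append((mx, my, glia_excl))

        if spec.saturated:
            peak = cluster_acc.max()
            factor = max(1.6, (config.ceiling + 30.0) / max(peak, 1.0))
            cluster_acc *= factor
            sat_mask |= cluster_acc >= config.ceiling
        else:
            factor = 1.0
        fluor += cluster_acc

        # union footprint over members (scaled), loose cluster box
        union = np.zeros((h, w), dtype=bool)
        for patch, x0, y0, _color in member_patches:
            m = patch * factor > level
            ys, xs = np.nonzero(m)
            gx, gy = xs + x0, ys + y0
            keep = (gx >= 0) & (gx < w) & (gy >= 0) & (gy < h)
            union[gy[keep], gx[keep]] = True
        ys, xs = np.nonzero(union)
        box = BoundingBox(
            max(0, xs.min() - _CLUSTER_MARGIN_PX),
            max(0, ys.min() - _CLUSTER_MARGIN_PX),
            min(w, xs.max() + 1 + _CLUSTER_MARGIN_PX),
            min(h, ys.max() + 1 + _CLUSTER_MARGIN_PX),
        )
        rec = GroundTruthRecord(box, CellClass("glia_cluster"), dict(spec.members))
        cluster_records.append((rec, float(union.sum()) * ps * ps))

    for color in COLORS:
        for _ in range(config.glia.get(color, 0)):
            cx, cy = _place_one(rng, config, glia_margin, glia_excl, placed)
            placed.append((cx, cy, glia_excl))
            patch = _render_glia_patch(rng, config.glia_radius, ps)
            for ch in _COLOR_CHANNELS[color]:
                x0, y0 = _add_patch(fluor[:, :, ch], patch, cx, cy)
            box, _m, npx, _x0, _y0 = _footprint_record(patch, x0, y0, level, (w, h))
            cell_records.append(
                (GroundTruthRecord(box, CellClass("glia", color)), npx * ps * ps)
            )

    neuron_excl = 16.0
    neuron_margin = neuron_excl / ps + 3
    for color in COLORS:
        for _ in range(config.neurons.get(color, 0)):
            cx, cy = _place_one(rng, config, neuron_margin, neuron_excl, placed)
            placed.append((cx, cy, neuron_excl))
            patch = _render_neuron_patch(rng, ps)
            for ch in _COLOR_CHANNELS[color]:
                x0, y0 = _add_patch(fluor[:, :, ch], patch, cx, cy)
            box, _m, npx, _x0, _y0 = _footprint_record(patch, x0, y0, level, (w, h))
            cell_records.append(
                (GroundTruthRecord(box, CellClass("neuron", color)), npx * ps * ps)
            )

    # DAPI: nuclei everywhere, independent of the reporter labels
    dapi = np.zeros((h, w), dtype=np.float64)
    n_nuclei = int(round(config.dapi_density * w * h * ps * ps))
    for _ in range(n_nuclei):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        _add_patch(dapi, _render_nucleus_patch(rng, ps), cx, cy)

    image = np.zeros((h, w, 3), dtype=np.float64)
    image[:, :, GFP] = fluor[:, :, 0]
    image[:, :, RFP] = fluor[:, :, 1]
    image[:, :, DAPI] = dapi
    image += config.background_level
    image += rng.normal(0.0, config.background_noise, size=image.shape)
    # unsaturated content stays strictly below the ceiling; only flagged
    # cluster pixels are driven to it exactly
    out = np.clip(np.rint(image), 0, config.ceiling - 1).astype(np.uint16)
    for ch_local, ch_img in ((0, GFP), (1, RFP)):
        out[:, :, ch_img][sat_mask[:, :, ch_local]] = config.ceiling
    if config.ceiling <= 255:
        out = out.astype(np.uint8)

    records = cell_records + cluster_records
    truth = SceneTruth(
        records=tuple(r for r, _a in records),
        footprint_areas_um2=tuple(a for _r, a in records),
        config=config,
    )
    return out, truth


# ---------------------------------------------------------------------------
# calibration


def calibrate_cell_area(
    config: SceneConfig, n_cells: int = 60, phenotype: str = "glia"
) -> float:
    """Empirical mean above-background footprint (um^2) of a rendered singleton.

    Renders ``n_cells`` independent singleton scenes from seeds derived from
    ``config.seed`` and measures each cell's area with the same adaptive
    threshold + morphology used by area-based counting, so the returned mean
    is the effective per-cell area quantum of this renderer configuration.
    """
    from .counting import cluster_threshold, clean_mask

    side_um = max(6.0 * config.glia_radius, 120.0)
    side = int(np.ceil(side_um / config.pixel_size))
    areas = []
    for i in range(n_cells):
        single = {"red": 1}
        cfg = dataclasses.replace(
            config,
            width=side,
            height=side,
            neurons=single if phenotype == "neuron" else {},
            glia=single if phenotype == "glia" else {},
            clusters=(),
            seed=(config.seed + 10_007 * i + 1) % (2**31),
        )
        image, truth = make_scene(cfg)
        rec = truth.records[0]
        channel = image[:, :, RFP].astype(np.float64)
        inside = np.zeros(channel.shape, dtype=bool)
        inside[
            int(rec.box.y_min) : int(rec.box.y_max),
            int(rec.box.x_min) : int(rec.box.x_max),
        ] = True
        thr = cluster_threshold(channel[inside], channel[~inside])
        mask = clean_mask(
            (channel > thr) & inside,
            radius_px=max(1, round(2.0 / cfg.pixel_size)),
        )
        areas.append(mask.sum() * cfg.pixel_size**2)
    return float(np.mean(areas))
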