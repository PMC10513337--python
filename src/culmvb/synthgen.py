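"""Synthetic moso-bamboo culm cross-sections with instance ground truth.

The generator emulates the radial organization of a culm wall seen in
brightfield cross-sections: vascular bundles scattered in the ground
parenchyma between epidermis (row 0 side) and pith cavity, with

* bundle density and count highest on the epidermis side,
* bundle area increasing from epidermis to pith,
* aspect (tangential width / radial height) ~0.5 near the epidermis,
  rising above 1.0 toward the pith,
* morphology progressing through four stages — a single fiber strand,
  two fiber lobes around a phloem/xylem gap, then four lobes around
  enlarging metaxylem vessels (the pith-side stage tangentially widened),
* a single tangential row of tangentially elongated bundles hugging the
  pith margin,
* and internode archetypes: the basal internode (2) has a thicker wall,
  larger and more radially elongated bundles, and a lower whole-wall
  bundle area ratio than upper internodes (12, 22, 32).

Peripheral bundles in real culms are packed almost shoulder to shoulder
(area fractions near 70% at the epidermal side). Random sequential
placement cannot reach such coverage, so the outermost bundles are laid on
jittered structured tangential rows whose pitch is solved from the
archetype's target epidermal area fraction; the interior uses
density-profile-driven rejection sampling. Both structured zones can be
disabled through archetype overrides for uniform-placement experiments.

Calibration constants below are desk-scale defaults chosen to reproduce
the qualitative radial and internode gradients; they are module-level and
documented rather than hidden inside functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage as ndi

from .morphometry import TissueFrame

__all__ = [
    "InternodeArchetype",
    "SectionImage",
    "GroundTruth",
    "make_archetype",
    "render_bundle",
    "generate_section",
    "VALID_INTERNODES",
]

VALID_INTERNODES = (2, 12, 22, 32)

#: default pixel size, µm per pixel
PIXEL_SIZE_UM = 4.70

#: per-internode calibration of the default profiles (desk scale).
#: wall: culm-wall thickness in px; area0/area_ramp: bundle area ramp
#: A(p) = area0 * (1 + area_ramp * p); asp0/asp1: aspect endpoints;
#: coverage: interior coverage scale k in cov(p) = k * (1.5 - p).
_INTERNODE_DEFAULTS: dict[int, dict] = {
    2: dict(wall=640, area0=780.0, area_ramp=2.2, asp0=0.50, asp1=1.25, coverage=0.16),
    12: dict(wall=512, area0=700.0, area_ramp=2.0, asp0=0.56, asp1=1.25, coverage=0.20),
    22: dict(wall=416, area0=600.0, area_ramp=1.9, asp0=0.62, asp1=1.30, coverage=0.24),
    32: dict(wall=320, area0=500.0, area_ramp=1.8, asp0=0.68, asp1=1.30, coverage=0.28),
}

#: morphotype stage boundaries on the relative radial coordinate
_STAGE_EDGES = (0.12, 0.38, 0.70)

#: image formation (brightfield-like: bundles darker than parenchyma)
PARENCHYMA_INTENSITY = 0.78
BUNDLE_INTENSITY = 0.38  # contrast 0.4 vs parenchyma
BACKGROUND_INTENSITY = 0.97  # outside the tissue band (cavity / mount)
NOISE_SIGMA = 0.05

#: placement
MAX_ATTEMPTS_PER_BUNDLE = 200
_TOP_MARGIN = 8  # background rows above the epidermis
_BOTTOM_MARGIN = 24  # pith-cavity rows below the wall
_EPIDERMAL_GAP_MIN = 1.0  # px, minimum tangential gap in the packed rows
_PITH_ROW_ASPECT = 1.35
_PITH_ROW_GAP_FRAC = 0.30

#: per-stage interior holes (phloem / metaxylem / protoxylem lumina) as
#: (col_offset, row_offset, semi_axis_col, semi_axis_row) in units of the
#: bundle's semi-axes, plus the outline indentation depth. Holes stay well
#: inside the outline so each stamp remains a single connected component.
_STAGE_HOLES: dict[int, list[tuple[float, float, float, float]]] = {
    1: [],
    2: [(0.0, -0.05, 0.42, 0.30)],
    3: [(0.0, -0.45, 0.30, 0.18), (-0.35, 0.15, 0.30, 0.30), (0.35, 0.15, 0.30, 0.30)],
    4: [(0.0, -0.48, 0.32, 0.18), (-0.40, 0.10, 0.36, 0.36), (0.40, 0.10, 0.36, 0.36),
        (0.0, 0.55, 0.18, 0.14)],
}
_STAGE_DENT = {1: 0.0, 2: 0.04, 3: 0.05, 4: 0.06}
_MIN_STAGE_AREA = {1: 50, 2: 140, 3: 260, 4: 320}


@dataclass(frozen=True)
class InternodeArchetype:
    """Generator parameters for one internode of the culm."""

    internode_id: int
    wall_thickness_px: int
    tangential_width_px: int
    density_profile: Callable[[float], float]
    area_profile: Callable[[float], float]
    aspect_profile: Callable[[float], float]
    morphotype_profile: Callable[[float], int]
    target_area_fraction_epidermal: float
    seed: int
    epidermal_packing_rows: int = 2
    pith_margin_row: bool = True

    def __post_init__(self) -> None:
        if self.wall_thickness_px < 64:
            raise ValueError("wall_thickness_px must be >= 64")


@dataclass(frozen=True)
class SectionImage:
    """Grayscale radial strip; rows run radially, row 0 = epidermis side."""

    pixels: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")


@dataclass(frozen=True)
class GroundTruth:
    """Instance labels plus per-instance generating parameters."""

    instance_mask: np.ndarray
    params: tuple[dict, ...]
    tissue_frame: TissueFrame


def _interp_profile(v0: float, v1: float, power: float = 1.0):
    def f(p: float) -> float:
        p = min(1.0, max(0.0, p))
        return v0 + (v1 - v0) * p**power

    return f


def make_archetype(
    internode_id: int,
    overrides: dict | None = None,
    seed: int = 0,
) -> InternodeArchetype:
    """Calibrated default archetype for one of the sampled internodes.

    Internode 2 (near the base) gets the thickest wall, the largest bundle
    areas, the lowest (most radially elongated) aspect values and the lowest
    whole-wall bundle coverage; internode 32 the opposite. ``overrides`` may
    replace any :class:`InternodeArchetype` field, including the profile
    callables.
    """
    if internode_id not in VALID_INTERNODES:
        raise ValueError(
            f"unknown internode_id {internode_id!r}; valid ids: {VALID_INTERNODES}"
        )
    c = _INTERNODE_DEFAULTS[internode_id]
    area_profile = _interp_profile(c["area0"], c["area0"] * (1 + c["area_ramp"]))
    aspect_profile = _interp_profile(c["asp0"], c["asp1"])

    def morphotype_profile(p: float) -> int:
        for stage, edge in enumerate(_STAGE_EDGES, start=1):
            if p < edge:
                return stage
        return 4

    # epidermal plateau density (packed rows), then interior density
    # d(p) = k * (1.5 - p) / A(p): bundles per px^2, non-increasing in p
    # because A is non-decreasing.
    k = c["coverage"]
    w_epi = 2.0 * math.sqrt(c["area0"] * c["asp0"] / math.pi)
    h_epi = w_epi / c["asp0"]
    d_epi = 1.0 / ((w_epi + 0.15 * w_epi) * (h_epi + 4.0))

    def density_profile(p: float) -> float:
        p = min(1.0, max(0.0, p))
        interior = k * (1.5 - p) / area_profile(p)
        if p < _STAGE_EDGES[0]:
            return max(d_epi, interior)
        return interior

    arch = InternodeArchetype(
        internode_id=internode_id,
        wall_thickness_px=int(c["wall"]),
        tangential_width_px=1024,
        density_profile=density_profile,
        area_profile=area_profile,
        aspect_profile=aspect_profile,
        morphotype_profile=morphotype_profile,
        target_area_fraction_epidermal=0.70,
        seed=seed,
    )
    if overrides:
        bad = set(overrides) - set(arch.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown archetype override(s): {sorted(bad)}")
        arch = replace(arch, **overrides)
    return arch


# ---------------------------------------------------------------------------
# bundle stamps
# ---------------------------------------------------------------------------

def _render_outline(
    a: float, b: float, stage: int, rng: np.random.Generator | None
) -> np.ndarray:
    """Rasterize a lobed elliptical outline with interior lumina removed.

    ``a``/``b`` are the tangential/radial semi-axes. Stages >= 2 carve
    interior holes; stages >= 3 dent the outline on the axes so the four
    fiber lobes sit on the diagonals (convex area then exceeds area).
    """
    dent = _STAGE_DENT[stage]
    pad = 2
    half_w = int(math.ceil(a * (1 + dent))) + pad
    half_h = int(math.ceil(b * (1 + dent))) + pad
    yy, xx = np.mgrid[-half_h:half_h + 1, -half_w:half_w + 1].astype(np.float64)
    u = xx / a
    v = yy / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    # narrow dents (cos^4) keep the bounding box close to the full ellipse
    # so extent declines with the stage's lumina rather than via bbox shrink
    if stage == 2:
        boundary = 1.0 - dent * np.cos(theta) ** 4  # waist at tangential sides
    else:
        boundary = 1.0 - dent * np.cos(2 * theta) ** 4  # dents on both axes
    if rng is not None:
        # mild low-order boundary irregularity
        ph = rng.uniform(0, 2 * math.pi, 2)
        amp = rng.uniform(0.005, 0.02, 2)
        boundary = boundary + amp[0] * np.cos(3 * theta + ph[0]) \
            + amp[1] * np.cos(5 * theta + ph[1])
    stamp = rho <= boundary
    for (ox, oy, sa, sb) in _STAGE_HOLES[stage]:
        hole = ((u - ox) / sa) ** 2 + ((v - oy) / sb) ** 2 <= 1.0
        stamp &= ~hole
    return stamp


def _crop(stamp: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(stamp.any(axis=1))
    cols = np.flatnonzero(stamp.any(axis=0))
    return stamp[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


def render_bundle(
    stage: int,
    area_px: int,
    aspect: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary stamp of one vascular bundle at the requested developmental stage.

    The stamp's pixel count is brought within 15% of ``area_px`` by one
    corrective rescale, and its bounding-box width/height ratio stays within
    15% of ``aspect``. Raises if the area is too small to realize the stage's
    lobed geometry.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be in 1..4")
    if aspect <= 0:
        raise ValueError("aspect must be positive")
    if area_px < _MIN_STAGE_AREA[1]:
        raise ValueError(f"area_px must be >= {_MIN_STAGE_AREA[1]}")
    if area_px < _MIN_STAGE_AREA[stage]:
        raise ValueError(
            f"area {area_px} too small to realize stage {stage} "
            f"(needs >= {_MIN_STAGE_AREA[stage]})"
        )
    # start from the ellipse whose area anticipates hole/dent losses
    loss = {1: 0.0, 2: 0.13, 3: 0.24, 4: 0.34}[stage]
    a = math.sqrt(area_px / (1 - loss) * aspect / math.pi)
    b = a / aspect
    state = None if rng is None else rng.bit_generator.state
    for _ in range(3):
        if rng is not None:
            rng.bit_generator.state = state  # same irregularity each pass
        stamp = _render_outline(a, b, stage, rng)
        n = int(stamp.sum())
        if abs(n - area_px) <= 0.05 * area_px:
            break
        s = math.sqrt(area_px / max(n, 1))
        a *= s
        b *= s
    return _crop(stamp)


# ---------------------------------------------------------------------------
# section assembly
# ---------------------------------------------------------------------------

def _bundle_geometry(arch: InternodeArchetype, p: float, rng, jitter: bool = True):
    """Stage, target area and aspect for a bundle at relative position p."""
    stage = arch.morphotype_profile(p)
    area = arch.area_profile(p)
    aspect = arch.aspect_profile(p)
    if jitter:
        area = float(area * rng.lognormal(0.0, 0.08))
        aspect = float(aspect * rng.lognormal(0.0, 0.04))
    area = max(area, _MIN_STAGE_AREA[stage] * 1.2)
    return stage, int(round(area)), aspect


class _Canvas:
    """Instance mask plus a dilated occupancy grid for overlap rejection."""

    def __init__(self, rows: int, cols: int, frame: TissueFrame):
        self.mask = np.zeros((rows, cols), dtype=np.int32)
        self.occupied = np.zeros((rows, cols), dtype=bool)
        self.frame = frame
        self.params: list[dict] = []

    def try_place(self, stamp: np.ndarray, r0: int, c0: int, meta: dict,
                  enforce: bool = True) -> bool:
        """Place stamp with top-left at (r0, c0); columns may clip at edges.

        With ``enforce`` the placement is rejected if the 2-px-dilated
        occupancy is touched; without it the stamp is painted onto whatever
        pixels are still free (instances never share a pixel either way).
        """
        h, w = stamp.shape
        if r0 < self.frame.epidermis_row or r0 + h > self.frame.pith_row:
            return False
        cs, ce = max(c0, 0), min(c0 + w, self.mask.shape[1])
        if ce - cs < max(2, w // 4):  # nearly fully clipped: skip
            return False
        sub = stamp[:, cs - c0: ce - c0]
        if enforce and (self.occupied[r0:r0 + h, cs:ce] & sub).any():
            return False
        region = self.mask[r0:r0 + h, cs:ce]
        free = sub & (region == 0)
        if not free.any() or (enforce and free.sum() < sub.sum()):
            return False
        label = len(self.params) + 1
        region[free] = label
        grown = ndi.binary_dilation(sub, iterations=2)
        self.occupied[r0:r0 + h, cs:ce] |= grown
        self.params.append(meta)
        return True


def _packed_row_pitch(
    stamp: np.ndarray, band_rows: int, target_fraction: float, top_offset: int
) -> float:
    """Tangential pitch so one bundle per pitch yields the target coverage
    of the outermost radial band (rows [0, band_rows) of the wall)."""
    in_band = int(stamp[: max(band_rows - top_offset, 0)].sum())
    if in_band == 0:
        return stamp.shape[1] * 2.0
    pitch = in_band / (target_fraction * band_rows)
    return max(pitch, stamp.shape[1] + _EPIDERMAL_GAP_MIN)


def generate_section(
    archetype: InternodeArchetype,
    rows: int | None = None,
    seed: int = 0,
    tangential_width: int | None = None,
    reject: bool = True,
) -> tuple[SectionImage, GroundTruth]:
    """Render one synthetic radial strip and its instance ground truth.

    Deterministic for fixed (archetype, rows, seed). ``reject=False``
    disables the non-overlap test for interior placement (placement
    statistics experiments); instances may then share pixels only in the
    image, never in the mask (later bundles simply skip occupied pixels via
    the mask check).
    """
    wall = archetype.wall_thickness_px
    W = tangential_width or archetype.tangential_width_px
    H = rows if rows is not None else wall + _TOP_MARGIN + _BOTTOM_MARGIN
    if H < wall:
        raise ValueError(f"rows={H} smaller than wall thickness {wall}")
    top = min(_TOP_MARGIN, H - wall)
    frame = TissueFrame(epidermis_row=top, pith_row=top + wall)
    rng = np.random.default_rng(seed)
    canvas = _Canvas(H, W, frame)

    # symmetric default range so uniform-density experiments are unbiased;
    # the structured zones shrink it when they are enabled
    interior_top_p = 0.03
    interior_bot_p = 0.97

    # --- pith-margin row: single tangential row of tangentially elongated
    # bundles adjoining the pith boundary -------------------------------
    if archetype.pith_margin_row:
        stage = 4
        area = int(round(archetype.area_profile(1.0) * 0.8))
        aspect = max(_PITH_ROW_ASPECT, archetype.aspect_profile(1.0))
        proto = render_bundle(stage, area, aspect, None)
        pitch = proto.shape[1] * (1.0 + _PITH_ROW_GAP_FRAC)
        x = rng.uniform(0, pitch)
        while x < W:
            stamp = render_bundle(
                stage,
                int(round(area * rng.lognormal(0, 0.06))),
                aspect * rng.lognormal(0, 0.03),
                rng,
            )
            r0 = frame.pith_row - stamp.shape[0] - 1 - int(rng.integers(0, 2))
            p = (r0 + stamp.shape[0] / 2 - frame.epidermis_row) / wall
            canvas.try_place(
                stamp, r0, int(round(x - stamp.shape[1] / 2)),
                dict(stage=stage, target_area=area, target_aspect=aspect, p=p,
                     zone="pith_row"),
                enforce=False,
            )
            x += pitch * rng.uniform(0.97, 1.03)
        interior_bot_p = (frame.pith_row - proto.shape[0] - 6 - frame.epidermis_row) / wall

    # --- epidermal packed rows ------------------------------------------
    if archetype.epidermal_packing_rows > 0:
        band = max(2, int(round(0.05 * wall)))
        depth = 1  # rows below the epidermis boundary
        for irow in range(archetype.epidermal_packing_rows):
            # representative stamp at this row's expected center
            h_guess = 2.0 * math.sqrt(
                archetype.area_profile(depth / wall)
                / (math.pi * archetype.aspect_profile(depth / wall))
            )
            p_c = (depth + h_guess / 2) / wall
            stage, area, aspect = _bundle_geometry(archetype, p_c, rng, jitter=False)
            proto = render_bundle(stage, area, aspect, None)
            if irow == 0:
                pitch = _packed_row_pitch(
                    proto, band, archetype.target_area_fraction_epidermal, depth
                )
            else:
                pitch = proto.shape[1] * 1.25
            x = rng.uniform(0, pitch) - (pitch / 2 if irow % 2 else 0)
            while x < W:
                stage_i, area_i, aspect_i = _bundle_geometry(archetype, p_c, rng)
                stamp = render_bundle(stage_i, area_i, aspect_i, rng)
                r0 = frame.epidermis_row + depth + int(rng.integers(0, 2))
                p = (r0 + stamp.shape[0] / 2 - frame.epidermis_row) / wall
                canvas.try_place(
                    stamp, r0, int(round(x - stamp.shape[1] / 2 + rng.uniform(-1, 1))),
                    dict(stage=stage_i, target_area=area_i, target_aspect=aspect_i,
                         p=p, zone="epidermal"),
                    enforce=False,
                )
                x += pitch
            depth += proto.shape[0] + 3
        interior_top_p = (depth + 4) / wall

    # --- interior: inhomogeneous rejection sampling ----------------------
    p_lo, p_hi = interior_top_p, interior_bot_p
    if p_hi > p_lo:
        grid = np.linspace(p_lo, p_hi, 257)
        dens = np.array([archetype.density_profile(p) for p in grid])
        cell = (p_hi - p_lo) / 256 * wall * W  # tissue px per grid cell
        expected = dens[:-1] * cell
        n_target = int(round(expected.sum()))
        cdf = np.concatenate([[0.0], np.cumsum(expected)])
        cdf /= cdf[-1]
        placed_interior = 0
        for _ in range(n_target):
            ok = False
            for _attempt in range(MAX_ATTEMPTS_PER_BUNDLE):
                u = rng.uniform()
                idx = int(np.searchsorted(cdf, u) - 1)
                idx = min(max(idx, 0), 255)
                p = grid[idx] + rng.uniform() * (grid[idx + 1] - grid[idx])
                stage, area, aspect = _bundle_geometry(archetype, p, rng)
                stamp = render_bundle(stage, area, aspect, rng)
                r_c = frame.epidermis_row + p * wall
                r0 = int(round(r_c - stamp.shape[0] / 2))
                c0 = int(rng.integers(-stamp.shape[1] // 2,
                                      W - stamp.shape[1] // 2))
                meta = dict(stage=stage, target_area=area, target_aspect=aspect,
                            p=p, zone="interior")
                if canvas.try_place(stamp, r0, c0, meta, enforce=reject):
                    ok = True
                    placed_interior += 1
                    break
            if not ok and reject:
                if placed_interior < n_target // 4:
                    raise RuntimeError(
                        "could not place the minimum interior bundle count; "
                        "density_profile too high for non-overlap placement"
                    )
                break  # canvas saturated: accept fewer bundles

    if not canvas.params:
        raise RuntimeError("no bundles placed; density_profile yields zero bundles")

    # --- image formation --------------------------------------------------
    img = np.full((H, W), BACKGROUND_INTENSITY, dtype=np.float64)
    band_slice = slice(frame.epidermis_row, frame.pith_row)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (H, W)), 6.0)
    texture *= 0.03 / max(texture.std(), 1e-9)
    img[band_slice] = PARENCHYMA_INTENSITY + texture[band_slice]
    inst = canvas.mask
    shade = rng.uniform(-0.03, 0.03, len(canvas.params) + 1)
    shade[0] = 0.0
    img[inst > 0] = BUNDLE_INTENSITY + shade[inst[inst > 0]]
    img += rng.normal(0.0, NOISE_SIGMA, (H, W))
    np.clip(img, 0.0, 1.0, out=img)

    section = SectionImage(pixels=img.astype(np.float32))
    truth = GroundTruth(
        instance_mask=inst,
        params=tuple(canvas.params),
        tissue_frame=frame,
    )
    return section, truth
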