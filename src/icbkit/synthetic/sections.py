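"""Synthetic striatal hemisections: inhomogeneous point patterns over a
striatum-shaped outline.

The local intensity (cells/mm²) is a base level modulated by smooth
basis fields — a dorsolateral gradient, a focal lesion hotspot, and a
centro-medial-versus-dorsolateral shift — each RMS-normalised over the
template interior so that pattern weights are comparable.  Cells are a
Poisson process thinned against this intensity; right hemispheres are
mirror images of the template, and each section receives vertex jitter
plus a random placement (rotation, isometric scale, translation) for
the alignment stage to undo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from ..spatial import AP_LEVELS, ActivityMap, GridSpec, StriatalSection

PATTERN_NAMES = ("dorsolateral_gradient", "lesion_hotspot", "centromedial_shift")
TEMPLATE_RADIUS_UM = 2000.0


def default_outline(n_vertices: int = 64) -> np.ndarray:
    """Smooth striatum-like template outline (µm, left hemisphere,
    centred at the origin; dorsal = +y, lateral = -x)."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = TEMPLATE_RADIUS_UM * (
        1.0
        + 0.18 * np.cos(phi - 0.6)
        + 0.10 * np.cos(2 * phi + 1.0)
        - 0.06 * np.cos(3 * phi)
    )
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def default_lesion_polygon(n_vertices: int = 32) -> np.ndarray:
    """Circular dorsolateral lesion territory (µm, template frame)."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy, radius = -900.0, 900.0, 700.0
    return np.column_stack([cx + radius * np.cos(phi), cy + radius * np.sin(phi)])


def _raw_fields(x: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    u = np.asarray(x, float) / TEMPLATE_RADIUS_UM
    v = np.asarray(y, float) / TEMPLATE_RADIUS_UM
    dl = np.exp(-(((u + 0.5) ** 2) + (v - 0.5) ** 2) / (2 * 0.6**2))
    hot = np.exp(-(((u + 0.45) ** 2) + (v - 0.45) ** 2) / (2 * 0.22**2))
    cm = np.exp(-(((u - 0.45) ** 2) + (v + 0.1) ** 2) / (2 * 0.45**2)) - np.exp(
        -(((u + 0.5) ** 2) + (v - 0.5) ** 2) / (2 * 0.45**2)
    )
    return {"dorsolateral_gradient": dl, "lesion_hotspot": hot, "centromedial_shift": cm}


def _field_norms(outline: np.ndarray, n_grid: int = 80) -> dict[str, float]:
    lo = outline.min(axis=0)
    hi = outline.max(axis=0)
    gx = np.linspace(lo[0], hi[0], n_grid)
    gy = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(gx, gy)
    inside = contains_xy(Polygon(outline), X.ravel(), Y.ravel())
    fields = _raw_fields(X.ravel()[inside], Y.ravel()[inside])
    return {k: float(np.sqrt(np.mean(f**2))) for k, f in fields.items()}


def intensity(
    x: np.ndarray,
    y: np.ndarray,
    base: float,
    weights: dict[str, float],
    norms: dict[str, float],
) -> np.ndarray:
    """Local intensity in cells/mm² in the template frame (clipped at 0)."""
    mod = np.ones_like(np.asarray(x, float))
    fields = _raw_fields(x, y)
    for name, w in weights.items():
        if name not in fields:
            raise ValueError(f"unknown pattern {name!r}")
        if w:
            mod = mod + w * fields[name] / norms[name]
    return base * np.clip(mod, 0.0, None)


@dataclass
class SectionGenParams:
    outline_template: np.ndarray = field(default_factory=default_outline)
    base_intensity: float = 120.0  # cells/mm²
    pattern_weights: dict[str, float] = field(default_factory=dict)
    lesion_polygon: np.ndarray | None = None
    n_animals: int = 1
    levels_per_animal: int = 3
    hemispheres: int = 2
    jitter: float = 60.0  # µm vertex perturbation
    placement_rotation: float = 0.12  # rad, +- uniform
    placement_scale: float = 0.05  # +- uniform log-scale
    placement_shift: float = 200.0  # µm, +- uniform
    group: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.base_intensity < 0:
            raise ValueError("base_intensity must be >= 0")
        if Polygon(np.asarray(self.outline_template, float)).area <= 0:
            raise ValueError("degenerate outline template (area 0)")
        for name in self.pattern_weights:
            if name not in PATTERN_NAMES:
                raise ValueError(f"unknown pattern {name!r}")


def _sample_points(
    outline: np.ndarray,
    base: float,
    weights: dict[str, float],
    norms: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson point pattern by thinning against the intensity field."""
    if base == 0:
        return np.zeros((0, 2))
    poly = Polygon(outline)
    lo = outline.min(axis=0)
    hi = outline.max(axis=0)
    # upper bound on the modulated intensity over a probe grid
    gx = np.linspace(lo[0], hi[0], 60)
    gy = np.linspace(lo[1], hi[1], 60)
    X, Y = np.meshgrid(gx, gy)
    lam = intensity(X.ravel(), Y.ravel(), base, weights, norms)
    lam_max = float(lam.max()) * 1.1 + 1e-12
    bbox_mm2 = (hi[0] - lo[0]) * (hi[1] - lo[1]) / 1e6
    n = rng.poisson(lam_max * bbox_mm2)
    if n == 0:
        return np.zeros((0, 2))
    pts = rng.uniform(lo, hi, size=(n, 2))
    keep = contains_xy(poly, pts[:, 0], pts[:, 1])
    pts = pts[keep]
    lam_p = intensity(pts[:, 0], pts[:, 1], base, weights, norms)
    return pts[rng.random(len(pts)) < lam_p / lam_max]


def _smooth_jitter(outline: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency radial perturbation of the outline vertices."""
    if scale <= 0:
        return outline.copy()
    n = len(outline)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.normal(0.0, scale, size=3)
    k = np.arange(1, 4)
    theta = np.arctan2(outline[:, 1], outline[:, 0])
    radial = sum(a * np.cos(kk * theta + p) for a, kk, p in zip(amp, k, phase))
    r = np.hypot(outline[:, 0], outline[:, 1])
    factor = (r + radial) / np.where(r > 0, r, 1.0)
    return outline * factor[:, None]


def gen_sections(params: SectionGenParams) -> list[StriatalSection]:
    """Sections for ``n_animals`` x hemispheres x levels.

    Left/right outlines are mirror images up to jitter; each section is
    independently jittered, placed (random similarity transform), and
    populated with cells from the intensity field.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    template = np.asarray(params.outline_template, float)
    norms = _field_norms(template)
    lesion = (
        np.asarray(params.lesion_polygon, float)
        if params.lesion_polygon is not None
        else None
    )
    levels = AP_LEVELS[: params.levels_per_animal]
    hemis = ("left", "right")[: params.hemispheres]
    sections = []
    for a in range(params.n_animals):
        animal = f"{params.group or 'animal'}_{a:02d}"
        for level in levels:
            for hemi in hemis:
                out = _smooth_jitter(template, params.jitter, rng)
                cells = _sample_points(
                    out, params.base_intensity, params.pattern_weights, norms, rng
                )
                les = lesion.copy() if lesion is not None else None
                # mirror into the right hemisphere frame
                if hemi == "right":
                    out = out.copy()
                    out[:, 0] = -out[:, 0]
                    out = out[::-1]  # keep positive orientation
                    if cells.size:
                        cells = cells.copy()
                        cells[:, 0] = -cells[:, 0]
                    if les is not None:
                        les[:, 0] = -les[:, 0]
                        les = les[::-1]
                # random placement for the alignment stage to undo
                theta = rng.uniform(-params.placement_rotation, params.placement_rotation)
                scale = float(
                    np.exp(rng.uniform(-params.placement_scale, params.placement_scale))
                )
                shift = rng.uniform(-params.placement_shift, params.placement_shift, 2)
                c, s = math.cos(theta), math.sin(theta)
                R = scale * np.array([[c, -s], [s, c]])

                def place(pts):
                    return pts @ R.T + shift if pts is not None and len(pts) else pts

                sections.append(
                    StriatalSection(
                        animal=animal,
                        hemisphere=hemi,
                        level=level,
                        outline=place(out),
                        cells=place(cells) if cells.size else cells,
                        lesion=place(les) if les is not None else None,
                        group=params.group,
                        meta={"seed": params.seed},
                    )
                )
    return sections


# ---------------------------------------------------------------------------
# map-level planted cohorts (for pattern-recovery studies)
# ---------------------------------------------------------------------------


def pattern_basis(
    grid: GridSpec,
    outline: np.ndarray | None = None,
    names: tuple[str, ...] = PATTERN_NAMES,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal pixel-space versions of the planted patterns.

    The raw fields are evaluated at bin centres, masked to the outline,
    and Gram-Schmidt orthonormalised (unit L2 norm over all pixels).
    Returns (basis (k, n_pixels), mask (n_pixels,) bool).
    """
    outline = default_outline() if outline is None else np.asarray(outline, float)
    cx, cy = grid.centres()
    X, Y = np.meshgrid(cx, cy)
    mask = contains_xy(Polygon(outline), X.ravel(), Y.ravel())
    fields = _raw_fields(X.ravel(), Y.ravel())
    basis = []
    for name in names:
        f = np.where(mask, fields[name], 0.0)
        for b in basis:
            f = f - (f @ b) * b
        nrm = np.linalg.norm(f)
        if nrm <= 0:
            raise ValueError(f"pattern {name!r} vanishes on this grid")
        basis.append(f / nrm)
    return np.stack(basis), mask


def planted_map_cohort(
    n_sections: int,
    base_count: float,
    pattern_sds: tuple[float, ...],
    grid: GridSpec,
    outline: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """Activity maps with known planted covariance structure.

    Each map is Poisson(clip(base_count + sum_k c_k B_k, 0)) on the
    masked pixels with coefficients c_k ~ N(0, sd_k²) over the
    orthonormal basis.  The planted-variance:noise ratio of pattern k is
    sd_k² / (base_count * n_mask_pixels): the total variance the pattern
    contributes across the map against the summed per-pixel Poisson
    variance.

    Returns dict with ``maps``, ``coefficients``, ``basis``, ``mask``.
    """
    basis, mask = pattern_basis(grid, outline)
    k = len(pattern_sds)
    if k > basis.shape[0]:
        raise ValueError("more pattern sds than basis patterns")
    rng = np.random.default_rng(seed)
    coefs = rng.normal(0.0, np.asarray(pattern_sds), size=(n_sections, k))
    lam_base = np.where(mask, base_count, 0.0)
    maps = []
    for i in range(n_sections):
        lam = np.clip(lam_base + coefs[i] @ basis[:k], 0.0, None)
        counts = rng.poisson(lam).reshape(grid.n, grid.n)
        maps.append(
            ActivityMap(
                counts,
                grid,
                0,
                {"animal": f"synt_{i:03d}", "group": "planted", "hemisphere": "left",
                 "level": AP_LEVELS[0]},
            )
        )
    return {"maps": maps, "coefficients": coefs, "basis": basis[:k], "mask": mask}
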