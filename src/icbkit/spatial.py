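"""Spatial mapping of immunopositive cell distributions in striatal
sections.

Input per hemisection: cell x,y coordinates (µm), the traced striatal
outline polygon, an optional lesion (denervated-area) polygon, and
animal/hemisphere/level metadata.  The pipeline mirrors right
hemispheres into the left frame, registers every outline to a common
reference by a similarity transform (rotation, isometric scale,
translation), bins cells into a 75 x 75 histogram of 80 µm pixels, and
compares groups by difference maps and pixelwise two-sided Mann-Whitney
tests with Benjamini-Hochberg control at alpha = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from . import stats as _st

GRID_N = 75
BIN_UM = 80.0

HEMISPHERES = ("left", "right")
AP_LEVELS = (1.08, 0.72, 0.12)  # mm anterior to bregma


class SectionGeometryError(ValueError):
    pass


@dataclass
class StriatalSection:
    animal: str
    hemisphere: str  # left | right
    level: float  # AP, mm
    outline: np.ndarray  # (n, 2) µm
    cells: np.ndarray  # (m, 2) µm
    lesion: np.ndarray | None = None  # (k, 2) µm or None
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outline = np.asarray(self.outline, dtype=float)
        self.cells = np.asarray(self.cells, dtype=float).reshape(-1, 2)
        if self.lesion is not None:
            self.lesion = np.asarray(self.lesion, dtype=float)
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.outline.shape[0] < 3 or self.outline_polygon().area <= 0:
            raise SectionGeometryError("degenerate outline (area 0)")

    def outline_polygon(self) -> Polygon:
        return Polygon(self.outline)

    def lesion_polygon(self) -> Polygon | None:
        return Polygon(self.lesion) if self.lesion is not None else None

    def validate_cells(self, tol_um: float = 5.0) -> int:
        """Number of cells farther than ``tol_um`` outside the outline."""
        if self.cells.size == 0:
            return 0
        poly = self.outline_polygon()
        bad = 0
        for x, y in self.cells:
            if poly.distance(Point(x, y)) > tol_um:
                bad += 1
        return bad


# ---------------------------------------------------------------------------
# geometry measures
# ---------------------------------------------------------------------------


def lesion_extent(section: StriatalSection) -> float:
    """Percentage of the outline area left intact by the lesion
    polygon (100 when no lesion was traced)."""
    les = section.lesion_polygon()
    if les is None:
        return 100.0
    total = section.outline_polygon().area
    return 100.0 * (total - les.intersection(section.outline_polygon()).area) / total


def cell_density(section: StriatalSection, region: str = "total") -> float:
    """Cells per mm² inside the chosen region (``total`` outline or the
    ``lesioned`` polygon)."""
    if region == "total":
        poly = section.outline_polygon()
    elif region == "lesioned":
        poly = section.lesion_polygon()
        if poly is None:
            raise ValueError("section has no lesion polygon")
    else:
        raise ValueError(f"unknown region {region!r}")
    if section.cells.size == 0:
        return 0.0
    from shapely import contains_xy

    inside = contains_xy(poly, section.cells[:, 0], section.cells[:, 1])
    area_mm2 = poly.area / 1e6
    return float(np.count_nonzero(inside)) / area_mm2


def density_per_animal(sections: list[StriatalSection], region: str = "total"):
    """Densities averaged bilaterally over the rostrocaudal levels."""
    import pandas as pd

    rows = []
    for s in sections:
        if region == "lesioned" and s.lesion is None:
            continue
        rows.append(
            {
                "animal": s.animal,
                "group": s.group,
                "density": cell_density(s, region),
            }
        )
    df = pd.DataFrame(rows)
    return df.groupby(["animal", "group"], as_index=False)["density"].mean()


# ---------------------------------------------------------------------------
# hemisphere flipping and alignment
# ---------------------------------------------------------------------------


def flip_right(section: StriatalSection, midline_x: float = 0.0) -> StriatalSection:
    """Mirror a right hemisection into the left frame (x -> -x about the
    midline); left sections pass through unchanged.  Applying the flip
    twice recovers the original coordinates."""
    if section.hemisphere == "left":
        return section

    def mirror(a):
        if a is None:
            return None
        out = a.copy()
        out[:, 0] = 2 * midline_x - out[:, 0]
        return out

    return replace(
        section,
        hemisphere="left",
        outline=mirror(section.outline),
        cells=mirror(section.cells),
        lesion=mirror(section.lesion),
        meta={**section.meta, "flipped": True},
    )


@dataclass(frozen=True)
class AlignmentTransform:
    rotation: float  # radians
    scale: float  # isometric, > 0
    translation: tuple[float, float]  # µm
    residual: float = np.nan  # symmetric mean boundary distance, µm

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        return pts @ self.matrix().T + np.asarray(self.translation)

    def inverse(self) -> "AlignmentTransform":
        inv_rot = -self.rotation
        inv_scale = 1.0 / self.scale
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        tx, ty = self.translation
        it = inv_scale * np.array([[c, -s], [s, c]]) @ np.array([-tx, -ty])
        return AlignmentTransform(inv_rot, inv_scale, (float(it[0]), float(it[1])))


def _resample_boundary(outline: np.ndarray, n: int = 200) -> np.ndarray:
    """Evenly spaced points along the closed outline."""
    closed = np.vstack([outline, outline[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n, endpoint=False)
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(targets, arc, closed[:, d])
    return out


def _boundary_distance(a: np.ndarray, b: np.ndarray) -> float:
    ta, tb = cKDTree(a), cKDTree(b)
    return 0.5 * (tb.query(a)[0].mean() + ta.query(b)[0].mean())


def _principal_angle(pts: np.ndarray) -> float:
    c = pts - pts.mean(axis=0)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    ax = v[:, np.argmax(w)]
    return float(np.arctan2(ax[1], ax[0]))


def align_section(
    section: StriatalSection,
    reference_outline: np.ndarray,
    refine: bool = True,
    n_boundary: int = 200,
) -> AlignmentTransform:
    """Similarity transform registering the section outline onto the
    reference.

    Initialised in closed form from centroids, sqrt-area scale, and the
    principal axis (180-degree ambiguity resolved by residual), then
    refined by Nelder-Mead on the symmetric mean boundary distance.  If
    refinement fails to improve the closed-form initialisation, the
    latter is returned with a warning.
    """
    src = _resample_boundary(np.asarray(section.outline, float), n_boundary)
    ref = _resample_boundary(np.asarray(reference_outline, float), n_boundary)
    src_poly = Polygon(section.outline)
    ref_poly = Polygon(reference_outline)

    scale0 = np.sqrt(ref_poly.area / src_poly.area)
    c_src = np.asarray(src_poly.centroid.coords[0])
    c_ref = np.asarray(ref_poly.centroid.coords[0])

    def build(theta, log_s, tx, ty) -> AlignmentTransform:
        s = float(np.exp(log_s))
        c, sn = np.cos(theta), np.sin(theta)
        rot = s * np.array([[c, -sn], [sn, c]])
        t = c_ref - rot @ c_src + np.array([tx, ty])
        return AlignmentTransform(float(theta), s, (float(t[0]), float(t[1])))

    def cost(params) -> float:
        tr = build(*params)
        return _boundary_distance(tr.apply(src), ref)

    theta0 = _principal_angle(ref) - _principal_angle(src)
    cands = [
        (t, np.log(scale0), 0.0, 0.0)
        for t in (theta0, theta0 + np.pi)
    ]
    x0 = min(cands, key=cost)
    best = np.asarray(x0)
    best_cost = cost(x0)
    if refine and best_cost > 1e-9:
        res = minimize(
            cost,
            best,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-3, "maxiter": 400},
        )
        if res.fun < best_cost:
            best, best_cost = res.x, float(res.fun)
        else:  # pragma: no cover - optimizer regression is rare
            warnings.warn(
                "alignment refinement did not improve the closed-form "
                "initialisation; using centroid/area/principal-axis fit"
            )
    tr = build(*best)
    return replace(tr, residual=float(best_cost))


def apply_alignment(section: StriatalSection, tr: AlignmentTransform) -> StriatalSection:
    return replace(
        section,
        outline=tr.apply(section.outline),
        cells=tr.apply(section.cells) if section.cells.size else section.cells,
        lesion=tr.apply(section.lesion) if section.lesion is not None else None,
        meta={**section.meta, "aligned": True, "residual_um": tr.residual},
    )


def _resample_polar(outline: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Radius at given angles about the outline centroid (assumes a
    star-shaped outline, which traced striatal hemisections are)."""
    centre = np.asarray(Polygon(outline).centroid.coords[0])
    rel = _resample_boundary(outline, 4 * angles.size) - centre
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(theta)
    theta, radius = theta[order], np.hypot(rel[:, 0], rel[:, 1])[order]
    theta = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    radius = np.tile(radius, 3)
    return np.interp(angles, theta, radius)


def mean_reference_outline(
    sections: list[StriatalSection], n_boundary: int = 200
) -> np.ndarray:
    """Reference outline: the angular-mean of aligned section outlines.

    Sections are registered to the first outline, re-expressed as a
    radius profile about the common centroid, and averaged on a shared
    angular grid — immune to the arbitrary starting vertex of each
    trace.
    """
    ref0 = np.asarray(sections[0].outline, float)
    angles = np.linspace(-np.pi, np.pi, n_boundary, endpoint=False)
    radii = []
    for s in sections:
        tr = align_section(s, ref0, refine=False, n_boundary=n_boundary)
        radii.append(_resample_polar(tr.apply(s.outline), angles))
    mean_r = np.mean(radii, axis=0)
    centre = np.asarray(Polygon(ref0).centroid.coords[0])
    return centre + np.column_stack(
        [mean_r * np.cos(angles), mean_r * np.sin(angles)]
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Square histogram grid; the reference outline's bounding box is
    centred in the n x n window of ``bin_um`` pixels, bins half-open
    [lo, hi)."""

    n: int = GRID_N
    bin_um: float = BIN_UM
    origin: tuple[float, float] = (0.0, 0.0)  # lower-left corner, µm

    @classmethod
    def from_reference(
        cls, reference_outline: np.ndarray, n: int = GRID_N, bin_um: float = BIN_UM
    ) -> "GridSpec":
        ref = np.asarray(reference_outline, float)
        lo = ref.min(axis=0)
        hi = ref.max(axis=0)
        centre = (lo + hi) / 2
        half = n * bin_um / 2
        return cls(n, bin_um, (float(centre[0] - half), float(centre[1] - half)))

    @property
    def n_pixels(self) -> int:
        return self.n * self.n

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        ex = self.origin[0] + self.bin_um * np.arange(self.n + 1)
        ey = self.origin[1] + self.bin_um * np.arange(self.n + 1)
        return ex, ey

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        ex, ey = self.edges()
        return (ex[:-1] + self.bin_um / 2, ey[:-1] + self.bin_um / 2)


@dataclass
class ActivityMap:
    counts: np.ndarray  # (n, n) int, indexed [iy, ix]
    grid: GridSpec
    n_outside: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def flatten(self) -> np.ndarray:
        return self.counts.reshape(-1).astype(float)


def bin_cells(section: StriatalSection, grid: GridSpec) -> ActivityMap:
    """75 x 75 cell-count histogram of an aligned section; cells landing
    outside the grid are counted separately so that histogram mass plus
    the outside count always equals the number of cells."""
    ex, ey = grid.edges()
    if section.cells.size == 0:
        counts = np.zeros((grid.n, grid.n), dtype=int)
        return ActivityMap(counts, grid, 0, _map_meta(section))
    x, y = section.cells[:, 0], section.cells[:, 1]
    inside = (x >= ex[0]) & (x < ex[-1]) & (y >= ey[0]) & (y < ey[-1])
    ix = np.floor((x[inside] - ex[0]) / grid.bin_um).astype(int)
    iy = np.floor((y[inside] - ey[0]) / grid.bin_um).astype(int)
    counts = np.zeros((grid.n, grid.n), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    return ActivityMap(
        counts, grid, int(np.count_nonzero(~inside)), _map_meta(section)
    )


def _map_meta(section: StriatalSection) -> dict:
    meta = {
        "animal": section.animal,
        "group": section.group,
        "hemisphere": section.hemisphere,
        "level": section.level,
    }
    for key in ("lesion", "treatment"):
        if key in section.meta:
            meta[key] = section.meta[key]
    return meta


def striatum_mask(reference_outline: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Boolean (n, n) mask of bins whose centre lies inside the
    reference outline."""
    from shapely import contains_xy

    cx, cy = grid.centres()
    gx, gy = np.meshgrid(cx, cy)  # [iy, ix]
    poly = Polygon(np.asarray(reference_outline, float))
    return contains_xy(poly, gx.ravel(), gy.ravel()).reshape(grid.n, grid.n)


def build_maps(
    sections: list[StriatalSection],
    reference_outline: np.ndarray | None = None,
    grid: GridSpec | None = None,
    refine: bool = True,
) -> tuple[list[ActivityMap], np.ndarray, GridSpec]:
    """Full mapping pipeline: flip right hemisections, align each to the
    reference, and bin.  Returns (maps, reference outline, grid)."""
    flipped = [flip_right(s) for s in sections]
    if reference_outline is None:
        reference_outline = mean_reference_outline(flipped)
    if grid is None:
        grid = GridSpec.from_reference(reference_outline)
    maps = []
    for s in flipped:
        tr = align_section(s, reference_outline, refine=refine)
        maps.append(bin_cells(apply_alignment(s, tr), grid))
    return maps, reference_outline, grid


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def group_difference_map(
    maps_a: list[ActivityMap], maps_b: list[ActivityMap], mask: np.ndarray
) -> np.ndarray:
    """mean(A) - mean(B) per bin over the striatum mask (NaN outside)."""
    mean_a = np.mean([m.counts for m in maps_a], axis=0)
    mean_b = np.mean([m.counts for m in maps_b], axis=0)
    diff = mean_a - mean_b
    out = np.where(mask, diff, np.nan)
    return out


@dataclass
class StatMap:
    pvalues: np.ndarray  # (n, n), NaN where untested
    significant: np.ndarray  # (n, n) bool, BH-controlled
    direction: np.ndarray  # (n, n) sign of mean(A) - mean(B)
    alpha: float
    cutoff: float
    n_tested: int


def _mwu_pixelwise(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Mann-Whitney p per column.

    A: (n1, m), B: (n2, m).  Columns without ties and with min(n) <= 8
    use the exact U distribution; tied columns use the tie-corrected
    normal approximation with continuity correction.  All-tied columns
    get p = 1.
    """
    from scipy.stats import norm, rankdata

    n1, m = A.shape
    n2 = B.shape[0]
    pooled = np.vstack([A, B])
    ranks = rankdata(pooled, axis=0)
    u1 = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2

    # tie correction per column
    srt = np.sort(pooled, axis=0)
    n = n1 + n2
    tie = np.zeros(m)
    for col in range(m):
        _, counts = np.unique(srt[:, col], return_counts=True)
        tie[col] = np.sum(counts.astype(float) ** 3 - counts)

    p = np.ones(m)
    exact_ok = (tie == 0) & (min(n1, n2) <= 8)
    if exact_ok.any():
        cdf = np.asarray(_st.exact_u_cdf(n1, n2))
        u_min = np.minimum(u1[exact_ok], n1 * n2 - u1[exact_ok]).astype(int)
        p[exact_ok] = np.minimum(1.0, 2 * cdf[u_min])
    approx = ~exact_ok
    if approx.any():
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie[approx] / (n * (n - 1)))
        mu = n1 * n2 / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(u1[approx] - mu) - 0.5) / np.sqrt(sigma2)
        z = np.where(sigma2 > 0, np.maximum(z, 0.0), 0.0)
        pa = np.where(sigma2 > 0, 2 * norm.sf(z), 1.0)
        p[approx] = np.minimum(pa, 1.0)
    return p


def pixelwise_test(
    maps_a: list[ActivityMap],
    maps_b: list[ActivityMap],
    mask: np.ndarray,
    alpha: float = 0.01,
) -> StatMap:
    """Per-pixel two-sided Mann-Whitney comparison of two groups of
    activity maps with BH control at ``alpha`` over the tested bins.

    Tested bins are those inside the striatum mask with nonzero
    variance across the pooled maps; all-tied bins are reported p = 1
    and excluded from the BH universe.
    """
    if len(maps_a) < 3 or len(maps_b) < 3:
        raise ValueError("need at least 3 maps per group")
    grid = maps_a[0].grid
    A = np.stack([m.counts.reshape(-1) for m in maps_a]).astype(float)
    B = np.stack([m.counts.reshape(-1) for m in maps_b]).astype(float)
    flat_mask = mask.reshape(-1)
    pooled = np.vstack([A, B])
    nonzero_var = pooled.std(axis=0) > 0
    tested = flat_mask & nonzero_var

    pvals = np.full(grid.n_pixels, np.nan)
    if tested.any():
        pvals[tested] = _mwu_pixelwise(A[:, tested], B[:, tested])
        cutoff, rej = _st.bh_adjust(pvals[tested], alpha)
    else:
        cutoff, rej = 0.0, np.zeros(0, dtype=bool)
    sig = np.zeros(grid.n_pixels, dtype=bool)
    sig[np.nonzero(tested)[0]] = rej
    direction = np.sign(A.mean(axis=0) - B.mean(axis=0))
    return StatMap(
        pvalues=pvals.reshape(grid.n, grid.n),
        significant=sig.reshape(grid.n, grid.n),
        direction=direction.reshape(grid.n, grid.n),
        alpha=alpha,
        cutoff=cutoff,
        n_tested=int(np.count_nonzero(tested)),
    )
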