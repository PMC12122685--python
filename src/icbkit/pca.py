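"""Principal-component decomposition of stacked activity maps.

Every aligned hemisection contributes one row (its flattened 75 x 75
histogram, 5625 pixels); PCA of the column-mean-centred matrix yields
orthonormal pixel patterns ("covariance patterns") ordered by explained
variance.  The projection of a section's centred map onto pattern k is
its PC-k coefficient; each centred map is exactly the coefficient-
weighted sum of all patterns, so the per-animal mean coefficient
indexes how strongly a covariance pattern is expressed in that animal.

Centring is per column with no variance scaling: all pixels carry the
same units (cell counts) and scaling would inflate the empty margins of
the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import ActivityMap, GridSpec


@dataclass
class SectionMatrix:
    data: np.ndarray  # (n_sections, n_pixels)
    meta: pd.DataFrame  # one row per section: animal, group, hemisphere, level
    grid: GridSpec

    def __post_init__(self):
        if self.data.shape[0] != len(self.meta):
            raise ValueError("metadata rows must match matrix rows")
        if self.data.shape[1] != self.grid.n_pixels:
            raise ValueError(
                f"expected {self.grid.n_pixels} pixel columns, got {self.data.shape[1]}"
            )


def build_matrix(maps: list[ActivityMap]) -> SectionMatrix:
    """Stack flattened maps (row-major) with their metadata.  Masked-out
    pixels stay as zero-count columns; they carry no variance and hence
    receive zero loadings."""
    if not maps:
        raise ValueError("no maps supplied")
    data = np.stack([m.flatten() for m in maps])
    meta = pd.DataFrame([m.meta for m in maps])
    return SectionMatrix(data, meta, maps[0].grid)


def unflatten(row: np.ndarray, grid: GridSpec) -> np.ndarray:
    return np.asarray(row, float).reshape(grid.n, grid.n)


@dataclass
class PCModel:
    components: np.ndarray  # (k, n_pixels), orthonormal rows
    explained_variance: np.ndarray  # (k,)
    explained_variance_ratio: np.ndarray  # (k,)
    coefficients: np.ndarray  # (n_sections, k)
    column_means: np.ndarray  # (n_pixels,)
    meta: pd.DataFrame
    grid: GridSpec
    extra: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(matrix: SectionMatrix) -> PCModel:
    """Full-rank PCA by SVD of the column-centred section matrix.

    Components are unit-norm and ordered by explained variance; the
    coefficient of section i on component k is the inner product of its
    centred row with component k (= U_ik * s_k).  A rank-zero matrix
    (all rows identical) yields a model with zero components and a
    warning.
    """
    if matrix.data.shape[0] < 2:
        raise ValueError("need at least 2 sections")
    mu = matrix.data.mean(axis=0)
    X = matrix.data - mu
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    if not keep.any():
        warnings.warn("matrix has rank 0 (all rows identical); no components")
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    var = s**2 / (n - 1)
    total_var = float(X.var(axis=0, ddof=1).sum())
    evr = var / total_var if total_var > 0 else np.zeros_like(var)
    return PCModel(
        components=Vt,
        explained_variance=var,
        explained_variance_ratio=evr,
        coefficients=U * s,
        column_means=mu,
        meta=matrix.meta.copy(),
        grid=matrix.grid,
    )


def reconstruct(model: PCModel, rank: int | None = None) -> np.ndarray:
    """Rows rebuilt from the first ``rank`` components (all by default);
    with full rank this reproduces the original matrix to numerical
    precision."""
    k = model.n_components if rank is None else min(rank, model.n_components)
    return model.coefficients[:, :k] @ model.components[:k] + model.column_means


def sign_align(
    model: PCModel, reference_patterns: np.ndarray | None = None
) -> PCModel:
    """Fix the arbitrary PCA sign convention.

    With reference patterns (k', n_pixels), each component is flipped so
    its inner product with the matching reference is non-negative; by
    default the pixel of maximal absolute loading is made positive.
    Coefficients flip together with their component, leaving every
    reconstruction invariant.  The operation is idempotent.
    """
    comps = model.components.copy()
    coefs = model.coefficients.copy()
    for k in range(comps.shape[0]):
        if reference_patterns is not None and k < reference_patterns.shape[0]:
            dot = float(comps[k] @ reference_patterns[k])
            flip = dot < 0
        else:
            flip = comps[k, np.argmax(np.abs(comps[k]))] < 0
        if flip:
            comps[k] = -comps[k]
            coefs[:, k] = -coefs[:, k]
    return PCModel(
        comps,
        model.explained_variance.copy(),
        model.explained_variance_ratio.copy(),
        coefs,
        model.column_means.copy(),
        model.meta.copy(),
        model.grid,
        dict(model.extra),
    )


def coefficient_table(model: PCModel, n_components: int = 3) -> pd.DataFrame:
    """Long-form per-section coefficients for the leading components."""
    k = min(n_components, model.n_components)
    table = model.meta.copy()
    for j in range(k):
        table[f"pc{j + 1}"] = model.coefficients[:, j]
    return table


def pattern_expression(
    model: PCModel,
    n_components: int = 3,
    treatment_col: str = "treatment",
    lesion_col: str = "lesion",
) -> dict:
    """Per-animal mean coefficients and their two-factor comparison.

    Section coefficients are averaged within animal (sections are
    repeated measures of one brain), then each leading component's
    per-animal coefficient is submitted to a treatment x lesion ANOVA
    with pooled-or-within Tukey contrasts (see
    :func:`icbkit.stats.posthoc_with_pooling`).
    """
    from . import stats as _st

    table = coefficient_table(model, n_components)
    group_cols = ["animal"]
    for col in (treatment_col, lesion_col):
        if col in table.columns:
            group_cols.append(col)
        elif "group" in table.columns and col not in table.columns:
            pass
    pc_cols = [c for c in table.columns if c.startswith("pc")]
    per_animal = table.groupby(group_cols, as_index=False)[pc_cols].mean()
    comparisons = {}
    if treatment_col in per_animal.columns and lesion_col in per_animal.columns:
        for pc in pc_cols:
            try:
                comparisons[pc] = _st.posthoc_with_pooling(
                    per_animal[pc], per_animal[treatment_col],
                    per_animal[lesion_col],
                )
            except ValueError:
                # design too small for the two-factor comparison (e.g.
                # one animal per cell leaves no residual df)
                comparisons[pc] = None
    return {"per_animal": per_animal, "comparisons": comparisons}
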