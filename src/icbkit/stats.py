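"""Inferential primitives used throughout the pipelines.

These are implemented from first principles (sums of squares, rank
statistics, exact enumeration) rather than delegated to a stats library,
so that every downstream analysis in this package is self-contained and
each routine can be validated against an independent oracle.  SciPy is
used only for reference distributions (F, chi-square, normal,
studentized range).

Conventions
-----------
* All tests are two-sided unless stated otherwise.
* The two-factor ANOVA uses Type-III sums of squares with sum-to-zero
  contrasts, which is well defined for unbalanced cells.
* Post-hoc treatment contrasts follow an explicit pooling rule: when
  neither the second factor nor the interaction is significant, the
  levels of that factor are pooled before pairwise comparison;
  otherwise contrasts are computed within each of its levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dist


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    name: str
    statistic: float
    df: tuple
    pvalue: float
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        df = ",".join(f"{d:g}" for d in self.df)
        return f"{self.name}({df}) = {self.statistic:.4g}, p = {self.pvalue:.4g}"


# ---------------------------------------------------------------------------
# Two-factor ANOVA (Type III, sum-to-zero contrasts)
# ---------------------------------------------------------------------------


def _effect_codes(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    k = len(levels)
    cols = np.zeros((labels.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (labels == lev).astype(float)
    last = labels == levels[-1]
    cols[last, :] = -1.0
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_factor_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, TestResult]:
    """Two-way fixed-effects ANOVA with interaction.

    Returns a dict with keys ``"A"``, ``"B"``, ``"A:B"`` and
    ``"residual"`` (the latter carrying MSE and df in ``extra``).

    Raises
    ------
    ValueError
        If any cell of the A x B cross is empty (named in the message),
        or no residual degrees of freedom remain.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    la = sorted(pd.unique(fa).tolist())
    lb = sorted(pd.unique(fb).tolist())
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("each factor needs at least two levels")
    for a in la:
        for b in lb:
            if not np.any((fa == a) & (fb == b)):
                raise ValueError(f"empty design cell: A={a!r}, B={b!r}")

    Xa = _effect_codes(fa, la)
    Xb = _effect_codes(fb, lb)
    Xab = np.einsum("ij,ik->ijk", Xa, Xb).reshape(y.size, -1)
    one = np.ones((y.size, 1))
    full = np.hstack([one, Xa, Xb, Xab])

    n = y.size
    df_a, df_b = len(la) - 1, len(lb) - 1
    df_ab = df_a * df_b
    df_res = n - (1 + df_a + df_b + df_ab)
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    rss_full = _rss(full, y)
    mse = rss_full / df_res
    # a numerically perfect fit (e.g. exactly additive noiseless data)
    # leaves only rounding error in the residual; treat it as zero
    ss_total = float(((y - y.mean()) ** 2).sum())
    degenerate = mse <= 1e-12 * (ss_total + 1.0)

    out: dict[str, TestResult] = {}
    parts = {
        "A": (np.hstack([one, Xb, Xab]), df_a),
        "B": (np.hstack([one, Xa, Xab]), df_b),
        "A:B": (np.hstack([one, Xa, Xb]), df_ab),
    }
    for key, (reduced, df_eff) in parts.items():
        ss = max(_rss(reduced, y) - rss_full, 0.0)
        if degenerate:
            f, p = 0.0, 1.0
        else:
            f = (ss / df_eff) / mse
            p = float(_dist.f.sf(f, df_eff, df_res))
        out[key] = TestResult(f"F[{key}]", f, (df_eff, df_res), p, {"ss": ss})
    out["residual"] = TestResult(
        "residual", np.nan, (df_res,), np.nan, {"mse": mse, "ss": rss_full}
    )
    return out


# ---------------------------------------------------------------------------
# Tukey HSD (Tukey-Kramer for unbalanced groups)
# ---------------------------------------------------------------------------


def tukey_hsd(
    values: Sequence[float],
    groups: Sequence,
    mse: float | None = None,
    df_error: int | None = None,
) -> pd.DataFrame:
    """All pairwise contrasts with studentized-range adjusted p-values.

    ``mse``/``df_error`` default to the pooled within-group variance of
    the supplied data; pass the error term of a surrounding ANOVA to
    honour a larger model.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = {lev: y[g == lev] for lev in levels}
    if mse is None or df_error is None:
        df_error = y.size - len(levels)
        if df_error < 1:
            raise ValueError("no error degrees of freedom")
        mse = sum(
            float(((s - s.mean()) ** 2).sum()) for s in samples.values()
        ) / df_error
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            sa, sb = samples[a], samples[b]
            diff = float(sa.mean() - sb.mean())
            se = np.sqrt(mse / 2 * (1 / sa.size + 1 / sb.size))
            q = abs(diff) / se if se > 0 else 0.0
            p = float(_dist.studentized_range.sf(q, k, df_error)) if se > 0 else 1.0
            rows.append(
                {"group1": a, "group2": b, "diff": diff, "q": q, "p_adj": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def posthoc_with_pooling(
    values: Sequence[float],
    treatment: Sequence,
    lesion: Sequence,
    alpha: float = 0.05,
) -> dict:
    """Treatment contrasts honouring the pooling rule.

    Runs the two-factor ANOVA (A = treatment, B = lesion).  If neither
    the lesion main effect nor the interaction reaches ``alpha``, sham
    and lesioned animals are pooled within each treatment arm before
    the Tukey comparison; otherwise contrasts are computed within each
    lesion level.  The branch taken is reported.
    """
    anova = two_factor_anova(values, treatment, lesion)
    mse = anova["residual"].extra["mse"]
    dfe = int(anova["residual"].df[0])
    pooled = anova["B"].pvalue > alpha and anova["A:B"].pvalue > alpha
    y = np.asarray(values, dtype=float)
    tr = np.asarray(treatment)
    le = np.asarray(lesion)
    if pooled:
        tables = {"pooled": tukey_hsd(y, tr, mse=mse, df_error=dfe)}
    else:
        tables = {
            str(lev): tukey_hsd(y[le == lev], tr[le == lev], mse=mse, df_error=dfe)
            for lev in sorted(pd.unique(le).tolist())
        }
    return {"anova": anova, "pooled": pooled, "contrasts": tables}


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's test
# ---------------------------------------------------------------------------


def _ranks_with_ties(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks and the tie-correction term sum(t^3 - t)."""
    r = _dist.rankdata(x)
    _, counts = np.unique(x, return_counts=True)
    tie = float(np.sum(counts.astype(float) ** 3 - counts))
    return r, tie


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank-based one-way test with tie correction (chi-square p)."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks, tie = _ranks_with_ties(pooled)
    h = 0.0
    start = 0
    for s in samples:
        rs = ranks[start : start + s.size]
        h += rs.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    denom = 1.0 - tie / (n**3 - n) if n > 1 else 1.0
    if denom <= 0:  # all observations identical
        return TestResult("KW", 0.0, (len(samples) - 1,), 1.0)
    h /= denom
    df = len(samples) - 1
    return TestResult("KW", float(h), (df,), float(_dist.chi2.sf(h, df)))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after Kruskal-Wallis."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None else list(range(len(samples)))
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks, tie = _ranks_with_ties(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + s.size].mean())
        sizes.append(s.size)
        start += s.size
    var_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1)) if n > 1 else 0.0
    rows = []
    k = len(samples)
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * float(_dist.norm.sf(abs(z)))
            rows.append({"group1": labels[i], "group2": labels[j], "z": z, "p": p})
    table = pd.DataFrame(rows)
    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * m, 1.0)
    elif adjust == "bh":
        table["p_adj"] = bh_qvalues(table["p"].to_numpy())
    elif adjust == "none":
        table["p_adj"] = table["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of U via polynomial (Gaussian binomial) product."""
    # coefficient generating function: prod_{i=1..n1} (1-x^(n2+i))/(1-x^i)
    poly = np.array([1.0])
    for i in range(1, n1 + 1):
        # multiply by (1 + x^i + x^{2i} + ... ) up to needed degree, then
        # subtract the tail: implemented as repeated convolution with
        # sparse (1 - x^{n2+i}) / (1 - x^i)
        num = np.zeros(n2 + i + 1)
        num[0], num[n2 + i] = 1.0, -1.0
        poly = np.convolve(poly, num)
        # divide by (1 - x^i): cumulative sum with stride i
        q = poly.copy()
        for k in range(i, q.size):
            q[k] += q[k - i]
        poly = q[: n1 * n2 + 1]
    total = poly.sum()
    return poly / total


@lru_cache(maxsize=None)
def exact_u_cdf(n1: int, n2: int) -> tuple:
    pmf = _exact_u_pmf(n1, n2)
    return tuple(np.cumsum(pmf))


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses exact enumeration when min(n) <= 8 and the
    pooled data carry no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks, tie = _ranks_with_ties(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u2 = n1 * n2 - u1
    has_ties = tie > 0

    if mode not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = (mode == "exact") or (
        mode == "auto" and min(n1, n2) <= 8 and not has_ties
    )
    if use_exact and has_ties:
        raise ValueError("exact mode is undefined with ties")

    if use_exact:
        cdf = exact_u_cdf(n1, n2)
        u_min = int(round(min(u1, u2)))
        p = min(1.0, 2 * cdf[u_min])
        return TestResult("U", u1, (n1, n2), float(p), {"method": "exact"})

    n = n1 + n2
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if sigma2 <= 0:  # all observations tied
        return TestResult("U", u1, (n1, n2), 1.0, {"method": "approx"})
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2 * float(_dist.norm.sf(z))
    return TestResult("U", u1, (n1, n2), min(p, 1.0), {"method": "approx"})


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(pvals: Sequence[float], alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Step-up FDR control.

    Returns ``(cutoff, mask)`` where ``cutoff`` is the largest ordered
    p(i) with p(i) <= (i/m) * alpha (0.0 if none) and ``mask`` flags
    p <= cutoff.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1) / m)
    ok = p[order] <= thresh
    if not ok.any():
        return 0.0, np.zeros(m, dtype=bool)
    cutoff = float(p[order][np.nonzero(ok)[0][-1]])
    return cutoff, p <= cutoff


def bh_qvalues(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
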