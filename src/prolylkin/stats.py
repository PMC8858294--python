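"""Outlier-robust correlation statistics.

The variant library pairs quantities whose scales differ by orders of
magnitude (dissociation constants, enthalpies, activities) and is small
(n of 8-11), so the analysis leans on rank statistics and on depth-based
outlier screening rather than on moment-based tools:

* Tukey halfspace depth, computed exactly in 2D by an angular sweep;
* a bagplot (bivariate boxplot): the "bag" is the deepest region holding
  at least half the points, the "fence" is the bag inflated threefold
  about the depth median, points beyond the fence are outliers;
* Spearman rank correlation with exact permutation p-values for small n
  (full-distribution dynamic programming without ties, enumeration with
  ties at n <= 7) and the asymptotic approximation otherwise;
* ordinary least squares with pointwise confidence bands;
* centred/scaled PCA with a deterministic sign convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scipy.stats import rankdata, spearmanr

__all__ = [
    "PairedObservations",
    "BagplotResult",
    "CorrelationResult",
    "halfspace_depth",
    "bagplot_outliers",
    "spearman",
    "linear_fit_ci",
    "pca_scores",
]


@dataclass(frozen=True)
class PairedObservations:
    """Labelled (x, y) pairs; entries with a missing coordinate are dropped
    by :meth:`complete` before any analysis."""

    labels: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        labels = tuple(str(v) for v in self.labels)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "labels", labels)
        if not (len(labels) == x.size == y.size):
            raise ValueError("labels, x and y must have equal lengths")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, x: str, y: str, label: str = "variant"):
        return cls(tuple(df[label]), df[x].to_numpy(), df[y].to_numpy())

    def complete(self) -> "PairedObservations":
        """Drop pairs where either coordinate is missing."""
        mask = np.isfinite(self.x) & np.isfinite(self.y)
        return PairedObservations(
            tuple(l for l, m in zip(self.labels, mask) if m),
            self.x[mask],
            self.y[mask],
        )

    def drop(self, labels_to_drop) -> "PairedObservations":
        drop = set(labels_to_drop)
        keep = [i for i, l in enumerate(self.labels) if l not in drop]
        return PairedObservations(
            tuple(self.labels[i] for i in keep), self.x[keep], self.y[keep]
        )

    @property
    def n(self) -> int:
        return len(self.labels)


def halfspace_depth(point, cloud) -> int:
    """Exact 2D Tukey halfspace depth.

    The depth of ``point`` is the minimum, over all closed halfplanes whose
    boundary passes through the point, of the number of cloud points in the
    halfplane.  The minimizing direction can always be taken perpendicular
    to some point-to-cloud vector, so an angular sweep over those critical
    directions (evaluated on and just off each boundary) is exact.  Cloud
    points coincident with ``point`` lie on every boundary and always
    count.  All-collinear clouds are handled by the same sweep.
    """
    p = np.asarray(point, dtype=float)
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("cloud must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError("need at least 3 cloud points")
    diff = pts - p
    r = np.hypot(diff[:, 0], diff[:, 1])
    coincident = int(np.sum(r < 1e-12))
    rest = diff[r >= 1e-12]
    if len(rest) == 0:
        return coincident
    phi = np.arctan2(rest[:, 1], rest[:, 0])
    eps = 1e-9
    # candidate halfplane normals: along each point direction and its
    # perpendiculars, nudged both ways to realize open/closed boundaries
    cands = np.concatenate(
        [phi + off for off in (0.0, eps, -eps,
                               np.pi / 2, np.pi / 2 + eps, np.pi / 2 - eps,
                               -np.pi / 2, -np.pi / 2 + eps, -np.pi / 2 - eps)]
    )
    u = np.stack([np.cos(cands), np.sin(cands)], axis=1)
    proj = rest @ u.T  # (m, n_cand)
    counts = np.sum(proj >= -1e-12, axis=0)
    return int(counts.min()) + coincident


@dataclass(frozen=True)
class BagplotResult:
    depths: np.ndarray
    bag_vertices: np.ndarray     # sampled bag boundary in analysis coordinates
    fence_vertices: np.ndarray
    depth_median: np.ndarray
    fence_factor: float
    interpolation_lambda: float
    outlier_labels: tuple[str, ...]
    standardized: bool


def _clip_halfplane(poly: np.ndarray, normal: np.ndarray, c: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex polygon with {x: normal.x <= c}."""
    if len(poly) == 0:
        return poly
    out: list[np.ndarray] = []
    m = len(poly)
    tol = 1e-12
    for i in range(m):
        a, b = poly[i], poly[(i + 1) % m]
        da, db = normal @ a - c, normal @ b - c
        if da <= tol:
            out.append(a)
            if db > tol:
                out.append(a + da / (da - db) * (b - a))
        elif db <= tol:
            out.append(a + da / (da - db) * (b - a))
    return np.array(out) if out else np.empty((0, 2))


def _depth_region(pts: np.ndarray, k: int) -> np.ndarray:
    """The convex depth contour {z: halfspace_depth(z, pts) >= k}.

    Equals the intersection of every closed halfplane containing at least
    n - k + 1 data points; the binding halfplanes are bounded by lines
    through data-point pairs, so clipping a large bounding box with all
    qualifying pair-halfplanes is exact.  May be empty for large k.
    """
    n = len(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1.0)
    poly = np.array(
        [
            [lo[0] - 10 * span[0], lo[1] - 10 * span[1]],
            [hi[0] + 10 * span[0], lo[1] - 10 * span[1]],
            [hi[0] + 10 * span[0], hi[1] + 10 * span[1]],
            [lo[0] - 10 * span[0], hi[1] + 10 * span[1]],
        ]
    )
    need = n - k + 1
    for i in range(n):
        for j in range(i + 1, n):
            dvec = pts[j] - pts[i]
            if np.hypot(*dvec) < 1e-12:
                continue
            normal = np.array([-dvec[1], dvec[0]])
            c = float(normal @ pts[i])
            s = pts @ normal - c
            if int(np.sum(s <= 1e-9)) >= need:
                poly = _clip_halfplane(poly, normal, c)
            if int(np.sum(s >= -1e-9)) >= need:
                poly = _clip_halfplane(poly, -normal, -c)
            if len(poly) == 0:
                return poly
    return poly


def _radial_extent(poly: np.ndarray, center: np.ndarray, theta: float) -> float:
    """Distance from center to the polygon boundary along direction theta."""
    if len(poly) == 0:
        return 0.0
    u = np.array([np.cos(theta), np.sin(theta)])
    best = 0.0
    m = len(poly)
    for i in range(m):
        a = poly[i] - center
        b = poly[(i + 1) % m] - center
        M = np.column_stack([u, a - b])
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        if abs(det) < 1e-14:
            continue
        r, s = np.linalg.solve(M, a)
        if r >= 0 and -1e-9 <= s <= 1 + 1e-9:
            best = max(best, float(r))
    return best


def bagplot_outliers(
    points: PairedObservations,
    fence_factor: float = 3.0,
    standardize: bool = True,
) -> BagplotResult:
    """Bagplot outlier screen on labelled (x, y) pairs.

    Incomplete pairs are dropped first.  The depth median is the centroid
    of the deepest data points.  The bag interpolates radially (about the
    depth median) between the exact depth contours D_k and D_{k-1} chosen
    so that D_k holds at most floor(n/2) data points and D_{k-1} more,
    with lambda = (floor(n/2) - #D_k) / (#D_{k-1} - #D_k); the fence
    inflates the bag ``fence_factor``-fold about the depth median, and
    points beyond the fence are the outliers.

    ``standardize`` (default) runs the construction on coordinates scaled
    to zero mean and unit SD.  The construction is affine-equivariant, so
    this does not change the flags; it only makes the stored geometry
    readable when x and y live on incommensurate scales.
    """
    obs = points.complete()
    if obs.n < 5:
        raise ValueError(f"bagplot needs n >= 5 complete pairs, got {obs.n}")
    raw = np.column_stack([obs.x, obs.y])
    if standardize:
        sd = raw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        pts = (raw - raw.mean(axis=0)) / sd
    else:
        pts = raw
    n = obs.n
    depths = np.array([halfspace_depth(pt, pts) for pt in pts])
    dmax = int(depths.max())
    T = pts[depths == dmax].mean(axis=0)
    half = n // 2
    counts = {k: int(np.sum(depths >= k)) for k in range(1, dmax + 2)}
    k = next(kk for kk in range(2, dmax + 2) if counts.get(kk, 0) <= half)
    n_in, n_out = counts.get(k, 0), counts[k - 1]
    lam = (half - n_in) / (n_out - n_in) if n_out > n_in else 0.0
    inner = _depth_region(pts, k)
    outer = _depth_region(pts, k - 1)
    thetas = [
        math.atan2(v[1] - T[1], v[0] - T[0]) for poly in (inner, outer) for v in poly
    ]
    thetas = np.unique(np.concatenate([thetas, np.linspace(-np.pi, np.pi, 145)]))

    def bag_radius(theta: float) -> float:
        r_in = _radial_extent(inner, T, theta)
        r_out = _radial_extent(outer, T, theta)
        return r_in + lam * (r_out - r_in)

    bag = np.array(
        [T + bag_radius(th) * np.array([np.cos(th), np.sin(th)]) for th in thetas]
    )
    fence = T + fence_factor * (bag - T)
    flags = []
    for pt in pts:
        v = pt - T
        r = float(np.hypot(*v))
        if r < 1e-12:
            flags.append(False)
            continue
        flags.append(r > fence_factor * bag_radius(math.atan2(v[1], v[0])) + 1e-9)
    outliers = tuple(obs.labels[i] for i, f in enumerate(flags) if f)
    return BagplotResult(
        depths=depths,
        bag_vertices=bag,
        fence_vertices=fence,
        depth_median=T,
        fence_factor=fence_factor,
        interpolation_lambda=float(lam),
        outlier_labels=outliers,
        standardized=standardize,
    )


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_used: int
    excluded_labels: tuple[str, ...]
    p_method: str


@lru_cache(maxsize=32)
def _spearman_d_distribution(n: int) -> np.ndarray:
    """Exact null counts of D = sum (rank_x - rank_y)^2 over all n! pairings.

    Bitmask dynamic programming over rank assignments: state = set of used
    y-ranks, processing x-ranks in order; counts[d] accumulates the number
    of permutations achieving each D.  O(2^n * n * Dmax) time, practical
    for n <= 12.
    """
    dmax = n * (n * n - 1) // 3
    size = 1 << n
    counts = [None] * size
    counts[0] = np.zeros(dmax + 1, dtype=np.float64)
    counts[0][0] = 1.0
    for mask in range(size):
        if counts[mask] is None:
            continue
        pos = bin(mask).count("1")  # next x-rank to assign (0-based)
        if pos == n:
            continue
        cur = counts[mask]
        nz = np.flatnonzero(cur)
        for j in range(n):
            bit = 1 << j
            if mask & bit:
                continue
            d = (pos - j) ** 2
            nxt = mask | bit
            if counts[nxt] is None:
                counts[nxt] = np.zeros(dmax + 1, dtype=np.float64)
            counts[nxt][nz + d] += cur[nz]
        counts[mask] = None  # free memory; each state is consumed once
    return counts[size - 1]


def _exact_p_no_ties(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho without ties."""
    n = len(rx)
    d_obs = int(np.sum((rx - ry) ** 2))
    dist = _spearman_d_distribution(n)
    dmax = len(dist) - 1
    rho = 1.0 - 6.0 * np.arange(dmax + 1) / (n * (n * n - 1))
    rho_obs = 1.0 - 6.0 * d_obs / (n * (n * n - 1))
    hits = dist[np.abs(rho) >= abs(rho_obs) - 1e-12].sum()
    return float(min(hits / math.factorial(n), 1.0))


def _exact_p_enumerate(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact p by full enumeration (handles midrank ties), n <= 7."""
    n = len(rx)
    sx = rx - rx.mean()
    denom_x = float(np.sqrt(np.sum(sx**2)))
    count = total = 0
    sy0 = ry - ry.mean()
    denom_y = float(np.sqrt(np.sum(sy0**2)))
    rho_obs = float(np.sum(sx * sy0) / (denom_x * denom_y))
    for perm in itertools.permutations(range(n)):
        sy = sy0[list(perm)]
        rho = float(np.sum(sx * sy) / (denom_x * denom_y))
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman(
    points: PairedObservations,
    p_method: str = "auto",
    exclude: tuple[str, ...] = (),
) -> CorrelationResult:
    """Spearman rank correlation with small-sample exact p-values.

    Pairs listed in ``exclude`` (e.g. bagplot outliers) and incomplete
    pairs are removed first; at least 4 pairs must remain.  Ties are
    handled by midranks.  ``p_method``: "exact" forces the permutation
    null (error if infeasible), "asymptotic" the large-sample t
    approximation, "auto" picks exact for n <= 10 (falling back to
    asymptotic when ties make the DP inapplicable and n > 7).
    A constant x or y leaves the coefficient undefined and raises.
    """
    obs = points.drop(exclude).complete()
    if obs.n < 4:
        raise ValueError(f"need >= 4 complete pairs after exclusions, got {obs.n}")
    if np.all(obs.x == obs.x[0]) or np.all(obs.y == obs.y[0]):
        raise ValueError("constant x or y: Spearman correlation undefined")
    rho, p_asym = spearmanr(obs.x, obs.y)
    rho = float(rho)
    rx, ry = rankdata(obs.x), rankdata(obs.y)
    has_ties = len(np.unique(rx)) < obs.n or len(np.unique(ry)) < obs.n

    method = p_method
    if method == "auto":
        method = "exact" if obs.n <= 10 and (not has_ties or obs.n <= 7) else "asymptotic"
    if method == "exact":
        if not has_ties and obs.n <= 12:
            p = _exact_p_no_ties(rx.astype(int), ry.astype(int))
        elif obs.n <= 7:
            p = _exact_p_enumerate(rx, ry)
        else:
            raise ValueError(
                f"exact permutation p infeasible for n={obs.n} with ties; "
                "use p_method='asymptotic'"
            )
    elif method == "asymptotic":
        p = float(p_asym)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(
        rho=rho,
        p_value=p,
        n_used=obs.n,
        excluded_labels=tuple(exclude),
        p_method=method,
    )


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    confidence: float
    _results: object

    def band(self, x_new: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted mean and pointwise confidence band at x_new."""
        x_new = np.asarray(x_new, dtype=float)
        exog = sm.add_constant(x_new, has_constant="add") if self._has_const else x_new[:, None]
        pred = self._results.get_prediction(exog)
        ci = pred.conf_int(alpha=1.0 - self.confidence)
        return pred.predicted_mean, ci[:, 0], ci[:, 1]

    @property
    def _has_const(self) -> bool:
        return not np.isnan(self.intercept)


def linear_fit_ci(
    points: PairedObservations,
    confidence: float = 0.95,
    through_origin: bool = False,
) -> LinearFit:
    """Ordinary least squares with a pointwise confidence band.

    With ``through_origin`` the intercept is constrained to zero (reported
    as NaN).  Rank-deficient designs (e.g. constant x with an intercept)
    raise a ValueError.
    """
    obs = points.complete()
    if obs.n < 3:
        raise ValueError("need at least 3 complete pairs")
    if through_origin:
        exog = obs.x[:, None]
    else:
        exog = sm.add_constant(obs.x)
        if np.linalg.matrix_rank(exog) < 2:
            raise ValueError("rank-deficient design: x is constant")
    res = sm.OLS(obs.y, exog).fit()
    if through_origin:
        slope, slope_se = float(res.params[0]), float(res.bse[0])
        intercept, intercept_se = float("nan"), float("nan")
    else:
        intercept, slope = (float(v) for v in res.params)
        intercept_se, slope_se = (float(v) for v in res.bse)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        confidence=confidence,
        _results=res,
    )


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame   # variables x components
    scores: pd.DataFrame     # observations x components
    explained_variance_ratio: np.ndarray


def pca_scores(
    table: pd.DataFrame,
    n_components: int | None = None,
    scale: bool = True,
) -> PCAResult:
    """Centred (and by default unit-variance scaled) PCA of complete cases.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so results are deterministic across SVD backends.
    """
    data = table.dropna()
    X = data.to_numpy(dtype=float)
    n_obs, n_var = X.shape
    k = n_components if n_components is not None else min(n_obs - 1, n_var)
    if k < 1 or n_obs <= k:
        raise ValueError(
            f"cannot extract {k} components from {n_obs} complete observations"
        )
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic signs
    for j in range(Vt.shape[0]):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2
    evr = var / var.sum()
    comps = [f"PC{i+1}" for i in range(k)]
    loadings = pd.DataFrame(Vt[:k].T, index=table.columns, columns=comps)
    scores = pd.DataFrame((U[:, :k] * S[:k]), index=data.index, columns=comps)
    return PCAResult(loadings=loadings, scores=scores, explained_variance_ratio=evr[:k])
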