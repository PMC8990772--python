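"""Vertexwise GLM statistics with Monte Carlo cluster-size correction.

Group differences and interactions are tested with a "different offset,
different slope" (DODS) design: every group gets its own intercept and its
own slope for each covariate, so the offset contrast tests the group
difference and a slope contrast tests an interaction.  Vertexwise t maps
are thresholded two-sided and supra-threshold clusters are tested against
the max-cluster-area distribution of smoothed Gaussian null maps (the
Monte Carlo null-Z simulation family of corrections).  Longitudinal change
is reduced to a per-vertex rate (change per month) before testing, and
cluster summaries are related to cognition through covariate-adjusted
partial correlation of composite Z-scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps
from scipy.sparse.csgraph import connected_components

from .mesh import CorticalMesh

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """DODS design: per-group intercepts and per-group covariate slopes."""

    X: np.ndarray  # (n, p)
    columns: list[str]
    contrasts: dict[str, np.ndarray] = dfield(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


def median_split(values: np.ndarray) -> np.ndarray:
    """Binarize at the cohort median; values at or below the median are 0."""
    v = np.asarray(values, float)
    return (v > np.median(v)).astype(float)


def build_dods_design(design: pd.DataFrame, group_col: str = "group",
                      covariates: tuple[str, ...] = (),
                      moderator: str | None = None,
                      demean: bool = True) -> DesignMatrix:
    """Build a two-group DODS design matrix with offset/interaction contrasts.

    Each covariate contributes one column per group (slope allowed to
    differ).  ``moderator`` is binarized at the cohort median before entering
    as a per-group slope; its slope-difference contrast tests the
    group x moderator interaction.  Covariates are demeaned across the
    cohort (``demean=True``) so the per-group intercepts — and hence the
    offset contrast — refer to the average covariate value rather than an
    extrapolation to zero; this also makes the contrast t invariant to
    affine rescaling of the covariates.  Raises on rank deficiency, naming
    the collinear columns.
    """
    g = np.asarray(design[group_col])
    groups = np.unique(g)
    if len(groups) != 2:
        raise ValueError("DODS design requires exactly two groups")
    ind = [(g == grp).astype(float) for grp in groups]
    n = len(design)
    cols, names = [], []
    for i, grp in enumerate(groups):
        cols.append(ind[i])
        names.append(f"intercept[g{grp}]")
    regressors = [(c, np.asarray(design[c], float)) for c in covariates]
    if moderator is not None:
        regressors.append((f"{moderator}_high", median_split(design[moderator])))
    for cname, values in regressors:
        if demean:
            values = values - values.mean()
        for i, grp in enumerate(groups):
            cols.append(values * ind[i])
            names.append(f"{cname}[g{grp}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    p = X.shape[1]
    offset = np.zeros(p)
    offset[1], offset[0] = 1.0, -1.0
    contrasts = {"group_offset": offset}
    if moderator is not None:
        inter = np.zeros(p)
        inter[p - 1], inter[p - 2] = 1.0, -1.0  # moderator slope columns come last
        contrasts["interaction"] = inter
    return DesignMatrix(X=X, columns=names, contrasts=contrasts)


# ---------------------------------------------------------------------------
# vertexwise GLM
# ---------------------------------------------------------------------------

@dataclass
class VertexStatResult:
    """Per-vertex OLS contrast estimates, t and p maps, and residuals."""

    effect: np.ndarray  # (V,) c'beta
    t: np.ndarray  # (V,)
    p: np.ndarray  # (V,) two-sided
    df: np.ndarray  # (V,) residual degrees of freedom
    residuals: np.ndarray  # (n, V), NaN where a subject was dropped


def _ols_contrast(Y: np.ndarray, X: np.ndarray, c: np.ndarray):
    """Vectorized OLS of every column of Y on X with contrast c."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    df = n - rank
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom (n={n}, rank={rank})")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    sigma2 = np.sum(resid ** 2, axis=0) / df
    xtx_inv = pinv @ pinv.T  # (X'X)^+ for full-rank X
    var_c = float(c @ xtx_inv @ c)
    effect = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(sigma2 * var_c)
    return effect, t, df, resid


def fit_glm_vertexwise(maps: np.ndarray, design: DesignMatrix,
                       contrast: np.ndarray | str) -> VertexStatResult:
    """Ordinary least squares at every vertex with a linear contrast.

    ``maps`` is (n_subjects, n_vertices); vertices with missing subjects are
    refit on the observed subset with the degrees of freedom adjusted;
    all-missing vertices return NaN.
    """
    if isinstance(contrast, str):
        contrast = design.contrasts[contrast]
    c = np.asarray(contrast, float)
    Y = np.asarray(maps, float)
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("map count must equal design rows")
    nv = Y.shape[1]
    effect = np.full(nv, np.nan)
    t = np.full(nv, np.nan)
    df = np.zeros(nv)
    residuals = np.full_like(Y, np.nan)

    missing = np.isnan(Y)
    complete = ~missing.any(axis=0)
    if complete.any():
        e, tt, d, r = _ols_contrast(Y[:, complete], X, c)
        effect[complete], t[complete], df[complete] = e, tt, d
        residuals[:, complete] = r
    if (~complete).any():
        # group incomplete vertices by missingness pattern
        patt = missing[:, ~complete]
        idx = np.flatnonzero(~complete)
        keys, inverse = np.unique(patt.T, axis=0, return_inverse=True)
        for k, key in enumerate(keys):
            sub = ~key
            cols = idx[inverse == k]
            if sub.sum() - np.linalg.matrix_rank(X[sub]) <= 0:
                continue
            e, tt, d, r = _ols_contrast(Y[np.ix_(sub, cols)], X[sub], c)
            effect[cols], t[cols], df[cols] = e, tt, d
            residuals[np.ix_(sub, cols)] = r
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1))
    p[np.isnan(t)] = np.nan
    return VertexStatResult(effect=effect, t=t, p=p, df=df, residuals=residuals)


# ---------------------------------------------------------------------------
# smoothness estimation
# ---------------------------------------------------------------------------

def estimate_smoothness(residuals: np.ndarray, mesh: CorticalMesh,
                        clamp_mm: tuple[float, float] | None = None) -> float:
    """Residual smoothness (FWHM, mm) from neighbor-difference variance.

    For edges of length h, the normalized neighbor-difference variance
    Delta = var(diff) / var(values) determines the equivalent Gaussian
    kernel via FWHM = h * sqrt(-2 ln 2 / ln(1 - Delta/2)).  Edges are
    bucketed by length (a mixed-length average would bias the estimate),
    estimates are count-weighted within a map and averaged over maps, then
    clamped to [mean edge length, 50 mm].
    """
    R = np.atleast_2d(np.asarray(residuals, float))
    if R.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    e = mesh.edges
    h_all = mesh.edge_lengths
    h_mean = float(h_all.mean())
    lo, hi = clamp_mm if clamp_mm is not None else (h_mean, 50.0)
    buckets = np.round(h_all, 6)
    uniq = np.unique(buckets)

    # center each vertex across maps: pooling across maps keeps the variance
    # estimate unbiased even when the field is correlated across most of the
    # mesh (a per-map spatial variance would be deflated there)
    C = R - np.nanmean(R, axis=0, keepdims=True)
    var = float(np.nanmean(C ** 2))
    if var <= 0 or not np.isfinite(var):
        raise ValueError("zero-variance residual maps")
    diffs = C[:, e[:, 0]] - C[:, e[:, 1]]  # (maps, edges)

    est, wts = [], []
    for u in uniq:
        sel = buckets == u
        d2 = diffs[:, sel]
        ok = ~np.isnan(d2)
        if ok.sum() < 2:
            continue
        delta = float(np.nanmean(d2 ** 2)) / var
        arg = 1.0 - delta / 2.0
        if arg <= 0:
            est.append(lo)  # rougher than representable: unsmoothed limit
        else:
            est.append(u * np.sqrt(-2.0 * np.log(2.0) / np.log(arg)))
        wts.append(ok.sum())
    if not est:
        raise ValueError("no valid edges to estimate smoothness")
    return float(np.clip(np.average(est, weights=wts), lo, hi))


def expected_operator_smoothness(mesh: CorticalMesh, W) -> float:
    """Analytic value `estimate_smoothness` converges to for fields W @ white.

    For y = W x with x unit white noise, cov(y) = W W', so the expected
    neighbor-difference second moment along edge (i, j) is
    (WW')_ii + (WW')_jj - 2 (WW')_ij and the expected variance is
    mean(diag(WW')).  Feeding these moments through the same bucketed FWHM
    formula gives the estimator's asymptotic value without simulation.
    """
    W = W.tocsr()
    diag = np.asarray(W.multiply(W).sum(axis=1)).ravel()
    var = float(diag.mean())
    e = mesh.edges
    cross = np.asarray(W[e[:, 0]].multiply(W[e[:, 1]]).sum(axis=1)).ravel()
    d2 = diag[e[:, 0]] + diag[e[:, 1]] - 2.0 * cross
    buckets = np.round(mesh.edge_lengths, 6)
    h_mean = float(mesh.edge_lengths.mean())
    est, wts = [], []
    for u in np.unique(buckets):
        sel = buckets == u
        delta = float(d2[sel].mean()) / var
        arg = 1.0 - delta / 2.0
        est.append(h_mean if arg <= 0
                   else u * np.sqrt(-2.0 * np.log(2.0) / np.log(arg)))
        wts.append(int(sel.sum()))
    return float(np.average(est, weights=wts))


def _null_operator(mesh: CorticalMesh, target_fwhm: float):
    """Smoothing operator whose output field *measures* ``target_fwhm``.

    Truncation and lattice discretization make a kernel of nominal width f
    produce a field whose estimated smoothness is slightly below f; one
    proportional correction of the kernel width (cached per mesh) closes
    the gap so null maps match the residuals' measured smoothness.
    """
    from .density import smoothing_operator

    target = round(float(target_fwhm), 6)
    key = ("null_kernel_fwhm", target)
    if key not in mesh._cache:
        W0 = smoothing_operator(mesh, target)
        measured = expected_operator_smoothness(mesh, W0)
        mesh._cache[key] = target * target / measured if measured > 0 else target
    return smoothing_operator(mesh, mesh._cache[key])


# ---------------------------------------------------------------------------
# cluster-wise Monte Carlo correction
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    vertices: np.ndarray
    sign: int
    area_mm2: float
    peak_vertex: int
    p_corrected: float = np.nan


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    null_max_area: np.ndarray
    vertex_p: float
    cluster_p: float
    n_iter: int
    fwhm_mm: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.cluster_p]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "cluster_id": i, "sign": c.sign, "n_vertices": len(c.vertices),
            "peak_vertex": c.peak_vertex, "area_mm2": c.area_mm2,
            "p_corrected": c.p_corrected,
        } for i, c in enumerate(self.clusters)])


def _supra_clusters(values: np.ndarray, above: np.ndarray,
                    adjacency: sparse.csr_matrix,
                    vertex_areas: np.ndarray) -> list[tuple[np.ndarray, float, int]]:
    """Connected components among `above` vertices: (members, area, peak)."""
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return []
    sub = adjacency[idx][:, idx]
    _, comp = connected_components(sub, directed=False)
    out = []
    for cid in np.unique(comp):
        members = idx[comp == cid]
        area = float(vertex_areas[members].sum())
        peak = members[np.argmax(np.abs(values[members]))]
        out.append((members, area, int(peak)))
    return out


def cluster_correct_montecarlo(res: VertexStatResult, mesh: CorticalMesh,
                               vertex_p: float = 0.01, cluster_p: float = 0.01,
                               n_iter: int = 10000, fwhm: float | None = None,
                               rng_seed: int = 0) -> ClusterReport:
    """Familywise cluster-area correction against smoothed Gaussian nulls.

    The observed t/p map is thresholded two-sided at ``vertex_p`` (positive
    and negative clusters kept separately).  The null distribution is built
    from ``n_iter`` maps of unit white noise smoothed to ``fwhm`` (estimated
    from the residuals when not given), standardized per vertex by the
    operator's analytic output SD (sqrt of diag WW'), so the null marginal
    is exactly unit Gaussian everywhere, matching the uniform marginal of
    the observed t map; each map is thresholded identically and its maximum
    cluster area retained.
    Cluster-wise p uses the add-one estimator (1 + #{null >= obs}) /
    (1 + n_iter), so it is never zero and is monotone in area.
    """
    if not (0 < vertex_p < 1 and 0 < cluster_p < 1):
        raise ValueError("thresholds must be in (0, 1)")
    if n_iter < 100:
        log.warning("n_iter=%d is very low for cluster-level inference", n_iter)
    if fwhm is None:
        fwhm = estimate_smoothness(res.residuals, mesh)
    # quantize so the calibrated null operator is shared across nearby runs
    fwhm = round(4.0 * float(fwhm)) / 4.0

    areas = mesh.vertex_areas
    adj = mesh.adjacency
    signed = np.where(np.isnan(res.t), 0.0, res.t)
    supra = (res.p < vertex_p) & ~np.isnan(res.p)
    observed = []
    for sign in (1, -1):
        for members, area, peak in _supra_clusters(
                signed, supra & (np.sign(signed) == sign), adj, areas):
            observed.append(Cluster(vertices=members, sign=sign,
                                    area_mm2=area, peak_vertex=peak))

    z_crit = sps.norm.isf(vertex_p / 2.0)
    rng = np.random.default_rng(rng_seed)
    W = _null_operator(mesh, fwhm)
    nv = mesh.n_vertices
    # analytic per-vertex SD of W @ white: exact unit-normal null marginal
    sd_vec = np.sqrt(np.asarray(W.multiply(W).sum(axis=1)).ravel())
    sd_vec[sd_vec == 0] = 1.0
    null_max = np.zeros(n_iter)
    batch = max(1, min(n_iter, int(2e7) // max(nv, 1)))
    done = 0
    while done < n_iter:
        nb = min(batch, n_iter - done)
        noise = rng.standard_normal((nv, nb))
        sm = (W @ noise) / sd_vec[:, None]
        for j in range(nb):
            zmap = sm[:, j]
            best = 0.0
            for sign in (1, -1):
                above = sign * zmap > z_crit
                for _, area, _ in _supra_clusters(zmap, above, adj, areas):
                    best = max(best, area)
            null_max[done + j] = best
        done += nb

    for c in observed:
        c.p_corrected = (1.0 + np.sum(null_max >= c.area_mm2)) / (1.0 + n_iter)
    observed.sort(key=lambda c: c.p_corrected)
    return ClusterReport(clusters=observed, null_max_area=null_max,
                         vertex_p=vertex_p, cluster_p=cluster_p,
                         n_iter=n_iter, fwhm_mm=float(fwhm))


# ---------------------------------------------------------------------------
# longitudinal reduction
# ---------------------------------------------------------------------------

def longitudinal_rate(map_t0: np.ndarray, map_t1: np.ndarray,
                      months: float) -> np.ndarray:
    """Per-vertex change per month, (t1 - t0) / months; NaN propagates."""
    if months <= 0:
        raise ValueError("months must be > 0")
    a, b = np.asarray(map_t0, float), np.asarray(map_t1, float)
    if a.shape != b.shape:
        raise ValueError("timepoint maps must share the mesh")
    return (b - a) / months


def within_group_rate_test(rate_maps: np.ndarray) -> VertexStatResult:
    """One-sample (intercept-only GLM) t-test of the rate at every vertex."""
    R = np.asarray(rate_maps, float)
    if R.shape[0] < 3:
        raise ValueError("need at least 3 rate maps")
    design = DesignMatrix(X=np.ones((R.shape[0], 1)), columns=["intercept"],
                          contrasts={"time": np.array([1.0])})
    res = fit_glm_vertexwise(R, design, "time")
    # tolerance-based: a constant map accumulates ~eps^2 rounding variance
    zero_var = np.nanvar(R, axis=0) <= np.finfo(float).eps ** 2 * (
        1.0 + np.nanmean(R ** 2, axis=0))
    if zero_var.any():
        res.t[zero_var] = np.nan
        res.p[zero_var] = np.nan
        log.warning("%d vertices with zero rate variance flagged", int(zero_var.sum()))
    return res


# ---------------------------------------------------------------------------
# partial correlation and composite cognition
# ---------------------------------------------------------------------------

def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on the covariates plus an intercept;
    p comes from t = r sqrt((n - 2 - k) / (1 - r^2)) with k covariates.
    With no covariates this reduces exactly to the plain Pearson test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or (np.size(covariates) == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.column_stack(covariates) if isinstance(covariates, (list, tuple)) \
            else np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
        k = C.shape[1]
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_ ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


#: NTB tests feeding each composite cognitive domain
COMPOSITE_DOMAINS = {
    "executive": ("COWAT", "CFT"),
    "psychomotor": ("SRT", "CRT"),
    "memory": ("CPAL", "ISLT"),
}


def composite_zscores(scores: pd.DataFrame, baseline_means: dict[str, float],
                      baseline_sds: dict[str, float]) -> pd.DataFrame:
    """Per-test Z-scores against baseline norms plus domain composites.

    Z = (score - baseline mean) / baseline SD per test; the executive,
    psychomotor and memory composites are means of their two tests.
    """
    out = pd.DataFrame(index=scores.index)
    for test in scores.columns:
        if test not in baseline_means:
            continue
        sd = baseline_sds[test]
        if sd <= 0:
            raise ValueError(f"baseline SD for {test} must be > 0")
        out[f"Z_{test}"] = (scores[test] - baseline_means[test]) / sd
    for domain, tests in COMPOSITE_DOMAINS.items():
        cols = [f"Z_{t}" for t in tests]
        if all(c in out.columns for c in cols):
            out[domain] = out[cols].mean(axis=1)
    return out
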