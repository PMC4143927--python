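"""Polygenic mixed model, kinship-adjusted score-test GWAS and conditional scans.

Per adjusted trait y (n individuals) with fixed-effect design X and genomic
relationship matrix K, the polygenic model is

    y ~ N(X beta, Omega),   Omega = sigma2_g K + sigma2_e I

with narrow-sense heritability h2 = sigma2_g / (sigma2_g + sigma2_e).  The
likelihood is maximized by a single eigendecomposition of K followed by 1-D
optimization over h2 with beta and the total variance profiled out: in the
eigenbasis Omega is diagonal with weights h2*lambda_i + (1 - h2), so each
likelihood evaluation is O(n p^2).  K is normalized by its mean diagonal
internally, which makes h2 invariant to rescaling K by a constant.

Marker association uses the mmscore statistic: with gc the dosage projected
onto the orthogonal complement of X under the Omega^{-1} inner product and
y* the polygenic-model residual,

    beta_hat = (gc' Omega^-1 y*) / (gc' Omega^-1 gc)
    se       = (gc' Omega^-1 gc)^{-1/2}
    chi2     = (beta_hat / se)^2

which is algebraically identical to the generalized-least-squares Wald test
of the marker at fixed variance components.  Variance components are not
re-estimated per marker; conditional scans refit the polygenic model with
the top marker's dosage appended to the fixed effects.  The per-marker
effect-size summary is the variance-explained fraction chi2 / N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import KinshipMatrix
from .synthetic import GenotypeDosages

logger = logging.getLogger(__name__)

#: Median of the 1-df chi-square distribution, to four decimals; divisor in
#: the median-based genomic inflation factor.
CHI2_1_MEDIAN = 0.4549

_H2_LO, _H2_HI = 1e-6, 1.0 - 1e-6
_EIG_FLOOR = 1e-8


@dataclass
class EigenK:
    """Eigendecomposition of a (diagonal-normalized) kinship matrix."""

    ids: pd.Index
    lam: np.ndarray     # eigenvalues, floored at _EIG_FLOOR
    U: np.ndarray       # eigenvectors, columns
    scale: float        # mean diagonal of the input K


def eigen_kinship(K: KinshipMatrix | pd.DataFrame) -> EigenK:
    """One O(n^3) eigendecomposition reused by every fit on the same sample."""
    V = K.values if isinstance(K, KinshipMatrix) else K
    ids = V.index
    A = V.to_numpy(dtype=float)
    scale = float(np.mean(np.diag(A)))
    if scale <= 0:
        raise ValueError("kinship diagonal must be positive")
    lam, U = np.linalg.eigh(A / scale)
    lam = np.maximum(lam, _EIG_FLOOR)
    return EigenK(ids=ids, lam=lam, U=U, scale=scale)


@dataclass
class PolygenicFit:
    """Fitted polygenic model: variance components, fixed effects, residuals.

    ``sigma2_g`` is reported on the scale of the input K; ``h2`` refers to
    the diagonal-normalized K (so it is the fraction of trait variance that
    is additive-genetic for a non-inbred individual).
    """

    ids: pd.Index
    beta: pd.Series
    h2: float
    sigma2_g: float
    sigma2_e: float
    loglik: float
    loglik_h0: float
    n: int
    boundary: bool
    residuals: pd.Series          # y - X beta, original basis
    # internals for score tests
    eig: EigenK = field(repr=False)
    sigma2: float = field(repr=False, default=0.0)   # ML total variance (normalized-K scale)
    _w: np.ndarray = field(repr=False, default=None)
    _Xt: np.ndarray = field(repr=False, default=None)
    _yt_resid: np.ndarray = field(repr=False, default=None)
    _XtWiX_inv: np.ndarray = field(repr=False, default=None)


def _profile(h2: float, lam: np.ndarray, Xt: np.ndarray, yt: np.ndarray, reml: bool):
    """Profiled (beta, sigma2 out) log-likelihood at a given h2."""
    n, p = Xt.shape
    w = h2 * lam + (1.0 - h2)
    wi = 1.0 / w
    A = Xt.T @ (wi[:, None] * Xt)
    b = Xt.T @ (wi * yt)
    beta = np.linalg.solve(A, b)
    r = yt - Xt @ beta
    rss = float(np.sum(r * r * wi))
    if reml:
        sigma2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sigma2)
            + float(np.sum(np.log(w)))
            + float(np.linalg.slogdet(A)[1])
            + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + float(np.sum(np.log(w))) + n)
    return ll, beta, sigma2, w, wi, r


def fit_polygenic(
    y: pd.Series,
    K: KinshipMatrix | pd.DataFrame | None = None,
    X: pd.DataFrame | None = None,
    eig: EigenK | None = None,
    reml: bool = False,
    min_n: int = 30,
) -> PolygenicFit:
    """Maximum-likelihood fit of the polygenic model for one trait.

    Either ``K`` or a precomputed ``eig`` must be given; when ``eig`` is
    supplied, ``y`` must be complete on exactly its sample.  ``X`` defaults
    to an intercept (traits are normally pre-adjusted for covariates).  The
    optimum over h2 is located on a coarse grid and refined by bounded
    scalar minimization; fits on the h2 boundary are returned flagged, and
    a likelihood indistinguishable from the h2 = 0 model collapses to
    ordinary least squares.
    """
    if eig is None:
        if K is None:
            raise ValueError("either K or eig must be given")
        ids = y.dropna().index
        Kv = K.values if isinstance(K, KinshipMatrix) else K
        eig = eigen_kinship(KinshipMatrix(Kv.loc[ids, ids], n_markers=0))
    ids = eig.ids
    yv = y.loc[ids].to_numpy(dtype=float)
    if np.isnan(yv).any():
        raise ValueError("trait has missing values on the kinship sample")
    n = len(yv)
    if n < min_n:
        raise ValueError(f"need at least {min_n} individuals, got {n}")
    if X is None:
        Xv = np.ones((n, 1))
        beta_names = ["intercept"]
    else:
        Xd = X.loc[ids]
        Xv = np.column_stack([np.ones(n), Xd.to_numpy(dtype=float)])
        beta_names = ["intercept"] + list(Xd.columns)
    if np.isnan(Xv).any():
        raise ValueError("fixed-effect design has missing values")

    lam = eig.lam
    Xt = eig.U.T @ Xv
    yt = eig.U.T @ yv

    def nll(h2: float) -> float:
        return -_profile(h2, lam, Xt, yt, reml)[0]

    grid = np.linspace(_H2_LO, _H2_HI, 41)
    vals = np.array([nll(h) for h in grid])
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9})
    # bounded Brent cannot land on the bracket ends; keep whichever of the
    # refined point and the grid optimum has the higher likelihood (the
    # likelihood can peak at the h2 boundary for near-singular K)
    candidates = [(float(res.fun), float(res.x)), (float(vals[k]), float(grid[k]))]
    nll_hat, h2_hat = min(candidates)
    ll_hat = -nll_hat
    ll0 = _profile(0.0, lam, Xt, yt, reml)[0]
    if not np.isfinite(ll_hat) or not np.isfinite(ll0):
        raise FloatingPointError("non-finite polygenic likelihood")
    boundary = False
    if ll_hat - ll0 <= 1e-8:     # flat or decreasing likelihood: no genetic variance
        h2_hat, ll_hat = 0.0, ll0
        boundary = True
    elif h2_hat <= _H2_LO * 2 or h2_hat >= 1.0 - 2e-6:
        boundary = True

    ll, beta, sigma2, w, wi, r = _profile(h2_hat, lam, Xt, yt, reml)
    A = Xt.T @ (wi[:, None] * Xt)
    resid = yv - Xv @ beta
    fit = PolygenicFit(
        ids=ids,
        beta=pd.Series(beta, index=beta_names),
        h2=h2_hat,
        sigma2_g=h2_hat * sigma2 / eig.scale,
        sigma2_e=(1.0 - h2_hat) * sigma2,
        loglik=ll,
        loglik_h0=ll0,
        n=n,
        boundary=boundary,
        residuals=pd.Series(resid, index=ids),
        eig=eig,
        sigma2=sigma2,
        _w=w,
        _Xt=Xt,
        _yt_resid=r,
        _XtWiX_inv=np.linalg.inv(A),
    )
    return fit


def heritability_pvalue(fit: PolygenicFit) -> float:
    """Likelihood-ratio test of h2 = 0 against the boundary mixture null.

    The statistic 2(l_hat - l_0) is referred to the 50:50 mixture of a point
    mass at zero and chi-square with 1 df, the null distribution for a
    variance component tested on its boundary; a fit on the h2 = 0 boundary
    gives p = 0.5.
    """
    lrt = 2.0 * (fit.loglik - fit.loglik_h0)
    if lrt < -1e-6:
        raise FloatingPointError("restricted likelihood exceeds unrestricted")
    return float(0.5 * stats.chi2.sf(max(lrt, 0.0), 1))


@dataclass
class ScoreResult:
    """One marker's kinship-adjusted score test."""

    marker: str
    beta: float
    se: float
    chi2: float
    pvalue: float
    var_explained: float
    n: int
    phase: str = ""
    skipped_reason: str | None = None


def _project_rotated(fit: PolygenicFit, Gt: np.ndarray) -> np.ndarray:
    """Remove the fixed-effect span from rotated dosages (Omega^-1 metric)."""
    wi = 1.0 / fit._w
    coef = fit._XtWiX_inv @ (fit._Xt.T @ (wi[:, None] * Gt))
    return Gt - fit._Xt @ coef


def score_scan(
    fit: PolygenicFit,
    dosages: pd.DataFrame,
    phase: str = "",
    min_mac: int = 3,
) -> pd.DataFrame:
    """mmscore over a dosage matrix (individuals x markers), vectorized.

    Markers with minor-allele count below ``min_mac`` on the fit sample, or
    with zero residual dosage variance, are skipped with a reason.  Missing
    dosages are mean-imputed per marker for the test statistic.
    """
    G = dosages.loc[fit.ids].to_numpy(dtype=float)
    n, m = G.shape
    mu = np.nanmean(G, axis=0)
    nanmask = np.isnan(G)
    if nanmask.any():
        G = np.where(nanmask, mu, G)
    s = G.sum(axis=0)
    mac = np.minimum(s, 2 * n - s) if min_mac > 0 else np.full(m, np.inf)
    Gt = fit.eig.U.T @ G
    Gc = _project_rotated(fit, Gt)
    wi = 1.0 / fit._w
    b = np.einsum("ij,ij->j", Gc, wi[:, None] * Gc)
    a = (wi * fit._yt_resid) @ Gc
    ok = (b > 1e-12) & (mac >= min_mac)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    chi2 = np.full(m, np.nan)
    beta[ok] = a[ok] / b[ok]
    se[ok] = np.sqrt(fit.sigma2 / b[ok])
    chi2[ok] = a[ok] ** 2 / (b[ok] * fit.sigma2)
    pvals = stats.chi2.sf(chi2, 1)
    out = pd.DataFrame(
        {
            "marker": dosages.columns,
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": pvals,
            "var_expl": chi2 / n,
            "n": n,
            "phase": phase,
            "skipped": np.where(ok, "", np.where(mac < min_mac, "mac", "zero_variance")),
        }
    )
    return out


def mmscore(fit: PolygenicFit, g: pd.Series, marker: str = "", min_mac: int = 0) -> ScoreResult:
    """Score test for a single marker; see :func:`score_scan`."""
    name = marker or str(g.name)
    row = score_scan(fit, g.to_frame(name), min_mac=min_mac).iloc[0]
    if row["skipped"]:
        return ScoreResult(name, np.nan, np.nan, np.nan, np.nan, np.nan, fit.n,
                           skipped_reason=str(row["skipped"]))
    return ScoreResult(
        marker=name,
        beta=float(row["beta"]),
        se=float(row["se"]),
        chi2=float(row["chi2"]),
        pvalue=float(row["p"]),
        var_explained=float(row["var_expl"]),
        n=fit.n,
    )


def inflation_lambda(chi2_values: np.ndarray) -> float:
    """Median-based genomic inflation factor: median(chi2) / 0.4549."""
    v = np.asarray(chi2_values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite chi-square statistics")
    return float(np.median(v) / CHI2_1_MEDIAN)


def variance_explained_from_p(p: float, n: int) -> float:
    """Invert a 1-df p-value to chi2 and divide by the sample size.

    The per-marker effect-size summary on the adjusted phenotype scale;
    returned as a fraction (multiply by 100 for percent).
    """
    return float(stats.chi2.isf(p, 1) / n)


def variance_explained_raw(y: pd.Series, g: pd.Series, min_n: int = 10) -> float:
    """R^2 of a single-marker linear fit on the unadjusted ddCq values."""
    df = pd.concat([y.rename("y"), g.rename("g")], axis=1, join="inner").dropna()
    if len(df) < min_n:
        raise ValueError(f"need at least {min_n} complete cases, got {len(df)}")
    if df["y"].var() == 0:
        raise ValueError("zero trait variance")
    if df["g"].var() == 0:
        raise ValueError("zero dosage variance")
    r = stats.pearsonr(df["y"], df["g"]).statistic
    return float(r * r)


# ---------------------------------------------------------------------------
# phased GWAS


@dataclass(frozen=True)
class GwasRunConfig:
    """Significance thresholds of the discovery/replication/combined design."""

    alpha: float = 0.05
    conditional_cutoff: float = 5e-8
    min_mac: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.conditional_cutoff < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class GwasResult:
    """All three scans for one trait, with hits and inflation factors."""

    trait: str
    results: pd.DataFrame            # concatenated scans, column `phase`
    hits: dict[str, list[str]]       # phase -> significant marker ids
    lambdas: dict[str, float]
    thresholds: dict[str, float]
    combined_fit: PolygenicFit = field(repr=False, default=None)

    def phase(self, name: str) -> pd.DataFrame:
        return self.results[self.results["phase"] == name]

    @property
    def top_marker(self) -> str | None:
        comb = self.phase("combined").dropna(subset=["p"])
        if comb.empty:
            return None
        return str(comb.loc[comb["p"].idxmin(), "marker"])


class _FitCache:
    """Shares eigendecompositions across traits with identical sample sets."""

    def __init__(self, K: KinshipMatrix):
        self.K = K
        self._eigs: dict[tuple, EigenK] = {}

    def eig_for(self, ids: pd.Index) -> EigenK:
        key = tuple(ids)
        if key not in self._eigs:
            self._eigs[key] = eigen_kinship(self.K.subset(ids))
        return self._eigs[key]


def run_gwas(
    adjusted: pd.DataFrame,
    genotypes: GenotypeDosages,
    cohorts: pd.Series,
    K: KinshipMatrix,
    config: GwasRunConfig = GwasRunConfig(),
    discovery_label: str = "discovery",
) -> dict[str, GwasResult]:
    """Discovery / replication / combined score-test GWAS per adjusted trait.

    ``adjusted`` is proteins x individuals (NaN = unusable cell); ``cohorts``
    maps individual to cohort label, with ``discovery_label`` naming the
    discovery cohort and every other label pooled as replication.  Per
    trait: the discovery scan covers all markers at the Bonferroni threshold
    alpha/m; the replication scan re-tests only discovery hits at
    alpha/(number of discovery hits); the combined scan pools both cohorts
    (polygenic model refit on the pooled sample) at the discovery
    threshold.  The genomic inflation factor is reported per scan.
    """
    labels = cohorts.loc[adjusted.columns]
    disc_ids = labels.index[labels == discovery_label]
    repl_ids = labels.index[labels != discovery_label]
    if len(disc_ids) == 0 or len(repl_ids) == 0:
        raise ValueError("both discovery and replication cohorts must be non-empty")
    cache = _FitCache(K)
    D = genotypes.dosages
    m = D.shape[1]
    out: dict[str, GwasResult] = {}
    for trait in adjusted.index:
        y = adjusted.loc[trait]
        scans = []
        hits: dict[str, list[str]] = {}
        lambdas: dict[str, float] = {}
        thr_disc = config.alpha / m
        fits = {}
        for phase, ids in (("discovery", disc_ids), ("replication", repl_ids), ("combined", adjusted.columns)):
            use = y.loc[ids].dropna().index
            fits[phase] = fit_polygenic(y, eig=cache.eig_for(use))
        disc = score_scan(fits["discovery"], D, phase="discovery", min_mac=config.min_mac)
        lambdas["discovery"] = inflation_lambda(disc["chi2"])
        hits["discovery"] = disc.loc[disc["p"] < thr_disc, "marker"].tolist()
        scans.append(disc)

        thresholds = {"discovery": thr_disc, "combined": thr_disc}
        if hits["discovery"]:
            thr_rep = config.alpha / len(hits["discovery"])
            thresholds["replication"] = thr_rep
            rep = score_scan(
                fits["replication"], D[hits["discovery"]], phase="replication", min_mac=config.min_mac
            )
            # the inflation factor is a genome-wide null summary; a scan
            # restricted to a handful of hit markers cannot estimate it
            if len(rep) >= 100:
                lambdas["replication"] = inflation_lambda(rep["chi2"])
            hits["replication"] = rep.loc[rep["p"] < thr_rep, "marker"].tolist()
            scans.append(rep)
        else:
            hits["replication"] = []

        comb = score_scan(fits["combined"], D, phase="combined", min_mac=config.min_mac)
        lambdas["combined"] = inflation_lambda(comb["chi2"])
        hits["combined"] = comb.loc[comb["p"] < thr_disc, "marker"].tolist()
        scans.append(comb)

        results = pd.concat(scans, ignore_index=True).merge(
            genotypes.markers[["id", "chrom", "pos", "ref", "alt"]],
            left_on="marker", right_on="id", how="left",
        ).drop(columns="id")
        out[trait] = GwasResult(
            trait=str(trait),
            results=results,
            hits=hits,
            lambdas=lambdas,
            thresholds=thresholds,
            combined_fit=fits["combined"],
        )
        logger.info(
            "GWAS %s: %d discovery, %d replicated, %d combined hits",
            trait, len(hits["discovery"]), len(hits["replication"]), len(hits["combined"]),
        )
    return out


def conditional_scan(
    y_adjusted: pd.Series,
    genotypes: GenotypeDosages,
    K: KinshipMatrix,
    top_marker: str,
    cutoff: float = 5e-8,
    chromosomes: list[int] | None = None,
    min_mac: int = 3,
) -> pd.DataFrame:
    """Re-scan with the top marker's dosage as a fixed-effect covariate.

    The polygenic model is refit on the combined sample with the top
    dosage appended to the design; remaining markers on the hit
    chromosome(s) (default: the top marker's own) are then score-tested.
    Returns the scan with a ``significant`` column at ``cutoff``.
    """
    if top_marker not in genotypes.dosages.columns:
        raise ValueError(f"top marker {top_marker!r} not in dosage matrix")
    ids = y_adjusted.dropna().index.intersection(genotypes.dosages.index)
    g_top = genotypes.dosages.loc[ids, top_marker]
    g_top = g_top.fillna(g_top.mean())
    if g_top.var() == 0:
        raise ValueError(f"top marker {top_marker!r} is constant on the sample")
    eig = eigen_kinship(K.subset(ids))
    fit = fit_polygenic(y_adjusted, eig=eig, X=g_top.to_frame(top_marker))
    meta = genotypes.markers.set_index("id")
    chroms = chromosomes or [int(meta.loc[top_marker, "chrom"])]
    scan_markers = meta.index[meta["chrom"].isin(chroms)]
    res = score_scan(fit, genotypes.dosages[list(scan_markers)], phase="conditional", min_mac=min_mac)
    res = res.merge(
        meta.reset_index()[["id", "chrom", "pos", "ref", "alt"]],
        left_on="marker", right_on="id", how="left",
    ).drop(columns="id")
    res["significant"] = res["p"] < cutoff
    return res
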