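"""Per-protein covariate modelling and variance decomposition.

Each protein's ddCq values are regressed on the full covariate set in one
ordinary-least-squares fit on complete cases (below-LOD cells excluded).
Each covariate's contribution to trait variance is measured by sequential
(type-I) analysis of variance: the incremental sum of squares of each term,
in the fixed covariate-table column order, divided by the total sum of
squares.  Covariates are declared significant per protein when their
sequential F-test p-value clears a Bonferroni threshold (0.05 over the
number of covariates tested).  Traits are then residualized on their
significant covariates and rank-transformed to normality before any genetic
analysis; inter-biomarker correlations use Spearman's rho on pairwise
complete observations of the adjusted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

CovariateKind = str  # "continuous" | "binary" | "categorical"


@dataclass
class CovariateTable:
    """Individuals x covariates with per-covariate type metadata.

    Categorical covariates expand deterministically into indicator
    contrasts: levels sorted alphabetically, first level as reference.
    Kinds not given are inferred (two distinct non-missing values -> binary,
    non-numeric dtype -> categorical, else continuous).
    """

    data: pd.DataFrame
    kinds: dict[str, CovariateKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if col not in self.kinds:
                self.kinds[col] = self._infer_kind(self.data[col])
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"kinds given for unknown covariates: {sorted(unknown)}")

    @staticmethod
    def _infer_kind(col: pd.Series) -> CovariateKind:
        if not pd.api.types.is_numeric_dtype(col):
            return "categorical"
        nun = col.dropna().nunique()
        return "binary" if nun <= 2 else "continuous"

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def design(self) -> tuple[pd.DataFrame, dict[str, list[str]]]:
        """Numeric design (no intercept) plus term -> column-block mapping."""
        blocks: dict[str, list[str]] = {}
        cols: dict[str, pd.Series] = {}
        for name in self.data.columns:
            kind = self.kinds[name]
            col = self.data[name]
            if kind == "categorical":
                levels = sorted(col.dropna().astype(str).unique())
                block = []
                for lev in levels[1:]:
                    cname = f"{name}[{lev}]"
                    ind = (col.astype(str) == lev).astype(float)
                    ind[col.isna()] = np.nan
                    cols[cname] = ind
                    block.append(cname)
                blocks[name] = block
            else:
                cols[name] = col.astype(float)
                blocks[name] = [name]
        return pd.DataFrame(cols, index=self.data.index), blocks


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m


@dataclass
class FullModelFit:
    """OLS fit of a trait on all covariates, with sequential sums of squares."""

    trait: str
    n: int
    terms: list[str]                 # term order used (covariate-table order)
    seq_ss: pd.Series                # per-term sequential SS
    df: pd.Series                    # per-term degrees of freedom
    pvalues: pd.Series               # per-term sequential F-test p-values
    total_ss: float                  # centered total SS
    resid_ss: float
    dropped: list[str]               # aliased/constant terms removed
    params: pd.Series                # coefficients (incl. intercept)
    resid_df: int

    @property
    def model_ss(self) -> float:
        return float(self.seq_ss.sum())


def _incremental_qr(X: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, list[int]]:
    """Orthonormal basis built column-by-column; returns (Q, kept indices).

    Columns linearly dependent on their predecessors (relative residual norm
    below ``tol``) are skipped — this is what makes sequential sums of
    squares well-defined under aliasing.
    """
    n = X.shape[0]
    Q = np.empty((n, 0))
    kept: list[int] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if Q.shape[1]:
            v = v - Q @ (Q.T @ v)
            v = v - Q @ (Q.T @ v)  # re-orthogonalize for stability
        norm = np.linalg.norm(v)
        if norm0 == 0 or norm <= tol * max(norm0, 1.0):
            continue
        Q = np.hstack([Q, (v / norm)[:, None]])
        kept.append(j)
    return Q, kept


def fit_full_model(trait: pd.Series, covariates: CovariateTable) -> FullModelFit:
    """Fit one protein on all covariates simultaneously (complete cases).

    Sequential (type-I) ANOVA in covariate-table column order: term j's sum
    of squares is the incremental explained SS when added after terms
    1..j-1; significance by the F test against the residual mean square.
    Aliased or constant terms are dropped with a logged warning.
    """
    design, blocks = covariates.design()
    df = pd.concat([trait.rename("__y__"), design], axis=1, join="inner").dropna()
    y = df["__y__"].to_numpy(dtype=float)
    n = len(y)
    n_params = 1 + design.shape[1]
    if n <= n_params:
        raise ValueError(
            f"trait {trait.name!r}: {n} complete cases cannot support {n_params} parameters"
        )
    colnames = list(design.columns)
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in colnames])
    Q, kept = _incremental_qr(X)
    kept_cols = {colnames[j - 1] for j in kept if j > 0}  # offset for intercept
    proj = Q.T @ y
    total_ss = float(np.sum((y - y.mean()) ** 2))
    resid_ss = float(y @ y - proj @ proj)

    # map retained orthonormal columns back to term blocks
    col_term = {}
    for term, block in blocks.items():
        for c in block:
            col_term[c] = term
    seq_ss: dict[str, float] = {}
    dfs: dict[str, int] = {}
    dropped: list[str] = []
    pos = 0
    for j in kept:
        if j == 0:
            pos += 1
            continue
        term = col_term[colnames[j - 1]]
        seq_ss[term] = seq_ss.get(term, 0.0) + float(proj[pos] ** 2)
        dfs[term] = dfs.get(term, 0) + 1
        pos += 1
    terms = []
    for term, block in blocks.items():
        if term in seq_ss:
            terms.append(term)
        else:
            dropped.append(term)
    if dropped:
        logger.warning("trait %r: dropped aliased/constant terms %s", trait.name, dropped)

    resid_df = n - len(kept)
    mse = resid_ss / resid_df
    pvals = {}
    for term in terms:
        f = (seq_ss[term] / dfs[term]) / mse if mse > 0 else np.inf
        pvals[term] = float(stats.f.sf(f, dfs[term], resid_df))

    ols_cols = ["const"] + [c for c in colnames if c in kept_cols]
    Xo = sm.add_constant(df[[c for c in colnames if c in kept_cols]].astype(float), has_constant="add")
    ols = sm.OLS(y, Xo).fit()
    params = pd.Series(ols.params, index=ols_cols)

    return FullModelFit(
        trait=str(trait.name),
        n=n,
        terms=terms,
        seq_ss=pd.Series(seq_ss).reindex(terms),
        df=pd.Series(dfs).reindex(terms),
        pvalues=pd.Series(pvals).reindex(terms),
        total_ss=total_ss,
        resid_ss=resid_ss,
        dropped=dropped,
        params=params,
        resid_df=resid_df,
    )


@dataclass
class VarianceDecomposition:
    """Per-covariate explained variance fractions for one trait."""

    trait: str
    fractions: pd.Series    # sequential SS / total SS, in model order
    pvalues: pd.Series
    order: list[str]
    combined: float         # model SS / total SS (full-model R^2)
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "pvalue": self.pvalues}
        ).rename_axis("covariate")


def variance_decomposition(fit: FullModelFit) -> VarianceDecomposition:
    """Attribute trait variance to covariates by sequential sums of squares."""
    if fit.total_ss <= 0:
        raise ValueError(f"trait {fit.trait!r}: zero total sum of squares")
    fractions = fit.seq_ss / fit.total_ss
    return VarianceDecomposition(
        trait=fit.trait,
        fractions=fractions,
        pvalues=fit.pvalues,
        order=list(fit.terms),
        combined=float(fit.model_ss / fit.total_ss),
        n=fit.n,
    )


def significant_covariates(
    decomp: VarianceDecomposition, alpha: float = 0.05, m: int | None = None
) -> list[str]:
    """Covariates clearing the Bonferroni screen for this trait."""
    thr = bonferroni_threshold(alpha, m if m is not None else len(decomp.order))
    return [t for t in decomp.order if decomp.pvalues[t] < thr]


@dataclass
class AdjustedTrait:
    """Residualized, rank-inverse-normal trait values (mean 0, variance ~1)."""

    trait: str
    values: pd.Series          # NaN where the input was missing
    adjusted_for: list[str]


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Map values through ranks to standard normal quantiles.

    Average ranks for ties, then Phi^{-1}((rank - 0.5)/n); invariant to any
    strictly monotone transform of the input.
    """
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def adjust_and_rint(
    trait: pd.Series,
    covariates: CovariateTable,
    significant: Sequence[str],
) -> AdjustedTrait:
    """Residualize on significant covariates, then rank-transform to normality."""
    design, blocks = covariates.design()
    use_cols = [c for t in significant for c in blocks[t]]
    df = pd.concat([trait.rename("__y__"), design[use_cols]], axis=1, join="inner").dropna()
    y = df["__y__"].to_numpy(dtype=float)
    if len(np.unique(y)) < 3:
        raise ValueError(f"trait {trait.name!r}: need at least 3 distinct values")
    if use_cols:
        X = sm.add_constant(df[use_cols].astype(float), has_constant="add")
        resid = sm.OLS(y, X).fit().resid
    else:
        resid = y - y.mean()
    if np.ptp(resid) == 0:
        raise ValueError(f"trait {trait.name!r}: constant residuals")
    z = rank_inverse_normal(np.asarray(resid))
    out = pd.Series(np.nan, index=trait.index, name=trait.name)
    out.loc[df.index] = z
    return AdjustedTrait(trait=str(trait.name), values=out, adjusted_for=list(significant))


def correlate_pairs(
    adjusted: pd.DataFrame, r2_min: float = 0.5, min_overlap: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations between adjusted biomarkers.

    ``adjusted`` is proteins x individuals.  Returns pairs with rho^2
    strictly above ``r2_min``, ranked by rho^2 descending.  Pairs with too
    few shared observations are skipped with a warning.
    """
    proteins = list(adjusted.index)
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    rows = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a = adjusted.iloc[i]
            b = adjusted.iloc[j]
            ok = a.notna() & b.notna()
            if ok.sum() < min_overlap:
                logger.warning(
                    "pair (%s, %s): only %d shared observations, skipped",
                    proteins[i], proteins[j], int(ok.sum()),
                )
                continue
            rho, _ = stats.spearmanr(a[ok], b[ok])
            rows.append((proteins[i], proteins[j], float(rho), float(rho**2), int(ok.sum())))
    out = pd.DataFrame(rows, columns=["protein_a", "protein_b", "rho", "r2", "n"])
    out = out[out["r2"] > r2_min].sort_values("r2", ascending=False).reset_index(drop=True)
    return out
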