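"""Personalized, stratified biomarker reference intervals.

A population-wide reference interval ignores that a biomarker's 'normal'
level can differ several-fold between genotype groups, age bands or
medication users.  Here a reference profile is computed per stratum: a
normal distribution is fitted (mean, SD on the ddCq scale) within each
stratum of at least ``min_group_size`` individuals, and the stratum's
central reference interval and interquartile range are read off the fitted
normal.  Since ddCq is a log2 scale, between-stratum level ratios are
reported linearized as 100 * 2^(mean difference) percent.

The numeric choice of reference percentile is a package convention (the
central 95% by default) — outputs label it explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import VarianceDecomposition

logger = logging.getLogger(__name__)


@dataclass
class CutoffProfile:
    """Per-stratum normal-fit reference intervals for one biomarker."""

    biomarker: str
    stratifier: str
    table: pd.DataFrame          # index: stratum; n, mean, sd, ref_lo, ref_hi, iqr_lo, iqr_hi
    central: float               # central interval mass, e.g. 0.95
    suppressed: list[str] = field(default_factory=list)

    def interval_for(self, stratum: str) -> tuple[float, float]:
        """Per-individual lookup: the reference interval of a stratum."""
        row = self.table.loc[stratum]
        return float(row["ref_lo"]), float(row["ref_hi"])


def stratified_reference(
    values: pd.Series,
    strata: pd.Series,
    biomarker: str = "",
    stratifier: str = "",
    min_group_size: int = 10,
    central: float = 0.95,
) -> CutoffProfile:
    """Normal-fit reference intervals within each stratum.

    Strata with fewer than ``min_group_size`` non-missing values are
    suppressed (logged, not reported).  Intervals are symmetric about the
    stratum mean on the ddCq scale: mean +/- z * SD with z the standard
    normal quantile of the central mass (1.96 for 95%), and the IQR
    half-width 0.6745 * SD.
    """
    if not (0 < central < 1):
        raise ValueError("central must lie in (0, 1)")
    z_ref = stats.norm.ppf(0.5 + central / 2.0)
    z_iqr = stats.norm.ppf(0.75)
    df = pd.concat([values.rename("v"), strata.rename("s")], axis=1, join="inner").dropna()
    rows = {}
    suppressed = []
    for s, grp in df.groupby("s", sort=True):
        n = len(grp)
        if n < min_group_size:
            suppressed.append(str(s))
            logger.info("stratum %r suppressed (n=%d < %d)", s, n, min_group_size)
            continue
        mu = float(grp["v"].mean())
        sd = float(grp["v"].std(ddof=1))
        rows[str(s)] = {
            "n": n,
            "mean": mu,
            "sd": sd,
            "ref_lo": mu - z_ref * sd,
            "ref_hi": mu + z_ref * sd,
            "iqr_lo": mu - z_iqr * sd,
            "iqr_hi": mu + z_iqr * sd,
        }
    if not rows:
        logger.warning("no stratum of %r reaches n >= %d", biomarker, min_group_size)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return CutoffProfile(
        biomarker=biomarker, stratifier=stratifier, table=table,
        central=central, suppressed=suppressed,
    )


def linearized_ratio(mean_a: float, mean_b: float) -> float:
    """Level of stratum a relative to b, in percent on the linear scale.

    Means are on the log2 (ddCq) scale, so the ratio is 100 * 2^(a - b):
    a one-unit ddCq difference is a doubling (200%).
    """
    if not (np.isfinite(mean_a) and np.isfinite(mean_b)):
        raise ValueError("stratum means must be finite")
    return float(100.0 * 2.0 ** (mean_a - mean_b))


def age_tertiles(age: pd.Series) -> pd.Series:
    """Default age stratification: tertiles labelled by their bounds."""
    q = age.quantile([1 / 3, 2 / 3])
    lab = pd.Series(index=age.index, dtype=object)
    lab[age <= q.iloc[0]] = f"age<={q.iloc[0]:.0f}"
    lab[(age > q.iloc[0]) & (age <= q.iloc[1])] = f"age{q.iloc[0]:.0f}-{q.iloc[1]:.0f}"
    lab[age > q.iloc[1]] = f"age>{q.iloc[1]:.0f}"
    return lab


def covariate_profile(
    decomposition: VarianceDecomposition,
    snp_var_explained: dict[str, float] | None = None,
    combined_with_snps: float | None = None,
) -> pd.DataFrame:
    """Ranked factor-contribution table for one biomarker.

    Merges covariate variance fractions with per-SNP variance-explained
    fractions (top marker and, when present, the top conditional marker)
    and ranks factors by fraction.  The combined-model total is taken from
    ``combined_with_snps`` when a refit including the SNPs is available;
    otherwise the covariate-only combined fraction is reported and flagged.
    """
    rows = [
        {"factor": t, "kind": "covariate", "fraction": float(decomposition.fractions[t])}
        for t in decomposition.order
    ]
    for marker, frac in (snp_var_explained or {}).items():
        rows.append({"factor": marker, "kind": "snp", "fraction": float(frac)})
    out = pd.DataFrame(rows).sort_values("fraction", ascending=False).reset_index(drop=True)
    combined = combined_with_snps
    flag = ""
    if combined is None:
        combined = decomposition.combined
        if snp_var_explained:
            flag = "covariates_only"
    if combined > 1.0 + 1e-9:
        raise ValueError("combined fraction exceeds 1")
    out.attrs["combined"] = float(combined)
    out.attrs["combined_flag"] = flag
    out.attrs["biomarker"] = decomposition.trait
    return out
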