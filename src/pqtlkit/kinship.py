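"""Genotype QC and genomic kinship estimation.

QC follows the usual array-genotyping conventions: marker and individual
call-rate thresholds, an exact Hardy-Weinberg test with a Bonferroni
correction across markers, and a minor-allele count of at least one
chromosome.  The relationship matrix is the allele-frequency-standardized
genomic estimator

    K_ij = (1/L) sum_l (g_il - 2 p_l)(g_jl - 2 p_l) / (2 p_l (1 - p_l))

whose expectation is twice the kinship coefficient (1 on the diagonal for
non-inbred individuals, 0.5 for parent-offspring).  The absolute scale is
internal: the polygenic model normalizes by the mean diagonal, so
heritability is invariant to rescaling K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .synthetic import GenotypeDosages

logger = logging.getLogger(__name__)


@dataclass
class HWEResult:
    """Genotype counts and the exact two-sided Hardy-Weinberg p-value."""

    n_aa: int
    n_ab: int
    n_bb: int
    pvalue: float


def _log_het_prob(n_ab: int, n: int, n_a: int) -> float:
    """Log probability of ``n_ab`` heterozygotes given n genotypes, n_a minor alleles."""
    n_aa = (n_a - n_ab) // 2
    n_bb = n - n_aa - n_ab
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_ab + 1)
        - gammaln(n_bb + 1)
        + n_ab * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(2 * n - n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> HWEResult:
    """Exact conditional Hardy-Weinberg test.

    Two-sided in the standard sense: the p-value sums the conditional
    probabilities (given the allele counts) of every heterozygote count no
    more probable than the observed one.  Invariant to swapping allele
    labels; monomorphic tables give p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_a = min(n_a, 2 * n - n_a)  # minor allele count
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.array([_log_het_prob(int(h), n, n_a) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[int(np.where(hets == n_ab)[0][0])]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return HWEResult(n_aa, n_ab, n_bb, min(1.0, p))


@dataclass
class GenotypeQCReport:
    """Markers/individuals removed during genotype QC, with reasons."""

    removed_markers: dict[str, str] = field(default_factory=dict)
    removed_individuals: dict[str, str] = field(default_factory=dict)
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    hwe_threshold: float | None = None


def genotype_qc(
    genotypes: GenotypeDosages,
    marker_call_rate: float = 0.95,
    individual_call_rate: float = 0.98,
    hwe_alpha: float = 0.05,
    min_mac: int = 1,
) -> tuple[GenotypeDosages, GenotypeQCReport]:
    """Filter markers and individuals by call rate, HWE and minor-allele count.

    Thresholds are inclusive (a marker at exactly 95% call rate is
    retained).  The HWE cutoff is Bonferroni-corrected over the markers
    tested; HWE is evaluated on hard calls only (dosage-only data skip it
    with a logged note).  ``min_mac`` counts minor-allele chromosomes.
    """
    for name, v in (("marker_call_rate", marker_call_rate), ("individual_call_rate", individual_call_rate)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1]")
    if not (0.0 < hwe_alpha < 1.0):
        raise ValueError("hwe_alpha must lie in (0, 1)")
    D = genotypes.dosages
    report = GenotypeQCReport(
        n_markers_in=D.shape[1], n_individuals_in=D.shape[0]
    )
    eps = 1e-12

    m_rate = D.notna().mean(axis=0)
    for mk in D.columns[m_rate < marker_call_rate - eps]:
        report.removed_markers[mk] = "marker_call_rate"
    keep_m = [c for c in D.columns if c not in report.removed_markers]

    i_rate = D[keep_m].notna().mean(axis=1)
    for iid in D.index[i_rate < individual_call_rate - eps]:
        report.removed_individuals[str(iid)] = "individual_call_rate"
    keep_i = [i for i in D.index if str(i) not in report.removed_individuals]
    sub = D.loc[keep_i, keep_m]

    if genotypes.hard_call:
        thr = hwe_alpha / max(1, len(keep_m))
        report.hwe_threshold = thr
        for mk in keep_m:
            g = sub[mk].dropna().to_numpy()
            counts = [(g == k).sum() for k in (0, 1, 2)]
            if sum(counts) == 0:
                report.removed_markers[mk] = "no_calls"
                continue
            if hwe_exact(*[int(c) for c in counts]).pvalue < thr:
                report.removed_markers[mk] = "hwe"
        keep_m = [c for c in keep_m if c not in report.removed_markers]
        sub = sub[keep_m]
    else:
        logger.info("dosage-only genotypes: Hardy-Weinberg filter skipped")

    s = sub.sum(axis=0, skipna=True)
    n_called = sub.notna().sum(axis=0)
    mac = np.minimum(s, 2 * n_called - s)
    for mk in sub.columns[mac < min_mac]:
        report.removed_markers[mk] = "mac"
    keep_m = [c for c in keep_m if c not in report.removed_markers]

    markers = genotypes.markers[genotypes.markers["id"].isin(keep_m)].reset_index(drop=True)
    out = GenotypeDosages(markers=markers, dosages=sub[keep_m], hard_call=genotypes.hard_call)
    report.n_markers_out = len(keep_m)
    report.n_individuals_out = len(keep_i)
    logger.info(
        "genotype QC: %d/%d markers, %d/%d individuals retained",
        report.n_markers_out, report.n_markers_in,
        report.n_individuals_out, report.n_individuals_in,
    )
    return out, report


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix on the 2*kinship scale."""

    values: pd.DataFrame
    n_markers: int
    estimator: str = "standardized_grm"

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def subset(self, iids) -> "KinshipMatrix":
        return KinshipMatrix(self.values.loc[list(iids), list(iids)], self.n_markers, self.estimator)


def genomic_kinship(genotypes: GenotypeDosages, min_markers: int = 100) -> KinshipMatrix:
    """Allele-frequency-standardized genomic relationship matrix.

    Sample allele frequencies use complete cases per marker; missing
    dosages contribute zero after centering (mean imputation).  Monomorphic
    markers must be filtered beforehand — their zero variance would divide
    by zero — so their presence raises.
    """
    D = genotypes.dosages.to_numpy(dtype=float)
    n, L = D.shape
    if L < min_markers:
        raise ValueError(f"need at least {min_markers} markers, got {L}")
    p = np.nanmean(D, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)) or np.any(~np.isfinite(p)):
        bad = genotypes.dosages.columns[(p <= 0) | (p >= 1) | ~np.isfinite(p)]
        raise ValueError(f"monomorphic markers reached kinship estimation: {list(bad[:5])}")
    C = D - 2.0 * p
    C[np.isnan(C)] = 0.0
    w = 1.0 / (2.0 * p * (1.0 - p))
    K = (C * w) @ C.T / L
    K = (K + K.T) / 2.0
    ids = genotypes.dosages.index
    return KinshipMatrix(pd.DataFrame(K, index=ids, columns=ids), n_markers=L)
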