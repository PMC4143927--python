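"""Synthetic family cohorts with the statistical structure the pipeline assumes.

Generates a two-cohort, family-structured sample (nuclear families plus
singletons), gene-dropped genotype dosages, clinical/lifestyle covariates
with realistic age-medication collinearity, heritable protein traits under
an additive polygenic model, and raw plate-level Cq data whose normalization
inverts exactly.  Every generator is seed-deterministic.

The trait model is the generative inverse of the analysis model:

    y = baseline + X beta_cov + g beta_snp + batch + u + e

with ``u ~ MVN(0, sigma2_g K)`` (K the expected-kinship matrix on the
2*kinship scale), ``e ~ N(0, sigma2_e I)``, and sigma2_g = h2 * sigma_total.
Below-LOD censoring is emulated at plate-rendering time by placing the
negative control at a per-assay quantile of the true ddCq distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pea import CONTROL_CHANNELS, WELL_NEGATIVE, WELL_POSITIVE, WELL_SAMPLE, AssayDefinition, PlateRun

COHORT_DISCOVERY = "discovery"
COHORT_REPLICATION = "replication"


# ---------------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class PedigreeSpec:
    """Layout of a synthetic sample: nuclear families plus unrelated singletons.

    ``cohort_split`` is the fraction of families (and of singletons)
    assigned to the discovery cohort; families are never split across
    cohorts, mirroring recruitment by village/collection round.
    """

    n_families: int
    offspring_per_family: int
    n_singletons: int = 0
    parents_per_family: int = 2
    cohort_split: float = 2 / 3

    def __post_init__(self) -> None:
        for name in ("n_families", "offspring_per_family", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.parents_per_family != 2:
            raise ValueError("only two-parent families are supported")
        if not (0.0 <= self.cohort_split <= 1.0):
            raise ValueError("cohort_split must be in [0, 1]")
        if self.n_individuals == 0:
            raise ValueError("empty pedigree")

    @property
    def n_individuals(self) -> int:
        return self.n_families * (2 + self.offspring_per_family) + self.n_singletons


def simulate_pedigree(spec: PedigreeSpec, seed: int) -> pd.DataFrame:
    """Build a pedigree table: iid, father, mother, family, cohort, sex.

    Founders (parents and singletons) have empty parent fields.  Rows are in
    topological order (parents precede offspring).
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_disc_fam = int(round(spec.cohort_split * spec.n_families))
    for f in range(spec.n_families):
        fam = f"F{f:04d}"
        cohort = COHORT_DISCOVERY if f < n_disc_fam else COHORT_REPLICATION
        pa, ma = f"{fam}_P1", f"{fam}_P2"
        rows.append((pa, "", "", fam, cohort, 1))
        rows.append((ma, "", "", fam, cohort, 2))
        for k in range(spec.offspring_per_family):
            sex = int(rng.integers(1, 3))
            rows.append((f"{fam}_C{k}", pa, ma, fam, cohort, sex))
    n_disc_single = int(round(spec.cohort_split * spec.n_singletons))
    for s in range(spec.n_singletons):
        cohort = COHORT_DISCOVERY if s < n_disc_single else COHORT_REPLICATION
        rows.append((f"S{s:04d}", "", "", f"S{s:04d}", cohort, int(rng.integers(1, 3))))
    ped = pd.DataFrame(rows, columns=["iid", "father", "mother", "family", "cohort", "sex"])
    return ped.set_index("iid", drop=False)


def expected_kinship(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Pedigree-expected relationship matrix on the 2*kinship scale.

    Computed by the standard recursive kinship algorithm (path counting):
    phi(i,i) = (1 + phi(f_i, m_i))/2 and phi(i,j) = (phi(f_i,j) +
    phi(m_i,j))/2 for j born before i.  Returned as 2*phi so that
    non-inbred self-relationship is 1 and parent-offspring is 0.5, matching
    the genomic-relationship estimator scale.
    """
    iids = list(pedigree["iid"])
    idx = {iid: k for k, iid in enumerate(iids)}
    n = len(iids)
    phi = np.zeros((n, n))
    fa = pedigree["father"].tolist()
    mo = pedigree["mother"].tolist()
    for i in range(n):
        f, m = fa[i], mo[i]
        fi = idx.get(f, -1) if f else -1
        mi = idx.get(m, -1) if m else -1
        if fi >= i or mi >= i:
            raise ValueError("pedigree rows must be topologically ordered")
        for j in range(i):
            p = 0.0
            if fi >= 0:
                p += 0.5 * phi[fi, j]
            if mi >= 0:
                p += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = p
        self_k = 0.5
        if fi >= 0 and mi >= 0:
            self_k = 0.5 * (1.0 + phi[fi, mi])
        phi[i, i] = self_k
    return pd.DataFrame(2.0 * phi, index=iids, columns=iids)


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeDosages:
    """Marker metadata plus an individuals x markers dosage matrix.

    Dosages count the effect allele (0..2); NaN marks a missing call.
    ``hard_call`` indicates integer genotypes (True for gene-dropped data).
    """

    markers: pd.DataFrame  # id, chrom, pos, ref, alt, af
    dosages: pd.DataFrame  # individuals x marker ids
    hard_call: bool = True

    def __post_init__(self) -> None:
        d = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(d) | ((d >= 0) & (d <= 2))
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2]")
        af = self.markers["af"].to_numpy(dtype=float)
        if ((af <= 0) | (af >= 1)).any():
            raise ValueError("allele frequencies must lie in (0, 1)")
        for _, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def ids(self) -> pd.Index:
        return self.dosages.index

    def subset_individuals(self, iids: Sequence[str]) -> "GenotypeDosages":
        return GenotypeDosages(self.markers, self.dosages.loc[list(iids)], self.hard_call)


def _default_maf_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.05, 0.5, size=n)


def simulate_genotypes(
    pedigree: pd.DataFrame,
    n_markers: int,
    seed: int,
    maf_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    missing_rate: float = 0.0,
    n_chromosomes: int = 22,
) -> GenotypeDosages:
    """Gene-drop genotypes through a pedigree.

    Founder haplotypes are Bernoulli draws at each marker's allele
    frequency; non-founders inherit one allele from each parent with free
    recombination between markers.  Hard calls in {0,1,2} by construction;
    Mendelian transmission holds exactly.
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    rng = np.random.default_rng(seed)
    maf_sampler = maf_sampler or _default_maf_sampler
    p = np.asarray(maf_sampler(rng, n_markers), dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("founder allele frequencies must lie strictly in (0, 1)")

    iids = list(pedigree["iid"])
    idx = {iid: k for k, iid in enumerate(iids)}
    n = len(iids)
    hap = np.zeros((n, n_markers, 2), dtype=np.int8)
    fa, mo = pedigree["father"].tolist(), pedigree["mother"].tolist()
    for i in range(n):
        if fa[i] and mo[i]:
            for h, parent in enumerate((fa[i], mo[i])):
                pick = rng.integers(0, 2, size=n_markers)
                hap[i, :, h] = hap[idx[parent], np.arange(n_markers), pick]
        else:
            hap[i] = rng.random((n_markers, 2)) < p[:, None]
    dos = hap.sum(axis=2).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan

    per_chrom = max(1, math.ceil(n_markers / n_chromosomes))
    k = np.arange(n_markers)
    markers = pd.DataFrame(
        {
            "id": [f"snp{j:06d}" for j in k],
            "chrom": (k // per_chrom + 1).astype(int),
            "pos": ((k % per_chrom + 1) * 997).astype(int),
            "ref": "A",
            "alt": "G",
            "af": p,
        }
    )
    dosages = pd.DataFrame(dos, index=iids, columns=markers["id"].tolist())
    return GenotypeDosages(markers=markers, dosages=dosages, hard_call=True)


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(
    pedigree: pd.DataFrame,
    seed: int,
    n_medications: int = 10,
    med_prevalence: tuple[float, float] = (0.002, 0.054),
    age_logodds_per_sd: float = 1.2,
) -> "pd.DataFrame":
    """Clinical/lifestyle covariate table for a pedigree.

    Emulates a population health survey: age uniform on 15-90, sex from the
    pedigree, anthropometrics and blood pressure with mild age trends,
    smoking and a traditional-lifestyle flag, and ``n_medications`` rare
    binary medication indicators whose prevalence rises with age through a
    logistic link (so the medication count is age-correlated, as in real
    questionnaire data).  Returns a plain DataFrame indexed by iid; wrap in
    :class:`pqtlkit.covariates.CovariateTable` for model fitting.
    """
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    age = rng.uniform(15, 90, size=n)
    age_z = (age - age.mean()) / age.std()
    df = pd.DataFrame(index=pedigree.index)
    df["age"] = age
    df["sex"] = pedigree["sex"].to_numpy()
    df["bmi"] = 26 + 2.0 * age_z + rng.normal(0, 3.5, n)
    df["sbp"] = 125 + 6.0 * age_z + rng.normal(0, 12, n)
    df["smoker"] = (rng.random(n) < 0.20).astype(int)
    df["traditional_lifestyle"] = (rng.random(n) < 0.15).astype(int)
    df["cohort"] = pedigree["cohort"].to_numpy()
    lo, hi = med_prevalence
    prevs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_medications))
    for k, prev in enumerate(prevs):
        eta = logit(prev) + age_logodds_per_sd * age_z
        df[f"med_{k:02d}"] = (rng.random(n) < expit(eta)).astype(int)
    return df


# ---------------------------------------------------------------------------
# traits


@dataclass(frozen=True)
class TraitModel:
    """Generative model for one protein trait on the ddCq scale.

    ``h2`` is the target narrow-sense heritability; ``sigma_total`` the
    total trait variance (ddCq^2).  ``covariate_effects`` are (name, beta)
    pairs; ``cis_snp`` an optional (marker id, beta per dosage unit).  The
    residual variance absorbs whatever the genetic and fixed parts do not
    claim; the claimed fractions may not exceed 1 (checked once covariate
    and dosage variances are known).  ``batch_effect`` is an additive shift
    applied to the replication cohort, outside the variance budget.
    """

    name: str
    h2: float
    sigma_total: float = 1.0
    covariate_effects: tuple[tuple[str, float], ...] = ()
    cis_snp: tuple[str, float] | None = None
    lod_censor_fraction: float = 0.0
    batch_effect: float = 0.0
    baseline: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
        if self.sigma_total <= 0:
            raise ValueError("sigma_total must be positive")
        if not (0.0 <= self.lod_censor_fraction < 1.0):
            raise ValueError("lod_censor_fraction must lie in [0, 1)")


@dataclass
class TraitPanel:
    """Simulated protein panel with realized variance components per trait."""

    ddcq: pd.DataFrame  # proteins x individuals
    components: dict[str, dict[str, float]] = field(default_factory=dict)
    models: dict[str, TraitModel] = field(default_factory=dict)
    realized: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def simulate_traits(
    models: Sequence[TraitModel],
    kinship: pd.DataFrame,
    seed: int,
    genotypes: GenotypeDosages | None = None,
    covariates: pd.DataFrame | None = None,
) -> TraitPanel:
    """Draw heritable traits: y = baseline + X b + g b_snp + batch + u + e.

    ``u`` is multivariate normal with covariance sigma2_g * K (one Cholesky
    factorization shared across traits), ``e`` independent normal.  Raises
    if a model's heritability plus fixed-effect explained fractions exceed
    one.  Realized per-component variances are recorded for recovery tests.
    """
    rng = np.random.default_rng(seed)
    iids = list(kinship.index)
    n = len(iids)
    K = kinship.to_numpy(dtype=float)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    panel = {}
    components: dict[str, dict[str, float]] = {}
    realized: dict[str, dict[str, np.ndarray]] = {}
    for model in models:
        st = model.sigma_total
        fixed = np.zeros(n)
        frac_fixed = 0.0
        comp: dict[str, float] = {}
        for name, beta in model.covariate_effects:
            if covariates is None or name not in covariates.columns:
                raise ValueError(f"covariate {name!r} required by trait {model.name} not given")
            x = covariates.loc[iids, name].to_numpy(dtype=float)
            fixed = fixed + beta * x
            f = beta**2 * np.var(x) / st
            frac_fixed += f
            comp[f"frac_{name}"] = f
        if model.cis_snp is not None:
            marker, beta = model.cis_snp
            if genotypes is None or marker not in genotypes.dosages.columns:
                raise ValueError(f"cis marker {marker!r} for trait {model.name} not given")
            g = genotypes.dosages.loc[iids, marker].to_numpy(dtype=float)
            g = np.where(np.isnan(g), np.nanmean(g), g)
            fixed = fixed + beta * g
            f = beta**2 * np.var(g) / st
            frac_fixed += f
            comp["frac_cis_snp"] = f
        if model.h2 + frac_fixed > 1.0 + 1e-12:
            raise ValueError(
                f"trait {model.name}: h2 ({model.h2:.3f}) plus fixed-effect fractions "
                f"({frac_fixed:.3f}) exceed 1"
            )
        sigma2_g = model.h2 * st
        sigma2_e = st * (1.0 - model.h2 - frac_fixed)
        u = math.sqrt(sigma2_g) * (L @ rng.standard_normal(n))
        e = math.sqrt(sigma2_e) * rng.standard_normal(n)
        y = model.baseline + fixed + u + e
        if model.batch_effect != 0.0 and covariates is not None and "cohort" in covariates.columns:
            shift = (covariates.loc[iids, "cohort"] == COHORT_REPLICATION).to_numpy(dtype=float)
            y = y + model.batch_effect * shift
        panel[model.name] = y
        comp.update(
            sigma2_g=sigma2_g,
            sigma2_e=sigma2_e,
            var_polygenic=float(np.var(u)),
            var_env=float(np.var(e)),
            var_fixed=float(np.var(fixed)),
            frac_fixed=frac_fixed,
        )
        components[model.name] = comp
        realized[model.name] = {"polygenic": u, "environment": e, "fixed": fixed}
    ddcq = pd.DataFrame(panel, index=iids).T
    return TraitPanel(
        ddcq=ddcq,
        components=components,
        models={m.name: m for m in models},
        realized=realized,
    )


# ---------------------------------------------------------------------------
# plate rendering


def default_assays(panel: TraitPanel, correction: float = 3.0) -> list[AssayDefinition]:
    """One assay per trait with a constant manufacturer correction."""
    return [AssayDefinition(f"assay_{p}", p, correction) for p in panel.ddcq.index]


def render_plates(
    panel: TraitPanel,
    assays: list[AssayDefinition],
    seed: int,
    n_wells: int = 96,
    samples_per_plate: int = 92,
    ext_mean: float = 18.0,
    ext_sd: float = 0.5,
    control_sd: float = 0.05,
    control_outlier_samples: Sequence[str] = (),
) -> list[PlateRun]:
    """Render a trait panel into raw plate-level Cq data.

    Exact inverse of ddCq normalization on uncensored cells:
    Cq = Cq(ext) + correction - ddCq.  Negative-control wells are placed at
    the per-assay ddCq quantile given by each trait's
    ``lod_censor_fraction`` (or well below the sample minimum when zero), so
    that masking at the resulting LOD censors about that fraction of cells.
    Samples named in ``control_outlier_samples`` get a grossly shifted
    incubation control, for exercising sample QC.
    """
    if samples_per_plate > n_wells - 4:
        raise ValueError("plate layout needs 4 control wells")
    rng = np.random.default_rng(seed)
    if panel.ddcq.shape[1] == 0:
        return []
    proteins = list(panel.ddcq.index)
    by_protein = {a.protein: a for a in assays}
    missing = [p for p in proteins if p not in by_protein]
    if missing:
        raise ValueError(f"no assay defined for proteins: {missing}")

    # per-assay negative-control ddCq (shared across plates so the LOD has
    # zero between-plate SD and equals the censoring threshold exactly)
    neg_ddcq = {}
    for p in proteins:
        vals = panel.ddcq.loc[p].to_numpy(dtype=float)
        frac = panel.models[p].lod_censor_fraction if p in panel.models else 0.0
        if frac > 0:
            neg_ddcq[p] = float(np.quantile(vals, frac))
        else:
            neg_ddcq[p] = float(vals.min() - 3.0)

    individuals = list(panel.ddcq.columns)
    plates: list[PlateRun] = []
    outlier_set = set(control_outlier_samples)
    for pi, start in enumerate(range(0, len(individuals), samples_per_plate)):
        chunk = individuals[start : start + samples_per_plate]
        wells = [f"W{w + 1:02d}" for w in range(len(chunk) + 4)]
        types = [WELL_SAMPLE] * len(chunk) + [WELL_NEGATIVE] + [WELL_POSITIVE] * 3
        sids = chunk + ["NEG", "POS1", "POS2", "POS3"]
        ext = rng.normal(ext_mean, ext_sd, size=len(wells))
        cq = np.empty((len(wells), len(proteins)))
        for j, p in enumerate(proteins):
            corr = by_protein[p].correction
            ddcq_col = np.empty(len(wells))
            ddcq_col[: len(chunk)] = panel.ddcq.loc[p, chunk].to_numpy(dtype=float)
            ddcq_col[len(chunk)] = neg_ddcq[p]
            ddcq_col[len(chunk) + 1 :] = float(panel.ddcq.loc[p].max() + 2.0)
            cq[:, j] = ext + corr - ddcq_col
        controls = pd.DataFrame(
            {
                "inc1": rng.normal(10.0, control_sd, len(wells)),
                "inc2": rng.normal(12.0, control_sd, len(wells)),
                "ext": ext,
                "det": rng.normal(14.0, control_sd, len(wells)),
            },
            index=wells,
        )
        for w, sid in zip(wells, sids):
            if sid in outlier_set:
                controls.loc[w, "inc1"] += 10.0
        plates.append(
            PlateRun(
                plate_id=f"plate{pi:03d}",
                cq=pd.DataFrame(
                    cq, index=wells, columns=[by_protein[p].assay_id for p in proteins]
                ),
                well_type=pd.Series(types, index=wells),
                sample_id=pd.Series(sids, index=wells),
                controls=controls,
            )
        )
    return plates


# ---------------------------------------------------------------------------
# ABO haplotypes

#: Realistic European ABO haplotype frequencies (sum to one).
DEFAULT_ABO_FREQS = {"O01": 0.55, "O02": 0.05, "A1": 0.22, "A2": 0.08, "B": 0.10}


def simulate_abo(
    iids: Sequence[str],
    seed: int,
    haplotype_freqs: dict[str, float] | None = None,
    missing_rate: float = 0.005,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ABO diplotypes and the corresponding four-SNP tag genotypes.

    Returns ``(truth, genotypes)``: truth has columns hap1/hap2/diplotype,
    genotypes is individuals x four tag SNPs with tag-allele counts (NaN
    where a call is missing at ``missing_rate``).  Haplotypes are drawn
    independently per individual at the given frequencies (no family
    structure; blood group enters the pipeline only as a covariate).
    """
    from .abo import TAG_SNPS, haplotype_signature

    freqs = haplotype_freqs or DEFAULT_ABO_FREQS
    names = sorted(freqs)
    pvec = np.array([freqs[h] for h in names], dtype=float)
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(seed)
    h1 = rng.choice(names, size=len(iids), p=pvec)
    h2 = rng.choice(names, size=len(iids), p=pvec)
    dip = ["/".join(sorted([a, b])) for a, b in zip(h1, h2)]
    truth = pd.DataFrame({"hap1": h1, "hap2": h2, "diplotype": dip}, index=list(iids))
    geno = np.array(
        [np.asarray(haplotype_signature(a)) + np.asarray(haplotype_signature(b)) for a, b in zip(h1, h2)],
        dtype=float,
    )
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = np.nan
    genotypes = pd.DataFrame(geno, index=list(iids), columns=list(TAG_SNPS))
    return truth, genotypes
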