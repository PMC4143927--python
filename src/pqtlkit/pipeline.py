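"""End-to-end pipeline: simulate -> QC -> covariates -> kinship ->
heritability -> GWAS -> conditional -> ABO -> cutoffs.

Each stage reads its inputs from the run directory (or from user-supplied
paths), writes delimited-text artifacts, and logs counts at every filter.
Reruns with the same configuration and seed produce byte-identical
artifacts.  The configuration is a YAML file mirroring
:class:`PipelineConfig`; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, abo, covariates as cov, cutoffs as cut, gwas as gw, io, kinship as kin, pea, synthetic as syn

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "qc", "covariates", "kinship", "heritability",
    "gwas", "conditional", "abo", "cutoffs",
]


def _from_dict(cls, data: dict, path: str = ""):
    if data is None:
        data = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown configuration key(s) {unknown} under '{path or 'top level'}'")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if dataclasses.is_dataclass(f.type) or (isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)):
                v = _from_dict(f.default_factory, v, f"{path}.{f.name}" if path else f.name)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class SyntheticConfig:
    n_families: int = 130
    offspring_per_family: int = 4
    n_singletons: int = 120
    cohort_split: float = 2 / 3
    n_markers: int = 5000
    n_proteins: int = 10
    genotype_missing_rate: float = 0.002
    abo_missing_rate: float = 0.005


@dataclass
class QcConfig:
    min_protein_obs: int = 200
    max_below_lod_fraction: float = 0.75
    lod_n_sd: float = 3.0
    control_outlier_mads: float = 3.0


@dataclass
class CovariateConfig:
    alpha: float = 0.05
    r2_min: float = 0.5


@dataclass
class GenotypeQcConfig:
    marker_call_rate: float = 0.95
    individual_call_rate: float = 0.98
    hwe_alpha: float = 0.05
    min_mac: int = 1


@dataclass
class GwasConfig:
    alpha: float = 0.05
    conditional_cutoff: float = 5e-8
    min_mac: int = 3


@dataclass
class CutoffConfig:
    min_group_size: int = 10
    central: float = 0.95


@dataclass
class StageToggles:
    simulate: bool = True
    qc: bool = True
    covariates: bool = True
    kinship: bool = True
    heritability: bool = True
    gwas: bool = True
    conditional: bool = True
    abo: bool = True
    cutoffs: bool = True


@dataclass
class InputPaths:
    """External inputs; empty fields fall back to artifacts in the run dir."""

    plates_dir: str = ""
    assays: str = ""
    covariates: str = ""
    dosages: str = ""
    markers: str = ""
    abo_genotypes: str = ""


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "pqtlkit_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    inputs: InputPaths = field(default_factory=InputPaths)
    qc: QcConfig = field(default_factory=QcConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    genotype_qc: GenotypeQcConfig = field(default_factory=GenotypeQcConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    stages: StageToggles = field(default_factory=StageToggles)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return _from_dict(cls, data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    def out(self, name: str) -> Path:
        return Path(self.outdir) / name

    def input_or_artifact(self, input_name: str, artifact: str) -> Path:
        p = getattr(self.inputs, input_name)
        return Path(p) if p else self.out(artifact)


def default_trait_models(
    n_proteins: int, markers: pd.DataFrame, covariate_names: list[str]
) -> list[syn.TraitModel]:
    """Study-condition trait models for the synthetic cohort.

    Heritabilities span 0.2-0.78; a few proteins carry a cis SNP explaining
    up to ~27% of variance, an age effect of up to ~27%, a rare-medication
    effect, a cohort batch shift, and below-LOD censoring — the features the
    downstream analysis is built to detect.
    """
    h2s = np.linspace(0.20, 0.78, n_proteins)
    cis_fracs = {0: 0.27, 1: 0.15, 2: 0.08}
    age_fracs = {0: 0.05, 3: 0.27, 4: 0.10}
    models = []
    step = max(1, len(markers) // (n_proteins + 1))
    age_var = (90 - 15) ** 2 / 12.0  # uniform age variance
    for k in range(n_proteins):
        budget = 0.90 - h2s[k]  # fixed effects may not crowd out the residual
        effects = []
        if k in age_fracs:
            frac = min(age_fracs[k], max(budget, 0.0))
            budget -= frac
            if frac > 0.01:
                effects.append(("age", float(np.sqrt(frac / age_var))))
        if k == 5 and any(c.startswith("med_") for c in covariate_names):
            effects.append(("med_00", 1.5))
        cis = None
        if k in cis_fracs:
            frac = min(cis_fracs[k], max(budget, 0.0))
            if frac > 0.01:
                mrow = markers.iloc[(k + 1) * step]
                p = float(mrow["af"])
                beta = float(np.sqrt(frac / (2 * p * (1 - p))))
                cis = (str(mrow["id"]), beta)
        models.append(
            syn.TraitModel(
                name=f"protein_{k:02d}",
                h2=float(h2s[k]),
                sigma_total=1.0,
                covariate_effects=tuple(effects),
                cis_snp=cis,
                lod_censor_fraction=0.15 if k == 7 else (0.05 if k == 8 else 0.0),
                batch_effect=0.2 if k in (2, 6) else 0.0,
            )
        )
    return models


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> None:
    s = cfg.synthetic
    spec = syn.PedigreeSpec(
        n_families=s.n_families,
        offspring_per_family=s.offspring_per_family,
        n_singletons=s.n_singletons,
        cohort_split=s.cohort_split,
    )
    ped = syn.simulate_pedigree(spec, seed=cfg.seed)
    genotypes = syn.simulate_genotypes(
        ped, n_markers=s.n_markers, seed=cfg.seed + 1, missing_rate=s.genotype_missing_rate
    )
    covars = syn.simulate_covariates(ped, seed=cfg.seed + 2)
    kin_exp = syn.expected_kinship(ped)
    models = default_trait_models(s.n_proteins, genotypes.markers, list(covars.columns))
    panel = syn.simulate_traits(
        models, kin_exp, seed=cfg.seed + 3, genotypes=genotypes, covariates=covars
    )
    assays = syn.default_assays(panel)
    plates = syn.render_plates(panel, assays, seed=cfg.seed + 4)
    truth, abo_geno = syn.simulate_abo(
        list(ped.index), seed=cfg.seed + 5, missing_rate=s.abo_missing_rate
    )

    io.write_table(ped, cfg.out("pedigree.tsv"), index=False)
    io.write_dosages(genotypes, cfg.out("dosages.tsv"), cfg.out("markers.tsv"))
    io.write_table(covars, cfg.out("covariates.tsv"))
    io.write_plates(plates, cfg.out("plates"))
    io.write_assays(assays, cfg.out("assays.yaml"))
    io.write_table(abo_geno, cfg.out("abo_genotypes.tsv"))
    io.write_table(truth, cfg.out("abo_truth.tsv"))
    io.write_table(pd.DataFrame(panel.components).T, cfg.out("true_components.tsv"))
    cis = {
        m.name: {"marker": m.cis_snp[0], "beta": m.cis_snp[1]}
        for m in models if m.cis_snp
    }
    cfg.out("true_cis.yaml").write_text(yaml.safe_dump(cis, sort_keys=True))
    logger.info("simulated %d individuals, %d markers, %d proteins",
                len(ped), s.n_markers, s.n_proteins)


def stage_qc(cfg: PipelineConfig) -> tuple[pea.NormalizedPanel, pea.QCReport]:
    plates = io.read_plates(cfg.input_or_artifact("plates_dir", "plates"))
    assays = io.read_assays(cfg.input_or_artifact("assays", "assays.yaml"))
    panel = pea.normalize_panel(plates, assays, lod_n_sd=cfg.qc.lod_n_sd)
    filtered, report = pea.apply_qc(
        panel,
        min_protein_obs=cfg.qc.min_protein_obs,
        max_below_lod_fraction=cfg.qc.max_below_lod_fraction,
        control_outlier_mads=cfg.qc.control_outlier_mads,
    )
    io.write_table(filtered.ddcq, cfg.out("ddcq.tsv"))
    io.write_table(filtered.below_lod.astype(int), cfg.out("below_lod.tsv"))
    excl = pd.DataFrame(
        [(e.kind, e.unit, e.reason) for e in report.exclusions],
        columns=["kind", "unit", "reason"],
    )
    io.write_table(excl, cfg.out("qc_exclusions.tsv"), index=False)
    cfg.out("qc_summary.yaml").write_text(
        yaml.safe_dump({k: float(v) for k, v in pea.qc_summary(report).items()}, sort_keys=True)
    )
    return filtered, report


def _load_panel(cfg: PipelineConfig) -> pd.DataFrame:
    ddcq = io.read_table(cfg.out("ddcq.tsv"))
    mask = io.read_table(cfg.out("below_lod.tsv")).astype(bool)
    return ddcq.mask(mask)


def _load_covariates(cfg: PipelineConfig) -> cov.CovariateTable:
    df = io.read_table(cfg.input_or_artifact("covariates", "covariates.tsv"))
    return cov.CovariateTable(df)


def stage_covariates(cfg: PipelineConfig) -> None:
    panel = _load_panel(cfg)
    table = _load_covariates(cfg)
    m = len(table.names)
    adjusted = {}
    decomp_rows = []
    report_rows = []
    for protein in panel.index:
        y = panel.loc[protein]
        fit = cov.fit_full_model(y, table)
        dec = cov.variance_decomposition(fit)
        sig = cov.significant_covariates(dec, alpha=cfg.covariates.alpha, m=m)
        adj = cov.adjust_and_rint(y, table, sig)
        adjusted[protein] = adj.values
        for term in dec.order:
            coef_cols = [c for c in fit.params.index if c == term or c.startswith(f"{term}[")]
            direction = ""
            if coef_cols:
                direction = "up" if fit.params[coef_cols[0]] > 0 else "down"
            decomp_rows.append(
                (protein, term, dec.fractions[term], dec.pvalues[term],
                 term in sig, direction, dec.n)
            )
        report_rows.append((protein, dec.combined, dec.n, ";".join(sig)))
    decomp = pd.DataFrame(
        decomp_rows,
        columns=["protein", "covariate", "fraction", "pvalue", "significant", "direction", "n"],
    )
    io.write_table(decomp, cfg.out("variance_decomposition.tsv"), index=False)

    sig_decomp = decomp[decomp["significant"]]
    cov_report = (
        sig_decomp.groupby("covariate")
        .agg(
            n_proteins=("protein", "nunique"),
            n_up=("direction", lambda d: int((d == "up").sum())),
            n_down=("direction", lambda d: int((d == "down").sum())),
        )
        .sort_values("n_proteins", ascending=False)
    )
    io.write_table(cov_report, cfg.out("covariate_report.tsv"))
    io.write_table(
        pd.DataFrame(report_rows, columns=["protein", "combined_fraction", "n", "significant_covariates"]),
        cfg.out("combined_model.tsv"), index=False,
    )
    adj_panel = pd.DataFrame(adjusted).T
    io.write_table(adj_panel, cfg.out("adjusted.tsv"))
    pairs = cov.correlate_pairs(adj_panel, r2_min=cfg.covariates.r2_min)
    io.write_table(pairs, cfg.out("correlated_pairs.tsv"), index=False)


def _load_genotypes(cfg: PipelineConfig) -> syn.GenotypeDosages:
    return io.read_dosages(
        cfg.input_or_artifact("dosages", "dosages.tsv"),
        cfg.input_or_artifact("markers", "markers.tsv"),
    )


def stage_kinship(cfg: PipelineConfig) -> None:
    genotypes = _load_genotypes(cfg)
    g = cfg.genotype_qc
    filtered, report = kin.genotype_qc(
        genotypes,
        marker_call_rate=g.marker_call_rate,
        individual_call_rate=g.individual_call_rate,
        hwe_alpha=g.hwe_alpha,
        min_mac=g.min_mac,
    )
    K = kin.genomic_kinship(filtered)
    io.write_table(K.values, cfg.out("kinship.tsv"))
    removed = pd.DataFrame(
        [("marker", k, v) for k, v in sorted(report.removed_markers.items())]
        + [("individual", k, v) for k, v in sorted(report.removed_individuals.items())],
        columns=["kind", "unit", "reason"],
    )
    io.write_table(removed, cfg.out("genotype_qc_report.tsv"), index=False)
    (cfg.out("qc_markers.txt")).write_text("\n".join(filtered.dosages.columns) + "\n")


def _load_adjusted(cfg: PipelineConfig) -> pd.DataFrame:
    return io.read_table(cfg.out("adjusted.tsv"))


def _load_kinship(cfg: PipelineConfig) -> kin.KinshipMatrix:
    V = io.read_table(cfg.out("kinship.tsv"))
    return kin.KinshipMatrix(values=V, n_markers=0, estimator="loaded")


def stage_heritability(cfg: PipelineConfig) -> None:
    adjusted = _load_adjusted(cfg)
    K = _load_kinship(cfg)
    rows = []
    n_proteins = len(adjusted.index)
    for protein in adjusted.index:
        y = adjusted.loc[protein]
        ids = y.dropna().index.intersection(K.ids)
        fit = gw.fit_polygenic(y, K=K.values.loc[ids, ids])
        p = gw.heritability_pvalue(fit)
        rows.append(
            (protein, fit.n, fit.h2, fit.sigma2_g, fit.sigma2_e, fit.loglik, p,
             p < 0.05 / n_proteins, fit.boundary)
        )
    out = pd.DataFrame(
        rows,
        columns=["protein", "n", "h2", "sigma2_g", "sigma2_e", "loglik", "p_lrt",
                 "significant", "boundary"],
    )
    io.write_table(out, cfg.out("heritability.tsv"), index=False)


def _qc_genotypes(cfg: PipelineConfig) -> syn.GenotypeDosages:
    genotypes = _load_genotypes(cfg)
    marker_file = cfg.out("qc_markers.txt")
    if marker_file.exists():
        keep = marker_file.read_text().split()
        genotypes = syn.GenotypeDosages(
            markers=genotypes.markers[genotypes.markers["id"].isin(keep)].reset_index(drop=True),
            dosages=genotypes.dosages[keep],
            hard_call=genotypes.hard_call,
        )
    return genotypes


def stage_gwas(cfg: PipelineConfig) -> None:
    adjusted = _load_adjusted(cfg)
    genotypes = _qc_genotypes(cfg)
    K = _load_kinship(cfg)
    ped = pd.read_csv(cfg.out("pedigree.tsv"), sep="\t").set_index("iid")
    cohorts = ped["cohort"]
    config = gw.GwasRunConfig(
        alpha=cfg.gwas.alpha,
        conditional_cutoff=cfg.gwas.conditional_cutoff,
        min_mac=cfg.gwas.min_mac,
    )
    results = gw.run_gwas(adjusted, genotypes, cohorts, K, config)
    all_rows = []
    summary_rows = []
    for protein, res in results.items():
        df = res.results.copy()
        df.insert(0, "protein", protein)
        all_rows.append(df)
        best = {}
        for phase in ("discovery", "replication", "combined"):
            ph = res.phase(phase).dropna(subset=["p"])
            if ph.empty:
                best[phase] = (np.nan, np.nan, 0, np.nan)
                continue
            top = ph.loc[ph["p"].idxmin()]
            best[phase] = (top["p"], top["var_expl"], len(res.hits.get(phase, [])),
                           res.lambdas.get(phase, np.nan))
        summary_rows.append(
            (protein,
             *best["discovery"], *best["replication"], *best["combined"],
             res.top_marker or "")
        )
    full = pd.concat(all_rows, ignore_index=True)
    keep = full[(full["skipped"] == "") | full["skipped"].isna()].drop(columns=["skipped"])
    # write the per-protein scans; the flat summary mirrors the released
    # summary-statistics artifact shape
    frames = []
    for protein, grp in keep.groupby("protein", sort=True):
        g2 = grp.drop(columns=["protein"]).copy()
        g2["marker"] = g2["marker"].astype(str)
        frames.append(g2.assign(protein=protein))
    io.write_table(pd.concat(frames, ignore_index=True), cfg.out("gwas_full.tsv"), index=False)
    table2 = pd.DataFrame(
        summary_rows,
        columns=[
            "protein",
            "p_discovery", "var_expl_discovery", "hits_discovery", "lambda_discovery",
            "p_replication", "var_expl_replication", "hits_replication", "lambda_replication",
            "p_combined", "var_expl_combined", "hits_combined", "lambda_combined",
            "top_marker",
        ],
    )
    io.write_table(table2, cfg.out("gwas_summary_table.tsv"), index=False)
    hits = [
        {"protein": p, "phase": phase, "markers": markers}
        for p, res in results.items()
        for phase, markers in res.hits.items()
    ]
    cfg.out("gwas_hits.yaml").write_text(yaml.safe_dump(hits, sort_keys=True))
    # per-protein combined summaries through the canonical writer (the shape
    # of a released full-summary-statistics artifact)
    comb_dir = cfg.out("gwas_combined")
    comb_dir.mkdir(parents=True, exist_ok=True)
    for protein, grp in keep[keep["phase"] == "combined"].groupby("protein", sort=True):
        io.write_gwas_summary(grp.drop(columns=["protein"]), comb_dir / f"{protein}.tsv")


def stage_conditional(cfg: PipelineConfig) -> None:
    adjusted = _load_adjusted(cfg)
    genotypes = _qc_genotypes(cfg)
    K = _load_kinship(cfg)
    hits = yaml.safe_load(cfg.out("gwas_hits.yaml").read_text()) or []
    table2 = pd.read_csv(cfg.out("gwas_summary_table.tsv"), sep="\t").set_index("protein")
    replicated = {h["protein"] for h in hits if h["phase"] == "replication" and h["markers"]}
    rows = []
    for protein in sorted(replicated):
        top = str(table2.loc[protein, "top_marker"])
        if not top:
            continue
        res = gw.conditional_scan(
            adjusted.loc[protein], genotypes, K, top,
            cutoff=cfg.gwas.conditional_cutoff, min_mac=cfg.gwas.min_mac,
        )
        sig = res[res["significant"] & (res["marker"] != top)]
        if sig.empty:
            rows.append((protein, top, "", np.nan, np.nan, False))
        else:
            best = sig.loc[sig["p"].idxmin()]
            rows.append((protein, top, best["marker"], best["p"], best["var_expl"], True))
    out = pd.DataFrame(
        rows,
        columns=["protein", "top_marker", "second_marker", "p_conditional",
                 "var_expl_conditional", "independent_signal"],
    )
    io.write_table(out, cfg.out("conditional.tsv"), index=False)


def stage_abo(cfg: PipelineConfig) -> None:
    geno = io.read_table(cfg.input_or_artifact("abo_genotypes", "abo_genotypes.tsv"))
    calls = abo.assign_abo(geno)
    io.write_table(abo.calls_to_frame(calls), cfg.out("abo_calls.tsv"))
    cfg.out("abo_summary.yaml").write_text(
        yaml.safe_dump({"assignment_rate": float(abo.assignment_rate(calls))})
    )


def stage_cutoffs(cfg: PipelineConfig) -> None:
    panel = _load_panel(cfg)
    covars = io.read_table(cfg.input_or_artifact("covariates", "covariates.tsv"))
    top_markers: dict[str, str] = {}
    t2_path = cfg.out("gwas_summary_table.tsv")
    if t2_path.exists():
        t2 = pd.read_csv(t2_path, sep="\t").set_index("protein")
        top_markers = {p: str(t2.loc[p, "top_marker"]) for p in t2.index
                       if isinstance(t2.loc[p, "top_marker"], str) and t2.loc[p, "top_marker"]}
    else:
        logger.info("no GWAS artifacts found: cutoff profiles omit SNP strata")
    genotypes = _load_genotypes(cfg) if top_markers else None

    abo_path = cfg.out("abo_calls.tsv")
    abo_groups = None
    if abo_path.exists():
        abo_groups = io.read_table(abo_path)["group"]

    profiles = []
    ratio_rows = []
    for protein in panel.index:
        y = panel.loc[protein]
        stratifiers: dict[str, pd.Series] = {
            "age_tertile": cut.age_tertiles(covars["age"]),
            "sex": covars["sex"].map({1: "male", 2: "female"}),
        }
        med_cols = [c for c in covars.columns if c.startswith("med_")]
        if med_cols:
            stratifiers["medication"] = covars[med_cols[0]].map({0: "non-user", 1: "user"})
        if abo_groups is not None:
            stratifiers["abo_group"] = abo_groups
        if protein in top_markers and genotypes is not None:
            mk = top_markers[protein]
            if mk in genotypes.dosages.columns:
                g = genotypes.dosages[mk].round()
                stratifiers[f"genotype:{mk}"] = g.map({0.0: "0", 1.0: "1", 2.0: "2"})
        for name, strat in stratifiers.items():
            prof = cut.stratified_reference(
                y, strat, biomarker=str(protein), stratifier=name,
                min_group_size=cfg.cutoffs.min_group_size, central=cfg.cutoffs.central,
            )
            t = prof.table.copy()
            if t.empty:
                continue
            t.insert(0, "stratum", t.index)
            t.insert(0, "stratifier", name)
            t.insert(0, "biomarker", str(protein))
            t["central"] = cfg.cutoffs.central
            profiles.append(t)
            if name.startswith("genotype:") and len(prof.table) >= 2:
                strata = list(prof.table.index)
                ref = strata[0]
                for s in strata[1:]:
                    ratio_rows.append(
                        (protein, name, s, ref,
                         cut.linearized_ratio(prof.table.loc[s, "mean"], prof.table.loc[ref, "mean"]))
                    )
    if profiles:
        io.write_table(pd.concat(profiles, ignore_index=True), cfg.out("cutoff_profiles.tsv"), index=False)
    io.write_table(
        pd.DataFrame(ratio_rows, columns=["biomarker", "stratifier", "stratum", "reference", "linearized_pct"]),
        cfg.out("linearized_ratios.tsv"), index=False,
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "covariates": stage_covariates,
    "kinship": stage_kinship,
    "heritability": stage_heritability,
    "gwas": stage_gwas,
    "conditional": stage_conditional,
    "abo": stage_abo,
    "cutoffs": stage_cutoffs,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> None:
    """Run the requested stages in canonical order, writing all artifacts.

    ``stages`` defaults to every stage enabled in the configuration.  A
    manifest with the package version, seed and thresholds is written last;
    it contains no wall-clock information, so reruns are byte-identical.
    """
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    selected = stages if stages is not None else [
        s for s in STAGES if getattr(cfg.stages, s)
    ]
    unknown = sorted(set(selected) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    for stage in STAGES:
        if stage not in selected:
            continue
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except FileNotFoundError as err:
            raise FileNotFoundError(f"stage '{stage}': missing input — {err}") from err
        except Exception as err:
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
    manifest = {
        "pqtlkit_version": __version__,
        "seed": cfg.seed,
        "stages_run": [s for s in STAGES if s in selected],
        "config": _config_dict(cfg),
    }
    cfg.out("manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("outdir")  # a filesystem location, not part of the run identity
    return d
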