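"""Delimited-text readers and writers for pipeline artifacts.

All tabular interchange is tab-separated text with a header row; floats are
written with ``%.10g`` so that reruns with the same seed produce
byte-identical artifacts.  Genotypes travel either as a dosage matrix
(individuals x markers, NaN for missing) with a marker-metadata sidecar, or
as a VCF with a dosage FORMAT field (read through cyvcf2, an optional
dependency).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pea import CONTROL_CHANNELS, AssayDefinition, PlateRun
from .synthetic import GenotypeDosages

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: Path | str, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def read_table(path: Path | str, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -- genotypes ---------------------------------------------------------------


def write_dosages(genotypes: GenotypeDosages, dosage_path, marker_path) -> None:
    write_table(genotypes.dosages, dosage_path)
    write_table(genotypes.markers, marker_path, index=False)


def read_dosages(dosage_path, marker_path, hard_call: bool = True) -> GenotypeDosages:
    dosages = read_table(dosage_path).astype(float)
    markers = pd.read_csv(marker_path, sep="\t")
    return GenotypeDosages(markers=markers, dosages=dosages, hard_call=hard_call)


def read_vcf_dosages(path, dosage_field: str = "DS") -> GenotypeDosages:
    """Read dosages from a VCF; falls back to GT hard calls if no DS field."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        try:
            ds = var.format(dosage_field)
            d = np.asarray(ds, dtype=float).reshape(-1)
        except (KeyError, TypeError):
            gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 het coding; 2=unknown
            d = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        mid = var.ID or f"{var.CHROM}:{var.POS}"
        meta.append((mid, var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else ".",
                     float(np.nanmean(d) / 2.0)))
        rows.append(d)
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt", "af"])
    dosages = pd.DataFrame(np.asarray(rows).T, index=ids, columns=markers["id"].tolist())
    hard = bool(np.all(np.isin(dosages.to_numpy()[~np.isnan(dosages.to_numpy())], [0.0, 1.0, 2.0])))
    return GenotypeDosages(markers=markers, dosages=dosages, hard_call=hard)


# -- plates ------------------------------------------------------------------


def write_plates(plates: list[PlateRun], directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for plate in plates:
        write_table(plate.cq, d / f"{plate.plate_id}_cq.tsv")
        wells = pd.DataFrame(
            {"well_type": plate.well_type, "sample_id": plate.sample_id}
        ).join(plate.controls)
        write_table(wells, d / f"{plate.plate_id}_wells.tsv")


def read_plates(directory) -> list[PlateRun]:
    d = Path(directory)
    plates = []
    for cq_path in sorted(d.glob("*_cq.tsv")):
        pid = cq_path.name[: -len("_cq.tsv")]
        cq = read_table(cq_path)
        wells = read_table(d / f"{pid}_wells.tsv")
        plates.append(
            PlateRun(
                plate_id=pid,
                cq=cq,
                well_type=wells["well_type"],
                sample_id=wells["sample_id"],
                controls=wells[list(CONTROL_CHANNELS)],
            )
        )
    if not plates:
        raise FileNotFoundError(f"no plates (*_cq.tsv) under {d}")
    return plates


# -- assays ------------------------------------------------------------------


def write_assays(assays: list[AssayDefinition], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data = [
        {"assay_id": a.assay_id, "protein": a.protein, "correction": float(a.correction)}
        for a in assays
    ]
    Path(path).write_text(yaml.safe_dump({"assays": data}, sort_keys=True))


def read_assays(path) -> list[AssayDefinition]:
    data = yaml.safe_load(Path(path).read_text())
    return [AssayDefinition(a["assay_id"], a["protein"], a["correction"]) for a in data["assays"]]


# -- GWAS summary ------------------------------------------------------------

GWAS_COLUMNS = [
    "marker", "chrom", "pos", "other_allele", "effect_allele",
    "n", "beta", "se", "chi2", "p", "var_expl", "phase",
]


def write_gwas_summary(results: pd.DataFrame, path) -> None:
    """Fixed-column GWAS summary: sorted by (chrom, pos), 1-based positions.

    ``results`` needs columns marker, chrom, pos, ref, alt, n, beta, se,
    chi2, p, var_expl, phase.  Duplicate (marker, phase) pairs are an
    error.  p is formatted in scientific notation with four significant
    digits.
    """
    df = results.rename(columns={"ref": "other_allele", "alt": "effect_allele"}).copy()
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS summary missing columns: {missing}")
    dup = df.duplicated(subset=["marker", "phase"])
    if dup.any():
        raise ValueError(
            f"duplicate marker ids in GWAS summary: {df.loc[dup, 'marker'].unique()[:5].tolist()}"
        )
    df = df[GWAS_COLUMNS].sort_values(["phase", "chrom", "pos"], kind="mergesort")
    df["p"] = df["p"].map(lambda v: "" if pd.isna(v) else f"{v:.3e}")
    write_table(df, path, index=False)


def read_gwas_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
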