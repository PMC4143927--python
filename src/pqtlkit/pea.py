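"""Normalization and QC of multiplexed PEA (proximity extension assay) data.

Raw output of a PEA panel is a plate of qPCR quantification cycles (Cq), one
per well x assay.  Each plate carries 92 sample wells, one negative-control
well and three positive-control wells, and every well is spiked with internal
controls (two incubation controls, one extension control, one detection
control).  Normalization proceeds in two steps:

    dCq  = Cq(assay) - Cq(extension control of the same well)
    ddCq = correction_constant(assay) - dCq

The per-assay correction constant is chosen by the kit manufacturer so that
ddCq lands on a positive log2-like scale: one ddCq unit corresponds to a
doubling of protein abundance.  ddCq values are used as-is downstream (no
second log transform); "linearized" abundance is ``2**ddCq``.

The negative-control wells define a per-assay lower limit of detection
(LOD): mean negative-control ddCq plus three standard deviations across
plates.  Cells at or below the LOD are masked as non-detects.  Sample- and
protein-level QC then removes samples with internal-control outliers or an
excessive non-detect fraction, and proteins with too few detected
observations to support downstream modelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Well roles on a PEA plate.
WELL_SAMPLE = "sample"
WELL_NEGATIVE = "negative_control"
WELL_POSITIVE = "positive_control"

#: Internal per-well control channels; ``ext`` is used for normalization.
CONTROL_CHANNELS = ("inc1", "inc2", "ext", "det")


@dataclass(frozen=True)
class AssayDefinition:
    """One PEA assay: the protein it measures and its correction constant.

    The correction constant is on the log2 (Cq) scale and shifts dCq onto a
    positive ddCq scale; it is supplied by the assay manufacturer.
    """

    assay_id: str
    protein: str
    correction: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.correction):
            raise ValueError(f"correction constant for {self.assay_id} must be finite")


@dataclass
class PlateRun:
    """One physical plate: Cq matrix plus well annotations and controls.

    Attributes
    ----------
    plate_id
        Identifier of the plate.
    cq
        DataFrame, wells x assays, of raw Cq values (NaN = failed reaction).
    well_type
        Series indexed by well: one of ``sample``, ``negative_control``,
        ``positive_control``.
    sample_id
        Series indexed by well mapping sample wells to individual ids
        (control wells carry synthetic ids such as ``NEG``).
    controls
        DataFrame, wells x 4, internal-control Cq values with columns
        ``inc1, inc2, ext, det``.
    """

    plate_id: str
    cq: pd.DataFrame
    well_type: pd.Series
    sample_id: pd.Series
    controls: pd.DataFrame

    def __post_init__(self) -> None:
        n_neg = int((self.well_type == WELL_NEGATIVE).sum())
        if len(self.cq) > 0 and n_neg != 1:
            raise ValueError(
                f"plate {self.plate_id}: expected exactly one negative-control "
                f"well, found {n_neg}"
            )
        with np.errstate(invalid="ignore"):
            if not np.isfinite(self.cq.to_numpy(dtype=float)[~self.cq.isna().to_numpy()]).all():
                raise ValueError(f"plate {self.plate_id}: non-finite Cq present")

    @property
    def sample_wells(self) -> pd.Index:
        return self.well_type.index[self.well_type == WELL_SAMPLE]

    @property
    def negative_wells(self) -> pd.Index:
        return self.well_type.index[self.well_type == WELL_NEGATIVE]


@dataclass
class QCExclusion:
    """A unit removed during QC, with the reason."""

    kind: str  # "sample" | "protein"
    unit: str
    reason: str


@dataclass
class QCReport:
    """Counts and reasons for everything removed during QC."""

    exclusions: list[QCExclusion] = field(default_factory=list)
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_proteins_in: int = 0
    n_proteins_out: int = 0
    # cell counts over retained proteins x all input samples
    n_cells_total: int = 0
    n_cells_detected: int = 0
    # cell counts over removed ("silent") proteins x all input samples
    n_cells_removed_total: int = 0
    n_cells_removed_below_lod: int = 0

    def excluded(self, kind: str) -> list[str]:
        return [e.unit for e in self.exclusions if e.kind == kind]


@dataclass
class NormalizedPanel:
    """ddCq matrix (proteins x individuals) with LOD mask and QC provenance.

    ``ddcq`` holds all normalized values; ``below_lod`` is a boolean mask of
    the same shape (True = at/below detection limit; such cells must be
    treated as missing downstream).  ``lod`` is the per-protein detection
    limit, ``negative_ddcq`` the per-plate negative-control ddCq values it
    was derived from.  ``sample_controls`` keeps per-individual internal
    control Cq values (with plate id) for sample-level QC.
    """

    ddcq: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series
    negative_ddcq: pd.DataFrame  # plates x proteins
    sample_controls: pd.DataFrame  # individuals x (plate, inc1, inc2, ext, det)
    exclusions: list[QCExclusion] = field(default_factory=list)
    qc_applied: bool = False

    def values_masked(self) -> pd.DataFrame:
        """ddCq with below-LOD cells set to NaN — the downstream view."""
        return self.ddcq.mask(self.below_lod)

    @property
    def proteins(self) -> pd.Index:
        return self.ddcq.index

    @property
    def individuals(self) -> pd.Index:
        return self.ddcq.columns


def normalize_ddcq(plate: PlateRun, assays: list[AssayDefinition]) -> pd.DataFrame:
    """Normalize one plate's Cq values into ddCq, indexed by protein.

    Returns a proteins x wells DataFrame covering every well (sample and
    control wells alike; the negative-control column feeds the LOD
    estimate).  Wells with a missing extension control are flagged via an
    exclusion appended to ``plate``'s exclusion list by the caller; here
    their ddCq is NaN.
    """
    ext = plate.controls["ext"]
    dcq = plate.cq.sub(ext, axis=0)  # Cq(assay) - Cq(extension control)
    corrections = pd.Series({a.assay_id: a.correction for a in assays})
    missing = corrections.index.difference(plate.cq.columns)
    if len(missing):
        raise ValueError(f"plate {plate.plate_id}: assays absent from Cq table: {list(missing)}")
    ddcq = (-dcq[corrections.index]).add(corrections, axis=1)
    protein_of = {a.assay_id: a.protein for a in assays}
    ddcq = ddcq.rename(columns=protein_of)
    return ddcq.T  # proteins x wells


def estimate_lod(negative_ddcq: pd.DataFrame, n_sd: float = 3.0) -> pd.Series:
    """Per-protein limit of detection from negative-control ddCq values.

    ``negative_ddcq`` is plates x proteins.  LOD = mean + ``n_sd`` * sample
    standard deviation across plates; with a single plate the SD term
    vanishes and the LOD is the negative-control ddCq itself.
    """
    if negative_ddcq.shape[0] < 1:
        raise ValueError("at least one negative-control measurement required")
    mean = negative_ddcq.mean(axis=0)
    sd = negative_ddcq.std(axis=0, ddof=1).fillna(0.0) if negative_ddcq.shape[0] > 1 else 0.0
    return mean + n_sd * sd


def normalize_panel(
    plates: list[PlateRun],
    assays: list[AssayDefinition],
    lod_n_sd: float = 3.0,
) -> NormalizedPanel:
    """Normalize a full plate run into a masked proteins x individuals panel.

    Applies :func:`normalize_ddcq` per plate, pools negative controls into a
    per-protein LOD via :func:`estimate_lod`, and masks cells with
    ddCq <= LOD (boundary inclusive).  Samples whose extension control is
    missing are flagged (not silently dropped): their cells are NaN and an
    exclusion record is attached.
    """
    if not plates:
        raise ValueError("no plates given")
    sample_cols: list[pd.DataFrame] = []
    controls_rows: list[pd.DataFrame] = []
    neg_rows = {}
    exclusions: list[QCExclusion] = []
    for plate in plates:
        ddcq = normalize_ddcq(plate, assays)
        no_ext = plate.controls["ext"].isna()
        for well in plate.controls.index[no_ext]:
            if plate.well_type[well] == WELL_SAMPLE:
                exclusions.append(
                    QCExclusion("sample", str(plate.sample_id[well]), "missing_extension_control")
                )
        swells = plate.sample_wells
        block = ddcq[swells]
        block.columns = plate.sample_id[swells]
        sample_cols.append(block)
        ctrl = plate.controls.loc[swells].copy()
        ctrl.index = plate.sample_id[swells]
        ctrl.insert(0, "plate", plate.plate_id)
        controls_rows.append(ctrl)
        nwell = plate.negative_wells[0]
        neg_rows[plate.plate_id] = ddcq[nwell]
    ddcq_all = pd.concat(sample_cols, axis=1)
    if ddcq_all.columns.duplicated().any():
        dup = ddcq_all.columns[ddcq_all.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids across plates: {dup}")
    negative_ddcq = pd.DataFrame(neg_rows).T
    lod = estimate_lod(negative_ddcq, n_sd=lod_n_sd)
    below = ddcq_all.le(lod, axis=0) | ddcq_all.isna()
    return NormalizedPanel(
        ddcq=ddcq_all,
        below_lod=below,
        lod=lod,
        negative_ddcq=negative_ddcq,
        sample_controls=pd.concat(controls_rows, axis=0),
        exclusions=exclusions,
    )


def _control_outlier_samples(
    sample_controls: pd.DataFrame, n_mads: float = 3.0
) -> list[str]:
    """Samples with any internal control outlying within its plate.

    Rule: |value - median| > ``n_mads`` * 1.4826 * MAD, per control channel
    per plate (robust location/scale; plates with zero MAD are skipped for
    that channel).
    """
    flagged: set[str] = set()
    for _, grp in sample_controls.groupby("plate", sort=False):
        for ch in CONTROL_CHANNELS:
            v = grp[ch].astype(float)
            med = v.median()
            mad = (v - med).abs().median()
            if not np.isfinite(mad) or mad == 0:
                continue
            out = (v - med).abs() > n_mads * 1.4826 * mad
            flagged.update(str(s) for s in v.index[out.fillna(False)])
        # a missing control value is itself disqualifying
        miss = grp[list(CONTROL_CHANNELS)].isna().any(axis=1)
        flagged.update(str(s) for s in grp.index[miss])
    return sorted(flagged)


def apply_qc(
    panel: NormalizedPanel,
    min_protein_obs: int = 200,
    max_below_lod_fraction: float = 0.75,
    control_outlier_mads: float = 3.0,
) -> tuple[NormalizedPanel, QCReport]:
    """Sample- and protein-level QC of a normalized panel.

    Removes samples with any internal-control outlier or with a below-LOD
    fraction strictly greater than ``max_below_lod_fraction``, then proteins
    with fewer than ``min_protein_obs`` above-LOD observations among the
    retained samples.  Idempotent: re-applying to the output changes
    nothing.
    """
    if not (0 < max_below_lod_fraction < 1):
        raise ValueError("max_below_lod_fraction must be in (0, 1)")
    if min_protein_obs < 1:
        raise ValueError("min_protein_obs must be >= 1")
    report = QCReport(
        n_samples_in=panel.ddcq.shape[1],
        n_proteins_in=panel.ddcq.shape[0],
    )
    report.exclusions.extend(panel.exclusions)
    pre_flagged = {e.unit for e in panel.exclusions if e.kind == "sample"}

    outliers = set(_control_outlier_samples(panel.sample_controls, control_outlier_mads))
    for s in sorted(outliers - pre_flagged):
        report.exclusions.append(QCExclusion("sample", s, "internal_control_outlier"))

    frac_below = panel.below_lod.mean(axis=0)
    too_censored = set(str(s) for s in frac_below.index[frac_below > max_below_lod_fraction])
    for s in sorted(too_censored - outliers - pre_flagged):
        report.exclusions.append(QCExclusion("sample", s, "below_lod_fraction"))

    drop_samples = pre_flagged | outliers | too_censored
    keep_samples = [c for c in panel.ddcq.columns if str(c) not in drop_samples]

    above = (~panel.below_lod[keep_samples]).sum(axis=1)
    keep_proteins = above.index[above >= min_protein_obs]
    for p in above.index.difference(keep_proteins):
        report.exclusions.append(
            QCExclusion("protein", str(p), f"above_lod_obs<{min_protein_obs}")
        )

    filtered = NormalizedPanel(
        ddcq=panel.ddcq.loc[keep_proteins, keep_samples],
        below_lod=panel.below_lod.loc[keep_proteins, keep_samples],
        lod=panel.lod.loc[keep_proteins] if panel.lod.index.equals(panel.ddcq.index) else panel.lod,
        negative_ddcq=panel.negative_ddcq,
        sample_controls=panel.sample_controls.loc[
            [s for s in panel.sample_controls.index if str(s) not in drop_samples]
        ],
        exclusions=[],
        qc_applied=True,
    )
    report.n_samples_out = filtered.ddcq.shape[1]
    report.n_proteins_out = filtered.ddcq.shape[0]
    removed_proteins = above.index.difference(keep_proteins)
    report.n_cells_total = len(keep_proteins) * report.n_samples_in
    report.n_cells_detected = int((~panel.below_lod.loc[keep_proteins]).to_numpy().sum())
    report.n_cells_removed_total = len(removed_proteins) * report.n_samples_in
    report.n_cells_removed_below_lod = int(
        panel.below_lod.loc[removed_proteins].to_numpy().sum()
    )
    logger.info(
        "QC: %d/%d samples, %d/%d proteins retained",
        report.n_samples_out,
        report.n_samples_in,
        report.n_proteins_out,
        report.n_proteins_in,
    )
    return filtered, report


def percent(numerator: float, denominator: float) -> float:
    """100*numerator/denominator rounded to one decimal (display convention)."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in percentage")
    return round(100.0 * numerator / denominator, 1)


def qc_summary(report: QCReport) -> dict[str, float]:
    """Headline QC fractions: reaction success, detection and sample pass rates.

    Reaction success counts above-LOD cells among retained proteins over all
    input samples; the silent-protein percentage counts below-LOD cells
    among removed proteins.  Percentages are rounded to one decimal for
    display; the raw fractions are returned alongside.
    """
    if report.n_samples_in == 0 or report.n_cells_total == 0:
        raise ValueError("empty QC report")
    out = {
        "reaction_success_pct": percent(report.n_cells_detected, report.n_cells_total),
        "sample_pass_pct": percent(report.n_samples_out, report.n_samples_in),
        "sample_excluded_pct": percent(
            report.n_samples_in - report.n_samples_out, report.n_samples_in
        ),
        "reaction_success_fraction": report.n_cells_detected / report.n_cells_total,
        "sample_pass_fraction": report.n_samples_out / report.n_samples_in,
    }
    if report.n_cells_removed_total:
        out["silent_below_lod_pct"] = percent(
            report.n_cells_removed_below_lod, report.n_cells_removed_total
        )
    return out
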