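"""Tab-delimited table I/O and conversion to domain objects.

Canonical exchange formats are UTF-8 TSV files with a header row and empty
fields for missing values:

* ``lesions.tsv``  — one FDG-avid lesion per patient x timepoint;
* ``scans.tsv``    — scan-level QC metadata and reference-tissue SUV stats;
* ``variants.tsv`` — candidate somatic plasma variants per patient x timepoint;
* ``clinical.tsv`` — outcome (PFS, event) and covariates;
* ``samples.tsv``  — optional plasma-sample manifest distinguishing
  "assayed, negative" from "sample missing".
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .ctdna import CtdnaStatus, VariantCall, filter_variants, patient_status
from .pet import Lesion, ReferenceUptake, Scan, ScanMeta, ScanPair

LESION_COLUMNS = [
    "patient_id",
    "timepoint",
    "lesion_id",
    "organ",
    "suvmax",
    "suvpeak",
    "diameter_cm",
    "matv_cm3",
    "is_new",
]
SCAN_COLUMNS = [
    "patient_id",
    "timepoint",
    "injected_activity_mbq",
    "uptake_time_min",
    "glucose_mg_dl",
    "scanner_id",
    "days_from_treatment_start",
    "liver_suvmean",
    "liver_suvsd",
    "bloodpool_suvmean",
    "bloodpool_suvsd",
    "liver_abnormal",
]
VARIANT_COLUMNS = [
    "patient_id",
    "timepoint",
    "gene",
    "protein_change",
    "consequence",
    "classification",
    "vaf_pct",
    "mut_copies_per_ml",
    "total_copies_per_ml",
    "coverage",
    "fwd_fraction",
]
CLINICAL_COLUMNS = [
    "patient_id",
    "pfs_months",
    "event",
    "age_years",
    "ecog",
    "n_sites",
    "visceral",
    "prior_ct_lines",
    "prior_et_lines",
    "nsai_sensitive",
    "prior_cdk46",
]
SAMPLE_COLUMNS = ["patient_id", "timepoint", "sample_present"]

__all__ = [
    "LESION_COLUMNS",
    "SCAN_COLUMNS",
    "VARIANT_COLUMNS",
    "CLINICAL_COLUMNS",
    "SAMPLE_COLUMNS",
    "read_lesions",
    "read_scans",
    "read_variants",
    "read_clinical",
    "read_samples",
    "build_scan_pairs",
    "variants_to_calls",
    "build_ctdna_statuses",
]


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_lesions(path: str | Path) -> pd.DataFrame:
    return _read(path, LESION_COLUMNS)


def read_scans(path: str | Path) -> pd.DataFrame:
    return _read(path, SCAN_COLUMNS)


def read_variants(path: str | Path) -> pd.DataFrame:
    return _read(path, VARIANT_COLUMNS)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return _read(path, ["patient_id", "pfs_months", "event"])


def read_samples(path: str | Path) -> pd.DataFrame:
    return _read(path, SAMPLE_COLUMNS)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _lesion_from_row(row) -> Lesion:
    return Lesion(
        lesion_id=str(row.lesion_id),
        organ=str(row.organ),
        suvmax=float(row.suvmax),
        suvpeak=_opt(row.suvpeak),
        diameter_cm=_opt(row.diameter_cm),
        matv_cm3=_opt(row.matv_cm3),
        is_new=bool(int(row.is_new)) if not pd.isna(row.is_new) else False,
    )


def _scan_from_rows(meta_row, lesion_rows: pd.DataFrame) -> Scan:
    meta = ScanMeta(
        timepoint=str(meta_row.timepoint),
        injected_activity_mbq=float(meta_row.injected_activity_mbq),
        uptake_time_min=float(meta_row.uptake_time_min),
        glucose_mg_dl=float(meta_row.glucose_mg_dl),
        scanner_id=str(meta_row.scanner_id),
        days_from_treatment_start=int(meta_row.days_from_treatment_start),
    )
    ref = ReferenceUptake(
        liver_suvmean=_opt(meta_row.liver_suvmean),
        liver_suvsd=_opt(meta_row.liver_suvsd),
        bloodpool_suvmean=_opt(meta_row.bloodpool_suvmean),
        bloodpool_suvsd=_opt(meta_row.bloodpool_suvsd),
        liver_abnormal=bool(int(meta_row.liver_abnormal)),
    )
    lesions = tuple(_lesion_from_row(r) for r in lesion_rows.itertuples())
    return Scan(meta=meta, ref=ref, lesions=lesions)


def build_scan_pairs(
    lesions: pd.DataFrame, scans: pd.DataFrame, followup_timepoint: str = "d14"
) -> list[ScanPair]:
    """Assemble one :class:`ScanPair` per patient with both scans on file.

    Patients lacking either the baseline or the follow-up scan row are
    skipped (an early-response classification is undefined for them).
    """
    pairs: list[ScanPair] = []
    les_by = dict(tuple(lesions.groupby(["patient_id", "timepoint"], sort=False)))
    for pid, grp in scans.groupby("patient_id", sort=True):
        by_tp = {r.timepoint: r for r in grp.itertuples()}
        if "baseline" not in by_tp or followup_timepoint not in by_tp:
            continue
        empty = lesions.iloc[0:0]
        base = _scan_from_rows(by_tp["baseline"], les_by.get((pid, "baseline"), empty))
        fu = _scan_from_rows(by_tp[followup_timepoint], les_by.get((pid, followup_timepoint), empty))
        pairs.append(ScanPair(patient_id=str(pid), baseline=base, followup=fu))
    return pairs


def variants_to_calls(variants: pd.DataFrame) -> list[VariantCall]:
    return [
        VariantCall(
            patient_id=str(r.patient_id),
            timepoint=str(r.timepoint),
            gene=str(r.gene),
            protein_change=str(r.protein_change),
            consequence=str(r.consequence),
            classification=str(r.classification),
            vaf_pct=float(r.vaf_pct),
            mut_copies_per_ml=float(r.mut_copies_per_ml),
            total_copies_per_ml=float(r.total_copies_per_ml),
            coverage=int(r.coverage),
            fwd_fraction=float(r.fwd_fraction),
        )
        for r in variants.itertuples()
    ]


def build_ctdna_statuses(
    variants: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    pathogenic_only: bool = False,
) -> list[CtdnaStatus]:
    """Filter the variant table and summarise each patient's ctDNA status.

    Without a sample manifest every listed patient is assumed assayed at all
    timepoints; with one, patients keep NA statuses at timepoints whose
    plasma is marked absent, and patients appearing only in the manifest
    (no variants at all) are included as ctDNA-negative where assayed.
    """
    retained = filter_variants(variants_to_calls(variants))
    by_patient: dict[str, list[VariantCall]] = {}
    for c in retained:
        by_patient.setdefault(c.patient_id, []).append(c)

    presence: dict[str, dict[str, bool]] = {}
    if samples is not None:
        for r in samples.itertuples():
            presence.setdefault(str(r.patient_id), {})[str(r.timepoint)] = bool(
                int(r.sample_present)
            )
        patient_ids = sorted(presence)
    else:
        patient_ids = sorted(set(by_patient) | set(variants["patient_id"].astype(str)))

    return [
        patient_status(
            pid,
            by_patient.get(pid, []),
            samples_present=presence.get(pid),
            pathogenic_only=pathogenic_only,
        )
        for pid in patient_ids
    ]
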