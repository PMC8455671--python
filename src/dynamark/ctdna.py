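"""Circulating tumor DNA detection and longitudinal dynamics.

Consumes variant-level calls from targeted sequencing of serial plasma
samples (baseline, day 14 of treatment, progression) and derives
patient-level quantities:

* quality filtering of candidate somatic calls (depth, strand balance,
  protein-affecting consequence);
* per-timepoint detection calls, distinguishing "assayed, nothing found"
  from "sample missing";
* the circulating DNA ratio (CDR): total mutated copies/ml at day 14 over
  baseline, summed across all retained mutations of a patient;
* variant-allele-fraction strata, baseline-normalised trajectories, cohort
  detection rates and per-gene prevalence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "silent", "intronic")
RETAINED_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice"})
CLASSIFICATIONS = ("pathogenic", "vus")
CTDNA_TIMEPOINTS = ("baseline", "d14", "progression")

#: Genes of the targeted panel that the package recognises by default; the
#: full commercial 40-gene content is site-specific, so the vocabulary is
#: open and configurable.
DEFAULT_PANEL = ("ESR1", "PIK3CA", "TP53", "AKT1", "PTEN", "ERBB2", "FGFR1")

MIN_COVERAGE = 100  # retained strictly above
FWD_FRACTION_RANGE = (0.10, 0.90)  # inclusive strand-balance window

__all__ = [
    "VariantCall",
    "CtdnaStatus",
    "DetectionRate",
    "DEFAULT_PANEL",
    "filter_variants",
    "first_failing_rule",
    "detect",
    "patient_status",
    "detection_rate",
    "compute_cdr",
    "dichotomize_at_median",
    "vaf_stratum",
    "normalize_to_baseline",
    "gene_prevalence",
]


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic variant in one plasma sample."""

    patient_id: str
    timepoint: str
    gene: str
    protein_change: str
    consequence: str
    classification: str
    vaf_pct: float
    mut_copies_per_ml: float
    total_copies_per_ml: float
    coverage: int
    fwd_fraction: float

    def __post_init__(self) -> None:
        if self.timepoint not in CTDNA_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unparseable consequence {self.consequence!r}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if not 0.0 <= self.vaf_pct <= 100.0:
            raise ValueError("vaf_pct must lie in [0, 100]")
        if self.mut_copies_per_ml < 0 or self.total_copies_per_ml < 0:
            raise ValueError("copies/ml must be non-negative")
        if self.mut_copies_per_ml > self.total_copies_per_ml + 1e-9:
            raise ValueError("mutated copies cannot exceed total copies")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if not 0.0 <= self.fwd_fraction <= 1.0:
            raise ValueError("fwd_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CtdnaStatus:
    """Patient-level ctDNA summary across timepoints.

    ``None`` encodes a missing plasma sample (not assayed), distinct from a
    negative assay. ``cdr`` is defined only when ctDNA was detected at
    baseline and a day-14 sample exists.
    """

    patient_id: str
    detected_baseline: bool | None
    detected_d14: bool | None
    cdr: float | None
    max_vaf_baseline: float
    max_vaf_d14: float
    n_mutations: dict[str, int] = field(default_factory=dict)
    genes: dict[str, frozenset[str]] = field(default_factory=dict)


class DetectionRate(NamedTuple):
    k: int
    n: int
    pct: float


def first_failing_rule(call: VariantCall) -> str | None:
    """Name of the first retention rule a call violates, or None if retained.

    Rule order: coverage, strand balance, consequence.
    """
    if call.coverage <= MIN_COVERAGE:
        return "coverage"
    lo, hi = FWD_FRACTION_RANGE
    if not lo <= call.fwd_fraction <= hi:
        return "strand_ratio"
    if call.consequence not in RETAINED_CONSEQUENCES:
        return "consequence"
    return None


def filter_variants(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Retain calls passing depth, strand-balance and consequence rules.

    Retained iff coverage > 100, forward-read fraction within [0.10, 0.90],
    and the consequence is protein-affecting (missense, nonsense, frameshift
    or splice); silent and intronic changes are discarded. Removals are
    logged with the first failing rule. Idempotent and order-preserving.
    """
    retained: list[VariantCall] = []
    for call in calls:
        reason = first_failing_rule(call)
        if reason is None:
            retained.append(call)
        else:
            logger.debug(
                "removed %s %s %s at %s: %s",
                call.patient_id,
                call.gene,
                call.protein_change,
                call.timepoint,
                reason,
            )
    return retained


def detect(
    calls: Sequence[VariantCall], sample_present: bool = True, pathogenic_only: bool = False
) -> bool | None:
    """ctDNA detection call for one patient-timepoint (calls pre-filtered).

    ``None`` when no plasma sample was assayed; otherwise True iff at least
    one retained call carries mutated copies. ``pathogenic_only`` restricts
    to calls classified pathogenic (by default variants of unknown
    significance count too).
    """
    if not sample_present:
        return None
    considered = [c for c in calls if not pathogenic_only or c.classification == "pathogenic"]
    return any(c.mut_copies_per_ml > 0 for c in considered)


def patient_status(
    patient_id: str,
    calls: Sequence[VariantCall],
    samples_present: Mapping[str, bool] | None = None,
    pathogenic_only: bool = False,
) -> CtdnaStatus:
    """Assemble a patient's :class:`CtdnaStatus` from their retained calls.

    ``samples_present`` maps timepoint -> whether a plasma sample was
    assayed; timepoints default to present.
    """
    present = {tp: True for tp in CTDNA_TIMEPOINTS}
    if samples_present:
        present.update(samples_present)
    by_tp: dict[str, list[VariantCall]] = {tp: [] for tp in CTDNA_TIMEPOINTS}
    for c in calls:
        if c.patient_id != patient_id:
            raise ValueError(f"call for {c.patient_id!r} passed to patient {patient_id!r}")
        by_tp[c.timepoint].append(c)

    det_base = detect(by_tp["baseline"], present["baseline"], pathogenic_only)
    det_d14 = detect(by_tp["d14"], present["d14"], pathogenic_only)
    cdr = None
    if det_base:
        cdr = compute_cdr(by_tp["baseline"], by_tp["d14"], d14_sample_present=present["d14"])

    def max_vaf(tp: str) -> float:
        vs = [c.vaf_pct for c in by_tp[tp]]
        return max(vs) if vs else 0.0

    return CtdnaStatus(
        patient_id=patient_id,
        detected_baseline=det_base,
        detected_d14=det_d14,
        cdr=cdr,
        max_vaf_baseline=max_vaf("baseline"),
        max_vaf_d14=max_vaf("d14"),
        n_mutations={tp: len(by_tp[tp]) for tp in CTDNA_TIMEPOINTS},
        genes={tp: frozenset(c.gene for c in by_tp[tp]) for tp in CTDNA_TIMEPOINTS},
    )


def _rate(k: int, n: int) -> DetectionRate:
    if n == 0:
        return DetectionRate(0, 0, float("nan"))
    return DetectionRate(k, n, round(100.0 * k / n, 1))


def detection_rate(statuses: Iterable[CtdnaStatus], timepoint: str) -> DetectionRate:
    """(k, n, percent) of ctDNA-positive patients among assayed ones."""
    attr = {"baseline": "detected_baseline", "d14": "detected_d14"}
    if timepoint not in attr:
        raise ValueError("detection_rate supports timepoints 'baseline' and 'd14'")
    flags = [getattr(s, attr[timepoint]) for s in statuses]
    known = [f for f in flags if f is not None]
    return _rate(sum(known), len(known))


def compute_cdr(
    baseline_calls: Sequence[VariantCall],
    d14_calls: Sequence[VariantCall],
    d14_sample_present: bool = True,
) -> float | None:
    """Circulating DNA ratio: day-14 over baseline total mutated copies/ml.

    Summed over all retained mutations of the patient; a mutation undetected
    at day 14 contributes zero to the numerator, and a mutation first seen
    at day 14 adds to the numerator. ``None`` (undefined) when the baseline
    total is zero (ctDNA not detected) or the day-14 sample is missing.
    Scale-invariant and monotone in every day-14 copy value.
    """
    base_sum = sum(c.mut_copies_per_ml for c in baseline_calls)
    if base_sum <= 0:
        logger.debug("CDR undefined: baseline mutated copies sum to zero")
        return None
    if not d14_sample_present:
        logger.debug("CDR undefined: day-14 sample missing")
        return None
    d14_sum = sum(c.mut_copies_per_ml for c in d14_calls)
    return d14_sum / base_sum


def dichotomize_at_median(values: Mapping[str, float | None]) -> tuple[float, dict[str, str]]:
    """Median split of a patient -> value map into 'low' (<= median) / 'high'.

    Median uses the midpoint-of-middle-two convention for even counts, so
    an observed middle value labels itself low (matching inclusive "<=
    median" group definitions). Patients with missing values are dropped
    from both the median and the labels.
    """
    known = {k: v for k, v in values.items() if v is not None and not math.isnan(v)}
    if not known:
        raise ValueError("no non-missing values to dichotomize")
    med = float(np.median(list(known.values())))
    labels = {k: ("low" if v <= med else "high") for k, v in known.items()}
    return med, labels


def vaf_stratum(max_vaf_pct: float | None, edges: Sequence[float] = (20.0,)) -> int:
    """Ordinal VAF stratum of a patient's maximal variant allele fraction.

    Stratum 0: nothing detected (``None`` or VAF 0). Detected patients fall
    into 1 + the number of ``edges`` at or below their VAF; with the default
    single edge at 20%, stratum 1 is detected-below-20% and stratum 2 is
    VAF >= 20% (boundary inclusive upward). Edges must increase strictly.
    """
    if list(edges) != sorted(set(edges)):
        raise ValueError("edges must be strictly increasing")
    if max_vaf_pct is None or max_vaf_pct == 0:
        return 0
    if max_vaf_pct < 0:
        raise ValueError("VAF cannot be negative")
    return 1 + sum(max_vaf_pct >= e for e in edges)


def normalize_to_baseline(trajectory: Mapping[str, float]) -> dict[str, float] | None:
    """Divide a per-timepoint trajectory by its baseline value.

    Baseline maps to 1.0; ``None`` (undefined trajectory) when the baseline
    value is zero or missing.
    """
    base = trajectory.get("baseline")
    if base is None or base <= 0:
        return None
    return {tp: v / base for tp, v in trajectory.items()}


def gene_prevalence(
    statuses: Iterable[CtdnaStatus],
    gene: str,
    timepoint: str,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> DetectionRate:
    """(k, n, percent) of assayed patients carrying >=1 retained mutation in a gene."""
    if gene not in panel:
        raise ValueError(f"gene {gene!r} not in the configured panel {tuple(panel)}")
    attr = {"baseline": "detected_baseline", "d14": "detected_d14"}
    if timepoint not in attr:
        raise ValueError("gene_prevalence supports timepoints 'baseline' and 'd14'")
    k = n = 0
    for s in statuses:
        if getattr(s, attr[timepoint]) is None:
            continue
        n += 1
        if gene in s.genes.get(timepoint, frozenset()):
            k += 1
    return _rate(k, n)
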