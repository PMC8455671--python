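"""FDG-PET metabolic response from lesion-level SUV tables.

Implements patient-level metabolic-response classification for serial
^18F-FDG-PET/CT in metastatic disease:

* lesion evaluability against liver (or, when the liver is involved,
  blood-pool) reference uptake;
* advisory quality control of a baseline/early-scan pair (injected activity,
  uptake time, scanner identity, scheduling, glycaemia);
* the Consist ("dominance") four-class patient-based classification driven
  by per-lesion SUVmax change, at a configurable reduction cut-off;
* PERCIST-style target selection (<=10 lesions, <=2 per organ, size and
  uptake gates) and hottest-lesion SUVpeak response;
* disease-burden summaries (total metabolically active tumor volume, lesion
  count) with the standard prognostic dichotomies;
* inter-rater agreement (Cohen's kappa) for binary response calls.

The module consumes lesion-level measurements; it does not touch images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from sklearn.metrics import cohen_kappa_score

logger = logging.getLogger(__name__)

ORGANS = ("liver", "lung", "bone", "node", "other")
TIMEPOINTS = ("baseline", "d14", "d28", "progression")

__all__ = [
    "Lesion",
    "ReferenceUptake",
    "ScanMeta",
    "Scan",
    "ScanPair",
    "ConsistResult",
    "PercistResult",
    "QCFinding",
    "DiseaseBurden",
    "check_lesion_evaluability",
    "qc_scan_pair",
    "lesion_delta_pct",
    "classify_consist",
    "select_percist_targets",
    "classify_percist",
    "disease_burden",
    "cohen_kappa",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Lesion:
    """One FDG-avid lesion at one timepoint."""

    lesion_id: str
    organ: str
    suvmax: float
    suvpeak: float | None = None
    diameter_cm: float | None = None
    matv_cm3: float | None = None
    is_new: bool = False

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.suvmax < 0:
            raise ValueError("suvmax must be non-negative")
        if self.suvpeak is not None:
            if self.suvpeak < 0:
                raise ValueError("suvpeak must be non-negative")
            if self.suvpeak > self.suvmax + 1e-9:
                raise ValueError("suvpeak cannot exceed suvmax")
        if self.diameter_cm is not None and self.diameter_cm <= 0:
            raise ValueError("diameter_cm must be positive")
        if self.matv_cm3 is not None and self.matv_cm3 < 0:
            raise ValueError("matv_cm3 must be non-negative")


@dataclass(frozen=True)
class ReferenceUptake:
    """Reference-tissue SUV statistics for one scan.

    Liver statistics come from a 3 cm spherical ROI in a normal right liver
    lobe; blood-pool statistics from a 1 cm ROI in the descending thoracic
    aorta, used when the liver is itself abnormal.
    """

    liver_suvmean: float | None = None
    liver_suvsd: float | None = None
    bloodpool_suvmean: float | None = None
    bloodpool_suvsd: float | None = None
    liver_abnormal: bool = False

    def __post_init__(self) -> None:
        for name in ("liver_suvmean", "liver_suvsd", "bloodpool_suvmean", "bloodpool_suvsd"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class ScanMeta:
    timepoint: str
    injected_activity_mbq: float
    uptake_time_min: float
    glucose_mg_dl: float
    scanner_id: str
    days_from_treatment_start: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected_activity_mbq must be positive")
        if self.uptake_time_min <= 0:
            raise ValueError("uptake_time_min must be positive")


@dataclass(frozen=True)
class Scan:
    meta: ScanMeta
    ref: ReferenceUptake
    lesions: tuple[Lesion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        ids = [l.lesion_id for l in self.lesions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate lesion_id within one scan")


@dataclass(frozen=True)
class ScanPair:
    """A patient's baseline and early follow-up scan, lesions matched by id."""

    patient_id: str
    baseline: Scan
    followup: Scan

    def __post_init__(self) -> None:
        if any(l.is_new for l in self.baseline.lesions):
            raise ValueError("baseline lesions cannot be flagged is_new")
        base_ids = {l.lesion_id for l in self.baseline.lesions}
        for l in self.followup.lesions:
            if not l.is_new and l.lesion_id not in base_ids:
                raise ValueError(
                    f"follow-up lesion {l.lesion_id!r} is not new but absent at baseline"
                )


@dataclass(frozen=True)
class ConsistResult:
    consist_class: int
    responder: bool
    cutoff_pct: float
    per_lesion_delta_pct: dict[str, float]
    new_lesion: bool
    load_weight_used: str


@dataclass(frozen=True)
class PercistResult:
    # status is "MR", "MNR", or None when no target has follow-up SUVpeak
    status: str | None
    target_lesion_ids: tuple[str, ...]
    hottest_delta_pct: float


@dataclass(frozen=True)
class QCFinding:
    code: str
    message: str


@dataclass(frozen=True)
class DiseaseBurden:
    matv_total_cm3: float
    n_lesions: int
    matv_gt_100cm3: bool
    gt_7_lesions: bool
    matv_incomplete: bool = False


# ---------------------------------------------------------------------------
# operations


def check_lesion_evaluability(lesion: Lesion, ref: ReferenceUptake) -> bool:
    """Whether a lesion's uptake clears the reference-tissue threshold.

    Normal liver: SUVmax at least 1.5 x (liver SUVmean + 2 SD), inclusive.
    Abnormal liver: SUVmax strictly above 2.0 x (blood-pool SUVmean + 2 SD).
    The inequality strictness mirrors the wording of each branch's rule.
    """
    if ref.liver_abnormal:
        if ref.bloodpool_suvmean is None or ref.bloodpool_suvsd is None:
            raise ValueError(
                "liver abnormal but blood-pool reference statistics are missing"
            )
        threshold = 2.0 * (ref.bloodpool_suvmean + 2.0 * ref.bloodpool_suvsd)
        # strict ">": a lesion exactly at the threshold is not evaluable
        return lesion.suvmax > threshold and not math.isclose(
            lesion.suvmax, threshold, rel_tol=1e-12
        )
    if ref.liver_suvmean is None or ref.liver_suvsd is None:
        raise ValueError("liver reference statistics are missing")
    threshold = 1.5 * (ref.liver_suvmean + 2.0 * ref.liver_suvsd)
    return lesion.suvmax >= threshold or math.isclose(lesion.suvmax, threshold, rel_tol=1e-12)


def qc_scan_pair(pair: ScanPair) -> list[QCFinding]:
    """Advisory protocol-compliance checks on a baseline/early scan pair.

    Findings never invalidate a pair; they carry machine-readable codes so a
    caller can decide. Rules: injected-activity difference within 25% of
    baseline; uptake time 60-70 min on each scan and within 10 min between
    scans; same scanner; baseline at most 7 days before treatment start;
    glycaemia below 200 mg/dL on each scan.
    """
    findings: list[QCFinding] = []
    b, f = pair.baseline.meta, pair.followup.meta

    rel = abs(f.injected_activity_mbq - b.injected_activity_mbq) / b.injected_activity_mbq
    if rel > 0.25:
        findings.append(
            QCFinding(
                "activity_diff_gt_25pct",
                f"injected activity differs by {100 * rel:.1f}% of baseline",
            )
        )
    for label, meta in (("baseline", b), ("followup", f)):
        if not 60.0 <= meta.uptake_time_min <= 70.0:
            findings.append(
                QCFinding(
                    "uptake_time_out_of_window",
                    f"{label} uptake time {meta.uptake_time_min:g} min outside 60-70 min",
                )
            )
    if abs(f.uptake_time_min - b.uptake_time_min) > 10.0:
        findings.append(
            QCFinding(
                "uptake_time_diff_gt_10min",
                f"uptake times differ by {abs(f.uptake_time_min - b.uptake_time_min):g} min",
            )
        )
    if b.scanner_id != f.scanner_id:
        findings.append(
            QCFinding("scanner_mismatch", f"scanners differ: {b.scanner_id} vs {f.scanner_id}")
        )
    if b.days_from_treatment_start < -7:
        findings.append(
            QCFinding(
                "baseline_gt_7d_before_start",
                f"baseline scan {-b.days_from_treatment_start} days before treatment start",
            )
        )
    for label, meta in (("baseline", b), ("followup", f)):
        if meta.glucose_mg_dl >= 200.0:
            findings.append(
                QCFinding("glucose_ge_200", f"{label} glucose {meta.glucose_mg_dl:g} mg/dL >= 200")
            )
    return findings


def lesion_delta_pct(baseline_suv: float, followup_suv: float) -> float:
    """Signed percent change of an SUV metric relative to baseline."""
    if baseline_suv <= 0:
        raise ValueError("baseline SUV must be positive for a percent change")
    return 100.0 * (followup_suv - baseline_suv) / baseline_suv


def _matched_lesions(pair: ScanPair, require_evaluable: bool) -> list[tuple[Lesion, Lesion]]:
    base = {l.lesion_id: l for l in pair.baseline.lesions}
    out = []
    for fl in pair.followup.lesions:
        if fl.is_new:
            continue
        bl = base[fl.lesion_id]
        if require_evaluable and not check_lesion_evaluability(bl, pair.baseline.ref):
            continue
        out.append((bl, fl))
    return out


def classify_consist(
    pair: ScanPair,
    cutoff_pct: float = 25.0,
    load_weight: str = "matv",
    require_evaluable: bool = True,
) -> ConsistResult:
    """Consist (dominance) four-class patient-based metabolic response.

    A lesion *responds* when its SUVmax reduction strictly exceeds
    ``cutoff_pct``. Classes:

    1. every matched lesion responds and no new lesion — the responder class;
    2. mixed response, the load-weighted majority (> 0.5) of tumor burden
       responds;
    3. mixed response, the responding share is <= 0.5;
    4. progression: a new FDG-positive lesion, any SUVmax increase in a known
       lesion, or no responding lesion at all.

    Load weights are taken at baseline: per-lesion MATV when
    ``load_weight='matv'`` (falling back to baseline SUVmax when any MATV is
    missing), or baseline SUVmax directly. All-zero weights degrade to an
    unweighted lesion count (logged).
    """
    if cutoff_pct <= 0:
        raise ValueError("cutoff_pct must be positive")
    if load_weight not in ("matv", "baseline_suvmax"):
        raise ValueError("load_weight must be 'matv' or 'baseline_suvmax'")

    matched = _matched_lesions(pair, require_evaluable)
    if not matched:
        raise ValueError(f"patient {pair.patient_id}: no matched evaluable lesion")

    deltas = {bl.lesion_id: lesion_delta_pct(bl.suvmax, fl.suvmax) for bl, fl in matched}
    responds = {lid: d < -cutoff_pct for lid, d in deltas.items()}
    increased = any(d > 0 for d in deltas.values())
    new_lesion = any(l.is_new for l in pair.followup.lesions)

    weight_used = load_weight
    if load_weight == "matv" and any(bl.matv_cm3 is None for bl, _ in matched):
        weight_used = "baseline_suvmax"
    if weight_used == "matv":
        weights = {bl.lesion_id: bl.matv_cm3 for bl, _ in matched}
    else:
        weights = {bl.lesion_id: bl.suvmax for bl, _ in matched}
    total = sum(weights.values())
    if total <= 0:
        logger.warning(
            "patient %s: all load weights zero, falling back to unweighted counts",
            pair.patient_id,
        )
        weight_used = "unweighted"
        weights = {lid: 1.0 for lid in weights}
        total = float(len(weights))

    if new_lesion or increased or not any(responds.values()):
        cls = 4
    elif all(responds.values()):
        cls = 1
    else:
        responding_share = sum(w for lid, w in weights.items() if responds[lid]) / total
        cls = 2 if responding_share > 0.5 else 3

    # class 1 requires no new lesion by construction (new lesion forces 4)
    return ConsistResult(
        consist_class=cls,
        responder=(cls == 1),
        cutoff_pct=cutoff_pct,
        per_lesion_delta_pct=deltas,
        new_lesion=new_lesion,
        load_weight_used=weight_used,
    )


def select_percist_targets(
    lesions: list[Lesion] | tuple[Lesion, ...], ref: ReferenceUptake
) -> list[str]:
    """PERCIST target selection on baseline lesions.

    Candidates must measure >= 1.5 cm, carry an SUVpeak, and clear the
    reference-uptake threshold. Within each organ the two hottest (by
    SUVpeak) are kept, then the ten hottest overall; ties break on
    lexicographic lesion_id so the selection is deterministic under input
    permutation. An empty list means the patient is PERCIST-inevaluable.
    """
    candidates = [
        l
        for l in lesions
        if l.diameter_cm is not None
        and l.diameter_cm >= 1.5
        and l.suvpeak is not None
        and check_lesion_evaluability(l, ref)
    ]
    hotness = lambda l: (-l.suvpeak, l.lesion_id)  # noqa: E731
    by_organ: dict[str, list[Lesion]] = {}
    for l in sorted(candidates, key=hotness):
        by_organ.setdefault(l.organ, []).append(l)
    pooled = [l for org in by_organ.values() for l in org[:2]]
    return [l.lesion_id for l in sorted(pooled, key=hotness)[:10]]


def classify_percist(pair: ScanPair, targets: list[str]) -> PercistResult:
    """Hottest-lesion SUVpeak response over PERCIST targets.

    Compares the maximum baseline SUVpeak over targets with the maximum
    follow-up SUVpeak over the same targets (the hottest lesion may change
    identity between scans). Metabolic response (MR) requires a decrease
    strictly greater than 30%; otherwise metabolic non-response (MNR).
    Returns status ``None`` when no target carries a follow-up SUVpeak.
    """
    if not targets:
        raise ValueError("no PERCIST targets supplied")
    target_set = set(targets)
    base_peaks = [
        l.suvpeak
        for l in pair.baseline.lesions
        if l.lesion_id in target_set and l.suvpeak is not None
    ]
    if not base_peaks:
        raise ValueError("no baseline SUVpeak among targets")
    fu_peaks = [
        l.suvpeak
        for l in pair.followup.lesions
        if l.lesion_id in target_set and l.suvpeak is not None
    ]
    if not fu_peaks:
        return PercistResult(None, tuple(targets), float("nan"))
    delta = lesion_delta_pct(max(base_peaks), max(fu_peaks))
    status = "MR" if delta < -30.0 else "MNR"
    return PercistResult(status, tuple(targets), delta)


def disease_burden(
    lesions: list[Lesion] | tuple[Lesion, ...], ref: ReferenceUptake | None = None
) -> DiseaseBurden:
    """Baseline disease-burden summary: total MATV and lesion count.

    The count covers evaluable lesions when a reference is given, otherwise
    all lesions. MATV totals over lesions reporting a volume; a partial
    total is flagged ``matv_incomplete`` rather than rejected. Emits the two
    prognostic dichotomies: MATV > 100 cm^3 and more than 7 lesions.
    """
    if ref is not None:
        counted = [l for l in lesions if check_lesion_evaluability(l, ref)]
    else:
        counted = list(lesions)
    matvs = [l.matv_cm3 for l in counted if l.matv_cm3 is not None]
    total = float(sum(matvs))
    incomplete = len(matvs) < len(counted)
    if incomplete:
        logger.info("MATV total over %d of %d lesions (missing volumes)", len(matvs), len(counted))
    return DiseaseBurden(
        matv_total_cm3=total,
        n_lesions=len(counted),
        matv_gt_100cm3=total > 100.0,
        gt_7_lesions=len(counted) > 7,
        matv_incomplete=incomplete,
    )


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa between two binary raters, (po - pe) / (1 - pe).

    NaN when chance agreement pe = 1 (both raters constant on the same
    label). Delegates to scikit-learn's implementation.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if not a:
        raise ValueError("rating vectors must be non-empty")
    if len(set(a)) == 1 and set(a) == set(b):
        return float("nan")  # pe = 1, undefined
    return float(cohen_kappa_score(a, b))
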