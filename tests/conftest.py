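"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from dynamark.pet import Lesion, ReferenceUptake, Scan, ScanMeta, ScanPair

# liver-branch evaluability threshold for this reference: 1.5*(2.0 + 2*0.3) = 3.9
REF = ReferenceUptake(
    liver_suvmean=2.0,
    liver_suvsd=0.3,
    bloodpool_suvmean=1.5,
    bloodpool_suvsd=0.2,
    liver_abnormal=False,
)


def make_meta(
    timepoint="baseline",
    activity=300.0,
    uptake=65.0,
    glucose=95.0,
    scanner="scanner1",
    days=-2,
):
    return ScanMeta(
        timepoint=timepoint,
        injected_activity_mbq=activity,
        uptake_time_min=uptake,
        glucose_mg_dl=glucose,
        scanner_id=scanner,
        days_from_treatment_start=days,
    )


def make_pair(
    deltas,
    matvs=None,
    new_lesion=False,
    baseline_suvmax=10.0,
    organs=None,
    ref=REF,
    **meta_kwargs,
) -> ScanPair:
    """Build a two-timepoint scan pair whose lesions realise given SUVmax deltas (%)."""
    n = len(deltas)
    matvs = matvs if matvs is not None else [10.0] * n
    organs = organs if organs is not None else ["liver"] * n
    base_lesions = [
        Lesion(f"L{i:02d}", organs[i], baseline_suvmax, matv_cm3=matvs[i]) for i in range(n)
    ]
    fu_lesions = [
        Lesion(f"L{i:02d}", organs[i], baseline_suvmax * (1 + deltas[i] / 100.0))
        for i in range(n)
    ]
    if new_lesion:
        fu_lesions.append(Lesion("Lnew", "other", 8.0, is_new=True))
    return ScanPair(
        patient_id="PX",
        baseline=Scan(make_meta("baseline", **meta_kwargs), ref, tuple(base_lesions)),
        followup=Scan(make_meta("d14", days=14, **meta_kwargs), ref, tuple(fu_lesions)),
    )


def consist_oracle(deltas, weights, new_lesion: bool, cutoff: float) -> int:
    """Exhaustive rule enumeration for the four-class dominance method.

    Independent restatement of the classification rules, applied in the
    order the classes are defined: progression (new lesion, any SUVmax
    increase, or nothing responding) is class 4; a uniform response is
    class 1; otherwise the load-weighted responding share decides 2 vs 3.
    """
    responds = [d < -cutoff for d in deltas]
    if new_lesion:
        return 4
    if any(d > 0 for d in deltas):
        return 4
    if not any(responds):
        return 4
    if all(responds):
        return 1
    total = sum(weights)
    share = sum(w for w, r in zip(weights, responds) if r) / total
    return 2 if share > 0.5 else 3


@pytest.fixture
def ref():
    return REF
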