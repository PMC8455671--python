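"""Combining PET metabolic response with ctDNA detection.

Cross-classifies patients by early metabolic response (responder R vs
non-responder NR) and day-14 ctDNA detection (detected D vs not-detected
ND), and quantifies how well each unfavorable test — and their combination —
identifies rapid progressors. The headline statistic is the proportion of
test-unfavorable patients whose progression-free survival falls short of a
horizon (3 months by default); this matches the clinical usage of "negative
predictive value" for predicting non-benefit, and the full 2x2 table is
emitted alongside so textbook operating characteristics remain derivable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

GROUPS = ("R_and_ND", "R_and_D", "NR_and_ND", "NR_and_D", "incomplete")

__all__ = ["CombinedGroup", "PredictiveSummary", "combine", "npv_early_progression"]


@dataclass(frozen=True)
class CombinedGroup:
    patient_id: str
    pet_responder: bool | None
    ctdna_detected_d14: bool | None
    group: str


@dataclass(frozen=True)
class PredictiveSummary:
    """Horizon-progression summary for one unfavorable test definition.

    ``npv_pct`` = 100 * k / n where k counts unfavorable patients with an
    observed progression/death before the horizon and n counts unfavorable
    patients with a determinable horizon status. ``table2x2`` is
    ((unfav & early-prog, unfav & not), (favorable & early-prog, favorable
    & not)) over all determinable patients.
    """

    test_name: str
    k_progressed_lt_horizon: int
    n_test_unfavorable: int
    npv_pct: float
    horizon_months: float
    n_excluded_censored: int
    table2x2: tuple[tuple[int, int], tuple[int, int]]


def _round_half_away(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def combine(
    pet_responder: Mapping[str, bool | None],
    ctdna_detected_d14: Mapping[str, bool | None],
) -> dict[str, CombinedGroup]:
    """Four-way cross-classification of PET response and day-14 ctDNA.

    Inputs are patient -> flag maps (``None`` = component unavailable).
    Patients appearing in either map are classified; any missing or ``None``
    component yields group ``incomplete``.
    """
    out: dict[str, CombinedGroup] = {}
    for pid in sorted(set(pet_responder) | set(ctdna_detected_d14)):
        r = pet_responder.get(pid)
        d = ctdna_detected_d14.get(pid)
        if r is None or d is None:
            grp = "incomplete"
        else:
            grp = ("R" if r else "NR") + "_and_" + ("D" if d else "ND")
        out[pid] = CombinedGroup(pid, r, d, grp)
    return out


def combine_records(
    pet_records: Iterable[tuple[str, bool | None]],
    ctdna_records: Iterable[tuple[str, bool | None]],
) -> dict[str, CombinedGroup]:
    """Like :func:`combine` but over (patient_id, flag) rows, rejecting duplicates."""
    maps = []
    for name, records in (("pet", pet_records), ("ctdna", ctdna_records)):
        m: dict[str, bool | None] = {}
        for pid, flag in records:
            if pid in m:
                raise ValueError(f"duplicate patient_id {pid!r} in {name} input")
            m[pid] = flag
        maps.append(m)
    return combine(maps[0], maps[1])


def npv_early_progression(
    unfavorable: Sequence[bool | None],
    pfs_months: Sequence[float],
    event: Sequence[bool],
    horizon_months: float = 3.0,
    test_name: str = "test",
) -> PredictiveSummary:
    """Proportion of test-unfavorable patients progressing before the horizon.

    A patient's horizon status is *early progression* when a progression or
    death event is observed before ``horizon_months``, and *no early
    progression* when they are followed (with or without later event) to at
    least the horizon. Patients censored before the horizon without an event
    have an undeterminable status and are excluded from numerator and
    denominator; patients with an unknown (``None``) test result are likewise
    excluded.
    """
    if not len(unfavorable) == len(pfs_months) == len(event):
        raise ValueError("input vectors must have equal length")
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")

    k = n = excluded = 0
    table = [[0, 0], [0, 0]]
    for unfav, t, e in zip(unfavorable, pfs_months, event):
        if unfav is None:
            continue
        early = None
        if t < horizon_months:
            early = True if e else None  # censored short of the horizon
        else:
            early = False
        if early is None:
            if unfav:
                excluded += 1
            continue
        table[0 if unfav else 1][0 if early else 1] += 1
        if unfav:
            n += 1
            if early:
                k += 1
    if n == 0:
        npv = float("nan")
    else:
        npv = _round_half_away(100.0 * k / n, 1)
    return PredictiveSummary(
        test_name=test_name,
        k_progressed_lt_horizon=k,
        n_test_unfavorable=n,
        npv_pct=npv,
        horizon_months=horizon_months,
        n_excluded_censored=excluded,
        table2x2=(tuple(table[0]), tuple(table[1])),
    )
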