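"""Log-rank trial design under exponential survival.

Two small calculations that sit behind the sample-size justification of an
early-response biomarker trial: the hazard ratio implied by a pair of
fixed-horizon survival fractions when both arms are exponential, and the
Schoenfeld approximation for the number of events a log-rank test needs to
detect that hazard ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["DesignSpec", "exponential_hr", "schoenfeld_events"]


def exponential_hr(s_control: float, s_experimental: float, horizon_months: float = 6.0) -> float:
    """Hazard ratio (experimental vs control) implied by survival fractions.

    Under exponential survival S(t) = exp(-lambda t), the ratio of hazards is
    the ratio of log survival fractions at any common horizon:

        HR = ln(S_experimental(t)) / ln(S_control(t))

    The horizon cancels algebraically; it is accepted for interface symmetry
    with :class:`DesignSpec` and must merely be positive.

    Parameters
    ----------
    s_control, s_experimental
        Survival probabilities at the horizon, strictly inside (0, 1).
    horizon_months
        Common horizon at which both fractions are read (unused in the
        arithmetic, see above).
    """
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    for name, s in (("s_control", s_control), ("s_experimental", s_experimental)):
        if not 0.0 < s < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {s}")
    return math.log(s_experimental) / math.log(s_control)


def schoenfeld_events(
    hr: float,
    alpha_two_sided: float = 0.05,
    power: float = 0.90,
    allocation_fraction: float = 0.5,
) -> int:
    """Required number of events for a two-group log-rank test (Schoenfeld).

        d = ceil( (z_{1-alpha/2} + z_{power})^2 / (p (1-p) ln^2 HR) )

    where ``p`` is the fraction of patients in one arm.  Normal quantiles are
    evaluated in double precision and the result is rounded up to a whole
    event.  Symmetric in ``ln HR``: ``schoenfeld_events(h) ==
    schoenfeld_events(1/h)``.
    """
    if hr <= 0:
        raise ValueError("hr must be positive")
    if hr == 1:
        raise ValueError("hr = 1 implies an infinite event requirement")
    for name, q in (
        ("alpha_two_sided", alpha_two_sided),
        ("power", power),
        ("allocation_fraction", allocation_fraction),
    ):
        if not 0.0 < q < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {q}")
    z_alpha = norm.ppf(1.0 - alpha_two_sided / 2.0)
    z_power = norm.ppf(power)
    p = allocation_fraction
    d = (z_alpha + z_power) ** 2 / (p * (1.0 - p) * math.log(hr) ** 2)
    return math.ceil(d)


@dataclass(frozen=True)
class DesignSpec:
    """A complete two-arm log-rank design read off survival fractions.

    Attributes
    ----------
    s_control, s_experimental
        Fixed-horizon progression-free survival fractions of the two arms
        (e.g. 6-month PFS of metabolic non-responders vs responders).
    horizon_months
        The horizon the fractions refer to.
    alpha_two_sided
        Two-sided significance level.
    power
        Target power.
    allocation_fraction
        Anticipated share of patients in one arm (e.g. the non-response rate
        observed in a pilot phase).
    """

    s_control: float
    s_experimental: float
    horizon_months: float = 6.0
    alpha_two_sided: float = 0.05
    power: float = 0.90
    allocation_fraction: float = 0.5

    def __post_init__(self) -> None:
        # exponential_hr validates the fractions; run it eagerly so a bad
        # spec fails at construction, not first use.
        exponential_hr(self.s_control, self.s_experimental, self.horizon_months)

    @property
    def hazard_ratio(self) -> float:
        return exponential_hr(self.s_control, self.s_experimental, self.horizon_months)

    def required_events(self) -> int:
        return schoenfeld_events(
            self.hazard_ratio, self.alpha_two_sided, self.power, self.allocation_fraction
        )
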