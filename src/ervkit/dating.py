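"""Insertion-age estimation from LTR divergence.

The two LTRs of a provirus are identical at integration and accumulate
substitutions independently afterwards, so their divergence D clocks the
insertion age:

    T = (D / R) / 2

where R is the neutral substitution rate per site per year.  Because the LTR
substitution rate of felid ERVs is unknown, ages are reported under a panel
of rates from the literature: 2.3e-9 and 5e-9 (human ERV LTRs) and 1.2e-8
(felid nuclear DNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .distances import DistanceEstimate

__all__ = ["AgeEstimate", "RatePanel", "DEFAULT_RATE_PANEL", "date_insertion", "date_with_rate_panel"]


@dataclass(frozen=True)
class AgeEstimate:
    """An insertion age T = D/(2R) with the inputs that produced it."""

    D: float
    R: float
    T_years: float
    T_MY: float
    T_se_MY: float = 0.0
    rate_label: str = ""

    def __post_init__(self) -> None:
        if self.T_MY < 0:
            raise ValueError("negative age")


@dataclass(frozen=True)
class RatePanel:
    """Ordered (label, rate) pairs; rates in substitutions/site/year."""

    rates: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError("empty rate panel")
        for label, r in self.rates:
            if r <= 0:
                raise ValueError(f"rate {label!r} must be positive, got {r}")

    def __iter__(self):
        return iter(self.rates)

    def __len__(self) -> int:
        return len(self.rates)


#: Slow/fast human-ERV LTR rates and the felid nuclear rate.
DEFAULT_RATE_PANEL = RatePanel(
    rates=(
        ("human_erv_2.3e-9", 2.3e-9),
        ("human_erv_5e-9", 5e-9),
        ("felid_nuclear_1.2e-8", 1.2e-8),
    )
)


def date_insertion(
    D: float | DistanceEstimate,
    R: float,
    rate_label: str = "",
) -> AgeEstimate:
    """Convert an LTR divergence into an insertion age via T = D/(2R).

    ``D`` may be a bare divergence or a :class:`DistanceEstimate`, in which
    case its standard error is propagated through the same linear map.
    Arithmetic is exact; rounding happens only in the reporting layer.
    """
    if R <= 0:
        raise ValueError(f"substitution rate must be positive, got {R}")
    d, se = (D.value, D.se) if isinstance(D, DistanceEstimate) else (float(D), 0.0)
    if d < 0:
        raise ValueError(f"divergence must be non-negative, got {d}")
    t_years = d / (2.0 * R)
    return AgeEstimate(
        D=d,
        R=R,
        T_years=t_years,
        T_MY=t_years / 1e6,
        T_se_MY=se / (2.0 * R) / 1e6,
        rate_label=rate_label,
    )


def date_with_rate_panel(
    D: float | DistanceEstimate,
    panel: RatePanel | Iterable[tuple[str, float]] = DEFAULT_RATE_PANEL,
) -> list[AgeEstimate]:
    """One age estimate per rate in the panel, panel order preserved."""
    if not isinstance(panel, RatePanel):
        panel = RatePanel(rates=tuple(panel))
    return [date_insertion(D, r, label) for label, r in panel]
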