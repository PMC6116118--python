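"""Physical-activity classification from summarized accelerometry.

The pipeline consumes already-summarized activity: mean daily ENMO-based
total physical activity (mg) and MVPA minutes per day. A child is *active*
when reaching at least 60 min/day of moderate-to-vigorous physical activity,
*inactive* below; the 60-min boundary is inclusive on the active side.
Raw signal processing (ENMO extraction, cut-points, wear-time rules) is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

#: MVPA min/day at or above which a child counts as active.
MVPA_ACTIVE_MIN = 60.0


def classify_activity(mvpa_min_day: float) -> bool:
    """True (active) iff MVPA >= 60 min/day; negative input is a domain error."""
    if mvpa_min_day < 0:
        raise DomainError(f"mvpa_min_day must be >= 0, got {mvpa_min_day!r}")
    return mvpa_min_day >= MVPA_ACTIVE_MIN


@dataclass(frozen=True)
class ActivitySummary:
    """Summarized activity of one participant; ``is_active`` is derived."""

    total_pa_enmo: float
    mvpa_min_day: float

    def __post_init__(self) -> None:
        if self.total_pa_enmo < 0:
            raise DomainError("total_pa_enmo must be >= 0")
        if self.mvpa_min_day < 0:
            raise DomainError("mvpa_min_day must be >= 0")

    @property
    def is_active(self) -> bool:
        return classify_activity(self.mvpa_min_day)
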