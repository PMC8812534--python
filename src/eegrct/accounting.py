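"""Sample-flow accounting for a home-visit EEG study arm.

CONSORT-style bookkeeping: from visit, consent and usability counts to the
rates a study report prints, plus the annualized arm difference of a
monthly cash transfer.  Pure arithmetic on counts, kept in one place so the
reported percentages are always recomputed from their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SampleFlow:
    """Counts of the in-person visit → usable-EEG funnel."""

    n_visited: int            # completed in-person age-1 visits
    n_consented: int          # mothers consenting to EEG
    unusable_reasons: dict[str, int]  # reason → count of unusable recordings
    n_usable: int             # usable recordings entering analysis

    def __post_init__(self) -> None:
        if not 0 <= self.n_consented <= self.n_visited:
            raise ValueError("consent count must be between 0 and visits")
        if self.n_usable + self.n_unusable != self.n_consented:
            raise ValueError(
                f"usable ({self.n_usable}) + unusable ({self.n_unusable}) "
                f"must equal consented ({self.n_consented})"
            )

    @property
    def n_unusable(self) -> int:
        return sum(self.unusable_reasons.values())

    @property
    def consent_rate_pct(self) -> float:
        """Consenting mothers as % of completed visits."""
        return 100.0 * self.n_consented / self.n_visited

    @property
    def usable_rate_pct(self) -> float:
        """Usable recordings as % of consenting mothers."""
        return 100.0 * self.n_usable / self.n_consented


def survey_completion_pct(n_completed: int, n_enrolled: int) -> float:
    """Follow-up survey completion as a percentage of the enrolled cohort."""
    if not 0 <= n_completed <= n_enrolled:
        raise ValueError("completed must be between 0 and enrolled")
    return 100.0 * n_completed / n_enrolled


def annualized_gift_difference(high_monthly: float, low_monthly: float) -> float:
    """Yearly dollar difference between the two monthly transfer amounts."""
    return 12.0 * (high_monthly - low_monthly)
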