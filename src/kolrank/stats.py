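"""Small descriptive-statistics helpers for corpus summaries."""

from __future__ import annotations

from typing import Iterable

from .models import DoctorRecord, SENIOR_TITLES


def percentage(numerator: int | float, denominator: int | float, digits: int = 2) -> float:
    """Share of ``numerator`` in ``denominator`` as a percentage rounded
    to ``digits`` decimals (e.g. 18418/29203 -> 63.07)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round(100.0 * numerator / denominator, digits)


def senior_title_percentage(doctors: Iterable[DoctorRecord], digits: int = 2) -> float:
    """Percentage of doctors holding a senior professional title
    (chief or associate chief physician)."""
    docs = list(doctors)
    n_senior = sum(1 for d in docs if d.professional_title in SENIOR_TITLES)
    return percentage(n_senior, len(docs), digits)
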