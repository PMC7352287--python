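"""Partial calendar dates.

Spontaneous reports routinely carry truncated dates (year only, or
year-month). The package never imputes a missing component: a partial date
is usable for period filtering through interval-overlap semantics (it
passes a window if *any* completion falls inside) but counts as missing
for day-level arithmetic such as time-to-onset.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re
from dataclasses import dataclass

from .errors import ValidationError

_ISO = re.compile(r"^(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?$")
_COMPACT = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")


@dataclass(frozen=True, slots=True)
class PartialDate:
    """A calendar date whose month and/or day may be unknown."""

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValidationError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValidationError(f"month out of range: {self.month}")
        if self.day is not None:
            last = calendar.monthrange(self.year, self.month)[1]
            if not 1 <= self.day <= last:
                raise ValidationError(f"day out of range: {self.day}")

    # -- parsing / formatting -------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "PartialDate | None":
        """Parse ISO-8601 (possibly truncated) or compact ``YYYY[MM[DD]]``.

        Returns ``None`` for an empty string.
        """
        text = text.strip()
        if not text:
            return None
        m = _ISO.match(text) or _COMPACT.match(text)
        if m is None:
            raise ValidationError(f"unparseable date: {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    # -- completeness ---------------------------------------------------------

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> dt.date:
        """Exact date; only valid when complete."""
        if not self.is_complete:
            raise ValidationError(f"partial date {self.isoformat()} has no exact day")
        return dt.date(self.year, self.month, self.day)

    # -- interval semantics ---------------------------------------------------

    def earliest(self) -> dt.date:
        """Earliest completion of this partial date."""
        return dt.date(self.year, self.month or 1, self.day or 1)

    def latest(self) -> dt.date:
        """Latest completion of this partial date."""
        month = self.month or 12
        day = self.day or calendar.monthrange(self.year, month)[1]
        return dt.date(self.year, month, day)

    def in_window(self, start: dt.date, end: dt.date) -> bool:
        """True if any completion falls inside ``[start, end]``."""
        return self.earliest() <= end and self.latest() >= start

    def sort_key(self) -> tuple[int, int, int]:
        """Deterministic ordering key; unknown components sort first."""
        return (self.year, self.month or 0, self.day or 0)
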