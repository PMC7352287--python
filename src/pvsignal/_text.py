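"""Term and drug-name normalization.

Spontaneous-report sources spell the same preferred term inconsistently:
case differs, en/em dashes replace hyphens, and accented characters come
and go ("Guillain–Barré" vs "guillain-barre"). All term comparisons in the
package go through :func:`normalize_term` so that these variants collapse
to a single key.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache

_DASHES = str.maketrans({"‐": "-", "‑": "-", "‒": "-",
                         "–": "-", "—": "-", "−": "-"})
_WS = re.compile(r"\s+")


@lru_cache(maxsize=65536)
def normalize_term(term: str) -> str:
    """Return the canonical form of a MedDRA-style term or drug name.

    Unicode-decomposes and strips combining marks (accents), maps all dash
    variants to ``-``, case-folds, and collapses internal whitespace.
    """
    s = unicodedata.normalize("NFKD", term)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.translate(_DASHES).casefold()
    return _WS.sub(" ", s).strip()
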