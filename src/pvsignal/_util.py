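"""Small shared helpers: string normalization and percentage rounding."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_WS_PUNCT = re.compile(r"[^\w]+")
# tokens that carry dose/form, not identity: "5MG", "10", "MG", "TABLET", ...
_DOSE_TOKEN = re.compile(
    r"^\d|^(mg|mcg|ug|g|ml|iu|tab|tabs|tablet|tablets|cap|caps|capsule|capsules)$"
)


def normalize_text(s: str) -> str:
    """Case-fold and collapse whitespace/punctuation to single spaces."""
    return _WS_PUNCT.sub(" ", str(s)).strip().casefold()


def normalize_term(s: str) -> str:
    """Canonical form of an event preferred term: trimmed, case-folded."""
    return str(s).strip().casefold()


def drug_name_stem(normalized: str) -> str:
    """Leading tokens of a normalized drug string up to the first dose-like token.

    "norvasc 5mg" -> "norvasc"; "amlodipine besylate" -> "amlodipine besylate".
    """
    out = []
    for tok in normalized.split():
        if _DOSE_TOKEN.match(tok):
            break
        out.append(tok)
    return " ".join(out)


def pct_half_up(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up (the convention of printed summary tables)."""
    if total == 0:
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(100 * count / total).quantize(q, rounding=ROUND_HALF_UP))
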