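"""ICD-9-CM code primitives: normalization, prefix matching, washout-range tests.

ICD-9-CM diagnosis codes are written with an optional dot ("182.0"); claims
systems store them dot-stripped. Numeric codes carry a 3-digit *category*
("182" = malignant neoplasm of body of uterus); "182.xx" in a case definition
means the whole category, i.e. any code whose category is 182. V- and E-codes
are non-numeric and never fall in a numeric category range.
"""

from __future__ import annotations

from collections.abc import Iterable

from .errors import CodeFormatError


def normalize_dx_code(raw: str) -> str:
    """Canonicalize a raw diagnosis code: strip whitespace, drop dots, uppercase.

    >>> normalize_dx_code("182.0")
    '1820'
    """
    code = str(raw).strip().replace(".", "").upper()
    if not code:
        raise CodeFormatError(f"empty diagnosis code: {raw!r}")
    return code


def code_matches(code: str, prefixes: Iterable[str]) -> bool:
    """True iff ``code`` falls under any of the category ``prefixes``.

    A 3-digit numeric prefix denotes a full ICD-9 category: it matches a
    numeric code only when the code's leading 3-digit category equals the
    prefix (so "182" matches "1820" and "182", never "18" or "1821x"-style
    longer categories, which cannot occur in ICD-9).
    Longer prefixes use plain string-prefix semantics.
    """
    for prefix in prefixes:
        if not code.startswith(prefix):
            continue
        if code.isdigit() and len(prefix) == 3:
            if code[:3] == prefix:
                return True
        else:
            return True
    return False


def in_washout_range(code: str, low: int = 140, high: int = 209) -> bool:
    """True iff a canonical code is numeric with 3-digit category in [low, high].

    The default range 140-209 covers the ICD-9-CM malignant-neoplasm chapter
    used as the cancer-history washout; those categories are numeric-only, so
    V- and E-codes are never in range.
    """
    if not code.isdigit() or len(code) < 3:
        return False
    return low <= int(code[:3]) <= high
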