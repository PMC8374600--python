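"""Accent- and case-insensitive text normalisation.

Food names in the catalogue are Spanish and carry accents ("café",
"azúcar"); interviewers type queries without them. All matching in the
engine goes through :func:`normalize`: Unicode canonical decomposition,
removal of combining marks, casefold, whitespace collapse.
"""

import unicodedata

__all__ = ["normalize", "tokens"]


def normalize(s: str) -> str:
    """Fold a string for matching: strip diacritics, casefold, collapse spaces."""
    decomposed = unicodedata.normalize("NFKD", s)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


def tokens(s: str) -> list[str]:
    """Normalised whitespace-delimited tokens of *s*."""
    return normalize(s).split()
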