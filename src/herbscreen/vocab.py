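"""Controlled vocabulary for traditional drug-property terms.

A herb's drug property is the triple of nature ("four properties" plus
neutral), flavor ("five flavors" plus astringent/tasteless) and channel
tropism (the twelve meridians).  Together they form a fixed 24-term
vocabulary, encoded downstream as a 24-bit binary vector in the order
defined here.
"""

from __future__ import annotations

NATURES: tuple[str, ...] = ("cold", "hot", "warm", "cool", "neutral")

FLAVORS: tuple[str, ...] = (
    "pungent",
    "bitter",
    "sweet",
    "sour",
    "salty",
    "astringent",
    "tasteless",
)

CHANNELS: tuple[str, ...] = (
    "liver",
    "lung",
    "stomach",
    "spleen",
    "kidney",
    "heart",
    "large intestine",
    "gall bladder",
    "bladder",
    "small intestine",
    "pericardium",
    "triple energizer",
)

#: Fixed encoding order: 5 natures, 7 flavors, 12 channels.
PROPERTY_TERMS: tuple[str, ...] = NATURES + FLAVORS + CHANNELS

#: Position of each term in the 24-bit vector.
TERM_INDEX: dict[str, int] = {t: i for i, t in enumerate(PROPERTY_TERMS)}


def normalize_term(raw: str) -> str:
    """Normalize case/whitespace of a property term.

    Raises ``ValueError`` naming the offending term if it is not in the
    24-term vocabulary.
    """
    term = " ".join(raw.strip().lower().split())
    if term not in TERM_INDEX:
        raise ValueError(f"unknown drug-property term: {raw!r}")
    return term
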