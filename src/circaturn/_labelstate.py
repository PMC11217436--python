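"""SILAC labelling-state classification from modification strings.

A peptide is *heavy* when it carries at least one heavy arginine
(Arg10) or heavy lysine (Lys8); everything else — including peptides
with only variable modifications such as methionine oxidation — is
*light*. Modification strings follow the MaxQuant dialect: tokens
separated by ``;`` or ``,``, each optionally prefixed with a count
("2 Arg10"); matching is a case-insensitive substring test per token so
that dialect drift between MaxQuant versions ("TMTpro K + K8") still
classifies correctly.
"""

from __future__ import annotations

import re

from .errors import FormatError

HEAVY = "heavy"
LIGHT = "light"

_HEAVY_PATTERN = re.compile(r"arg10|lys8", re.IGNORECASE)
_COUNT_PREFIX = re.compile(r"^\d+\s+")


def _tokens(modifications: str | list[str]) -> list[str]:
    if isinstance(modifications, (list, tuple)):
        raw = [str(t) for t in modifications]
    elif isinstance(modifications, str):
        raw = re.split(r"[;,]", modifications)
    else:
        raise FormatError(f"unparseable modification value: {modifications!r}")
    out = []
    for tok in raw:
        tok = _COUNT_PREFIX.sub("", tok.strip())
        if tok:
            out.append(tok)
    return out


def classify_label_state(modifications: str | list[str]) -> str:
    """Return ``"heavy"`` or ``"light"`` for a modification annotation."""
    toks = _tokens(modifications)
    if any(_HEAVY_PATTERN.search(t) for t in toks):
        return HEAVY
    return LIGHT
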