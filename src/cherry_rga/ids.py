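"""Transcript / gene identifier conventions.

Gene models follow the ``PCE_{A|F}_Chro<N>G<NNNNNNN>`` scheme, with splice
variants distinguished by a trailing ``.<k>``; the subgenome letter after the
species prefix tells the *P. avium*-like (A) from the *P. fruticosa*-like (F)
chromosome set apart.  The rules are configurable regular expressions because
other annotations use other schemes.
"""

from __future__ import annotations

import re

#: Default transcript -> gene rule: strip one trailing ".<integer>".
DEFAULT_ID_PATTERN = r"^(?P<gene>.+)\.\d+$"

#: Default subgenome rule: letter between the first two underscores.
DEFAULT_SUBGENOME_PATTERN = r"^[A-Za-z]+_(?P<subgenome>[AF])_"


def transcript_to_gene(transcript_id: str, id_pattern: str = DEFAULT_ID_PATTERN) -> str:
    """Collapse a transcript ID to its gene ID.

    IDs that do not match the pattern (no splice-variant suffix) are returned
    unchanged, so the function is a projection: applying it twice equals
    applying it once for the default pattern.
    """
    m = re.match(id_pattern, transcript_id)
    return m.group("gene") if m else transcript_id


def subgenome_of(any_id: str, subgenome_pattern: str = DEFAULT_SUBGENOME_PATTERN) -> str:
    """Return ``"A"``, ``"F"``, or ``"OTHER"`` for a transcript or gene ID."""
    m = re.match(subgenome_pattern, any_id)
    return m.group("subgenome") if m else "OTHER"
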