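"""Shared alphabet conventions.

Amino-acid letters are always handled in the fixed order ``ACDEFGHIKLMNPQRSTVWY``
(alphabetical one-letter codes); integer letter indices refer to positions in
this string.
"""

from __future__ import annotations

AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

N_LETTERS: int = 20
#: number of distinct full-alphabet sequence trimers (20^3)
N_TRIMERS: int = N_LETTERS**3

#: the ten amino acids widely held to have been abundant prebiotically
PREBIOTIC_LETTERS: frozenset[str] = frozenset("ADEGILPSTV")

#: contact definition: minimum sequence separation and hard distance cap (Angstrom)
MIN_CONTACT_SEPARATION: int = 5
CONTACT_DISTANCE_CAP: float = 12.0
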