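"""Comorbidity outcome coding.

Three binary illness indicators (diarrhoea, fever, cough — "had the illness
in the two weeks before interview") are collapsed into one 8-level
categorical outcome.  Category 0 (no illness) is the reference level of
every downstream model; categories 1..7 enumerate the non-empty illness
combinations in a fixed, documented order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CATEGORY_LABELS",
    "ComorbidityOutcome",
    "encode_outcome",
    "encode_outcomes",
    "decode_outcome",
]

#: Category index -> canonical label.  The order is fixed: all three
#: illnesses first, then the two-illness combinations, then singles.
CATEGORY_LABELS: dict[int, str] = {
    0: "none",
    1: "diarrhoea+fever+cough",
    2: "diarrhoea+fever",
    3: "diarrhoea+cough",
    4: "fever+cough",
    5: "diarrhoea",
    6: "fever",
    7: "cough",
}

# (diarrhoea, fever, cough) triple -> category.  A bijection on {0,1}^3.
_TRIPLE_TO_K: dict[tuple[int, int, int], int] = {
    (1, 1, 1): 1,
    (1, 1, 0): 2,
    (1, 0, 1): 3,
    (0, 1, 1): 4,
    (1, 0, 0): 5,
    (0, 1, 0): 6,
    (0, 0, 1): 7,
    (0, 0, 0): 0,
}
_K_TO_TRIPLE = {k: t for t, k in _TRIPLE_TO_K.items()}

N_CATEGORIES = 8


@dataclass(frozen=True)
class ComorbidityOutcome:
    """One child's comorbidity state: category index ``k`` and its label."""

    k: int

    def __post_init__(self) -> None:
        if self.k not in CATEGORY_LABELS:
            raise ValueError(f"category must be in 0..7, got {self.k}")

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self.k]

    @property
    def flags(self) -> tuple[int, int, int]:
        """(diarrhoea, fever, cough) triple for this category."""
        return _K_TO_TRIPLE[self.k]


def encode_outcome(diarrhoea: int, fever: int, cough: int) -> ComorbidityOutcome:
    """Collapse the three illness flags into the 8-level outcome.

    Raises
    ------
    ValueError
        If any flag is missing (None/NaN) or outside {0, 1}.  Missing flags
        must be handled by exclusion upstream, never silently imputed.
    """
    triple = []
    for name, flag in (("diarrhoea", diarrhoea), ("fever", fever), ("cough", cough)):
        if flag is None or (isinstance(flag, float) and np.isnan(flag)):
            raise ValueError(f"missing illness flag: {name}")
        if flag not in (0, 1):
            raise ValueError(f"illness flag {name} must be 0 or 1, got {flag!r}")
        triple.append(int(flag))
    return ComorbidityOutcome(_TRIPLE_TO_K[tuple(triple)])


def encode_outcomes(diarrhoea, fever, cough) -> np.ndarray:
    """Vectorised :func:`encode_outcome` over aligned 0/1 arrays."""
    d = np.asarray(diarrhoea)
    f = np.asarray(fever)
    c = np.asarray(cough)
    for name, a in (("diarrhoea", d), ("fever", f), ("cough", c)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"illness flag column {name} contains values outside {{0,1}}")
    # Weighted-sum lookup reproducing the combination table exactly.
    lut = np.empty(8, dtype=np.int64)
    for (dd, ff, cc), k in _TRIPLE_TO_K.items():
        lut[dd * 4 + ff * 2 + cc] = k
    return lut[d.astype(np.int64) * 4 + f.astype(np.int64) * 2 + c.astype(np.int64)]


def decode_outcome(k: int) -> tuple[int, int, int]:
    """Inverse of :func:`encode_outcome`: category -> (diarrhoea, fever, cough)."""
    if k not in _K_TO_TRIPLE:
        raise ValueError(f"category must be in 0..7, got {k}")
    return _K_TO_TRIPLE[k]
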