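"""Canonical amino-acid alphabet shared by every vector and matrix in the package.

The order is the PAML rate-matrix convention (A R N D C Q E G H I L K M F P S T W Y V),
so frequency vectors index directly into rate matrices read from PAML-dialect files.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
N_TYPES: int = 20

GAP: str = "-"
UNKNOWN: str = "X"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: characters allowed in an aligned row
VALID_CHARS: frozenset[str] = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}


def index_of(aa: str) -> int:
    """Index of a one-letter amino-acid code in the canonical order."""
    try:
        return AA_INDEX[aa]
    except KeyError:
        raise ValueError(f"not a canonical amino-acid code: {aa!r}") from None
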