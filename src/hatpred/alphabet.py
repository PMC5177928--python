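"""Amino-acid alphabet and integer encoding shared across the package.

The working alphabet is the 20 standard residues plus two reserved symbols:
``X`` for unknown/ambiguous residues and ``*`` for positions that fall
outside a protein when a peptide window overhangs a terminus.  Both reserved
symbols contribute a substitution score of 0 against everything, so they are
neutral under the similarity functions.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard residues, in the row order of the published BLOSUM62 table.
RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: Symbol for unknown / ambiguous residues.
UNKNOWN = "X"

#: Padding symbol used when a window overhangs a sequence terminus.
PAD = "*"

#: Full working alphabet (22 symbols).  Index order is load-bearing: the
#: substitution matrix is stored as a 22x22 array in this order.
ALPHABET = RESIDUES + UNKNOWN + PAD

N_RESIDUES = len(RESIDUES)
N_SYMBOLS = len(ALPHABET)

UNKNOWN_INDEX = ALPHABET.index(UNKNOWN)
PAD_INDEX = ALPHABET.index(PAD)

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
# Ambiguity codes and rare residues collapse to 'X'.
for _amb in "BZJUO":
    _INDEX[_amb] = UNKNOWN_INDEX

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _ch, _i in _INDEX.items():
    _LOOKUP[ord(_ch)] = _i


def index_of(symbol: str) -> int:
    """Return the alphabet index of a single residue symbol."""
    try:
        return _INDEX[symbol]
    except KeyError:
        raise ValueError(f"unknown residue symbol {symbol!r}") from None


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as an array of alphabet indices.

    Ambiguity codes (B, Z, J, U, O) map to the unknown symbol; any other
    character outside the alphabet raises ``ValueError``.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    idx = _LOOKUP[raw]
    if (idx < 0).any():
        bad = sequence[int(np.argmax(idx < 0))]
        raise ValueError(f"unknown residue symbol {bad!r} in {sequence!r}")
    return idx.astype(np.uint8)


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode` (reserved symbols decode to 'X'/'*')."""
    return "".join(ALPHABET[i] for i in indices)
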