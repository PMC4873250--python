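"""Canonical amino-acid alphabet shared by every module.

All feature encoders, generators and enrichment statistics are defined over
the 20 standard residues in the fixed order below; indices into feature
vectors are positions in this string.
"""

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES: int = 20
N_DIPEPTIDES: int = 400

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: ordered residue pairs, first residue major: AA, AC, AD, ..., YW, YY
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

# residues the sanitizer treats as non-canonical noise (ambiguity codes,
# rare residues, stops, gaps)
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ*-.")

# byte -> residue index lookup (255 = invalid), for vectorised counting
_BYTE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _BYTE_TO_INDEX[ord(_aa)] = _i


def residue_indices(residues: str) -> np.ndarray:
    """Map a canonical residue string to an int array of alphabet indices."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    idx = _BYTE_TO_INDEX[raw]
    if (idx == 255).any():
        bad = sorted({residues[i] for i in np.nonzero(idx == 255)[0]})
        raise ValueError(f"non-canonical residues {bad!r} in sequence")
    return idx.astype(np.intp)
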