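"""Amino-acid alphabet and background frequencies shared across the package."""

from __future__ import annotations

import numpy as np

#: Canonical 20 amino acids, fixed column order for all emission tables.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"

# Robinson & Robinson (1991) amino-acid frequencies, the background commonly
# used for protein log-odds scoring; renormalized over the 20 canonical
# residues in AMINO_ACIDS order.
_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

BACKGROUND = np.array([_ROBINSON[aa] for aa in AMINO_ACIDS])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


def encode(seq: str) -> np.ndarray:
    """Map a residue string to integer indices; raises on non-canonical residues."""
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from None


def is_canonical(seq: str) -> bool:
    return all(c in AA_INDEX for c in seq)
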