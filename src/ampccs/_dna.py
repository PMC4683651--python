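"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"
DNA_N_ALPHABET = "ACGTN"

# fixed base <-> code mapping used by the vectorized aligner and simulators
BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}
CODE_TO_BASE = np.array(list("ACGTN"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, b in enumerate(seq):
        try:
            out[i] = BASE_TO_CODE[b]
        except KeyError:
            raise ValueError(f"non-DNA character {b!r} at position {i}") from None
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(CODE_TO_BASE[codes])


def validate_dna(seq: str, *, allow_n: bool = True, context: str = "sequence") -> None:
    alphabet = set(DNA_N_ALPHABET if allow_n else DNA_ALPHABET)
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{context} contains non-DNA characters: {sorted(bad)}")
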