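"""RNA alphabet normalization and small sequence utilities.

Everything downstream of I/O works on the RNA alphabet {A, C, G, U};
DNA input is transcribed (T -> U) on read. Masked positions produced by
the PAS-exclusion step use the symbol ``N``, which never matches any
k-mer.
"""

from __future__ import annotations

RNA_BASES = "ACGU"
MASK = "N"

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class AlphabetError(ValueError):
    """A sequence contains a character outside the RNA alphabet."""


def normalize_rna(raw: str, *, name: str = "sequence") -> str:
    """Uppercase, transcribe T->U and validate against {A,C,G,U}.

    Raises :class:`AlphabetError` naming the 1-based position of the
    first illegal character.
    """
    up = raw.upper()
    out = []
    for i, ch in enumerate(up):
        if ch == "T":
            ch = "U"
        if ch not in RNA_BASES:
            raise AlphabetError(
                f"illegal character {ch!r} at position {i + 1} in {name}"
            )
        out.append(ch)
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_rna(seq: str, *, allow_mask: bool = False) -> bool:
    allowed = set(RNA_BASES + (MASK if allow_mask else ""))
    return bool(seq) and set(seq) <= allowed
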