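"""Small sequence helpers shared across modules.

All sequences are handled internally as uppercase DNA strings; RNA input is
accepted anywhere and transcribed back and forth with :func:`to_dna` /
:func:`to_rna`.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUN", "TGCAAN")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result in DNA alphabet)."""
    return seq.translate(_COMP)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


def gc_pairable(a: str, b: str) -> bool:
    """True if bases a, b (DNA alphabet) can pair as Watson-Crick or G:T(U) wobble."""
    pair = a + b
    return pair in ("AT", "TA", "GC", "CG", "GT", "TG")


def is_watson_crick(a: str, b: str) -> bool:
    return a + b in ("AT", "TA", "GC", "CG")


def is_wobble(a: str, b: str) -> bool:
    return a + b in ("GT", "TG")
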