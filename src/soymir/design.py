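"""Library design for the 2 genotype x 2 tissue x 2 treatment x 2 term crossing.

Sixteen sequencing libraries arise from crossing two genotypes (a low-N
tolerant line, "116", and a low-N sensitive line, "84"), two tissues (root,
shoot), two stress terms (short, long; each a pool of several time points)
and two treatments (low-N stress vs. control).  Library identifiers follow
the field convention ``<genotype><R|S><S|L>[C]``, e.g. ``116RS`` for the
tolerant-genotype root short-term stress library and ``116RSC`` for its
control partner.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

GENOTYPES = ("tolerant", "sensitive")
TISSUES = ("root", "shoot")
TREATMENTS = ("stress", "control")
TERMS = ("short", "long")

_GENO_CODE = {"tolerant": "116", "sensitive": "84"}
_TISSUE_CODE = {"root": "R", "shoot": "S"}
_TERM_CODE = {"short": "S", "long": "L"}


@dataclass(frozen=True)
class LibraryDesign:
    """One sequencing library of the 16-library crossing."""

    genotype: str
    tissue: str
    treatment: str
    term: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.term not in TERMS:
            raise ValueError(f"unknown term {self.term!r}")

    @property
    def library_id(self) -> str:
        code = (
            _GENO_CODE[self.genotype]
            + _TISSUE_CODE[self.tissue]
            + _TERM_CODE[self.term]
        )
        if self.treatment == "control":
            code += "C"
        return code


def make_design() -> list[LibraryDesign]:
    """Return the full 16-library crossing in canonical order.

    The crossing of 2 genotypes x 2 tissues x 2 terms x 2 treatments yields
    exactly 16 libraries with unique identifiers.
    """
    libs = [
        LibraryDesign(genotype=g, tissue=ti, treatment=tr, term=te)
        for g, ti, te, tr in product(GENOTYPES, TISSUES, TERMS, TREATMENTS)
    ]
    ids = [l.library_id for l in libs]
    assert len(set(ids)) == 16
    return libs


def library_ids() -> list[str]:
    return [l.library_id for l in make_design()]


def stress_control_pairs() -> list[tuple[str, str]]:
    """The eight stress-vs-control comparisons, as (stress_id, control_id).

    Each stress library is compared against the control library matched on
    genotype, tissue and term.
    """
    pairs = []
    for lib in make_design():
        if lib.treatment == "stress":
            control = LibraryDesign(
                genotype=lib.genotype,
                tissue=lib.tissue,
                treatment="control",
                term=lib.term,
            )
            pairs.append((lib.library_id, control.library_id))
    return pairs


def comparison_id(stress_id: str, control_id: str) -> str:
    return f"{stress_id}_vs_{control_id}"
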