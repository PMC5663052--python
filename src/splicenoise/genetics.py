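"""Genetic codes and low-level sequence helpers.

PTC detection in *Paramecium tetraurelia* must use the ciliate nuclear code,
in which TAA and TAG encode glutamine and TGA is the only stop codon; the
standard code would call spurious stops throughout A/T-rich ciliate coding
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code reduced to what splicing analysis needs: its stop set."""

    name: str
    stop_codons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.stop_codons:
            raise ValueError("a genetic code needs at least one stop codon")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


#: Ciliate nuclear code: TGA is the sole stop (TAA/TAG encode Gln).
CILIATE_CODE = GeneticCode("ciliate", frozenset({"TGA"}))

#: Standard nuclear code.
STANDARD_CODE = GeneticCode("standard", frozenset({"TAA", "TAG", "TGA"}))

CODES = {"ciliate": CILIATE_CODE, "standard": STANDARD_CODE}


def first_stop(seq: str, code: GeneticCode, start: int = 0) -> int | None:
    """Nucleotide offset of the first in-frame stop codon at or after ``start``.

    ``start`` must be a codon boundary offset. Returns None when no full
    in-frame stop codon occurs.
    """
    for i in range(start, len(seq) - 2, 3):
        if code.is_stop(seq[i : i + 3]):
            return i
    return None
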