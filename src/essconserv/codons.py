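"""Genetic codes and CDS translation.

The organisms this package targets are bacteria, so the default genetic
code is NCBI translation table 11; *Mycoplasma* and relatives use table 4,
which is why the code is configurable per organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"


class InternalStopError(ValueError):
    """A stop codon occurs before the final codon of a CDS."""

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(
            f"internal stop codon {codon!r} at codon index {codon_index}"
        )


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon genetic code.

    Parameters
    ----------
    table_id : int
        NCBI translation table number.
    forward : mapping
        codon -> one-letter amino acid, for all 64 codons; stop codons map
        to ``'*'``.
    stops : frozenset of str
        The stop codons of the table.
    """

    # identity (equality, hashing) is by table number: codes are canonical
    table_id: int
    forward: Mapping[str, str] = field(repr=False, compare=False)
    stops: frozenset = field(repr=False, compare=False)

    def __post_init__(self):
        if len(self.forward) != 64:
            raise ValueError("genetic code must define all 64 codons")
        if any(self.forward[c] != "*" for c in self.stops):
            raise ValueError("stop set inconsistent with codon mapping")

    @classmethod
    @lru_cache(maxsize=None)
    def from_table_id(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        for stop in table.stop_codons:
            forward[stop] = "*"
        return cls(
            table_id=table_id,
            forward=forward,
            stops=frozenset(table.stop_codons),
        )

    @property
    def sense_codons(self) -> tuple:
        """All codons that encode an amino acid, in lexicographic order."""
        return tuple(sorted(c for c in self.forward if c not in self.stops))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops

    def amino_acid(self, codon: str) -> str:
        """Translate one codon; codons containing N/ambiguity give 'X'."""
        aa = self.forward.get(codon)
        if aa is None:
            return "X"
        return aa


def iter_codons(cds: str):
    for i in range(0, len(cds), 3):
        yield cds[i : i + 3]


def trim_terminal_stop(cds: str, code: GeneticCode) -> str:
    """Drop a terminal stop codon if present (length must be divisible by 3)."""
    if len(cds) % 3 == 0 and len(cds) >= 3 and code.is_stop(cds[-3:]):
        return cds[:-3]
    return cds


def translate_cds(cds: str, code: GeneticCode | int = 11) -> str:
    """Translate a coding sequence to protein.

    A terminal stop codon is trimmed silently; an internal stop raises
    :class:`InternalStopError` with the offending codon index. Codons
    containing ``N`` (or any non-ACGT character) translate to ``'X'``.
    """
    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds)} is not a multiple of 3"
        )
    cds = trim_terminal_stop(cds, code)
    aas = []
    for i, codon in enumerate(iter_codons(cds)):
        aa = code.amino_acid(codon)
        if aa == "*":
            raise InternalStopError(i, codon)
        aas.append(aa)
    return "".join(aas)
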