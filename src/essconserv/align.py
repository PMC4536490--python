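"""Protein pairwise alignment and protein-guided codon alignment.

A deterministic optimal global alignment (BLOSUM62, affine gaps) stands in
for a progressive multiple aligner: for exactly two sequences the optimal
pairwise alignment is the canonical choice. The protein alignment is then
back-translated onto the coding sequences so that downstream substitution
counting operates on codon columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Tuple

from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import GAP_CODON, GeneticCode, iter_codons, translate_cds, trim_terminal_stop

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap protein scoring (defaults follow common global-alignment
    practice with BLOSUM62: gap open 10, gap extend 0.5)."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class ProteinAlignment:
    aligned_query: str
    aligned_subject: str
    score: float

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned rows must have equal length")

    @property
    def columns(self) -> int:
        return len(self.aligned_query)

    def identity_fraction(self) -> float:
        """Identical residues over aligned (both non-gap) columns."""
        pairs = [
            (a, b)
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != "-" and b != "-"
        ]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)

    def query_aligned_fraction(self) -> float:
        """Fraction of query residues placed opposite a subject residue."""
        n_query = sum(a != "-" for a in self.aligned_query)
        aligned = sum(
            a != "-" and b != "-"
            for a, b in zip(self.aligned_query, self.aligned_subject)
        )
        return aligned / n_query if n_query else 0.0


@dataclass(frozen=True)
class CodonAlignment:
    """Codon columns paired between two coding sequences; gaps are '---'."""

    columns: Tuple[Tuple[str, str], ...]

    def ungapped(self, row: int) -> str:
        return "".join(col[row] for col in self.columns if col[row] != GAP_CODON)


@lru_cache(maxsize=8)
def _aligner(scoring: AlignmentScoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aligner.mode = "global"
    return aligner


def align_protein_pair(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> ProteinAlignment:
    """Optimal global alignment of two protein sequences.

    Deterministic: among co-optimal alignments the first in the aligner's
    fixed enumeration order is returned, so repeated calls agree.
    """
    for name, seq in (("first", a), ("second", b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{name} sequence contains non-amino-acid characters: {sorted(bad)}"
            )
    alignment = _aligner(scoring).align(a, b)[0]
    return ProteinAlignment(
        aligned_query=str(alignment[0]),
        aligned_subject=str(alignment[1]),
        score=float(alignment.score),
    )


def backtranslate_alignment(
    pa: ProteinAlignment,
    cds_a: str,
    cds_b: str,
    code: GeneticCode | int = 11,
) -> CodonAlignment:
    """Thread two coding sequences onto their protein alignment.

    Each amino-acid column becomes the corresponding codon column; a
    protein gap becomes a codon gap. The coding sequences must translate
    exactly to the ungapped alignment rows (terminal stops are trimmed).
    """
    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)
    rows = []
    for label, aligned, cds in (
        ("query", pa.aligned_query, cds_a),
        ("subject", pa.aligned_subject, cds_b),
    ):
        protein = aligned.replace("-", "")
        translated = translate_cds(cds, code)
        if translated != protein:
            pos = next(
                (i for i, (x, y) in enumerate(zip(translated, protein)) if x != y),
                min(len(translated), len(protein)),
            )
            raise ValueError(
                f"{label} CDS does not translate to its alignment row "
                f"(first mismatch at residue {pos})"
            )
        codons = list(iter_codons(trim_terminal_stop(cds.upper(), code)))
        row, k = [], 0
        for aa in aligned:
            if aa == "-":
                row.append(GAP_CODON)
            else:
                row.append(codons[k])
                k += 1
        rows.append(row)
    return CodonAlignment(columns=tuple(zip(rows[0], rows[1])))
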