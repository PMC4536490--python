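"""COG-subcategory significance matrix, conserved-subcategory rule, and
persistent-nonessential (PNE) gene classification.

PNE genes are nonessential genes that show zero nucleotide divergence from
their ortholog (Ka = Ks = 0) yet have homologous proteins in two or more
other organisms — dispensable in the assayed laboratory condition but
apparently maintained by selection across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .io import OrganismDataset
from .ng86 import KaKsResult
from .stats import mann_whitney_u

#: COG letters excluded from the category tests ("general function
#: prediction only" and "function unknown").
DEFAULT_EXCLUDED_LETTERS = frozenset("RS")

DEFAULT_ALPHA = 0.01

DIRECTIONS = ("essential_conserved", "nonessential_conserved", "none")


@dataclass(frozen=True)
class PNERecord:
    gene_id: str
    organism_id: str
    is_pne: bool
    ka: Optional[float]
    ks: Optional[float]
    homolog_organism_count: int


@dataclass(frozen=True)
class PNEReport:
    records: Tuple[PNERecord, ...]
    n_pne: int
    n_nonessential: int
    proportion: Optional[float]


def classify_pne(
    results: Mapping[str, KaKsResult],
    dataset: OrganismDataset,
) -> PNEReport:
    """Classify each paired gene as PNE or not.

    A gene is PNE iff it is nonessential, its pair shows no nucleotide
    variation at all (Ka = Ks = 0, i.e. zero_variation), and homologous
    proteins exist in at least two other organisms. The reported
    proportion divides PNE count by the number of nonessential genes with
    an ortholog pair; it is None when that denominator is zero.
    """
    records: List[PNERecord] = []
    n_ne = 0
    n_pne = 0
    for gene_id in sorted(results):
        res = results[gene_id]
        gene = dataset.genes[gene_id]
        if gene.essential:
            is_pne = False
        else:
            n_ne += 1
            is_pne = res.zero_variation and dataset.homolog_count(gene_id) >= 2
            n_pne += is_pne
        records.append(
            PNERecord(
                gene_id=gene_id,
                organism_id=dataset.organism_id,
                is_pne=is_pne,
                ka=res.Ka,
                ks=res.Ks,
                homolog_organism_count=dataset.homolog_count(gene_id),
            )
        )
    return PNEReport(
        records=tuple(records),
        n_pne=n_pne,
        n_nonessential=n_ne,
        proportion=(n_pne / n_ne) if n_ne else None,
    )


@dataclass(frozen=True)
class COGMatrixCell:
    """Signed significance of the essential-vs-nonessential Ka/Ks contrast
    within one (organism, COG letter) cell."""

    organism_id: str
    category: str
    p_value: Optional[float]
    direction: str
    n_essential: int
    n_nonessential: int


def cog_significance_matrix(
    results: Sequence[Tuple[str, bool, FrozenSet, KaKsResult]],
    organism_id: str,
    alpha: float = DEFAULT_ALPHA,
    excluded_letters: FrozenSet = DEFAULT_EXCLUDED_LETTERS,
) -> List[COGMatrixCell]:
    """One matrix cell per COG letter present in this organism.

    ``results`` holds (gene_id, essential, cog_letters, KaKsResult). Only
    genes with a defined Ka/Ks ratio enter the tests; a gene annotated
    with several letters contributes to every one of them. Cells whose
    essential or nonessential side is empty carry p = None and direction
    "none". Significant cells (two-sided Mann-Whitney p < alpha) are
    signed by the class means.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    by_letter: Dict[str, Tuple[List[float], List[float]]] = {}
    for _, essential, letters, res in results:
        if res.ratio is None:
            continue
        for letter in letters:
            if letter in excluded_letters:
                continue
            ess, ness = by_letter.setdefault(letter, ([], []))
            (ess if essential else ness).append(res.ratio)
    cells = []
    for letter in sorted(by_letter):
        ess, ness = by_letter[letter]
        if not ess or not ness:
            cells.append(
                COGMatrixCell(
                    organism_id=organism_id,
                    category=letter,
                    p_value=None,
                    direction="none",
                    n_essential=len(ess),
                    n_nonessential=len(ness),
                )
            )
            continue
        _, p = mann_whitney_u(ess, ness)
        direction = "none"
        if p < alpha:
            if np.mean(ess) < np.mean(ness):
                direction = "essential_conserved"
            elif np.mean(ess) > np.mean(ness):
                direction = "nonessential_conserved"
        cells.append(
            COGMatrixCell(
                organism_id=organism_id,
                category=letter,
                p_value=p,
                direction=direction,
                n_essential=len(ess),
                n_nonessential=len(ness),
            )
        )
    return cells


def conserved_subcategories(
    matrix: Sequence[COGMatrixCell], n_organisms: int
) -> Set[str]:
    """COG letters in which essential genes are significantly more
    conserved than nonessential genes in more than half of all organisms.

    The denominator is the full organism panel (strict majority), not just
    organisms where the category was testable; cells in the opposite
    direction do not subtract.
    """
    counts: Dict[str, int] = {}
    for cell in matrix:
        if cell.direction == "essential_conserved":
            counts[cell.category] = counts.get(cell.category, 0) + 1
    return {
        letter for letter, c in counts.items() if c > n_organisms / 2
    }
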