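"""Synthetic multi-organism codon-evolution panels.

Generates, for a panel of bacterial-like organisms, pairs of coding
sequences diverged under controlled class-specific selective pressure
(essential genes with low dN/dS, nonessential genes with higher dN/dS),
plus essentiality labels, COG letters, homolog-presence counts, and a
ground-truth table — exactly the file set the analysis pipeline reads, so
every downstream stage is testable without any external database.

The substitution process is a rejection sampler, not a continuous-time
codon model: single-nucleotide changes are proposed uniformly, changes
creating stop codons are rejected, synonymous changes are always accepted
and nonsynonymous changes are accepted with probability omega. Sampling
stops when the number of accepted synonymous substitutions reaches
divergence x (synonymous sites of the starting sequence), so the NG86 Ks
of a generated pair concentrates around ``divergence`` and Ka/Ks around
``omega`` for long sequences.

What this emulates — and what it does not: the panel reproduces the
statistical structure the analysis assumes (class-differential dN/dS,
zero-divergence persistent-nonessential genes with homologs elsewhere,
category labels), but homolog counts are drawn rather than derived from
cross-organism alignment, sequences are gap-free (no indel evolution),
and codon usage is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .codons import GeneticCode, iter_codons, translate_cds
from .io import write_fasta, write_table
from .ng86 import StopPolicy, codon_site_fractions

#: COG letters simulated by default: J and L inherit the class omegas
#: (differential conservation), C and E are null categories where both
#: classes evolve at the same rate.
DEFAULT_COG_OMEGAS: Mapping[str, Optional[Tuple[float, float]]] = {
    "J": None,
    "L": None,
    "C": (0.2, 0.2),
    "E": (0.2, 0.2),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic panel.

    omega values are target dN/dS per class; ``divergence`` is the
    expected number of synonymous substitutions per synonymous site
    between a gene and its homolog; ``pne_fraction`` of nonessential
    genes are emitted with zero divergence and homologs in >= 2 other
    organisms (true persistent-nonessential genes).
    """

    n_organisms: int = 5
    genes_per_organism: int = 200
    codons_per_gene: int = 300
    fraction_essential: float = 0.2
    omega_essential: float = 0.05
    omega_nonessential: float = 0.3
    divergence: float = 0.2
    pne_fraction: float = 0.05
    cog_omegas: Mapping[str, Optional[Tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_COG_OMEGAS)
    )
    genetic_code: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.omega_essential <= 0 or self.omega_nonessential <= 0:
            raise ValueError("omega values must be positive")
        for name in ("fraction_essential", "pne_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")
        if self.fraction_essential == 1 and self.pne_fraction > 0:
            raise ValueError(
                "pne_fraction > 0 requires nonessential genes "
                "(fraction_essential < 1)"
            )


def random_cds(
    codons: int, code: GeneticCode | int = 11, seed: int | np.random.Generator = 0
) -> str:
    """Random coding sequence: uniform sense codons plus a terminal stop."""
    if codons < 1:
        raise ValueError("codons must be >= 1")
    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sense = code.sense_codons
    stops = sorted(code.stops)
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=codons))
    return body + stops[rng.integers(0, len(stops))]


def _synonymous_sites(cds_body: str, code: GeneticCode, policy: StopPolicy) -> float:
    return float(
        sum(codon_site_fractions(c, code, policy)[0] for c in iter_codons(cds_body))
    )


def evolve_codon_sequence(
    cds: str,
    omega: float,
    divergence: float,
    code: GeneticCode | int = 11,
    seed: int | np.random.Generator = 0,
) -> str:
    """Diverge a coding sequence to a target synonymous divergence.

    Proposes uniform single-nucleotide changes; rejects changes creating a
    stop codon; accepts synonymous changes with probability 1 and
    nonsynonymous changes with probability ``omega``. Stops once
    round(divergence x S0) synonymous substitutions have been accepted,
    where S0 is the NG86 synonymous site count of the input. A terminal
    stop codon, if present, is preserved untouched.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if divergence < 0:
        raise ValueError("divergence must be non-negative")
    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    policy = StopPolicy()

    cds = cds.upper()
    terminal = ""
    if len(cds) % 3 == 0 and len(cds) >= 3 and code.is_stop(cds[-3:]):
        terminal = cds[-3:]
        cds = cds[:-3]
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")

    target_syn = round(divergence * _synonymous_sites(cds, code, policy))
    seq = list(cds)
    nucleotides = "ACGT"
    accepted_syn = 0
    while accepted_syn < target_syn:
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        alts = [c for c in nucleotides if c != old]
        alt = alts[int(rng.integers(0, 3))]
        start = pos - pos % 3
        codon = "".join(seq[start : start + 3])
        mutant = codon[: pos - start] + alt + codon[pos - start + 1 :]
        if code.is_stop(mutant):
            continue
        if code.amino_acid(mutant) == code.amino_acid(codon):
            seq[pos] = alt
            accepted_syn += 1
        elif rng.random() < omega:
            seq[pos] = alt
    return "".join(seq) + terminal


@dataclass(frozen=True)
class PanelPaths:
    """File locations of one generated organism."""

    organism_id: str
    cds: Path
    protein: Path
    homolog_cds: Path
    homolog_protein: Path
    essentiality: Path
    cog: Path
    homolog_presence: Path


@dataclass(frozen=True)
class Panel:
    root: Path
    organisms: Tuple[PanelPaths, ...]
    ground_truth: Path
    config: SimulationConfig


def generate_panel(config: SimulationConfig, root) -> Panel:
    """Write a full synthetic panel under ``root`` (one directory per
    organism plus a panel-wide ground-truth table).

    Byte-identical for identical configs: all randomness flows from
    ``config.seed`` through per-organism child generators.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    code = GeneticCode.from_table_id(config.genetic_code)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_organisms)
    letters = sorted(config.cog_omegas)
    truth_rows: List[dict] = []
    organisms = []
    n_ess = round(config.genes_per_organism * config.fraction_essential)
    for k in range(config.n_organisms):
        org = f"org{k + 1}"
        rng = np.random.default_rng(children[k])
        org_dir = root / org
        org_dir.mkdir(exist_ok=True)
        cds_records: Dict[str, str] = {}
        prot_records: Dict[str, str] = {}
        hom_cds: Dict[str, str] = {}
        hom_prot: Dict[str, str] = {}
        ess_rows, cog_rows, hom_rows = [], [], []

        n_genes = config.genes_per_organism
        gene_ids = [f"{org}_g{i + 1:04d}" for i in range(n_genes)]
        essential_flags = [i < n_ess for i in range(n_genes)]
        ne_ids = [g for g, e in zip(gene_ids, essential_flags) if not e]
        n_pne = round(len(ne_ids) * config.pne_fraction)
        pne_ids = set(ne_ids[:n_pne])

        for gene_id, essential in zip(gene_ids, essential_flags):
            letter = letters[int(rng.integers(0, len(letters)))] if letters else None
            override = config.cog_omegas.get(letter) if letter else None
            if override is not None:
                omega = override[0] if essential else override[1]
            else:
                omega = (
                    config.omega_essential
                    if essential
                    else config.omega_nonessential
                )
            cds = random_cds(config.codons_per_gene, code, rng)
            is_pne = gene_id in pne_ids
            divergence = 0.0 if is_pne else config.divergence
            homolog = evolve_codon_sequence(cds, omega, divergence, code, rng)
            if is_pne:
                homolog_count = int(rng.integers(2, config.n_organisms + 1))
            else:
                homolog_count = int(rng.integers(0, config.n_organisms + 1))

            cds_records[gene_id] = cds
            prot_records[gene_id] = translate_cds(cds, code)
            hom_id = gene_id + "_h"
            hom_cds[hom_id] = homolog
            hom_prot[hom_id] = translate_cds(homolog, code)
            ess_rows.append(
                {"gene_id": gene_id, "label": "E" if essential else "NE"}
            )
            if letter is not None:
                cog_rows.append({"gene_id": gene_id, "letters": letter})
            hom_rows.append({"gene_id": gene_id, "n_organisms": homolog_count})
            truth_rows.append(
                {
                    "organism_id": org,
                    "gene_id": gene_id,
                    "essential": essential,
                    "omega": omega,
                    "cog_letters": letter or "",
                    "is_pne": is_pne,
                    "homolog_count": homolog_count,
                }
            )

        paths = PanelPaths(
            organism_id=org,
            cds=org_dir / "cds.fasta",
            protein=org_dir / "protein.fasta",
            homolog_cds=org_dir / "homolog_cds.fasta",
            homolog_protein=org_dir / "homolog_protein.fasta",
            essentiality=org_dir / "essentiality.tsv",
            cog=org_dir / "cog.tsv",
            homolog_presence=org_dir / "homolog_presence.tsv",
        )
        write_fasta(cds_records, paths.cds)
        write_fasta(prot_records, paths.protein)
        write_fasta(hom_cds, paths.homolog_cds)
        write_fasta(hom_prot, paths.homolog_protein)
        write_table(ess_rows, paths.essentiality, ["gene_id", "label"])
        write_table(cog_rows, paths.cog, ["gene_id", "letters"])
        write_table(hom_rows, paths.homolog_presence, ["gene_id", "n_organisms"])
        organisms.append(paths)

    truth_path = root / "ground_truth.tsv"
    write_table(
        truth_rows,
        truth_path,
        [
            "organism_id",
            "gene_id",
            "essential",
            "omega",
            "cog_letters",
            "is_pne",
            "homolog_count",
        ],
    )
    return Panel(
        root=root,
        organisms=tuple(organisms),
        ground_truth=truth_path,
        config=config,
    )
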