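"""End-to-end orchestration: pairing -> codon alignment -> NG86 -> statistics.

For each organism the pipeline pairs query proteins with a homologous
strain (external BLAST tabular hits, or the built-in aligner), estimates
Ka/Ks for every ortholog pair, and then compares essential against
nonessential genes: class means with Mann-Whitney tests, the half-sampling
bootstrap, the COG-subcategory significance matrix, the conserved-
subcategory rule, and persistent-nonessential gene calls. A cross-organism
paired t-test closes the analysis.

All results are written as header-bearing TSV tables plus a JSON manifest
(config echo, library versions, per-stage counts) sufficient to reproduce
the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .align import align_protein_pair, backtranslate_alignment
from .codons import GeneticCode, InternalStopError, translate_cds
from .cog import (
    DEFAULT_ALPHA,
    classify_pne,
    cog_significance_matrix,
    conserved_subcategories,
)
from .io import (
    OrganismDataset,
    read_annotations,
    read_fasta,
    read_hit_table,
    write_table,
)
from .ng86 import KaKsResult, StopPolicy, compute_kaks
from .ortholog import (
    DEFAULT_EVALUE_MAX,
    built_in_pairing,
    pair_qc_report,
    select_best_hits,
)
from .stats import METRICS, bootstrap_means, cross_organism_ttest, summarize_organism
from .simulate import Panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for actionable messages."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class OrganismInput:
    """Input files for one organism (COG and hit tables are optional)."""

    organism_id: str
    cds: Path
    homolog_cds: Path
    essentiality: Path
    cog: Optional[Path] = None
    homolog_presence: Optional[Path] = None
    hits: Optional[Path] = None
    genetic_code: int = 11


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; the defaults are the study thresholds
    (ortholog e-value < 1e-5, COG significance alpha = 0.01, 1000
    bootstrap replicates)."""

    organisms: Tuple[OrganismInput, ...]
    out_dir: Path
    evalue_max: float = DEFAULT_EVALUE_MAX
    alpha: float = DEFAULT_ALPHA
    bootstrap_reps: int = 1000
    seed: int = 0
    stop_policy: StopPolicy = StopPolicy()

    @classmethod
    def from_panel(cls, panel: Panel, out_dir, **overrides) -> "PipelineConfig":
        organisms = tuple(
            OrganismInput(
                organism_id=p.organism_id,
                cds=p.cds,
                homolog_cds=p.homolog_cds,
                essentiality=p.essentiality,
                cog=p.cog,
                homolog_presence=p.homolog_presence,
                genetic_code=panel.config.genetic_code,
            )
            for p in panel.organisms
        )
        return cls(organisms=organisms, out_dir=Path(out_dir), **overrides)


@dataclass
class OrganismResult:
    dataset: OrganismDataset
    pairs: Dict[str, object]
    qc: object
    kaks: Dict[str, KaKsResult]
    subject_of: Dict[str, str]
    summary: object
    pne: object
    cog_cells: List[object]


@dataclass
class PipelineResult:
    out_dir: Path
    organisms: Dict[str, OrganismResult]
    ttests: Dict[str, Tuple[float, float]]
    conserved_letters: set
    n_cog_organisms: int


def _bootstrap_seed(base_seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, *key]).generate_state(1)[0] % (2**31)
    )


def analyse_organism(
    inp: OrganismInput,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    alpha: float = DEFAULT_ALPHA,
    stop_policy: StopPolicy = StopPolicy(),
) -> OrganismResult:
    """Run pairing, Ka/Ks estimation and the per-organism statistics."""
    code = GeneticCode.from_table_id(inp.genetic_code)

    try:
        cds_by_id = read_fasta(inp.cds)
        dataset = read_annotations(
            inp.organism_id,
            cds_by_id,
            inp.essentiality,
            cog_path=inp.cog,
            homolog_path=inp.homolog_presence,
            code=code,
        )
        subject_cds = read_fasta(inp.homolog_cds)
    except (OSError, ValueError) as exc:
        raise PipelineError("read_inputs", f"{inp.organism_id}: {exc}") from exc

    try:
        subject_proteins = {}
        for sid, scds in subject_cds.items():
            try:
                subject_proteins[sid] = translate_cds(scds, code)
            except InternalStopError as exc:
                logger.warning(
                    "organism %s: skipping subject %s (%s)",
                    inp.organism_id,
                    sid,
                    exc,
                )
        if inp.hits is not None:
            hits = read_hit_table(inp.hits)
        else:
            query_proteins = {g.gene_id: g.protein for g in dataset.genes.values()}
            hits = built_in_pairing(query_proteins, subject_proteins)
        query_lengths = {g.gene_id: len(g.protein) for g in dataset.genes.values()}
        pairs = select_best_hits(hits, evalue_max, query_lengths=query_lengths)
        pairs = {q: p for q, p in pairs.items() if q in dataset.genes}
        qc = pair_qc_report(pairs)
    except (OSError, ValueError) as exc:
        raise PipelineError("pairing", f"{inp.organism_id}: {exc}") from exc

    kaks: Dict[str, KaKsResult] = {}
    subject_of: Dict[str, str] = {}
    for query in sorted(pairs):
        pair = pairs[query]
        sid = pair.subject_gene
        if sid not in subject_cds:
            raise PipelineError(
                "kaks",
                f"{inp.organism_id}: subject {sid!r} for query {query!r} "
                "missing from homolog CDS FASTA",
            )
        try:
            pa = align_protein_pair(
                dataset.genes[query].protein, subject_proteins[sid]
            )
            ca = backtranslate_alignment(
                pa, dataset.genes[query].cds, subject_cds[sid], code
            )
            kaks[query] = compute_kaks(ca, code, stop_policy)
            subject_of[query] = sid
        except ValueError as exc:
            raise PipelineError(
                "kaks", f"{inp.organism_id}: pair {query}/{sid}: {exc}"
            ) from exc

    try:
        triples = [
            (q, dataset.genes[q].essential, res) for q, res in kaks.items()
        ]
        summary = summarize_organism(inp.organism_id, triples)
        pne = classify_pne(kaks, dataset)
        cog_cells: List[object] = []
        if inp.cog is not None:
            quads = [
                (q, dataset.genes[q].essential, dataset.genes[q].cog_letters, res)
                for q, res in kaks.items()
            ]
            cog_cells = cog_significance_matrix(
                quads, inp.organism_id, alpha=alpha
            )
        else:
            logger.warning(
                "organism %s: no COG table, skipped in the COG matrix",
                inp.organism_id,
            )
    except ValueError as exc:
        raise PipelineError("statistics", f"{inp.organism_id}: {exc}") from exc

    return OrganismResult(
        dataset=dataset,
        pairs=pairs,
        qc=qc,
        kaks=kaks,
        subject_of=subject_of,
        summary=summary,
        pne=pne,
        cog_cells=cog_cells,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all result tables.

    Results are computed in memory first and written in a single pass, so
    a failing stage leaves no partial output tree; a failing write removes
    whatever had been written.
    """
    organisms: Dict[str, OrganismResult] = {}
    for inp in config.organisms:
        organisms[inp.organism_id] = analyse_organism(
            inp,
            evalue_max=config.evalue_max,
            alpha=config.alpha,
            stop_policy=config.stop_policy,
        )

    summaries = [r.summary for r in organisms.values()]
    ttests: Dict[str, Tuple[float, float]] = {}
    try:
        for metric in METRICS:
            ttests[metric] = cross_organism_ttest(summaries, metric)
    except ValueError as exc:
        logger.warning("cross-organism t-test skipped: %s", exc)

    all_cells = [c for r in organisms.values() for c in r.cog_cells]
    cog_organisms = [
        inp.organism_id for inp in config.organisms if inp.cog is not None
    ]
    conserved = conserved_subcategories(all_cells, len(cog_organisms))

    result = PipelineResult(
        out_dir=Path(config.out_dir),
        organisms=organisms,
        ttests=ttests,
        conserved_letters=conserved,
        n_cog_organisms=len(cog_organisms),
    )
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        _write_outputs(config, result)
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError("write_outputs", str(exc)) from exc
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)

    pair_rows, qc_rows, kaks_rows, summary_rows = [], [], [], []
    boot_rows, pne_rows, cog_rows = [], [], []
    counts = {}
    for org_idx, inp in enumerate(config.organisms):
        r = result.organisms[inp.organism_id]
        counts[inp.organism_id] = {
            "genes_labelled": len(r.dataset.genes),
            "pairs_formed": len(r.pairs),
            "pairs_with_kaks": len(r.kaks),
            "ratio_defined": sum(
                1 for res in r.kaks.values() if res.ratio is not None
            ),
            "zero_variation": sum(
                1 for res in r.kaks.values() if res.zero_variation
            ),
        }
        for q in sorted(r.pairs):
            p = r.pairs[q]
            pair_rows.append(
                {
                    "organism_id": inp.organism_id,
                    "query": p.query_gene,
                    "subject": p.subject_gene,
                    "bit_score": p.bit_score,
                    "evalue": p.evalue,
                    "percent_identity": p.percent_identity,
                    "aligned_fraction": p.aligned_fraction,
                    "qc_pass": r.qc.pass_flags.get(q),
                }
            )
        qc_rows.append(
            {
                "organism_id": inp.organism_id,
                "n_pairs": r.qc.n_pairs,
                "n_pass": r.qc.n_pass,
                "fraction_pass": r.qc.fraction_pass,
            }
        )
        for q in sorted(r.kaks):
            res = r.kaks[q]
            kaks_rows.append(
                {
                    "organism_id": inp.organism_id,
                    "query": q,
                    "subject": r.subject_of[q],
                    "S": res.S,
                    "N": res.N,
                    "Sd": res.Sd,
                    "Nd": res.Nd,
                    "pS": res.pS,
                    "pN": res.pN,
                    "Ka": res.Ka,
                    "Ks": res.Ks,
                    "KaKs": res.ratio,
                    "valid": res.valid_ka and res.valid_ks,
                    "zero_variation": res.zero_variation,
                }
            )
        for m_idx, metric in enumerate(METRICS):
            ms = r.summary.metrics[metric]
            summary_rows.append(
                {
                    "organism_id": inp.organism_id,
                    "metric": metric,
                    "mean_essential": ms.mean_essential,
                    "mean_nonessential": ms.mean_nonessential,
                    "p_value": ms.p_value,
                    "n_essential": ms.n_essential,
                    "n_nonessential": ms.n_nonessential,
                }
            )
            for c_idx, (gene_class, essential) in enumerate(
                (("essential", True), ("nonessential", False))
            ):
                values = [
                    v
                    for q, res in r.kaks.items()
                    if r.dataset.genes[q].essential == essential
                    for v in [_metric_value(res, metric)]
                    if v is not None
                ]
                if not values:
                    continue
                seed = _bootstrap_seed(config.seed, org_idx, m_idx, c_idx)
                boot = bootstrap_means(
                    values,
                    reps=config.bootstrap_reps,
                    seed=seed,
                    organism_id=inp.organism_id,
                    metric=metric,
                    gene_class=gene_class,
                )
                for rep, mean in enumerate(boot.replicate_means):
                    boot_rows.append(
                        {
                            "organism_id": inp.organism_id,
                            "metric": metric,
                            "gene_class": gene_class,
                            "replicate": rep,
                            "mean": float(mean),
                        }
                    )
        for rec in r.pne.records:
            pne_rows.append(
                {
                    "organism_id": rec.organism_id,
                    "gene_id": rec.gene_id,
                    "is_pne": rec.is_pne,
                    "Ka": rec.ka,
                    "Ks": rec.ks,
                    "homolog_organism_count": rec.homolog_organism_count,
                }
            )
        for cell in r.cog_cells:
            cog_rows.append(
                {
                    "organism_id": cell.organism_id,
                    "category": cell.category,
                    "n_essential": cell.n_essential,
                    "n_nonessential": cell.n_nonessential,
                    "p_value": cell.p_value,
                    "direction": cell.direction,
                }
            )

    write_table(
        pair_rows,
        out / "pairs.tsv",
        [
            "organism_id",
            "query",
            "subject",
            "bit_score",
            "evalue",
            "percent_identity",
            "aligned_fraction",
            "qc_pass",
        ],
    )
    write_table(
        qc_rows,
        out / "qc.tsv",
        ["organism_id", "n_pairs", "n_pass", "fraction_pass"],
    )
    write_table(
        kaks_rows,
        out / "kaks.tsv",
        [
            "organism_id",
            "query",
            "subject",
            "S",
            "N",
            "Sd",
            "Nd",
            "pS",
            "pN",
            "Ka",
            "Ks",
            "KaKs",
            "valid",
            "zero_variation",
        ],
    )
    write_table(
        summary_rows,
        out / "summary.tsv",
        [
            "organism_id",
            "metric",
            "mean_essential",
            "mean_nonessential",
            "p_value",
            "n_essential",
            "n_nonessential",
        ],
    )
    write_table(
        boot_rows,
        out / "bootstrap.tsv",
        ["organism_id", "metric", "gene_class", "replicate", "mean"],
    )
    write_table(
        cog_rows,
        out / "cog_matrix.tsv",
        [
            "organism_id",
            "category",
            "n_essential",
            "n_nonessential",
            "p_value",
            "direction",
        ],
    )
    write_table(
        pne_rows,
        out / "pne.tsv",
        [
            "organism_id",
            "gene_id",
            "is_pne",
            "Ka",
            "Ks",
            "homolog_organism_count",
        ],
    )
    ttest_rows = [
        {"metric": m, "t": t, "p_value": p}
        for m, (t, p) in result.ttests.items()
    ]
    write_table(ttest_rows, out / "ttest.tsv", ["metric", "t", "p_value"])
    with open(out / "conserved_letters.txt", "w") as fh:
        for letter in sorted(result.conserved_letters):
            fh.write(letter + "\n")

    manifest = {
        "package": "essconserv",
        "version": __version__,
        "seed": config.seed,
        "evalue_max": config.evalue_max,
        "alpha": config.alpha,
        "bootstrap_reps": config.bootstrap_reps,
        "stop_policy": dataclasses.asdict(config.stop_policy),
        "organisms": [
            {
                "organism_id": inp.organism_id,
                "genetic_code": inp.genetic_code,
                "paths": {
                    k: str(v) if v is not None else None
                    for k, v in {
                        "cds": inp.cds,
                        "homolog_cds": inp.homolog_cds,
                        "essentiality": inp.essentiality,
                        "cog": inp.cog,
                        "homolog_presence": inp.homolog_presence,
                        "hits": inp.hits,
                    }.items()
                },
            }
            for inp in config.organisms
        ],
        "counts": counts,
        "n_cog_organisms": result.n_cog_organisms,
        "versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _metric_value(res: KaKsResult, metric: str):
    if metric == "Ka":
        return res.Ka if res.valid_ka else None
    if metric == "Ks":
        return res.Ks if res.valid_ks else None
    return res.ratio


def _library_versions() -> Dict[str, str]:
    import Bio
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "biopython": Bio.__version__,
    }


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    organisms = tuple(
        OrganismInput(
            organism_id=o["organism_id"],
            cds=base / o["cds"],
            homolog_cds=base / o["homolog_cds"],
            essentiality=base / o["essentiality"],
            cog=(base / o["cog"]) if o.get("cog") else None,
            homolog_presence=(base / o["homolog_presence"])
            if o.get("homolog_presence")
            else None,
            hits=(base / o["hits"]) if o.get("hits") else None,
            genetic_code=int(o.get("genetic_code", 11)),
        )
        for o in raw["organisms"]
    )
    sp = raw.get("stop_policy", {})
    return PipelineConfig(
        organisms=organisms,
        out_dir=Path(raw.get("out_dir", "results")),
        evalue_max=float(raw.get("evalue_max", DEFAULT_EVALUE_MAX)),
        alpha=float(raw.get("alpha", DEFAULT_ALPHA)),
        bootstrap_reps=int(raw.get("bootstrap_reps", 1000)),
        seed=int(raw.get("seed", 0)),
        stop_policy=StopPolicy(
            sites=sp.get("sites", "nonsynonymous"),
            paths=sp.get("paths", "exclude"),
        ),
    )
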