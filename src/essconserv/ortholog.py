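"""Best-hit ortholog pairing between an organism and a homologous strain.

Orthology is approximated one-directionally: for each query protein, the
subject hit with the highest bit score among hits below the e-value
threshold is taken as the ortholog. Real analyses supply BLAST tabular
files; :func:`built_in_pairing` provides an offline substitute based on
exhaustive global alignment with a word-match prescreen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .align import AlignmentScoring, align_protein_pair
from .io import HitRecord

# Karlin-Altschul-style constants for the synthetic bit-score/e-value
# transform of built_in_pairing (ungapped BLOSUM62 values). The resulting
# e-values are a synthetic stand-in for BLAST statistics: monotone in the
# alignment score and length-normalized, not database-calibrated.
_KA_LAMBDA = 0.267
_KA_K = 0.041
_LN2 = math.log(2.0)

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class OrthologPair:
    """Best-hit ortholog assignment for one query gene."""

    query_gene: str
    subject_gene: str
    bit_score: float
    evalue: float
    percent_identity: float
    aligned_fraction: float


def select_best_hits(
    hits: Iterable[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    query_lengths: Optional[Mapping[str, int]] = None,
) -> Dict[str, OrthologPair]:
    """Keep, per query, the surviving hit with the highest bit score.

    Hits with evalue >= ``evalue_max`` are discarded first. Ties on bit
    score are broken by lower e-value, then lexicographically smallest
    subject id, making the result independent of input order. Queries with
    no surviving hit are absent from the mapping.

    ``query_lengths`` (optional) converts the aligned query span into a
    query-relative aligned fraction; without it the fraction is reported
    as NaN.
    """
    best: Dict[str, HitRecord] = {}
    for hit in hits:
        if hit.evalue >= evalue_max:
            continue
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
            best[hit.query_id] = hit
    pairs = {}
    for query, hit in best.items():
        if query_lengths and query in query_lengths:
            span = hit.query_end - hit.query_start + 1
            aligned_fraction = span / query_lengths[query]
        else:
            aligned_fraction = math.nan
        pairs[query] = OrthologPair(
            query_gene=hit.query_id,
            subject_gene=hit.subject_id,
            bit_score=hit.bit_score,
            evalue=hit.evalue,
            percent_identity=hit.percent_identity,
            aligned_fraction=aligned_fraction,
        )
    return pairs


def _hit_rank(hit: HitRecord):
    # sort key: maximal bit score, then minimal evalue, then subject id
    return (-hit.bit_score, hit.evalue, hit.subject_id)


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def built_in_pairing(
    query_proteins: Mapping[str, str],
    subject_proteins: Mapping[str, str],
    scoring: AlignmentScoring = AlignmentScoring(),
    score_floor: float = 50.0,
    word_size: int = 4,
    min_shared_words: int = 10,
) -> List[HitRecord]:
    """All-vs-all protein pairing by optimal global alignment.

    An offline substitute for a database search: candidate pairs sharing at
    least ``min_shared_words`` exact ``word_size``-mers (the analogue of
    word seeding) are globally aligned, and pairs whose raw alignment score
    reaches ``score_floor`` are emitted as 12-column hit records. Bit score
    and e-value come from a simple length-normalized transform of the raw
    score; they order hits exactly as the raw score does.

    The default word screen keeps pairs down to roughly 50% protein
    identity for ~300-residue proteins; for very distant homologs lower
    ``min_shared_words`` (at the cost of aligning more random pairs) or
    supply an external hit table instead.
    """
    if not query_proteins or not subject_proteins:
        raise ValueError("query and subject protein sets must be non-empty")
    for name, seqs in (("query", query_proteins), ("subject", subject_proteins)):
        for gid, seq in seqs.items():
            if not seq:
                raise ValueError(f"empty {name} sequence {gid!r}")

    subject_kmers = {
        sid: _kmer_set(seq, word_size) for sid, seq in subject_proteins.items()
    }
    hits: List[HitRecord] = []
    for qid, qseq in query_proteins.items():
        qwords = _kmer_set(qseq, word_size)
        for sid, sseq in subject_proteins.items():
            if len(qwords & subject_kmers[sid]) < min_shared_words:
                continue
            pa = align_protein_pair(qseq, sseq, scoring)
            if pa.score < score_floor:
                continue
            hits.append(_alignment_to_hit(qid, sid, qseq, sseq, pa))
    return hits


def _alignment_to_hit(qid, sid, qseq, sseq, pa) -> HitRecord:
    bits = (_KA_LAMBDA * pa.score - math.log(_KA_K)) / _LN2
    evalue = len(qseq) * len(sseq) * math.exp(-_LN2 * bits)
    aligned_cols = [
        (a, b)
        for a, b in zip(pa.aligned_query, pa.aligned_subject)
        if a != "-" and b != "-"
    ]
    matches = sum(a == b for a, b in aligned_cols)
    mismatches = len(aligned_cols) - matches
    gap_opens = _count_gap_opens(pa.aligned_query) + _count_gap_opens(
        pa.aligned_subject
    )
    identity = 100.0 * matches / len(aligned_cols) if aligned_cols else 0.0
    return HitRecord(
        query_id=qid,
        subject_id=sid,
        percent_identity=identity,
        alignment_length=pa.columns,
        mismatches=mismatches,
        gap_opens=gap_opens,
        query_start=1,
        query_end=len(qseq),
        subject_start=1,
        subject_end=len(sseq),
        evalue=evalue,
        bit_score=bits,
    )


def _count_gap_opens(row: str) -> int:
    opens = 0
    in_gap = False
    for c in row:
        if c == "-":
            if not in_gap:
                opens += 1
            in_gap = True
        else:
            in_gap = False
    return opens


@dataclass(frozen=True)
class PairQC:
    """Per-pair quality flags plus the fraction passing the orthology
    plausibility screen (>30% identity and >=50% of query residues aligned)."""

    n_pairs: int
    n_pass: int
    fraction_pass: Optional[float]
    pass_flags: Mapping[str, bool]


def pair_qc_report(
    pairs: Mapping[str, OrthologPair],
    identity_min: float = 30.0,
    aligned_fraction_min: float = 0.5,
) -> PairQC:
    """Fraction of pairs with identity strictly above ``identity_min`` percent
    and query coverage at least ``aligned_fraction_min``.

    The identity cut is strict (a pair at exactly 30% fails); the coverage
    cut is inclusive. With no pairs the fraction is undefined (None).
    """
    flags = {
        q: (p.percent_identity > identity_min)
        and (p.aligned_fraction >= aligned_fraction_min)
        for q, p in pairs.items()
    }
    n = len(flags)
    n_pass = sum(flags.values())
    return PairQC(
        n_pairs=n,
        n_pass=n_pass,
        fraction_pass=(n_pass / n) if n else None,
        pass_flags=flags,
    )
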