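"""Independent brute-force oracles used to cross-check the package.

These implementations deliberately share no code with the package: codon
translation comes straight from Biopython's codon tables, site and pathway
counting are written as direct enumerations, the Mann-Whitney null
distribution is enumerated from rank sums, and the paired t-test is the
textbook one-sample formula on the differences.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, permutations

from Bio.Data import CodonTable
from scipy.stats import rankdata
from scipy.stats import t as t_dist

NT = "ACGT"


def _table(table_id: int):
    return CodonTable.unambiguous_dna_by_id[table_id]


def aa_of(codon: str, table_id: int = 11) -> str:
    t = _table(table_id)
    if codon in t.stop_codons:
        return "*"
    return t.forward_table[codon]


def is_stop(codon: str, table_id: int = 11) -> bool:
    return codon in _table(table_id).stop_codons


def site_fractions(codon: str, table_id: int = 11):
    """(s, n) by enumerating all nine single-nucleotide neighbours."""
    s = Fraction(0)
    n = Fraction(0)
    for pos in range(3):
        for nt in NT:
            if nt == codon[pos]:
                continue
            neighbour = codon[:pos] + nt + codon[pos + 1 :]
            if is_stop(neighbour, table_id):
                n += Fraction(1, 3)
            elif aa_of(neighbour, table_id) == aa_of(codon, table_id):
                s += Fraction(1, 3)
            else:
                n += Fraction(1, 3)
    return s, n


def pathway_counts(codon_a: str, codon_b: str, table_id: int = 11):
    """(sd, nd) by enumerating every mutational ordering explicitly."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return Fraction(0), Fraction(0)
    paths = []
    for order in permutations(diffs):
        codons = [codon_a]
        for pos in order:
            prev = codons[-1]
            codons.append(prev[:pos] + codon_b[pos] + prev[pos + 1 :])
        paths.append(codons)
    valid = [p for p in paths if not any(is_stop(c, table_id) for c in p[1:-1])]
    chosen = valid if valid else paths
    sd = Fraction(0)
    nd = Fraction(0)
    for codons in chosen:
        for prev, nxt in zip(codons, codons[1:]):
            if (
                not is_stop(prev, table_id)
                and not is_stop(nxt, table_id)
                and aa_of(prev, table_id) == aa_of(nxt, table_id)
            ):
                sd += Fraction(1, len(chosen))
            else:
                nd += Fraction(1, len(chosen))
    return sd, nd


def ng86(codons_a, codons_b, table_id: int = 11):
    """Whole-pipeline NG86 oracle on two gap-free codon lists.

    Returns a dict with S, N, Sd, Nd, pS, pN, Ka, Ks, ratio (None where
    undefined). Columns containing stops or non-ACGT characters are
    skipped.
    """
    S_a = N_a = S_b = N_b = Fraction(0)
    Sd = Nd = Fraction(0)
    counted = 0
    for ca, cb in zip(codons_a, codons_b):
        ok = all(c in NT for c in ca + cb) and len(ca) == len(cb) == 3
        if not ok or is_stop(ca, table_id) or is_stop(cb, table_id):
            continue
        counted += 1
        sa, na = site_fractions(ca, table_id)
        sb, nb = site_fractions(cb, table_id)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = pathway_counts(ca, cb, table_id)
        Sd += sd
        Nd += nd
    if counted == 0:
        raise ValueError("nothing to count")
    S = (S_a + S_b) / 2
    N = (N_a + N_b) / 2
    pS = Sd / S if S else None
    pN = Nd / N if N else None

    def jc(p):
        if p is None or p >= Fraction(3, 4):
            return None
        return -0.75 * math.log(1 - 4 * float(p) / 3)

    Ks = jc(pS)
    Ka = jc(pN)
    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return {
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "pS": pS,
        "pN": pN,
        "Ka": Ka,
        "Ks": Ks,
        "ratio": ratio,
        "n_codons": counted,
    }


def mwu_exact(x, y):
    """Two-sided exact Mann-Whitney p by enumerating group assignments,
    computing U from midranks (a different route than pairwise wins)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)
    ranks = rankdata(pooled)
    center = n1 * (n - n1) / 2

    def u_of(indices):
        r1 = sum(ranks[i] for i in indices)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    # observed sample occupies the first n1 pooled slots by construction
    total = 0
    extreme = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - center) >= abs(u_obs - center):
            extreme += 1
    return u_obs, extreme / total


def paired_t(ess, ness):
    """Closed-form one-sample t on the pairwise differences."""
    d = [e - n for e, n in zip(ess, ness)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * t_dist.sf(abs(t), n - 1)
    return t, p
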