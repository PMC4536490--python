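"""Nei–Gojobori (1986) Ka/Ks estimation on codon alignments.

The estimator proceeds in three counting steps followed by a multiple-hit
correction:

1. *Sites.* Each codon contributes fractional synonymous (s) and
   nonsynonymous (n) site counts: at each of its three positions the three
   possible single-nucleotide changes are classified, and s is the mean
   fraction of synonymous changes; s + n = 3 always. Changes that create a
   stop codon count as nonsynonymous under the default policy.
2. *Differences.* For a codon pair differing at k positions, the k!
   orderings in which the changes could have occurred are enumerated; each
   single-nucleotide step is synonymous or nonsynonymous, and (sd, nd) is
   the unweighted mean over orderings. Orderings passing through a stop
   codon are excluded (falling back to all orderings if none survive).
   sd + nd = k exactly.
3. *Proportions.* S and N are averaged over the two sequences, pS = Sd/S,
   pN = Nd/N.
4. *Correction.* Jukes–Cantor, d = -(3/4) ln(1 - 4p/3), converts observed
   proportions to substitution rates Ks and Ka. p >= 3/4 is outside the
   model and marks the estimate invalid.

All site and difference arithmetic is carried out in exact rationals;
floating point enters only at the Jukes–Cantor step, so counting results
are bit-stable across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import permutations
from typing import Optional, Tuple

from .align import CodonAlignment
from .codons import GAP_CODON, NUCLEOTIDES, GeneticCode

#: how single-nucleotide changes that create a stop codon enter site counts
STOP_SITE_POLICIES = ("nonsynonymous", "excluded")
#: how mutational orderings whose intermediates are stop codons are treated
STOP_PATH_POLICIES = ("exclude", "include")


class UncountableCodonError(ValueError):
    """Codon contains a gap or ambiguous base and cannot be counted."""


@dataclass(frozen=True)
class StopPolicy:
    """Treatment of stop codons during NG86 counting (both knobs logged in
    the run manifest because published pipelines rarely state them)."""

    sites: str = "nonsynonymous"
    paths: str = "exclude"

    def __post_init__(self):
        if self.sites not in STOP_SITE_POLICIES:
            raise ValueError(f"unknown stop-site policy {self.sites!r}")
        if self.paths not in STOP_PATH_POLICIES:
            raise ValueError(f"unknown stop-path policy {self.paths!r}")


@dataclass(frozen=True)
class KaKsResult:
    """NG86 counts, proportions and corrected rates for one gene pair.

    ``ratio`` is ``None`` unless both rates are valid and Ks > 0;
    ``zero_variation`` flags pairs with no differences at all (Ka = Ks = 0),
    which matter downstream for persistent-nonessential gene calls.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    Ka: Optional[float]
    Ks: Optional[float]
    ratio: Optional[float]
    valid_ka: bool
    valid_ks: bool
    zero_variation: bool
    n_codons: int


def _check_sense(codon: str, code: GeneticCode) -> None:
    if codon == GAP_CODON or any(c not in NUCLEOTIDES for c in codon):
        raise UncountableCodonError(f"codon {codon!r} cannot be counted")
    if code.is_stop(codon):
        raise UncountableCodonError(f"stop codon {codon!r} cannot be counted")


@lru_cache(maxsize=None)
def codon_site_fractions(
    codon: str,
    code: GeneticCode,
    stop_policy: StopPolicy = StopPolicy(),
) -> Tuple[Fraction, Fraction]:
    """Fractional synonymous/nonsynonymous site counts (s, n) of one codon.

    At each position the three alternative nucleotides are classified
    against the genetic code; s sums the per-position synonymous fractions.
    Under the default policy s + n = 3 exactly.
    """
    _check_sense(codon, code)
    aa = code.amino_acid(codon)
    s = Fraction(0)
    n = Fraction(0)
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if code.is_stop(mutant):
                if stop_policy.sites == "nonsynonymous":
                    n += Fraction(1, 3)
                # "excluded": contributes to neither class
            elif code.amino_acid(mutant) == aa:
                s += Fraction(1, 3)
            else:
                n += Fraction(1, 3)
    return s, n


@lru_cache(maxsize=None)
def pathway_differences(
    codon_a: str,
    codon_b: str,
    code: GeneticCode,
    stop_policy: StopPolicy = StopPolicy(),
) -> Tuple[Fraction, Fraction]:
    """Synonymous/nonsynonymous difference counts (sd, nd) for a codon pair.

    Averages the step classifications over all orderings of the differing
    positions. Orderings whose intermediate codons are stops are dropped
    under the default policy; if every ordering is dropped the average
    falls back to all orderings (steps touching a stop codon are then
    nonsynonymous). sd + nd equals the number of differing positions.
    """
    _check_sense(codon_a, code)
    _check_sense(codon_b, code)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return Fraction(0), Fraction(0)

    def walk(order):
        """Classify each step along one mutational ordering."""
        current = codon_a
        steps = []  # (is_synonymous, touches_stop)
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            stop_involved = code.is_stop(current) or code.is_stop(nxt)
            if stop_involved:
                syn = False
            else:
                syn = code.amino_acid(current) == code.amino_acid(nxt)
            steps.append((syn, stop_involved))
            current = nxt
        # endpoints are sense codons, so any stop-flagged step means the
        # ordering visits a stop intermediate
        return steps, any(stop for _, stop in steps)

    orderings = [walk(order) for order in permutations(diff_positions)]
    if stop_policy.paths == "exclude":
        usable = [steps for steps, bad in orderings if not bad]
        if not usable:
            usable = [steps for steps, _ in orderings]
    else:
        usable = [steps for steps, _ in orderings]
    sd = Fraction(0)
    nd = Fraction(0)
    m = len(usable)
    for steps in usable:
        for syn, _ in steps:
            if syn:
                sd += Fraction(1, m)
            else:
                nd += Fraction(1, m)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3).

    Corrects an observed proportion of differences for multiple hits;
    undefined (raises ValueError) for p >= 3/4.
    """
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p} outside Jukes-Cantor domain [0, 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


#: scale for integer accumulation of site/difference counts: site
#: fractions are thirds and pathway means have denominators dividing
#: lcm(1..6) = 60, so 60x-scaled counts are exact integers.
_SCALE = 60


@lru_cache(maxsize=None)
def _scaled_site_table(code: GeneticCode, stop_policy: StopPolicy):
    table = {}
    for codon in code.sense_codons:
        s, n = codon_site_fractions(codon, code, stop_policy)
        table[codon] = (int(s * _SCALE), int(n * _SCALE))
    return table


@lru_cache(maxsize=None)
def _scaled_path_table(code: GeneticCode, stop_policy: StopPolicy):
    table = {}
    for a in code.sense_codons:
        for b in code.sense_codons:
            sd, nd = pathway_differences(a, b, code, stop_policy)
            sd60, nd60 = sd * _SCALE, nd * _SCALE
            assert sd60.denominator == 1 and nd60.denominator == 1
            table[(a, b)] = (int(sd60), int(nd60))
    return table


def compute_kaks(
    ca: CodonAlignment,
    code: GeneticCode | int = 11,
    stop_policy: StopPolicy = StopPolicy(),
) -> KaKsResult:
    """NG86 Ka/Ks over a codon alignment.

    Columns containing a gap, an ambiguous base, or a stop codon in either
    row are excluded from counting. Raises ValueError if no column is
    countable.
    """
    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)
    # exact arithmetic on 60x-scaled integer counts (see _SCALE)
    sites = _scaled_site_table(code, stop_policy)
    paths = _scaled_path_table(code, stop_policy)
    Sa = Na = Sb = Nb = 0
    Sd60 = Nd60 = 0
    n_codons = 0
    for codon_a, codon_b in ca.columns:
        entry_a = sites.get(codon_a)
        entry_b = sites.get(codon_b)
        if entry_a is None or entry_b is None:
            continue  # gap, ambiguity or stop codon in this column
        n_codons += 1
        Sa += entry_a[0]
        Na += entry_a[1]
        Sb += entry_b[0]
        Nb += entry_b[1]
        sd, nd = paths[(codon_a, codon_b)]
        Sd60 += sd
        Nd60 += nd
    if n_codons == 0:
        raise ValueError("no countable codon columns in alignment")

    S = Fraction(Sa + Sb, 2 * _SCALE)
    N = Fraction(Na + Nb, 2 * _SCALE)
    Sd = Fraction(Sd60, _SCALE)
    Nd = Fraction(Nd60, _SCALE)
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    valid_ks = pS is not None and pS < Fraction(3, 4)
    valid_ka = pN is not None and pN < Fraction(3, 4)
    Ks = jukes_cantor(float(pS)) if valid_ks else None
    Ka = jukes_cantor(float(pN)) if valid_ka else None
    ratio = None
    if valid_ka and valid_ks and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        S=float(S),
        N=float(N),
        Sd=float(Sd),
        Nd=float(Nd),
        pS=float(pS) if pS is not None else None,
        pN=float(pN) if pN is not None else None,
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        valid_ka=valid_ka,
        valid_ks=valid_ks,
        zero_variation=(Sd == 0 and Nd == 0),
        n_codons=n_codons,
    )


def kaks_from_cds_pair(
    cds_a: str,
    cds_b: str,
    code: GeneticCode | int = 11,
    stop_policy: StopPolicy = StopPolicy(),
) -> KaKsResult:
    """Convenience path: align translations, back-translate, run NG86."""
    from .align import align_protein_pair, backtranslate_alignment
    from .codons import translate_cds

    if isinstance(code, int):
        code = GeneticCode.from_table_id(code)
    pa = align_protein_pair(translate_cds(cds_a, code), translate_cds(cds_b, code))
    ca = backtranslate_alignment(pa, cds_a, cds_b, code)
    return compute_kaks(ca, code, stop_policy)
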