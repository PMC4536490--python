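"""Per-organism essential-vs-nonessential statistics.

Three engines: class means with two-sided Mann-Whitney U tests per metric
(Ka, Ks, Ka/Ks), a half-sampling bootstrap of class means, and a paired
Student's t-test of class means across organisms.

The Mann-Whitney test uses exhaustive permutation enumeration for pooled
sample sizes up to 10 (exact even under ties) and the midrank normal
approximation with tie correction above that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .ng86 import KaKsResult

METRICS = ("Ka", "Ks", "KaKs")

EXACT_MWU_MAX_N = 10


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    For n1 + n2 <= 10 the null distribution is enumerated over all
    C(n1+n2, n1) group assignments of the pooled values (handles ties
    exactly); larger samples use the midrank normal approximation with
    tie correction.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    if n1 + n2 <= EXACT_MWU_MAX_N:
        return _mwu_exact(x, y)
    if len(set(x) | set(y)) == 1:
        # all pooled values identical: no evidence either way
        return n1 * n2 / 2.0, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def _mwu_exact(x: List[float], y: List[float]) -> Tuple[float, float]:
    pooled = x + y
    n = len(pooled)
    n1 = len(x)
    center = n1 * (n - n1) / 2.0
    u_obs = _u_statistic(x, y)
    extreme = 0
    total = 0
    idx = range(n)
    for group1 in combinations(idx, n1):
        g1 = set(group1)
        xs = [pooled[i] for i in group1]
        ys = [pooled[i] for i in idx if i not in g1]
        u = _u_statistic(xs, ys)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


@dataclass(frozen=True)
class MetricSummary:
    mean_essential: Optional[float]
    mean_nonessential: Optional[float]
    p_value: Optional[float]
    n_essential: int
    n_nonessential: int


@dataclass(frozen=True)
class OrganismSummary:
    """Class means and Mann-Whitney p-values for one organism."""

    organism_id: str
    metrics: Mapping[str, MetricSummary]


def metric_values(result: KaKsResult) -> Dict[str, Optional[float]]:
    """Per-gene metric values entering class comparisons.

    Ka and Ks are taken for every gene whose estimate is valid (zero-
    variation genes contribute 0); the ratio only where defined, so
    zero-variation genes never enter Ka/Ks comparisons.
    """
    return {
        "Ka": result.Ka if result.valid_ka else None,
        "Ks": result.Ks if result.valid_ks else None,
        "KaKs": result.ratio,
    }


def summarize_organism(
    organism_id: str,
    results: Sequence[Tuple[str, bool, KaKsResult]],
) -> OrganismSummary:
    """Compare essential and nonessential genes on Ka, Ks and Ka/Ks.

    ``results`` holds (gene_id, essential, KaKsResult) triples. For each
    metric, genes lacking a defined value are excluded, class means are
    computed over the rest, and a two-sided Mann-Whitney U test is run on
    the per-gene values. A metric with an empty class reports None entries.
    """
    per_metric: Dict[str, MetricSummary] = {}
    for metric in METRICS:
        ess, ness = [], []
        for _, essential, res in results:
            value = metric_values(res)[metric]
            if value is None:
                continue
            (ess if essential else ness).append(value)
        if not ess or not ness:
            per_metric[metric] = MetricSummary(
                mean_essential=float(np.mean(ess)) if ess else None,
                mean_nonessential=float(np.mean(ness)) if ness else None,
                p_value=None,
                n_essential=len(ess),
                n_nonessential=len(ness),
            )
            continue
        _, p = mann_whitney_u(ess, ness)
        per_metric[metric] = MetricSummary(
            mean_essential=float(np.mean(ess)),
            mean_nonessential=float(np.mean(ness)),
            p_value=p,
            n_essential=len(ess),
            n_nonessential=len(ness),
        )
    return OrganismSummary(organism_id=organism_id, metrics=per_metric)


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate means from half-sampling with replacement."""

    organism_id: str
    metric: str
    gene_class: str
    replicate_means: np.ndarray
    seed: int


def bootstrap_means(
    values: Sequence[float],
    reps: int = 1000,
    seed: int = 0,
    organism_id: str = "",
    metric: str = "",
    gene_class: str = "",
) -> BootstrapResult:
    """Half-sampling bootstrap: each replicate draws floor(n/2) values
    (minimum 1) with replacement and records their mean.

    Damps the influence of extreme per-gene estimates on class means.
    Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if reps <= 0:
        raise ValueError("reps must be positive")
    half = max(1, values.size // 2)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, values.size, size=(reps, half))
    # centre on the first value for numerical stability (constant input
    # then yields exactly constant replicate means)
    centre = values[0]
    means = centre + (values - centre)[draws].mean(axis=1)
    return BootstrapResult(
        organism_id=organism_id,
        metric=metric,
        gene_class=gene_class,
        replicate_means=means,
        seed=seed,
    )


def cross_organism_ttest(
    summaries: Sequence[OrganismSummary], metric: str
) -> Tuple[float, float]:
    """Paired two-sided t-test of (essential mean, nonessential mean)
    across organisms; organisms are the pairing unit."""
    pairs = [
        (m.mean_essential, m.mean_nonessential)
        for s in summaries
        for m in [s.metrics[metric]]
        if m.mean_essential is not None and m.mean_nonessential is not None
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 organisms with both class means for metric {metric}, "
            f"got {len(pairs)}"
        )
    ess, ness = zip(*pairs)
    if all(e == n for e, n in pairs):
        return 0.0, 1.0
    t, p = sps.ttest_rel(ess, ness)
    return float(t), float(p)
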