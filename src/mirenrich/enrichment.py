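"""Per-family target-set fold-change enrichment scan.

For each miRNA family, the predicted-target gene universe (the union of all
families' predicted targets, restricted to genes with measured fold changes)
is partitioned into the family's targets and all remaining predicted targets
(the competitive non-target background). The two groups' log fold changes
are compared with a Mann–Whitney rank-sum test, and the family is reported
with both group medians, the U statistic for the target group and a p-value.

The Mann–Whitney implementation is self-contained because its exact-path
semantics are part of the method's contract:

* **exact path** — when the pooled sample is small (``|x|+|y| <= exact_limit``)
  and tie-free, the p-value is computed from the complete null distribution
  of U over all C(|x|+|y|, |x|) equally likely group assignments;
* **normal approximation** — otherwise, a tie-corrected normal approximation
  with continuity correction is used (mid-ranks for ties).

The two-sided p-value is twice the smaller tail, clamped to (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import EmptyResultError, InputError
from .io import FoldChangeTable, TargetPredictionMap

logger = logging.getLogger("mirenrich.enrichment")

ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class FamilyEnrichmentResult:
    """One row of the scan: a family's target/non-target comparison.

    ``median_fc_targets`` / ``median_fc_non_targets`` are the group medians
    of the log fold changes ("FC Targets" / "FC Non-Targets");
    ``u_statistic`` is the Mann–Whitney U for the target group, in
    [0, n_targets * n_non_targets]; ``method`` records whether the p-value
    came from the exact distribution or the normal approximation.
    """

    family_id: str
    n_targets: int
    n_non_targets: int
    median_fc_targets: float
    median_fc_non_targets: float
    u_statistic: float
    p_value: float
    method: str

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")
        if not (0.0 <= self.u_statistic <= self.n_targets * self.n_non_targets + 1e-9):
            raise ValueError("u_statistic outside [0, n_targets * n_non_targets]")


class MannWhitneyOutcome(NamedTuple):
    u: float
    p: float
    method: str


# ---------------------------------------------------------------------------
# Exact null distribution of U
# ---------------------------------------------------------------------------

def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of group assignments by U value under the null.

    ``counts[u]`` is the number of ways to choose ``n1`` of the ranks
    ``1..n1+n2`` so that the resulting tie-free Mann–Whitney statistic equals
    ``u``; built by convolving the choose-rank generating function, one rank
    at a time. Total mass is C(n1+n2, n1).
    """
    n = n1 + n2
    max_sum = n1 * n2 + n1 * (n1 + 1) // 2  # largest attainable rank sum
    # dp[k, s] = #subsets of size k with rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        upper = min(n1, rank)
        for k in range(upper, 0, -1):
            dp[k, rank:] += dp[k - 1, : max_sum + 1 - rank]
    offset = n1 * (n1 + 1) // 2  # U = rank_sum - offset
    return dp[n1, offset:]


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 16,
) -> MannWhitneyOutcome:
    """Mann–Whitney U test of ``x`` (targets) against ``y`` (background).

    U is computed from mid-ranks, so ties are handled consistently on both
    code paths; the exact path is only taken for tie-free pooled samples of
    size at most ``exact_limit``. ``alternative`` follows the usual
    convention for the first sample: ``"less"`` asks whether ``x`` values are
    stochastically smaller than ``y`` values.

    Returns ``(u, p, method)``; p is clamped to (0, 1].
    """
    if alternative not in ALTERNATIVES:
        raise InputError(f"unknown alternative {alternative!r}; choose from {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("mann_whitney requires both groups non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("mann_whitney requires finite values")

    n1, n2, n = x.size, y.size, x.size + y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n <= exact_limit and not has_ties:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        k = int(round(u))  # integer when tie-free
        cdf = counts[: k + 1].sum() / total
        sf = counts[k:].sum() / total
        if alternative == "less":
            p = cdf
        elif alternative == "greater":
            p = sf
        else:
            p = 2.0 * min(cdf, sf)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0.0:  # all pooled values identical
            return MannWhitneyOutcome(u, 1.0, "normal-approximation")
        sigma = np.sqrt(sigma2)
        cc = 0.5  # continuity correction toward the mean
        if alternative == "less":
            p = sps.norm.cdf((u - mu + cc) / sigma)
        elif alternative == "greater":
            p = sps.norm.sf((u - mu - cc) / sigma)
        else:
            z = max(abs(u - mu) - cc, 0.0) / sigma
            p = 2.0 * sps.norm.sf(z)
        method = "normal-approximation"

    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return MannWhitneyOutcome(float(u), p, method)


# ---------------------------------------------------------------------------
# Universe and partitions
# ---------------------------------------------------------------------------

def build_universe(predictions: TargetPredictionMap, fc: FoldChangeTable) -> frozenset:
    """Genes eligible for testing: predicted target of at least one family
    AND measured in the fold-change table.

    Measured genes with no prediction are excluded and counted in the log;
    an empty intersection is a hard error.
    """
    predicted = predictions.gene_universe
    measured = fc.genes
    universe = predicted & measured
    n_unpredicted = len(measured - predicted)
    if n_unpredicted:
        logger.info("EXCLUDE_UNPREDICTED_GENES count=%d", n_unpredicted)
    n_unmeasured = len(predicted - measured)
    if n_unmeasured:
        logger.info("EXCLUDE_UNMEASURED_TARGETS count=%d", n_unmeasured)
    if not universe:
        raise InputError("no overlap between predicted targets and measured genes")
    return frozenset(universe)


def partition_for_family(
    family_id: str,
    predictions: TargetPredictionMap,
    universe: frozenset,
) -> Tuple[frozenset, frozenset]:
    """Split the universe into the family's targets and everything else.

    The non-target group is the competitive background: genes that are
    predicted targets of some *other* family but not of this one.
    """
    if family_id not in predictions.family_targets:
        raise InputError(f"unknown family: {family_id!r}")
    targets = predictions.family_targets[family_id] & universe
    non_targets = universe - targets
    return frozenset(targets), frozenset(non_targets)


def scan_families(
    fc: FoldChangeTable,
    predictions: TargetPredictionMap,
    alternative: str = "two-sided",
    exact_limit: int = 16,
    min_targets: int = 5,
    prefilter: str = "none",
) -> List[FamilyEnrichmentResult]:
    """Run the per-family enrichment test over every family in the map.

    Families whose usable target set is smaller than ``min_targets``, or
    whose non-target background is empty, are skipped with a logged reason
    and produce no row. ``prefilter="down"`` restricts the fold-change table
    to down-regulated genes (log_fc < 0) before building the universe;
    the default tests the full universe.

    Results are sorted by p-value ascending, then family id, so output is
    deterministic for fixed inputs. Raises :class:`EmptyResultError` if no
    family was testable.
    """
    if prefilter not in ("none", "down"):
        raise InputError(f"unknown prefilter {prefilter!r}")
    if prefilter == "down":
        fc = FoldChangeTable(fc.values[fc.values < 0])
        if len(fc) == 0:
            raise EmptyResultError("prefilter='down' removed every gene")
    universe = build_universe(predictions, fc)
    fc_u = fc.values.loc[list(universe)]

    results: List[FamilyEnrichmentResult] = []
    for family_id in sorted(predictions.family_targets):
        targets, non_targets = partition_for_family(family_id, predictions, universe)
        if len(targets) < min_targets:
            logger.info("SKIP_FAMILY_TOO_FEW_TARGETS family=%s n_targets=%d min=%d",
                        family_id, len(targets), min_targets)
            continue
        if not non_targets:
            logger.info("SKIP_FAMILY_NO_NON_TARGETS family=%s", family_id)
            continue
        x = fc_u.loc[list(targets)].to_numpy(dtype=float)
        y = fc_u.loc[list(non_targets)].to_numpy(dtype=float)
        u, p, method = mann_whitney(x, y, alternative=alternative, exact_limit=exact_limit)
        results.append(FamilyEnrichmentResult(
            family_id=family_id,
            n_targets=len(targets),
            n_non_targets=len(non_targets),
            median_fc_targets=float(np.median(x)),
            median_fc_non_targets=float(np.median(y)),
            u_statistic=u,
            p_value=p,
            method=method,
        ))
    if not results:
        raise EmptyResultError("no family passed the testability filters")
    results.sort(key=lambda r: (r.p_value, r.family_id))
    return results
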