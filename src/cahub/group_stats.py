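"""Population-level statistics: matched subsampling and exact 2x2 tests.

The matched-subsampling bootstrap asks whether a small tagged
population (e.g. fate-mapped early-born GABA cells) shows a larger
statistic (proportion modulated, mean parameter, mean out-connections)
than equally sized random draws of untagged cells: each of ``n_reps``
surrogates picks, per field of view, as many untagged cells as there
are tagged cells, without replacement, and recomputes the statistic.
The observed tagged value is significant when it exceeds the 95th
percentile of the surrogate distribution (upper tail; a two-sided
variant uses the 2.5/97.5 percentiles).

Contingency comparisons use the exact two-sided Fisher test with the
"sum of all tables at most as probable as the observed one" convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Matched-subsampling bootstrap result."""

    statistic: str
    observed: float
    surrogate: np.ndarray
    p: float
    significant: bool
    alternative: str                    # "greater" or "two-sided"
    quantiles: dict[str, float]
    n_tagged: int
    n_reps: int


@dataclass
class FisherResult:
    """Exact two-sided Fisher test on a 2x2 table."""

    p: float
    odds_ratio: float
    table: np.ndarray
    degenerate: bool = False            # a zero margin: p = 1 by convention


def matched_subsample_test(
    values: np.ndarray,
    tags: np.ndarray,
    fov_ids: np.ndarray,
    statistic: str = "proportion",
    n_reps: int = 1000,
    alternative: str = "greater",
    rng: np.random.Generator | int | None = None,
) -> GroupComparison:
    """Matched-subsampling bootstrap for a tagged-cell statistic.

    Parameters
    ----------
    values
        Per-cell value: boolean flags for ``statistic="proportion"``,
        numeric for ``statistic="mean"``.
    tags
        Boolean per-cell array; True marks the tagged population.
    fov_ids
        Per-cell field-of-view identifier; each surrogate draw matches
        the tagged-cell count per field of view.
    alternative
        ``"greater"`` (Methods rule: observed above the surrogate 95th
        percentile) or ``"two-sided"`` (outside the 2.5/97.5 band).
    """
    values = np.asarray(values, dtype=float)
    tags = np.asarray(tags, dtype=bool)
    fov_ids = np.asarray(fov_ids)
    if not (len(values) == len(tags) == len(fov_ids)):
        raise ValueError("values, tags and fov_ids must share their length")
    if statistic not in ("proportion", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(rng)

    n_tagged = int(tags.sum())
    if n_tagged == 0:
        raise ValueError("no tagged cells")
    observed = float(values[tags].mean())

    sums = np.zeros(n_reps)
    for fov in np.unique(fov_ids):
        in_fov = fov_ids == fov
        k = int((tags & in_fov).sum())
        if k == 0:
            continue
        pool = values[in_fov & ~tags]
        if len(pool) < k:
            raise ValueError(
                f"FOV {fov!r} holds {k} tagged but only {len(pool)} untagged cells"
            )
        ranks = np.argsort(rng.random((n_reps, len(pool))), axis=1)[:, :k]
        sums += pool[ranks].sum(axis=1)
    surrogate = sums / n_tagged

    q = {
        "q2.5": float(np.percentile(surrogate, 2.5)),
        "q5": float(np.percentile(surrogate, 5)),
        "q95": float(np.percentile(surrogate, 95)),
        "q97.5": float(np.percentile(surrogate, 97.5)),
    }
    if alternative == "greater":
        significant = observed > q["q95"]
        p = float(np.mean(surrogate >= observed))
    else:
        significant = observed > q["q97.5"] or observed < q["q2.5"]
        p = float(
            min(1.0, 2 * min(np.mean(surrogate >= observed),
                             np.mean(surrogate <= observed)))
        )
    return GroupComparison(
        statistic, observed, surrogate, p, bool(significant), alternative,
        q, n_tagged, n_reps,
    )


def fisher_exact_test(table: np.ndarray) -> FisherResult:
    """Exact two-sided Fisher test of a 2x2 contingency table.

    The two-sided p-value sums the hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed
    that of the observed table.  A table with a zero margin carries no
    information about association; by convention p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    degenerate = bool(
        np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0)
    )
    if degenerate:
        logger.info("zero margin in contingency table: p = 1 by convention")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(float(p), float(odds), t, degenerate)
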