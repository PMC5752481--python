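"""Association tests between a sample ordering and responder status.

The rank-sum score of an ordering is the sum of the (1-based, from the
top) positions occupied by responder samples: small scores mean
responders are concentrated at the top. Its null distribution under
label exchangeability is built by permuting responder status among
patients — exhaustively when the number of label assignments is small,
by seeded Monte-Carlo sampling otherwise. A Welch two-sample t-test on
a single differential-pair value is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PermResult:
    score: float
    B: int
    null_mean: float
    null_sd: float
    p: float
    p_lower: float
    p_upper: float
    seed: int | None
    alternative: str
    method: str  # "exhaustive" | "sampled"

    def to_dict(self) -> dict:
        return {
            "score": self.score, "B": self.B, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "p": self.p, "p_lower": self.p_lower,
            "p_upper": self.p_upper, "seed": self.seed,
            "alternative": self.alternative, "method": self.method,
        }


@dataclass
class PairTestResult:
    mean_responder: float
    mean_nonresponder: float
    t: float
    df: float
    p: float


def _responder_mask(order: Sequence, labels) -> np.ndarray:
    """Boolean mask over positions of ``order``: True where responder."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(labels, Mapping):
        lab = [labels[s] for s in order]
    else:
        lab = list(labels)
        if len(lab) != len(order):
            raise ValueError("labels length does not match ordering")
    mask = np.array([_as_bool(v) for v in lab], dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both responder and non-responder labels are required")
    return mask


def _as_bool(v) -> bool:
    if isinstance(v, str):
        u = v.strip().upper()
        if u in ("R", "RESPONDER", "1", "TRUE"):
            return True
        if u in ("NR", "NONRESPONDER", "NON-RESPONDER", "0", "FALSE"):
            return False
        raise ValueError(f"unrecognized label {v!r}")
    return bool(v)


def ranksum_score(order: Sequence, labels) -> int:
    """Sum of 1-based top-down positions occupied by responders."""
    if len(set(order)) != len(order):
        raise ValueError("ordering contains duplicates; not a permutation")
    mask = _responder_mask(order, labels)
    positions = np.arange(1, len(order) + 1)
    return int(positions[mask].sum())


def permutation_test(
    order: Sequence,
    labels,
    B: int = 100_000,
    seed: int = 0,
    alternative: str = "two-sided",
    exhaustive_limit: int = 200_000,
) -> PermResult:
    """Permutation null for the rank-sum score.

    Responder status is permuted among samples; the score is recomputed
    and compared with the observed one. When C(n, n_R) <= the exhaustive
    limit all label assignments are enumerated and p is exact; otherwise
    B random permutations are drawn and the add-one estimator
    p = (1 + #as-or-more-extreme) / (B + 1) is used. ``alternative`` is
    "two-sided" (min-tail doubling, capped at 1), "lower" (responders on
    top) or "upper".
    """
    if alternative not in ("two-sided", "lower", "upper"):
        raise ValueError(f"unknown alternative {alternative!r}")
    mask = _responder_mask(order, labels)
    n = len(order)
    n_r = int(mask.sum())
    observed = float(np.arange(1, n + 1)[mask].sum())

    n_assign = comb(n, n_r)
    if n_assign <= exhaustive_limit:
        scores = np.array(
            [sum(c) for c in combinations(range(1, n + 1), n_r)], dtype=float
        )
        total = scores.size
        p_lower = float((scores <= observed).sum()) / total
        p_upper = float((scores >= observed).sum()) / total
        method, B_used, seed_used = "exhaustive", total, None
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        positions = np.arange(1, n + 1)
        scores = np.empty(B)
        for b in range(B):
            scores[b] = positions[rng.permutation(n)[:n_r]].sum()
        p_lower = (1.0 + (scores <= observed).sum()) / (B + 1)
        p_upper = (1.0 + (scores >= observed).sum()) / (B + 1)
        method, B_used, seed_used = "sampled", B, seed

    if alternative == "lower":
        p = p_lower
    elif alternative == "upper":
        p = p_upper
    else:
        p = min(1.0, 2.0 * min(p_lower, p_upper))
    return PermResult(
        score=observed, B=B_used,
        null_mean=float(scores.mean()), null_sd=float(scores.std(ddof=1)),
        p=float(p), p_lower=float(p_lower), p_upper=float(p_upper),
        seed=seed_used, alternative=alternative, method=method,
    )


def cluster_restricted_test(
    ordering, labels, cluster: int, **kwargs
) -> PermResult:
    """Rank-sum permutation test within one NMF cluster block.

    ``ordering`` is an :class:`~hypomel.nmf.NMFOrdering`; only samples
    assigned to ``cluster`` enter, ranked by their within-block order.
    """
    members = [s for s in ordering.sample_order
               if ordering.samples.loc[s, "cluster"] == cluster]
    if not members:
        raise ValueError(f"cluster {cluster} is empty")
    return permutation_test(members, labels, **kwargs)


def pair_ttest(
    diff_values, labels, equal_var: bool = False
) -> PairTestResult:
    """Two-sample t-test (Welch by default) of a differential-pair value
    between responders and non-responders."""
    if isinstance(diff_values, pd.Series):
        order = list(diff_values.index)
        vals = diff_values.to_numpy(float)
    else:
        vals = np.asarray(diff_values, float)
        order = list(range(len(vals)))
    mask = _responder_mask(order, labels)
    x, y = vals[mask], vals[~mask]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 samples per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return PairTestResult(float(x.mean()), float(y.mean()),
                                  0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    df = float(getattr(res, "df", len(x) + len(y) - 2))
    return PairTestResult(
        mean_responder=float(x.mean()), mean_nonresponder=float(y.mean()),
        t=float(res.statistic), df=df, p=float(res.pvalue),
    )
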