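"""Statistical comparison of group-optimal landscapes and of the morphospace.

Two complementary tests:

* **Top-set sharing.** Two groups' landscape preferences are compared through
  the overlap of their top-percentile candidate sets. Under the null that the
  two top sets are independent draws from the common candidate pool, the
  shared count is hypergeometric; the test is one-sided toward *fewer* shared
  landscapes than expected (small p = the groups favor different landscapes).
  A seeded permutation null is available as a fallback/cross-check.

* **Permutational MANOVA.** Association between the morphospace (multivariate
  PC scores) and a categorical ecological factor, using the one-way
  pseudo-F statistic with p-values from label permutation:
  p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from morphlands.errors import ValidationError
from morphlands.optimize import GroupFitnessRanking, WeightVector

HYPERGEOMETRIC = "hypergeometric"
PERMUTATION = "permutation"


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    top_percentile: float
    size_a: int
    size_b: int
    n_shared: int
    p_value: float
    null_method: str

    def __post_init__(self) -> None:
        if not (0 <= self.n_shared <= min(self.size_a, self.size_b)):
            raise ValidationError("shared count exceeds a top-set size")


@dataclass
class ManovaResult:
    r_squared: float
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "r_squared": float(self.r_squared),
                    "f_statistic": float(self.f_statistic),
                    "p_value": float(self.p_value),
                    "n_permutations": int(self.n_permutations),
                    "seed": int(self.seed),
                },
                fh,
            )


def top_set(ranking: GroupFitnessRanking, percentile: float = 5.0) -> frozenset[WeightVector]:
    """The ceil(percentile% * N) best candidates, with cutoff ties included."""
    if not 0 < percentile <= 100:
        raise ValidationError("percentile must lie in (0, 100]")
    n = ranking.n_candidates
    if n == 0:
        raise ValidationError("empty ranking")
    k = int(np.ceil(percentile / 100.0 * n))
    cutoff = ranking.fitness[ranking.order[k - 1]]
    idx = ranking.order[: k]
    # ties at the cutoff fitness are included deterministically
    rest = ranking.order[k:]
    extra = rest[ranking.fitness[rest] == cutoff]
    chosen = np.concatenate([idx, extra])
    return frozenset(ranking.weight_vectors[int(i)] for i in chosen)


def average_top_weights(ranking: GroupFitnessRanking, percentile: float = 5.0) -> np.ndarray:
    """Mean weight vector of the tie-inclusive top-percentile candidate set.

    Because each candidate's fitness is linear in its weights, the single
    best-ranked candidate is always a vertex of the weight simplex; the mean
    over the top set is the standard way to report a group's optimal
    weighting W' with interior (non-vertex) values.
    """
    chosen = top_set(ranking, percentile)
    return np.mean([wv.weights for wv in chosen], axis=0)


def _check_same_pool(rank_a: GroupFitnessRanking, rank_b: GroupFitnessRanking) -> None:
    if rank_a.n_candidates != rank_b.n_candidates or set(rank_a.weight_vectors) != set(
        rank_b.weight_vectors
    ):
        raise ValidationError("rankings must cover the identical candidate set")


def landscape_group_test(
    rank_a: GroupFitnessRanking,
    rank_b: GroupFitnessRanking,
    percentile: float = 5.0,
    null_method: str = HYPERGEOMETRIC,
    seed: int = 0,
    n_permutations: int = 10_000,
) -> ComparisonResult:
    """Sharing test between two groups' top-percentile landscape sets.

    p is the null probability of observing *at most* the shared count, so low
    sharing yields small p (groups differ) and complete sharing yields p = 1.
    """
    _check_same_pool(rank_a, rank_b)
    set_a, set_b = top_set(rank_a, percentile), top_set(rank_b, percentile)
    n_shared = len(set_a & set_b)
    pool = rank_a.n_candidates
    if null_method == HYPERGEOMETRIC:
        p = float(hypergeom.cdf(n_shared, pool, len(set_a), len(set_b)))
    elif null_method == PERMUTATION:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_permutations, dtype=int)
        marked = np.zeros(pool, dtype=bool)
        marked[: len(set_a)] = True
        for i in range(n_permutations):
            picked = rng.choice(pool, size=len(set_b), replace=False)
            draws[i] = int(marked[picked].sum())
        p = float((1 + np.sum(draws <= n_shared)) / (1 + n_permutations))
    else:
        raise ValidationError(f"unknown null method {null_method!r}")
    return ComparisonResult(
        group_a=rank_a.group_label,
        group_b=rank_b.group_label,
        top_percentile=percentile,
        size_a=len(set_a),
        size_b=len(set_b),
        n_shared=n_shared,
        p_value=min(p, 1.0),
        null_method=null_method,
    )


def pairwise_comparison_matrix(
    rankings: Sequence[GroupFitnessRanking],
    percentile: float = 5.0,
    null_method: str = HYPERGEOMETRIC,
    seed: int = 0,
) -> pd.DataFrame:
    """All-pairs sharing tests: upper triangle shared counts, lower p-values."""
    if len(rankings) < 2:
        raise ValidationError("need at least two groups to compare")
    labels = [r.group_label for r in rankings]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate group labels")
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, ra in enumerate(rankings):
        for j in range(i + 1, len(rankings)):
            rb = rankings[j]
            res = landscape_group_test(
                ra, rb, percentile=percentile, null_method=null_method, seed=seed + i * 997 + j
            )
            mat.iloc[i, j] = res.n_shared
            mat.iloc[j, i] = res.p_value
    return mat


def _pseudo_f(scores: np.ndarray, group_codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """One-way multivariate pseudo-F and R^2 on Euclidean sums of squares."""
    n = scores.shape[0]
    grand = scores.mean(axis=0)
    ss_total = float(((scores - grand) ** 2).sum())
    counts = np.bincount(group_codes, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, scores.shape[1]))
    np.add.at(sums, group_codes, scores)
    means = sums / counts[:, None]
    ss_between = float((counts[:, None] * (means - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    if ss_total <= 0:
        return 0.0, 0.0
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        return np.inf, 1.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between / ss_total


def permutation_manova(
    scores: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> ManovaResult:
    """One-factor permutational MANOVA of multivariate scores on a grouping.

    R^2 = SS_between / SS_total on the raw (Euclidean) scores; significance by
    permuting group labels ``n_permutations`` times with the stated seed.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValidationError("scores must be a 2-D array (observations x variables)")
    codes, uniques = pd.factorize(pd.Series(list(labels)))
    if len(uniques) < 2:
        raise ValidationError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = uniques[int(np.argmin(counts))]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    if len(codes) != X.shape[0]:
        raise ValidationError("labels must align with score rows")
    if n_permutations < 99:
        raise ValidationError("use at least 99 permutations")
    g = len(uniques)
    f_obs, r2 = _pseudo_f(X, codes, g)
    rng = np.random.default_rng(seed)
    count_ge = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f_perm, _ = _pseudo_f(X, perm, g)
        if f_perm >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return ManovaResult(
        r_squared=r2,
        f_statistic=f_obs,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )
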