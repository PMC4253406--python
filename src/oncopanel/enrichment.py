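"""Gene-set enrichment with a Fisher/rank-deviation combined score.

For each term in a gene-set library the overlap with a query list is
scored by the hypergeometric upper tail (Fisher's exact one-sided p).
Because raw Fisher p-values favor large terms, each term's observed rank
(terms ordered by ascending p) is compared with the rank distribution it
attains on B random queries of the same size drawn uniformly from the
universe; the deviation z = (rank - mu)/sigma enters the combined score

    c = ln(p) * z

which is positive for terms enriched beyond expectation (ln p < 0 and
z < 0).  Scores derived from a down-regulated query are negated for
presentation, leaving |c| unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr
from .panel_io import GeneSetLibrary

__all__ = [
    "fisher_p",
    "rank_calibration",
    "combined_score",
    "enrich",
]


def fisher_p(k: int, query_size: int, term_size: int, universe_size: int) -> float:
    """Hypergeometric upper tail P(X >= k) for a k-gene overlap."""
    _check_sizes(k, query_size, term_size, universe_size)
    return float(stats.hypergeom.sf(k - 1, universe_size, term_size, query_size))


def _check_sizes(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent contingency sizes: k={k}, query={n}, term={K}, universe={N}"
        )


def _membership(library: GeneSetLibrary) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Terms (sorted by id), universe gene order, and a T × N bool matrix."""
    terms = library.term_names
    genes = sorted(library.universe)
    gene_index = {g: i for i, g in enumerate(genes)}
    matrix = np.zeros((len(terms), len(genes)), dtype=bool)
    for ti, term in enumerate(terms):
        for g in library.terms[term]:
            matrix[ti, gene_index[g]] = True
    return terms, np.array(genes, dtype=object), matrix


def _fisher_vector(k: np.ndarray, n: int, sizes: np.ndarray, N: int) -> np.ndarray:
    return stats.hypergeom.sf(k - 1, N, sizes, n)


def _ranks(p: np.ndarray) -> np.ndarray:
    """1-based ranks by ascending p with mid-rank ties.

    Tied p-values (ubiquitous: every zero-overlap term has p = 1) share
    their average rank, which is deterministic and keeps exchangeable
    terms exchangeable — a name-based tie-break would systematically
    favor lexicographically early terms in the calibration.
    """
    return stats.rankdata(p, method="average")


def _random_rank_moments(
    matrix: np.ndarray, query_size: int, universe_size: int, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-term mean and sample SD of ranks over B uniform random queries."""
    if B < 2:
        raise ValueError("B must be >= 2")
    sizes = matrix.sum(axis=1)
    rank_sum = np.zeros(matrix.shape[0])
    rank_sq = np.zeros(matrix.shape[0])
    for _ in range(B):
        idx = rng.choice(universe_size, size=query_size, replace=False)
        k = matrix[:, idx].sum(axis=1)
        r = _ranks(_fisher_vector(k, query_size, sizes, universe_size))
        rank_sum += r
        rank_sq += r.astype(float) ** 2
    mu = rank_sum / B
    var = (rank_sq - B * mu**2) / (B - 1)
    sigma = np.sqrt(np.maximum(var, 0.0))
    return mu, sigma


def rank_calibration(
    term: str,
    query_size: int,
    library: GeneSetLibrary,
    B: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo (mu, sigma) of one term's rank under random queries."""
    if len(library.terms) < 2:
        raise ValueError("rank calibration needs a library with >= 2 terms")
    terms, _genes, matrix = _membership(library)
    rng = np.random.default_rng(seed)
    mu, sigma = _random_rank_moments(matrix, query_size, len(library.universe), B, rng)
    ti = terms.index(term)
    return float(mu[ti]), float(sigma[ti])


def combined_score(fisher_p_value: float, rank: float, mu: float, sigma: float) -> float:
    """c = ln(p) * z with z = (rank - mu)/sigma (z = 0 when sigma = 0).

    Terms ranking worse than their random expectation (z > 0) are not
    enriched; their score is floored at 0, keeping c nonnegative before
    the direction sign is applied.
    """
    if not 0.0 < fisher_p_value <= 1.0:
        raise ValueError(f"fisher p must lie in (0, 1], got {fisher_p_value}")
    z = 0.0 if sigma == 0 else (rank - mu) / sigma
    return float(max(np.log(fisher_p_value) * z, 0.0))


def enrich(
    query: Iterable[str],
    direction: str,
    library: GeneSetLibrary,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every term against a query gene list.

    Genes outside the universe are dropped (their count is reported in
    ``attrs['dropped']``).  Results are sorted by |combined_score|
    descending; ``direction='down'`` negates the reported scores.  BH
    q-values over the Fisher p-values are reported as supplementary
    information.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    query_set = set(query)
    dropped = len(query_set - library.universe)
    query_set &= library.universe
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")
    terms, genes, matrix = _membership(library)
    N = len(genes)
    n = len(query_set)
    q_mask = np.isin(genes, list(query_set))
    sizes = matrix.sum(axis=1)
    k = matrix[:, q_mask].sum(axis=1)
    p = _fisher_vector(k, n, sizes, N)
    ranks = _ranks(p)
    rng = np.random.default_rng(seed)
    mu, sigma = _random_rank_moments(matrix, n, N, B, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (ranks - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    c = np.maximum(np.log(p) * z, 0.0)
    sign = 1.0 if direction == "up" else -1.0
    out = pd.DataFrame(
        {
            "term": terms,
            "overlap": k,
            "term_size": sizes,
            "fisher_p": p,
            "fisher_q": bh_fdr(p),
            "rank": ranks,
            "expected_rank": mu,
            "rank_sd": sigma,
            "z": z,
            "combined_score": sign * c,
            "direction": direction,
        }
    )
    out["degenerate_sigma"] = sigma == 0
    out = out.sort_values(
        by=["combined_score", "term"],
        key=lambda col: np.abs(col) if col.name == "combined_score" else col,
        ascending=[False, True],
    ).reset_index(drop=True)
    out.attrs["dropped"] = dropped
    out.attrs["permutations"] = B
    out.attrs["log_base"] = "e"
    return out
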