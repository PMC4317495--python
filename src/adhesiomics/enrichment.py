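"""Functional overrepresentation statistics and the enrichment map.

Two overrepresentation protocols are provided, mirroring common keyword- and
ontology-level analyses of adhesion proteomes:

* a keyword screen: hypergeometric (Fisher one-tail) and EASE p-values with
  Bonferroni correction, retained when fold enrichment >= 1.5, Bonferroni
  P < 0.05, EASE < 0.05 and at least two query proteins carry the keyword;
* a randomization false discovery rate: random same-size queries are drawn
  from the background (100 by default) and the FDR of each term is the mean
  number of random terms at least as significant, divided by the number of
  observed terms at least as significant.

The enrichment map places the log2 fold change of each annotated protein
into an overrepresented-terms x proteins matrix and clusters the term rows
with uncentred-Pearson complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterTree, hclust_complete

__all__ = [
    "ora_test",
    "filter_keywords",
    "permutation_fdr",
    "build_enrichment_map",
]


def _term_pvalues(k: np.ndarray, n: int, K: np.ndarray, N: int) -> np.ndarray:
    """Hypergeometric upper tail P(X >= k) for overlap vector k."""
    return stats.hypergeom.sf(k - 1, N, K, n)


def ora_test(query: set, background: set, terms: dict) -> pd.DataFrame:
    """Overrepresentation of annotation terms in a query protein list.

    For each term with member set T over background B and query Q (Q a subset
    of B), with k = |Q & T|, n = |Q|, K = |T & B|, N = |B|:

    * ``p_fisher`` is the hypergeometric upper tail P(X >= k);
    * ``p_ease`` is the EASE score, the same tail with the overlap reduced by
      one (a conservative, jackknifed Fisher variant); P = 1 when k <= 1 is
      reduced past zero;
    * ``fold_enrichment`` = (k/n) / (K/N);
    * ``p_bonferroni`` = p_fisher times the number of terms tested, capped at 1.
    """
    query, background = set(query), set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 proteins")
    stray = query - background
    if stray:
        raise ValueError(f"query proteins not in background: {sorted(map(str, stray))}")
    term_ids = sorted(terms)
    N, n = len(background), len(query)
    K = np.array([len(set(terms[t]) & background) for t in term_ids])
    k = np.array([len(set(terms[t]) & query) for t in term_ids])
    p_fisher = _term_pvalues(k, n, K, N)
    p_ease = _term_pvalues(np.maximum(k - 1, 0), n, K, N)
    p_ease[k - 1 < 0] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = np.where((n > 0) & (K > 0), (k / n) / (K / N), 0.0)
    m = len(term_ids)
    return pd.DataFrame(
        {
            "k": k,
            "n": n,
            "K": K,
            "N": N,
            "fold_enrichment": fe,
            "p_fisher": p_fisher,
            "p_ease": p_ease,
            "p_bonferroni": np.minimum(p_fisher * m, 1.0),
        },
        index=pd.Index(term_ids, name="term"),
    )


def filter_keywords(
    results: pd.DataFrame,
    fe_min: float = 1.5,
    p_bonf_max: float = 0.05,
    ease_max: float = 0.05,
    k_min: int = 2,
) -> pd.DataFrame:
    """Significantly overrepresented keywords: fold enrichment >= fe_min,
    Bonferroni P < p_bonf_max, EASE < ease_max, and at least k_min proteins.
    """
    passes = (
        (results["fold_enrichment"] >= fe_min)
        & (results["p_bonferroni"] < p_bonf_max)
        & (results["p_ease"] < ease_max)
        & (results["k"] >= k_min)
    )
    out = results.copy()
    out["passes"] = passes
    return out


def permutation_fdr(
    query: set,
    background: set,
    terms: dict,
    n_rand: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Randomization false discovery rate per term.

    ``n_rand`` uniform random queries of the same size are drawn from the
    background; for each term the FDR estimate is

        mean_r #(random-run terms with p <= p_obs(term)) /
               #(observed terms with p <= p_obs(term)),

    capped at 1. Deterministic given ``seed``.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    obs = ora_test(query, background, terms)
    p_obs = obs["p_fisher"].to_numpy()
    order = np.sort(p_obs)
    # observed discoveries at each term's own threshold
    n_obs_at = np.searchsorted(order, p_obs, side="right")
    bg = sorted(map(str, set(background)))
    bg_arr = np.array(bg, dtype=object)
    n = len(set(query))
    N = len(bg)
    term_ids = list(obs.index)
    K = obs["K"].to_numpy()
    rng = np.random.default_rng(seed)
    term_members = [set(map(str, set(terms[t]) & set(background))) for t in term_ids]
    rand_counts = np.zeros(len(term_ids))
    for _ in range(n_rand):
        draw = set(bg_arr[rng.choice(N, size=n, replace=False)])
        k_r = np.array([len(m & draw) for m in term_members])
        p_r = _term_pvalues(k_r, n, K, N)
        p_r_sorted = np.sort(p_r)
        rand_counts += np.searchsorted(p_r_sorted, p_obs, side="right")
    fdr = np.minimum(rand_counts / n_rand / n_obs_at, 1.0)
    return pd.Series(fdr, index=obs.index, name="fdr")


@dataclass
class EnrichmentMap:
    """Overrepresented terms x proteins matrix of log2 fold changes."""

    matrix: pd.DataFrame  # NaN where the protein is not annotated to the term
    term_stats: pd.DataFrame  # median_log2fc, neg_log10_p per term
    tree: ClusterTree | None


def build_enrichment_map(
    passing_terms: dict,
    log2fc: pd.Series,
    pvalues: pd.Series | None = None,
    size_range: tuple[int, int] = (5, 500),
) -> EnrichmentMap:
    """Construct the fold-change-annotated functional enrichment map.

    Terms are restricted to those with between 5 and 500 assigned identified
    proteins. Matrix entries are the log2 fold change of each protein
    annotated to each term (NaN elsewhere). For the term-row clustering,
    missing entries are treated as 0 ("no enrichment evidence") during
    distance computation only; the stored matrix keeps them missing.
    """
    lo, hi = size_range
    kept = {}
    for t, members in passing_terms.items():
        ms = sorted(set(members) & set(log2fc.index), key=str)
        if lo <= len(ms) <= hi:
            kept[t] = ms
    if not kept:
        empty = pd.DataFrame(dtype=float)
        return EnrichmentMap(matrix=empty, term_stats=pd.DataFrame(), tree=None)
    proteins = sorted({p for ms in kept.values() for p in ms}, key=str)
    term_ids = sorted(kept)
    mat = pd.DataFrame(np.nan, index=term_ids, columns=proteins)
    for t in term_ids:
        mat.loc[t, kept[t]] = log2fc[kept[t]].to_numpy()
    stats_rows = {
        "median_log2fc": mat.median(axis=1, skipna=True),
    }
    if pvalues is not None:
        with np.errstate(divide="ignore"):
            stats_rows["neg_log10_p"] = -np.log10(pvalues.reindex(term_ids))
    term_stats = pd.DataFrame(stats_rows)
    tree = None
    if len(term_ids) >= 2:
        tree = hclust_complete(mat.fillna(0.0).to_numpy(), labels=term_ids)
    return EnrichmentMap(matrix=mat, term_stats=term_stats, tree=tree)
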