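"""Statistical core: over-representation and contrast tests with FDR control.

Two complementary tests per gene module:

* a one-tailed hypergeometric over-representation test of the overlap
  between the module and a differentially-expressed gene sample, against
  the analyzed gene universe;
* the resampling *contrast test*: the module's mean signed log2 fold minus
  the universe mean fold, with a two-tailed null built from random
  same-size gene subsets of the universe (default 20,000 samplings;
  exhaustive enumeration replaces sampling when the number of distinct
  subsets is small enough to afford exactness).

Multiple-testing control is Storey–Tibshirani q-values (pi0 estimated on a
lambda grid with a cubic-smoother extrapolation) for the module screen and
Benjamini–Hochberg adjustment where a plain FDR step-up is wanted.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: exhaustive enumeration replaces Monte-Carlo when C(N, k) is at most this
EXHAUSTIVE_LIMIT = 10_000

_ABS_TOL = 1e-12  # |sampled contrast| >= |observed| comparisons up to roundoff


def hypergeom_test(
    module: set[str], sample: set[str], universe: set[str]
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns (n_overlap, expected overlap, p) where p = P(X >= n_overlap)
    when |sample| genes are drawn without replacement from |universe|
    containing |module| successes.
    """
    if not universe:
        raise ValueError("empty universe")
    if not module <= set(universe) or not sample <= set(universe):
        raise ValueError("module and sample must be subsets of the universe")
    n_overlap = len(module & sample)
    n_u, n_m, n_s = len(universe), len(module), len(sample)
    expected = n_s * n_m / n_u
    p = float(hypergeom.sf(n_overlap - 1, n_u, n_m, n_s))
    return n_overlap, expected, min(p, 1.0)


@njit(cache=True)
def _mc_extreme_count(
    folds: np.ndarray,
    k: int,
    n_samplings: int,
    obs_abs: float,
    universe_mean: float,
    seed: int,
) -> int:
    """Count random size-k subsets (partial Fisher–Yates draws) whose
    |mean - universe mean| is at least the observed |contrast|."""
    n = folds.size
    idx = np.arange(n)
    np.random.seed(seed)
    count = 0
    for _ in range(n_samplings):
        s = 0.0
        for j in range(k):
            r = j + np.random.randint(0, n - j)
            tmp = idx[j]
            idx[j] = idx[r]
            idx[r] = tmp
            s += folds[idx[j]]
        if abs(s / k - universe_mean) >= obs_abs - 1e-12:
            count += 1
    return count


def contrast_test(
    module: set[str],
    folds: pd.Series,
    n_samplings: int = 20_000,
    seed: int = 0,
    force_monte_carlo: bool = False,
) -> tuple[float, float]:
    """Resampling test of a module's mean fold against the universe mean.

    `folds` maps every universe gene to its signed log2 fold; `module` must
    be a nonempty subset of its index.  The statistic is
    ``mean(fold | module) - mean(fold | universe)`` and the two-tailed p is
    the probability that a uniformly random gene subset of the same size
    shows an at-least-as-extreme absolute contrast.  Monte-Carlo p uses the
    plus-one rule (count+1)/(n_samplings+1) so a finite null never reports
    zero; when C(N, k) <= 10,000 all subsets are enumerated and the p is
    exact.
    """
    if len(module) == 0:
        raise ValueError("module must contain at least one gene")
    arr = folds.to_numpy(dtype=float)
    index = folds.index
    if not set(module) <= set(index):
        raise ValueError("module must be a subset of the fold-table genes")
    k, n = len(module), len(arr)
    if k > n:
        raise ValueError("module larger than the universe")
    universe_mean = float(arr.mean())
    module_mean = float(folds.loc[sorted(module)].mean())
    contrast = module_mean - universe_mean
    obs_abs = abs(contrast)

    if not force_monte_carlo and math.comb(n, k) <= EXHAUSTIVE_LIMIT:
        count = total = 0
        for subset in combinations(range(n), k):
            total += 1
            m = sum(arr[i] for i in subset) / k
            if abs(m - universe_mean) >= obs_abs - _ABS_TOL:
                count += 1
        return contrast, count / total

    sub_seed = int(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, k]).generate_state(1)[0]
        % (2**31)
    )
    count = _mc_extreme_count(arr, k, int(n_samplings), obs_abs, universe_mean, sub_seed)
    return contrast, (count + 1) / (n_samplings + 1)


# ---------------------------------------------------------------------------
# multiple-testing control


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_pi0(pvals, lambdas=None) -> float:
    """Storey–Tibshirani estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid
    0.05..0.90 (step 0.05); a least-squares cubic smoother is extrapolated
    to the largest lambda and the result clamped to (0, 1].  Degenerate
    fits fall back to pi0 = 1.
    """
    p = np.asarray(pvals, dtype=float)
    lambdas = np.arange(0.05, 0.9001, 0.05) if lambdas is None else np.asarray(lambdas)
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    try:
        coef = np.polynomial.polynomial.polyfit(lambdas, pi0_lam, 3)
        pi0 = float(np.polynomial.polynomial.polyval(lambdas.max(), coef))
    except Exception:  # numerically unstable fit
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        logger.warning("pi0 estimate %.3g unstable; falling back to 1.0", pi0)
        pi0 = 1.0
    return min(pi0, 1.0)


def storey_q(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey–Tibshirani q-values.

    q_i = min over {j : p_j >= p_i} of pi0 * m * p_j / rank_j, i.e. the BH
    step-up scaled by the estimated null proportion pi0.  The lambda-grid
    smoother is a large-scale estimator: with fewer than 100 p-values its
    tail extrapolation is dominated by noise, so pi0 = 1 is used there
    (the q-values then equal BH-adjusted values).  `pi0` may be forced
    explicitly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if p.size < 100:
            logger.warning("too few p-values for a stable pi0 estimate: using pi0 = 1")
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    m = p.size
    ranks = np.arange(1, m + 1)
    # (p / (rank/m)) matches the BH step-up's evaluation order exactly,
    # so pi0 = 1 reproduces bh_adjust bit-for-bit
    q_sorted = pi0 * (p[order] / (ranks / m))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# catalog-level driver and classification


def enrich_catalog(
    modules: dict[str, frozenset[str]],
    folds: pd.Series,
    de_sample: set[str],
    n_samplings: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run both tests over a whole module catalog and attach q-values.

    `folds` indexes the analyzed gene universe; `de_sample` is the gene
    sample for the hypergeometric test (conventionally the 2-fold DE set).
    Each module gets an independent derived resampling stream so results
    do not depend on catalog iteration order.

    Returns a DataFrame (index module_id) with columns ``n_module,
    n_overlap, expected, hyper_p, hyper_q, contrast, contrast_p,
    contrast_q, direction``; direction is filled by `classify_modules`
    with its default q < 0.10 rule.
    """
    universe = set(folds.index)
    de_sample = set(de_sample) & universe
    rows = []
    for i, mid in enumerate(sorted(modules)):
        genes = set(modules[mid]) & universe
        if not genes:
            continue
        n_overlap, expected, hp = hypergeom_test(genes, de_sample, universe)
        mod_seed = int(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7919, i]).generate_state(1)[0]
            % (2**31)
        )
        contrast, cp = contrast_test(genes, folds, n_samplings=n_samplings, seed=mod_seed)
        rows.append((mid, len(genes), n_overlap, expected, hp, contrast, cp))
    res = pd.DataFrame(
        rows,
        columns=["module_id", "n_module", "n_overlap", "expected", "hyper_p", "contrast", "contrast_p"],
    ).set_index("module_id")
    if len(res):
        res["hyper_q"] = storey_q(res["hyper_p"].to_numpy())
        res["contrast_q"] = storey_q(res["contrast_p"].to_numpy())
    else:
        res["hyper_q"] = res["contrast_q"] = np.nan
    induced, inhibited = classify_modules(res)
    res["direction"] = "none"
    res.loc[induced, "direction"] = "induced"
    res.loc[inhibited, "direction"] = "inhibited"
    return res[
        ["n_module", "n_overlap", "expected", "hyper_p", "hyper_q",
         "contrast", "contrast_p", "contrast_q", "direction"]
    ]


def classify_modules(
    results: pd.DataFrame, q_threshold: float = 0.10
) -> tuple[list[str], list[str]]:
    """Split modules into induced/inhibited at a contrast-q threshold.

    induced: contrast_q < q_threshold and contrast > 0; inhibited likewise
    with contrast < 0.
    """
    if "contrast_q" not in results:
        raise ValueError("results must carry contrast_q values")
    sig = results["contrast_q"] < q_threshold
    induced = list(results.index[sig & (results["contrast"] > 0)])
    inhibited = list(results.index[sig & (results["contrast"] < 0)])
    return induced, inhibited


def read_enrichment_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="module_id")


def write_enrichment_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t")
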