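"""Cross-study expression-direction concordance.

Given a reference study's most-deregulated genes with their log2 folds and
this study's fold table, each reference gene is classed as

* ``same`` — expressed here with the same fold sign as the reference,
* ``opposite`` — expressed here with the opposite sign,
* ``silent`` — not expressed in this study (absent from the fold table,
  i.e. silent in both conditions, or missing from the count universe).

A gene expressed here with an exactly zero fold has no direction; it is
classed ``none`` and excluded from the binomial test and the correlation
(exact zeros have measure zero on real data).

The prevalence of one direction class over the other is tested with an
exact two-sided binomial test at p = 0.5, and the fold agreement with a
Pearson correlation over the genes carrying folds in both studies.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from scipy.stats import binom, pearsonr

logger = logging.getLogger(__name__)

CLASSES = ("same", "opposite", "silent")


def classify_directions(
    ref_folds: pd.Series | dict, this_folds: pd.DataFrame
) -> pd.DataFrame:
    """One row per reference gene with its concordance class.

    `ref_folds` maps gene id -> reference log2 fold; `this_folds` is this
    study's fold table (index gene_id, column ``log2fold``).  Reference
    genes absent from the fold table are classed silent (logged).
    Returns a DataFrame indexed by gene_id with columns ``log2fold_A,
    log2fold_B, expressed_B, cls``.
    """
    ref = pd.Series(ref_folds, dtype=float)
    if ref.empty:
        raise ValueError("reference fold list is empty")
    rows = []
    n_missing = 0
    for gene, fold_a in ref.items():
        if gene in this_folds.index:
            fold_b = float(this_folds.loc[gene, "log2fold"])
            if np.sign(fold_a) == np.sign(fold_b) != 0:
                cls = "same"
            elif np.sign(fold_b) == 0:
                cls = "none"
            else:
                cls = "opposite"
            rows.append((gene, fold_a, fold_b, True, cls))
        else:
            n_missing += 1
            rows.append((gene, fold_a, np.nan, False, "silent"))
    if n_missing:
        logger.info("%d reference genes not expressed in this study", n_missing)
    return pd.DataFrame(
        rows, columns=["gene_id", "log2fold_A", "log2fold_B", "expressed_B", "cls"]
    ).set_index("gene_id")


def binomial_direction_test(n_same: int, n_opposite: int) -> float:
    """Exact two-sided binomial test of direction-class prevalence.

    Tests the larger of the two counts against p = 0.5 on
    n = n_same + n_opposite trials; two-sided p = 2 * min(tail, 0.5),
    clamped to 1.  Symmetric in its arguments.
    """
    n = n_same + n_opposite
    if n < 1:
        raise ValueError("need at least one gene with a direction call")
    larger = max(n_same, n_opposite)
    tail = float(binom.sf(larger - 1, n, 0.5))
    return min(1.0, 2.0 * min(tail, 0.5))


def fold_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of the two studies' log2 folds.

    Restricted to genes classed same/opposite (silent genes carry no fold
    in this study); requires at least 3 such genes and nonzero variance in
    both fold vectors.
    """
    sub = table[table["cls"].isin(("same", "opposite"))]
    if len(sub) < 3:
        raise ValueError("need at least 3 genes with folds in both studies")
    a = sub["log2fold_A"].to_numpy(dtype=float)
    b = sub["log2fold_B"].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a fold vector")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def concordance_summary(table: pd.DataFrame) -> dict:
    """Counts per class, binomial p (both variants), and fold correlation.

    ``binomial_p`` compares same vs opposite; ``binomial_p_include_silent``
    pools silent genes with the discordant arm (same vs not-same), an
    alternative reading of "changed in the same direction" prevalence.
    """
    counts = {cls: int((table["cls"] == cls).sum()) for cls in CLASSES}
    counts["none"] = int((table["cls"] == "none").sum())
    summary: dict = {"counts": counts, "n_genes": int(len(table))}
    if counts["same"] + counts["opposite"] >= 1:
        summary["binomial_p"] = binomial_direction_test(counts["same"], counts["opposite"])
        summary["binomial_p_include_silent"] = binomial_direction_test(
            counts["same"], counts["opposite"] + counts["silent"]
        )
    try:
        r, p = fold_correlation(table)
        summary["pearson_r"], summary["pearson_p"] = r, p
    except ValueError:
        summary["pearson_r"] = summary["pearson_p"] = None
    return summary


# ---------------------------------------------------------------------------
# i/o


def read_reference_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id")["log2fold"].astype(float)


def write_concordance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
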