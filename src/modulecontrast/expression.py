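"""Count-matrix handling: low-count filtering, normalization, fold changes.

The downstream statistics consume only per-gene signed log2 fold changes
(treated minus control mean on the normalized log2 scale) plus per-condition
expressed/silent flags, so the fold estimator here is a plain group-mean
difference of ``log2(count + 1)``-transformed, normalized values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"
CONDITIONS = (CONTROL, TREATED)

#: columns of a fold table (index: gene_id)
FOLD_COLUMNS = ("log2fold", "expressed_control", "expressed_treated")


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample expression counts with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample id.
    condition
        Series mapping sample id -> ``"control"`` or ``"treated"``; must cover
        every column of `counts`, and both conditions must be nonempty.
    """

    counts: pd.DataFrame
    condition: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("gene and sample identifiers must be unique")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        missing = set(self.counts.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        self.condition = self.condition.loc[self.counts.columns]
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        for cond in CONDITIONS:
            if not (self.condition == cond).any():
                raise ValueError(f"no samples with condition {cond!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, cond: str) -> list[str]:
        return list(self.condition.index[self.condition == cond])

    # --- TSV round trip (counts TSV: first column gene_id; samples TSV:
    # sample_id<TAB>condition) ---

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts=counts, condition=samples["condition"])

    def write_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        self.condition.rename("condition").rename_axis("sample_id").to_csv(
            samples_path, sep="\t"
        )


@dataclass
class ExpressionTable:
    """Normalized expression on the log2 scale (genes x samples)."""

    values: pd.DataFrame
    normalization_method: str


def filter_low_counts(m: CountMatrix, min_count: int = 10) -> CountMatrix:
    """Discard genes whose count is below `min_count` in every sample.

    A gene is retained iff its count is >= `min_count` in at least one
    sample; the sample set is unchanged.  An empty result raises a warning,
    not an error.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep = (m.counts >= min_count).any(axis=1)
    if not keep.any():
        warnings.warn("filter_low_counts removed every gene", stacklevel=2)
    return CountMatrix(counts=m.counts.loc[keep], condition=m.condition)


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Replace each sample's sorted values by the across-sample mean of
    sorted values; ties resolved by average rank (half-ranks interpolate
    between the two adjacent means)."""
    n = values.shape[0]
    sorted_mean = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    df = pd.DataFrame(values)
    for j in range(values.shape[1]):
        ranks = df.iloc[:, j].rank(method="average").to_numpy() - 1.0
        out[:, j] = np.interp(ranks, np.arange(n), sorted_mean)
    return out


def _scale_normalize(values: np.ndarray) -> np.ndarray:
    med = np.median(np.abs(values), axis=0)
    if np.any(med == 0):
        raise ValueError("scale normalization undefined: a sample has zero median absolute level")
    return values * (med.mean() / med)


def _tmm_factors(
    counts: np.ndarray, m_trim: float = 0.30, a_trim: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (M-trim 30%, A-trim 5%).

    The reference sample is the one whose upper-quartile count fraction is
    closest to the across-sample mean.  Factors are normalized to geometric
    mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if np.any(lib == 0):
        raise ValueError("tmm undefined: a sample has all-zero counts")
    uq = np.array(
        [np.quantile(c[c > 0] / l, 0.75) if (c > 0).any() else 0.0 for c, l in zip(counts.T, lib)]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref, lib_ref = counts[:, ref_idx].astype(float), lib[ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs, lib_obs = counts[:, j].astype(float), lib[j]
        mask = (obs > 0) & (ref > 0)
        if not mask.any():
            continue
        o, r = obs[mask], ref[mask]
        m = np.log2((o / lib_obs) / (r / lib_ref))
        a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
        # inverse asymptotic variance weights, then double trim on M and A
        w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
        m_lo, m_hi = np.quantile(m, [m_trim, 1 - m_trim])
        a_lo, a_hi = np.quantile(a, [a_trim, 1 - a_trim])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi) & (w > 0)
        if keep.any():
            factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def normalize(m: CountMatrix, method: str = "quantile") -> ExpressionTable:
    """log2(count + 1) transform followed by cross-sample normalization.

    ``quantile``
        each sample's sorted values are replaced by the across-sample mean of
        sorted values (the multiset of values becomes identical across
        samples);
    ``scale``
        samples rescaled to equal median absolute level;
    ``tmm``
        trimmed-mean-of-M-values scaling factors computed on the raw counts
        and applied as library-size adjustments in log2 space.
    """
    if m.counts.empty:
        raise ValueError("cannot normalize an empty count matrix")
    raw = m.counts.to_numpy(dtype=float)
    logged = np.log2(raw + 1.0)
    if method == "quantile":
        vals = _quantile_normalize(logged)
    elif method == "scale":
        vals = _scale_normalize(logged)
    elif method == "tmm":
        factors = _tmm_factors(raw)
        lib = raw.sum(axis=0) * factors
        vals = logged - np.log2(lib / np.exp(np.mean(np.log(lib))))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    values = pd.DataFrame(vals, index=m.counts.index, columns=m.counts.columns)
    return ExpressionTable(values=values, normalization_method=method)


def compute_folds(
    e: ExpressionTable, m: CountMatrix, expressed_min: int = 10
) -> pd.DataFrame:
    """Per-gene signed log2 fold change plus expressed/silent flags.

    ``log2fold`` is mean(treated) - mean(control) of the normalized log2
    values.  A gene is "expressed" in a condition iff its raw count is
    >= `expressed_min` in at least one sample of that condition.  Genes
    silent in both conditions are dropped.

    Returns a DataFrame indexed by gene_id with columns
    ``log2fold, expressed_control, expressed_treated``.
    """
    ctrl = m.samples_in(CONTROL)
    trt = m.samples_in(TREATED)
    if not ctrl or not trt:
        raise ValueError("both conditions need at least one sample")
    vals = e.values.loc[m.gene_ids]
    log2fold = vals[trt].mean(axis=1) - vals[ctrl].mean(axis=1)
    expressed_control = (m.counts[ctrl] >= expressed_min).any(axis=1)
    expressed_treated = (m.counts[trt] >= expressed_min).any(axis=1)
    folds = pd.DataFrame(
        {
            "log2fold": log2fold,
            "expressed_control": expressed_control,
            "expressed_treated": expressed_treated,
        }
    ).rename_axis("gene_id")
    return folds[expressed_control | expressed_treated]


def select_de(
    folds: pd.DataFrame, fold_threshold: float, strict: bool = False
) -> tuple[set[str], set[str]]:
    """Fold-threshold DE gene sets.

    `fold_threshold` is on the linear scale (2 means two-fold).  With
    ``strict=False`` the comparison is inclusive (|log2fold| >= log2(t),
    used for the 2-fold DE call); ``strict=True`` uses a strict inequality
    ("changed by more than t-fold", used for the 8- and 10-fold network
    selections).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    cut = np.log2(fold_threshold)
    lf = folds["log2fold"]
    if strict:
        up, down = lf > cut, lf < -cut
    else:
        up, down = lf >= cut, lf <= -cut
    return set(folds.index[up]), set(folds.index[down])


def read_folds_tsv(path) -> pd.DataFrame:
    folds = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("expressed_control", "expressed_treated"):
        folds[col] = folds[col].astype(bool)
    return folds


def write_folds_tsv(folds: pd.DataFrame, path) -> None:
    folds.to_csv(path, sep="\t")
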