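"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here with known truth:
a negative-binomial two-condition count matrix with planted up/down gene
modules, a toy acyclic ontology with gene annotations, a planted-partition
protein-interaction network with confidence scores, and a cross-study fold
pair table realizing requested direction-concordance class fractions.

A single integer seed drives all generators; each generator derives an
independent stream from (seed, stream-name) so adding one generator never
perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import CountMatrix, CONTROL, TREATED

GENE_FMT = "G{:05d}"


def derived_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent child stream keyed by a stable hash of `stream`."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


@dataclass
class PlantedModule:
    """Specification of one planted gene module: `size` genes sharing a true
    mean log2 effect `log2_effect` (sign encodes up/down regulation)."""

    module_id: str
    size: int
    log2_effect: float


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic dataset.

    Only the fields a given generator controls are populated; `merge`
    combines truths from several generators into one record.
    """

    seed: int
    planted_module_ids: list[str] = field(default_factory=list)
    module_genes: dict[str, list[str]] = field(default_factory=dict)
    true_log2_fold: dict[str, float] = field(default_factory=dict)
    planted_cluster_assignment: dict[str, int] = field(default_factory=dict)
    planted_hubs: list[str] = field(default_factory=list)
    concordance_class: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "SimulationTruth") -> "SimulationTruth":
        merged = SimulationTruth(seed=self.seed)
        for name in (
            "planted_module_ids",
            "planted_hubs",
        ):
            seen = list(getattr(self, name))
            seen += [x for x in getattr(other, name) if x not in seen]
            setattr(merged, name, seen)
        for name in (
            "module_genes",
            "true_log2_fold",
            "planted_cluster_assignment",
            "concordance_class",
        ):
            setattr(merged, name, {**getattr(self, name), **getattr(other, name)})
        return merged

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# counts


def generate_counts(
    n_genes: int,
    n_per_group: int = 3,
    planted: list[PlantedModule] | None = None,
    baseline_logmean_range: tuple[float, float] = (3.0, 10.0),
    nb_dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Two-condition negative-binomial count matrix with planted modules.

    Counts for gene g, sample s are NB with mean
    ``2**(baseline_g +/- effect_g / 2)`` (the planted log2 effect is split
    symmetrically between the two conditions so library sizes stay
    comparable) and variance ``mu + nb_dispersion * mu**2``.  Baseline log2
    means are uniform on `baseline_logmean_range`.  Planted modules claim
    disjoint random gene sets; overlap of requested sizes beyond `n_genes`
    is an error.
    """
    planted = planted or []
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    total_planted = sum(p.size for p in planted)
    if total_planted > n_genes:
        raise ValueError("planted modules need more genes than n_genes provides")
    if len({p.module_id for p in planted}) != len(planted):
        raise ValueError("planted module ids must be unique (disjoint sets)")

    rng = derived_rng(seed, "counts")
    genes = [GENE_FMT.format(i) for i in range(n_genes)]
    pool = rng.permutation(n_genes)
    truth = SimulationTruth(seed=seed)
    effect = np.zeros(n_genes)
    cursor = 0
    for mod in planted:
        idx = np.sort(pool[cursor : cursor + mod.size])
        cursor += mod.size
        members = [genes[i] for i in idx]
        truth.planted_module_ids.append(mod.module_id)
        truth.module_genes[mod.module_id] = members
        effect[idx] = mod.log2_effect
    truth.true_log2_fold = {g: float(e) for g, e in zip(genes, effect)}

    lo, hi = baseline_logmean_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    n_nb = 1.0 / nb_dispersion  # numpy NB(n, p): mean n(1-p)/p, var mean + mean^2/n
    cols, names, conds = [], [], []
    for cond, sign, tag in ((CONTROL, -0.5, "ctrl"), (TREATED, +0.5, "treat")):
        mu = 2.0 ** (baseline + sign * effect)
        p_nb = n_nb / (n_nb + mu)
        for r in range(n_per_group):
            cols.append(rng.negative_binomial(n_nb, p_nb))
            names.append(f"{tag}_{r + 1}")
            conds.append(cond)
    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene_id"), columns=names
    )
    condition = pd.Series(conds, index=pd.Index(names, name="sample_id"))
    return CountMatrix(counts=counts, condition=condition), truth


# ---------------------------------------------------------------------------
# ontology


def generate_ontology(
    n_leaves: int,
    depth: int,
    genes_per_leaf: int = 10,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Toy acyclic ontology (child -> parent edges) plus gene annotations.

    Layer 0 is a single root; layer `depth` holds the `n_leaves` leaves,
    each annotated with `genes_per_leaf` genes.  Nodes may take a second
    parent from the layer above, producing diamonds.  When `n_leaves` > 1 a
    pass-through category with a single leaf child is added so at least one
    pair of categories always shares an identical propagated gene set.

    `genes` optionally supplies the gene-id pool (length >= n_leaves *
    genes_per_leaf); by default sequential synthetic ids are used.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = derived_rng(seed, "ontology")
    root = "CAT:ROOT"
    layers: list[list[str]] = [[root]]
    for level in range(1, depth):
        width = max(1, int(round(n_leaves * level / depth)))
        layers.append([f"CAT:L{level}:{i}" for i in range(width)])
    layers.append([f"CAT:LEAF:{i}" for i in range(n_leaves)])

    edges: list[tuple[str, str]] = []
    for level in range(1, depth + 1):
        above = layers[level - 1]
        for node in layers[level]:
            parents = {above[rng.integers(len(above))]}
            if len(above) > 1 and rng.random() < 0.3:
                parents.add(above[rng.integers(len(above))])
            edges.extend((node, p) for p in sorted(parents))
    if n_leaves > 1:  # guaranteed duplicate propagated set for dedup testing
        edges.append((layers[depth][0], "CAT:PASSTHROUGH"))
        edges.append(("CAT:PASSTHROUGH", root))

    need = n_leaves * genes_per_leaf
    if genes is None:
        pool = [GENE_FMT.format(i) for i in range(need)]
    else:
        if len(genes) < need:
            raise ValueError("gene pool smaller than n_leaves * genes_per_leaf")
        pool = [genes[i] for i in rng.permutation(len(genes))[:need]]
    annotations = [
        (pool[i * genes_per_leaf + j], leaf)
        for i, leaf in enumerate(layers[depth])
        for j in range(genes_per_leaf)
    ]
    return edges, annotations


# ---------------------------------------------------------------------------
# protein-interaction network


def generate_ppi(
    n_proteins: int,
    n_clusters: int,
    p_within: float = 0.9,
    p_between: float = 0.05,
    score_high: tuple[float, float] = (0.91, 1.0),
    score_low: tuple[float, float] = (0.40, 0.90),
    seed: int = 0,
    node_ids: list[str] | None = None,
) -> tuple[list[tuple[str, str, float]], SimulationTruth]:
    """Planted-partition interaction graph with confidence scores.

    Proteins are split into `n_clusters` near-equal blocks; each
    within-block pair gets an edge with probability `p_within` (score
    uniform on `score_high`), each between-block pair with probability
    `p_between` (score uniform on `score_low`).  Truth records the block
    assignment and the hub set (degree strictly greater than 5).
    """
    if not (0 <= p_between < p_within <= 1):
        raise ValueError("require 0 <= p_between < p_within <= 1")
    if node_ids is not None:
        if len(node_ids) != n_proteins:
            raise ValueError("node_ids length must equal n_proteins")
        nodes = list(node_ids)
    else:
        nodes = [f"P{i:04d}" for i in range(n_proteins)]
    rng = derived_rng(seed, "ppi")
    blocks = np.array_split(np.arange(n_proteins), n_clusters)
    cluster = np.empty(n_proteins, dtype=int)
    for c, blk in enumerate(blocks):
        cluster[blk] = c
    edges: list[tuple[str, str, float]] = []
    degree = np.zeros(n_proteins, dtype=int)
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            within = cluster[i] == cluster[j]
            if rng.random() < (p_within if within else p_between):
                lo, hi = score_high if within else score_low
                edges.append((nodes[i], nodes[j], float(rng.uniform(lo, hi))))
                degree[i] += 1
                degree[j] += 1
    truth = SimulationTruth(
        seed=seed,
        planted_cluster_assignment={nodes[i]: int(cluster[i]) for i in range(n_proteins)},
        planted_hubs=[nodes[i] for i in range(n_proteins) if degree[i] > 5],
    )
    return edges, truth


# ---------------------------------------------------------------------------
# cross-study fold pairs


def _largest_remainder(n: int, fracs: list[float]) -> list[int]:
    raw = [n * f for f in fracs]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(fracs)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_cross_study(
    n_genes: int,
    frac_same: float,
    frac_opposite: float,
    frac_silent: float,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Cross-study fold pair table realizing exact class counts.

    Emits one row per reference-study gene with its reference log2 fold
    (`log2fold_A`), this study's log2 fold (`log2fold_B`, NaN when silent),
    and the expressed flag.  Class counts are the requested fractions
    resolved to integers by largest remainder, so e.g. fractions
    (21/123, 42/123, 60/123) at n=123 give exactly (21, 42, 60).
    """
    fracs = [frac_same, frac_opposite, frac_silent]
    if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("class fractions must be >= 0 and sum to 1")
    rng = derived_rng(seed, "cross_study")
    n_same, n_opp, n_sil = _largest_remainder(n_genes, fracs)
    classes = ["same"] * n_same + ["opposite"] * n_opp + ["silent"] * n_sil
    if gene_ids is None:
        gene_ids = [f"REF{i:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    sign_a = rng.choice([-1.0, 1.0], size=n_genes)
    mag_a = rng.uniform(1.0, 4.0, size=n_genes)
    mag_b = rng.uniform(0.5, 4.0, size=n_genes)
    rows = []
    truth = SimulationTruth(seed=seed)
    for g, cls, sa, ma, mb in zip(gene_ids, classes, sign_a, mag_a, mag_b):
        fold_a = sa * ma
        if cls == "same":
            fold_b, expressed = sa * mb, True
        elif cls == "opposite":
            fold_b, expressed = -sa * mb, True
        else:
            fold_b, expressed = np.nan, False
        rows.append((g, fold_a, fold_b, expressed))
        truth.concordance_class[g] = cls
    table = pd.DataFrame(
        rows, columns=["gene_id", "log2fold_A", "log2fold_B", "expressed_B"]
    ).set_index("gene_id")
    return table, truth


# ---------------------------------------------------------------------------
# plain-text writers


def write_ontology_tsv(edges, path) -> None:
    pd.DataFrame(edges, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def write_annotations_tsv(annotations, path) -> None:
    pd.DataFrame(annotations, columns=["gene_id", "category_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_ppi_tsv(edges, path) -> None:
    pd.DataFrame(edges, columns=["protein1", "protein2", "score"]).to_csv(
        path, sep="\t", index=False
    )
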