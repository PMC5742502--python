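"""Gene-module catalog: ontology annotation propagation and deduplication.

A gene belongs to an ontology category if it is annotated to that category
or to any of its descendants (the true-path rule on an acyclic child->parent
graph).  Flat pathway collections (GMT) are merged in afterwards.  Entries
with identical gene sets are united — identical observable sets are
statistically indistinguishable, so redundancy is removed both after
propagation and again after restriction to the analyzed gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass
class ModuleCatalog:
    """Named gene sets after propagation/merging and deduplication.

    `modules` maps module id -> gene set; a united entry's id is its source
    ids joined by ``|`` in lexicographic order, and `provenance` lists those
    sources.  `universe` is the gene background enrichment is computed
    against.
    """

    modules: dict[str, frozenset[str]]
    provenance: dict[str, tuple[str, ...]]
    universe: frozenset[str]

    def __len__(self) -> int:
        return len(self.modules)


def _dedupe(
    modules: dict[str, frozenset[str]], provenance: dict[str, tuple[str, ...]]
) -> tuple[dict[str, frozenset[str]], dict[str, tuple[str, ...]]]:
    by_set: dict[frozenset[str], list[str]] = {}
    for mid, genes in modules.items():
        by_set.setdefault(genes, []).extend(provenance.get(mid, (mid,)))
    out_mod, out_prov = {}, {}
    for genes, sources in by_set.items():
        sources = tuple(sorted(set(sources)))
        mid = "|".join(sources)
        out_mod[mid] = genes
        out_prov[mid] = sources
    return out_mod, out_prov


def build_ontology(edges: list[tuple[str, str]]) -> nx.DiGraph:
    """Directed child -> parent graph; raises on cycles, naming one edge."""
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        child, parent = next(iter(nx.find_cycle(g)))[:2]
        raise ValueError(f"ontology contains a cycle through edge {child} -> {parent}")
    return g


def propagate_annotations(
    ontology: nx.DiGraph | list[tuple[str, str]],
    annotations: list[tuple[str, str]],
) -> ModuleCatalog:
    """Propagate gene annotations up the ontology.

    module(C) = { g : g annotated to C or to any descendant of C }.
    Categories with empty propagated sets are dropped; identical propagated
    sets are united.  Every annotated category must exist in the ontology.
    """
    g = ontology if isinstance(ontology, nx.DiGraph) else build_ontology(ontology)
    direct: dict[str, set[str]] = {}
    for gene, cat in annotations:
        if cat not in g:
            raise ValueError(f"annotated category {cat!r} not in ontology")
        direct.setdefault(cat, set()).add(gene)
    sets: dict[str, set[str]] = {n: set(direct.get(n, ())) for n in g.nodes}
    # child->parent edges: children precede parents in topological order,
    # so one pass accumulates each node's descendants' genes
    for node in nx.topological_sort(g):
        for parent in g.successors(node):
            sets[parent] |= sets[node]
    modules = {c: frozenset(s) for c, s in sets.items() if s}
    provenance = {c: (c,) for c in modules}
    modules, provenance = _dedupe(modules, provenance)
    universe = frozenset().union(*modules.values()) if modules else frozenset()
    return ModuleCatalog(modules=modules, provenance=provenance, universe=universe)


def merge_flat_pathways(
    c: ModuleCatalog, gmt: dict[str, set[str]]
) -> ModuleCatalog:
    """Union the catalog with flat pathway gene sets, then deduplicate."""
    modules = {mid: frozenset(genes) for mid, genes in gmt.items() if genes}
    clash = set(modules) & set(c.modules)
    if clash:
        raise ValueError(f"pathway ids collide with catalog ids: {sorted(clash)[:5]}")
    merged = {**c.modules, **modules}
    provenance = {**c.provenance, **{mid: (mid,) for mid in modules}}
    merged, provenance = _dedupe(merged, provenance)
    universe = c.universe | frozenset().union(*modules.values()) if modules else c.universe
    return ModuleCatalog(modules=merged, provenance=provenance, universe=universe)


def restrict_to_universe(
    c: ModuleCatalog,
    universe: set[str],
    min_size: int = 5,
    max_size: int = 2000,
) -> ModuleCatalog:
    """Intersect every module with the analyzed gene universe.

    Modules falling outside [min_size, max_size] after intersection are
    dropped and deduplication is re-applied (two modules may become
    identical once restricted).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not universe:
        raise ValueError("empty universe")
    universe = frozenset(universe)
    modules, provenance = {}, {}
    for mid, genes in c.modules.items():
        cut = genes & universe
        if min_size <= len(cut) <= max_size:
            modules[mid] = cut
            provenance[mid] = c.provenance[mid]
    modules, provenance = _dedupe(modules, provenance)
    return ModuleCatalog(modules=modules, provenance=provenance, universe=universe)


# ---------------------------------------------------------------------------
# GMT i/o (set_id<TAB>description<TAB>gene1<TAB>gene2...)


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(modules: dict[str, frozenset[str] | set[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for mid in sorted(modules):
            desc = descriptions.get(mid, "na")
            fh.write("\t".join([mid, desc, *sorted(modules[mid])]) + "\n")


def read_ontology_tsv(path) -> list[tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))


def read_annotations_tsv(path) -> list[tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))
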