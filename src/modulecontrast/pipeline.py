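"""End-to-end pipeline: counts -> folds -> module enrichment -> networks ->
cross-study concordance, from one config, with a JSON run report.

In ``simulate`` mode every input is generated by the synthetic module with
planted ground truth (written alongside the outputs); otherwise inputs are
read from the configured paths.  All stage outputs are plain-text TSV/GMT/
JSON files under the output directory, and every count in the report is
recomputable from those files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import catalog as cat
from . import concordance as conc
from . import enrichment as enr
from . import expression as expr
from . import network as net
from . import synthetic as syn

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("quantile", "scale", "tmm")


@dataclass
class SimulationParams:
    """Shape of the synthetic experiment (defaults mirror the planted-module
    recovery conditions: a 10,000-gene 3v3 negative-binomial experiment with
    20 up- and 4 down-regulated modules of 50 genes at |log2 effect| 2, plus
    one strongly induced and one strongly inhibited module whose genes
    exceed the 8-fold network cutoff)."""

    n_genes: int = 10_000
    n_per_group: int = 3
    n_up_modules: int = 20
    n_down_modules: int = 4
    module_size: int = 50
    log2_effect: float = 2.0
    strong_module_size: int = 60
    strong_log2_effect: float = 4.0
    nb_dispersion: float = 0.1
    baseline_logmean_range: tuple[float, float] = (3.0, 10.0)
    n_null_pathways: int = 80
    null_pathway_sizes: tuple[int, int] = (10, 100)
    ontology_leaves: int = 12
    ontology_depth: int = 3
    genes_per_leaf: int = 30
    ppi_clusters: int = 3
    ppi_p_within: float = 0.9
    ppi_p_between: float = 0.05
    n_reference_genes: int = 123
    frac_same: float = 21 / 123
    frac_opposite: float = 42 / 123
    frac_silent: float = 60 / 123


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run.

    Thresholds default to the analysis conventions: low-count filter at 10,
    quantile normalization, 2-fold DE call (inclusive), strict 8-fold
    network selection and strict 10-fold tally, interaction stringency
    S > 0.9 (0.7 for marker panels), 20,000 contrast resamplings, module
    call at q < 0.10 with a secondary p < 0.01 / q < 0.15 regime.
    """

    counts_path: str | None = None
    samples_path: str | None = None
    ontology_path: str | None = None
    annotations_path: str | None = None
    gmt_path: str | None = None
    ppi_path: str | None = None
    reference_path: str | None = None
    simulate: bool = False
    min_count: int = 10
    expressed_min: int = 10
    normalization: str = "quantile"
    de_fold: float = 2.0
    network_fold: float = 8.0
    ten_fold: float = 10.0
    network_select: str = "fold"  # or "quantile"
    network_quantile: float = 0.25
    score_min: float = 0.9
    score_min_markers: float = 0.7
    n_samplings: int = 20_000
    q_threshold: float = 0.10
    alt_p_threshold: float = 0.01
    alt_q_threshold: float = 0.15
    min_module_size: int = 5
    max_module_size: int = 2000
    k: int | None = None
    seed: int = 0
    sim: SimulationParams = field(default_factory=SimulationParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationParams(**raw.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of violated-invariant messages (empty iff valid)."""
    v = []
    if cfg.min_count < 0:
        v.append("min_count: must be >= 0")
    for name in ("de_fold", "network_fold", "ten_fold"):
        if getattr(cfg, name) <= 1:
            v.append(f"{name}: fold thresholds must be > 1")
    if not (0 < cfg.q_threshold < 1):
        v.append("q_threshold: must lie in (0, 1)")
    if not (0 < cfg.alt_q_threshold < 1):
        v.append("alt_q_threshold: must lie in (0, 1)")
    if not (0 < cfg.alt_p_threshold < 1):
        v.append("alt_p_threshold: must lie in (0, 1)")
    if cfg.n_samplings < 1:
        v.append("n_samplings: must be >= 1")
    for name in ("score_min", "score_min_markers"):
        if not (0 <= getattr(cfg, name) < 1):
            v.append(f"{name}: must lie in [0, 1)")
    if cfg.normalization not in NORMALIZATIONS:
        v.append(f"normalization: must be one of {NORMALIZATIONS}")
    if cfg.network_select not in ("fold", "quantile"):
        v.append("network_select: must be 'fold' or 'quantile'")
    if cfg.min_module_size < 1:
        v.append("min_module_size: must be >= 1")
    if cfg.k is not None and cfg.k < 1:
        v.append("k: must be >= 1")
    if not cfg.simulate:
        for name in ("counts_path", "samples_path"):
            if getattr(cfg, name) is None:
                v.append(f"{name}: required unless simulate is set")
    return v


# ---------------------------------------------------------------------------
# synthetic input assembly


def _planted_modules(sim: SimulationParams) -> list[syn.PlantedModule]:
    mods = [
        syn.PlantedModule(f"UP{i:02d}", sim.module_size, sim.log2_effect)
        for i in range(sim.n_up_modules)
    ]
    mods += [
        syn.PlantedModule(f"DOWN{i:02d}", sim.module_size, -sim.log2_effect)
        for i in range(sim.n_down_modules)
    ]
    if sim.strong_module_size > 0:
        mods.append(
            syn.PlantedModule("STRONG_UP", sim.strong_module_size, sim.strong_log2_effect)
        )
        mods.append(
            syn.PlantedModule("STRONG_DOWN", sim.strong_module_size, -sim.strong_log2_effect)
        )
    return mods


def _null_pathways(sim: SimulationParams, genes: list[str], seed: int) -> dict[str, set[str]]:
    rng = syn.derived_rng(seed, "null_pathways")
    lo, hi = sim.null_pathway_sizes
    out = {}
    for i in range(sim.n_null_pathways):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        out[f"NULL{i:03d}"] = {genes[j] for j in idx}
    return out


def make_reference_study(
    folds: pd.DataFrame,
    counts: expr.CountMatrix | None,
    n_genes: int,
    frac_same: float,
    frac_opposite: float,
    frac_silent: float,
    seed: int,
) -> pd.Series:
    """Reference-study fold list that realizes the requested concordance
    class fractions against this study's actual folds.

    Genes for the same/opposite classes are drawn from the fold table with
    reference fold signs set to agree/disagree with the observed signs;
    silent-class rows prefer genes present in the counts but absent from
    the fold table (silent in both conditions), topping up with foreign
    gene ids when too few exist.
    """
    rng = syn.derived_rng(seed, "reference_study")
    n_same, n_opp, n_sil = syn._largest_remainder(
        n_genes, [frac_same, frac_opposite, frac_silent]
    )
    candidates = folds.index[folds["log2fold"] != 0.0].to_numpy()
    if n_same + n_opp > len(candidates):
        raise ValueError("not enough genes with nonzero folds for the reference list")
    chosen = rng.choice(len(candidates), size=n_same + n_opp, replace=False)
    genes = candidates[chosen]
    mags = rng.uniform(1.0, 4.0, size=n_genes)
    ref = {}
    for i, g in enumerate(genes[:n_same]):
        ref[g] = float(np.sign(folds.loc[g, "log2fold"]) * mags[i])
    for i, g in enumerate(genes[n_same:], start=n_same):
        ref[g] = float(-np.sign(folds.loc[g, "log2fold"]) * mags[i])
    silent_pool = []
    if counts is not None:
        silent_pool = [g for g in counts.gene_ids if g not in folds.index]
    rng.shuffle(silent_pool)
    for i in range(n_sil):
        g = silent_pool[i] if i < len(silent_pool) else f"FOREIGN{i:04d}"
        ref[g] = float(rng.choice([-1.0, 1.0]) * mags[n_same + n_opp + i])
    return pd.Series(ref, name="log2fold").rename_axis("gene_id")


# ---------------------------------------------------------------------------
# the run


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute every stage and return the run report (also written as
    ``report.json``; timestamps live under their own key so two runs with
    the same seed are otherwise byte-identical)."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
    }

    # --- inputs -----------------------------------------------------------
    truth = syn.SimulationTruth(seed=cfg.seed)
    if cfg.simulate:
        counts, truth_counts = syn.generate_counts(
            n_genes=cfg.sim.n_genes,
            n_per_group=cfg.sim.n_per_group,
            planted=_planted_modules(cfg.sim),
            baseline_logmean_range=cfg.sim.baseline_logmean_range,
            nb_dispersion=cfg.sim.nb_dispersion,
            seed=cfg.seed,
        )
        truth = truth.merge(truth_counts)
        counts.write_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
        genes = list(counts.gene_ids)
        onto_edges, annotations = syn.generate_ontology(
            n_leaves=cfg.sim.ontology_leaves,
            depth=cfg.sim.ontology_depth,
            genes_per_leaf=cfg.sim.genes_per_leaf,
            seed=cfg.seed,
            genes=genes,
        )
        syn.write_ontology_tsv(onto_edges, outdir / "ontology.tsv")
        syn.write_annotations_tsv(annotations, outdir / "annotations.tsv")
        gmt = {**truth.module_genes, **_null_pathways(cfg.sim, genes, cfg.seed)}
        cat.write_gmt(gmt, outdir / "pathways.gmt")
    else:
        counts = expr.CountMatrix.read_tsv(cfg.counts_path, cfg.samples_path)
        onto_edges = (
            cat.read_ontology_tsv(cfg.ontology_path) if cfg.ontology_path else []
        )
        annotations = (
            cat.read_annotations_tsv(cfg.annotations_path) if cfg.annotations_path else []
        )
        gmt = cat.read_gmt(cfg.gmt_path) if cfg.gmt_path else {}

    report["n_genes_input"] = int(counts.counts.shape[0])
    report["n_samples"] = int(counts.counts.shape[1])

    # --- expression -------------------------------------------------------
    filtered = expr.filter_low_counts(counts, min_count=cfg.min_count)
    report["n_genes_analyzed"] = int(filtered.counts.shape[0])
    table = expr.normalize(filtered, method=cfg.normalization)
    folds = expr.compute_folds(table, filtered, expressed_min=cfg.expressed_min)
    expr.write_folds_tsv(folds, outdir / "folds.tsv")
    report["n_genes_with_folds"] = int(len(folds))

    up2, down2 = expr.select_de(folds, cfg.de_fold, strict=False)
    up10, down10 = expr.select_de(folds, cfg.ten_fold, strict=True)
    report["de_counts"] = {
        "up_2fold": len(up2),
        "down_2fold": len(down2),
        "total_2fold": len(up2) + len(down2),
        "up_10fold": len(up10),
        "down_10fold": len(down10),
    }

    # --- module catalog ---------------------------------------------------
    universe = set(folds.index)
    if onto_edges and annotations:
        catalog = cat.propagate_annotations(onto_edges, annotations)
    else:
        catalog = cat.ModuleCatalog(modules={}, provenance={}, universe=frozenset())
    catalog = cat.merge_flat_pathways(catalog, gmt)
    catalog = cat.restrict_to_universe(
        catalog, universe, min_size=cfg.min_module_size, max_size=cfg.max_module_size
    )
    cat.write_gmt(catalog.modules, outdir / "catalog.gmt")
    report["n_modules"] = len(catalog)

    # --- enrichment -------------------------------------------------------
    results = enr.enrich_catalog(
        catalog.modules,
        folds["log2fold"],
        de_sample=up2 | down2,
        n_samplings=cfg.n_samplings,
        seed=cfg.seed,
    )
    induced, inhibited = enr.classify_modules(results, q_threshold=cfg.q_threshold)
    results["direction"] = "none"
    results.loc[induced, "direction"] = "induced"
    results.loc[inhibited, "direction"] = "inhibited"
    enr.write_enrichment_tsv(results, outdir / "enrichment.tsv")
    report["modules"] = {
        "n_induced": len(induced),
        "n_inhibited": len(inhibited),
        "induced_fraction": (
            len(induced) / (len(induced) + len(inhibited))
            if induced or inhibited
            else None
        ),
        "induced_inhibited_ratio": (
            len(induced) / len(inhibited) if inhibited else None
        ),
    }

    # --- networks ---------------------------------------------------------
    up_net, down_net = expr.select_de(folds, cfg.network_fold, strict=True)
    if cfg.network_select == "quantile":
        up_net, down_net = net.select_network_genes(
            folds, mode="quantile", quantile=cfg.network_quantile
        )
    report["network_selection"] = {"up": len(up_net), "down": len(down_net)}

    if cfg.simulate:
        ppi_edges = []
        for tag, nodes in (("up", sorted(up_net)), ("down", sorted(down_net))):
            if len(nodes) >= cfg.sim.ppi_clusters:
                edges, truth_ppi = syn.generate_ppi(
                    n_proteins=len(nodes),
                    n_clusters=cfg.sim.ppi_clusters,
                    p_within=cfg.sim.ppi_p_within,
                    p_between=cfg.sim.ppi_p_between,
                    seed=cfg.seed + (0 if tag == "up" else 1),
                    node_ids=nodes,
                )
                ppi_edges += edges
                truth = truth.merge(truth_ppi)
        syn.write_ppi_tsv(ppi_edges, outdir / "ppi.tsv")
        ppi_source = ppi_edges
    else:
        ppi_source = cfg.ppi_path

    report["networks"] = {}
    if ppi_source is not None and (cfg.simulate or cfg.ppi_path):
        for tag, nodes in (("induced", up_net), ("inhibited", down_net)):
            g = net.load_graph(ppi_source, cfg.score_min, node_subset=nodes)
            comps = net.connected_components(g)
            hubs = net.find_hubs(g)
            sub = outdir / f"network_{tag}"
            sub.mkdir(exist_ok=True)
            net.write_components_tsv(comps, sub / "components.tsv")
            net.write_hubs_tsv(g, sub / "hubs.tsv")
            entry = {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "n_components": len(comps),
                "largest_component": len(comps[0]) if comps else 0,
                "hubs": sorted(hubs),
            }
            k = cfg.k or net.default_k(g)
            if 1 <= k <= g.number_of_nodes() and g.number_of_nodes() > 0:
                clustering = net.kmeans_cluster(g, k, seed=cfg.seed)
                clustering = net.annotate_clusters(
                    clustering, catalog.modules, universe
                )
                net.write_clusters_tsv(clustering, sub / "clusters.tsv")
                net.write_cluster_annotations_tsv(
                    clustering, sub / "cluster_annotations.tsv"
                )
                entry["k"] = k
                entry["n_annotated_clusters"] = sum(
                    1 for df in clustering.annotations.values() if len(df)
                )
            report["networks"][tag] = entry

    # --- cross-study concordance -----------------------------------------
    if cfg.simulate:
        ref = make_reference_study(
            folds,
            counts,
            cfg.sim.n_reference_genes,
            cfg.sim.frac_same,
            cfg.sim.frac_opposite,
            cfg.sim.frac_silent,
            seed=cfg.seed,
        )
        ref.reset_index().to_csv(outdir / "reference_folds.tsv", sep="\t", index=False)
    elif cfg.reference_path:
        ref = conc.read_reference_tsv(cfg.reference_path)
    else:
        ref = None
    if ref is not None:
        table = conc.classify_directions(ref, folds)
        conc.write_concordance_tsv(table, outdir / "concordance.tsv")
        summary = conc.concordance_summary(table)
        conc.write_summary_json(summary, outdir / "concordance_summary.json")
        report["concordance"] = summary

    if cfg.simulate:
        truth.to_json(outdir / "truth.json")

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    # timestamps go to a sidecar so report.json is seed-deterministic
    with open(outdir / "report_timestamps.json", "w") as fh:
        json.dump(
            {"started": t_start, "finished": time.time()}, fh, indent=1
        )
    logger.info("pipeline finished; report at %s", report_path)
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"] = dataclasses.asdict(cfg.sim)
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    for key, val in list(d["sim"].items()):
        if isinstance(val, tuple):
            d["sim"][key] = list(val)
    return d
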