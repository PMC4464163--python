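"""End-to-end orchestration: DEG calling -> network filter -> TF ranking ->
clustering -> cross-condition comparison, with a run manifest.

Each contrast is induced-vs-uninduced within one genotype (the usual design
for a treatment study with genotype strata); a genotype-vs-genotype contrast
can be expressed in the config but is not the default.  Every count class a
user would want to compare against a published analysis (DEGs per contrast,
retained interaction pairs, TFs tested, significant TFs) is logged at INFO
and recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .clustering import Dendrogram, two_way_cluster, write_dendrogram
from .deg_stats import call_degs, run_gene_tests
from .errors import ConsistencyError, RegulonRankError
from .io_formats import (
    ExpressionMatrix,
    RegulatoryNetwork,
    read_expression_table,
    read_network_pairs,
    write_results_table,
)
from .regnet import ActiveSubnetwork, filter_active_pairs, tf_target_sets, \
    write_active_subnetwork
from .synthetic_data import SyntheticConfig, generate_study
from .tf_enrichment import (
    TFEnrichmentResult,
    compare_conditions,
    rank_tfs,
    RESULT_COLUMNS as TF_COLUMNS,
)

logger = logging.getLogger(__name__)


@dataclass
class Contrast:
    genotype: str
    treated: str = "caerulein"
    control: str = "saline"

    @property
    def name(self) -> str:
        return f"{self.genotype}_{self.treated}_vs_{self.control}"


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on, loadable from YAML."""

    matrix_path: str | None = None
    design_path: str | None = None
    network_path: str | None = None
    synthetic: SyntheticConfig | None = None
    contrasts: list[Contrast] = field(default_factory=list)
    deg_alpha: float = 0.05
    threshold_on: str = "p"
    tf_alpha: float = 0.01
    fisher_alternative: str = "two-sided"
    pair_rule: str = "either"
    distance: str = "euclidean"
    linkage: str = "complete"
    top_k: int = 10
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_alpha", "tf_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        has_files = self.matrix_path and self.design_path and self.network_path
        if not has_files and self.synthetic is None:
            raise ValueError(
                "config needs either matrix/design/network paths or a "
                "synthetic block"
            )
        self.contrasts = [
            c if isinstance(c, Contrast) else Contrast(**c) for c in self.contrasts
        ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "targets_per_tf" in syn:
                syn["targets_per_tf"] = tuple(syn["targets_per_tf"])
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)


@dataclass
class ContrastResult:
    contrast: Contrast
    deg_table: Any                       # per-gene DataFrame
    degs: set[str]
    subnetwork: ActiveSubnetwork
    ranking: list[TFEnrichmentResult]
    row_dendrogram: Dendrogram | None
    col_dendrogram: Dendrogram | None


@dataclass
class PipelineResult:
    contrasts: dict[str, ContrastResult]
    comparison: dict[str, list[str]] | None
    manifest: dict[str, Any]
    out_dir: Path


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RegulonRankError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Guard()


def _load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, RegulatoryNetwork, dict[str, Any]]:
    truth: dict[str, Any] = {}
    if config.matrix_path:
        em = read_expression_table(config.matrix_path, config.design_path)
        network = read_network_pairs(
            config.network_path, universe=set(em.gene_ids)
        )
    else:
        syn = config.synthetic
        assert syn is not None
        bundle = generate_study(syn)
        em, network = bundle.expression, bundle.network
        truth = {
            "truth_degs": {k: sorted(v) for k, v in bundle.truth_degs.items()},
            "active_tfs": sorted(bundle.active_tfs),
        }
    return em, network, truth


def _default_contrasts(em: ExpressionMatrix) -> list[Contrast]:
    out = []
    for genotype in dict.fromkeys(em.design["genotype"]):
        treatments = set(em.design.loc[em.design["genotype"] == genotype,
                                       "treatment"])
        if {"caerulein", "saline"} <= treatments:
            out.append(Contrast(genotype, "caerulein", "saline"))
        elif len(treatments) == 2:
            treated, control = sorted(treatments)
            out.append(Contrast(genotype, treated, control))
    if not out:
        raise ConsistencyError("could not derive any contrast from the design")
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage for every contrast and write the result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load_inputs"):
        em, network, truth = _load_inputs(config)
    contrasts = config.contrasts or _default_contrasts(em)
    for c in contrasts:
        if not em.group_samples(c.genotype, c.treated) or not em.group_samples(
            c.genotype, c.control
        ):
            raise ConsistencyError(
                f"contrast {c.name} references groups absent from the design"
            )

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "deg_alpha": config.deg_alpha,
        "threshold_on": config.threshold_on,
        "tf_alpha": config.tf_alpha,
        "fisher_alternative": config.fisher_alternative,
        "pair_rule": config.pair_rule,
        "fdr_method": "benjamini-hochberg",
        "n_genes": em.n_genes,
        "n_samples": em.n_samples,
        "n_network_pairs": network.n_pairs,
        "contrasts": {},
    }
    results: dict[str, ContrastResult] = {}
    for c in contrasts:
        with _stage(f"deg_stats[{c.name}]"):
            induced = em.group_samples(c.genotype, c.treated)
            uninduced = em.group_samples(c.genotype, c.control)
            table = run_gene_tests(
                em, induced, uninduced,
                deg_alpha=config.deg_alpha, threshold_on=config.threshold_on,
            )
            degs = call_degs(table, config.deg_alpha, config.threshold_on)
            logger.info("%s: %d DEGs of %d genes", c.name, len(degs),
                        em.n_genes)
            table.to_csv(out_dir / f"degs_{c.name}.tsv", sep="\t", index=False)

        with _stage(f"regnet[{c.name}]"):
            sub = filter_active_pairs(network, degs, rule=config.pair_rule)
            write_active_subnetwork(
                sub,
                out_dir / f"active_edges_{c.name}.tsv",
                out_dir / f"active_nodes_{c.name}.tsv",
            )
            # TFs entering the ranking are those present in the active
            # subnetwork, but each is tested with its FULL regulon from the
            # whole network (the b cell counts non-DEG targets too)
            full_sets = tf_target_sets(network)
            active_tf_ids = {tf for tf, _ in sub.pairs}
            tf_sets = {tf: full_sets[tf] for tf in active_tf_ids}

        with _stage(f"tf_enrichment[{c.name}]"):
            ranking = rank_tfs(
                tf_sets, degs, set(em.gene_ids),
                tf_alpha=config.tf_alpha,
                alternative=config.fisher_alternative,
            )
            write_results_table(
                [r.to_row() for r in ranking],
                out_dir / f"tf_ranking_{c.name}.tsv",
                columns=list(TF_COLUMNS),
            )

        row_d = col_d = None
        if len(degs) >= 2:
            with _stage(f"clustering[{c.name}]"):
                sub_em = em.values.loc[
                    [g for g in em.gene_ids if g in degs],
                    induced + uninduced,
                ]
                row_d, col_d = two_way_cluster(
                    sub_em, distance=config.distance, linkage=config.linkage
                )
                write_dendrogram(
                    row_d,
                    out_dir / f"cluster_gene_merges_{c.name}.tsv",
                    out_dir / f"cluster_gene_leaves_{c.name}.tsv",
                )
                write_dendrogram(
                    col_d,
                    out_dir / f"cluster_sample_merges_{c.name}.tsv",
                    out_dir / f"cluster_sample_leaves_{c.name}.tsv",
                )
        else:
            logger.warning("%s: < 2 DEGs, clustering skipped", c.name)

        results[c.name] = ContrastResult(
            c, table, degs, sub, ranking, row_d, col_d
        )
        manifest["contrasts"][c.name] = {
            "n_degs": len(degs),
            "n_pairs_retained": sub.n_pairs,
            "n_tfs_tested": len(ranking),
            "n_significant_tfs": sum(r.significant for r in ranking),
        }

    comparison = None
    if len(contrasts) >= 2:
        with _stage("compare_conditions"):
            names = [c.name for c in contrasts[:2]]
            cmp_res = compare_conditions(
                results[names[0]].ranking,
                results[names[1]].ranking,
                top_k=config.top_k,
            )
            comparison = {
                "condition_a": names[0],
                "condition_b": names[1],
                "top_k": config.top_k,
                "shared": sorted(cmp_res.shared),
                "only_a": sorted(cmp_res.only_a),
                "only_b": sorted(cmp_res.only_b),
            }
            rows = (
                [{"tf": tf, "membership": "shared"} for tf in sorted(cmp_res.shared)]
                + [{"tf": tf, "membership": "only_a"} for tf in sorted(cmp_res.only_a)]
                + [{"tf": tf, "membership": "only_b"} for tf in sorted(cmp_res.only_b)]
            )
            write_results_table(rows, out_dir / "top_tf_comparison.tsv",
                                columns=["tf", "membership"])
            manifest["comparison"] = {
                "top_k": config.top_k,
                "n_shared_top_tfs": len(cmp_res.shared),
            }
    if truth:
        manifest["synthetic_truth"] = {
            "n_truth_degs": {k: len(v) for k, v in truth["truth_degs"].items()},
            "n_active_tfs": len(truth["active_tfs"]),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(results, comparison, manifest, out_dir)


def config_to_dict(config: PipelineConfig) -> dict:
    raw = asdict(config)
    return raw
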