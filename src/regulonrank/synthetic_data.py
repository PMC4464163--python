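"""Synthetic two-genotype, two-treatment expression studies with ground truth.

The generator emulates a replicated microarray design: ~10,000 genes on a
log2 intensity scale, Gaussian per-gene noise, three biological replicates
per (genotype, treatment) group, a planted fraction of DEGs with a tunable
log2 effect, and a tunable within-replicate-pair correlation between
induced and uninduced measurements (the correlation the paired t statistic
exploits).  A companion TF->target network is drawn with a subset of
"active" TFs whose targets are enriched for planted DEGs at a chosen odds
ratio.

Everything is reproducible from a single integer seed; per-stage generators
are derived via :class:`numpy.random.SeedSequence` spawning so stages can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    ExpressionMatrix,
    RegulatoryNetwork,
    write_expression_table,
    write_network_pairs,
)

GENOTYPES = ("WT", "Mist1KO")
TREATED, CONTROL = "caerulein", "saline"


@dataclass
class SyntheticConfig:
    """Tunable parameters of the synthetic study.

    Defaults mirror the scale of a typical mouse pancreatitis array study:
    ~10,000 detected genes, 3 biological replicates per group, ~15% DEGs in
    the wild-type contrast and about twice that in the sensitized knockout,
    and a network of ~1,000 TFs averaging a few dozen targets each.
    """

    n_genes: int = 10_000
    n_replicates: int = 3
    deg_fraction: float = 0.15
    effect_size: float = 1.5          # mean log2 shift of planted DEGs
    noise_sd: float = 0.5             # per-measurement SD on log2 scale
    pair_correlation: float = 0.5     # within replicate-pair correlation
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_tfs: int = 1_000
    targets_per_tf: tuple[int, int] = (5, 50)
    n_active_tfs: int = 50
    active_odds_ratio: float = 5.0
    ko_deg_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ValueError("need n_genes >= 1 and n_replicates >= 2")
        if not 0.0 < self.deg_fraction < 1.0:
            raise ValueError("deg_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1.0 <= self.pair_correlation <= 1.0:
            raise ValueError("pair_correlation must lie in [-1, 1]")
        lo, hi = self.targets_per_tf
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_tf must be a range 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("targets_per_tf upper bound exceeds the universe")
        if self.n_active_tfs > self.n_tfs:
            raise ValueError("n_active_tfs must not exceed n_tfs")
        if self.active_odds_ratio < 1.0:
            raise ValueError("active_odds_ratio must be >= 1")
        if self.ko_deg_multiplier < 0:
            raise ValueError("ko_deg_multiplier must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "targets_per_tf" in raw:
            raw["targets_per_tf"] = tuple(raw["targets_per_tf"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["targets_per_tf"] = list(raw["targets_per_tf"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _paired_noise(rng: np.random.Generator, n_genes: int, n_reps: int,
                  sd: float, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal noise pairs: (uninduced, induced), correlation rho."""
    e1 = rng.standard_normal((n_genes, n_reps))
    e2 = rng.standard_normal((n_genes, n_reps))
    un = sd * e1
    ind = sd * (rho * e1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * e2)
    return un, ind


def generate_expression(
    config: SyntheticConfig,
    genotype: str = "WT",
    rng: np.random.Generator | None = None,
    planted: set[str] | None = None,
    baselines: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, set[str]]:
    """One genotype's induced/uninduced matrix plus its planted-DEG truth.

    ``planted`` can be supplied (e.g. to share a DEG core across genotypes);
    otherwise a fresh random fraction ``deg_fraction`` of genes is planted.
    The planted log2 shift is ``±effect_size`` with random sign, applied to
    the induced group only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    if baselines is None:
        baselines = rng.normal(config.baseline_mean, config.baseline_sd,
                               config.n_genes)
    if planted is None:
        n_planted = int(round(config.deg_fraction * config.n_genes))
        idx = rng.choice(config.n_genes, size=n_planted, replace=False)
        planted = {genes[i] for i in idx}
    planted_mask = np.array([g in planted for g in genes])
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    shift = np.where(planted_mask, signs * config.effect_size, 0.0)

    un_noise, in_noise = _paired_noise(
        rng, config.n_genes, config.n_replicates,
        config.noise_sd, config.pair_correlation,
    )
    uninduced = baselines[:, None] + un_noise
    induced = baselines[:, None] + shift[:, None] + in_noise

    sample_ids, design_rows, cols = [], [], []
    for treatment, block in ((CONTROL, uninduced), (TREATED, induced)):
        for r in range(1, config.n_replicates + 1):
            sid = f"{genotype}_{treatment}_{r}"
            sample_ids.append(sid)
            design_rows.append(
                {"sample_id": sid, "genotype": genotype,
                 "treatment": treatment, "replicate": r}
            )
            cols.append(block[:, r - 1])
    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene_id"),
        columns=sample_ids,
    )
    design = pd.DataFrame(design_rows).set_index("sample_id")
    return ExpressionMatrix(values, design), set(planted)


def generate_network(
    config: SyntheticConfig,
    planted_degs: set[str],
    universe: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RegulatoryNetwork, set[str]]:
    """Draw a TF->target network with ``n_active_tfs`` DEG-enriched regulons.

    TF ids are drawn from the gene universe (a TF is itself a gene, so it can
    be a DEG and can self-regulate).  Inactive TFs sample targets uniformly;
    active TFs weight planted DEGs by ``active_odds_ratio`` so that each
    target draw has odds ``active_odds_ratio`` times the background odds of
    hitting a planted DEG.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if universe is None:
        universe = _gene_ids(config.n_genes)
    genes = np.asarray(universe, dtype=object)
    if config.targets_per_tf[1] > genes.size:
        raise ValueError("targets_per_tf upper bound exceeds the universe")
    tf_ids = rng.choice(genes, size=config.n_tfs, replace=False)
    active = set(rng.choice(tf_ids, size=config.n_active_tfs, replace=False))

    deg_mask = np.array([g in planted_degs for g in genes], dtype=float)
    w_active = np.where(deg_mask > 0, config.active_odds_ratio, 1.0)
    w_active = w_active / w_active.sum()
    lo, hi = config.targets_per_tf
    pairs: set[tuple[str, str]] = set()
    for tf in tf_ids:
        size = int(rng.integers(lo, hi + 1))
        if tf in active:
            targets = rng.choice(genes, size=size, replace=False, p=w_active)
        else:
            targets = rng.choice(genes, size=size, replace=False)
        pairs.update((str(tf), str(t)) for t in targets)
    return RegulatoryNetwork(pairs, set(map(str, universe))), {str(t) for t in active}


@dataclass
class StudyBundle:
    """A full synthetic study: 12-sample matrix, network and all ground truth."""

    expression: ExpressionMatrix
    network: RegulatoryNetwork
    truth_degs: dict[str, set[str]]     # genotype -> planted DEG ids
    active_tfs: set[str]
    config: SyntheticConfig = field(repr=False)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / "matrix.tsv",
            "design": outdir / "design.tsv",
            "network": outdir / "network.tsv",
            "truth_degs": outdir / "truth_degs.tsv",
            "truth_tfs": outdir / "truth_tfs.tsv",
            "config": outdir / "synthetic_config.yaml",
        }
        write_expression_table(self.expression, paths["matrix"], paths["design"])
        write_network_pairs(self.network, paths["network"])
        with open(paths["truth_degs"], "w") as fh:
            fh.write("gene_id\tgenotype\n")
            for gt in sorted(self.truth_degs):
                for g in sorted(self.truth_degs[gt]):
                    fh.write(f"{g}\t{gt}\n")
        with open(paths["truth_tfs"], "w") as fh:
            fh.write("tf_id\n")
            for tf in sorted(self.active_tfs):
                fh.write(f"{tf}\n")
        self.config.to_yaml(paths["config"])
        return paths


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate the four-group (genotype x treatment) study with shared truth.

    The knockout genotype receives ``ko_deg_multiplier`` times the wild-type
    planted-DEG fraction, built as a superset of the wild-type planted set so
    that the two contrasts share a DEG core; the network's active TFs are
    enriched against that shared core, so they should surface in both
    contrasts' TF rankings.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_wt, rng_ko, rng_net, rng_base = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    genes = _gene_ids(config.n_genes)
    baselines = rng_base.normal(config.baseline_mean, config.baseline_sd,
                                config.n_genes)

    wt_expr, wt_planted = generate_expression(
        config, genotype=GENOTYPES[0], rng=rng_wt, baselines=baselines
    )
    ko_fraction = min(0.95, config.deg_fraction * config.ko_deg_multiplier)
    n_ko = int(round(ko_fraction * config.n_genes))
    extra_pool = [g for g in genes if g not in wt_planted]
    n_extra = max(0, n_ko - len(wt_planted))
    extra = set(
        rng_ko.choice(np.asarray(extra_pool, dtype=object),
                      size=min(n_extra, len(extra_pool)), replace=False)
    ) if n_extra else set()
    ko_planted = wt_planted | {str(g) for g in extra}
    ko_expr, _ = generate_expression(
        config, genotype=GENOTYPES[1], rng=rng_ko,
        planted=ko_planted, baselines=baselines,
    )

    values = pd.concat([wt_expr.values, ko_expr.values], axis=1)
    design = pd.concat([wt_expr.design, ko_expr.design], axis=0)
    expression = ExpressionMatrix(values, design)

    network, active = generate_network(
        config, planted_degs=wt_planted, universe=genes, rng=rng_net
    )
    return StudyBundle(
        expression=expression,
        network=network,
        truth_degs={GENOTYPES[0]: wt_planted, GENOTYPES[1]: ko_planted},
        active_tfs=active,
        config=config,
    )
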