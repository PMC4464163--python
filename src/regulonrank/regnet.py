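"""Project DEGs onto a TF->target network and expose per-TF regulons.

The active subnetwork keeps exactly the interaction pairs that involve at
least one DEG.  "Involve" is configurable: ``either`` endpoint (TF or
target) being a DEG retains the pair (the default, which maximises retained
evidence), or ``target_only``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import RegulatoryNetwork, write_results_table

logger = logging.getLogger(__name__)

PAIR_RULES = ("either", "target_only")


@dataclass
class ActiveSubnetwork:
    """Pairs retained by the DEG-involvement filter plus per-node DEG flags."""

    pairs: set[tuple[str, str]]
    deg_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


def filter_active_pairs(
    network: RegulatoryNetwork, degs: set[str], rule: str = "either"
) -> ActiveSubnetwork:
    """Retain the pairs in which at least one endpoint is a DEG.

    With ``rule="target_only"`` only the target endpoint counts.  An empty
    DEG set is legal and yields an empty subnetwork.
    """
    if rule not in PAIR_RULES:
        raise ValueError(f"rule must be one of {PAIR_RULES}, got {rule!r}")
    degs = set(degs)
    if rule == "either":
        kept = {p for p in network.pairs if p[0] in degs or p[1] in degs}
    else:
        kept = {p for p in network.pairs if p[1] in degs}
    logger.info(
        "filter_active_pairs(rule=%s): retained %d of %d pairs (%d DEGs)",
        rule,
        len(kept),
        network.n_pairs,
        len(degs),
    )
    flags = {g: (g in degs) for pair in kept for g in pair}
    return ActiveSubnetwork(kept, flags)


def tf_target_sets(network: RegulatoryNetwork) -> dict[str, set[str]]:
    """Map every TF to its de-duplicated target set intersected with the universe.

    TFs whose intersected set is empty are reported with an empty set rather
    than dropped.
    """
    out: dict[str, set[str]] = {}
    for tf, tg in network.pairs:
        out.setdefault(tf, set())
        if tg in network.universe:
            out[tf].add(tg)
    n_empty = sum(1 for s in out.values() if not s)
    if n_empty:
        logger.info(
            "tf_target_sets: %d TF(s) have no targets inside the universe",
            n_empty,
        )
    return out


def write_active_subnetwork(sub: ActiveSubnetwork, edges_path, nodes_path) -> None:
    """Export edge and node tables (Cytoscape-importable TSV)."""
    edge_rows = [
        {
            "tf_id": tf,
            "target_id": tg,
            "deg_endpoint": ",".join(
                k
                for k, is_deg in (("tf", sub.deg_flags.get(tf, False)),
                                  ("target", sub.deg_flags.get(tg, False)))
                if is_deg
            ),
        }
        for tf, tg in sorted(sub.pairs)
    ]
    write_results_table(
        edge_rows, edges_path, columns=["tf_id", "target_id", "deg_endpoint"]
    )
    node_rows = [
        {"node_id": node, "is_deg": sub.deg_flags.get(node, False)}
        for node in sorted(sub.nodes)
    ]
    write_results_table(node_rows, nodes_path, columns=["node_id", "is_deg"])


def check_deg_coverage(network: RegulatoryNetwork, degs: set[str]) -> None:
    """Warn when DEGs are absent from both the universe and the TF id set."""
    known = network.universe | network.tfs
    orphan = set(degs) - known
    if orphan:
        logger.warning(
            "%d DEG(s) appear neither in the network universe nor as TFs",
            len(orphan),
        )


__all__ = [
    "ActiveSubnetwork",
    "filter_active_pairs",
    "tf_target_sets",
    "write_active_subnetwork",
    "check_deg_coverage",
    "PAIR_RULES",
]
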