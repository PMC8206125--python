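"""Proof-of-concept validation: consensus differential expression against
network-derived target sets.

Two DEG tables from distinct tests are intersected into consensus DEGs
(nominal p < 0.05 in both, concordant fold-change direction by default),
mapped through a one-to-one homology table, and tested for hypergeometric
enrichment of network targets at three nested scales of interconnectedness:
the broad interval network (all genes in interval-harboring modules), the
top-neighbor subnetwork, and the prioritized drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HomologyTable
from .prioritize import DriverSet, TopNeighborSet, hypergeom_overlap

logger = logging.getLogger(__name__)


def consensus_degs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = 0.05,
    require_sign_concordance: bool = True,
) -> pd.DataFrame:
    """Genes significant (p < alpha) in both DEG tables, with concordant
    fold-change sign by default. Returns gene, both log2FCs and a direction
    label."""
    for name, table in (("a", a), ("b", b)):
        if table["gene"].duplicated().any():
            dupes = table.loc[table["gene"].duplicated(), "gene"].tolist()[:5]
            raise ValueError(f"table {name} has duplicated genes: {dupes}")
    merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
    keep = (merged["pvalue_a"] < alpha) & (merged["pvalue_b"] < alpha)
    if require_sign_concordance:
        keep &= np.sign(merged["log2fc_a"]) == np.sign(merged["log2fc_b"])
    out = merged.loc[keep, ["gene", "log2fc_a", "log2fc_b"]].reset_index(drop=True)
    out["direction"] = np.where(out["log2fc_a"] > 0, "up", "down")
    return out


def map_homologs(genes: list[str], table: HomologyTable) -> list[str]:
    """Translate genes through the one-to-one homology map; unmapped genes
    are dropped with a logged count. Order is preserved."""
    mapping = table.one_to_one()
    mapped = [mapping[g] for g in genes if g in mapping]
    dropped = len(genes) - len(mapped)
    if dropped:
        logger.info("homology mapping dropped %d/%d genes", dropped, len(genes))
    return mapped


@dataclass
class NetworkTargetSets:
    """Network target genes at three nested scales of interconnectedness."""

    broad: list[str]  # all genes in interval-harboring modules
    subnetwork: list[str]  # union of top-neighbor sets plus their seeds
    drivers: list[str]  # prioritized driver genes

    def __post_init__(self) -> None:
        self.broad = sorted(set(self.broad))
        self.subnetwork = sorted(set(self.subnetwork))
        self.drivers = sorted(set(self.drivers))
        if not set(self.drivers) <= set(self.subnetwork):
            raise ValueError("drivers must be contained in the subnetwork scale")

    @classmethod
    def from_results(
        cls,
        partition: pd.Series,
        interval_modules: dict[int, list[str]],
        neighbor_sets: list[TopNeighborSet],
        drivers: DriverSet,
    ) -> "NetworkTargetSets":
        broad: set[str] = set()
        for m in interval_modules:
            broad |= set(partition.index[partition == m])
        sub = set()
        for ns in neighbor_sets:
            sub |= set(ns.genes)
            sub.add(ns.seed)
        return cls(broad=sorted(broad), subnetwork=sorted(sub), drivers=drivers.genes)


def validate_enrichment(
    degs: list[str],
    targets: NetworkTargetSets,
    universe: list[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """One exact upper-tail hypergeometric test per network scale.

    The universe should be the homology-filtered intersection of
    DEG-detectable genes and network genes, so both margins live in one
    namespace. No multiplicity correction across the three scales unless
    ``adjust`` is set (nominal p is the contract here).
    """
    rows = []
    for scale, target in (
        ("broad", targets.broad),
        ("subnetwork", targets.subnetwork),
        ("drivers", targets.drivers),
    ):
        if not target:
            logger.warning("target set %s is empty; scale skipped", scale)
            continue
        res = hypergeom_overlap(degs, target, universe)
        res.pop("overlap_genes")
        rows.append({"scale": scale, **res})
    table = pd.DataFrame(rows)
    if adjust and len(table):
        from .prioritize import bh_adjust

        table["p_adjusted"] = bh_adjust(table["p_raw"].tolist())
    return table
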