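"""Supported topological conflict detection and triage.

A *conflict* is one associate-tree (gene- or operon-tree) bipartition
that is supported above a bootstrap threshold and incompatible with at
least one bipartition of the reference tree.  Conflicts are triaged in
the order: (1) *fixable* -- the conflict disappears after error-aware
fixing of the associate tree against the reference; (2)
*reference-uncertain* -- the conflict survives fixing but every
reference bipartition it contradicts is itself weakly supported; (3)
*authentic HGT* -- the remainder, a supported contradiction of
supported reference structure.

Threshold semantics: detection requires associate support strictly
greater than ``theta_assoc`` (default 70); reference-uncertainty
requires the maximum contradicted reference support to be less than or
equal to ``theta_ref`` (default 70; a reference edge at exactly 70 is
treated as weak).  Edges without a support value count as support 0 on
both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .fixing import fix_tree
from .reconcile import CostScheme
from .tree import (
    Bipartition,
    PhyloTree,
    TreeError,
    are_compatible,
    bipartition_set,
    prune_to_taxa,
)

logger = logging.getLogger("hotrecon")

__all__ = [
    "UNCLASSIFIED",
    "FIXABLE",
    "REFERENCE_UNCERTAIN",
    "AUTHENTIC_HGT",
    "ConflictRecord",
    "find_supported_conflicts",
    "classify_conflicts",
    "scan_gene_set",
    "affected_gene_fraction",
]

UNCLASSIFIED = "unclassified"
FIXABLE = "fixable"
REFERENCE_UNCERTAIN = "reference_uncertain"
AUTHENTIC_HGT = "authentic_hgt"


@dataclass
class ConflictRecord:
    """One supported associate bipartition incompatible with the reference."""

    gene: str
    bipartition: Bipartition
    support: int
    ref_conflicts: list[tuple[Bipartition, int]]
    classification: str = UNCLASSIFIED

    @property
    def max_ref_support(self) -> int:
        return max(s for _, s in self.ref_conflicts)

    def as_row(self) -> dict:
        return {
            "gene": self.gene,
            "bipartition": ",".join(sorted(self.bipartition.smaller_side)),
            "support": self.support,
            "max_ref_support": self.max_ref_support,
            "class": self.classification,
        }


def _common_prune(
    assoc: PhyloTree, ref: PhyloTree
) -> tuple[PhyloTree, PhyloTree, frozenset]:
    common = assoc.leaf_labels & ref.leaf_labels
    if len(common) < 4:
        if not common:
            raise TreeError("associate and reference trees share no taxa")
        # < 4 shared taxa cannot display a non-trivial conflict
        logger.info("only %d shared taxa; no conflicts assessable", len(common))
    if common != assoc.leaf_labels:
        logger.info(
            "pruning associate tree to %d/%d shared taxa",
            len(common), len(assoc.leaf_labels),
        )
        assoc = prune_to_taxa(assoc, common)
    if common != ref.leaf_labels:
        logger.info(
            "pruning reference tree to %d/%d shared taxa",
            len(common), len(ref.leaf_labels),
        )
        ref = prune_to_taxa(ref, common)
    return assoc, ref, common


def find_supported_conflicts(
    assoc: PhyloTree,
    ref: PhyloTree,
    theta_assoc: float = 70,
    gene: str = "",
) -> list[ConflictRecord]:
    """Associate bipartitions with support strictly > ``theta_assoc``
    that are incompatible with at least one reference bipartition.

    Trees are pruned to their common taxon set first (logged).  Records
    come back in canonical bipartition order, unclassified.
    """
    assoc, ref, common = _common_prune(assoc, ref)
    if len(common) < 4:
        return []
    ref_bps = bipartition_set(ref)
    records = []
    for bp, sup in bipartition_set(assoc):
        eff = sup if sup is not None else 0
        if eff <= theta_assoc:
            continue
        hits = [
            (rbp, rsup if rsup is not None else 0)
            for rbp, rsup in ref_bps
            if not are_compatible(bp, rbp)
        ]
        if hits:
            records.append(ConflictRecord(gene, bp, eff, hits))
    return records


def classify_conflicts(
    records: Sequence[ConflictRecord],
    ref: PhyloTree,
    fixed_assoc: PhyloTree,
    theta_ref: float = 70,
    theta_assoc: float = 70,
) -> list[ConflictRecord]:
    """Triage conflict records given the fixed associate tree.

    A record whose bipartition no longer appears among the fixed tree's
    supported conflicts is *fixable*; otherwise it is
    *reference-uncertain* if every contradicted reference edge has
    support <= ``theta_ref``, else *authentic HGT*.
    """
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise TreeError(f"records from multiple associate trees: {sorted(genes)}")
    surviving = {
        r.bipartition
        for r in find_supported_conflicts(fixed_assoc, ref, theta_assoc)
    }
    for rec in records:
        if rec.bipartition not in surviving:
            rec.classification = FIXABLE
        elif rec.max_ref_support <= theta_ref:
            rec.classification = REFERENCE_UNCERTAIN
        else:
            rec.classification = AUTHENTIC_HGT
    return list(records)


def scan_gene_set(
    gene_trees: dict[str, PhyloTree],
    ref: PhyloTree,
    theta_assoc: float = 70,
    theta_ref: float = 70,
    costs: CostScheme = CostScheme(),
    fix_threshold: Optional[float] = None,
) -> tuple[pd.DataFrame, list[ConflictRecord]]:
    """Detect and triage supported conflicts for a set of gene trees.

    For each gene the tree is compared with the reference, fixed against
    it (negotiability threshold ``fix_threshold``, default =
    ``theta_assoc``), and its conflicts classified.  Returns a per-gene
    summary table (one row per gene plus a ``total`` row) and the full
    record list; genes with at least one authentic conflict are flagged
    for downstream exclusion.
    """
    if not gene_trees:
        raise TreeError("empty gene-tree set")
    if fix_threshold is None:
        fix_threshold = theta_assoc
    all_records: list[ConflictRecord] = []
    rows = []
    for gene in sorted(gene_trees):
        tree = gene_trees[gene]
        records = find_supported_conflicts(tree, ref, theta_assoc, gene=gene)
        if records:
            fixed = fix_tree(tree, ref, fix_threshold, costs).tree
            records = classify_conflicts(records, ref, fixed, theta_ref, theta_assoc)
        counts = {FIXABLE: 0, REFERENCE_UNCERTAIN: 0, AUTHENTIC_HGT: 0}
        for r in records:
            counts[r.classification] += 1
        rows.append(
            {
                "gene": gene,
                "conflicts": len(records),
                "fixable": counts[FIXABLE],
                "reference_uncertain": counts[REFERENCE_UNCERTAIN],
                "authentic_hgt": counts[AUTHENTIC_HGT],
                "flagged": counts[AUTHENTIC_HGT] > 0,
            }
        )
        all_records.extend(records)
    df = pd.DataFrame(rows).set_index("gene")
    total = df.drop(columns="flagged").sum()
    total["flagged"] = int(df["flagged"].sum())
    df.loc["total"] = total
    return df, all_records


def affected_gene_fraction(n_affected: int, n_genes: int, n_taxa: int) -> float:
    """Fraction (percent) of gene copies affected by single-gene transfer:
    affected gene x strain instances over the ``n_genes * n_taxa`` pool."""
    if n_genes <= 0 or n_taxa <= 0:
        raise ValueError("gene and taxon counts must be positive")
    return 100.0 * n_affected / (n_genes * n_taxa)
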