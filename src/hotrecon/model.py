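"""End-to-end horizontal-operon-transfer analysis.

:class:`HotTransferModel` bundles the inputs of the study design -- a
species tree, an operon tree, optional per-gene trees and an optional
presence/absence table -- and :meth:`HotTransferModel.fit` runs the
full workflow in order:

1. scan the gene trees against the operon reference for supported
   conflicts and triage them (fixable / reference-uncertain / authentic
   single-gene HGT), flagging genes with authentic conflicts;
2. fix the operon tree against the species tree (error-aware, collapse
   and re-resolve weakly supported edges);
3. reconcile the fixed operon tree with the species tree under DTL
   parsimony (2-3-1 costs by default), yielding the minimal number of
   horizontal operon transfers (HOTs) and losses plus the count of
   co-optimal scenarios;
4. count losses under the vertical-inheritance null (Dollo: single
   origin at the root, losses only) for the side-by-side contrast;
5. run the concerted-evolution test on per-gene transfer counts
   relative to the operon tree versus the species tree.

The result object carries every estimate with its provenance and
renders a deterministic text summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .conflicts import ConflictRecord, scan_gene_set
from .fixing import FixResult, fix_tree
from .markers import ConcertedReport, concerted_evolution_test, per_gene_transfer_counts
from .reconcile import (
    CostScheme,
    Reconciliation,
    dollo_loss_count,
    dtl_reconcile,
    event_summary,
)
from .tree import PhyloTree, TreeError, parse_newick, prune_to_taxa, serialize_newick

__all__ = ["HotTransferModel", "HotTransferResults", "run_hot_analysis"]


@dataclass
class HotTransferResults:
    """Fitted quantities of a horizontal-operon-transfer analysis."""

    model: "HotTransferModel"
    conflict_summary: Optional[pd.DataFrame]
    conflict_records: list[ConflictRecord]
    flagged_genes: list[str]
    fix_result: FixResult
    reconciliation: Reconciliation
    hot_count: int
    loss_count: int
    duplication_count: int
    n_optimal: int
    dollo_losses: int
    dollo_loss_edges: list[str]
    concerted: Optional[ConcertedReport]
    counts_vs_operon: Optional[dict[str, int]]
    counts_vs_species: Optional[dict[str, int]]
    config: dict

    def summary(self) -> str:
        """Deterministic human-readable report."""
        m = self.model
        lines = []
        push = lines.append
        push("Horizontal operon transfer analysis")
        push("=" * 51)
        push(f"species tree taxa          : {len(m.species_tree.leaf_labels)}")
        push(f"operon carriers            : {len(m.carriers)}")
        push(f"gene trees                 : {len(m.gene_trees or {})}")
        push(
            "costs (dup, transfer, loss): "
            f"{m.costs.duplication:g}, {m.costs.transfer:g}, {m.costs.loss:g}"
        )
        push(
            f"thresholds (assoc/ref/fix) : {m.theta_assoc:g} / {m.theta_ref:g} / "
            f"{m.fix_threshold:g}"
        )
        push("")
        if self.conflict_summary is not None:
            tot = self.conflict_summary.loc["total"]
            push("Single-gene conflict triage")
            push("-" * 51)
            push(f"supported conflicts        : {int(tot['conflicts'])}")
            push(f"  fixable                  : {int(tot['fixable'])}")
            push(f"  reference-uncertain      : {int(tot['reference_uncertain'])}")
            push(f"  authentic HGT            : {int(tot['authentic_hgt'])}")
            push(f"flagged genes              : {', '.join(self.flagged_genes) or '-'}")
            push("")
        push("Operon vs species reconciliation (after fixing)")
        push("-" * 51)
        push(
            f"fixing                     : cost {self.fix_result.cost_before:g} -> "
            f"{self.fix_result.cost_after:g}, "
            f"{len(self.fix_result.removed_bipartitions)} bipartitions changed"
        )
        push(f"reconciliation cost        : {self.reconciliation.cost:g}")
        push(f"horizontal operon transfers: {self.hot_count}")
        push(f"operon losses              : {self.loss_count}")
        push(f"duplications               : {self.duplication_count}")
        push(f"co-optimal scenarios       : {self.n_optimal}")
        if not self.reconciliation.time_consistent:
            push("warning: reported scenario fails the transfer time-consistency check")
        push("")
        push("Vertical-inheritance null (Dollo)")
        push("-" * 51)
        push(f"independent losses required: {self.dollo_losses}")
        push(
            f"reconciliation alternative : {self.hot_count} HOTs + "
            f"{self.loss_count} losses"
        )
        push("")
        if self.concerted is not None:
            c = self.concerted
            push("Concerted evolution of the operon")
            push("-" * 51)
            push(f"median transfers vs operon : {c.median_vs_operon:g}")
            push(f"median transfers vs species: {c.median_vs_species:g}")
            push(f"HOT count                  : {c.n_hot}")
            push(
                f"prediction 1 (gene<species): p={c.p_prediction1:.3g} "
                f"({'supported' if c.prediction1 else 'not supported'})"
            )
            push(
                f"prediction 2 (gene<HOTs)   : p={c.p_prediction2:.3g} "
                f"({'supported' if c.prediction2 else 'not supported'})"
            )
        return "\n".join(lines) + "\n"

    def to_files(self, outdir: str | Path) -> None:
        """Persist every stage's outputs (TSV + newick) under `outdir`."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.summary())
        (out / "fixed_operon.nwk").write_text(serialize_newick(self.fix_result.tree) + "\n")
        if self.conflict_summary is not None:
            self.conflict_summary.to_csv(out / "conflict_summary.tsv", sep="\t")
            pd.DataFrame([r.as_row() for r in self.conflict_records]).to_csv(
                out / "conflicts.tsv", sep="\t", index=False
            )
        ev_rows = [
            {
                "kind": e.kind,
                "gene_node": e.gene_node or "",
                "species_location": e.species_location,
                "donor": e.donor or "",
                "recipient": e.recipient or "",
            }
            for e in self.reconciliation.events
        ]
        pd.DataFrame(ev_rows).to_csv(out / "events.tsv", sep="\t", index=False)
        summary_rows = dict(
            cost=self.reconciliation.cost,
            hots=self.hot_count,
            losses=self.loss_count,
            duplications=self.duplication_count,
            n_optimal=self.n_optimal,
            dollo_losses=self.dollo_losses,
        )
        pd.DataFrame([summary_rows]).to_csv(out / "summary.tsv", sep="\t", index=False)
        if self.counts_vs_operon is not None:
            pd.DataFrame(
                {
                    "gene": sorted(self.counts_vs_operon),
                    "transfers_vs_operon": [
                        self.counts_vs_operon[g] for g in sorted(self.counts_vs_operon)
                    ],
                    "transfers_vs_species": [
                        self.counts_vs_species[g] for g in sorted(self.counts_vs_species)
                    ],
                }
            ).to_csv(out / "concerted_counts.tsv", sep="\t", index=False)


class HotTransferModel:
    """Comparative-phylogenetics model of operon evolution.

    Parameters
    ----------
    species_tree, operon_tree:
        Rooted trees with bootstrap supports; the operon tree's leaves
        are the operon-carrying strains.
    gene_trees:
        Optional mapping of gene name to per-gene tree (taxa a subset of
        the operon tree's).
    presence:
        Optional leaf -> present/absent mapping over the species tree's
        leaves; defaults to membership in the operon tree's leaf set.
    theta_assoc, theta_ref, fix_threshold:
        Bootstrap-percent thresholds for conflict detection (strictly
        greater), reference-uncertainty (less than or equal) and edge
        negotiability during fixing (strictly less).
    costs:
        DTL cost scheme (defaults 2-3-1).
    """

    def __init__(
        self,
        species_tree: PhyloTree,
        operon_tree: PhyloTree,
        gene_trees: Optional[Mapping[str, PhyloTree]] = None,
        presence: Optional[Mapping[str, object]] = None,
        theta_assoc: float = 70,
        theta_ref: float = 70,
        fix_threshold: float = 70,
        costs: CostScheme = CostScheme(),
        scenario_limit: int = 100000,
    ) -> None:
        self.species_tree = species_tree
        self.operon_tree = operon_tree
        self.gene_trees = dict(gene_trees) if gene_trees else None
        self.theta_assoc = theta_assoc
        self.theta_ref = theta_ref
        self.fix_threshold = fix_threshold
        self.costs = costs
        self.scenario_limit = scenario_limit

        sp_taxa = species_tree.leaf_labels
        self.carriers = operon_tree.leaf_labels & sp_taxa
        if len(self.carriers) < 3:
            raise TreeError("operon and species trees share fewer than 3 taxa")
        if presence is None:
            self.presence = {l: (l in operon_tree.leaf_labels) for l in sp_taxa}
        else:
            self.presence = {l: v for l, v in presence.items()}

    @classmethod
    def from_files(
        cls,
        species_path: str | Path,
        operon_path: str | Path,
        gene_paths: Optional[Mapping[str, str | Path]] = None,
        presence_path: Optional[str | Path] = None,
        **kwargs,
    ) -> "HotTransferModel":
        """Build the model from newick files and an optional presence TSV
        (two columns: leaf label, present/absent)."""
        species = parse_newick(Path(species_path).read_text())
        operon = parse_newick(Path(operon_path).read_text())
        genes = None
        if gene_paths:
            genes = {
                name: parse_newick(Path(p).read_text())
                for name, p in sorted(gene_paths.items())
            }
        presence = None
        if presence_path is not None:
            df = pd.read_csv(presence_path, sep="\t", header=0)
            presence = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1]))
        return cls(species, operon, genes, presence, **kwargs)

    def fit(self) -> HotTransferResults:
        """Run the full analysis and return the results object."""
        # stage 1: single-gene conflict triage against the operon tree
        conflict_summary = None
        records: list[ConflictRecord] = []
        flagged: list[str] = []
        if self.gene_trees:
            conflict_summary, records = scan_gene_set(
                self.gene_trees,
                self.operon_tree,
                theta_assoc=self.theta_assoc,
                theta_ref=self.theta_ref,
                costs=self.costs,
                fix_threshold=self.fix_threshold,
            )
            flagged = sorted(
                conflict_summary.index[
                    (conflict_summary.index != "total")
                    & (conflict_summary["flagged"] == True)  # noqa: E712
                ]
            )

        # stage 2+3: fix the operon tree against the species tree, reconcile
        sp_carrier = (
            prune_to_taxa(self.species_tree, self.carriers)
            if self.carriers != self.species_tree.leaf_labels
            else self.species_tree
        )
        fix_result = fix_tree(
            self.operon_tree, sp_carrier, self.fix_threshold, self.costs
        )
        rec = dtl_reconcile(fix_result.tree, sp_carrier, costs=self.costs)
        counts = event_summary(rec)

        # stage 4: Dollo null on the full species tree
        dollo_n, dollo_edges = dollo_loss_count(self.species_tree, self.presence)

        # stage 5: concerted-evolution test
        concerted = None
        cvo = cvs = None
        if self.gene_trees and len(self.gene_trees) >= 5:
            cvo = per_gene_transfer_counts(
                self.gene_trees, self.operon_tree, self.costs, self.fix_threshold
            )
            cvs = per_gene_transfer_counts(
                self.gene_trees, sp_carrier, self.costs, self.fix_threshold
            )
            genes_sorted = sorted(cvo)
            concerted = concerted_evolution_test(
                [cvo[g] for g in genes_sorted],
                [cvs[g] for g in genes_sorted],
                n_hot=counts["transfers"],
            )

        return HotTransferResults(
            model=self,
            conflict_summary=conflict_summary,
            conflict_records=records,
            flagged_genes=flagged,
            fix_result=fix_result,
            reconciliation=rec,
            hot_count=counts["transfers"],
            loss_count=counts["losses"],
            duplication_count=counts["duplications"],
            n_optimal=rec.n_optimal,
            dollo_losses=dollo_n,
            dollo_loss_edges=dollo_edges,
            concerted=concerted,
            counts_vs_operon=cvo,
            counts_vs_species=cvs,
            config=dict(
                theta_assoc=self.theta_assoc,
                theta_ref=self.theta_ref,
                fix_threshold=self.fix_threshold,
                duplication_cost=self.costs.duplication,
                transfer_cost=self.costs.transfer,
                loss_cost=self.costs.loss,
            ),
        )


def run_hot_analysis(
    species_tree: PhyloTree,
    operon_tree: PhyloTree,
    gene_trees: Optional[Mapping[str, PhyloTree]] = None,
    presence: Optional[Mapping[str, object]] = None,
    outdir: Optional[str | Path] = None,
    **kwargs,
) -> HotTransferResults:
    """Convenience wrapper: build the model, fit, optionally persist."""
    results = HotTransferModel(
        species_tree, operon_tree, gene_trees, presence, **kwargs
    ).fit()
    if outdir is not None:
        results.to_files(outdir)
    return results
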