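"""Marker selection, alignment column filtering, and the
concerted-evolution test.

The photosynthesis gene cluster (PGC) of *Rhodobacteraceae* is a
~50-gene superoperon.  Genes suitable as phylogenetic markers of the
cluster's joint history must be (i) specific to the cluster, (ii)
universally present in the sampled strains (not alternated with a
replacement gene), and (iii) long enough after alignment filtering
(>= 100 amino-acid positions by default).  :data:`PGC_REFERENCE_GENES`
transcribes the published reference annotation of the *Dinoroseobacter
shibae* PGC at the level of those criterion outcomes: per-gene
post-filter lengths were not published for most rows, so rows failing
the length cutoff are encoded just below it (99) and all others at it
(100); selection depends only on which side of the cutoff a row falls.

The concerted-evolution test asks whether single genes travel with the
operon: if they do, the per-gene transfer count relative to the operon
tree should be lower than (1) the same gene's transfer count relative
to the organism tree and (2) the number of whole-operon transfers
(HOTs).  Both predictions are assessed with one-sided exact sign tests
(zero differences dropped, as usual); Wilcoxon signed-rank is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .fixing import fix_tree
from .reconcile import CostScheme, dtl_reconcile, event_summary
from .tree import PhyloTree, TreeError

__all__ = [
    "GeneRecord",
    "ConcertedReport",
    "PGC_REFERENCE_GENES",
    "pgc_reference_gene_table",
    "select_markers",
    "read_fasta_alignment",
    "filter_alignment_columns",
    "per_gene_transfer_counts",
    "concerted_evolution_test",
    "state_monophyly",
]


def read_fasta_alignment(path) -> dict[str, str]:
    """Read a FASTA protein alignment into an ordered name -> row mapping."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene annotation driving marker selection."""

    name: str
    pgc_specific: bool = True
    universal: bool = True
    filtered_length: int = 100

    def __post_init__(self) -> None:
        if self.filtered_length < 0:
            raise ValueError("filtered_length must be non-negative")


# Reference annotation of the 50 genes of the D. shibae photosynthesis
# gene cluster (cluster order): (name, note) where note is one of
# None (marker), "not_specific", "short" (<100 aa after filtering),
# "alternated" (replaced by another gene in some strains).
_PGC_TABLE: list[tuple[str, Optional[str]]] = [
    ("hemH", "not_specific"),
    ("hyp02", "not_specific"),
    ("comF", "not_specific"),
    ("crtA", None),
    ("bchI", None),
    ("bchD", None),
    ("bchO", None),
    ("hyp08", "not_specific"),
    ("hyp09", "not_specific"),
    ("grxC", "not_specific"),
    ("crtI", None),
    ("crtB", None),
    ("tspO", None),
    ("hyp14", "not_specific"),
    ("crtC", None),
    ("crtD", None),
    ("crtE", None),
    ("crtF", None),
    ("bchC", None),
    ("bchX", None),
    ("bchY", None),
    ("bchZ", None),
    ("pufQ", "short"),
    ("pufB", "short"),
    ("pufA", "short"),
    ("pufL", None),
    ("pufM", None),
    ("pufC", "alternated"),
    ("dxps", None),
    ("idi", "short"),
    ("bchP", None),
    ("pucC2", None),
    ("bchG", None),
    ("ppsR", None),
    ("ppaA", "short"),
    ("bchF", None),
    ("bchN", None),
    ("bchB", None),
    ("bchH", None),
    ("bchL", None),
    ("bchM", None),
    ("lhaA", None),
    ("puhA", None),
    ("puhB", None),
    ("puhC", "short"),
    ("hyp46", "short"),
    ("acsF", None),
    ("puhE", None),
    ("hemA", "not_specific"),
    ("cycA", "short"),
]


def pgc_reference_gene_table() -> list[GeneRecord]:
    """The 50 reference PGC gene records (criterion-outcome encoding)."""
    records = []
    for name, note in _PGC_TABLE:
        records.append(
            GeneRecord(
                name=name,
                pgc_specific=note != "not_specific",
                universal=note != "alternated",
                filtered_length=99 if note == "short" else 100,
            )
        )
    return records


PGC_REFERENCE_GENES = pgc_reference_gene_table()


def select_markers(
    records: Sequence[GeneRecord], min_length: int = 100
) -> tuple[list[str], list[tuple[str, str]]]:
    """Split gene records into selected markers and exclusions.

    A gene is selected iff it is cluster-specific AND universal AND its
    post-filter length is >= ``min_length`` (strictly shorter is
    excluded).  Each exclusion is tagged with its first failing
    criterion: ``"not specific"``, ``"short"``, or ``"not universal"``.
    """
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names: {dupes}")
    selected: list[str] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        if not rec.pgc_specific:
            excluded.append((rec.name, "not specific"))
        elif rec.filtered_length < min_length:
            excluded.append((rec.name, "short"))
        elif not rec.universal:
            excluded.append((rec.name, "not universal"))
        else:
            selected.append(rec.name)
    return selected, excluded


def filter_alignment_columns(
    alignment: Mapping[str, str],
    max_gap_fraction: float = 0.5,
    min_conservation: Optional[float] = None,
    gap_chars: str = "-.",
) -> tuple[dict[str, str], list[int]]:
    """Remove alignment columns with too many gaps (and, optionally,
    too little conservation).

    A column is removed when its gap fraction is strictly greater than
    ``max_gap_fraction`` (a column at exactly the threshold is kept).
    With ``min_conservation`` set, columns whose modal non-gap residue
    frequency (among non-gap characters) is below that fraction are also
    removed -- a deliberately simple stand-in for block-based filters of
    highly variable positions, off by default.

    Returns the filtered alignment and the kept column indices
    (0-based, original coordinates).
    """
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    ncol = lengths.pop()
    nrow = len(alignment)
    names = list(alignment)
    kept: list[int] = []
    for j in range(ncol):
        col = [alignment[n][j] for n in names]
        gaps = sum(1 for c in col for _ in (c,) if c in gap_chars)
        if gaps / nrow > max_gap_fraction:
            continue
        if min_conservation is not None:
            residues = [c for c in col if c not in gap_chars]
            if residues:
                _, counts = np.unique(residues, return_counts=True)
                if counts.max() / len(residues) < min_conservation:
                    continue
        kept.append(j)
    filtered = {n: "".join(alignment[n][j] for j in kept) for n in names}
    return filtered, kept


def per_gene_transfer_counts(
    gene_trees: Mapping[str, PhyloTree],
    reference: PhyloTree,
    costs: CostScheme = CostScheme(),
    fix_threshold: float = 70,
) -> dict[str, int]:
    """Transfer count of each gene tree relative to a reference tree.

    Each gene tree is first fixed against the reference (error-aware,
    see :func:`hotrecon.fixing.fix_tree`), then reconciled with it; the
    transfer count of the optimal scenario is reported.
    """
    counts: dict[str, int] = {}
    for gene in sorted(gene_trees):
        fixed = fix_tree(gene_trees[gene], reference, fix_threshold, costs)
        shared = fixed.tree.leaf_labels & reference.leaf_labels
        ref_p = reference
        if shared != reference.leaf_labels:
            from .tree import prune_to_taxa

            ref_p = prune_to_taxa(reference, shared)
        rec = dtl_reconcile(fixed.tree, ref_p, costs=costs)
        counts[gene] = event_summary(rec)["transfers"]
    return counts


@dataclass
class ConcertedReport:
    """Outcome of the concerted-evolution test."""

    counts_vs_operon: np.ndarray
    counts_vs_species: np.ndarray
    median_vs_operon: float
    median_vs_species: float
    n_hot: int
    p_prediction1: float
    p_prediction2: float
    prediction1: bool
    prediction2: bool
    alpha: float
    method: str


def _sign_test_greater(diffs: np.ndarray) -> float:
    """One-sided exact sign test that the paired differences are > 0
    (ties dropped)."""
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    k = int((nonzero > 0).sum())
    return float(stats.binomtest(k, nonzero.size, 0.5, alternative="greater").pvalue)


def _wilcoxon_greater(diffs: np.ndarray) -> float:
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    return float(stats.wilcoxon(nonzero, alternative="greater").pvalue)


def concerted_evolution_test(
    counts_vs_operon: Sequence[int],
    counts_vs_species: Sequence[int],
    n_hot: int,
    alpha: float = 0.05,
    method: str = "sign",
) -> ConcertedReport:
    """Test the two predictions of concerted operon evolution.

    Prediction 1: per-gene transfer counts relative to the operon tree
    are lower than relative to the organism tree (paired one-sided test
    on species-relative minus operon-relative differences).
    Prediction 2: per-gene transfer counts relative to the operon tree
    are lower than the number of whole-operon transfers ``n_hot``
    (one-sided test of ``n_hot`` minus operon-relative counts > 0).
    """
    a = np.asarray(counts_vs_operon, dtype=float)
    b = np.asarray(counts_vs_species, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 genes for the paired tests")
    test = {"sign": _sign_test_greater, "wilcoxon": _wilcoxon_greater}.get(method)
    if test is None:
        raise ValueError(f"unknown method {method!r} (use 'sign' or 'wilcoxon')")
    p1 = test(b - a)
    p2 = test(n_hot - a)
    return ConcertedReport(
        counts_vs_operon=a.astype(int),
        counts_vs_species=b.astype(int),
        median_vs_operon=float(np.median(a)),
        median_vs_species=float(np.median(b)),
        n_hot=int(n_hot),
        p_prediction1=p1,
        p_prediction2=p2,
        prediction1=p1 <= alpha,
        prediction2=p2 <= alpha,
        alpha=alpha,
        method=method,
    )


def state_monophyly(
    tree: PhyloTree, leaf_states: Mapping[str, object]
) -> tuple[bool, Optional[int]]:
    """Is the set of state-1 leaves exactly a clade of the tree?

    Returns ``(is_clade, stem_support)``; the stem support is the
    support of the clade's edge (``None`` when the clade is the whole
    tree, i.e. its stem is the root, or when the edge is unsupported).
    """

    def as_bool(v: object) -> bool:
        if isinstance(v, str):
            return v.strip() in ("1", "true", "True", "present", "yes")
        return bool(v)

    taxa = tree.leaf_labels
    unknown = set(leaf_states) - set(taxa)
    if unknown:
        raise TreeError(f"states name unknown leaves: {sorted(unknown)}")
    missing = set(taxa) - set(leaf_states)
    if missing:
        raise TreeError(f"states missing for leaves: {sorted(missing)}")
    ones = frozenset(l for l in taxa if as_bool(leaf_states[l]))
    if not ones:
        raise TreeError("no leaf in state 1")
    clades = tree.clades()
    for node in tree.postorder():
        if clades[node] == ones:
            return True, (None if node is tree.root else node.support)
    return False, None
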