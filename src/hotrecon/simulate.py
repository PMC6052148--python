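"""Synthetic operon-evolution generator with ground-truth logging.

Emulates the study design the analysis pipeline is built for: an
ultrametric Yule species tree; one operon starting at the root and
evolving by vertical descent, horizontal operon transfer (HOT) and
loss; a set of genes inside the operon, each occasionally undergoing
its own single-gene transfer between operon carriers; and bootstrap
supports painted onto the true topologies (optionally with weakly
supported wrong edges introduced by random NNIs).

Transfers are modeled at topology level as timed subtree-prune-regraft
(SPR) events with replacement: the recipient lineage's operon (or gene)
genealogy is replaced by a copy of the donor's.  The recipient of an
operon transfer is drawn uniformly among contemporaneous *other*
lineages (carrier or not); the recipient of a single-gene transfer is
drawn among contemporaneous *carrier* lineages (a gene cannot land
where no operon exists).  Losses terminate an operon lineage for good
(regain only by transfer), matching Dollo logic.  Sequence evolution is
not simulated; supports are modeled directly, since every downstream
stage consumes trees plus supports only.

Everything is deterministic under the seed.  Species edges are
identified by the node below them, named ``<leaf>`` for terminal edges
and ``<smallest descendant leaf>+<clade size>`` for internal ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tree import Node, PhyloTree, TreeError

__all__ = [
    "SimConfig",
    "TransferEvent",
    "LossEvent",
    "OperonHistory",
    "simulate_species_tree",
    "simulate_operon_history",
    "replay_operon_history",
    "simulate_gene_trees",
    "assign_supports",
    "perturb_topology",
    "sample_noninteracting_tip_transfers",
    "simulate_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the emulation preset.

    The default sizes mirror the study design this generator emulates:
    44 operon-carrying strains, 33 genes in the operon, a handful of
    whole-operon transfers and losses over the tree, and a low
    single-gene transfer rate (about one event per gene tree).
    """

    n_species: int = 44
    birth_rate: float = 1.0
    hot_rate: float = 0.30
    loss_rate: float = 0.33
    n_genes: int = 33
    gene_hgt_rate: float = 0.03
    true_support: int = 100
    support_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("birth_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hot_rate", "loss_rate", "gene_hgt_rate", "support_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TransferEvent:
    time: float
    donor: str
    recipient: str


@dataclass(frozen=True)
class LossEvent:
    time: float
    edge: str


@dataclass
class OperonHistory:
    """Ground truth of one simulated operon history."""

    species_tree: PhyloTree
    transfers: list[TransferEvent]
    losses: list[LossEvent]
    presence: dict[str, bool]
    operon_tree: Optional[PhyloTree]
    carrier_length: float  # total branch length spent carrying the operon
    tree_length: float

    @property
    def carriers(self) -> frozenset:
        return frozenset(l for l, p in self.presence.items() if p)


# ----------------------------------------------------------------------
# species tree
# ----------------------------------------------------------------------
def simulate_species_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with ``n`` leaves ``s01..``.

    The root splits at time 0; each of ``k`` live lineages splits at
    rate ``birth_rate``; after the ``n``-th lineage appears one more
    exponential stretch is appended so terminal branches have positive
    length.  Fully deterministic under ``seed``.
    """
    if n < 2:
        raise TreeError("need at least 2 species")
    rng = np.random.default_rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active: list[tuple[Node, float]] = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, start = active.pop(i)
        node.length = t - start
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t += rng.exponential(1.0 / (birth_rate * n))
    width = len(str(n))
    for j, (node, start) in enumerate(active, start=1):
        node.length = t - start
        node.label = f"s{j:0{width}d}"
    return PhyloTree(root).canonicalize()


def _node_times(tree: PhyloTree) -> dict[int, tuple[float, float]]:
    """id(node) -> (start, end) time of the edge above the node
    (the root's 'edge' is the zero-length stem at time 0)."""
    times: dict[int, tuple[float, float]] = {}
    times[id(tree.root)] = (0.0, 0.0)
    for node in tree.preorder():
        if node is tree.root:
            continue
        start = times[id(node.parent)][1]
        length = node.length if node.length is not None else 1.0
        times[id(node)] = (start, start + length)
    return times


def _edge_ids(tree: PhyloTree) -> dict[int, str]:
    clades = tree.clades()
    out = {}
    for node in tree.postorder():
        cl = clades[node]
        out[id(node)] = node.label if node.is_leaf() else f"{min(cl)}+{len(cl)}"
    return out


def _check_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> float:
    times = _node_times(tree)
    tips = [times[id(l)][1] for l in tree.leaves()]
    t_max = max(tips)
    if t_max <= 0 or (t_max - min(tips)) > rel_tol * t_max:
        raise TreeError("species tree must be ultrametric (equal root-to-tip depths)")
    return t_max


# ----------------------------------------------------------------------
# forward sweep
# ----------------------------------------------------------------------
class _Lineage:
    """One live gene/operon lineage: a genealogy node under construction."""

    __slots__ = ("node", "start")

    def __init__(self, start: float) -> None:
        self.node = Node()
        self.start = start

    def branch(self, time: float, n_children: int = 2) -> list["_Lineage"]:
        self.node.length = None  # lengths assigned at the end from times
        kids = []
        for _ in range(n_children):
            lin = _Lineage(time)
            self.node.add_child(lin.node)
            kids.append(lin)
        return kids


def _sweep(
    species_tree: PhyloTree,
    rng: np.random.Generator,
    hot_rate: float,
    loss_rate: float,
    scheduled_operon: Optional[tuple[list[TransferEvent], list[LossEvent]]] = None,
    gene_rate: float = 0.0,
    scheduled_gene: Optional[list[TransferEvent]] = None,
):
    """Forward-in-time sweep over the species tree.

    Returns (genealogy root Node, presence dict, transfer log, loss log,
    gene-transfer log, carrier branch length, tree length).

    When ``scheduled_operon`` is given the operon-level events are
    replayed exactly (rates ignored); gene-level transfers come from
    ``gene_rate`` and/or ``scheduled_gene`` and replace the recipient
    carrier's genealogy without changing carrier status.
    """
    times = _node_times(species_tree)
    ids = _edge_ids(species_tree)
    by_id = {ids[id(n)]: n for n in species_tree.postorder()}
    t_end = _check_ultrametric(species_tree)

    # speciation agenda: (time, node) for internal nodes, children appear
    agenda = sorted(
        (
            (times[id(n)][1], ids[id(n)])
            for n in species_tree.postorder()
            if not n.is_leaf() and n is not species_tree.root
        ),
        key=lambda x: (x[0], x[1]),
    )
    sched: list[tuple[float, str, tuple]] = []
    if scheduled_operon is not None:
        tr, lo = scheduled_operon
        sched += [(e.time, "transfer", (e.donor, e.recipient)) for e in tr]
        sched += [(e.time, "loss", (e.edge,)) for e in lo]
    if scheduled_gene is not None:
        sched += [(e.time, "gene_transfer", (e.donor, e.recipient)) for e in scheduled_gene]
    sched.sort(key=lambda x: (x[0], x[1]))

    random_rates = scheduled_operon is None

    alive: set[str] = set()
    carrier: dict[str, _Lineage] = {}
    dead_tips: list[Node] = []

    genealogy_root = _Lineage(0.0)
    root_kids = genealogy_root.branch(0.0, len(species_tree.root.children))
    for child, lin in zip(species_tree.root.children, root_kids):
        alive.add(ids[id(child)])
        carrier[ids[id(child)]] = lin
    # non-root-child lineages enter via the agenda

    transfers: list[TransferEvent] = []
    losses: list[LossEvent] = []
    gene_transfers: list[TransferEvent] = []
    carrier_length = 0.0
    tree_length = 0.0

    def advance(t0: float, t1: float) -> None:
        nonlocal carrier_length, tree_length
        carrier_length += len(carrier) * (t1 - t0)
        tree_length += len(alive) * (t1 - t0)

    def do_speciation(eid: str) -> None:
        node = by_id[eid]
        alive.discard(eid)
        kid_ids = [ids[id(c)] for c in node.children]
        if eid in carrier:
            lin = carrier.pop(eid)
            tsp = times[id(node)][1]
            for kid_id, new_lin in zip(kid_ids, lin.branch(tsp, len(kid_ids))):
                carrier[kid_id] = new_lin
        alive.update(kid_ids)

    def do_loss(t: float, eid: str) -> None:
        lin = carrier.pop(eid)
        dead_tips.append(lin.node)
        losses.append(LossEvent(t, eid))

    def do_transfer(t: float, donor: str, recipient: str, gene_only: bool) -> None:
        lin = carrier[donor]
        cont, moved = lin.branch(t)
        carrier[donor] = cont
        prev = carrier.get(recipient)
        if prev is not None:
            dead_tips.append(prev.node)
        carrier[recipient] = moved
        if gene_only:
            gene_transfers.append(TransferEvent(t, donor, recipient))
        else:
            transfers.append(TransferEvent(t, donor, recipient))

    t = 0.0
    ai = 0  # agenda index
    si = 0  # scheduled index
    while True:
        next_sp = agenda[ai][0] if ai < len(agenda) else t_end
        next_sc = sched[si][0] if si < len(sched) else float("inf")
        horizon = min(next_sp, next_sc)
        if random_rates or gene_rate > 0:
            rate = 0.0
            if random_rates:
                rate += (hot_rate + loss_rate) * len(carrier)
            if gene_rate > 0:
                rate += gene_rate * len(carrier)
            if rate > 0 and carrier:
                dt = rng.exponential(1.0 / rate)
                if t + dt < horizon:
                    advance(t, t + dt)
                    t += dt
                    u = rng.uniform(0, rate)
                    hot_part = hot_rate * len(carrier) if random_rates else 0.0
                    loss_part = loss_rate * len(carrier) if random_rates else 0.0
                    if u < hot_part:
                        donor = sorted(carrier)[int(rng.integers(len(carrier)))]
                        others = sorted(alive - {donor})
                        if others:
                            recipient = others[int(rng.integers(len(others)))]
                            do_transfer(t, donor, recipient, gene_only=False)
                    elif u < hot_part + loss_part:
                        victim = sorted(carrier)[int(rng.integers(len(carrier)))]
                        do_loss(t, victim)
                    else:
                        donor = sorted(carrier)[int(rng.integers(len(carrier)))]
                        others = sorted(set(carrier) - {donor})
                        if others:
                            recipient = others[int(rng.integers(len(others)))]
                            do_transfer(t, donor, recipient, gene_only=True)
                    continue
        # no random event before the horizon
        advance(t, horizon)
        t = horizon
        if si < len(sched) and next_sc <= next_sp:
            et, kind, args = sched[si]
            si += 1
            if kind == "transfer":
                donor, recipient = args
                if donor not in carrier:
                    raise TreeError(f"scheduled transfer at t={et}: donor {donor} is not a carrier")
                if recipient not in alive:
                    raise TreeError(f"scheduled transfer at t={et}: recipient {recipient} not alive")
                do_transfer(et, donor, recipient, gene_only=False)
            elif kind == "loss":
                (eid,) = args
                if eid not in carrier:
                    raise TreeError(f"scheduled loss at t={et}: edge {eid} is not a carrier")
                do_loss(et, eid)
            else:  # gene_transfer
                donor, recipient = args
                if donor not in carrier or recipient not in carrier:
                    raise TreeError(
                        f"scheduled gene transfer at t={et}: both edges must be carriers"
                    )
                do_transfer(et, donor, recipient, gene_only=True)
            continue
        if ai < len(agenda):
            # process all speciations at this time
            while ai < len(agenda) and agenda[ai][0] <= t + 1e-12:
                do_speciation(agenda[ai][1])
                ai += 1
            continue
        break

    if si < len(sched):
        et, kind, _ = sched[si]
        raise TreeError(f"scheduled {kind} at t={et} lies beyond the tree depth {t_end}")

    presence = {}
    for leaf in species_tree.leaves():
        eid = ids[id(leaf)]
        presence[leaf.label] = eid in carrier
        if eid in carrier:
            carrier[eid].node.label = leaf.label

    return (
        genealogy_root.node,
        presence,
        transfers,
        losses,
        gene_transfers,
        carrier_length,
        tree_length,
    )


def _prune_genealogy(root: Node) -> Optional[PhyloTree]:
    """Drop dead (unlabeled) tips and suppress unary nodes."""

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf():
            return Node(node.label) if node.label else None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return Node(children=kids)

    pruned = rec(root)
    if pruned is None or pruned.is_leaf():
        return None
    return PhyloTree(pruned).canonicalize()


def simulate_operon_history(
    species_tree: PhyloTree,
    hot_rate: float,
    loss_rate: float,
    seed: int = 0,
) -> OperonHistory:
    """Simulate operon presence/genealogy forward over an ultrametric tree.

    The operon is present at the root.  On each carrier lineage losses
    arrive at rate ``loss_rate`` and transfers at rate ``hot_rate``;
    the transfer recipient is uniform among contemporaneous other
    lineages and has its operon replaced (one timed SPR on the operon
    genealogy).  All events are logged with times.
    """
    rng = np.random.default_rng(seed)
    root, presence, transfers, losses, _, clen, tlen = _sweep(
        species_tree, rng, hot_rate, loss_rate
    )
    return OperonHistory(
        species_tree=species_tree,
        transfers=transfers,
        losses=losses,
        presence=presence,
        operon_tree=_prune_genealogy(root),
        carrier_length=clen,
        tree_length=tlen,
    )


def replay_operon_history(
    species_tree: PhyloTree,
    transfers: Sequence[TransferEvent],
    losses: Sequence[LossEvent] = (),
) -> OperonHistory:
    """Deterministic history from an explicit (planted) event list."""
    rng = np.random.default_rng(0)  # unused: no random events
    root, presence, tr, lo, _, clen, tlen = _sweep(
        species_tree, rng, 0.0, 0.0, scheduled_operon=(list(transfers), list(losses))
    )
    return OperonHistory(
        species_tree=species_tree,
        transfers=tr,
        losses=lo,
        presence=presence,
        operon_tree=_prune_genealogy(root),
        carrier_length=clen,
        tree_length=tlen,
    )


def simulate_gene_trees(
    history: OperonHistory,
    hgt_rate: float,
    n_genes: int,
    seed: int = 0,
    planted: Optional[dict[int, list[TransferEvent]]] = None,
) -> tuple[dict[str, PhyloTree], dict[str, list[TransferEvent]]]:
    """Per-gene trees: the operon genealogy plus gene-specific transfers.

    Each gene replays the operon history exactly and adds its own
    transfer events at ``hgt_rate`` per carrier lineage (recipient
    uniform among other carriers).  ``planted`` maps a 0-based gene
    index to forced transfer events for that gene.  Returns gene trees
    keyed ``g01..`` and the per-gene event logs.
    """
    if n_genes < 1:
        raise TreeError("n_genes must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_genes)
    width = max(2, len(str(n_genes)))
    trees: dict[str, PhyloTree] = {}
    logs: dict[str, list[TransferEvent]] = {}
    for i in range(n_genes):
        name = f"g{i + 1:0{width}d}"
        rng = np.random.default_rng(seeds[i])
        forced = list(planted.get(i, [])) if planted else []
        root, presence, _, _, gtr, _, _ = _sweep(
            history.species_tree,
            rng,
            0.0,
            0.0,
            scheduled_operon=(history.transfers, history.losses),
            gene_rate=hgt_rate,
            scheduled_gene=forced or None,
        )
        trees[name] = _prune_genealogy(root)
        logs[name] = gtr
    return trees, logs


# ----------------------------------------------------------------------
# support models and perturbation
# ----------------------------------------------------------------------
def assign_supports(
    tree: PhyloTree,
    true_support: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhyloTree:
    """Attach supports to every internal non-root edge.

    Every edge gets ``true_support``; with ``noise_sd > 0`` a rounded
    Gaussian perturbation clipped to [0, 100] is applied (deterministic
    under ``seed``)."""
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in out.postorder():
        if node is out.root or node.is_leaf():
            continue
        val = float(true_support)
        if noise_sd > 0:
            val = float(rng.normal(true_support, noise_sd))
        node.support = int(np.clip(round(val), 0, 100))
    return out.canonicalize()


def perturb_topology(
    tree: PhyloTree,
    n_nni: int,
    low_support: int = 40,
    seed: int = 0,
) -> PhyloTree:
    """Apply ``n_nni`` random nearest-neighbor interchanges; each edge
    rearranged this way gets support ``low_support`` (creating weakly
    supported wrong edges), all other supports are untouched."""
    if n_nni < 0:
        raise TreeError("n_nni must be >= 0")
    if not tree.is_binary():
        raise TreeError("perturbation requires a binary tree")
    out = tree.copy()
    internal_edges = [
        n for n in out.postorder() if not n.is_leaf() and n.parent is not None
    ]
    if n_nni > len(internal_edges):
        raise TreeError(
            f"n_nni={n_nni} exceeds the {len(internal_edges)} internal edges"
        )
    if n_nni == 0:
        return out.canonicalize()
    rng = np.random.default_rng(seed)
    # order nodes canonically for reproducibility, then sample edges
    clades = out.clades()
    internal_edges.sort(key=lambda n: (min(clades[n]), len(clades[n])))
    chosen = rng.choice(len(internal_edges), size=n_nni, replace=False)
    for i in sorted(int(c) for c in chosen):
        c = internal_edges[i]
        p = c.parent
        sibling = next(x for x in p.children if x is not c)
        swap_child = c.children[int(rng.integers(len(c.children)))]
        # exchange swap_child <-> sibling across edge (p, c)
        c.children[c.children.index(swap_child)] = sibling
        sibling.parent = c
        p.children[p.children.index(sibling)] = swap_child
        swap_child.parent = p
        c.support = low_support
    return out.canonicalize()


def sample_noninteracting_tip_transfers(
    species_tree: PhyloTree,
    k: int,
    seed: int = 0,
) -> list[TransferEvent]:
    """Plant ``k`` pairwise non-interacting, topology-changing transfers.

    Each transfer moves the operon between two *terminal* edges late in
    the tree (after the last speciation), and the ``2k`` tips involved
    all have distinct parents (no two are sisters).  Each such event is
    one SPR whose most parsimonious explanation is exactly one transfer,
    independent of the others.
    """
    times = _node_times(species_tree)
    t_end = _check_ultrametric(species_tree)
    t_last = max(
        times[id(n)][1] for n in species_tree.postorder() if not n.is_leaf()
    )
    leaves = sorted(species_tree.leaves(), key=lambda n: n.label)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(leaves)))
    chosen: list[Node] = []
    parents: set[int] = set()
    for idx in order:
        leaf = leaves[idx]
        if id(leaf.parent) in parents:
            continue
        chosen.append(leaf)
        parents.add(id(leaf.parent))
        if len(chosen) == 2 * k:
            break
    if len(chosen) < 2 * k:
        raise TreeError(
            f"cannot place {k} non-interacting transfers on this tree "
            f"(only {len(chosen)} tips with distinct parents)"
        )
    t_window = t_end - t_last
    events = []
    for i in range(k):
        donor, recipient = chosen[2 * i], chosen[2 * i + 1]
        t = t_last + t_window * (i + 1) / (k + 1)
        events.append(TransferEvent(t, donor.label, recipient.label))
    return events


def simulate_study(config: SimConfig):
    """One full synthetic study bundle under the given configuration.

    Returns ``(history, gene_trees, gene_logs)`` where the species,
    operon and gene trees all carry supports per the config's support
    model."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    sp = simulate_species_tree(config.n_species, config.birth_rate, ss[0])
    history = simulate_operon_history(sp, config.hot_rate, config.loss_rate, ss[1])
    genes, logs = simulate_gene_trees(history, config.gene_hgt_rate, config.n_genes, ss[2])
    sup_seeds = ss[3].spawn(config.n_genes + 2)
    history.species_tree = assign_supports(
        sp, config.true_support, config.support_noise_sd, sup_seeds[0]
    )
    if history.operon_tree is not None:
        history.operon_tree = assign_supports(
            history.operon_tree, config.true_support, config.support_noise_sd, sup_seeds[1]
        )
    for i, name in enumerate(sorted(genes)):
        if genes[name] is not None:
            genes[name] = assign_supports(
                genes[name], config.true_support, config.support_noise_sd, sup_seeds[2 + i]
            )
    return history, genes, logs
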