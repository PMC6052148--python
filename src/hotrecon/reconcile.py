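"""Undated duplication-transfer-loss (DTL) parsimony reconciliation.

Reconciles a rooted binary gene (or operon) tree with a rooted binary
species tree under the undated DTL parsimony model: each internal gene
node is explained as a speciation, a duplication, or a horizontal
transfer, and losses are charged for every species edge a gene lineage
crosses without leaving a sampled descendant.  The minimum-cost
event-labeled mapping is found by the standard "cheapest entry into a
subtree" dynamic programme; ties are broken deterministically and the
number of co-optimal scenarios is counted exactly.

Model conventions
-----------------
* A gene node mapped to species node ``s`` means the gene lineage lives
  on the edge leading into ``s`` (or at ``s`` itself for a speciation).
* Transfers connect *incomparable* species edges (neither ancestral to
  the other); the recipient lineage starts on the recipient edge with no
  losses charged at the point of arrival.
* The gene root maps to any species location free of charge (no losses
  above it).
* The default cost scheme is duplication 2, transfer 3, loss 1
  (speciations are free).

Global time-consistency of the implied donor/recipient ordering across
transfers is *not* enforced (deciding it is NP-hard); a post-hoc cycle
check on the reported scenario sets :attr:`Reconciliation.time_consistent`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .tree import Node, PhyloTree, TreeError

__all__ = [
    "CostScheme",
    "Event",
    "Reconciliation",
    "dtl_reconcile",
    "enumerate_scenarios",
    "event_summary",
    "dollo_loss_count",
]

_INF = float("inf")


def _eq(a: float, b: float) -> bool:
    if a == b:
        return True
    if a == _INF or b == _INF:
        return False
    return abs(a - b) <= 1e-9 * max(1.0, abs(a), abs(b))


@dataclass(frozen=True)
class CostScheme:
    """Event costs for DTL parsimony (defaults 2-3-1)."""

    duplication: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        for name in ("duplication", "transfer", "loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be non-negative")


@dataclass(frozen=True)
class Event:
    """One reconciliation event.

    ``kind`` is one of ``speciation``, ``duplication``, ``transfer``,
    ``loss``.  ``gene_node`` is absent for losses.  For transfers,
    ``donor`` and ``recipient`` identify the two incomparable species
    edges (by the node below each edge); ``species_location`` equals the
    donor for transfers and the lost edge for losses.
    """

    kind: str
    gene_node: Optional[str]
    species_location: str
    donor: Optional[str] = None
    recipient: Optional[str] = None


@dataclass
class Reconciliation:
    """Result of a DTL reconciliation: one optimal scenario plus the
    exact count of co-optimal (mapping, event-label) assignments."""

    cost: float
    mapping: dict[str, str]
    events: list[Event]
    n_optimal: int
    costs: CostScheme
    time_consistent: bool = True

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Reconciliation cost={self.cost} events={len(self.events)} "
            f"n_optimal={self.n_optimal}>"
        )


def event_summary(rec: Reconciliation) -> dict[str, int]:
    """Event counts of the reported scenario."""
    counts = {"speciations": 0, "duplications": 0, "transfers": 0, "losses": 0}
    key = {
        "speciation": "speciations",
        "duplication": "duplications",
        "transfer": "transfers",
        "loss": "losses",
    }
    for ev in rec.events:
        counts[key[ev.kind]] += 1
    return counts


# ----------------------------------------------------------------------
# Tree indexing
# ----------------------------------------------------------------------
class _Index:
    """Postorder index of a canonicalized rooted tree with node ids.

    A node is identified by its leaf label (leaves) or
    ``"<smallest leaf>+<clade size>"`` (internal nodes), which is unique
    within a tree.
    """

    def __init__(self, tree: PhyloTree) -> None:
        self.tree = tree.copy().canonicalize()
        self.nodes: list[Node] = list(self.tree.postorder())
        self.idx: dict[int, int] = {id(n): i for i, n in enumerate(self.nodes)}
        clades = self.tree.clades()
        self.clade: list[frozenset] = [clades[n] for n in self.nodes]
        self.ids: list[str] = []
        for n, cl in zip(self.nodes, self.clade):
            if n.is_leaf():
                self.ids.append(n.label)
            else:
                self.ids.append(f"{min(cl)}+{len(cl)}")
        self.parent: list[Optional[int]] = [None] * len(self.nodes)
        self.children: list[tuple[int, ...]] = []
        for i, n in enumerate(self.nodes):
            self.children.append(tuple(self.idx[id(c)] for c in n.children))
            for c in n.children:
                self.parent[self.idx[id(c)]] = i

    def __len__(self) -> int:
        return len(self.nodes)


def _species_relations(sp: _Index) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(desc, anc, incomparable) boolean matrices; desc/anc include self."""
    m = len(sp)
    desc = np.zeros((m, m), dtype=bool)
    for i in range(m):  # postorder: children before parents
        desc[i, i] = True
        for c in sp.children[i]:
            desc[i] |= desc[c]
    anc = desc.T.copy()
    incomp = ~(desc | anc)
    return desc, anc, incomp


# ----------------------------------------------------------------------
# The DP engine
# ----------------------------------------------------------------------
class _Engine:
    def __init__(
        self,
        gene_tree: PhyloTree,
        species_tree: PhyloTree,
        leaf_map: Optional[Mapping[str, str]],
        costs: CostScheme,
    ) -> None:
        if not species_tree.is_binary():
            raise TreeError("species tree must be binary")
        if not gene_tree.is_binary():
            raise TreeError(
                "gene tree has polytomies; resolve it first (see hotrecon.fixing)"
            )
        self.costs = costs
        self.S = _Index(species_tree)
        self.G = _Index(gene_tree)
        self.desc, self.anc, self.incomp = _species_relations(self.S)
        sp_leaf_idx = {
            n.label: i for i, n in enumerate(self.S.nodes) if n.is_leaf()
        }
        if leaf_map is None:
            leaf_map = {
                lbl: lbl for lbl in gene_tree.leaf_labels if lbl in sp_leaf_idx
            }
        self.sigma: dict[int, int] = {}
        for gi, gn in enumerate(self.G.nodes):
            if gn.is_leaf():
                if gn.label not in leaf_map:
                    raise TreeError(f"gene leaf {gn.label!r} missing from leaf map")
                target = leaf_map[gn.label]
                if target not in sp_leaf_idx:
                    raise TreeError(
                        f"leaf map sends {gn.label!r} to unknown species {target!r}"
                    )
                self.sigma[gi] = sp_leaf_idx[target]
        self._run_dp()

    def _run_dp(self) -> None:
        """Vectorized DP with float64 scenario counts; falls back to the
        exact big-integer path if counts approach 2**52 (floats add
        exactly on integers far below that)."""
        m = len(self.S)
        D, T, L = self.costs.duplication, self.costs.transfer, self.costs.loss
        internal = np.array(
            [si for si in range(m) if self.S.children[si]], dtype=int
        )
        s1 = np.array([self.S.children[si][0] for si in internal], dtype=int)
        s2 = np.array([self.S.children[si][1] for si in internal], dtype=int)
        parent_post = [
            (si, self.S.children[si]) for si in range(m) if self.S.children[si]
        ]

        def eq_arr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            finite = (a != _INF) & (b != _INF)
            close = np.zeros(np.broadcast(a, b).shape, dtype=bool)
            if finite.any():
                scale = np.maximum(1.0, np.maximum(np.abs(a), np.abs(b)))
                with np.errstate(invalid="ignore"):
                    close = finite & (np.abs(a - b) <= 1e-9 * scale)
            return (a == b) | close

        self.C = {}
        self.IN = {}
        self.OUT = {}
        NCf: dict[int, np.ndarray] = {}
        NINf: dict[int, np.ndarray] = {}
        NOUTf: dict[int, np.ndarray] = {}
        max_count = 0.0

        for gi, gn in enumerate(self.G.nodes):
            if gn.is_leaf():
                C = np.full(m, _INF)
                ncg = np.zeros(m)
                C[self.sigma[gi]] = 0.0
                ncg[self.sigma[gi]] = 1.0
            else:
                a, b = self.G.children[gi]
                INa, INb = self.IN[a], self.IN[b]
                OUTa, OUTb = self.OUT[a], self.OUT[b]
                NINa, NINb = NINf[a], NINf[b]
                NOUTa, NOUTb = NOUTf[a], NOUTf[b]
                with np.errstate(invalid="ignore"):
                    spec1 = INa[s1] + INb[s2]
                    spec2 = INa[s2] + INb[s1]
                    dup = D + INa + INb
                    tr1 = T + INa + OUTb
                    tr2 = T + INb + OUTa
                C = np.minimum(dup, np.minimum(tr1, tr2))
                np.minimum.at(C, internal, np.minimum(spec1, spec2))
                ncg = np.zeros(m)
                spec_counts = np.zeros(m)
                spec_counts[internal] = np.where(
                    eq_arr(spec1, C[internal]), NINa[s1] * NINb[s2], 0.0
                ) + np.where(eq_arr(spec2, C[internal]), NINa[s2] * NINb[s1], 0.0)
                ncg = (
                    spec_counts
                    + np.where(eq_arr(dup, C), NINa * NINb, 0.0)
                    + np.where(eq_arr(tr1, C), NINa * NOUTb, 0.0)
                    + np.where(eq_arr(tr2, C), NINb * NOUTa, 0.0)
                )
                ncg[C == _INF] = 0.0
            self.C[gi] = C
            NCf[gi] = ncg

            IN = C.copy()
            nin = ncg.copy()
            for si, kids in parent_post:
                for c in kids:
                    cand = L + IN[c]
                    if cand == _INF:
                        continue
                    if cand < IN[si] and not _eq(cand, IN[si]):
                        IN[si] = cand
                        nin[si] = nin[c]
                    elif _eq(cand, IN[si]):
                        nin[si] += nin[c]
            self.IN[gi] = IN
            NINf[gi] = nin

            with np.errstate(invalid="ignore"):
                masked = np.where(self.incomp, C[None, :], _INF)
                OUT = masked.min(axis=1)
                eqmask = self.incomp & eq_arr(C[None, :], OUT[:, None])
            nout = eqmask.astype(float) @ ncg
            nout[OUT == _INF] = 0.0
            self.OUT[gi] = OUT
            NOUTf[gi] = nout
            max_count = max(max_count, float(ncg.max()), float(nin.max()), float(nout.max()))

        if max_count >= 2.0**52:
            self._run_dp_exact()
            return

        self.NC = {g: [int(x) for x in arr] for g, arr in NCf.items()}
        self.NIN = {g: [int(x) for x in arr] for g, arr in NINf.items()}
        self.NOUT = {g: [int(x) for x in arr] for g, arr in NOUTf.items()}
        root = len(self.G) - 1
        self.opt_cost = float(self.C[root].min())
        if self.opt_cost == _INF:  # pragma: no cover - cannot happen with total map
            raise TreeError("no feasible reconciliation")
        self.n_optimal = sum(
            self.NC[root][si]
            for si in range(m)
            if _eq(self.C[root][si], self.opt_cost)
        )

    def _run_dp_exact(self) -> None:
        m = len(self.S)
        D, T, L = self.costs.duplication, self.costs.transfer, self.costs.loss
        self.C: dict[int, np.ndarray] = {}
        self.IN: dict[int, np.ndarray] = {}
        self.OUT: dict[int, np.ndarray] = {}
        # co-optimal counts (Python ints, exact)
        self.NC: dict[int, list[int]] = {}
        self.NIN: dict[int, list[int]] = {}
        self.NOUT: dict[int, list[int]] = {}

        for gi, gn in enumerate(self.G.nodes):
            C = np.full(m, _INF)
            NCg = [0] * m
            if gn.is_leaf():
                C[self.sigma[gi]] = 0.0
                NCg[self.sigma[gi]] = 1
            else:
                a, b = self.G.children[gi]
                INa, INb = self.IN[a], self.IN[b]
                OUTa, OUTb = self.OUT[a], self.OUT[b]
                NINa, NINb = self.NIN[a], self.NIN[b]
                NOUTa, NOUTb = self.NOUT[a], self.NOUT[b]
                for si in range(m):
                    best = _INF
                    count = 0
                    options: list[tuple[float, int]] = []
                    kids = self.S.children[si]
                    if kids:
                        s1, s2 = kids
                        options.append(
                            (INa[s1] + INb[s2], NINa[s1] * NINb[s2])
                        )
                        options.append(
                            (INa[s2] + INb[s1], NINa[s2] * NINb[s1])
                        )
                    options.append((D + INa[si] + INb[si], NINa[si] * NINb[si]))
                    options.append((T + INa[si] + OUTb[si], NINa[si] * NOUTb[si]))
                    options.append((T + INb[si] + OUTa[si], NINb[si] * NOUTa[si]))
                    for cost, cnt in options:
                        if cost == _INF or cnt == 0:
                            continue
                        if cost < best and not _eq(cost, best):
                            best, count = cost, cnt
                        elif _eq(cost, best):
                            count += cnt
                    C[si] = best
                    NCg[si] = count
            self.C[gi] = C
            self.NC[gi] = NCg

            IN = np.full(m, _INF)
            NIN = [0] * m
            for si in range(m):  # postorder: children first
                best = C[si]
                cnt = NCg[si]
                for c in self.S.children[si]:
                    cand = L + IN[c]
                    if cand == _INF:
                        continue
                    if cand < best and not _eq(cand, best):
                        best, cnt = cand, NIN[c]
                    elif _eq(cand, best):
                        cnt += NIN[c]
                IN[si] = best
                NIN[si] = cnt
            self.IN[gi] = IN
            self.NIN[gi] = NIN

            OUT = np.full(m, _INF)
            NOUT = [0] * m
            with np.errstate(invalid="ignore"):
                masked = np.where(self.incomp, C[None, :], _INF)
                OUT = masked.min(axis=1)
            for si in range(m):
                if OUT[si] == _INF:
                    continue
                tot = 0
                row = self.incomp[si]
                for sj in np.flatnonzero(row):
                    if _eq(C[sj], OUT[si]):
                        tot += NCg[sj]
                NOUT[si] = tot
            self.OUT[gi] = OUT
            self.NOUT[gi] = NOUT

        root = len(self.G) - 1
        self.opt_cost = float(self.C[root].min())
        if self.opt_cost == _INF:  # pragma: no cover - cannot happen with total map
            raise TreeError("no feasible reconciliation")
        self.n_optimal = sum(
            self.NC[root][si]
            for si in range(m)
            if _eq(self.C[root][si], self.opt_cost)
        )

    # ------------------------------------------------------------------
    # scenario enumeration (deterministic order; first = reported scenario)
    # ------------------------------------------------------------------
    def scenarios(self) -> Iterator[tuple[dict[str, str], list[Event]]]:
        root = len(self.G) - 1
        for si in range(len(self.S)):
            if _eq(self.C[root][si], self.opt_cost):
                yield from self._expand(root, si)

    def _expand(self, gi: int, si: int) -> Iterator[tuple[dict, list]]:
        """All co-optimal sub-scenarios with gene node gi mapped at si."""
        gn = self.G.nodes[gi]
        gid = self.G.ids[gi]
        sid = self.S.ids[si]
        if gn.is_leaf():
            yield {gid: sid}, []
            return
        D, T = self.costs.duplication, self.costs.transfer
        a, b = self.G.children[gi]
        target = self.C[gi][si]
        kids = self.S.children[si]
        # priority: speciation > duplication > transfer
        if kids:
            s1, s2 = kids
            for (sa, sb) in ((s1, s2), (s2, s1)):
                if _eq(self.IN[a][sa] + self.IN[b][sb], target):
                    for ma, ea in self._expand_in(a, sa):
                        for mb, eb in self._expand_in(b, sb):
                            ev = Event("speciation", gid, sid)
                            yield {gid: sid, **ma, **mb}, [ev] + ea + eb
        if _eq(D + self.IN[a][si] + self.IN[b][si], target):
            for ma, ea in self._expand_in(a, si):
                for mb, eb in self._expand_in(b, si):
                    ev = Event("duplication", gid, sid)
                    yield {gid: sid, **ma, **mb}, [ev] + ea + eb
        for stay, move in ((a, b), (b, a)):
            if _eq(T + self.IN[stay][si] + self.OUT[move][si], target):
                for rj in np.flatnonzero(self.incomp[si]):
                    if not _eq(self.C[move][rj], self.OUT[move][si]):
                        continue
                    for ms, es in self._expand_in(stay, si):
                        for mm, em in self._expand(move, rj):
                            ev = Event(
                                "transfer",
                                gid,
                                sid,
                                donor=sid,
                                recipient=self.S.ids[rj],
                            )
                            yield {gid: sid, **ms, **mm}, [ev] + es + em

    def _expand_in(self, gi: int, si: int) -> Iterator[tuple[dict, list]]:
        """Scenarios for gene node gi entering the species subtree at si,
        descending with losses to its final mapping target."""
        target = self.IN[gi][si]
        if _eq(self.C[gi][si], target):
            yield from self._expand(gi, si)
        L = self.costs.loss
        kids = self.S.children[si]
        if kids:
            s1, s2 = kids
            for down, lost in ((s1, s2), (s2, s1)):
                if _eq(L + self.IN[gi][down], target):
                    loss = Event("loss", None, self.S.ids[lost])
                    for m, e in self._expand_in(gi, down):
                        yield m, [loss] + e


def _check_time_consistency(engine: _Engine, events: Sequence[Event]) -> bool:
    """Heuristic acyclicity check: species-tree descent arcs plus
    donor->recipient arcs for every transfer must form a DAG."""
    g = nx.DiGraph()
    for i in range(len(engine.S)):
        for c in engine.S.children[i]:
            g.add_edge(engine.S.ids[i], engine.S.ids[c])
    for ev in events:
        if ev.kind == "transfer":
            g.add_edge(ev.donor, ev.recipient)
    return nx.is_directed_acyclic_graph(g)


def dtl_reconcile(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: Optional[Mapping[str, str]] = None,
    costs: CostScheme = CostScheme(),
) -> Reconciliation:
    """Minimum-cost DTL reconciliation of a gene tree with a species tree.

    ``leaf_map`` sends each gene leaf label to a species leaf label
    (default: identity).  Returns one optimal scenario (deterministic
    tie-breaking: speciation preferred over duplication over transfer;
    mappings as shallow as possible; canonical species order otherwise)
    together with the exact count of co-optimal scenarios.
    """
    engine = _Engine(gene_tree, species_tree, leaf_map, costs)
    mapping, events = next(engine.scenarios())
    rec = Reconciliation(
        cost=engine.opt_cost,
        mapping=mapping,
        events=events,
        n_optimal=engine.n_optimal,
        costs=costs,
        time_consistent=_check_time_consistency(engine, events),
    )
    _assert_cost_identity(rec)
    return rec


def enumerate_scenarios(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    leaf_map: Optional[Mapping[str, str]] = None,
    costs: CostScheme = CostScheme(),
    limit: int = 1000,
) -> list[Reconciliation]:
    """All co-optimal scenarios (up to ``limit``), in deterministic order.

    The first element is identical to :func:`dtl_reconcile`'s reported
    scenario; the list has length ``min(n_optimal, limit)``.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    engine = _Engine(gene_tree, species_tree, leaf_map, costs)
    out = []
    for mapping, events in itertools.islice(engine.scenarios(), limit):
        rec = Reconciliation(
            cost=engine.opt_cost,
            mapping=mapping,
            events=events,
            n_optimal=engine.n_optimal,
            costs=costs,
            time_consistent=_check_time_consistency(engine, events),
        )
        _assert_cost_identity(rec)
        out.append(rec)
    return out


def _assert_cost_identity(rec: Reconciliation) -> None:
    counts = event_summary(rec)
    implied = (
        rec.costs.duplication * counts["duplications"]
        + rec.costs.transfer * counts["transfers"]
        + rec.costs.loss * counts["losses"]
    )
    if not _eq(implied, rec.cost):  # pragma: no cover - internal invariant
        raise AssertionError(
            f"scenario cost {implied} disagrees with DP optimum {rec.cost}"
        )


# ----------------------------------------------------------------------
# Dollo loss counting (vertical-inheritance null)
# ----------------------------------------------------------------------
def dollo_loss_count(
    species_tree: PhyloTree,
    presence: Mapping[str, object],
) -> tuple[int, list[str]]:
    """Minimal number of losses under a single-origin (Dollo) model with
    the character present at the root.

    ``presence`` maps every leaf label to a truthy value, or to one of
    the strings ``"present"``/``"absent"``.  The minimum equals the
    number of maximal all-absent clades; the returned edges are the stem
    edges of those clades (identified by the node below each edge).
    """

    def as_bool(v: object) -> bool:
        if isinstance(v, str):
            if v.lower() in ("present", "1", "true", "yes"):
                return True
            if v.lower() in ("absent", "0", "false", "no"):
                return False
            raise TreeError(f"unrecognized presence value {v!r}")
        return bool(v)

    taxa = species_tree.leaf_labels
    unknown = set(presence) - set(taxa)
    if unknown:
        raise TreeError(f"presence table names unknown leaves: {sorted(unknown)}")
    missing = set(taxa) - set(presence)
    if missing:
        raise TreeError(f"presence missing for leaves: {sorted(missing)}")

    idx = _Index(species_tree)
    states = {lbl: as_bool(v) for lbl, v in presence.items()}
    all_absent = [False] * len(idx)
    for i, n in enumerate(idx.nodes):
        if n.is_leaf():
            all_absent[i] = not states[n.label]
        else:
            all_absent[i] = all(all_absent[c] for c in idx.children[i])
    loss_edges = []
    for i in range(len(idx)):
        if not all_absent[i]:
            continue
        p = idx.parent[i]
        if p is None or not all_absent[p]:
            loss_edges.append(idx.ids[i])
    return len(loss_edges), sorted(loss_edges)
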