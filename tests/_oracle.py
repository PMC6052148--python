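"""Independent brute-force oracles for reconciliation tests.

These implementations follow the event-model definition directly --
explicitly enumerating, for every internal gene node, the event label and
the children's mapping targets (with losses read off the descent paths)
-- rather than the cheapest-entry (IN/OUT) recurrences used by the
package.  They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools

from hotrecon.reconcile import CostScheme
from hotrecon.tree import PhyloTree

INF = float("inf")


class OracleDTL:
    """Direct-definition minimum cost + co-optimal count for undated DTL."""

    def __init__(self, gene_tree: PhyloTree, species_tree: PhyloTree, sigma=None,
                 costs: CostScheme = CostScheme()):
        self.costs = costs
        self.g = gene_tree.copy().canonicalize()
        self.s = species_tree.copy().canonicalize()
        self.gnodes = list(self.g.postorder())
        self.snodes = list(self.s.postorder())
        self.gi = {id(n): i for i, n in enumerate(self.gnodes)}
        self.si = {id(n): i for i, n in enumerate(self.snodes)}
        # species relations
        m = len(self.snodes)
        self.desc = [[False] * m for _ in range(m)]
        self.depth_from: dict[tuple[int, int], int] = {}
        for i, n in enumerate(self.snodes):
            self._mark(i, i, 0)
        self.anc = [[self.desc[j][i] for j in range(m)] for i in range(m)]
        self.incomp = [
            [not self.desc[i][j] and not self.desc[j][i] and i != j for j in range(m)]
            for i in range(m)
        ]
        sp_leaf = {n.label: self.si[id(n)] for n in self.snodes if n.is_leaf()}
        if sigma is None:
            sigma = {lbl: lbl for lbl in self.g.leaf_labels}
        self.sigma = {}
        for n in self.gnodes:
            if n.is_leaf():
                self.sigma[self.gi[id(n)]] = sp_leaf[sigma[n.label]]
        self._memo: dict[tuple[int, int], tuple[float, int]] = {}

    def _mark(self, top: int, cur: int, d: int) -> None:
        self.desc[top][cur] = True
        self.depth_from[(top, cur)] = d
        for c in self.snodes[cur].children:
            self._mark(top, self.si[id(c)], d + 1)

    def _below(self, s: int) -> list[int]:
        return [j for j in range(len(self.snodes)) if self.desc[s][j]]

    def cost_count(self, g: int, s: int) -> tuple[float, int]:
        key = (g, s)
        if key in self._memo:
            return self._memo[key]
        gn = self.gnodes[g]
        if gn.is_leaf():
            res = (0.0, 1) if self.sigma[g] == s else (INF, 0)
            self._memo[key] = res
            return res
        D, T, L = self.costs.duplication, self.costs.transfer, self.costs.loss
        c1 = self.gi[id(gn.children[0])]
        c2 = self.gi[id(gn.children[1])]
        best, count = INF, 0

        def consider(cost: float, cnt: int) -> None:
            nonlocal best, count
            if cost == INF or cnt == 0:
                return
            if abs(cost - best) <= 1e-9:
                count += cnt
            elif cost < best:
                best, count = cost, cnt

        sn = self.snodes[s]
        if sn.children:
            s1, s2 = (self.si[id(c)] for c in sn.children)
            for (ta_root, tb_root) in ((s1, s2), (s2, s1)):
                for t1 in self._below(ta_root):
                    for t2 in self._below(tb_root):
                        l = self.depth_from[(ta_root, t1)] + self.depth_from[(tb_root, t2)]
                        a1, n1 = self.cost_count(c1, t1)
                        a2, n2 = self.cost_count(c2, t2)
                        consider(L * l + a1 + a2, n1 * n2)
        for t1 in self._below(s):
            for t2 in self._below(s):
                l = self.depth_from[(s, t1)] + self.depth_from[(s, t2)]
                a1, n1 = self.cost_count(c1, t1)
                a2, n2 = self.cost_count(c2, t2)
                consider(D + L * l + a1 + a2, n1 * n2)
        others = [j for j in range(len(self.snodes)) if self.incomp[s][j]]
        for stay, move in ((c1, c2), (c2, c1)):
            for t_in in self._below(s):
                l = self.depth_from[(s, t_in)]
                a1, n1 = self.cost_count(stay, t_in)
                if a1 == INF:
                    continue
                for t_out in others:
                    a2, n2 = self.cost_count(move, t_out)
                    consider(T + L * l + a1 + a2, n1 * n2)
        self._memo[key] = (best, count)
        return best, count

    def solve(self) -> tuple[float, int]:
        root = len(self.gnodes) - 1
        best, count = INF, 0
        for s in range(len(self.snodes)):
            c, n = self.cost_count(root, s)
            if c == INF:
                continue
            if abs(c - best) <= 1e-9:
                count += n
            elif c < best:
                best, count = c, n
        return best, count


def oracle_dtl(gene_tree, species_tree, sigma=None, costs=CostScheme()):
    return OracleDTL(gene_tree, species_tree, sigma, costs).solve()


def oracle_dollo(species_tree: PhyloTree, presence: dict[str, bool]) -> int:
    """Exhaustive minimum over all internal present/absent assignments
    consistent with a single origin at the root (no regain: an absent
    node's whole subtree is absent)."""
    tree = species_tree.copy().canonicalize()
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internal)}
    best = INF
    for bits in itertools.product((True, False), repeat=len(internal)):
        state = {}
        for n in nodes:
            if n.is_leaf():
                state[id(n)] = bool(presence[n.label])
            else:
                state[id(n)] = bits[idx[id(n)]]
        if not state[id(tree.root)]:  # root must be present
            continue
        ok = True
        losses = 0
        for n in nodes:
            for c in n.children:
                if not state[id(n)] and state[id(c)]:
                    ok = False  # regain
                    break
                if state[id(n)] and not state[id(c)]:
                    losses += 1
            if not ok:
                break
        if ok and losses < best:
            best = losses
    return int(best)
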