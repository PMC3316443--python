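"""A small reduced, ordered binary decision diagram (ROBDD) engine.

State sets and transition relations are Boolean functions; this module
gives them a canonical shared-subgraph representation with hash-consed
nodes and memoized ``ite``. Variables are identified by integer *levels*
(smaller level = nearer the root). Terminals are the node ids ``0`` and
``1``; equal functions always have equal node ids.

The engine is deliberately minimal: ``ite``-derived Boolean connectives,
existential quantification, variable renaming (arbitrary level bijections),
model counting and model enumeration — exactly what symbolic model checking
of networks of a few dozen bits needs. There is no garbage collection or
dynamic reordering.
"""

from __future__ import annotations

from typing import Iterable, Iterator

_TERMINAL_LEVEL = 1 << 30


class BDD:
    def __init__(self) -> None:
        # node id -> (level, lo, hi); ids 0 and 1 are the terminals
        self._level = [_TERMINAL_LEVEL, _TERMINAL_LEVEL]
        self._lo = [0, 1]
        self._hi = [0, 1]
        self._unique: dict[tuple[int, int, int], int] = {}
        self._ite_memo: dict[tuple[int, int, int], int] = {}
        self._exists_memo: dict[tuple[int, frozenset[int]], int] = {}

    # -- construction ----------------------------------------------------
    def _mk(self, level: int, lo: int, hi: int) -> int:
        if lo == hi:
            return lo
        key = (level, lo, hi)
        node = self._unique.get(key)
        if node is None:
            node = len(self._level)
            self._level.append(level)
            self._lo.append(lo)
            self._hi.append(hi)
            self._unique[key] = node
        return node

    def var(self, level: int) -> int:
        return self._mk(level, 0, 1)

    def nvar(self, level: int) -> int:
        return self._mk(level, 1, 0)

    def cube(self, assignment: dict[int, int]) -> int:
        """Conjunction of literals: ``{level: bit}``."""
        node = 1
        for level in sorted(assignment, reverse=True):
            if assignment[level]:
                node = self._mk(level, 0, node)
            else:
                node = self._mk(level, node, 0)
        return node

    # -- Boolean connectives ---------------------------------------------
    def ite(self, f: int, g: int, h: int) -> int:
        if f == 1:
            return g
        if f == 0:
            return h
        if g == h:
            return g
        if g == 1 and h == 0:
            return f
        key = (f, g, h)
        memo = self._ite_memo
        hit = memo.get(key)
        if hit is not None:
            return hit
        level = min(self._level[f], self._level[g], self._level[h])
        f0, f1 = self._cofactors(f, level)
        g0, g1 = self._cofactors(g, level)
        h0, h1 = self._cofactors(h, level)
        node = self._mk(level, self.ite(f0, g0, h0), self.ite(f1, g1, h1))
        memo[key] = node
        return node

    def _cofactors(self, u: int, level: int) -> tuple[int, int]:
        if self._level[u] == level:
            return self._lo[u], self._hi[u]
        return u, u

    def NOT(self, f: int) -> int:
        return self.ite(f, 0, 1)

    def AND(self, f: int, g: int) -> int:
        return self.ite(f, g, 0)

    def OR(self, f: int, g: int) -> int:
        return self.ite(f, 1, g)

    def DIFF(self, f: int, g: int) -> int:
        return self.ite(g, 0, f)

    def IFF(self, f: int, g: int) -> int:
        return self.ite(f, g, self.NOT(g))

    def all_and(self, items: Iterable[int]) -> int:
        node = 1
        for u in items:
            node = self.AND(node, u)
            if node == 0:
                break
        return node

    def all_or(self, items: Iterable[int]) -> int:
        node = 0
        for u in items:
            node = self.OR(node, u)
            if node == 1:
                break
        return node

    # -- quantification and renaming --------------------------------------
    def exists(self, levels: Iterable[int], f: int) -> int:
        levelset = frozenset(levels)

        def rec(u: int) -> int:
            if self._level[u] >= _TERMINAL_LEVEL:
                return u
            key = (u, levelset)
            hit = self._exists_memo.get(key)
            if hit is not None:
                return hit
            level, lo, hi = self._level[u], self._lo[u], self._hi[u]
            if level in levelset:
                node = self.OR(rec(lo), rec(hi))
            else:
                node = self._mk(level, rec(lo), rec(hi))
            self._exists_memo[key] = node
            return node

        return rec(f)

    def rename(self, mapping: dict[int, int], f: int) -> int:
        """Substitute variable ``l`` by variable ``mapping[l]``; the mapping
        need not preserve the level order."""
        memo: dict[int, int] = {}

        def rec(u: int) -> int:
            if self._level[u] >= _TERMINAL_LEVEL:
                return u
            hit = memo.get(u)
            if hit is not None:
                return hit
            level = self._level[u]
            v = self.var(mapping.get(level, level))
            node = self.ite(v, rec(self._hi[u]), rec(self._lo[u]))
            memo[u] = node
            return node

        return rec(f)

    # -- inspection --------------------------------------------------------
    def satcount(self, f: int, levels: Iterable[int]) -> int:
        """Number of satisfying assignments over exactly ``levels`` (which
        must cover the support of ``f``)."""
        order = sorted(levels)
        memo: dict[tuple[int, int], int] = {}

        def rec(u: int, i: int) -> int:
            if u == 0:
                return 0
            if i == len(order):
                if u != 1:
                    raise ValueError("levels do not cover the BDD support")
                return 1
            key = (u, i)
            hit = memo.get(key)
            if hit is not None:
                return hit
            if self._level[u] == order[i]:
                out = rec(self._lo[u], i + 1) + rec(self._hi[u], i + 1)
            elif self._level[u] > order[i]:
                out = 2 * rec(u, i + 1)
            else:
                raise ValueError("levels do not cover the BDD support")
            memo[key] = out
            return out

        return rec(f, 0)

    def iter_sat(self, f: int, levels: Iterable[int]) -> Iterator[tuple[int, ...]]:
        """Yield every satisfying assignment as a bit tuple over sorted
        ``levels`` (don't-care variables expanded)."""
        order = sorted(levels)

        def rec(u: int, i: int, prefix: list[int]) -> Iterator[tuple[int, ...]]:
            if u == 0:
                return
            if i == len(order):
                yield tuple(prefix)
                return
            if self._level[u] == order[i]:
                lo, hi = self._lo[u], self._hi[u]
            else:
                lo = hi = u
            prefix.append(0)
            yield from rec(lo, i + 1, prefix)
            prefix[-1] = 1
            yield from rec(hi, i + 1, prefix)
            prefix.pop()

        return rec(f, 0, [])

    def support(self, f: int) -> frozenset[int]:
        seen: set[int] = set()
        out: set[int] = set()
        stack = [f]
        while stack:
            u = stack.pop()
            if u < 2 or u in seen:
                continue
            seen.add(u)
            out.add(self._level[u])
            stack.append(self._lo[u])
            stack.append(self._hi[u])
        return frozenset(out)
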