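"""Seeded random Boolean GRN generation (table dialect).

Each gene draws ``k`` distinct regulators uniformly and a uniform random
truth table; each row is independently turned into a ``*``
(indetermination) with probability ``star_prob``. Identical seeds give
byte-identical output, so generated files double as reproducible fixtures.
"""

from __future__ import annotations

import random

from .network import GRN, Rule, grn_from_rules

__all__ = ["random_grn", "random_tables_text", "gene_names"]


def gene_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 10 else 1
    return [f"g{i:0{width}d}" for i in range(n)]


def random_grn(
    n: int,
    k: int = 2,
    star_prob: float = 0.0,
    seed: int | None = None,
    rng: random.Random | None = None,
) -> GRN:
    """A random ``n``-gene network with in-degree ``min(k, n)``."""
    if n < 1:
        raise ValueError("need at least one gene")
    if not (0.0 <= star_prob <= 1.0):
        raise ValueError("star_prob must be in [0, 1]")
    rng = rng if rng is not None else random.Random(seed)
    names = gene_names(n)
    k = min(k, n)
    rules = []
    for name in names:
        regulators = tuple(sorted(rng.sample(names, k)))
        outputs = tuple(
            "*" if rng.random() < star_prob else rng.choice("01")
            for _ in range(1 << k)
        )
        rules.append(Rule(target=name, regulators=regulators, outputs=outputs))
    return grn_from_rules(rules)


def random_tables_text(
    n: int, k: int = 2, star_prob: float = 0.0, seed: int | None = None
) -> str:
    return random_grn(n, k, star_prob, seed=seed).to_tables_text()
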