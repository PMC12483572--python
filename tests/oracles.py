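"""Independent brute-force oracles the implementation is checked against.

Deliberately written in a different style from the package internals: direct
textbook formulations, no shared code paths.
"""

import math
from functools import lru_cache


def levenshtein_recursive(a: str, b: str) -> int:
    """Edit distance by direct recursion on string prefixes."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)

    return d(len(a), len(b))


def conditional_entropy_brute(pairs, given="parent"):
    """H(other | given) by grouping pairs and summing per-group entropies.

    H(X|Y) = sum_y p(y) * H(X | Y=y), each inner entropy computed from the
    conditional distribution within the group.
    """
    n = len(pairs)
    groups = {}
    for parent, child in pairs:
        key, val = (parent, child) if given == "parent" else (child, parent)
        groups.setdefault(key, []).append(val)
    h = 0.0
    for vals in groups.values():
        p_y = len(vals) / n
        inner = 0.0
        for v in set(vals):
            p = vals.count(v) / len(vals)
            inner -= p * math.log2(p)
        h += p_y * inner
    return h


def h_sym_brute(pairs):
    return conditional_entropy_brute(pairs, "parent") + conditional_entropy_brute(
        pairs, "child"
    )


def support_is_perfect_matching(pairs):
    """True iff each parent term pairs with exactly one child term and vice versa."""
    parent_to_children = {}
    child_to_parents = {}
    for parent, child in pairs:
        parent_to_children.setdefault(parent, set()).add(child)
        child_to_parents.setdefault(child, set()).add(parent)
    return all(len(v) == 1 for v in parent_to_children.values()) and all(
        len(v) == 1 for v in child_to_parents.values()
    )
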