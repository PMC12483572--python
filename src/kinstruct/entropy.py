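"""Symmetric conditional entropy between two generations of kin terms.

The predictive structure of a kinship system is quantified as the sum of the
conditional entropies of each generation's terms given the other's, computed
over parent–child kin-type pairs:

    H(G0 | G+1) = - sum_{(T0, T1)} p(T0, T1) * log2( p(T0, T1) / p(T1) )
    H_sym(G0; G+1) = H(G0 | G+1) + H(G+1 | G0)

where p(T0, T1) is the probability that term T0 labels the child of a
relative labelled T1. Each parent–child link in the inventory contributes
equal weight, so p(T0, T1) is the fraction of observed links carrying that
term pair. H_sym is zero exactly when the observed term-pair support is a
one-to-one matching between the two generations' terms — every term uniquely
predicts its cross-generation partner — and grows as prediction in either
direction becomes uncertain. Entropies are in bits.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .kinspace import G0, G1, KinTypeInventory, KinshipSystem, observed_term_pairs

__all__ = [
    "PairDistribution",
    "EntropyResult",
    "AnalysabilityError",
    "joint_distribution",
    "conditional_entropy",
    "symmetric_conditional_entropy",
    "h_sym_of_pairs",
]

_ATOL = 1e-12


class AnalysabilityError(ValueError):
    """System cannot be analysed: no observed pairs or an empty generation.

    Mirrors the corpus filter requiring at least one term in each generation.
    """


@dataclass(frozen=True)
class PairDistribution:
    """Joint and marginal probabilities over (parent term, child term) pairs.

    Term labels are role-indexed: a string used in both generations is the
    same label inside a joint cell, but the parent and child marginals are
    kept distinct because the conditioning variable is the role, not the
    string.
    """

    joint: dict[tuple[str, str], float]
    marginal_parent: dict[str, float]
    marginal_child: dict[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.joint.values()):
            raise ValueError("joint probabilities must be non-negative")
        total = sum(self.joint.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint must sum to 1, got {total}")
        for t1, p in self.marginal_parent.items():
            slice_sum = sum(v for (j1, _), v in self.joint.items() if j1 == t1)
            if abs(slice_sum - p) > 1e-9:
                raise ValueError(f"parent marginal inconsistent for {t1!r}")
        for t0, p in self.marginal_child.items():
            slice_sum = sum(v for (_, j0), v in self.joint.items() if j0 == t0)
            if abs(slice_sum - p) > 1e-9:
                raise ValueError(f"child marginal inconsistent for {t0!r}")


@dataclass(frozen=True)
class EntropyResult:
    h_child_given_parent: float
    h_parent_given_child: float
    h_sym: float
    n_pairs: int = 0


def joint_distribution(
    system: KinshipSystem, inventory: KinTypeInventory
) -> PairDistribution:
    """Empirical joint distribution over observed (parent term, child term) pairs.

    Each observed kin-type link contributes weight 1/N; identical term pairs
    accumulate.

    Raises :class:`AnalysabilityError` when there are no observed pairs or a
    generation has no assigned terms at all.
    """
    if not system.assigned_codes(inventory, G1) or not system.assigned_codes(inventory, G0):
        raise AnalysabilityError(
            f"system {system.system_id!r} lacks assigned terms in one generation"
        )
    pairs = observed_term_pairs(system, inventory)
    if not pairs:
        raise AnalysabilityError(
            f"system {system.system_id!r} has no observed parent-child term pairs"
        )
    n = len(pairs)
    joint_counts = Counter(pairs)
    joint = {pair: c / n for pair, c in joint_counts.items()}
    marg_parent: Counter = Counter()
    marg_child: Counter = Counter()
    for (t1, t0), p in joint.items():
        marg_parent[t1] += p
        marg_child[t0] += p
    return PairDistribution(joint, dict(marg_parent), dict(marg_child), n)


def conditional_entropy(dist: PairDistribution, direction: str) -> float:
    """Conditional entropy of one generation's terms given the other's, in bits.

    ``direction`` is ``"child_given_parent"`` (condition on the G+1 term) or
    ``"parent_given_child"`` (condition on the G0 term). Zero-probability
    cells contribute nothing.
    """
    if direction == "child_given_parent":
        marginal = dist.marginal_parent
        cond_index = 0
    elif direction == "parent_given_child":
        marginal = dist.marginal_child
        cond_index = 1
    else:
        raise ValueError(f"unknown direction {direction!r}")
    h = 0.0
    for pair, p in dist.joint.items():
        if p <= _ATOL:
            continue
        h -= p * math.log2(p / marginal[pair[cond_index]])
    return max(h, 0.0)


def symmetric_conditional_entropy(
    system: KinshipSystem, inventory: KinTypeInventory
) -> EntropyResult:
    """Symmetric conditional entropy of a system over its observed term pairs."""
    dist = joint_distribution(system, inventory)
    h_cgp = conditional_entropy(dist, "child_given_parent")
    h_pgc = conditional_entropy(dist, "parent_given_child")
    return EntropyResult(h_cgp, h_pgc, h_cgp + h_pgc, dist.n_pairs)


def h_sym_of_pairs(pairs: list[tuple[str, str]]) -> float:
    """Symmetric conditional entropy straight from a term-pair list.

    Fast path used inside permutation loops and exhaustive searches, where
    the pair list has already been enumerated. Equivalent to building the
    joint distribution and summing both conditional entropies.
    """
    n = len(pairs)
    if n == 0:
        raise AnalysabilityError("no term pairs")
    joint = Counter(pairs)
    marg1: Counter = Counter()
    marg0: Counter = Counter()
    for (t1, t0), c in joint.items():
        marg1[t1] += c
        marg0[t0] += c
    log2 = math.log2
    h = 0.0
    for (t1, t0), c in joint.items():
        # bits for both directions at once: -p*log2(c/c1) - p*log2(c/c0)
        h -= (c / n) * (log2(c / marg1[t1]) + log2(c / marg0[t0]))
    return max(h, 0.0)
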