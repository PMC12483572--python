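"""Wordform similarity between parent and child kin terms.

Kin terms are often morphologically transparent: a cousin term may contain
its connecting aunt/uncle's term plus an affix (e.g. Kurdish *pur* 'mother's
sister' / *purza* 'mother's sister's daughter'). As a proxy for such
compositional structure, this module measures the normalized Levenshtein
distance between the terms at the two ends of each parent–child link —
unit-cost edits divided by the longer string's length — averages it over all
observed links, and compares the average against the same G0-shuffling
permutation baseline used for entropy. A mean distance significantly below
baseline (z < -1.96) marks a system as compositional: parent and child forms
resemble each other more than chance; significantly above marks it as
anti-compositional (form resemblance sits anywhere but on parent–child
pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .kinspace import KinTypeInventory, KinshipSystem, observed_term_pairs
from .permutation import PermutationResult, permutation_baseline

__all__ = [
    "EditDistanceSummary",
    "levenshtein",
    "normalized_levenshtein",
    "mean_parent_child_distance",
    "compositionality_test",
]


@dataclass(frozen=True)
class EditDistanceSummary:
    mean_normalized_distance: float
    n_pairs: int
    permutation: PermutationResult

    @property
    def classification(self) -> str:
        return self.permutation.classification


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, replacements).

    Operates on Unicode code points of the already-normalized strings;
    diacritics count as differences. d("", s) = len(s).
    """
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def normalized_levenshtein(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer string's length, in [0, 1].

    0 means identical strings, 1 means no cheaper alignment than replacing
    everything exists. Undefined (and an error) when both strings are empty.
    """
    longer = max(len(a), len(b))
    if longer == 0:
        raise ValueError("normalized distance is undefined for two empty strings")
    return levenshtein(a, b) / longer


def mean_parent_child_distance(
    system: KinshipSystem,
    inventory: KinTypeInventory,
    unique_pairs: bool = False,
) -> float:
    """Average normalized edit distance over observed parent-child term pairs.

    By default each observed link contributes once, so a term pair occurring
    on several links is weighted by its multiplicity (consistent with the
    link-weighted entropy distribution). ``unique_pairs=True`` deduplicates
    term pairs before averaging.
    """
    pairs = observed_term_pairs(system, inventory)
    if not pairs:
        raise ValueError(
            f"system {system.system_id!r} has no observed parent-child term pairs"
        )
    if unique_pairs:
        pairs = list(dict.fromkeys(pairs))
    return sum(normalized_levenshtein(t1, t0) for t1, t0 in pairs) / len(pairs)


def compositionality_test(
    system: KinshipSystem,
    inventory: KinTypeInventory,
    n_permutations: int = 1000,
    seed: int = 0,
    unique_pairs: bool = False,
) -> EditDistanceSummary:
    """Permutation test of parent-child wordform similarity.

    Statistic = mean normalized parent-child edit distance; baseline =
    G0-term shuffles. significantly_low means compositional,
    significantly_high anti-compositional.
    """
    result = permutation_baseline(
        system,
        inventory,
        statistic=lambda s: mean_parent_child_distance(s, inventory, unique_pairs),
        n_permutations=n_permutations,
        seed=seed,
    )
    n_pairs = len(observed_term_pairs(system, inventory))
    return EditDistanceSummary(
        mean_normalized_distance=result.observed,
        n_pairs=n_pairs,
        permutation=result,
    )
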