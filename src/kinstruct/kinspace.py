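"""Kin types, two-generation inventories, and kinship-system representation.

The unit of analysis throughout the package is a *kinship system*: one
language's (or one experiment participant's) partial mapping from structurally
defined kin types to term forms. Kin types are split across two generations —
Ego's own generation G0 (siblings and cousins) and the parents' generation G+1
(parents and parents' siblings) — and joined by explicit parent–child links,
over which every downstream statistic is computed.

Kin-type codes follow the usual anthropological shorthand: M = mother,
F = father, B = brother, Z = sister, e/y prefix = elder/younger, and
concatenation reads as a path through the family tree (``MeB`` = mother's
elder brother, ``MeBS`` = mother's elder brother's son). Codes are opaque to
the machinery; links are explicit data, never parsed out of the strings.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "KinType",
    "KinTypeInventory",
    "KinshipSystem",
    "load_inventory",
    "observed_term_pairs",
    "normalize_form",
    "G0",
    "G1",
    "INVENTORY_PRESETS",
]

G0 = "G0"
G1 = "G+1"

_GENDERS = {"male", "female", "unspecified"}
_SIDES = {"maternal", "paternal", "ego-line"}
_AGES = {"elder", "younger", "unspecified"}


def normalize_form(form: str) -> str:
    """Normalize a term form: Unicode NFC plus surrounding-whitespace trim.

    Case is preserved — orthographic case may be contrastive in source
    transcriptions.
    """
    return unicodedata.normalize("NFC", form).strip()


@dataclass(frozen=True)
class KinType:
    """One structurally defined kin position, independent of any language."""

    code: str
    generation: str
    referent_gender: str = "unspecified"
    side: str = "ego-line"
    relative_age: str = "unspecified"

    def __post_init__(self) -> None:
        if self.generation not in (G0, G1):
            raise ValueError(f"generation must be {G0!r} or {G1!r}, got {self.generation!r}")
        if self.referent_gender not in _GENDERS:
            raise ValueError(f"invalid referent_gender {self.referent_gender!r}")
        if self.side not in _SIDES:
            raise ValueError(f"invalid side {self.side!r}")
        if self.relative_age not in _AGES:
            raise ValueError(f"invalid relative_age {self.relative_age!r}")


class InventoryError(ValueError):
    """Raised for structurally invalid inventory configurations."""


@dataclass(frozen=True)
class KinTypeInventory:
    """A catalogue of kin types plus the parent–child links joining them.

    ``links`` is an ordered tuple of ``(parent_code, child_code)`` pairs, each
    joining a G+1 type to a G0 type. The tuple order is deterministic (it is
    the enumeration order used wherever a canonical ordering is needed) but
    the pairs are unique, i.e. the tuple represents a set.
    """

    kin_types: tuple[KinType, ...]
    links: tuple[tuple[str, str], ...]
    name: str = "custom"
    _by_code: Mapping[str, KinType] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        by_code: dict[str, KinType] = {}
        for kt in self.kin_types:
            if kt.code in by_code:
                raise InventoryError(f"duplicate kin-type code {kt.code!r}")
            by_code[kt.code] = kt
        seen = set()
        for parent, child in self.links:
            if (parent, child) in seen:
                raise InventoryError(f"duplicate link {(parent, child)!r}")
            seen.add((parent, child))
            if parent not in by_code or child not in by_code:
                raise InventoryError(f"link {(parent, child)!r} references unknown code")
            if by_code[parent].generation != G1 or by_code[child].generation != G0:
                raise InventoryError(f"link {(parent, child)!r} must join a G+1 code to a G0 code")
        linked_children = {c for _, c in self.links}
        for kt in self.kin_types:
            if kt.generation == G0 and kt.code not in linked_children:
                raise InventoryError(f"G0 type {kt.code!r} has no parent link")
        object.__setattr__(self, "_by_code", by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> KinType:
        return self._by_code[code]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(kt.code for kt in self.kin_types)

    def generation_codes(self, generation: str) -> tuple[str, ...]:
        return tuple(kt.code for kt in self.kin_types if kt.generation == generation)

    def parents_of(self, child_code: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.links if c == child_code)

    def restrict(self, codes: Iterable[str], name: str | None = None) -> "KinTypeInventory":
        """Restrict to a subset of kin-type codes, keeping only internal links.

        G0 types left without any parent link by the restriction are dropped
        (they can no longer participate in any statistic).
        """
        keep = set(codes)
        unknown = keep - set(self.codes)
        if unknown:
            raise InventoryError(f"restrict: unknown codes {sorted(unknown)}")
        links = tuple((p, c) for p, c in self.links if p in keep and c in keep)
        linked_children = {c for _, c in links}
        kin_types = tuple(
            kt
            for kt in self.kin_types
            if kt.code in keep and (kt.generation == G1 or kt.code in linked_children)
        )
        return KinTypeInventory(kin_types, links, name=name or f"{self.name}:restricted")


@dataclass
class KinshipSystem:
    """One language's (or participant's) partial kin-type → term assignment."""

    system_id: str
    assignment: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for code, form in self.assignment.items():
            norm = normalize_form(form)
            if not norm:
                raise ValueError(
                    f"system {self.system_id!r}: empty form for kin type {code!r} "
                    "after normalization"
                )
            clean[code] = norm
        self.assignment = clean

    def validate_against(self, inventory: KinTypeInventory) -> None:
        unknown = set(self.assignment) - set(inventory.codes)
        if unknown:
            raise ValueError(
                f"system {self.system_id!r} assigns codes outside the inventory: "
                f"{sorted(unknown)}"
            )

    def assigned_codes(self, inventory: KinTypeInventory, generation: str) -> tuple[str, ...]:
        return tuple(
            c for c in inventory.generation_codes(generation) if c in self.assignment
        )

    def with_assignment(self, assignment: dict[str, str]) -> "KinshipSystem":
        return KinshipSystem(self.system_id, assignment, dict(self.metadata))


def observed_term_pairs(
    system: KinshipSystem, inventory: KinTypeInventory
) -> list[tuple[str, str]]:
    """Enumerate the (parent term, child term) pairs observed in a system.

    One entry per inventory link whose parent and child kin types both carry
    an assigned term; links touching a missing code are silently dropped
    (pairwise deletion). Multiplicity is preserved: the same term pair
    re-occurring over several links appears once per link.
    """
    a = system.assignment
    return [
        (a[parent], a[child])
        for parent, child in inventory.links
        if parent in a and child in a
    ]


# ---------------------------------------------------------------------------
# Inventory presets and configuration loading
# ---------------------------------------------------------------------------

def _default_preset() -> dict:
    # G+1: parents plus parents' siblings, split by side, gender, relative age.
    # G0: siblings (by gender and relative age) plus one son and one daughter
    # per aunt/uncle type. Siblings link to BOTH parents; each cousin links
    # only to its connecting aunt/uncle.
    g1 = [
        {"code": "M", "generation": G1, "referent_gender": "female", "side": "ego-line"},
        {"code": "F", "generation": G1, "referent_gender": "male", "side": "ego-line"},
    ]
    aunts_uncles = []
    for side_code, side in (("M", "maternal"), ("F", "paternal")):
        for age_code, age in (("e", "elder"), ("y", "younger")):
            for g_code, gender in (("B", "male"), ("Z", "female")):
                aunts_uncles.append(
                    {
                        "code": f"{side_code}{age_code}{g_code}",
                        "generation": G1,
                        "referent_gender": gender,
                        "side": side,
                        "relative_age": age,
                    }
                )
    siblings = [
        {"code": f"{age_code}{g_code}", "generation": G0, "referent_gender": gender,
         "side": "ego-line", "relative_age": age}
        for age_code, age in (("e", "elder"), ("y", "younger"))
        for g_code, gender in (("B", "male"), ("Z", "female"))
    ]
    cousins = []
    links = []
    for sib in siblings:
        links.append(["M", sib["code"]])
        links.append(["F", sib["code"]])
    for au in aunts_uncles:
        side = au["side"]
        for child_suffix, gender in (("S", "male"), ("D", "female")):
            code = au["code"] + child_suffix
            cousins.append(
                {"code": code, "generation": G0, "referent_gender": gender, "side": side}
            )
            links.append([au["code"], code])
    return {
        "name": "default",
        "kin_types": g1 + aunts_uncles + siblings + cousins,
        "links": links,
    }


def _experiment16_preset() -> dict:
    # The 16-referent space of the generalisation experiment: 6 G+1 referents
    # (mother, father, and one aunt/uncle per side x gender, no relative-age
    # split) and 10 G0 referents (one sibling per gender, one son and one
    # daughter per aunt/uncle).
    g1 = [
        {"code": "M", "generation": G1, "referent_gender": "female", "side": "ego-line"},
        {"code": "F", "generation": G1, "referent_gender": "male", "side": "ego-line"},
        {"code": "MZ", "generation": G1, "referent_gender": "female", "side": "maternal"},
        {"code": "MB", "generation": G1, "referent_gender": "male", "side": "maternal"},
        {"code": "FZ", "generation": G1, "referent_gender": "female", "side": "paternal"},
        {"code": "FB", "generation": G1, "referent_gender": "male", "side": "paternal"},
    ]
    g0 = [
        {"code": "B", "generation": G0, "referent_gender": "male", "side": "ego-line"},
        {"code": "Z", "generation": G0, "referent_gender": "female", "side": "ego-line"},
    ]
    links = [["M", "B"], ["M", "Z"], ["F", "B"], ["F", "Z"]]
    for au in ("MZ", "MB", "FZ", "FB"):
        side = "maternal" if au[0] == "M" else "paternal"
        for suffix, gender in (("S", "male"), ("D", "female")):
            g0.append(
                {"code": au + suffix, "generation": G0, "referent_gender": gender, "side": side}
            )
            links.append([au, au + suffix])
    return {"name": "experiment16", "kin_types": g1 + g0, "links": links}


INVENTORY_PRESETS = {
    "default": _default_preset,
    "experiment16": _experiment16_preset,
}


def load_inventory(config: str | Path | dict = "default") -> KinTypeInventory:
    """Build a validated inventory from a preset name, config file, or dict.

    The config maps ``kin_types`` (list of attribute dicts) and ``links``
    (list of ``[parent_code, child_code]`` pairs). Presets: ``"default"``
    (10 G+1 and 20 G0 types, 24 links) and ``"experiment16"`` (the 16-referent
    experiment space).
    """
    if isinstance(config, str) and config in INVENTORY_PRESETS:
        config = INVENTORY_PRESETS[config]()
    elif isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise InventoryError("inventory config must be a preset name, path, or mapping")
    kin_types = tuple(KinType(**spec) for spec in config["kin_types"])
    links = tuple((str(p), str(c)) for p, c in config.get("links", ()))
    if not links:
        raise InventoryError("inventory config must list parent-child links")
    return KinTypeInventory(kin_types, links, name=str(config.get("name", "custom")))
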