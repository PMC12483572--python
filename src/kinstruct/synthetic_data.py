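"""Synthetic kinship corpora and simulated experiment participants.

The generators here define the study conditions the pipeline is exercised
under, replacing the cross-linguistic database and the human participants
with inputs whose ground truth is known and controllable.

Corpus generation plants a tunable amount of predictive structure: each
language partitions its G+1 kin types into term classes, links each class to
a dedicated G0 base term, and then labels each G0 kin type with its parent
class's base term with probability rho (the predictiveness knob) or with a
uniformly random G0 term otherwise. rho = 1 produces maximally predictive
systems for the drawn class layout; rho = 0 severs all dependence between the
generations. Missingness erases assignments independently at a fixed rate.

Participant simulation answers experiment trials under simple agent
policies: uniform random choice, greedy minimisation of partial-system
H_sym (predictive), or a gender-biased policy that preferentially preserves
a gender distinction with the referent's already-labelled opposite-gender
counterpart before acting predictively.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import (
    DEFAULT_SYSTEM_TYPES,
    GENDER_DUOS,
    ResponseRecord,
    Trial,
    TrialRun,
    build_trial,
    candidate_entropies,
)
from .kinspace import G0, G1, KinTypeInventory, KinshipSystem
from .permutation import derive_seed

__all__ = [
    "GeneratorSpec",
    "AgentPolicy",
    "generate_system",
    "generate_corpus",
    "default_label_pool",
    "build_participant_trials",
    "simulate_participant",
    "simulate_participants",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic corpus generator."""

    n_languages: int = 100
    n_g1_terms: int = 8
    n_g0_terms: int = 8
    predictiveness: float = 1.0
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_languages < 1:
            raise ValueError("n_languages must be >= 1")
        if self.n_g1_terms < 1 or self.n_g0_terms < 1:
            raise ValueError("term counts must be >= 1")
        if self.n_g0_terms < self.n_g1_terms:
            raise ValueError(
                "n_g0_terms must be >= n_g1_terms (the class -> base-term map is injective)"
            )
        if not 0.0 <= self.predictiveness <= 1.0:
            raise ValueError("predictiveness must lie in [0, 1]")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")


@dataclass(frozen=True)
class AgentPolicy:
    """A simulated respondent policy for the generalisation experiment."""

    kind: str = "random"
    gender_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random", "predictive_greedy", "gender_biased"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.gender_weight <= 1.0:
            raise ValueError("gender_weight must lie in [0, 1]")


def generate_system(
    spec: GeneratorSpec,
    inventory: KinTypeInventory,
    rng: np.random.Generator,
    system_id: str = "synthetic",
) -> KinshipSystem:
    """Draw one kinship system with predictiveness rho and the given missingness.

    G+1 kin types are partitioned into ``n_g1_terms`` non-empty classes, each
    labelled with its own G+1 term. Each class is linked injectively to a G0
    base term. Each G0 kin type then takes the base term of its parent's
    class with probability rho, otherwise a uniform draw from the G0 term
    pool. For kin types with parents in more than one class (siblings link to
    both mother and father), the first-listed parent link decides the class.
    Finally every assignment is erased independently at the missingness rate.
    """
    g1_codes = list(inventory.generation_codes(G1))
    g0_codes = list(inventory.generation_codes(G0))
    k = spec.n_g1_terms
    if k > len(g1_codes):
        raise ValueError(f"n_g1_terms={k} exceeds the {len(g1_codes)} G+1 kin types")
    # Random surjective class layout: one anchor per class, the rest uniform.
    order = rng.permutation(len(g1_codes))
    class_of: dict[str, int] = {}
    for idx, pos in enumerate(order):
        code = g1_codes[pos]
        class_of[code] = idx if idx < k else int(rng.integers(k))
    g0_pool = [f"g0_{i}" for i in range(spec.n_g0_terms)]
    base_term_idx = rng.choice(spec.n_g0_terms, size=k, replace=False)
    base_term = {cls: g0_pool[i] for cls, i in enumerate(base_term_idx)}

    assignment = {code: f"g1_{class_of[code]}" for code in g1_codes}
    for code in g0_codes:
        parent = inventory.parents_of(code)[0]
        if rng.random() < spec.predictiveness:
            assignment[code] = base_term[class_of[parent]]
        else:
            assignment[code] = g0_pool[int(rng.integers(spec.n_g0_terms))]
    if spec.missingness > 0:
        assignment = {
            code: form
            for code, form in assignment.items()
            if rng.random() >= spec.missingness
        }
    return KinshipSystem(system_id, assignment, {"rho": spec.predictiveness})


def generate_corpus(
    spec: GeneratorSpec,
    inventory: KinTypeInventory,
    path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a long-format synthetic corpus, optionally writing it to CSV.

    Returns the term table (language_id, kin_type_code, form). The
    ground-truth parameters per language (rho, missingness, seed) are written
    to ``truth_path`` when given — a separate file, so the analysis path
    never sees them.
    """
    rows = []
    truth_rows = []
    for i in range(spec.n_languages):
        lang_id = f"lang_{i:04d}"
        rng = np.random.default_rng(derive_seed(spec.seed, lang_id))
        system = generate_system(spec, inventory, rng, system_id=lang_id)
        for code in inventory.codes:
            if code in system.assignment:
                rows.append((lang_id, code, system.assignment[code]))
        truth_rows.append((lang_id, spec.predictiveness, spec.missingness, spec.seed))
    table = pd.DataFrame(rows, columns=["language_id", "kin_type_code", "form"])
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(path, index=False, encoding="utf-8")
    if truth_path is not None:
        truth = pd.DataFrame(
            truth_rows, columns=["language_id", "rho", "missingness", "seed"]
        )
        Path(truth_path).parent.mkdir(parents=True, exist_ok=True)
        truth.to_csv(truth_path, index=False, encoding="utf-8")
    return table


# ---------------------------------------------------------------------------
# Simulated participants
# ---------------------------------------------------------------------------

def default_label_pool(trial_index: int) -> tuple[str, ...]:
    """A deterministic 10-form label pool per trial index."""
    return tuple(f"t{trial_index}_w{j}" for j in range(10))


def build_participant_trials(
    rng: np.random.Generator,
    system_types: dict | None = None,
    label_pools: list[tuple[str, ...]] | None = None,
) -> list[Trial]:
    """One trial per system type, in randomised order, each with its own pool."""
    system_types = system_types or DEFAULT_SYSTEM_TYPES
    type_ids = list(system_types)
    order = rng.permutation(len(type_ids))
    trials = []
    for slot, pos in enumerate(order):
        type_id = type_ids[pos]
        pool = (
            label_pools[slot]
            if label_pools is not None
            else default_label_pool(slot)
        )
        trials.append(
            build_trial(system_types[type_id], pool, rng, trial_id=f"trial_{slot}")
        )
    return trials


def _gender_partner(referent: str) -> str | None:
    for a, b in GENDER_DUOS:
        if referent == a:
            return b
        if referent == b:
            return a
    return None


def _choose(
    policy: AgentPolicy,
    trial: Trial,
    prior: dict[str, str],
    referent: str,
    rng: np.random.Generator,
) -> str:
    candidates = list(trial.candidates)
    if policy.kind == "random":
        return candidates[int(rng.integers(len(candidates)))]
    restricted = candidates
    if policy.kind == "gender_biased" and rng.random() < policy.gender_weight:
        partner = _gender_partner(referent)
        labelled = {**trial.given_g0, **prior}
        if partner is not None and partner in labelled:
            distinct = [c for c in candidates if c != labelled[partner]]
            if distinct:
                restricted = distinct
    entropies = candidate_entropies(trial, prior, referent)
    h_min = min(entropies[c] for c in restricted)
    argmin = [c for c in restricted if entropies[c] <= h_min + _TIE_TOL]
    return argmin[int(rng.integers(len(argmin)))]


def simulate_participant(
    policy: AgentPolicy,
    trials: list[Trial],
    rng: np.random.Generator,
    participant_id: str = "agent",
) -> list[TrialRun]:
    """Answer every trial under the policy, one referent at a time.

    Referents are highlighted in a fresh uniformly random order per trial,
    as in the live task.
    """
    runs = []
    for trial in trials:
        unlabelled = list(trial.unlabelled)
        order = rng.permutation(len(unlabelled))
        prior: dict[str, str] = {}
        records = []
        for sel_idx, pos in enumerate(order):
            referent = unlabelled[pos]
            chosen = _choose(policy, trial, prior, referent, rng)
            records.append(
                ResponseRecord(participant_id, trial.trial_id, referent, chosen, sel_idx)
            )
            prior[referent] = chosen
        runs.append(TrialRun(participant_id, trial, records))
    return runs


def simulate_participants(
    policy: AgentPolicy,
    n_participants: int,
    seed: int | None = None,
    system_types: dict | None = None,
) -> list[TrialRun]:
    """Simulate a cohort: each participant gets fresh trials and responses."""
    root = policy.seed if seed is None else seed
    runs: list[TrialRun] = []
    for i in range(n_participants):
        pid = f"agent_{i:04d}"
        rng = np.random.default_rng(derive_seed(root, pid))
        trials = build_participant_trials(rng, system_types)
        runs.extend(simulate_participant(policy, trials, rng, participant_id=pid))
    return runs
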