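"""Artificial kin-term generalisation experiment: trials, coding, summaries.

The task emulated here shows a participant a two-generation family tree with
six parents'-generation referents (mother, father, and one aunt/uncle per
side x gender) and ten referents of Ego's generation (a brother, a sister,
and a son and daughter for each aunt/uncle). All six G+1 labels plus two G0
labels are given; the participant assigns one of four candidate labels (the
two given G0 forms plus two novel forms) to each of the eight remaining G0
referents, one referent at a time in random order.

Eight *system types* vary how the four aunts/uncles are partitioned into
term classes (mother and father are always distinct): no distinctions
(Type I), a two-way split by side, gender, or same/opposite parent gender
(Type II), or one aunt/uncle singled out (Type III).

Each choice is coded for predictive generalisation: among the four
candidates, did the chosen label yield the greatest possible decrease in
symmetric conditional entropy of the partial system, given the labels fixed
so far? Completed systems are additionally scored against a permutation
baseline, as in the cross-linguistic analysis, and summarised by referent
co-occurrence and gender-distinction coding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import h_sym_of_pairs
from .kinspace import KinTypeInventory, load_inventory
from .permutation import (
    DEFAULT_THRESHOLD,
    SD_EPS,
    PermutationResult,
    _classify_percentile,
    classify,
)

__all__ = [
    "SystemType",
    "Trial",
    "ResponseRecord",
    "CodedChoice",
    "TrialRun",
    "DEFAULT_SYSTEM_TYPES",
    "G1_REFERENTS",
    "G0_REFERENTS",
    "TREE_LINKS",
    "GENDER_DUOS",
    "build_trial",
    "candidate_entropies",
    "code_choice",
    "code_trial_run",
    "proportion_predictive",
    "participant_system_z",
    "ideal_predictive_completion",
    "cooccurrence_matrix",
    "code_gender_distinctions",
    "gender_distinction_table",
    "responses_frame",
    "trials_frame",
    "load_experiment_log",
    "experiment_inventory",
]

G1_REFERENTS = ("M", "F", "MZ", "MB", "FZ", "FB")
G0_REFERENTS = ("B", "Z", "MZS", "MZD", "MBS", "MBD", "FZS", "FZD", "FBS", "FBD")

#: Fixed family-tree links: both parents to both siblings, each aunt/uncle to
#: its own son and daughter.
TREE_LINKS: tuple[tuple[str, str], ...] = (
    ("M", "B"), ("M", "Z"), ("F", "B"), ("F", "Z"),
    ("MZ", "MZS"), ("MZ", "MZD"), ("MB", "MBS"), ("MB", "MBD"),
    ("FZ", "FZS"), ("FZ", "FZD"), ("FB", "FBS"), ("FB", "FBD"),
)

#: Gender-paired duos differing only in referent gender.
GENDER_DUOS: tuple[tuple[str, str], ...] = (
    ("B", "Z"), ("MZS", "MZD"), ("MBS", "MBD"), ("FZS", "FZD"), ("FBS", "FBD"),
)

_TIE_TOL = 1e-9


def experiment_inventory() -> KinTypeInventory:
    """The 16-referent inventory used throughout the experiment machinery."""
    return load_inventory("experiment16")


@dataclass(frozen=True)
class SystemType:
    """A partition of the six G+1 referents into term classes.

    ``g1_partition`` is a tuple of frozensets covering {M, F, MZ, MB, FZ, FB};
    mother and father always sit in separate singleton classes.
    """

    type_id: str
    g1_partition: tuple[frozenset, ...]
    #: coarse family for grouped analyses: "I", "II" or "III"
    group: str = ""

    def __post_init__(self) -> None:
        covered = frozenset(itertools.chain.from_iterable(self.g1_partition))
        if covered != frozenset(G1_REFERENTS):
            raise ValueError(f"{self.type_id}: partition must cover {G1_REFERENTS}")
        if sum(len(c) for c in self.g1_partition) != len(G1_REFERENTS):
            raise ValueError(f"{self.type_id}: partition classes overlap")
        if frozenset({"M"}) not in self.g1_partition or frozenset({"F"}) not in self.g1_partition:
            raise ValueError(f"{self.type_id}: M and F must be singleton-distinct classes")
        if not self.group:
            object.__setattr__(self, "group", self.type_id.split("_")[0])

    def class_of(self, referent: str) -> frozenset:
        for cls in self.g1_partition:
            if referent in cls:
                return cls
        raise KeyError(referent)

    def child_groups(self) -> tuple[tuple[str, ...], ...]:
        """Group G0 referents by the term classes of their parents.

        The siblings (children of both mother and father) always form one
        group; cousins group by their aunt/uncle's class. These are the
        groups a maximally predictive completion labels uniformly.
        """
        keyed: dict[frozenset, list[str]] = {}
        for ref in G0_REFERENTS:
            parents = tuple(p for p, c in TREE_LINKS if c == ref)
            key = frozenset(self.class_of(p) for p in parents)
            keyed.setdefault(key, []).append(ref)
        return tuple(tuple(group) for group in keyed.values())


def _partition(*classes: str) -> tuple[frozenset, ...]:
    return tuple(frozenset(c.split("+")) for c in classes)


DEFAULT_SYSTEM_TYPES: dict[str, SystemType] = {
    st.type_id: st
    for st in (
        SystemType("I", _partition("M", "F", "MZ+MB+FZ+FB")),
        SystemType("II_side", _partition("M", "F", "MZ+MB", "FZ+FB")),
        SystemType("II_gen", _partition("M", "F", "MZ+FZ", "MB+FB")),
        SystemType("II_opp", _partition("M", "F", "MZ+FB", "MB+FZ")),
        SystemType("III_fb", _partition("M", "F", "FB", "MZ+MB+FZ")),
        SystemType("III_mz", _partition("M", "F", "MZ", "MB+FZ+FB")),
        SystemType("III_mb", _partition("M", "F", "MB", "MZ+FZ+FB")),
        SystemType("III_fz", _partition("M", "F", "FZ", "MZ+MB+FB")),
    )
}


@dataclass(frozen=True)
class Trial:
    """One experiment trial: an artificial language plus its candidate labels."""

    system_type: SystemType
    label_pool: tuple[str, ...]
    g1_labels: dict[str, str]
    given_g0: dict[str, str]
    candidates: tuple[str, ...]
    trial_id: str = ""

    def __post_init__(self) -> None:
        if set(self.g1_labels) != set(G1_REFERENTS):
            raise ValueError("g1_labels must cover all six G+1 referents")
        for cls in self.system_type.g1_partition:
            labels = {self.g1_labels[r] for r in cls}
            if len(labels) != 1:
                raise ValueError(f"class {sorted(cls)} must share one label")
        if self.g1_labels["M"] == self.g1_labels["F"]:
            raise ValueError("mother and father labels must differ")
        if len(self.given_g0) < 2:
            raise ValueError("at least two G0 labels must be given")
        if len(self.candidates) != 4:
            raise ValueError("exactly four candidate labels required")
        given_forms = set(self.given_g0.values())
        if len(set(self.candidates) & given_forms) != 2:
            raise ValueError("exactly two candidates must match given G0 forms")

    @property
    def unlabelled(self) -> tuple[str, ...]:
        return tuple(r for r in G0_REFERENTS if r not in self.given_g0)


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    trial_id: str
    referent: str
    chosen_form: str
    selection_index: int


@dataclass(frozen=True)
class CodedChoice:
    participant_id: str
    trial_id: str
    system_type: str
    referent: str
    chosen_form: str
    selection_index: int
    predictive: int
    n_argmin: int


@dataclass
class TrialRun:
    """One participant's pass through one trial."""

    participant_id: str
    trial: Trial
    responses: list[ResponseRecord] = field(default_factory=list)

    def completion(self) -> dict[str, str]:
        """Full G0 referent → form map (given plus chosen); errors if incomplete."""
        assignment = dict(self.trial.given_g0)
        for rec in sorted(self.responses, key=lambda r: r.selection_index):
            assignment[rec.referent] = rec.chosen_form
        missing = [r for r in G0_REFERENTS if r not in assignment]
        if missing:
            raise ValueError(
                f"participant {self.participant_id!r} trial {self.trial.trial_id!r} "
                f"incomplete: unlabelled referents {missing}"
            )
        return assignment


def build_trial(
    system_type: SystemType,
    label_pool: tuple[str, ...],
    rng: np.random.Generator,
    trial_id: str = "",
) -> Trial:
    """Construct a trial for one system type from a label pool.

    The G+1 classes are labelled injectively from the pool. A hidden
    predictive map assigns each child group (see
    :meth:`SystemType.child_groups`) a distinct unused form; two of those
    groups are revealed through one randomly chosen referent each, giving the
    participant two G0 labels consistent with a maximally predictive system
    while leaving the remaining distinctions open. The four candidates are
    the two given forms plus two novel (so far unused) forms.
    """
    pool = tuple(dict.fromkeys(label_pool))
    if len(pool) != len(label_pool):
        raise ValueError("label pool contains duplicate forms")
    groups = system_type.child_groups()
    if len(groups) < 2:
        raise ValueError(f"{system_type.type_id}: fewer than 2 G+1 classes with children")
    n_classes = len(system_type.g1_partition)
    if len(pool) < n_classes + len(groups) + 2:
        raise ValueError(
            f"label pool too small: need at least {n_classes + len(groups) + 2} "
            f"distinct forms, got {len(pool)}"
        )
    shuffled = [pool[i] for i in rng.permutation(len(pool))]
    g1_labels: dict[str, str] = {}
    for cls in system_type.g1_partition:
        label = shuffled.pop()
        for ref in cls:
            g1_labels[ref] = label
    hidden_map = {group: shuffled.pop() for group in groups}
    revealed_idx = rng.choice(len(groups), size=2, replace=False)
    given_g0: dict[str, str] = {}
    for gi in revealed_idx:
        group = groups[gi]
        ref = group[rng.integers(len(group))]
        given_g0[ref] = hidden_map[group]
    novel = [shuffled.pop(), shuffled.pop()]
    candidates = tuple(sorted(given_g0.values()) + novel)
    return Trial(system_type, pool, g1_labels, given_g0, candidates, trial_id)


# ---------------------------------------------------------------------------
# Choice coding
# ---------------------------------------------------------------------------

def _partial_pairs(
    trial: Trial, g0_labels: dict[str, str]
) -> list[tuple[str, str]]:
    """Term pairs over tree links whose endpoints are both labelled."""
    g1 = trial.g1_labels
    return [
        (g1[p], g0_labels[c]) for p, c in TREE_LINKS if c in g0_labels
    ]


def candidate_entropies(
    trial: Trial, prior_choices: dict[str, str], referent: str
) -> dict[str, float]:
    """H_sym of the partial system under each of the four candidate labels.

    The partial system comprises the G+1 labels, the given G0 labels, the
    prior choices, and the candidate under evaluation; only tree links with
    both endpoints labelled contribute.
    """
    base = {**trial.given_g0, **prior_choices}
    if referent in base:
        raise ValueError(f"referent {referent!r} is already labelled")
    out = {}
    for cand in trial.candidates:
        labels = {**base, referent: cand}
        out[cand] = h_sym_of_pairs(_partial_pairs(trial, labels))
    return out


def code_choice(
    trial: Trial,
    prior_choices: dict[str, str],
    referent: str,
    chosen: str,
    participant_id: str = "",
    selection_index: int = 0,
) -> CodedChoice:
    """Code one choice for predictive generalisation.

    ``predictive`` is 1 iff the chosen candidate is in the argmin set of
    partial-system H_sym over the four candidates — i.e. it yields the
    greatest possible decrease in symmetric conditional entropy given the
    choices made so far. ``n_argmin`` records how many candidates tie at the
    minimum, so downstream analyses can separate forced/tied choices from
    genuinely diagnostic ones.
    """
    if chosen not in trial.candidates:
        raise ValueError(f"chosen form {chosen!r} is not a trial candidate")
    entropies = candidate_entropies(trial, prior_choices, referent)
    h_min = min(entropies.values())
    argmin = {c for c, h in entropies.items() if h <= h_min + _TIE_TOL}
    return CodedChoice(
        participant_id=participant_id,
        trial_id=trial.trial_id,
        system_type=trial.system_type.type_id,
        referent=referent,
        chosen_form=chosen,
        selection_index=selection_index,
        predictive=int(chosen in argmin),
        n_argmin=len(argmin),
    )


def code_trial_run(run: TrialRun) -> list[CodedChoice]:
    """Replay one participant-trial in selection order, coding every choice."""
    coded: list[CodedChoice] = []
    prior: dict[str, str] = {}
    for rec in sorted(run.responses, key=lambda r: r.selection_index):
        coded.append(
            code_choice(
                run.trial, prior, rec.referent, rec.chosen_form,
                participant_id=run.participant_id,
                selection_index=rec.selection_index,
            )
        )
        prior[rec.referent] = rec.chosen_form
    return coded


def proportion_predictive(
    coded: list[CodedChoice] | pd.DataFrame,
    group_by: str | list[str] | None = None,
    unique_argmin_only: bool = False,
) -> pd.DataFrame:
    """Mean of the predictive flags, overall or per group.

    ``unique_argmin_only=True`` restricts to choices where a single candidate
    minimised H_sym (chance level 1/4).
    """
    df = coded if isinstance(coded, pd.DataFrame) else pd.DataFrame([c.__dict__ for c in coded])
    if df.empty:
        raise ValueError("no coded choices")
    if unique_argmin_only:
        df = df[df["n_argmin"] == 1]
        if df.empty:
            raise ValueError("no unique-argmin choices")
    if group_by is None:
        return pd.DataFrame(
            [{"proportion_predictive": df["predictive"].mean(), "n_choices": len(df)}]
        )
    grouped = df.groupby(group_by)["predictive"].agg(["mean", "count"]).reset_index()
    return grouped.rename(columns={"mean": "proportion_predictive", "count": "n_choices"})


# ---------------------------------------------------------------------------
# System-level scoring
# ---------------------------------------------------------------------------

def participant_system_z(
    run: TrialRun,
    n_permutations: int = 1000,
    seed: int = 0,
    include_given: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
) -> PermutationResult:
    """Permutation z-score of H_sym for one completed participant system.

    The statistic is the symmetric conditional entropy of the completed
    16-referent system. Each baseline draw shuffles which G0 referents carry
    which of the ten G0 forms (multiset preserved). By default the given
    labels are shuffled along with the chosen ones; ``include_given=False``
    holds the given labels fixed and shuffles only the participant's own
    choices.
    """
    completion = run.completion()
    slots = list(G0_REFERENTS) if include_given else list(run.trial.unlabelled)
    fixed = {} if include_given else dict(run.trial.given_g0)
    g1 = run.trial.g1_labels
    link_parents = [g1[p] for p, _ in TREE_LINKS]
    link_children = [c for _, c in TREE_LINKS]

    def h_of(g0_labels: dict[str, str]) -> float:
        return h_sym_of_pairs(
            [(pl, g0_labels[c]) for pl, c in zip(link_parents, link_children)]
        )

    observed = h_of(completion)
    forms = [completion[s] for s in slots]
    rng = np.random.default_rng(seed)
    baseline = []
    for _ in range(n_permutations):
        order = rng.permutation(len(forms))
        labels = dict(fixed)
        for slot, idx in zip(slots, order):
            labels[slot] = forms[idx]
        baseline.append(h_of(labels))
    mean = sum(baseline) / len(baseline)
    sd = math.sqrt(sum((b - mean) ** 2 for b in baseline) / len(baseline))
    if sd <= SD_EPS:
        sd = 0.0
    z = (observed - mean) / sd if sd > 0 else 0.0
    return PermutationResult(
        observed=observed,
        baseline_mean=mean,
        baseline_sd=sd,
        z=z,
        n_permutations=n_permutations,
        seed=seed,
        classification=classify(z, threshold),
        percentile_classification=_classify_percentile(observed, baseline),
    )


def ideal_predictive_completion(trial: Trial) -> tuple[float, list[dict[str, str]]]:
    """Exhaustive search for the minimum-H_sym completions of a trial.

    Enumerates every assignment of the four candidates to the unlabelled
    referents (at most 4^8 = 65,536 states) and returns the global minimum
    symmetric conditional entropy together with all completions attaining it
    (each as a full G0 referent → form map including the given labels).
    """
    unlabelled = trial.unlabelled
    g1 = trial.g1_labels
    static_pairs = [
        (g1[p], trial.given_g0[c]) for p, c in TREE_LINKS if c in trial.given_g0
    ]
    slot_parents = [
        [g1[p] for p, c in TREE_LINKS if c == ref] for ref in unlabelled
    ]
    best = math.inf
    minimizers: list[tuple[str, ...]] = []
    for assignment in itertools.product(trial.candidates, repeat=len(unlabelled)):
        pairs = list(static_pairs)
        for form, parents in zip(assignment, slot_parents):
            for pl in parents:
                pairs.append((pl, form))
        h = h_sym_of_pairs(pairs)
        if h < best - _TIE_TOL:
            best = h
            minimizers = [assignment]
        elif h <= best + _TIE_TOL:
            minimizers.append(assignment)
    completions = [
        {**trial.given_g0, **dict(zip(unlabelled, assignment))}
        for assignment in minimizers
    ]
    return best, completions


# ---------------------------------------------------------------------------
# Categorisation summaries
# ---------------------------------------------------------------------------

def cooccurrence_matrix(completions: list[dict[str, str]]) -> pd.DataFrame:
    """10x10 matrix of how often pairs of G0 referents share a form.

    Entry (i, j) is the proportion of completed systems in which referents i
    and j bear the same form; the diagonal is 1 (every referent shares a form
    with itself) and the matrix is symmetric.
    """
    if not completions:
        raise ValueError("no completions")
    refs = G0_REFERENTS
    mat = np.zeros((len(refs), len(refs)))
    for comp in completions:
        forms = [comp[r] for r in refs]
        for i in range(len(refs)):
            for j in range(i, len(refs)):
                if forms[i] == forms[j]:
                    mat[i, j] += 1
                    mat[j, i] += 1 if i != j else 0
    mat /= len(completions)
    return pd.DataFrame(mat, index=list(refs), columns=list(refs))


def code_gender_distinctions(completion: dict[str, str]) -> dict[str, int]:
    """1 per gender-paired duo iff its two referents bear different forms."""
    return {
        f"{a}/{b}": int(completion[a] != completion[b]) for a, b in GENDER_DUOS
    }


def gender_distinction_table(runs: list[TrialRun]) -> pd.DataFrame:
    """Long-format gender-distinction coding over completed participant-trials."""
    rows = []
    for run in runs:
        comp = run.completion()
        for duo, flag in code_gender_distinctions(comp).items():
            rows.append(
                {
                    "participant_id": run.participant_id,
                    "trial_id": run.trial.trial_id,
                    "system_type": run.trial.system_type.type_id,
                    "duo": duo,
                    "distinguished": flag,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "trial_id", "system_type", "duo", "distinguished"]
    )


# ---------------------------------------------------------------------------
# Response-log (de)serialisation
# ---------------------------------------------------------------------------

def responses_frame(runs: list[TrialRun]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": rec.participant_id,
            "trial_id": rec.trial_id,
            "system_type": run.trial.system_type.type_id,
            "referent": rec.referent,
            "chosen_form": rec.chosen_form,
            "selection_index": rec.selection_index,
        }
        for run in runs
        for rec in sorted(run.responses, key=lambda r: r.selection_index)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "trial_id", "system_type",
            "referent", "chosen_form", "selection_index",
        ],
    )


def trials_frame(runs: list[TrialRun]) -> pd.DataFrame:
    """Long-format trial configuration: G+1 labels, given G0 labels, candidates."""
    rows = []
    for run in runs:
        t = run.trial
        for ref in G1_REFERENTS:
            rows.append((run.participant_id, t.trial_id, t.system_type.type_id,
                         "g1_label", ref, t.g1_labels[ref]))
        for ref, form in sorted(t.given_g0.items()):
            rows.append((run.participant_id, t.trial_id, t.system_type.type_id,
                         "given_g0", ref, form))
        for form in t.candidates:
            rows.append((run.participant_id, t.trial_id, t.system_type.type_id,
                         "candidate", "", form))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "trial_id", "system_type", "kind", "referent", "form"],
    )


def load_experiment_log(
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    system_types: dict[str, SystemType] | None = None,
) -> list[TrialRun]:
    """Reassemble TrialRuns from a response log and its trial-configuration table.

    Raises a ValueError naming the participant and trial when a trial is
    incomplete (an unlabelled referent never answered).
    """
    system_types = system_types or DEFAULT_SYSTEM_TYPES
    runs = []
    for (pid, tid), tgroup in trials.groupby(["participant_id", "trial_id"], sort=True):
        type_id = tgroup["system_type"].iloc[0]
        if type_id not in system_types:
            raise ValueError(f"unknown system type {type_id!r} for trial {tid!r}")
        g1_labels = {
            r["referent"]: r["form"]
            for _, r in tgroup[tgroup["kind"] == "g1_label"].iterrows()
        }
        given_g0 = {
            r["referent"]: r["form"]
            for _, r in tgroup[tgroup["kind"] == "given_g0"].iterrows()
        }
        candidates = tuple(tgroup[tgroup["kind"] == "candidate"]["form"])
        pool = tuple(dict.fromkeys(list(g1_labels.values()) + list(candidates)))
        trial = Trial(system_types[type_id], pool, g1_labels, given_g0, candidates, str(tid))
        rgroup = responses[
            (responses["participant_id"] == pid) & (responses["trial_id"] == tid)
        ]
        records = [
            ResponseRecord(str(pid), str(tid), r["referent"], r["chosen_form"],
                           int(r["selection_index"]))
            for _, r in rgroup.iterrows()
        ]
        run = TrialRun(str(pid), trial, records)
        run.completion()  # validates completeness, names participant/trial on error
        runs.append(run)
    return runs
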