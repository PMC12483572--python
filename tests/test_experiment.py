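import numpy as np
import pytest

from kinstruct.entropy import h_sym_of_pairs
from kinstruct.experiment import (
    DEFAULT_SYSTEM_TYPES,
    G0_REFERENTS,
    G1_REFERENTS,
    TREE_LINKS,
    ResponseRecord,
    SystemType,
    Trial,
    TrialRun,
    build_trial,
    candidate_entropies,
    code_choice,
    code_gender_distinctions,
    code_trial_run,
    cooccurrence_matrix,
    ideal_predictive_completion,
    load_experiment_log,
    participant_system_z,
    proportion_predictive,
    responses_frame,
    trials_frame,
)
from kinstruct.synthetic_data import (
    AgentPolicy,
    default_label_pool,
    simulate_participants,
)


def make_trial(type_id="I", given=None, trial_id="t"):
    """Deterministic trial for a system type with fixed labels."""
    st = DEFAULT_SYSTEM_TYPES[type_id]
    labels = {}
    for i, cls in enumerate(st.g1_partition):
        for ref in cls:
            labels[ref] = f"g1form_{i}"
    given = given or {"B": "sib", "MZD": "kuz"}
    pool = tuple(sorted(set(labels.values()))) + ("sib", "kuz", "nov1", "nov2")
    return Trial(st, pool, labels, given, ("sib", "kuz", "nov1", "nov2"), trial_id)


class TestSystemTypes:
    def test_eight_defaults(self):
        assert len(DEFAULT_SYSTEM_TYPES) == 8
        assert set(DEFAULT_SYSTEM_TYPES) == {
            "I", "II_side", "II_gen", "II_opp", "III_fb", "III_mz", "III_mb", "III_fz",
        }

    def test_mother_father_always_distinct_singletons(self):
        for st in DEFAULT_SYSTEM_TYPES.values():
            assert frozenset({"M"}) in st.g1_partition
            assert frozenset({"F"}) in st.g1_partition

    @pytest.mark.parametrize(
        "type_id, n_groups", [("I", 2), ("II_side", 3), ("II_gen", 3),
                              ("II_opp", 3), ("III_fb", 3), ("III_mz", 3)]
    )
    def test_child_group_counts(self, type_id, n_groups):
        assert len(DEFAULT_SYSTEM_TYPES[type_id].child_groups()) == n_groups

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError, match="M and F"):
            SystemType("bad", (frozenset({"M", "F"}),
                               frozenset({"MZ", "MB", "FZ", "FB"})))


class TestBuildTrial:
    @pytest.mark.parametrize("type_id", list(DEFAULT_SYSTEM_TYPES))
    def test_trial_well_formed(self, type_id):
        rng = np.random.default_rng(5)
        trial = build_trial(
            DEFAULT_SYSTEM_TYPES[type_id], default_label_pool(0), rng
        )
        # all six G+1 referents labelled, mother != father
        assert set(trial.g1_labels) == set(G1_REFERENTS)
        assert trial.g1_labels["M"] != trial.g1_labels["F"]
        # exactly 4 candidates, exactly 2 matching given forms
        assert len(trial.candidates) == 4
        assert len(set(trial.candidates) & set(trial.given_g0.values())) == 2
        assert len(trial.unlabelled) == 8

    def test_given_referents_from_different_child_groups(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            trial = build_trial(
                DEFAULT_SYSTEM_TYPES["II_side"], default_label_pool(1), rng
            )
            groups = trial.system_type.child_groups()
            homes = [
                next(i for i, g in enumerate(groups) if ref in g)
                for ref in trial.given_g0
            ]
            assert homes[0] != homes[1]
            # given forms are distinct (one per hidden class)
            assert len(set(trial.given_g0.values())) == 2

    def test_pool_too_small_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="pool too small"):
            build_trial(DEFAULT_SYSTEM_TYPES["II_side"],
                        ("a", "b", "c", "d", "e"), rng)


class TestCodeChoice:
    def test_within_class_merge_is_predictive(self):
        """MZD bears 'kuz'; giving MZS (same aunt class) 'kuz' is predictive."""
        trial = make_trial("I")
        coded = code_choice(trial, {}, "MZS", "kuz")
        assert coded.predictive == 1

    def test_novel_form_against_available_merge_is_not(self):
        trial = make_trial("I")
        coded = code_choice(trial, {}, "MZS", "nov1")
        assert coded.predictive == 0

    def test_cross_class_merge_is_not_predictive(self):
        """Giving MZS the sibling form merges children of distinct G+1 classes."""
        trial = make_trial("I")
        coded = code_choice(trial, {}, "MZS", "sib")
        assert coded.predictive == 0

    def test_coding_matches_brute_force_argmin(self):
        trial = make_trial("II_gen")
        prior = {"MBS": "nov1"}
        entropies = candidate_entropies(trial, prior, "FBS")
        h_min = min(entropies.values())
        for cand, h in entropies.items():
            coded = code_choice(trial, prior, "FBS", cand)
            assert coded.predictive == int(h <= h_min + 1e-9)
            assert coded.n_argmin == sum(
                1 for v in entropies.values() if v <= h_min + 1e-9
            )

    def test_novel_forms_tie(self):
        """Two unused novel forms are exchangeable: both in or out of the argmin."""
        trial = make_trial("III_fb", given={"B": "sib", "FBD": "kuz"})
        entropies = candidate_entropies(trial, {}, "MZS")
        assert entropies["nov1"] == pytest.approx(entropies["nov2"])

    def test_invariant_under_form_relabelling(self):
        trial = make_trial("I")
        relabel = {"sib": "AAA", "kuz": "BBB", "nov1": "CCC", "nov2": "DDD",
                   "g1form_0": "E", "g1form_1": "FF", "g1form_2": "G"}
        trial2 = Trial(
            trial.system_type,
            tuple(relabel.get(f, f) for f in trial.label_pool),
            {r: relabel.get(f, f) for r, f in trial.g1_labels.items()},
            {r: relabel[f] for r, f in trial.given_g0.items()},
            tuple(relabel[f] for f in trial.candidates),
            "t2",
        )
        for cand, cand2 in zip(trial.candidates, trial2.candidates):
            c1 = code_choice(trial, {}, "FZS", cand)
            c2 = code_choice(trial2, {}, "FZS", cand2)
            assert (c1.predictive, c1.n_argmin) == (c2.predictive, c2.n_argmin)

    def test_already_labelled_referent_rejected(self):
        trial = make_trial("I")
        with pytest.raises(ValueError, match="already labelled"):
            code_choice(trial, {}, "B", "sib")

    def test_non_candidate_rejected(self):
        trial = make_trial("I")
        with pytest.raises(ValueError, match="not a trial candidate"):
            code_choice(trial, {}, "MZS", "plainly_wrong")


class TestProportionPredictive:
    def test_simple_mean(self):
        import pandas as pd

        df = pd.DataFrame(
            {"predictive": [1, 1, 0, 1], "n_argmin": [1, 1, 1, 1]}
        )
        out = proportion_predictive(df)
        assert out["proportion_predictive"].iloc[0] == pytest.approx(0.75)

    def test_greedy_agent_is_fully_predictive(self):
        runs = simulate_participants(
            AgentPolicy("predictive_greedy", seed=1), 1, seed=1
        )
        coded = [c for run in runs for c in code_trial_run(run)]
        out = proportion_predictive(coded)
        assert out["proportion_predictive"].iloc[0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            proportion_predictive([])


class TestParticipantSystemZ:
    def _uniform_run(self, seed=0):
        rng = np.random.default_rng(seed)
        trial = make_trial("I")
        records = [
            ResponseRecord("p", "t", ref,
                           trial.candidates[rng.integers(4)], i)
            for i, ref in enumerate(trial.unlabelled)
        ]
        return TrialRun("p", trial, records)

    def test_single_choice_form_with_fixed_given_gives_z_zero(self):
        """Shuffling identical chosen forms only: zero baseline spread, z = 0."""
        trial = make_trial("I")
        records = [
            ResponseRecord("p", "t", ref, "nov1", i)
            for i, ref in enumerate(trial.unlabelled)
        ]
        run = TrialRun("p", trial, records)
        result = participant_system_z(run, n_permutations=100, seed=0,
                                      include_given=False)
        assert result.z == 0.0 and result.baseline_sd == 0.0

    def test_minimum_entropy_completion_scores_low(self):
        runs = simulate_participants(
            AgentPolicy("predictive_greedy", seed=2), 1, seed=2
        )
        for run in runs:
            result = participant_system_z(run, n_permutations=500, seed=3)
            assert result.z <= 0
            assert result.observed <= result.baseline_mean + 1e-9

    def test_random_completions_rarely_significant(self):
        hits = 0
        n_reps = 60
        for rep in range(n_reps):
            run = self._uniform_run(seed=rep)
            result = participant_system_z(run, n_permutations=300, seed=rep)
            hits += abs(result.z) < 1.96
        assert hits / n_reps >= 0.90

    def test_incomplete_trial_rejected(self):
        trial = make_trial("I")
        run = TrialRun("p7", trial, [])
        with pytest.raises(ValueError, match="p7"):
            participant_system_z(run, n_permutations=10, seed=0)

    def test_reproducible(self):
        run = self._uniform_run(seed=5)
        r1 = participant_system_z(run, n_permutations=100, seed=9)
        r2 = participant_system_z(run, n_permutations=100, seed=9)
        assert r1 == r2


class TestIdealPredictiveCompletion:
    def test_type_i_minimum_maps_classes_consistently(self):
        trial = make_trial("I")
        min_h, completions = ideal_predictive_completion(trial)
        # the irreducible uncertainty: siblings' term maps back to mother OR
        # father, each carrying 2 of the 12 tree links -> (4/12) * 1 bit
        assert min_h == pytest.approx(4 / 12)
        for comp in completions:
            # all cousins share one form, both siblings share another
            cousins = {comp[r] for r in G0_REFERENTS if r not in ("B", "Z")}
            sibs = {comp["B"], comp["Z"]}
            assert len(cousins) == 1 and len(sibs) == 1
            assert cousins != sibs

    def test_minimum_bounds_greedy_agents(self):
        runs = simulate_participants(
            AgentPolicy("predictive_greedy", seed=4), 1, seed=4
        )
        for run in runs[:3]:
            comp = run.completion()
            g1 = run.trial.g1_labels
            h = h_sym_of_pairs([(g1[p], comp[c]) for p, c in TREE_LINKS])
            min_h, completions = ideal_predictive_completion(run.trial)
            assert h == pytest.approx(min_h, abs=1e-9)
            # all reported completions attain exactly the minimum
            for ideal in completions[:5]:
                h_ideal = h_sym_of_pairs(
                    [(g1[p], ideal[c]) for p, c in TREE_LINKS]
                )
                assert h_ideal == pytest.approx(min_h, abs=1e-9)


class TestCategorisationSummaries:
    def test_cooccurrence_diagonal_and_symmetry(self):
        runs = simulate_participants(AgentPolicy("random", seed=6), 3, seed=6)
        mat = cooccurrence_matrix([r.completion() for r in runs])
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.allclose(mat.values, mat.values.T)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()

    def test_greedy_type_i_cousins_fully_cocategorised(self):
        runs = simulate_participants(
            AgentPolicy("predictive_greedy", seed=8), 4, seed=8
        )
        type_i = [r.completion() for r in runs if r.trial.system_type.type_id == "I"]
        mat = cooccurrence_matrix(type_i)
        cousins = [r for r in G0_REFERENTS if r not in ("B", "Z")]
        assert np.allclose(mat.loc[cousins, cousins].values, 1.0)

    def test_gender_coding_examples(self):
        comp = {r: "a" for r in G0_REFERENTS}
        comp["MZD"] = "b"
        coded = code_gender_distinctions(comp)
        assert coded["MZS/MZD"] == 1
        assert coded["MBS/MBD"] == 0
        all_same = code_gender_distinctions({r: "x" for r in G0_REFERENTS})
        assert set(all_same.values()) == {0}
        all_distinct = code_gender_distinctions(
            {r: f"form_{i}" for i, r in enumerate(G0_REFERENTS)}
        )
        assert set(all_distinct.values()) == {1}


class TestResponseLogs:
    def test_roundtrip(self):
        runs = simulate_participants(AgentPolicy("random", seed=10), 2, seed=10)
        responses = responses_frame(runs)
        trials = trials_frame(runs)
        loaded = load_experiment_log(responses, trials)
        assert len(loaded) == len(runs)
        original = {(r.participant_id, r.trial.trial_id): r.completion() for r in runs}
        for run in loaded:
            assert run.completion() == original[(run.participant_id, run.trial.trial_id)]

    def test_incomplete_trial_error_names_participant(self):
        runs = simulate_participants(AgentPolicy("random", seed=11), 1, seed=11)
        responses = responses_frame(runs)
        trials = trials_frame(runs)
        broken = responses.drop(index=responses.index[0])
        with pytest.raises(ValueError, match="agent_0000"):
            load_experiment_log(broken, trials)
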