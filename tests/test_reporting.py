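import numpy as np
import pandas as pd
import pytest

from pporl import (CohortData, PosteriorDraws, SubjectCovariates, SubjectData,
                   TrialRecord, block_play_proportions, drop_dyad_members,
                   frames_to_cohort, group_contrasts, read_cohort,
                   summarize_posterior, task_components, write_cohort)
from pporl.inference import InferenceError
from pporl.io import CohortIOError, cohort_to_frames
from pporl.reporting import ReportingError


def draws_from_beta(beta):
    """Wrap a (chain, draw, 4, 5) array in a PosteriorDraws shell."""
    c, d = beta.shape[:2]
    sigma = np.ones((c, d, 4))
    z = np.zeros((c, d, 2, 4))
    return PosteriorDraws(beta, sigma, z, np.ones((2, 5)), ("a", "b"))


class TestSummarizePosterior:
    def test_symmetric_draws_are_not_significant(self, rng):
        beta = rng.normal(size=(2, 500, 4, 5))
        table = summarize_posterior(draws_from_beta(beta))
        coef_rows = table[table["coef"] != "sigma"]
        assert not coef_rows["significant"].any()
        assert np.allclose(coef_rows["p_gt_0"], 0.5, atol=0.1)

    def test_constant_draws_collapse_interval(self):
        beta = np.full((1, 50, 4, 5), 2.0)
        table = summarize_posterior(draws_from_beta(beta))
        row = table[(table["param"] == "a_rew") & (table["coef"] == "b0")].iloc[0]
        assert row["mean"] == row["lo95"] == row["hi95"] == 2.0
        assert row["significant"]

    def test_flag_means_interval_excludes_zero(self, rng):
        beta = rng.normal(size=(2, 400, 4, 5)) + rng.normal(
            size=(1, 1, 4, 5)) * 2
        table = summarize_posterior(draws_from_beta(beta))
        coef_rows = table[table["coef"] != "sigma"]
        for _, r in coef_rows.iterrows():
            assert r["significant"] == (r["lo95"] > 0 or r["hi95"] < 0)
            assert r["lo95"] <= r["hi95"]

    def test_empty_draws_rejected(self):
        with pytest.raises(InferenceError):
            summarize_posterior(draws_from_beta(np.zeros((1, 0, 4, 5))))

    def test_hdi_option(self, rng):
        beta = rng.normal(size=(2, 500, 4, 5))
        table = summarize_posterior(draws_from_beta(beta), interval="hdi")
        assert (table["lo95"] <= table["hi95"]).all()


class TestGroupContrasts:
    def test_zero_effect_contrasts_center_on_zero(self, rng):
        beta = rng.normal(size=(2, 800, 4, 5)) * 0.02
        table = group_contrasts(draws_from_beta(beta))
        assert np.allclose(table["mean"], 0.0, atol=0.01)
        assert len(table) == 16  # 4 params x 4 indicators

    def test_contrast_equals_coefficient_for_indicators(self, rng):
        beta = rng.normal(size=(1, 300, 4, 5))
        draws = draws_from_beta(beta)
        table = group_contrasts(draws)
        anx_bf = table[(table["param"] == "beta_f")
                       & (table["contrast"].str.startswith("anx"))].iloc[0]
        direct = draws.coef_draws("beta_f", "anx")
        assert anx_bf["mean"] == pytest.approx(float(direct.mean()))


def toy_cohort():
    """Two hand-built subjects on a 8-trial two-block miniature task."""
    _, schedule, sequences = task_components()
    decks = schedule.presented_deck

    def subject(sid, plays):
        pos = {d: 0 for d in "ABCD"}
        recs = []
        for t, deck in enumerate(decks, start=1):
            if t in plays:
                out = sequences[deck].outcomes[pos[deck]]
                pos[deck] += 1
                recs.append(TrialRecord(t, deck, 1, out))
            else:
                recs.append(TrialRecord(t, deck, 0, None))
        return SubjectData(sid, tuple(recs))

    covs = (SubjectCovariates(1, 0, 0, 0, "d1"),
            SubjectCovariates(0, 0, 0, 1, "d1"))
    behavior = (subject("S1", set(range(1, 121))), subject("S2", set()))
    return CohortData(covs, behavior, None, schedule, sequences)


class TestBlockPlayProportions:
    def test_all_play_and_all_pass_rows(self):
        table = block_play_proportions(toy_cohort())
        assert set(table["block"]) == {1, 2, 3}
        assert np.allclose(table["play_proportion"], 0.5)
        assert np.allclose(table["last_minus_first"], 0.0)

    def test_groups_split_the_two_subjects(self):
        table = block_play_proportions(toy_cohort(), group_by="anxiety")
        anx = table[table["group"] == "anxiety=1"]
        ctrl = table[table["group"] == "anxiety=0"]
        assert np.allclose(anx["play_proportion"], 1.0)
        assert np.allclose(ctrl["play_proportion"], 0.0)

    def test_hand_counted_cell(self, small_cohort):
        table = block_play_proportions(small_cohort, block_size=10)
        deck_pos = {d: [] for d in "ABCD"}
        for t, d in enumerate(small_cohort.schedule.presented_deck):
            deck_pos[d].append(t)
        cols = deck_pos["B"][10:20]  # deck-B block 2
        manual = np.mean([[s.trials[t].choice for t in cols]
                          for s in small_cohort.behavior])
        cell = table[(table["group"] == "all") & (table["deck"] == "B")
                     & (table["block"] == 2)].iloc[0]
        assert cell["play_proportion"] == pytest.approx(manual)

    def test_invariant_to_subject_order(self, small_cohort):
        rev = CohortData(small_cohort.covariates[::-1],
                         small_cohort.behavior[::-1],
                         None, small_cohort.schedule, small_cohort.sequences)
        a = block_play_proportions(small_cohort)
        b = block_play_proportions(rev)
        pd.testing.assert_frame_equal(a, b)

    def test_block_size_must_divide_deck(self, small_cohort):
        with pytest.raises(ReportingError):
            block_play_proportions(small_cohort, block_size=7)


class TestDropDyadMembers:
    def make_cohort(self, n, n_dyads):
        from pporl import CohortSpec, generate_cohort
        frac = 2 * n_dyads / n
        return generate_cohort(CohortSpec(n_subjects=n, dyad_fraction=frac))

    def test_removes_exactly_one_per_dyad(self):
        cohort = self.make_cohort(20, 6)
        for seed in (0, 1, 99):
            sub = drop_dyad_members(cohort, seed)
            assert sub.n_subjects == 14
            remaining = [c.dyad_id for c in sub.covariates
                         if c.dyad_id is not None]
            assert len(remaining) == len(set(remaining)) == 6

    def test_study_scale_arithmetic(self):
        cohort = self.make_cohort(293, 67)
        assert drop_dyad_members(cohort, 3).n_subjects == 226

    def test_no_dyads_no_change(self):
        cohort = self.make_cohort(10, 0)
        sub = drop_dyad_members(cohort, 0)
        assert sub.covariates == cohort.covariates

    def test_same_seed_same_subset(self):
        cohort = self.make_cohort(30, 10)
        a = drop_dyad_members(cohort, 7)
        b = drop_dyad_members(cohort, 7)
        assert a.subject_ids == b.subject_ids

    def test_overfull_dyad_rejected(self):
        cohort = self.make_cohort(12, 3)
        covs = list(cohort.covariates)
        bad = [SubjectCovariates(c.anxiety, c.depression, c.sud, c.sex, "dX")
               for c in covs[:3]]
        broken = CohortData(tuple(bad + covs[3:]), cohort.behavior,
                            cohort.true_params, cohort.schedule,
                            cohort.sequences)
        with pytest.raises(ReportingError):
            drop_dyad_members(broken, 0)


class TestCohortIO:
    def test_round_trip_preserves_everything(self, small_cohort, tmp_path):
        t, c, tr = (tmp_path / "t.csv", tmp_path / "c.csv",
                    tmp_path / "truth.csv")
        write_cohort(small_cohort, t, c, tr)
        back = read_cohort(t, c, tr)
        assert back.covariates == small_cohort.covariates
        assert back.behavior == small_cohort.behavior
        assert back.true_params == small_cohort.true_params

    def test_missing_column_named(self, small_cohort, tmp_path):
        trials, covs, _ = cohort_to_frames(small_cohort)
        with pytest.raises(CohortIOError, match="choice"):
            frames_to_cohort(trials.drop(columns=["choice"]), covs)

    def test_outcome_on_pass_row_listed(self, small_cohort):
        trials, covs, _ = cohort_to_frames(small_cohort)
        idx = trials.index[trials["choice"] == 0][0]
        trials.loc[idx, "outcome"] = 50.0
        with pytest.raises(CohortIOError, match="pass"):
            frames_to_cohort(trials, covs)

    def test_duplicate_trial_key_rejected(self, small_cohort):
        trials, covs, _ = cohort_to_frames(small_cohort)
        trials = pd.concat([trials, trials.iloc[[0]]])
        with pytest.raises(CohortIOError, match="duplicated"):
            frames_to_cohort(trials, covs)

    def test_non_binary_indicator_rejected(self, small_cohort):
        trials, covs, _ = cohort_to_frames(small_cohort)
        covs.loc[0, "anxiety"] = 2
        with pytest.raises(CohortIOError, match="anxiety"):
            frames_to_cohort(trials, covs)
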