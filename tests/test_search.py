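"""Interaction search: splitting, candidate enumeration, scoring,
control veto, and validation-set estimation."""
import numpy as np
import pandas as pd
import pytest

from suicohort.coding import code_records, filter_complete
from suicohort.interaction_search import (
    BASE_TERMS,
    DEFAULT_VARIABLES,
    InteractionFeature,
    InteractionSearchLogit,
    LeakageError,
    SearchConfig,
    SearchState,
    SplitBundle,
    control_improves,
    enumerate_candidates,
    phase1_search,
    phase2_estimate,
    score_candidate,
    split_data,
)
from suicohort.univariate import fit_logistic
from .conftest import make_raw, structure_cohort


@pytest.fixture(scope="module")
def coded():
    kept, _ = filter_complete(code_records(make_raw(n=400, seed=9)))
    return kept


class TestSplit:
    def test_largest_remainder_sizes(self, coded):
        b = split_data(coded.head(100), seed=0)
        assert (len(b.primary_training), len(b.control), len(b.validation)) == (40, 10, 50)

    def test_deterministic(self, coded):
        a = split_data(coded, seed=5)
        b = split_data(coded, seed=5)
        assert list(a.validation.index) == list(b.validation.index)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_properties(self, coded, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, len(coded)))
        sub = coded.sample(n, random_state=seed)
        b = split_data(sub, seed=seed)
        idx = [set(b.primary_training.index), set(b.control.index), set(b.validation.index)]
        assert sum(map(len, idx)) == n
        assert set().union(*idx) == set(sub.index)
        for size, frac in zip(map(len, idx), (0.4, 0.1, 0.5)):
            assert abs(size - frac * n) <= 1

    def test_bad_fractions(self, coded):
        with pytest.raises(ValueError):
            split_data(coded, seed=0, fractions=(0.5, 0.2, 0.5))


class TestInteractionFeature:
    def test_canonical_name_fixed_variable_order(self):
        f = InteractionFeature((("risk", "high"), ("age_band_ml", "<18")))
        assert f.name == "<18 + high"
        assert f.order == 2

    def test_rejects_duplicate_variable_or_order_one(self):
        with pytest.raises(ValueError):
            InteractionFeature((("risk", "high"), ("risk", "low")))
        with pytest.raises(ValueError):
            InteractionFeature((("risk", "high"),))

    def test_indicator_is_conjunction(self, coded):
        f = InteractionFeature((("gender", "male"), ("risk", "high")))
        ind = f.indicator(coded)
        manual = ((coded["gender"] == "male") & (coded["risk"] == "high")).to_numpy()
        assert (ind == manual.astype(float)).all()


class TestEnumerate:
    def test_two_binary_variables_order_two(self, coded):
        state = SearchState()
        variables = {"gender": ("male", "female"), "era": ("pre_corona", "corona")}
        cfg = SearchConfig(max_order=2, min_count=0)
        out = enumerate_candidates(state, variables, cfg, coded)
        assert len(out) == 4

    def test_study_variables_pairwise_count(self, coded):
        state = SearchState()
        cfg = SearchConfig(max_order=2, min_count=0)
        out = enumerate_candidates(state, DEFAULT_VARIABLES, cfg, coded)
        assert len(out) == 37

    def test_all_in_list_yields_empty(self, coded):
        cfg = SearchConfig(max_order=2, min_count=0)
        state = SearchState()
        first = enumerate_candidates(state, DEFAULT_VARIABLES, cfg, coded)
        state.considered = [f.name for f in first]
        assert enumerate_candidates(state, DEFAULT_VARIABLES, cfg, coded) == []

    def test_sparse_cell_guard(self, coded):
        cfg = SearchConfig(max_order=2, min_count=10**6)
        assert enumerate_candidates(SearchState(), DEFAULT_VARIABLES, cfg, coded) == []


class TestScoring:
    def test_collinear_feature_scores_zero(self, coded):
        y = coded["si"].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(coded)), (coded["gender"] == "female").to_numpy(float)]
        )
        fit = fit_logistic(X, y, ridge=1e-8)
        score, _ = score_candidate(fit, X, X[:, 1].copy(), y)
        assert score == pytest.approx(0.0, abs=1e-6)

    def test_identical_models_do_not_improve_control(self, coded):
        y = coded["si"].to_numpy(float)
        X = np.ones((len(coded), 1))
        fit = fit_logistic(X, y)
        assert not control_improves(fit, fit, X, X, y)


class TestPhase1:
    def test_immediate_termination_above_any_score(self, coded):
        bundle = split_data(coded, seed=0)
        cfg = SearchConfig(threshold=1e9)
        state = phase1_search(bundle, "si", cfg)
        assert state.accepted == []
        assert state.considered == []
        assert state.log[-1]["stop"] == "no candidate above threshold"

    def test_log_replays_deterministically(self, coded):
        bundle = split_data(coded, seed=3)
        cfg = SearchConfig(threshold=2.0)  # permissive: forces iterations
        a = phase1_search(bundle, "si", cfg)
        b = phase1_search(bundle, "si", cfg)
        assert a.log == b.log
        assert [f.name for f in a.accepted] == [f.name for f in b.accepted]

    def test_considered_list_grows_monotonically(self, coded):
        bundle = split_data(coded, seed=3)
        state = phase1_search(bundle, "si", SearchConfig(threshold=2.0))
        # every accepted feature was considered, no feature considered twice
        names = state.considered
        assert len(names) == len(set(names))
        assert {f.name for f in state.accepted} <= set(names)


class TestPhase2:
    def test_empty_accepted_reduces_to_base_model(self, coded):
        bundle = split_data(coded, seed=1)
        rep = phase2_estimate(bundle, [], "si")
        terms = rep.to_frame()["term"].tolist()
        assert terms == [
            "B0 (full population)", "male", "<18", "low", "pre_corona",
            *BASE_TERMS,
        ]

    def test_reference_rows_and_wald_duality(self, coded):
        bundle = split_data(coded, seed=1)
        rep = phase2_estimate(
            bundle,
            [InteractionFeature((("gender", "female"), ("era", "corona")))],
            "si",
        ).to_frame()
        refs = rep[rep["reference"]]
        assert (refs["estimate"] == 0).all() and (refs["odds_ratio"] == 1).all()
        est = rep[~rep["reference"]]
        np.testing.assert_allclose(
            est["odds_ratio"], np.exp(est["estimate"]), rtol=1e-12
        )
        excludes_one = (est["ci_low"] > 1) | (est["ci_high"] < 1)
        assert (excludes_one == (est["t"].abs() > 1.959964)).all()

    def test_intercept_row_counts_validation_events(self, coded):
        bundle = split_data(coded, seed=1)
        rep = phase2_estimate(bundle, [], "si").to_frame()
        assert rep.loc[0, "n"] == int(bundle.validation["si"].sum())

    def test_leakage_raises(self, coded):
        bundle = split_data(coded, seed=2)
        leaky = SplitBundle(
            primary_training=bundle.primary_training,
            control=bundle.control,
            validation=pd.concat(
                [bundle.validation, bundle.primary_training.head(1)]
            ),
            seed=2,
            fractions=bundle.fractions,
        )
        with pytest.raises(LeakageError):
            phase2_estimate(leaky, [], "si")


class TestModelObject:
    def test_fit_returns_trace_and_report(self, coded):
        res = InteractionSearchLogit(coded, "si").fit(seed=0)
        assert res.summary().shape[0] >= 11  # intercept + 4 refs + 6 dummies
        assert isinstance(res.considered, list)

    def test_search_config_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(threshold=-1.0)
        with pytest.raises(ValueError):
            SearchConfig(max_order=1)
        assert 0 < SearchConfig().candidate_alpha < 0.002

    def test_recovers_planted_interaction_single_seed(self):
        # one medium-size planted-truth run; the multi-seed power study
        # lives in the acceptance suite
        kept = structure_cohort(200_000, seed=1000)
        res = InteractionSearchLogit(kept, "si").fit(seed=2000)
        assert "<18 + high" in [f.name for f in res.accepted_features]
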