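import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracles import kozak_oracle
from periscore.pepscore import (
    PepScoreModel,
    aa_category_fractions,
    feature_t1,
    feature_t2,
    feature_t3,
    kozak_score,
    kozak_score_at,
    optimal_codon_fraction,
    score_peptides,
    tau_index,
    train_pepscore,
)
from periscore.synthetic import simulate_pepscore_features


class TestFeatureT1:
    def test_log_identity(self):
        assert feature_t1(0.01, 1000) == pytest.approx(2.0)
        assert feature_t1(1.0, 1000) == 0.0

    def test_zero_fdr_clamped_by_pseudocount(self):
        assert feature_t1(0.0, 999) == pytest.approx(3.0)

    def test_nonincreasing_in_fdr(self):
        fdrs = np.linspace(0.0, 1.0, 50)
        t1s = [feature_t1(f, 500) for f in fdrs]
        assert all(a >= b - 1e-12 for a, b in zip(t1s, t1s[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            feature_t1(1.5, 100)
        with pytest.raises(ValueError):
            feature_t1(0.5, 0)


class TestFeatureT2:
    def test_domain_presence(self):
        table = {"a": {"PF00001"}, "b": set(), "c": {"TMhelix"}}
        assert feature_t2(table, "a") == 1
        assert feature_t2(table, "b") == 0
        assert feature_t2(table, "c") == 1  # TMHMM-only hit suffices

    def test_absent_orf_counts_as_negative(self):
        assert feature_t2({}, "missing") == 0


class TestFeatureT3:
    def test_signed_log_examples(self):
        assert feature_t3([50.0, 49.0]) == pytest.approx(2.0)  # sum 99
        assert feature_t3([-999.0]) == pytest.approx(-3.0)
        assert feature_t3([0.0, 0.0]) == 0.0

    def test_empty_vector_is_error(self):
        with pytest.raises(ValueError):
            feature_t3([])

    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=1, max_size=20
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_odd_under_negation(self, scores):
        assert feature_t3([-s for s in scores]) == pytest.approx(-feature_t3(scores))


class TestTrainPepscore:
    def _separable(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        pos = pd.DataFrame(
            {"t1": rng.uniform(3, 5, n), "t2": 1.0, "t3": rng.uniform(1, 3, n), "label": 1}
        )
        neg = pd.DataFrame(
            {"t1": rng.uniform(0, 1, n), "t2": 0.0, "t3": rng.uniform(-3, -1, n), "label": 0}
        )
        return (
            pd.concat([pos, neg], ignore_index=True)
            .sample(frac=1, random_state=seed)
            .reset_index(drop=True)
        )

    def test_separable_gives_perfect_test_auroc(self):
        model = train_pepscore(self._separable(), n_train=200, n_test=100, rng_seed=1)
        assert model.test_auroc == 1.0
        assert model.n_train == 200 and model.n_test == 100

    def test_permuted_labels_give_null_auroc(self):
        data = self._separable(n=2000)
        rng = np.random.default_rng(3)
        data["label"] = rng.permutation(data["label"].to_numpy())
        model = train_pepscore(data, n_train=1000, n_test=1000, rng_seed=3)
        assert 0.4 < model.test_auroc < 0.6

    def test_single_class_is_error(self):
        data = self._separable().query("label == 1")
        with pytest.raises(ValueError, match="both classes"):
            train_pepscore(data)

    def test_synthetic_effects_recover_positive_coefficients(self):
        data = simulate_pepscore_features(150, 150, rng=4)
        model = train_pepscore(data, n_train=200, n_test=100, rng_seed=4)
        assert all(v > 0 for v in model.coef.values())
        assert model.test_auroc >= 0.9

    def test_json_roundtrip(self, tmp_path):
        model = train_pepscore(self._separable(), rng_seed=0)
        path = tmp_path / "pepscore.json"
        model.to_json(path)
        assert PepScoreModel.from_json(path) == model


class TestScorePeptides:
    def _model(self):
        return PepScoreModel(intercept=0.0, coef={"t1": 1.0, "t2": 0.0, "t3": 0.0})

    def test_zero_model_scores_half(self):
        model = PepScoreModel(intercept=0.0, coef={"t1": 0.0, "t2": 0.0, "t3": 0.0})
        df = pd.DataFrame({"t1": [5.0], "t2": [1.0], "t3": [2.0]})
        assert score_peptides(model, df)["pepscore"].iloc[0] == 0.5

    def test_monotone_in_t1_with_positive_coefficient(self):
        df = pd.DataFrame({"t1": np.linspace(0, 5, 20), "t2": 0.0, "t3": 0.0})
        scores = score_peptides(self._model(), df)["pepscore"].to_numpy()
        assert (np.diff(scores) > 0).all()

    def test_threshold_is_strict(self):
        model = PepScoreModel(intercept=0.0, coef={"t1": 0.0, "t2": 0.0, "t3": 0.0})
        df = pd.DataFrame({"t1": [0.0], "t2": [0.0], "t3": [0.0]})
        out = score_peptides(model, df, threshold=0.5)
        assert out["pepscore"].iloc[0] == 0.5 and not out["high_pepscore"].iloc[0]

    def test_non_aug_refused_without_force(self):
        df = pd.DataFrame(
            {"t1": [1.0, 1.0], "t2": [0, 0], "t3": [0.0, 0.0],
             "start_codon": ["ATG", "CTG"]}
        )
        with pytest.raises(ValueError, match="non-AUG"):
            score_peptides(self._model(), df)
        out = score_peptides(self._model(), df, force=True)
        assert len(out) == 2

    def test_missing_feature_named_in_error(self):
        df = pd.DataFrame({"t1": [1.0], "t2": [0]})
        with pytest.raises(ValueError, match="t3"):
            score_peptides(self._model(), df)


class TestKozakScore:
    def test_strongest_context(self):
        assert kozak_score("GCCGCC", "G") == 13

    def test_no_rule_fires(self):
        assert kozak_score("TTTTTT", "T") == 0

    def test_mixed_context(self):
        assert kozak_score("ACCGCC", "A") == 7  # 0+1+1+3+1+1+0

    def test_matches_rule_table_oracle_sample(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(500):
            ctx = "".join(bases[i] for i in rng.integers(0, 4, size=7))
            assert kozak_score(ctx[:6], ctx[6]) == kozak_oracle(ctx)

    def test_invariant_outside_scored_positions(self):
        # the AUG itself and further context never change the score
        seq1 = "GCCGCC" + "ATG" + "GAAATAG"
        seq2 = "GCCGCC" + "ATG" + "GTTTTAG"
        assert kozak_score_at(seq1, 6) == kozak_score_at(seq2, 6) == 13

    def test_short_context_scores_available_positions(self):
        # only -3..-1 present: A at -3 (+3), C at -2 (+1), C at -1 (+1)
        assert kozak_score("ACC", "G") == 3 + 1 + 1 + 3

    def test_bad_character_is_error(self):
        with pytest.raises(ValueError):
            kozak_score("GCCGCX", "G")


class TestOptimalCodonFraction:
    def test_all_optimal(self):
        assert optimal_codon_fraction("GCCGCC") == 1.0

    def test_stop_codons_excluded_from_denominator(self):
        assert optimal_codon_fraction("GCCAAATAA") == 0.5

    def test_none_optimal(self):
        assert optimal_codon_fraction("AAAAAA") == 0.0

    def test_bad_length_is_error(self):
        with pytest.raises(ValueError):
            optimal_codon_fraction("GCCA")


class TestAaCategoryFractions:
    def test_pure_hydrophobic(self):
        out = aa_category_fractions("FFFF")
        assert out["hydrophobic"] == 1.0
        assert out["charged"] == out["polar"] == out["amphipathic"] == 0.0

    def test_overlapping_categories(self):
        out = aa_category_fractions("C")
        assert out["polar"] == 1.0 and out["hydrophilic"] == 1.0

    def test_mixed_peptide(self):
        # F hydrophobic; R charged+hydrophilic; Q polar+hydrophilic;
        # C polar+hydrophilic; W amphipathic
        out = aa_category_fractions("FRQCW")
        assert out == {
            "hydrophobic": pytest.approx(0.2),
            "charged": pytest.approx(0.2),
            "polar": pytest.approx(0.4),
            "hydrophilic": pytest.approx(0.6),
            "amphipathic": pytest.approx(0.2),
        }

    def test_nonstandard_residue_is_error(self):
        with pytest.raises(ValueError):
            aa_category_fractions("FRX")


class TestTauIndex:
    def test_uniform_is_zero(self):
        assert tau_index([5.0, 5.0, 5.0]) == 0.0

    def test_one_hot_is_one(self):
        assert tau_index([10.0, 0.0, 0.0, 0.0]) == 1.0

    def test_two_tissue_example(self):
        assert tau_index([10.0, 5.0]) == 0.5

    def test_all_zero_is_nan(self):
        assert math.isnan(tau_index([0.0, 0.0]))

    def test_single_tissue_is_error(self):
        with pytest.raises(ValueError):
            tau_index([5.0])

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=12),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_positive_scaling(self, x, scale):
        if max(x) == 0 or max(v * scale for v in x) == 0:  # underflow guard
            return
        assert tau_index([v * scale for v in x]) == pytest.approx(
            tau_index(x), abs=1e-9
        )
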