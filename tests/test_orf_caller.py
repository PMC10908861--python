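import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracles import pme_oracle
from periscore.annotation_io import Transcript
from periscore.orf_caller import (
    CandidateORF,
    CodonReadMatrix,
    ORF_TYPES,
    TranslationModel,
    assemble_training_set,
    classify_orf_type,
    consensus_calls,
    enumerate_candidates,
    expression_filter,
    feature_f1,
    feature_f2,
    feature_pme,
    most_even_allocation,
    orf_rpkm,
    train_translation_model,
)


def _tx(seq, biotype="protein_coding", cds=None):
    return Transcript(
        "t", "g", biotype, "c", "+", [(0, len(seq))], cds=cds, sequence=seq
    )


class TestEnumerateCandidates:
    def test_single_orf(self):
        (orf,) = enumerate_candidates(_tx("ATGAAATAG"), start_codons=("ATG",))
        assert (orf.start, orf.end, orf.length_aa) == (0, 9, 2)

    def test_nested_starts_share_stop(self):
        orfs = enumerate_candidates(_tx("ATGATGTGTTAA"), start_codons=("ATG",))
        assert [(o.start, o.end) for o in orfs] == [(0, 12), (3, 12)]
        assert [o.length_aa for o in orfs] == [3, 2]

    def test_no_stop_no_orf(self):
        assert enumerate_candidates(_tx("ATGAAACCC"), start_codons=("ATG",)) == []

    def test_nug_and_auc_starts(self):
        orfs = enumerate_candidates(_tx("CTGAAATAG"))
        assert len(orfs) == 1 and orfs[0].start_codon == "CTG"

    def test_n_in_start_codon_skipped(self):
        assert enumerate_candidates(_tx("ATNAAATAG"), start_codons=("ATN",)) == []

    def test_min_reads_is_strict(self):
        seq = "ATGAAATAG"
        counts = np.zeros(9, dtype=int)
        counts[3] = 10
        assert (
            enumerate_candidates(_tx(seq), ("ATG",), asite_counts=counts, min_reads=10)
            == []
        )
        counts[4] = 1
        orfs = enumerate_candidates(_tx(seq), ("ATG",), asite_counts=counts, min_reads=10)
        assert len(orfs) == 1 and orfs[0].total_reads == 11


class TestPeriodicityFeatures:
    def test_f1_examples(self):
        assert feature_f1(CodonReadMatrix([(10, 0, 0)])) == 1.0
        m = CodonReadMatrix([(5, 1, 0), (2, 2, 1), (0, 3, 1), (4, 0, 0)])
        assert feature_f1(m) == pytest.approx(11 / 19)
        assert feature_f1(CodonReadMatrix([(1, 1, 1)])) == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            feature_f1(CodonReadMatrix([(0, 0, 0)]))

    def test_f2_strict_inequality(self):
        m = CodonReadMatrix([(5, 1, 0), (2, 2, 1), (0, 3, 1), (4, 0, 0)])
        assert feature_f2(m) == 0.5  # (2,2,1) fails strictness
        assert feature_f2(CodonReadMatrix([(3, 0, 0), (7, 0, 0)])) == 1.0
        assert feature_f2(CodonReadMatrix([(0, 0, 0)])) == 0.0

    def test_pme_examples(self):
        even = CodonReadMatrix([(1, 0, 0)] * 4)
        assert feature_pme(even) == 1.0
        localized = CodonReadMatrix([(4, 0, 0), (0, 0, 0), (0, 0, 0), (0, 0, 0)])
        assert feature_pme(localized) == 0.0
        # N=6 over L=4: (2,2,1,1) is itself the most even integer split
        m = CodonReadMatrix([(2, 0, 0), (0, 2, 0), (1, 0, 0), (0, 0, 1)])
        assert feature_pme(m) == 1.0

    def test_pme_partial_final_region(self):
        # L=5, N=2 -> region length 2, final region of 1 codon retained
        per_codon = [1, 0, 0, 1, 0]
        m = CodonReadMatrix([(c, 0, 0) for c in per_codon])
        assert feature_pme(m) == pytest.approx(pme_oracle(per_codon))

    def test_pme_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            L = int(rng.integers(1, 8))
            counts = rng.integers(0, 4, size=(L, 3))
            if counts.sum() == 0 or counts.sum() > 12:
                continue
            m = CodonReadMatrix(counts)
            assert feature_pme(m) == pytest.approx(
                pme_oracle(list(counts.sum(axis=1))), abs=1e-12
            )

    def test_pme_invariant_under_region_permutation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = int(rng.integers(2, 10))
            per_codon = rng.integers(0, 5, size=L)
            if per_codon.sum() == 0:
                continue
            m1 = CodonReadMatrix([(c, 0, 0) for c in per_codon])
            if per_codon.sum() > L:  # regions are single codons -> permutable
                m2 = CodonReadMatrix([(c, 0, 0) for c in rng.permutation(per_codon)])
                assert feature_pme(m1) == pytest.approx(feature_pme(m2))

    def test_adding_read_to_emptiest_region_never_decreases_pme(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            L = int(rng.integers(2, 8))
            per_codon = rng.integers(0, 5, size=L)
            n = per_codon.sum()
            if n <= L or n == 0:  # stay in the 1-codon-region regime
                continue
            before = feature_pme(CodonReadMatrix([(c, 0, 0) for c in per_codon]))
            bumped = per_codon.copy()
            bumped[np.argmin(bumped)] += 1
            after = feature_pme(CodonReadMatrix([(c, 0, 0) for c in bumped]))
            assert after >= before - 1e-12

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_features_bounded_in_unit_interval(self, rows):
        m = CodonReadMatrix(rows)
        if m.N == 0:
            return
        assert 0.0 <= feature_f1(m) <= 1.0
        assert 0.0 <= feature_f2(m) <= 1.0
        assert 0.0 <= feature_pme(m) <= 1.0

    def test_most_even_allocation(self):
        assert list(most_even_allocation(6, 4)) == [2, 2, 1, 1]
        assert list(most_even_allocation(3, 5)) == [1, 1, 1, 0, 0]


class TestClassifyOrfType:
    CDS = (50, 200)

    def _coding_tx(self):
        return _tx("A" * 300, cds=self.CDS)

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (50, 200, "canonical"),
            (5, 35, "uORF"),
            (60, 120, "iORF"),  # 60-50=10, off-frame
            (5, 101, "ouORF"),  # starts 5' of CDS, ends inside, off-frame
            (200, 230, "dORF"),
            (190, 220, "odORF"),  # starts inside off-frame, ends 3' of CDS
            (80, 200, "truncated/extended-canonical"),  # shares stop, in-frame
        ],
    )
    def test_partition_rules(self, start, end, expected):
        orf = CandidateORF("t", start, end, "ATG")
        assert classify_orf_type(orf, self._coding_tx()) == expected

    def test_biotype_rules(self):
        orf = CandidateORF("t", 10, 40, "ATG")
        assert classify_orf_type(orf, _tx("A" * 100, biotype="lncRNA")) == "lncRNA-ORF"
        assert (
            classify_orf_type(orf, _tx("A" * 100, biotype="processed_pseudogene"))
            == "pseudogene-ORF"
        )

    def test_coding_without_cds_is_error(self):
        orf = CandidateORF("t", 10, 40, "ATG")
        with pytest.raises(ValueError, match="lacks a CDS"):
            classify_orf_type(orf, _tx("A" * 100))

    def test_every_benchmark_candidate_gets_exactly_one_label(self, benchmark):
        table = benchmark["result"].orf_table
        assert table["orf_type"].isin(ORF_TYPES).all()


class TestTrainingSetAssembly:
    def _table(self, n_canon=1500, n_iorf=5000):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n_canon):
            rows.append(("canonical", "in-frame", 0.8, 0.7, 0.9))
        for i in range(n_iorf):
            rows.append(("iORF", "off-frame", 0.3, 0.2, 0.6))
        df = pd.DataFrame(
            rows, columns=["orf_type", "frame_vs_cds", "f1", "f2", "f3"]
        )
        return df.sample(frac=1, random_state=1).reset_index(drop=True)

    def test_exact_counts(self):
        out = assemble_training_set(self._table(), 1000, 3000, rng_seed=7)
        assert (out["label"] == 1).sum() == 1000
        assert (out["label"] == 0).sum() == 3000

    def test_same_seed_same_rows(self):
        t = self._table()
        a = assemble_training_set(t, 1000, 3000, rng_seed=7)
        b = assemble_training_set(t, 1000, 3000, rng_seed=7)
        assert list(a.index) == list(b.index)

    def test_shortfall_takes_all_available(self, caplog):
        out = assemble_training_set(self._table(n_canon=500), 1000, 3000, rng_seed=0)
        assert (out["label"] == 1).sum() == 500
        assert "only 500" in caplog.text

    def test_low_pme_candidates_enter_negative_pool(self):
        t = self._table(n_canon=100, n_iorf=0)
        t.loc[t.index[:50], "orf_type"] = "uORF"
        t.loc[t.index[:50], "f3"] = 0.05
        out = assemble_training_set(t, 10, 30, rng_seed=0)
        assert (out["label"] == 0).sum() == 30

    def test_disjoint_train_test_via_exclude(self):
        t = self._table()
        train = assemble_training_set(t, 1000, 3000, rng_seed=1)
        test = assemble_training_set(t, 400, 1200, rng_seed=2, exclude=train.index)
        assert set(train.index).isdisjoint(test.index)


class TestTranslationModel:
    def _separable(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        pos = pd.DataFrame(
            {
                "f1": rng.uniform(0.7, 0.95, n),
                "f2": rng.uniform(0.7, 0.95, n),
                "f3": rng.uniform(0.6, 1.0, n),
                "label": 1,
            }
        )
        neg = pd.DataFrame(
            {
                "f1": rng.uniform(0.1, 0.4, n),
                "f2": rng.uniform(0.0, 0.3, n),
                "f3": rng.uniform(0.0, 0.5, n),
                "label": 0,
            }
        )
        return pd.concat([pos, neg], ignore_index=True)

    def test_separable_data_gives_perfect_test_auroc(self):
        data = self._separable()
        model = train_translation_model(data.iloc[::2], data.iloc[1::2])
        assert model.test_auroc == 1.0

    def test_shuffled_labels_give_null_auroc(self):
        data = self._separable(n=500)
        rng = np.random.default_rng(1)
        data["label"] = rng.permutation(data["label"].to_numpy())
        train, test = data.iloc[::2], data.iloc[1::2]
        if train["label"].nunique() < 2:
            pytest.skip("degenerate shuffle")
        model = train_translation_model(train, test)
        assert 0.4 < model.test_auroc < 0.6

    def test_single_class_is_error(self):
        data = self._separable().query("label == 1")
        with pytest.raises(ValueError, match="both classes"):
            train_translation_model(data)

    def test_predict_closed_form(self):
        model = TranslationModel(intercept=0.0, coef={"f1": 1.0, "f2": 0.0, "f3": 0.0})
        df = pd.DataFrame({"f1": [1.0], "f2": [0.0], "f3": [0.0]})
        assert model.predict(df)[0] == pytest.approx(1 / (1 + np.exp(-1)))
        flat = TranslationModel(intercept=0.0, coef={"f1": 0.0, "f2": 0.0, "f3": 0.0})
        assert flat.predict(df)[0] == 0.5

    def test_json_roundtrip(self, tmp_path):
        model = TranslationModel(
            intercept=-1.5, coef={"f1": 2.0, "f2": 1.0, "f3": 0.5}, test_auroc=0.99
        )
        path = tmp_path / "m.json"
        model.to_json(path)
        back = TranslationModel.from_json(path)
        assert back == model

    def test_benchmark_coefficients_positive(self, benchmark):
        for model in benchmark["result"].models.values():
            assert all(v > 0 for v in model.coef.values())


class TestConsensusAndExpression:
    def test_consensus_examples(self):
        probs = pd.DataFrame(
            [
                [0.7, 0.5, 0.55],  # one support -> rejected
                [0.7, 0.65, 0.1],  # two supports -> retained
                [0.6, 0.9, 0.9],  # 0.6 is not > 0.6; two supports -> retained
                [0.6, 0.9, 0.2],  # only one strict support -> rejected
            ]
        )
        assert list(consensus_calls(probs)) == [False, True, True, False]

    def test_nan_probabilities_never_support(self):
        probs = pd.DataFrame([[np.nan, 0.9], [np.nan, np.nan]])
        assert list(consensus_calls(probs)) == [False, False]

    def test_rpkm_formula(self):
        assert orf_rpkm(100, 1000, 10_000_000) == pytest.approx(10.0)
        assert orf_rpkm(0, 500, 1_000_000) == 0.0
        with pytest.raises(ValueError):
            orf_rpkm(10, 0, 1_000_000)

    def test_expression_filter_any_exceeds(self):
        assert expression_filter([0.1, 0.25])
        assert not expression_filter([0.0, 0.0])
        assert not expression_filter([0.2, 0.2])  # strict
        assert expression_filter({"a": 0.05, "b": 0.21})


class TestEndToEndBenchmark:
    def test_translated_vs_untranslated_auroc(self, benchmark):
        merged = benchmark["result"].models["merged"]
        assert merged.test_auroc is not None and merged.test_auroc >= 0.95

    def test_canonical_consensus_sensitivity(self, benchmark):
        table = benchmark["result"].orf_table
        canon = table[table["orf_type"] == "canonical"]
        assert len(canon) > 50
        assert canon["consensus"].mean() >= 0.95
        assert canon["called"].mean() >= 0.95

    def test_translated_uorf_recall(self, benchmark):
        table = benchmark["result"].orf_table.set_index(
            ["transcript_id", "start", "end"]
        )
        truth = benchmark["truth"]
        planted = truth[(truth["orf_type"] == "uORF") & truth["translated"]]
        hits = sum(
            (r.transcript_id, r.start, r.end) in table.index
            and bool(table.loc[(r.transcript_id, r.start, r.end), "called"])
            for r in planted.itertuples()
        )
        assert hits / len(planted) >= 0.95
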