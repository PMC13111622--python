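"""Stimulus selection: similarity consolidation, distance fusion, pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from voicelearn import (
    SpeakerFeatures,
    build_pair_table,
    consolidate_similarity,
    delta_f0_table,
    fuse_distance,
    select_pairs,
)


def _spk(sid, gender, f0, vecs):
    return SpeakerFeatures(
        sid, gender, f0, {f"r{i}": np.asarray(v, float) for i, v in enumerate(vecs)}
    )


def _cosine(u, v):
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


class TestConsolidateSimilarity:
    @pytest.mark.parametrize(
        "vec_a, vec_b, expected",
        [
            ([(1.0, 0.0)], [(1.0, 0.0)], 1.0),  # identical embeddings
            ([(1.0, 0.0)], [(0.0, 1.0)], 0.0),  # orthogonal embeddings
            # mean over recording pairs: cos((1,0),(1,1)/sqrt2)=cos((0,1),(1,1)/sqrt2)=0.7071
            ([(1.0, 0.0), (0.0, 1.0)], [(2**-0.5, 2**-0.5)], 0.70710678),
        ],
    )
    def test_two_speaker_examples(self, vec_a, vec_b, expected):
        feats = [_spk("a", "male", 100, vec_a), _spk("b", "male", 110, vec_b)]
        table = consolidate_similarity(feats)
        assert len(table) == 1
        assert table["avg_cosine"].iloc[0] == pytest.approx(expected, abs=1e-8)

    def test_matches_brute_force_double_loop(self, tiny_speakers):
        table = consolidate_similarity(tiny_speakers)
        by_id = {f.speaker_id: f for f in tiny_speakers}
        for row in table.itertuples():
            a, b = by_id[row.speaker_i], by_id[row.speaker_k]
            sims = [
                _cosine(u, v)
                for u in a.recordings.values()
                for v in b.recordings.values()
            ]
            assert row.avg_cosine == pytest.approx(np.mean(sims), abs=1e-10)

    def test_cross_gender_pairs_absent(self, tiny_speakers):
        table = consolidate_similarity(tiny_speakers)
        males = {f.speaker_id for f in tiny_speakers if f.gender == "male"}
        for row in table.itertuples():
            assert (row.speaker_i in males) == (row.speaker_k in males)
        # all within-gender pairs present: C(4,2) per gender
        assert len(table) == 12

    def test_single_speaker_gender_names_gender(self):
        feats = [
            _spk("a", "male", 100, [(1, 0)]),
            _spk("b", "female", 200, [(1, 0)]),
            _spk("c", "female", 210, [(0, 1)]),
        ]
        with pytest.raises(ValueError, match="male"):
            consolidate_similarity(feats)

    def test_dimension_mismatch_rejected(self):
        feats = [
            _spk("a", "male", 100, [(1, 0)]),
            _spk("b", "male", 110, [(1, 0, 0)]),
        ]
        with pytest.raises(ValueError, match="dimension"):
            consolidate_similarity(feats)


class TestDeltaF0:
    def test_enumerates_all_pairs(self):
        feats = [
            _spk("a", "male", 100, [(1, 0)]),
            _spk("b", "male", 110, [(1, 0)]),
            _spk("c", "male", 125, [(0, 1)]),
        ]
        table = delta_f0_table(feats)
        got = sorted(table["delta_f0"])
        assert got == pytest.approx([10.0, 15.0, 25.0])

    def test_equal_f0_gives_zero(self):
        feats = [_spk("a", "male", 120, [(1, 0)]), _spk("b", "male", 120, [(0, 1)])]
        assert delta_f0_table(feats)["delta_f0"].iloc[0] == 0.0

    def test_invalid_f0_identifies_speaker(self):
        with pytest.raises(ValueError, match="bad_spk"):
            _spk("bad_spk", "male", -5.0, [(1, 0)])


class TestFuseDistance:
    def _row_vector_oracle(self, feats):
        """Brute-force reimplementation over explicit per-speaker vectors."""
        table = build_pair_table(feats)
        lut = {}
        for row in table.itertuples():
            lut[(row.speaker_i, row.speaker_k)] = (row.avg_cosine, row.delta_f0)
            lut[(row.speaker_k, row.speaker_i)] = (row.avg_cosine, row.delta_f0)
        speakers = sorted(f.speaker_id for f in feats)
        expected = {}
        for i, k in itertools.combinations(speakers, 2):
            others = [s for s in speakers if s not in (i, k)]
            vi = [lut[(i, o)][0] for o in others] + [lut[(i, o)][1] for o in others]
            vk = [lut[(k, o)][0] for o in others] + [lut[(k, o)][1] for o in others]
            expected[(i, k)] = np.linalg.norm(np.subtract(vi, vk))
        return expected

    def test_row_vector_matches_brute_force(self):
        rng = np.random.default_rng(3)
        feats = [
            _spk(f"s{i}", "male", 100 + 7 * i,
                 rng.standard_normal((3, 5)))
            for i in range(6)
        ]
        fused = fuse_distance(build_pair_table(feats))
        expected = self._row_vector_oracle(feats)
        for row in fused.itertuples():
            assert row.distance == pytest.approx(
                expected[(row.speaker_i, row.speaker_k)], abs=1e-10
            )

    def test_pair_2d_matches_hand_formula(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers), mode="pair_2d")
        for row in fused.itertuples():
            assert row.distance == pytest.approx(
                np.hypot(1.0 - row.avg_cosine, row.delta_f0), abs=1e-12
            )

    def test_identical_features_all_zero_with_tiebreak_ranks(self):
        feats = [
            _spk(s, "male", 100, [(1.0, 0.0)]) for s in ("a", "b", "c", "d")
        ]
        fused = fuse_distance(build_pair_table(feats))
        assert np.allclose(fused["distance"], 0.0)
        ordered = fused.sort_values("rank")[["speaker_i", "speaker_k"]]
        assert list(map(tuple, ordered.to_numpy())) == sorted(
            map(tuple, ordered.to_numpy())
        )

    def test_ranks_are_permutation_within_gender(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers))
        for _, grp in fused.groupby("gender"):
            assert sorted(grp["rank"]) == list(range(1, len(grp) + 1))

    def test_zscore_constant_column_contributes_nothing(self):
        # equal F0 everywhere: the dF0 block is constant and must not matter
        rng = np.random.default_rng(5)
        feats = [
            _spk(f"s{i}", "male", 150, rng.standard_normal((2, 4))) for i in range(4)
        ]
        fused = fuse_distance(build_pair_table(feats), scaling="zscore")
        assert np.all(np.isfinite(fused["distance"]))

    def test_two_speakers_rejected_in_row_vector_mode(self):
        feats = [_spk("a", "male", 100, [(1, 0)]), _spk("b", "male", 110, [(0, 1)])]
        with pytest.raises(ValueError, match="3 speakers"):
            fuse_distance(build_pair_table(feats))


class TestSelectPairs:
    def _ranked_table(self, rows):
        df = pd.DataFrame(
            rows, columns=["gender", "speaker_i", "speaker_k", "distance"]
        )
        df["avg_cosine"] = 0.5
        df["delta_f0"] = 1.0
        df["rank"] = df["distance"].rank(method="first").astype(int)
        return df

    def test_alternating_task_assignment(self):
        table = self._ranked_table(
            [
                ("male", "A", "B", 0.1),
                ("male", "C", "D", 0.2),
            ]
        )
        out = select_pairs(table, n_pairs_per_task=1, seed=0)
        assert list(out["task"]) == ["implicit", "explicit"]
        assert set(out.iloc[0][["learned_id", "impostor_id"]]) == {"A", "B"}
        assert set(out.iloc[1][["learned_id", "impostor_id"]]) == {"C", "D"}

    def test_overlapping_pair_skipped(self):
        # pair 2 shares speaker B with pair 1 -> skipped, pair 3 accepted
        table = self._ranked_table(
            [
                ("male", "A", "B", 0.1),
                ("male", "B", "C", 0.2),
                ("male", "C", "D", 0.3),
                ("male", "E", "F", 0.4),
            ]
        )
        out = select_pairs(table, n_pairs_per_task=1, seed=0)
        chosen = {frozenset(r) for r in out[["learned_id", "impostor_id"]].to_numpy()}
        assert chosen == {frozenset("AB"), frozenset("CD")}

    def test_greedy_matches_exhaustive_on_small_instance(self):
        # oracle: walk the ranked list, accept any pair disjoint from accepted
        rows = [
            ("male", "A", "B", 0.10),
            ("male", "A", "C", 0.12),
            ("male", "C", "D", 0.15),
            ("male", "B", "E", 0.20),
            ("male", "E", "F", 0.25),
        ]
        table = self._ranked_table(rows)
        used, oracle = set(), []
        for _, i, k, _d in sorted(rows, key=lambda r: r[3]):
            if i not in used and k not in used:
                used |= {i, k}
                oracle.append(frozenset((i, k)))
        out = select_pairs(table, n_pairs_per_task=1, seed=0)
        got = [frozenset(r) for r in out[["learned_id", "impostor_id"]].to_numpy()]
        assert got == oracle[:2]

    def test_zero_pairs_gives_empty_assignment(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers))
        out = select_pairs(fused, n_pairs_per_task=0, seed=0)
        assert len(out) == 0

    def test_each_speaker_used_at_most_once_and_equal_task_counts(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers))
        out = select_pairs(fused, n_pairs_per_task=2, seed=7)
        ids = list(out["learned_id"]) + list(out["impostor_id"])
        assert len(ids) == len(set(ids))
        assert (out["task"] == "implicit").sum() == (out["task"] == "explicit").sum()

    def test_sentences_globally_unique(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers))
        out = select_pairs(fused, n_pairs_per_task=2, seed=7)
        sentences = list(out["learn_sentence_id"]) + list(out["test_sentence_id"])
        assert len(sentences) == len(set(sentences))

    def test_same_seed_bit_identical(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers))
        a = select_pairs(fused, n_pairs_per_task=2, seed=123)
        b = select_pairs(fused, n_pairs_per_task=2, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_pairs_reports_achievable(self, tiny_speakers):
        fused = fuse_distance(build_pair_table(tiny_speakers))
        with pytest.raises(ValueError, match="disjoint pairs"):
            select_pairs(fused, n_pairs_per_task=5, seed=0)
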