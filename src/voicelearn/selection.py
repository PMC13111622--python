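"""Similarity-controlled stimulus selection.

Voices that are acoustically distinctive are easier to remember than voices
that sit close to the population prototype.  To keep two learning tasks
comparable, to-be-learned voices are paired with similarity-matched impostor
voices and pairs are allocated to the tasks alternately down a ranked
similarity list, so each task receives the same spread of pair similarities.

The pipeline:

1. per-recording speaker embeddings -> per-speaker-pair mean cosine
   similarity (``consolidate_similarity``),
2. per-speaker mean F0 -> absolute pair |dF0| in Hz (``delta_f0_table``),
3. both cues fused into a single Euclidean distance per same-gender pair,
   ranked ascending so rank 1 is the most similar pair (``fuse_distance``),
4. greedy extraction of speaker-disjoint pairs from the top of the ranked
   list, assigned alternately to the implicit and explicit tasks with
   learned/impostor roles and unique sentence draws (``select_pairs``).

All pair computations are within-gender; cross-gender pairs never appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeakerFeatures",
    "load_speaker_features",
    "consolidate_similarity",
    "delta_f0_table",
    "build_pair_table",
    "fuse_distance",
    "select_pairs",
]

GENDERS = ("male", "female")


@dataclass
class SpeakerFeatures:
    """One speaker's identity, gender, mean F0 (Hz) and recording embeddings.

    ``recordings`` maps recording_id -> embedding vector; all embeddings must
    share one dimension D >= 2.  Embeddings need not be unit-norm (cosine
    similarity normalises internally).
    """

    speaker_id: str
    gender: str
    mean_f0: float
    recordings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(
                f"speaker {self.speaker_id!r}: gender must be one of {GENDERS}, "
                f"got {self.gender!r}"
            )
        if not np.isfinite(self.mean_f0) or self.mean_f0 <= 0:
            raise ValueError(
                f"speaker {self.speaker_id!r}: mean_f0 must be finite and > 0, "
                f"got {self.mean_f0!r}"
            )
        self.recordings = {
            rid: np.asarray(vec, dtype=float) for rid, vec in self.recordings.items()
        }
        dims = {vec.shape for vec in self.recordings.values()}
        if len(dims) > 1:
            raise ValueError(
                f"speaker {self.speaker_id!r}: embeddings have mixed shapes {dims}"
            )
        for rid, vec in self.recordings.items():
            if vec.ndim != 1 or vec.size < 2:
                raise ValueError(
                    f"speaker {self.speaker_id!r} recording {rid!r}: embedding "
                    "must be a vector of dimension >= 2"
                )

    @property
    def embedding_matrix(self) -> np.ndarray:
        """Recordings stacked row-wise, in insertion order."""
        return np.vstack([self.recordings[r] for r in self.recordings])


def load_speaker_features(path) -> list[SpeakerFeatures]:
    """Read a long-format feature CSV into SpeakerFeatures.

    Expected columns: speaker_id, gender, mean_f0_hz, recording_id, then the
    embedding columns e0..e{D-1} (one row per recording).
    """
    df = pd.read_csv(path)
    required = {"speaker_id", "gender", "mean_f0_hz", "recording_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    emb_cols = sorted(
        (c for c in df.columns if c.startswith("e") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if len(emb_cols) < 2:
        raise ValueError("feature table needs at least 2 embedding columns e0, e1, ...")
    out = []
    for sid, grp in df.groupby("speaker_id", sort=True):
        if grp["recording_id"].duplicated().any():
            raise ValueError(f"speaker {sid!r}: duplicate recording ids")
        recs = {
            str(row["recording_id"]): row[emb_cols].to_numpy(dtype=float)
            for _, row in grp.iterrows()
        }
        out.append(
            SpeakerFeatures(
                speaker_id=str(sid),
                gender=str(grp["gender"].iloc[0]),
                mean_f0=float(grp["mean_f0_hz"].iloc[0]),
                recordings=recs,
            )
        )
    return out


def _check_genders(features: list[SpeakerFeatures]) -> None:
    ids = [f.speaker_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate speaker ids in feature list")
    dims = {next(iter(f.recordings.values())).size for f in features if f.recordings}
    if len(dims) > 1:
        raise ValueError(f"embedding dimension differs across speakers: {sorted(dims)}")
    for f in features:
        if not f.recordings:
            raise ValueError(f"speaker {f.speaker_id!r} has no recordings")
    for g in sorted({f.gender for f in features}):
        n = sum(1 for f in features if f.gender == g)
        if n < 2:
            raise ValueError(
                f"gender {g!r} has only {n} speaker(s); need at least 2 to form pairs"
            )


def _same_gender_pairs(features: list[SpeakerFeatures]):
    by_gender: dict[str, list[SpeakerFeatures]] = {}
    for f in features:
        by_gender.setdefault(f.gender, []).append(f)
    for g in sorted(by_gender):
        speakers = sorted(by_gender[g], key=lambda f: f.speaker_id)
        for i in range(len(speakers)):
            for k in range(i + 1, len(speakers)):
                yield g, speakers[i], speakers[k]


def consolidate_similarity(features: list[SpeakerFeatures]) -> pd.DataFrame:
    """Mean cross-speaker cosine similarity for every same-gender pair.

    For a pair {i, k} the consolidated score is the mean of the cosine
    similarities over all recording pairs taking one recording from each
    speaker (the full file-level similarity matrix averaged per speaker pair).

    Returns a tidy frame with columns gender, speaker_i, speaker_k,
    avg_cosine; speaker_i < speaker_k lexicographically.
    """
    _check_genders(features)
    rows = []
    for g, a, b in _same_gender_pairs(features):
        ma = a.embedding_matrix
        mb = b.embedding_matrix
        na = np.linalg.norm(ma, axis=1)
        nb = np.linalg.norm(mb, axis=1)
        if np.any(na == 0) or np.any(nb == 0):
            raise ValueError(
                f"zero-norm embedding in pair ({a.speaker_id}, {b.speaker_id})"
            )
        sims = (ma / na[:, None]) @ (mb / nb[:, None]).T
        rows.append(
            {
                "gender": g,
                "speaker_i": a.speaker_id,
                "speaker_k": b.speaker_id,
                "avg_cosine": float(sims.mean()),
            }
        )
    return pd.DataFrame(rows)


def delta_f0_table(features: list[SpeakerFeatures]) -> pd.DataFrame:
    """Absolute difference of per-speaker mean F0, per same-gender pair (Hz)."""
    _check_genders(features)
    rows = [
        {
            "gender": g,
            "speaker_i": a.speaker_id,
            "speaker_k": b.speaker_id,
            "delta_f0": abs(a.mean_f0 - b.mean_f0),
        }
        for g, a, b in _same_gender_pairs(features)
    ]
    return pd.DataFrame(rows)


def build_pair_table(features: list[SpeakerFeatures]) -> pd.DataFrame:
    """Consolidated similarity and |dF0| merged into one pair table."""
    sim = consolidate_similarity(features)
    df0 = delta_f0_table(features)
    return sim.merge(df0, on=["gender", "speaker_i", "speaker_k"], validate="1:1")


def _feature_rows(pairs: pd.DataFrame, speakers: list[str]) -> dict[str, dict]:
    """Per-speaker lookup: other speaker -> (avg_cosine, delta_f0)."""
    lut: dict[str, dict] = {s: {} for s in speakers}
    for row in pairs.itertuples():
        lut[row.speaker_i][row.speaker_k] = (row.avg_cosine, row.delta_f0)
        lut[row.speaker_k][row.speaker_i] = (row.avg_cosine, row.delta_f0)
    return lut


def fuse_distance(
    pair_table: pd.DataFrame,
    mode: str = "row_vector",
    scaling: str = "none",
    drop_self: bool = True,
) -> pd.DataFrame:
    """Fuse cosine similarity and |dF0| into one Euclidean distance per pair.

    mode="row_vector" (default) mirrors the table construction in which |dF0|
    values are appended to the consolidated similarity matrix as additional
    columns: each speaker's feature row is [avg_cosine to every other
    same-gender speaker, delta_f0 to every other same-gender speaker] and the
    pair distance is the Euclidean distance between the two rows.  With
    ``drop_self`` (default) the columns referring to either member of the
    pair are removed first, so a pair's distance reflects how the two
    speakers relate to the *rest* of the gender group rather than to each
    other.  Requires >= 3 speakers per gender.

    mode="pair_2d" is the alternative reading: the distance is the norm of
    the 2-vector ((1 - avg_cosine), delta_f0) for the pair itself.

    scaling="zscore" standardises each feature column (row_vector) or each of
    the two pair features (pair_2d) before the distance; zero-variance
    columns are dropped rather than divided by zero.

    Adds ``distance`` and a within-gender ``rank`` (1 = most similar =
    smallest distance; ties broken by (speaker_i, speaker_k) lexicographic
    order).
    """
    if mode not in ("row_vector", "pair_2d"):
        raise ValueError(f"unknown mode {mode!r}")
    if scaling not in ("none", "zscore"):
        raise ValueError(f"unknown scaling {scaling!r}")
    out = []
    for g, pairs in pair_table.groupby("gender", sort=True):
        pairs = pairs.reset_index(drop=True)
        speakers = sorted(set(pairs["speaker_i"]) | set(pairs["speaker_k"]))
        if mode == "row_vector":
            if len(speakers) < 3:
                raise ValueError(
                    f"gender {g!r}: row_vector mode needs >= 3 speakers "
                    f"(got {len(speakers)}); rows would be empty after "
                    "self-column removal"
                )
            dist = _row_vector_distances(pairs, speakers, scaling, drop_self)
        else:
            dist = _pair_2d_distances(pairs, scaling)
        pairs = pairs.assign(distance=dist)
        order = pairs.sort_values(
            ["distance", "speaker_i", "speaker_k"], kind="mergesort"
        ).index
        rank = pd.Series(0, index=pairs.index)
        rank.loc[order] = np.arange(1, len(pairs) + 1)
        pairs = pairs.assign(rank=rank.astype(int))
        out.append(pairs)
    return pd.concat(out, ignore_index=True)


def _row_vector_distances(pairs, speakers, scaling, drop_self):
    lut = _feature_rows(pairs, speakers)
    n = len(speakers)
    idx = {s: j for j, s in enumerate(speakers)}
    cos = np.zeros((n, n))
    df0 = np.zeros((n, n))
    for a, partners in lut.items():
        for b, (c, d) in partners.items():
            cos[idx[a], idx[b]] = c
            df0[idx[a], idx[b]] = d
    # column j of each block describes similarity/dF0 *to* speaker j
    feats = np.hstack([cos, df0])  # (n, 2n); diagonal cells are 0 placeholders
    if scaling == "zscore":
        feats = _zscore_columns(feats)
    dists = []
    for row in pairs.itertuples():
        i, k = idx[row.speaker_i], idx[row.speaker_k]
        if drop_self:
            keep = [j for j in range(n) if j not in (i, k)]
        else:
            keep = list(range(n))
        cols = keep + [n + j for j in keep]
        vi = feats[i, cols]
        vk = feats[k, cols]
        dists.append(float(np.linalg.norm(vi - vk)))
    return np.array(dists)


def _pair_2d_distances(pairs, scaling):
    feats = np.column_stack(
        [1.0 - pairs["avg_cosine"].to_numpy(), pairs["delta_f0"].to_numpy()]
    )
    if scaling == "zscore":
        feats = _zscore_columns(feats)
    return np.linalg.norm(feats, axis=1)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    # zero-variance columns map to 0 so they contribute nothing to distances
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    out = np.zeros_like(x, dtype=float)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def select_pairs(
    pair_table: pd.DataFrame,
    n_pairs_per_task: int,
    seed: int | np.random.Generator = 0,
    n_sentences: int = 256,
) -> pd.DataFrame:
    """Extract disjoint pairs from the ranked list and assign them to tasks.

    The ranked pair list (both genders merged, ascending distance, i.e. most
    similar first) is scanned greedily from the top; a pair is accepted only
    if neither speaker has been used.  Accepted pairs are assigned
    alternately implicit, explicit, implicit, ...  Within each pair the
    learned (old) vs impostor (new) role is drawn with the run seed, and one
    learning sentence plus one distinct test sentence are drawn per pair,
    with no sentence index reused anywhere in the assignment.

    Returns one row per selected pair: selection_order, task, learned_id,
    impostor_id, gender, distance, rank, learn_sentence_id, test_sentence_id.
    """
    if n_pairs_per_task < 0:
        raise ValueError("n_pairs_per_task must be >= 0")
    needed = 2 * n_pairs_per_task
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if "distance" not in pair_table.columns:
        raise ValueError("pair_table must carry distances; run fuse_distance first")
    ranked = pair_table.sort_values(
        ["distance", "speaker_i", "speaker_k"], kind="mergesort"
    )
    used: set[str] = set()
    accepted = []
    for row in ranked.itertuples():
        if len(accepted) == needed:
            break
        if row.speaker_i in used or row.speaker_k in used:
            continue
        used.update((row.speaker_i, row.speaker_k))
        accepted.append(row)
    if len(accepted) < needed:
        raise ValueError(
            f"only {len(accepted)} disjoint pairs achievable; "
            f"{needed} required for {n_pairs_per_task} pairs per task"
        )
    if 2 * needed > n_sentences:
        raise ValueError(
            f"{2 * needed} unique sentences required but only {n_sentences} available"
        )
    sentence_ids = rng.choice(n_sentences, size=2 * needed, replace=False)
    rows = []
    for j, row in enumerate(accepted):
        task = "implicit" if j % 2 == 0 else "explicit"
        a, b = row.speaker_i, row.speaker_k
        if rng.random() < 0.5:
            a, b = b, a
        rows.append(
            {
                "selection_order": j + 1,
                "task": task,
                "learned_id": a,
                "impostor_id": b,
                "gender": row.gender,
                "distance": row.distance,
                "rank": row.rank,
                "learn_sentence_id": int(sentence_ids[2 * j]),
                "test_sentence_id": int(sentence_ids[2 * j + 1]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "selection_order",
            "task",
            "learned_id",
            "impostor_id",
            "gender",
            "distance",
            "rank",
            "learn_sentence_id",
            "test_sentence_id",
        ],
    )
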