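"""Counterbalanced two-phase experiment plans.

Each participant group runs two exposure-plus-test phases: one implicit
exposure (a same-different voice discrimination task, participants unaware
of the later memory test) and one explicit exposure (a prompted
listen-and-memorize task), each followed by an old-new voice recognition
test on that phase's learned voices plus their similarity-matched impostor
voices.  The exposure order is counterbalanced across participant groups
(I->E vs E->I), and the experiment comes in a simple (4 voices per task)
and a challenging (10 voices per task) version.

Structural invariants enforced here:

* discrimination: each voice occurs in exactly ``same_per_voice`` (default 4)
  same-speaker trials and ``diff_per_voice`` (default 4) different-speaker
  trial appearances — 8 exposure appearances and 12 distinct snippets per
  voice at the defaults;
* memorization: 12 snippets per voice in a single per-voice block, so total
  exposure time per voice is identical across the two exposure types;
* recognition: 3 trials per identity, truth "old" iff the identity was in
  that phase's exposure set;
* no snippet (speaker + sentence index) is used twice anywhere in a plan,
  and recognition snippets are disjoint from exposure snippets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnippetPool",
    "DesignParams",
    "ExperimentPlan",
    "build_discrimination",
    "build_memorization",
    "build_recognition",
    "build_plan",
    "VERSION_VOICES",
]

VERSION_VOICES = {"simple": 4, "challenging": 10}
ORDERS = ("IE", "EI")

# nominal stimulus timing, seconds (schedules carry these as metadata only)
SNIPPET_S = 1.2
DISCRIMINATION_ISI_S = 1.0
MEMORIZATION_PAUSE_S = 0.5
MEMORIZATION_FIXATION_S = 3.0


class SnippetPool:
    """Allocates snippets (speaker + sentence index) without reuse.

    Each speaker owns ``n_sentences`` sentence snippets; a draw removes the
    snippet from the pool for good, which is what guarantees the
    each-snippet-used-once property across a whole plan.
    """

    def __init__(self, n_sentences: int = 256, rng: np.random.Generator | int = 0):
        self.n_sentences = n_sentences
        self.rng = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        self._free: dict[str, list[int]] = {}

    def draw(self, speaker: str, k: int = 1) -> list[str]:
        free = self._free.setdefault(speaker, list(range(self.n_sentences)))
        if len(free) < k:
            raise ValueError(
                f"speaker {speaker!r}: {k} fresh snippets requested but only "
                f"{len(free)} remain of {self.n_sentences}"
            )
        picks = self.rng.choice(len(free), size=k, replace=False)
        ids = [free[i] for i in picks]
        for i in sorted(picks, reverse=True):
            free.pop(i)
        return [f"{speaker}:s{j:03d}" for j in ids]


@dataclass(frozen=True)
class DesignParams:
    """Tunable per-voice trial counts.

    At the defaults a discrimination block has 4 same trials and 4
    different-trial appearances per voice (8 appearances, 12 snippets), a
    memorization block plays 12 snippets per voice, and recognition probes
    every identity 3 times.
    """

    same_per_voice: int = 4
    diff_per_voice: int = 4
    memorize_per_voice: int = 12
    recognition_per_identity: int = 3
    n_sentences: int = 256


def _diff_pairings(n_voices: int, diff_per_voice: int) -> list[tuple[int, int]]:
    """Balanced round-robin pairing: every voice appears in exactly
    ``diff_per_voice`` different-speaker trials."""
    n, d = n_voices, diff_per_voice
    if (n * d) % 2:
        raise ValueError(
            f"cannot pair an odd total of different-trial appearances "
            f"({n} voices x {d} appearances)"
        )
    pairs: list[tuple[int, int]] = []
    for k in range(1, d // 2 + 1):
        off = (k - 1) % (n - 1) + 1  # stay in 1..n-1 so a voice never meets itself
        pairs.extend((i, (i + off) % n) for i in range(n))
    if d % 2:  # n is even here (n*d even, d odd)
        pairs.extend((i, i + n // 2) for i in range(n // 2))
    return pairs


def build_discrimination(
    voices: list[str],
    pool: SnippetPool,
    params: DesignParams = DesignParams(),
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Same-different discrimination schedule over the exposure voices.

    Returns one row per trial: stimulus_a/b speaker and snippet, truth
    ("same"/"different"), trial order shuffled with the rng.  Different
    trials pair voices within the exposure set; impostors never appear
    during exposure.
    """
    if len(voices) < 2:
        raise ValueError("discrimination needs at least 2 voices")
    if len(set(voices)) != len(voices):
        raise ValueError("duplicate voice ids")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    trials = []
    for v in voices:
        for _ in range(params.same_per_voice):
            sa, sb = pool.draw(v, 2)
            trials.append((v, sa, v, sb, "same"))
    for i, k in _diff_pairings(len(voices), params.diff_per_voice):
        va, vb = voices[i], voices[k]
        (sa,) = pool.draw(va, 1)
        (sb,) = pool.draw(vb, 1)
        trials.append((va, sa, vb, sb, "different"))
    order = rng.permutation(len(trials))
    rows = [trials[i] for i in order]
    df = pd.DataFrame(
        rows, columns=["speaker_a", "snippet_a", "speaker_b", "snippet_b", "truth"]
    )
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


def build_memorization(
    voices: list[str],
    pool: SnippetPool,
    params: DesignParams = DesignParams(),
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Prompted memorization schedule: one block of snippets per voice.

    Block (voice) order is seeded-random; within a block the snippets play
    back-to-back with short pauses, and a fixation interval separates
    consecutive voices.
    """
    if not voices:
        raise ValueError("memorization needs at least 1 voice")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    block_order = [voices[i] for i in rng.permutation(len(voices))]
    rows = []
    for b, v in enumerate(block_order):
        for j, snip in enumerate(pool.draw(v, params.memorize_per_voice)):
            rows.append((b, v, j, snip))
    df = pd.DataFrame(rows, columns=["block", "speaker", "position", "snippet"])
    df.insert(0, "presentation_index", np.arange(len(df)))
    return df


def build_recognition(
    learned: list[str],
    impostors: list[str],
    pool: SnippetPool,
    params: DesignParams = DesignParams(),
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Old-new recognition schedule: 3 trials per identity, shuffled.

    ``learned`` identities are truth "old"; ``impostors`` (similarity-matched
    voices unseen during exposure) are truth "new".  Snippet draws come from
    the shared pool, so test snippets can never repeat exposure snippets.
    """
    if set(learned) & set(impostors):
        raise ValueError("learned and impostor sets must be disjoint")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    trials = []
    for v in learned:
        trials.extend((v, s, "old") for s in pool.draw(v, params.recognition_per_identity))
    for v in impostors:
        trials.extend((v, s, "new") for s in pool.draw(v, params.recognition_per_identity))
    order = rng.permutation(len(trials))
    df = pd.DataFrame(
        [trials[i] for i in order], columns=["speaker", "snippet", "truth"]
    )
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


@dataclass
class Phase:
    task: str  # "implicit" | "explicit"
    exposure: pd.DataFrame  # discrimination or memorization schedule
    recognition: pd.DataFrame


@dataclass
class ExperimentPlan:
    """A full two-phase plan for one (version, order) participant group."""

    version: str
    order: str  # "IE" or "EI"
    seed: int
    phases: list[Phase] = field(default_factory=list)
    timing: dict = field(
        default_factory=lambda: {
            "snippet_s": SNIPPET_S,
            "discrimination_isi_s": DISCRIMINATION_ISI_S,
            "memorization_pause_s": MEMORIZATION_PAUSE_S,
            "memorization_fixation_s": MEMORIZATION_FIXATION_S,
        }
    )

    def all_snippets(self) -> list[str]:
        out: list[str] = []
        for ph in self.phases:
            exp = ph.exposure
            if "snippet_a" in exp.columns:
                out.extend(exp["snippet_a"])
                out.extend(exp["snippet_b"])
            else:
                out.extend(exp["snippet"])
            out.extend(ph.recognition["snippet"])
        return out

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "order": self.order,
            "seed": self.seed,
            "timing": self.timing,
            "phases": [
                {
                    "task": ph.task,
                    "exposure": ph.exposure.to_dict(orient="records"),
                    "recognition": ph.recognition.to_dict(orient="records"),
                }
                for ph in self.phases
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        plan = cls(version=d["version"], order=d["order"], seed=d["seed"])
        plan.timing = d.get("timing", plan.timing)
        plan.phases = [
            Phase(
                task=p["task"],
                exposure=pd.DataFrame(p["exposure"]),
                recognition=pd.DataFrame(p["recognition"]),
            )
            for p in d["phases"]
        ]
        return plan

    @classmethod
    def from_json(cls, path) -> "ExperimentPlan":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_plan(
    assignment: pd.DataFrame,
    version: str,
    order: str = "IE",
    seed: int = 0,
    params: DesignParams = DesignParams(),
) -> ExperimentPlan:
    """Assemble the counterbalanced plan from a pair-to-task assignment.

    ``assignment`` is the selection output (one row per pair with task,
    learned_id, impostor_id).  The implicit task's voices go to the
    discrimination phase, the explicit task's to the memorization phase; in
    order "IE" the implicit phase runs first, in "EI" second.  Voice sets of
    the two phases are disjoint by construction of the assignment.
    """
    if version not in VERSION_VOICES:
        raise ValueError(f"unknown version {version!r}; expected {set(VERSION_VOICES)}")
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}; expected {ORDERS}")
    need = VERSION_VOICES[version]
    by_task = {}
    for task in ("implicit", "explicit"):
        sub = assignment[assignment["task"] == task]
        if len(sub) < need:
            raise ValueError(
                f"version {version!r} needs {need} pairs for task {task!r}, "
                f"assignment provides {len(sub)}"
            )
        sub = sub.sort_values("selection_order").head(need)
        by_task[task] = (list(sub["learned_id"]), list(sub["impostor_id"]))
    rng = np.random.default_rng(seed)
    pool = SnippetPool(n_sentences=params.n_sentences, rng=rng)
    phases = []
    tasks = ("implicit", "explicit") if order == "IE" else ("explicit", "implicit")
    for task in tasks:
        learned, impostors = by_task[task]
        if task == "implicit":
            exposure = build_discrimination(learned, pool, params, rng)
        else:
            exposure = build_memorization(learned, pool, params, rng)
        recognition = build_recognition(learned, impostors, pool, params, rng)
        phases.append(Phase(task=task, exposure=exposure, recognition=recognition))
    return ExperimentPlan(version=version, order=order, seed=seed, phases=phases)
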