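"""Synthetic data: speaker features and SDT-generated behavioural responses.

Two generators live here.

``gen_speakers`` fabricates the *inputs* to stimulus selection: per-speaker
embedding clusters on the unit sphere (a centroid per speaker, recordings
jittered around it) plus gender-specific mean F0 draws.  It stands in for a
recorded corpus with neural speaker-verification embeddings; it reproduces
the one structural property selection relies on — within-speaker cosine
similarity exceeding between-speaker similarity — and nothing else about
real speech.

``simulate_experiment`` fabricates the *outputs*: trial-level binary
responses from an equal-variance Gaussian signal-detection model.  Each
participant gets a latent sensitivity d' per (task, phase) cell drawn from
a Normal(cell mean, cell SD); on each trial

    P(respond signal | signal trial) = Phi(d'/2 - c)
    P(respond signal | noise  trial) = Phi(-d'/2 - c)

where "signal" means "old" in recognition and "different" in
discrimination, and c is the response criterion (0 = unbiased).  This model
is the exact inverse of the d' estimator used in analysis, so analysing a
simulated log is a parameter-recovery exercise.  Default cell parameters
are the study's observed condition means and SDs, so recovery doubles as
reproduction of the printed descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .design import VERSION_VOICES, DesignParams, ExperimentPlan, build_plan
from .selection import SpeakerFeatures, build_pair_table, fuse_distance, select_pairs

__all__ = [
    "GenerativeConfig",
    "gen_speakers",
    "simulate_trial",
    "simulate_experiment",
    "make_assignment",
    "simulate_study",
]


@dataclass
class GenerativeConfig:
    """Generative SDT parameters per condition cell, with study defaults.

    Recognition d' means/SDs are keyed by (version, task); discrimination
    means/SDs by version.  Between-participant SDs absorb the participant
    random intercept; there is no trial-level overdispersion beyond the
    binomial.  ``order_effect`` shifts phase-1 latent d' additively (in d'
    units); ``truncate_at_zero`` clips negative recognition draws at 0 and
    is off by default (near-zero cell medians imply genuinely negative
    individual sensitivities).
    """

    n_participants: dict = field(
        default_factory=lambda: {"simple": 81, "challenging": 51}
    )
    recognition_mean: dict = field(
        default_factory=lambda: {
            ("simple", "explicit"): 0.472,
            ("simple", "implicit"): 0.592,
            ("challenging", "explicit"): 0.056,
            ("challenging", "implicit"): 0.341,
        }
    )
    recognition_sd: dict = field(
        default_factory=lambda: {
            ("simple", "explicit"): 0.653,
            ("simple", "implicit"): 0.679,
            ("challenging", "explicit"): 0.379,
            ("challenging", "implicit"): 0.408,
        }
    )
    discrimination_mean: dict = field(
        default_factory=lambda: {"simple": 1.96, "challenging": 2.02}
    )
    discrimination_sd: dict = field(
        default_factory=lambda: {"simple": 0.41, "challenging": 0.45}
    )
    criterion: float = 0.0
    order_effect: float = 0.0
    truncate_at_zero: bool = False

    def __post_init__(self):
        for d in (self.recognition_sd, self.discrimination_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"SD for cell {k} must be >= 0, got {v}")

    def cell(self, version: str, task: str, kind: str) -> tuple[float, float]:
        """(mean, sd) of the latent d' for a condition cell.

        kind is "recognition" or "discrimination"; discrimination cells only
        exist for the implicit task.
        """
        try:
            if kind == "recognition":
                return (
                    self.recognition_mean[(version, task)],
                    self.recognition_sd[(version, task)],
                )
            if kind == "discrimination":
                return self.discrimination_mean[version], self.discrimination_sd[version]
        except KeyError:
            raise KeyError(f"no generative parameters for cell ({version}, {task}, {kind})")
        raise ValueError(f"unknown kind {kind!r}")

    def to_yaml(self, path) -> None:
        def keyed(d):
            return {"|".join(k) if isinstance(k, tuple) else k: v for k, v in d.items()}

        data = {
            "n_participants": dict(self.n_participants),
            "recognition_mean": keyed(self.recognition_mean),
            "recognition_sd": keyed(self.recognition_sd),
            "discrimination_mean": dict(self.discrimination_mean),
            "discrimination_sd": dict(self.discrimination_sd),
            "criterion": self.criterion,
            "order_effect": self.order_effect,
            "truncate_at_zero": self.truncate_at_zero,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)

        def unkeyed(d):
            return {
                tuple(k.split("|")) if "|" in k else k: v for k, v in d.items()
            }

        cfg = cls()
        for name in ("n_participants", "discrimination_mean", "discrimination_sd"):
            if name in data:
                setattr(cfg, name, dict(data[name]))
        for name in ("recognition_mean", "recognition_sd"):
            if name in data:
                setattr(cfg, name, unkeyed(data[name]))
        for name in ("criterion", "order_effect", "truncate_at_zero"):
            if name in data:
                setattr(cfg, name, data[name])
        return cfg


# ---------------------------------------------------------------------------
# synthetic speaker features


def gen_speakers(
    n_per_gender: int = 12,
    dim: int = 16,
    n_recordings: int = 5,
    within_speaker_spread: float = 0.3,
    f0_params: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SpeakerFeatures]:
    """Draw synthetic speakers: spherical embedding clusters + gendered F0.

    Each speaker has a unit-norm centroid drawn uniformly on the
    D-dimensional sphere; recordings are centroid + isotropic Gaussian
    jitter (scale ``within_speaker_spread``), renormalised to unit length.
    Mean F0 is Gaussian per gender: defaults 120 +/- 20 Hz (male),
    210 +/- 25 Hz (female), truncated at 50 Hz.
    """
    if n_per_gender < 2:
        raise ValueError("need at least 2 speakers per gender")
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if within_speaker_spread < 0:
        raise ValueError("within_speaker_spread must be >= 0")
    f0 = {"male": (120.0, 20.0), "female": (210.0, 25.0)}
    if f0_params:
        f0.update(f0_params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for gender in ("male", "female"):
        mu_f0, sd_f0 = f0[gender]
        for i in range(n_per_gender):
            centroid = rng.standard_normal(dim)
            centroid /= np.linalg.norm(centroid)
            recs = {}
            for r in range(n_recordings):
                v = centroid + within_speaker_spread * rng.standard_normal(dim)
                n = np.linalg.norm(v)
                recs[f"r{r:02d}"] = v / n if n > 0 else centroid
            mean_f0 = max(50.0, rng.normal(mu_f0, sd_f0))
            out.append(
                SpeakerFeatures(
                    speaker_id=f"{gender[0]}{i:02d}",
                    gender=gender,
                    mean_f0=mean_f0,
                    recordings=recs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# SDT response generation


def simulate_trial(
    truth_is_signal: bool,
    d_eff: float,
    c: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> bool:
    """One equal-variance SDT trial: returns True for a "signal" response."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = signal_response_prob(truth_is_signal, d_eff, c)
    return bool(rng.random() < p)


def signal_response_prob(truth_is_signal, d_eff, c=0.0):
    """P(respond "signal") under the equal-variance model; vectorised."""
    d_eff = np.asarray(d_eff, dtype=float)
    sign = np.where(np.asarray(truth_is_signal, dtype=bool), 1.0, -1.0)
    return norm.cdf(sign * d_eff / 2.0 - c)


_SIGNAL_TRUTH = {"old": True, "new": False, "different": True, "same": False}


def simulate_experiment(
    plan: ExperimentPlan,
    config: GenerativeConfig,
    participant_ids: list,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Simulate every scheduled trial for each participant on one plan.

    Participants draw one latent d' per (task, phase, trial kind) cell;
    memorization exposure produces no responses (it is passive listening).
    Returns a tidy log: participant_id, version, order, phase_index, task,
    kind, trial_index, speaker_id, snippet_id, truth, response — with
    response in {"signal", "noise"} semantics ("signal" = "old" in
    recognition, "different" in discrimination).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for pid in participant_ids:
        for phase_index, phase in enumerate(plan.phases, start=1):
            order_shift = config.order_effect if phase_index == 1 else 0.0
            # exposure responses only exist for the discrimination task
            if phase.task == "implicit":
                d = rng.normal(*config.cell(plan.version, phase.task, "discrimination"))
                _simulate_block(
                    rows, phase.exposure, "discrimination", pid, plan, phase_index,
                    phase.task, d + order_shift, config.criterion, rng,
                )
            d = rng.normal(*config.cell(plan.version, phase.task, "recognition"))
            if config.truncate_at_zero:
                d = max(0.0, d)
            _simulate_block(
                rows, phase.recognition, "recognition", pid, plan, phase_index,
                phase.task, d + order_shift, config.criterion, rng,
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "version", "order", "phase_index", "task", "kind",
            "trial_index", "speaker_id", "snippet_id", "truth", "response",
        ],
    )


def _simulate_block(rows, schedule, kind, pid, plan, phase_index, task, d_eff, c, rng):
    truths = schedule["truth"].to_numpy()
    is_signal = np.array([_SIGNAL_TRUTH[t] for t in truths])
    p = signal_response_prob(is_signal, d_eff, c)
    resp = rng.random(len(p)) < p
    if kind == "discrimination":
        speakers = schedule["speaker_a"].astype(str) + "+" + schedule["speaker_b"].astype(str)
        snippets = schedule["snippet_a"].astype(str) + "+" + schedule["snippet_b"].astype(str)
    else:
        speakers = schedule["speaker"]
        snippets = schedule["snippet"]
    for i, (t, sp, sn, r) in enumerate(
        zip(truths, speakers, snippets, resp)
    ):
        rows.append(
            (
                pid, plan.version, plan.order, phase_index, task, kind,
                int(schedule["trial_index"].iloc[i]) if "trial_index" in schedule else i,
                sp, sn, t, "signal" if r else "noise",
            )
        )


# ---------------------------------------------------------------------------
# end-to-end study simulation


def make_assignment(
    version: str,
    seed: int | np.random.Generator = 0,
    n_per_gender: int | None = None,
    **gen_kwargs,
) -> pd.DataFrame:
    """Synthetic speakers -> pair table -> ranked selection, for a version.

    Generates enough speakers per gender to extract 2 x voices-per-task
    disjoint pairs, then runs the full selection chain.
    """
    need_pairs = 2 * VERSION_VOICES[version]
    if n_per_gender is None:
        # disjoint greedy selection wastes some speakers; 1.5x headroom
        n_per_gender = max(4, int(np.ceil(need_pairs * 1.5)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    feats = gen_speakers(n_per_gender=n_per_gender, seed=rng, **gen_kwargs)
    table = fuse_distance(build_pair_table(feats))
    return select_pairs(table, n_pairs_per_task=VERSION_VOICES[version], seed=rng)


def simulate_study(
    config: GenerativeConfig | None = None,
    seed: int = 0,
    versions: tuple = ("simple", "challenging"),
    params: DesignParams = DesignParams(),
) -> pd.DataFrame:
    """The full synthetic study: selection, plans, and responses.

    For each version, speakers are generated and selected, one plan is built
    per counterbalanced order, and participants are allocated to orders
    alternately by index.  Returns the pooled trial-level response log.
    """
    config = config or GenerativeConfig()
    rng = np.random.default_rng(seed)
    logs = []
    for version in versions:
        assignment = make_assignment(version, seed=rng)
        plans = {
            order: build_plan(
                assignment, version, order,
                seed=int(rng.integers(2**31)), params=params,
            )
            for order in ("IE", "EI")
        }
        n = config.n_participants[version]
        pids = [f"{version[0]}p{i:03d}" for i in range(n)]
        by_order = {"IE": [], "EI": []}
        for i, pid in enumerate(pids):
            by_order["IE" if i % 2 == 0 else "EI"].append(pid)
        for order, group in by_order.items():
            logs.append(simulate_experiment(plans[order], config, group, rng))
    return pd.concat(logs, ignore_index=True)
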