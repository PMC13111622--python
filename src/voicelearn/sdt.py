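"""Signal-detection analysis: corrected rates, d', per-speaker accuracy,
and the soft-ceiling diagnostic.

Sensitivity is the equal-variance SDT measure

    d' = Z(hit rate) - Z(false-alarm rate)

with Z the standard-normal quantile.  A hit is a correct "signal" response
on a signal trial ("old" voice called old; "different" pair called
different); a false alarm is a "signal" response on a noise trial.  Rates
of exactly 0 or 1 give infinite d', so a boundary correction is applied
first; both canonical variants are available:

* ``loglinear`` (default): (count + 0.5) / (N + 1) applied to every cell —
  the rule with the smallest small-sample bias, and the one the field's
  standard treatments recommend;
* ``halfN``: 0 -> 1/(2N), 1 -> 1 - 1/(2N), interior rates untouched.

The soft-ceiling diagnostic asks whether more participants pile up at the
top of the d' distribution than a Gaussian would predict: the threshold is
the empirical 90th percentile, the observed count is compared with an
expected count via a two-cell chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "SDTCounts",
    "counts_from_log",
    "corrected_rates",
    "dprime",
    "score_log",
    "percent_correct_by_speaker",
    "chi_square_gof",
    "ceiling_analysis",
]


@dataclass(frozen=True)
class SDTCounts:
    """Raw trial counts for one analysis unit."""

    n_signal: int
    n_noise: int
    hits: int
    false_alarms: int

    def __post_init__(self):
        if not (0 <= self.hits <= self.n_signal):
            raise ValueError(f"hits {self.hits} outside [0, {self.n_signal}]")
        if not (0 <= self.false_alarms <= self.n_noise):
            raise ValueError(
                f"false alarms {self.false_alarms} outside [0, {self.n_noise}]"
            )


def corrected_rates(
    counts: SDTCounts, method: str = "loglinear"
) -> tuple[float, float, bool]:
    """Boundary-corrected (hit_rate, fa_rate, correction_applied).

    halfN leaves interior rates untouched (idempotent there); loglinear
    shifts every cell, so its flag reports whether a boundary was present.
    """
    if counts.n_signal < 1 or counts.n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")
    at_boundary = counts.hits in (0, counts.n_signal) or counts.false_alarms in (
        0,
        counts.n_noise,
    )
    if method == "halfN":

        def fix(k, n):
            if k == 0:
                return 1.0 / (2 * n)
            if k == n:
                return 1.0 - 1.0 / (2 * n)
            return k / n

        return fix(counts.hits, counts.n_signal), fix(
            counts.false_alarms, counts.n_noise
        ), at_boundary
    if method == "loglinear":
        return (
            (counts.hits + 0.5) / (counts.n_signal + 1),
            (counts.false_alarms + 0.5) / (counts.n_noise + 1),
            at_boundary,
        )
    raise ValueError(f"unknown correction method {method!r}")


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Z(hit rate) - Z(false-alarm rate); rates must be in the open (0,1)."""
    if not (0 < hit_rate < 1 and 0 < fa_rate < 1):
        raise ValueError(
            "rates must lie strictly inside (0,1); apply corrected_rates first"
        )
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


_SIGNAL_TRUTH = {"old": True, "new": False, "different": True, "same": False}


def counts_from_log(log: pd.DataFrame) -> SDTCounts:
    """Tally hits and false alarms from trial rows (truth + response cols)."""
    is_signal = log["truth"].map(_SIGNAL_TRUTH)
    if is_signal.isna().any():
        bad = sorted(log.loc[is_signal.isna(), "truth"].unique())
        raise ValueError(f"unknown truth labels: {bad}")
    said_signal = log["response"] == "signal"
    return SDTCounts(
        n_signal=int(is_signal.sum()),
        n_noise=int((~is_signal).sum()),
        hits=int((is_signal & said_signal).sum()),
        false_alarms=int((~is_signal & said_signal).sum()),
    )


def score_log(
    log: pd.DataFrame,
    by: tuple = ("participant_id", "version", "order", "phase_index", "task", "kind"),
    method: str = "loglinear",
) -> pd.DataFrame:
    """Per-unit SDT results from a trial-level response log.

    Groups the log by ``by`` (default: one row per participant x phase x
    trial kind) and returns counts, corrected rates, d' and the correction
    flag for each unit.
    """
    if log.empty:
        raise ValueError("empty response log")
    rows = []
    for keys, grp in log.groupby(list(by), sort=True):
        c = counts_from_log(grp)
        hr, fr, corrected = corrected_rates(c, method)
        rows.append(
            dict(zip(by, keys))
            | {
                "n_signal": c.n_signal,
                "n_noise": c.n_noise,
                "hits": c.hits,
                "false_alarms": c.false_alarms,
                "hit_rate": hr,
                "fa_rate": fr,
                "dprime": dprime(hr, fr),
                "correction_applied": corrected,
            }
        )
    return pd.DataFrame(rows)


def percent_correct_by_speaker(log: pd.DataFrame) -> pd.DataFrame:
    """Per-speaker percent correct, pooled over participants.

    Operates on recognition-style rows (one speaker per trial).  A response
    is correct when it matches the trial's truth under the signal/noise
    mapping.  Returns one row per (version, speaker) with n_trials and
    pc (in percent).  Speakers absent from the log are simply absent.
    """
    log = log[log["kind"] == "recognition"] if "kind" in log.columns else log
    if log.empty:
        raise ValueError("no recognition trials in log")
    is_signal = log["truth"].map(_SIGNAL_TRUTH)
    if is_signal.isna().any():
        raise ValueError("unknown truth labels in log")
    correct = (log["response"] == "signal") == is_signal
    df = log.assign(correct=correct)
    grouped = (
        df.groupby(["version", "speaker_id"], sort=True)["correct"]
        .agg(n_trials="size", pc="mean")
        .reset_index()
    )
    grouped["pc"] *= 100.0
    return grouped


def chi_square_gof(observed: float, expected: float, n: int) -> tuple[float, float]:
    """Two-cell Pearson goodness-of-fit: at/above threshold vs below.

    chi2 = (o-e)^2/e + ((n-o)-(n-e))^2/(n-e), 1 df.
    """
    if not (0 < expected < n):
        raise ValueError(f"expected count {expected} must lie strictly in (0, {n})")
    chi2 = (observed - expected) ** 2 / expected + (
        (n - observed) - (n - expected)
    ) ** 2 / (n - expected)
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def ceiling_analysis(
    dprimes,
    percentile: float = 90.0,
    expected_mode: str = "normal_tail",
) -> dict:
    """Soft-ceiling diagnostic on a d' distribution.

    threshold = empirical ``percentile`` (linear-interpolation convention);
    observed = number of values at or above the threshold.  The expected
    count under "no ceiling" is either the Gaussian tail mass at the
    threshold for a Normal(sample mean, sample SD) (``normal_tail``,
    default) or a fixed (1 - percentile/100) fraction of n
    (``fixed_fraction``).  Returns threshold, observed, expected, chi2, p
    plus the conventions used.
    """
    x = np.asarray(dprimes, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 values, got {x.size}")
    n = x.size
    threshold = float(np.percentile(x, percentile))  # linear interpolation
    observed = int(np.sum(x >= threshold))
    if expected_mode == "normal_tail":
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise ValueError("zero SD: normal_tail expectation undefined")
        expected = n * float(norm.sf(threshold, loc=x.mean(), scale=sd))
    elif expected_mode == "fixed_fraction":
        expected = n * (1.0 - percentile / 100.0)
    else:
        raise ValueError(f"unknown expected_mode {expected_mode!r}")
    chi2, p = chi_square_gof(observed, expected, n)
    return {
        "n": n,
        "threshold": threshold,
        "observed": observed,
        "expected": expected,
        "chi2": chi2,
        "p": p,
        "percentile": percentile,
        "percentile_convention": "linear",
        "expected_mode": expected_mode,
    }
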