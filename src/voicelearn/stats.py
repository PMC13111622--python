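"""Group-level inference and the mixed-effects recovery harness.

Covers the study's inferential toolkit: Welch's unequal-variances t-test
with caller-declared Bonferroni families, Shapiro-Wilk-gated Spearman
correlation, and the linear mixed-effects model of recognition sensitivity

    dprime ~ task_awareness + voice_load + task_order + (1 | participant)

fitted by maximum likelihood.  Factor coding is explicit 0/1 indicators
with documented directions — awareness: implicit - explicit; load:
simple - challenging; order: phase1 - phase2 — so a positive awareness
estimate means implicit exposure helped and a positive load estimate means
the simple version scored higher.  The numerical optimiser is statsmodels'
MixedLM; it provides Wald (normal-approximation) inference, and the
inference method is recorded in the result rather than silently assumed.

``recovery_harness`` closes the loop: simulate the full two-version study
from a generative config, score it, fit the model, and summarise the fixed
effects across seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sdt import score_log
from .simulate import GenerativeConfig, simulate_study

__all__ = [
    "compare_groups",
    "bonferroni",
    "correlate",
    "recognition_table",
    "fit_lmm",
    "FitResult",
    "recovery_harness",
]

TERMS = ("awareness_implicit", "load_simple", "order_phase1")
CONTRASTS = {
    "awareness_implicit": "implicit - explicit",
    "load_simple": "simple - challenging",
    "order_phase1": "phase1 - phase2",
}


def compare_groups(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test: (t, Welch-Satterthwaite df, p).

    Multiple-comparison adjustment is the caller's job (see ``bonferroni``);
    the family of tests is a declared parameter there, never inferred here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment over a declared family of m tests, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = int(m) if m is not None else p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(p * m, 1.0)


def correlate(x, y) -> dict:
    """Spearman rank correlation with a Shapiro-Wilk normality gate.

    Returns rho and its p-value plus the Shapiro-Wilk p for each input, so
    the (non-)normality that motivated the rank-based test is on record.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError("need n >= 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return {
        "rho": float(rho),
        "p": float(p),
        "n": int(x.size),
        "shapiro_p_x": float(sps.shapiro(x).pvalue),
        "shapiro_p_y": float(sps.shapiro(y).pvalue),
    }


def recognition_table(log: pd.DataFrame, method: str = "loglinear") -> pd.DataFrame:
    """Tidy model input: one row per participant x phase with recognition d'.

    Adds the three indicator-coded factors (awareness_implicit, load_simple,
    order_phase1) alongside the raw labels.
    """
    scored = score_log(log, method=method)
    rec = scored[scored["kind"] == "recognition"].copy()
    if rec.empty:
        raise ValueError("log contains no recognition trials")
    rec["awareness_implicit"] = (rec["task"] == "implicit").astype(float)
    rec["load_simple"] = (rec["version"] == "simple").astype(float)
    rec["order_phase1"] = (rec["phase_index"] == 1).astype(float)
    return rec.reset_index(drop=True)


@dataclass
class FitResult:
    """Fixed-effect table plus variance components for one LMM fit."""

    terms: pd.DataFrame  # term, contrast, estimate, se, stat, p, ci_low, ci_high
    group_var: float  # participant intercept variance
    resid_var: float
    converged: bool
    singular: bool
    p_method: str
    loglik: float
    n_obs: int
    n_groups: int
    warnings: list = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "estimate"])


def fit_lmm(
    data: pd.DataFrame,
    response: str = "dprime",
    terms: tuple = TERMS,
    group: str = "participant_id",
    interactions: bool = False,
) -> FitResult:
    """ML fit of the random-intercept model for recognition sensitivity.

    ``interactions=True`` fits the fully crossed fixed-effects structure
    (all two- and three-way products of the indicators); the default is the
    additive model.  Inference is Wald ("wald" recorded in the result);
    singular (zero) participant-variance fits are flagged, not dropped.
    """
    import statsmodels.formula.api as smf

    for col in (response, group, *terms):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from model data")
    for t in terms:
        if data[t].nunique() < 2:
            raise ValueError(f"factor {t!r} does not vary")
    rhs = " * ".join(terms) if interactions else " + ".join(terms)
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data, groups=data[group])
        fit = model.fit(reml=False)
    msgs = sorted({str(w.message) for w in caught})
    params = fit.params
    ses = fit.bse
    fe_names = [n for n in fit.fe_params.index]
    z975 = sps.norm.ppf(0.975)
    rows = []
    for name in fe_names:
        est, se = float(params[name]), float(ses[name])
        stat = est / se if se > 0 else np.nan
        rows.append(
            {
                "term": name,
                "contrast": CONTRASTS.get(name, ""),
                "estimate": est,
                "se": se,
                "stat": float(stat),
                "p": float(2 * sps.norm.sf(abs(stat))) if se > 0 else np.nan,
                "ci_low": est - z975 * se,
                "ci_high": est + z975 * se,
            }
        )
    group_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    return FitResult(
        terms=pd.DataFrame(rows),
        group_var=group_var,
        resid_var=float(fit.scale),
        converged=bool(fit.converged),
        singular=group_var <= 1e-10,
        p_method="wald",
        loglik=float(fit.llf),
        n_obs=int(fit.nobs),
        n_groups=int(data[group].nunique()),
        warnings=msgs,
    )


def recovery_harness(
    config: GenerativeConfig | None = None,
    n_seeds: int = 20,
    seed: int = 0,
    interactions: bool = False,
    method: str = "loglinear",
) -> dict:
    """Simulate -> score -> fit across seeds; summarise fixed effects.

    Each replicate simulates the full two-version study (selection, plans,
    counterbalanced participant allocation, trial responses), scores
    recognition d' per participant x phase, and fits the mixed model.
    Returns per-term mean estimate, empirical SD, and 95% Wald-CI coverage
    of the mean recovered value, plus the per-seed estimates and a count of
    failed fits (failures are recorded, not fatal).
    """
    config = config or GenerativeConfig()
    root = np.random.default_rng(seed)
    seeds = [int(root.integers(2**31)) for _ in range(n_seeds)]
    per_seed = []
    failures = 0
    for s in seeds:
        try:
            log = simulate_study(config, seed=s)
            table = recognition_table(log, method=method)
            fit = fit_lmm(table, interactions=interactions)
        except Exception as exc:  # pragma: no cover - defensive
            failures += 1
            per_seed.append({"seed": s, "error": str(exc)})
            continue
        row = {"seed": s, "singular": fit.singular}
        for rec in fit.terms.to_dict(orient="records"):
            row[rec["term"]] = rec["estimate"]
            row[rec["term"] + "_ci_low"] = rec["ci_low"]
            row[rec["term"] + "_ci_high"] = rec["ci_high"]
        per_seed.append(row)
    df = pd.DataFrame([r for r in per_seed if "error" not in r])
    summary = {}
    if not df.empty:
        for term in [c for c in df.columns if c in set(TERMS) | {"Intercept"}]:
            est = df[term].to_numpy()
            summary[term] = {
                "mean": float(est.mean()),
                "sd": float(est.std(ddof=1)) if est.size > 1 else 0.0,
                "n_seeds": int(est.size),
            }
    return {
        "summary": summary,
        "per_seed": per_seed,
        "n_failures": failures,
        "n_seeds": n_seeds,
    }
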