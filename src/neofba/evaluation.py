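"""Statistical evaluation of FBA predictions.

Covers the full assessment battery for an age-prediction biomarker:

* goodness of fit between FBA and PMA (Pearson r with bootstrap CI,
  bias, error variance, median absolute error, % within ±1/±2 weeks);
* bootstrap comparison of two models' correlations (Δr with percentile
  CI; significant when the CI excludes zero);
* TOST equivalence of absolute errors between two cohorts (two
  one-sided Welch t-tests against a ±0.5-week boundary);
* repeated-measures adjusted correlation from a linear mixed model with
  a random intercept per infant;
* PAD-versus-outcome analysis: one-way ANOVA with Levene's variance
  check, Tukey-corrected pairwise comparisons, per-group one-sample
  t-tests against zero, and Hedges-corrected Cohen's D effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FitMetrics",
    "goodness_of_fit",
    "bootstrap_delta_r",
    "tost_equivalence",
    "lmm_adjusted_r",
    "pad_outcome_analysis",
    "classify_outcome",
    "cohens_d_one_sample",
    "cohens_d_two_sample",
]

log = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_B = 1000
EQUIVALENCE_BOUNDARY_WEEKS = 0.5


@dataclass
class FitMetrics:
    r: float
    r_ci: tuple[float, float]
    bias_weeks: float
    variance_weeks: float
    median_abs_weeks: float
    abs_iqr_weeks: tuple[float, float]
    pct_within_1wk: float
    pct_within_2wk: float

    def as_dict(self) -> dict:
        return {
            "r": self.r, "r_ci_lo": self.r_ci[0], "r_ci_hi": self.r_ci[1],
            "bias_weeks": self.bias_weeks, "variance_weeks": self.variance_weeks,
            "median_abs_weeks": self.median_abs_weeks,
            "abs_iqr_lo": self.abs_iqr_weeks[0], "abs_iqr_hi": self.abs_iqr_weeks[1],
            "pct_within_1wk": self.pct_within_1wk, "pct_within_2wk": self.pct_within_2wk,
        }


def goodness_of_fit(fba: np.ndarray, pma: np.ndarray, seed: int = 0,
                    n_boot: int = DEFAULT_BOOTSTRAP_B) -> FitMetrics:
    """Per-recording goodness of fit between predicted and true age."""
    fba = np.asarray(fba, dtype=float)
    pma = np.asarray(pma, dtype=float)
    if len(fba) != len(pma) or len(fba) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(fba) == 0 or np.std(pma) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    err = fba - pma
    r = float(np.corrcoef(fba, pma)[0, 1])

    rng = np.random.default_rng(seed)
    boot = []
    n = len(fba)
    while len(boot) < n_boot:
        idx = rng.integers(0, n, n)
        if np.std(fba[idx]) == 0 or np.std(pma[idx]) == 0:
            continue
        boot.append(np.corrcoef(fba[idx], pma[idx])[0, 1])
    lo, hi = np.percentile(boot, [2.5, 97.5])

    abs_err = np.abs(err)
    q25, q75 = np.percentile(abs_err, [25, 75])
    return FitMetrics(
        r=r, r_ci=(float(lo), float(hi)),
        bias_weeks=float(np.mean(err)),
        variance_weeks=float(np.var(err, ddof=1)),
        median_abs_weeks=float(np.median(abs_err)),
        abs_iqr_weeks=(float(q25), float(q75)),
        pct_within_1wk=float(100.0 * np.mean(abs_err <= 1.0)),
        pct_within_2wk=float(100.0 * np.mean(abs_err <= 2.0)),
    )


def bootstrap_delta_r(preds_a: np.ndarray, preds_b: np.ndarray, pma: np.ndarray,
                      n_boot: int = DEFAULT_BOOTSTRAP_B, seed: int = 0) -> dict:
    """Bootstrap CI for r(A, PMA) − r(B, PMA) over paired recordings.

    Significant when the 95 % percentile interval excludes zero.
    Degenerate (zero-variance) resamples are redrawn and counted.
    """
    a = np.asarray(preds_a, float)
    b = np.asarray(preds_b, float)
    y = np.asarray(pma, float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("vectors must be aligned")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n = len(a)
    rng = np.random.default_rng(seed)
    deltas = []
    redrawn = 0
    while len(deltas) < n_boot:
        idx = rng.integers(0, n, n)
        ys = y[idx]
        if np.std(ys) == 0 or np.std(a[idx]) == 0 or np.std(b[idx]) == 0:
            redrawn += 1
            continue
        ra = np.corrcoef(a[idx], ys)[0, 1]
        rb = np.corrcoef(b[idx], ys)[0, 1]
        deltas.append(ra - rb)
    if redrawn:
        log.info("bootstrap_delta_r: %d degenerate resamples redrawn", redrawn)
    deltas = np.array(deltas)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    delta = float(np.corrcoef(a, y)[0, 1] - np.corrcoef(b, y)[0, 1])
    return {
        "delta_r": delta,
        "ci": (float(lo), float(hi)),
        "significant": bool(lo > 0 or hi < 0),
    }


def _welch_t_one_sided(x: np.ndarray, y: np.ndarray, shift: float, alternative: str) -> float:
    """One-sided Welch p-value for mean(x) − mean(y) vs ``shift``."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    diff = np.mean(x) - np.mean(y) - shift
    if se2 == 0:
        # zero-variance degenerate case: p is 0/1 by the sign of the difference
        if alternative == "greater":
            return 0.0 if diff > 0 else 1.0
        return 0.0 if diff < 0 else 1.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    return float(stats.t.cdf(t, df))


def tost_equivalence(abs_err_a: np.ndarray, abs_err_b: np.ndarray,
                     boundary_weeks: float = EQUIVALENCE_BOUNDARY_WEEKS,
                     alpha: float = 0.05) -> dict:
    """Two one-sided Welch t-tests of mean |error| difference vs ±boundary.

    p is the larger of the two one-sided p-values; the samples are
    equivalent at level alpha when p < alpha.  With two exactly equal
    zero-variance samples the difference is exactly 0, inside any
    positive boundary, so p = 0 by convention.
    """
    if boundary_weeks <= 0:
        raise ValueError("equivalence boundary must be positive")
    a = np.asarray(abs_err_a, float)
    b = np.asarray(abs_err_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per arm")
    p_lower = _welch_t_one_sided(a, b, -boundary_weeks, "greater")
    p_upper = _welch_t_one_sided(a, b, +boundary_weeks, "less")
    p = max(p_lower, p_upper)
    return {"p": float(p), "equivalent": bool(p < alpha),
            "mean_diff": float(np.mean(a) - np.mean(b)), "boundary": boundary_weeks}


def lmm_adjusted_r(fba: np.ndarray, pma: np.ndarray, subject_ids: np.ndarray,
                   n_boot: int = DEFAULT_BOOTSTRAP_B, seed: int = 0) -> dict:
    """Repeated-measures adjusted correlation via a random-intercept LMM.

    Fits PMA ~ FBA with a random intercept per infant (REML) and
    returns the Pearson correlation between observed PMA and the
    conditional fitted values (fixed + random effects), with a bootstrap
    CI over subjects.  When the between-subject variance collapses to
    zero the adjusted r equals the ordinary r and is flagged.
    """
    df = pd.DataFrame({"fba": np.asarray(fba, float), "pma": np.asarray(pma, float),
                       "subject": np.asarray(subject_ids).astype(str)})
    counts = df.groupby("subject").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 recordings each")

    def _fit_adjusted(d: pd.DataFrame) -> tuple[float, bool]:
        model = smf.mixedlm("pma ~ fba", d, groups=d["subject"])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True)
        re_var = float(fit.cov_re.iloc[0, 0])
        fitted = np.asarray(fit.fittedvalues, float)
        singular = re_var < 1e-10
        if singular:
            r = float(np.corrcoef(d["pma"], d["fba"])[0, 1])
        else:
            r = float(np.corrcoef(d["pma"], fitted)[0, 1])
        return r, singular

    r_adj, singular = _fit_adjusted(df)
    if singular:
        log.warning("LMM between-subject variance ~0; adjusted r equals ordinary r")

    subjects = df["subject"].unique()
    rng = np.random.default_rng(seed)
    boot = []
    attempts = 0
    while len(boot) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        parts = [df[df["subject"] == s].assign(subject=f"{s}_{k}") for k, s in enumerate(pick)]
        d = pd.concat(parts, ignore_index=True)
        if d["pma"].std() == 0 or d["fba"].std() == 0:
            continue
        try:
            boot.append(_fit_adjusted(d)[0])
        except Exception:
            continue
    ci = tuple(np.percentile(boot, [2.5, 97.5])) if boot else (np.nan, np.nan)
    return {"r_adjusted": r_adj, "ci": (float(ci[0]), float(ci[1])),
            "singular": singular, "r_pooled": float(np.corrcoef(df["pma"], df["fba"])[0, 1])}


def cohens_d_one_sample(x: np.ndarray) -> float:
    """One-sample Cohen's D vs 0 with the Hedges small-sample correction."""
    x = np.asarray(x, float)
    n = len(x)
    s = np.std(x, ddof=1)
    if s == 0:
        return np.nan
    return float(np.mean(x) / s * (1.0 - 3.0 / (4.0 * n - 5.0)))


def cohens_d_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Cohen's D (pooled SD) with the Hedges correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return np.nan
    d = (np.mean(x) - np.mean(y)) / np.sqrt(sp2)
    return float(d * (1.0 - 3.0 / (4.0 * (nx + ny) - 9.0)))


def classify_outcome(indices: dict[str, float], scale: str) -> str:
    """Stratify a Bayley assessment into normal / mildly_abnormal / abnormal.

    Scale II requires mental and psychomotor indices; scale III the
    cognitive, language and motor indices.  All indices > 85 → normal;
    any index < 70 → abnormal; otherwise mildly abnormal (boundary
    scores of exactly 70 or 85 are mildly abnormal by the strict
    inequalities).
    """
    required = {"II": ("mental", "psychomotor"), "III": ("cognitive", "language", "motor")}
    if scale not in required:
        raise ValueError(f"unknown Bayley scale {scale!r}")
    try:
        vals = [float(indices[k]) for k in required[scale]]
    except KeyError as exc:
        raise ValueError(f"missing Bayley index for scale {scale}: {exc}") from exc
    if any(np.isnan(v) for v in vals):
        raise ValueError("missing Bayley index value")
    if all(v > 85 for v in vals):
        return "normal"
    if any(v < 70 for v in vals):
        return "abnormal"
    return "mildly_abnormal"


GROUP_ORDER = ("normal", "mildly_abnormal", "abnormal")


def pad_outcome_analysis(records: pd.DataFrame, min_serial: int = 3, alpha: float = 0.05) -> dict:
    """PAD versus neurodevelopmental outcome on infants with serial EEGs.

    ``records`` needs columns subject_id, group, n_serial_recordings,
    mean_pad_weeks.  Infants with fewer than ``min_serial`` recordings
    are excluded; groups with n < 2 are reported descriptively but
    excluded from the ANOVA.  Returns a report dict with group
    descriptives, one-way ANOVA F/df/p, Levene p, Tukey-corrected
    pairwise p-values with two-sample effect sizes, and per-group
    two-sided one-sample t-tests against zero with Hedges-corrected
    effect sizes.
    """
    df = records[records["n_serial_recordings"] >= min_serial].copy()
    groups = {g: df.loc[df["group"] == g, "mean_pad_weeks"].to_numpy(float)
              for g in GROUP_ORDER if (df["group"] == g).any()}
    report: dict = {"min_serial": min_serial, "n_infants": int(len(df)), "groups": {}}

    for g, v in groups.items():
        entry = {"n": int(len(v)), "mean_pad": float(np.mean(v)),
                 "sd_pad": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan}
        if len(v) >= 2 and np.std(v, ddof=1) > 0:
            t, p = stats.ttest_1samp(v, 0.0)
            entry.update(t_vs_zero=float(t), p_vs_zero=float(p),
                         significant_vs_zero=bool(p < alpha),
                         cohens_d=cohens_d_one_sample(v))
        report["groups"][g] = entry

    anova_groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(anova_groups) < 2:
        raise ValueError("need >= 2 groups with n >= 2 after filtering")

    vals = list(anova_groups.values())
    f_stat, p_anova = stats.f_oneway(*vals)
    report["anova"] = {"F": float(f_stat), "df_between": len(vals) - 1,
                       "df_within": int(sum(len(v) for v in vals) - len(vals)),
                       "p": float(p_anova)}
    if all(np.std(v, ddof=1) == 0 for v in vals):
        log.warning("Levene degenerate: all groups have zero variance")
        report["levene"] = {"p": np.nan, "degenerate": True}
    else:
        _, p_lev = stats.levene(*vals)
        report["levene"] = {"p": float(p_lev), "degenerate": False}

    y = np.concatenate(vals)
    labels = np.concatenate([[g] * len(v) for g, v in anova_groups.items()])
    if len(set(labels)) >= 2 and np.std(y) > 0:
        tukey = pairwise_tukeyhsd(y, labels, alpha=alpha)
        pairwise = {}
        res = tukey.summary().data[1:]
        for row in res:
            g1, g2 = str(row[0]), str(row[1])
            pairwise[f"{g1}_vs_{g2}"] = {
                "p_adj": float(row[3]),
                "significant": bool(row[6]),
                "cohens_d": cohens_d_two_sample(anova_groups[g1], anova_groups[g2]),
            }
        report["tukey"] = pairwise
    else:
        report["tukey"] = {}
    return report
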