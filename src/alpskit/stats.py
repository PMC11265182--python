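"""Two-group statistical battery for ALPS cohorts.

Covers the comparisons a typical case-control diffusion study reports:
Lilliefors normality screening of the indices (Monte-Carlo p-values),
pooled/Welch two-sample t-tests (from samples or printed mean +/- SD
summaries), Mann-Whitney U for demographics (exact by enumeration on small
samples, tie-corrected normal approximation otherwise), a 2x2 chi-square for
sex composition, Pearson/Spearman index-covariate correlations, and a
mean +/- SD group report with significance stars at alpha = 0.05. No
multiple-testing correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    """A named test statistic with its p-value and bookkeeping."""

    name: str
    statistic: float
    p_value: float
    n: tuple
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# --- Lilliefors -------------------------------------------------------------

def _lilliefors_statistic(sample: np.ndarray) -> float:
    x = np.sort(np.asarray(sample, float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(ecdf_hi - cdf, cdf - ecdf_lo)))


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, reps: int, seed: int) -> np.ndarray:
    """Null distribution of the Lilliefors D for sample size n (Monte Carlo)."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.standard_normal((reps, n)), axis=1)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf(z)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    d = np.maximum(hi - cdf, cdf - lo).max(axis=1)
    d.setflags(write=False)
    return d


def lilliefors(sample, reps: int = 5000, seed: int = 0) -> TestResult:
    """Normality test with estimated mean and variance; Monte-Carlo p.

    D = sup |F_hat(x) - Phi((x - xbar)/s)|; p is the fraction of ``reps``
    standard-normal samples of the same size whose D meets or exceeds the
    observed one (add-one corrected). The null distribution depends only on
    n and is cached across calls.
    """
    sample = np.asarray(sample, float)
    if sample.size < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    if np.ptp(sample) == 0:
        raise ValueError("Lilliefors test undefined for a constant sample")
    d = _lilliefors_statistic(sample)
    null = _lilliefors_null(sample.size, reps, seed)
    p = (1 + int((null >= d).sum())) / (reps + 1)
    return TestResult("lilliefors", d, p, (sample.size,),
                      {"reps": reps, "seed": seed})


# --- t-tests ----------------------------------------------------------------

def t_from_summary(m1: float, s1: float, n1: int, m2: float, s2: float,
                   n2: int, variant: str = "student") -> TestResult:
    """Two-sample t-test from printed mean/SD/n summaries."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TestResult(f"t-{variant}", 0.0, 1.0, (n1, n2),
                              {"df": n1 + n2 - 2})
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "student":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif variant == "welch":
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t = (m1 - m2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(f"t-{variant}", float(t), float(p), (n1, n2),
                      {"df": float(df)})


def two_sample_t(a, b, variant: str = "student") -> TestResult:
    """Two-sample t-test on raw samples (pooled by default, Welch optional)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return t_from_summary(a.mean(), a.std(ddof=1), a.size,
                          b.mean(), b.std(ddof=1), b.size, variant=variant)


# --- Mann-Whitney -----------------------------------------------------------

EXACT_MWU_LIMIT = 20


def _u_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2)


@lru_cache(maxsize=8)
def _combination_indices(N: int, k: int) -> np.ndarray:
    idx = np.fromiter(
        (i for picks in combinations(range(N), k) for i in picks),
        dtype=np.intp, count=comb(N, k) * k,
    ).reshape(comb(N, k), k)
    idx.setflags(write=False)
    return idx


def mann_whitney(a, b, mode: str = "auto") -> TestResult:
    """Mann-Whitney U with midrank ties.

    ``exact`` enumerates all C(n1+n2, n1) group assignments of the pooled
    midranks (permitted up to 20 observations); ``normal`` uses the
    tie-corrected normal approximation with continuity correction. Two-sided
    exact p = 2 * min(lower tail, upper tail), capped at 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if min(n1, n2) < 1:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_MWU_LIMIT else "normal"
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1], n1)

    if mode == "exact":
        if n1 + n2 > EXACT_MWU_LIMIT:
            raise ValueError(f"exact mode limited to n1+n2 <= {EXACT_MWU_LIMIT}")
        combos = _combination_indices(n1 + n2, n1)
        total = combos.shape[0]
        u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2
        lo = int((u_all <= u_obs + 1e-9).sum())
        hi = int((u_all >= u_obs - 1e-9).sum())
        p = min(1.0, 2 * min(lo / total, hi / total))
        return TestResult("mann-whitney-exact", u_obs, p, (n1, n2),
                          {"enumerated": total})
    if mode == "normal":
        mu = n1 * n2 / 2.0
        N = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (N * (N - 1))
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            return TestResult("mann-whitney-normal", u_obs, 1.0, (n1, n2), {})
        z = (u_obs - mu - np.sign(u_obs - mu) * 0.5) / np.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
        return TestResult("mann-whitney-normal", u_obs, p, (n1, n2),
                          {"z": float(z)})
    raise ValueError(f"unknown mode {mode!r}")


# --- chi-square -------------------------------------------------------------

def chi2_upper_tail(statistic: float, df: int = 1) -> float:
    """Upper-tail probability of the chi-square distribution."""
    return float(sps.chi2.sf(statistic, df))


def chi2_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (df = 1), optional Yates correction."""
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    (a, b), (c, d) = t
    N = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("chi-square undefined with a zero margin")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - N / 2.0, 0.0)
    stat = N * delta ** 2 / (r1 * r2 * c1 * c2)
    return TestResult("chi2-2x2", float(stat), chi2_upper_tail(stat, 1),
                      (int(r1), int(r2)), {"yates": yates})


# --- correlations -----------------------------------------------------------

def correlate(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a two-sided t-transform p-value.

    Missing pairs are dropped listwise; Spearman applies the Pearson path to
    midranks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("correlation needs >= 3 complete pairs")
    if method == "spearman":
        x, y = sps.rankdata(x), sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return TestResult(f"correlation-{method}", r, p, (n,), {})


# --- group report -----------------------------------------------------------

INDEX_COLUMNS = ["dti_left", "dti_right", "dti_global",
                 "dki_left", "dki_right", "dki_global"]
DEMOGRAPHIC_COLUMNS = ["age", "education", "duration", "frequency",
                       "phq9", "gad7", "midas", "hit6"]


@dataclass
class GroupReport:
    """Mean +/- SD tables with the per-variable tests and significance stars."""

    demographics: pd.DataFrame
    indices: pd.DataFrame
    alpha: float
    inter_index_correlation: TestResult | None = None

    def to_text(self) -> str:
        out = ["Demographics and neuropsychological data",
               "=" * 56,
               self.demographics.to_string(index=False),
               "",
               "ALPS indices (two-sample t-test; * p < %g)" % self.alpha,
               "=" * 56,
               self.indices.to_string(index=False)]
        if self.inter_index_correlation is not None:
            c = self.inter_index_correlation
            out += ["", f"DKI-ALPS vs DTI-ALPS (global): r = {c.statistic:.3f}, "
                        f"p = {c.p_value:.4f}"]
        return "\n".join(out)


def _mean_sd(v: pd.Series) -> str:
    v = v.dropna()
    if v.empty:
        return "-"
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"


def group_report(cohort: pd.DataFrame, alpha: float = 0.05,
                 reps: int = 5000, seed: int = 0,
                 t_variant: str = "student",
                 inter_index: bool = False) -> GroupReport:
    """The study-style report: demographics via Mann-Whitney, sex via
    chi-square, indices via Lilliefors screening followed by a two-sample
    t-test, starred at ``alpha``."""
    groups = set(cohort["group"])
    if groups != {"migraine", "control"}:
        raise ValueError("cohort must contain exactly the groups "
                         "{'migraine', 'control'}")
    mig = cohort[cohort["group"] == "migraine"]
    ctl = cohort[cohort["group"] == "control"]

    demo_rows = []
    sex_tab = [[(mig["sex"] == "M").sum(), (mig["sex"] == "F").sum()],
               [(ctl["sex"] == "M").sum(), (ctl["sex"] == "F").sum()]]
    sex_res = chi2_2x2(sex_tab)
    demo_rows.append({
        "variable": "sex (M/F)",
        "migraine": f"{sex_tab[0][0]}/{sex_tab[0][1]}",
        "control": f"{sex_tab[1][0]}/{sex_tab[1][1]}",
        "test": "chi2", "statistic": round(sex_res.statistic, 3),
        "p": round(sex_res.p_value, 4),
        "sig": "*" if sex_res.p_value < alpha else "",
    })
    for col in DEMOGRAPHIC_COLUMNS:
        if col not in cohort:
            continue
        a = mig[col].dropna().to_numpy()
        b = ctl[col].dropna().to_numpy()
        if len(b) == 0 or len(a) == 0:
            stat = p = np.nan
            test = "-"
        else:
            res = mann_whitney(a, b, mode="auto")
            stat, p, test = res.statistic, res.p_value, "mwu"
        demo_rows.append({
            "variable": col, "migraine": _mean_sd(mig[col]),
            "control": _mean_sd(ctl[col]), "test": test,
            "statistic": round(stat, 3) if np.isfinite(stat) else "-",
            "p": round(p, 4) if np.isfinite(p) else "-",
            "sig": "*" if np.isfinite(p) and p < alpha else "",
        })

    index_rows = []
    for col in INDEX_COLUMNS:
        a = mig[col].dropna().to_numpy()
        b = ctl[col].dropna().to_numpy()
        lp = min(lilliefors(a, reps=reps, seed=seed).p_value,
                 lilliefors(b, reps=reps, seed=seed).p_value)
        res = two_sample_t(a, b, variant=t_variant)
        index_rows.append({
            "index": col, "migraine": _mean_sd(mig[col]),
            "control": _mean_sd(ctl[col]),
            "lilliefors_p": round(lp, 4),
            "t": round(res.statistic, 3), "p": round(res.p_value, 4),
            "sig": "*" if res.p_value < alpha else "",
        })

    inter = None
    if inter_index:
        inter = correlate(cohort["dti_global"], cohort["dki_global"],
                          method="pearson")
    return GroupReport(demographics=pd.DataFrame(demo_rows),
                       indices=pd.DataFrame(index_rows), alpha=alpha,
                       inter_index_correlation=inter)
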