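"""Recognition-memory scoring and behavioral inference.

Signal-detection scoring of the 4-point old/new recognition responses
(responses 3 and 4 count as "old" judgments), paired t statistics with
Cohen's d and confidence interval, the default-prior (JZS) Bayes factor,
and exact noncentral-t power analysis for the paired design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "SDTResult",
    "PairedTestResult",
    "PowerQuery",
    "score_recognition",
    "dprime",
    "paired_test",
    "jzs_bf10",
    "achieved_power",
    "required_n",
]


# ---------------------------------------------------------------------------
# Signal detection


@dataclass(frozen=True)
class SDTResult:
    """Equal-variance SDT indices from hit and false-alarm rates.

    ``criterion_cprime`` is c scaled by d' (c' = c / d'); it is NaN when
    d' = 0, in which case the propensity index is undefined.
    """

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    criterion_cprime: float


def _corrected_rate(count: int, n: int, correction: str) -> float:
    """Proportion with extreme-value protection.

    ``"half"``: 0 and 1 replaced by 1/(2N) and 1 - 1/(2N).
    ``"loglinear"``: (count + 0.5) / (N + 1) applied to every rate.
    """
    if n <= 0:
        raise ValueError("trial count must be positive")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    if correction == "loglinear":
        return (count + 0.5) / (n + 1)
    if correction == "half":
        rate = count / n
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate
    raise ValueError(f"unknown correction {correction!r}")


def dprime(hits: int, n_old: int, false_alarms: int, n_new: int,
           correction: str = "half") -> SDTResult:
    """d' = z(H) - z(F); c = -(z(H) + z(F)) / 2; c' = c / d'."""
    h = _corrected_rate(hits, n_old, correction)
    f = _corrected_rate(false_alarms, n_new, correction)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    d = zh - zf
    c = -(zh + zf) / 2.0
    cprime = c / d if d != 0.0 else np.nan
    return SDTResult(h, f, d, c, cprime)


def score_recognition(trials: pd.DataFrame, correction: str = "half") -> pd.DataFrame:
    """Score trial-level recognition responses into a per subject x condition table.

    ``trials`` columns: subject, condition, item_status (old|new),
    response (1-4).  Old trials carry their study condition; new items were
    never studied, so rows with item_status "new" are shared between
    conditions regardless of their condition field.  A response of 3 or 4
    is an "old" judgment: on old trials it is a hit, on new trials a false
    alarm.

    Returns one row per subject x condition with counts, corrected rates
    and SDT indices.
    """
    bad_status = set(trials["item_status"]) - {"old", "new"}
    if bad_status:
        raise ValueError(f"unknown item_status values: {sorted(bad_status)}")
    bad_resp = set(trials["response"]) - {1, 2, 3, 4}
    if bad_resp:
        raise ValueError(f"responses outside 1-4: {sorted(bad_resp)}")

    rows = []
    old = trials[trials["item_status"] == "old"]
    new = trials[trials["item_status"] == "new"]
    for subject, sub_new in new.groupby("subject", sort=True):
        n_new = len(sub_new)
        fas = int((sub_new["response"] >= 3).sum())
        sub_old = old[old["subject"] == subject]
        for condition, grp in sub_old.groupby("condition", sort=True):
            n_old = len(grp)
            hits = int((grp["response"] >= 3).sum())
            sdt = dprime(hits, n_old, fas, n_new, correction=correction)
            rows.append(
                dict(subject=subject, condition=condition, n_old=n_old,
                     n_new=n_new, hits=hits, false_alarms=fas,
                     hit_rate=sdt.hit_rate, fa_rate=sdt.fa_rate,
                     d_prime=sdt.d_prime, criterion_c=sdt.criterion_c,
                     criterion_cprime=sdt.criterion_cprime)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired inference


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test with effect size, 95% CI and JZS Bayes factor."""

    mean_diff: float
    ci_low: float
    ci_high: float
    t_value: float
    df: int
    p_value: float
    cohen_d: float
    bf10: float
    tails: str

    def summary(self) -> str:
        return (
            f"paired t-test ({self.tails}-tailed): diff = {self.mean_diff:.3f}, "
            f"95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}], "
            f"t({self.df}) = {self.t_value:.3f}, p = {self.p_value:.4g}, "
            f"Cohen's d = {self.cohen_d:.3f}, BF10 = {self.bf10:.4g}"
        )


def cohen_d_from_t(t_value: float, n: int) -> float:
    """Paired-design effect size from the t statistic: d = t / sqrt(n)."""
    return t_value / np.sqrt(n)


def ci_from_t(mean_diff: float, t_value: float, df: int,
              confidence: float = 0.95) -> tuple[float, float]:
    """Two-sided CI recovered from a reported mean difference and t.

    The standard error is ``mean_diff / t``; useful for checking reported
    statistics against each other.
    """
    if t_value == 0:
        raise ValueError("t must be nonzero to recover the standard error")
    se = mean_diff / t_value
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    return mean_diff - tcrit * se, mean_diff + tcrit * se


def paired_test(x, y, tails: str = "two") -> PairedTestResult:
    """Paired t-test of x - y with Cohen's d = t/sqrt(n) and a two-sided 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: t undefined")
    se = sd / np.sqrt(n)
    mean = diff.mean()
    t = mean / se
    df = n - 1
    if tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tails == "one":
        p = stats.t.sf(t, df)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    tcrit = stats.t.ppf(0.975, df)
    d = t / np.sqrt(n)
    bf = jzs_bf10(t, n, tails=tails)
    return PairedTestResult(mean, mean - tcrit * se, mean + tcrit * se,
                            t, df, p, d, bf, tails)


def jzs_bf10(t_value: float, n: int, cauchy_scale: float = np.sqrt(2) / 2,
             tails: str = "two") -> float:
    """Default-prior (JZS) Bayes factor for a one-sample / paired t statistic.

    BF10 is the ratio of the marginal likelihood of t under a Cauchy(0,
    ``cauchy_scale``) prior on the standardized effect size delta to the
    central-t likelihood under the null, computed by adaptive quadrature
    (relative tolerance 1e-8).  ``tails="one"`` restricts the prior to
    delta > 0 (half-Cauchy), the directional variant.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(t_value):
        raise ValueError("t must be finite")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return (stats.nct.pdf(t_value, df, delta * sqrt_n)
                * stats.cauchy.pdf(delta, loc=0.0, scale=cauchy_scale))

    if tails == "two":
        num, err = integrate.quad(integrand, -np.inf, np.inf,
                                  epsrel=1e-8, epsabs=0, limit=400)
    elif tails == "one":
        num, err = integrate.quad(integrand, 0.0, np.inf,
                                  epsrel=1e-8, epsabs=0, limit=400)
        num *= 2.0  # half-Cauchy normalization
    else:
        raise ValueError("tails must be 'one' or 'two'")
    if num <= 0 or (err > 0 and err / num > 1e-6):
        raise RuntimeError("Bayes factor integration did not converge")
    return num / stats.t.pdf(t_value, df)


# ---------------------------------------------------------------------------
# Power analysis


@dataclass(frozen=True)
class PowerQuery:
    """Solved sample size for a paired (one-sample-on-differences) t-test."""

    effect_size_d: float
    alpha: float
    target_power: float
    tails: str
    result_n: int
    achieved_power: float

    @property
    def beta(self) -> float:
        return 1.0 - self.achieved_power


def achieved_power(n: int, effect_size_d: float, alpha: float = 0.05,
                   tails: str = "one") -> float:
    """Exact noncentral-t power of a paired t-test with n pairs."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    nc = effect_size_d * np.sqrt(n)
    if tails == "one":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    if tails == "two":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    raise ValueError("tails must be 'one' or 'two'")


def required_n(effect_size_d: float, alpha: float = 0.05,
               target_power: float = 0.80, tails: str = "one",
               max_n: int = 1_000_000) -> PowerQuery:
    """Smallest n whose exact paired-t power reaches ``target_power``."""
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not 0 < target_power < 1:
        raise ValueError("alpha and target_power must lie in (0, 1)")
    lo, hi = 2, 2
    while achieved_power(hi, effect_size_d, alpha, tails) < target_power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise ValueError("target power unattainable within max_n")
    while lo < hi:  # first n with power >= target
        mid = (lo + hi) // 2
        if achieved_power(mid, effect_size_d, alpha, tails) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return PowerQuery(effect_size_d, alpha, target_power, tails, hi,
                      achieved_power(hi, effect_size_d, alpha, tails))
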