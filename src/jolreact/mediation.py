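"""Multilevel 1-1-1 mediation of the condition effect on d' by an EEG signal.

Condition (JOL = 0, no-JOL = 1), mediator and outcome all vary within
subject (two observations per subject, one per condition).  Path a comes
from a mixed model ``mediator ~ condition`` with a random subject
intercept; paths b and c' from ``outcome ~ condition + mediator`` with a
random subject intercept.  With only two observations per subject random
slopes are unidentifiable, so the models carry random intercepts only.

The indirect effect a*b gets a Monte Carlo confidence interval: draws
``a* ~ N(a_hat, SE_a)`` and ``b* ~ N(b_hat, SE_b)`` (independent), CI from
the 2.5/97.5 percentiles of ``a* b*``, and ``z = a_hat b_hat / SD(a* b*)``.
Mediator and outcome are grand-mean centered; when ``standardize=True``
they are also scaled to unit SD so coefficients are on the beta scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .epochs import CONDITION_CODE, CONDITIONS

__all__ = [
    "PathEstimate",
    "MediationResult",
    "MultilevelMediation",
    "assemble_mediation_input",
    "fit_mediation",
]


@dataclass(frozen=True)
class PathEstimate:
    coef: float
    se: float
    z: float
    p: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class MediationResult:
    """Estimated mediation paths with Monte Carlo CI for the indirect effect."""

    a: PathEstimate            # condition -> mediator
    b: PathEstimate            # mediator -> outcome (condition-adjusted)
    direct: PathEstimate       # c': condition -> outcome, mediator-adjusted
    indirect: PathEstimate     # a * b
    total: PathEstimate        # c: condition -> outcome
    standardized: bool
    mc_samples: int
    n_subjects: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, est in [("a (condition -> mediator)", self.a),
                          ("b (mediator -> outcome)", self.b),
                          ("indirect (a*b)", self.indirect),
                          ("direct (c')", self.direct),
                          ("total (c)", self.total)]:
            rows.append(dict(path=name, coef=est.coef, se=est.se, z=est.z,
                             p=est.p, ci_low=est.ci_low, ci_high=est.ci_high))
        return pd.DataFrame(rows)


def assemble_mediation_input(behavior: pd.DataFrame,
                             mediator: pd.DataFrame) -> pd.DataFrame:
    """Join per subject x condition outcome (d') and mediator tables.

    ``behavior`` needs columns subject, condition, d_prime; ``mediator``
    needs subject, condition, value.  Returns exactly two rows per subject
    with the numeric condition code (JOL = 0, no-JOL = 1).
    """
    beh = behavior[["subject", "condition", "d_prime"]].rename(
        columns={"d_prime": "outcome"})
    med = mediator[["subject", "condition", "value"]].rename(
        columns={"value": "mediator"})
    df = beh.merge(med, on=["subject", "condition"], how="outer", validate="1:1")
    if df[["outcome", "mediator"]].isna().any().any():
        missing = df[df[["outcome", "mediator"]].isna().any(axis=1)]
        raise ValueError(
            "subject/condition cells missing from one source: "
            + ", ".join(f"{r.subject}/{r.condition}" for r in missing.itertuples()))
    counts = df.groupby("subject")["condition"].agg(lambda s: tuple(sorted(s)))
    bad = counts[counts != tuple(sorted(CONDITIONS))]
    if len(bad):
        raise ValueError(f"subjects without both conditions: {list(bad.index)}")
    df["code"] = df["condition"].map(CONDITION_CODE).astype(float)
    if not np.all(np.isfinite(df[["mediator", "outcome"]].to_numpy())):
        raise ValueError("mediator and outcome must be finite")
    return df.sort_values(["subject", "code"]).reset_index(drop=True)


def _mixed_fit(endog, exog_df, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog_df, groups=groups)
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:
            res = model.fit(reml=True, method="powell")
    return res


class MultilevelMediation:
    """1-1-1 mediation model for a two-condition within-subject design.

    Parameters
    ----------
    data
        Output of :func:`assemble_mediation_input` (or any frame with
        columns subject, code, mediator, outcome; two rows per subject).
    standardize
        Scale centered mediator and outcome by their grand SDs so paths
        are reported on the beta scale.
    """

    def __init__(self, data: pd.DataFrame, standardize: bool = True):
        required = {"subject", "code", "mediator", "outcome"}
        if not required <= set(data.columns):
            raise ValueError(f"data needs columns {sorted(required)}")
        n_subjects = data["subject"].nunique()
        if n_subjects < 5:
            raise ValueError("need at least 5 subjects")
        if len(data) != 2 * n_subjects:
            raise ValueError("exactly two rows per subject required")
        self.data = data.reset_index(drop=True)
        self.standardize = standardize
        self.n_subjects = n_subjects

    def fit(self, mc_samples: int = 1000, seed: int | None = None) -> MediationResult:
        rng = np.random.default_rng(seed)
        d = self.data
        med = d["mediator"].to_numpy(float)
        out = d["outcome"].to_numpy(float)
        med_c = med - med.mean()
        out_c = out - out.mean()
        if self.standardize:
            med_sd = med.std(ddof=1)
            out_sd = out.std(ddof=1)
            if med_sd == 0 or out_sd == 0:
                raise ValueError("cannot standardize a constant variable")
            med_c = med_c / med_sd
            out_c = out_c / out_sd
        code = d["code"].to_numpy(float)
        groups = d["subject"].to_numpy()
        const = np.ones_like(code)

        xa = pd.DataFrame({"const": const, "condition": code})
        res_a = _mixed_fit(med_c, xa, groups)
        a = _path(res_a, "condition")

        xb = pd.DataFrame({"const": const, "condition": code, "mediator": med_c})
        res_b = _mixed_fit(out_c, xb, groups)
        b = _path(res_b, "mediator")
        direct = _path(res_b, "condition", rng=rng, mc_samples=mc_samples)

        res_c = _mixed_fit(out_c, xa, groups)
        total = _path(res_c, "condition")

        draws = (rng.normal(a.coef, a.se, size=mc_samples)
                 * rng.normal(b.coef, b.se, size=mc_samples))
        ab = a.coef * b.coef
        sd = draws.std(ddof=1)
        z = ab / sd if sd > 0 else np.inf * np.sign(ab)
        p = 2 * stats.norm.sf(abs(z))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        indirect = PathEstimate(ab, sd, z, p, float(lo), float(hi))

        return MediationResult(a, b, direct, indirect, total,
                               self.standardize, mc_samples, self.n_subjects)


def _path(res, name: str, rng=None, mc_samples: int = 0) -> PathEstimate:
    coef = float(res.params[name])
    se = float(res.bse[name])
    z = coef / se if se > 0 else np.inf * np.sign(coef)
    p = 2 * stats.norm.sf(abs(z))
    if rng is not None and mc_samples:
        draws = rng.normal(coef, se, size=mc_samples)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return PathEstimate(coef, se, z, p, float(lo), float(hi))
    lo, hi = coef - 1.96 * se, coef + 1.96 * se
    return PathEstimate(coef, se, z, p, lo, hi)


def fit_mediation(data: pd.DataFrame, mc_samples: int = 1000,
                  seed: int | None = None,
                  standardize: bool = True) -> MediationResult:
    """Convenience wrapper: build and fit :class:`MultilevelMediation`."""
    return MultilevelMediation(data, standardize=standardize).fit(
        mc_samples=mc_samples, seed=seed)
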