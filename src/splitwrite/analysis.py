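"""Estimators and tests for the split-manuscript trial.

The primary analysis is a linear mixed model for domain score y_{p,g,j}
(participant p, condition g, domain slot j):

    y_{p,g,j} = mu + beta * 1[g = tool] + b_p + c_{p,g} + e_{p,g,j}

with a fixed intervention effect beta, a random participant effect b_p
(variance sigma_b^2), a random participant-condition ("participant-group")
effect c_{p,g} (variance sigma_c^2) and residual e (variance sigma_e^2).
For the balanced 3+3 design the generalized-least-squares solution reduces
exactly to the paired contrast of per-participant condition means

    d_p = ybar_{p,tool} - ybar_{p,control},
    beta_hat = mean(d_p),   se = sd(d_p) / sqrt(N),

with t-based inference on N-1 degrees of freedom; the closed form is used
here and an iterative REML fit serves only as a cross-check in the test
suite.  Secondary analyses are classical equal-variance Student t-tests per
domain (each participant contributes a domain to exactly one condition, so
observations are independent), and the ancillary comparison against
published manuscripts is a paired contrast clustered by protocol (the
random-intercept model's balanced closed form).  No multiplicity adjustment
is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import DOMAINS
from .scoring import ScoreTable

__all__ = [
    "EffectEstimate",
    "VarianceComponents",
    "DomainTestResult",
    "AncillaryResult",
    "AnalysisError",
    "DegenerateDataError",
    "primary_effect",
    "fit_variance_components",
    "per_domain_ttest",
    "ancillary_comparison",
]


class AnalysisError(ValueError):
    """Malformed input to an estimator."""


class DegenerateDataError(AnalysisError):
    """No variability where the estimator needs some (e.g. sd of contrasts 0)."""


@dataclass(frozen=True)
class EffectEstimate:
    """Intervention-effect estimate with t-based inference."""

    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int
    n_participants: int


@dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition of domain scores.

    sigma2_b: between-participant; sigma2_c: participant-condition;
    sigma2_e: residual.  ``truncated`` is set when a raw method-of-moments
    solution was negative and clipped to zero.
    """

    sigma2_b: float
    sigma2_c: float
    sigma2_e: float
    truncated: bool = False

    @property
    def total(self) -> float:
        return self.sigma2_b + self.sigma2_c + self.sigma2_e

    @property
    def rho(self) -> float:
        """Within-condition intraclass correlation."""
        return (self.sigma2_b + self.sigma2_c) / self.total

    @property
    def rho_prime(self) -> float:
        """Cross-condition correlation."""
        return self.sigma2_b / self.total


@dataclass(frozen=True)
class DomainTestResult:
    """Two-sample Student t-test for one domain."""

    domain: str
    mean_tool: float
    mean_control: float
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_tool: int
    n_control: int


@dataclass(frozen=True)
class AncillaryResult:
    """Paired participant-vs-publication contrast within one condition subset."""

    condition: str
    mean_paired_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_protocols: int


def _paired_inference(d: np.ndarray, alpha: float) -> tuple[float, float, float, float, float, int]:
    """Mean, se, CI and p for a vector of paired contrasts (t, n-1 df)."""
    n = len(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError(
            "paired contrasts have zero variance; se and p are undefined"
        )
    se = sd / sqrt(n)
    df = n - 1
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    half = stats.t.ppf(1 - alpha / 2, df) * se
    return mean, se, mean - half, mean + half, p, df


def primary_effect(table: ScoreTable, alpha: float = 0.05) -> EffectEstimate:
    """Intervention effect under the split-manuscript mixed model.

    Computes the paired contrast of per-participant condition means, which
    for the balanced 3+3 design equals the GLS solution of the mixed model
    with participant and participant-condition random effects.
    """
    piv = table.pivot_means()
    d = (piv["tool"] - piv["control"]).to_numpy()
    if len(d) < 2:
        raise AnalysisError(
            f"need at least 2 participants, got {len(d)}"
        )
    mean, se, lo, hi, p, df = _paired_inference(d, alpha)
    return EffectEstimate(
        beta_hat=mean, se=se, ci_low=lo, ci_high=hi,
        p_value=p, df=df, n_participants=len(d),
    )


def fit_variance_components(table: ScoreTable) -> VarianceComponents:
    """ANOVA-type (method-of-moments) variance components for the balanced layout.

    Uses the three mean squares of the balanced two-way design — between
    participants, condition-within-participant, and residual — whose
    expectations are sigma_e^2 + m*sigma_c^2 + 2m*sigma_b^2,
    sigma_e^2 + m*sigma_c^2, and sigma_e^2.  Negative raw solutions are
    truncated at zero with the ``truncated`` flag set.
    """
    frame = table.frame
    n = len(table.participants)
    if n < 3:
        raise AnalysisError(f"need at least 3 participants, got {n}")
    m = 3  # domains per participant per condition (balance is validated)
    cell_means = frame.groupby(["participant_id", "condition"], observed=True)["score"].mean()
    resid_ss = float(
        ((frame.set_index(["participant_id", "condition"])["score"] - cell_means) ** 2).sum()
    )
    ms_e = resid_ss / (2 * n * (m - 1))
    piv = table.pivot_means()
    d = (piv["tool"] - piv["control"]).to_numpy()
    ms_pg = (m / 2.0) * float(np.var(d, ddof=1))  # condition-within-participant stratum
    part_means = piv.mean(axis=1).to_numpy()
    ms_p = 2 * m * float(np.var(part_means, ddof=1))
    sigma2_e = ms_e
    raw_c = (ms_pg - ms_e) / m
    raw_b = (ms_p - ms_pg) / (2 * m)
    truncated = raw_c < 0 or raw_b < 0
    return VarianceComponents(
        sigma2_b=max(raw_b, 0.0),
        sigma2_c=max(raw_c, 0.0),
        sigma2_e=sigma2_e,
        truncated=truncated,
    )


def per_domain_ttest(
    table: ScoreTable, domain: str, alpha: float = 0.05
) -> DomainTestResult:
    """Classical equal-variance two-sample Student t-test for one domain.

    Each participant contributes the named domain to exactly one condition,
    so the two groups are independent across participants.
    """
    if domain not in DOMAINS:
        raise AnalysisError(f"unknown domain: {domain!r}")
    sub = table.frame[table.frame["domain"] == domain]
    tool = sub.loc[sub["condition"] == "tool", "score"].to_numpy()
    control = sub.loc[sub["condition"] == "control", "score"].to_numpy()
    if len(tool) < 2 or len(control) < 2:
        raise AnalysisError(
            f"domain {domain!r}: need >= 2 observations per condition, "
            f"got {len(tool)} tool / {len(control)} control"
        )
    t_stat, p = stats.ttest_ind(tool, control, equal_var=True)
    n1, n2 = len(tool), len(control)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(tool, ddof=1) + (n2 - 1) * np.var(control, ddof=1)) / df
    se = sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = float(np.mean(tool) - np.mean(control))
    half = stats.t.ppf(1 - alpha / 2, df) * se
    return DomainTestResult(
        domain=domain,
        mean_tool=float(np.mean(tool)),
        mean_control=float(np.mean(control)),
        mean_difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        p_value=float(p),
        n_tool=n1,
        n_control=n2,
    )


def ancillary_comparison(
    participant_scores: ScoreTable,
    published_scores: pd.DataFrame | Mapping[tuple[str, str], float],
    condition: str,
    alpha: float = 0.05,
) -> AncillaryResult:
    """Participant-minus-publication contrast within one condition subset.

    ``published_scores`` maps (protocol_id, domain) to the published
    article's score (as a mapping, or a DataFrame with columns protocol_id,
    domain, score).  Per-domain paired differences are averaged within each
    protocol; the intercept of the protocol-random-effect model is the mean
    of protocol-mean differences, with its SE from between-protocol
    variability (t, n_protocols - 1 df).
    """
    if condition not in ("tool", "control"):
        raise AnalysisError(f"condition must be 'tool' or 'control', got {condition!r}")
    if isinstance(published_scores, pd.DataFrame):
        published = {
            (str(r.protocol_id), str(r.domain)): float(r.score)
            for r in published_scores.itertuples()
        }
    else:
        published = dict(published_scores)
    sub = participant_scores.frame[participant_scores.frame["condition"] == condition]
    diffs: dict[str, list[float]] = {}
    for row in sub.itertuples():
        key = (str(row.protocol_id), str(row.domain))
        if key not in published:
            raise AnalysisError(f"no published score for protocol/domain {key}")
        diffs.setdefault(key[0], []).append(float(row.score) - published[key])
    proto_means = np.array([np.mean(v) for v in diffs.values()])
    n = len(proto_means)
    if n < 2:
        raise AnalysisError(
            f"need >= 2 protocols for between-protocol SE, got {n}"
        )
    if np.std(proto_means, ddof=1) == 0.0:
        # no between-protocol variability: degenerate CI at the mean; the
        # t statistic is 0/0 (p=1) for a zero mean and +-inf (p=0) otherwise
        mean = float(proto_means.mean())
        lo = hi = mean
        p = 1.0 if mean == 0.0 else 0.0
    else:
        mean, se, lo, hi, p, _ = _paired_inference(proto_means, alpha)
    return AncillaryResult(
        condition=condition,
        mean_paired_difference=mean,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_protocols=n,
    )
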