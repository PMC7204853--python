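"""Matched-pair inference for the case–crossover analysis.

Two estimators are provided for the within-person comparison:

* paired t-tests on case-minus-control differences of each exposure or
  covariate (the univariate screen);
* 1:1 conditional logistic regression, the design's canonical model.
  With exactly one case and one control observation per matched set the
  conditional likelihood reduces to

      L(beta) = prod_i  exp(beta' x_case_i)
                        / (exp(beta' x_case_i) + exp(beta' x_control_i))
              = prod_i  sigmoid(beta' d_i),       d_i = x_case_i - x_control_i

  i.e. an intercept-free logit on within-pair differences with all
  responses equal to one.  The fit maximises this likelihood by
  Newton–Raphson with the analytic score and observed information;
  confidence intervals are Wald, exp(beta +/- 1.96 SE).

For a single binary exposure the maximum has the classical closed form
OR = n10/n01 over the discordant pairs (McNemar's odds ratio), exposed
here as :func:`discordant_or` and used as an exact cross-check of the
iterative fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_builder import MatchedPairRecord

__all__ = [
    "PairedTestResult",
    "ClrFitResult",
    "DiscordantTable",
    "paired_t_test",
    "discordant_or",
    "conditional_logistic_fit",
    "fit_clr_from_differences",
    "fit_clr_from_table",
    "pair_differences",
    "discordant_table_from_pairs",
    "DegenerateInputError",
    "NoInformationError",
    "SeparationError",
    "ConvergenceError",
]

_Z95 = 1.96  # conventional normal quantile for 95% Wald intervals


class DegenerateInputError(ValueError):
    """Too few pairs or no variance to support the test."""


class NoInformationError(ValueError):
    """No discordant information: every within-pair difference is zero."""


class SeparationError(RuntimeError):
    """Complete separation: the conditional likelihood has no finite maximum."""


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_beta: np.ndarray, last_score: np.ndarray):
        super().__init__(message)
        self.last_beta = last_beta
        self.last_score = last_score


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    n_pairs: int


def paired_t_test(case_values: Sequence[float], control_values: Sequence[float]) -> PairedTestResult:
    """Two-tailed paired t-test of case minus control differences.

    95% CI from the t distribution on n-1 degrees of freedom.  Identical
    vectors give the null result (t=0, p=1); zero variance around a
    nonzero mean is degenerate and raises.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.shape != control.shape or case.ndim != 1:
        raise ValueError("case and control must be equal-length 1-d vectors")
    n = case.size
    if n < 2:
        raise DegenerateInputError("paired t-test needs at least 2 pairs")
    d = case - control
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, 0.0, 0.0, 1.0, n)
        raise DegenerateInputError("differences are constant and nonzero: no sampling variance")
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
    half = float(stats.t.ppf(0.975, df=n - 1)) * se
    return PairedTestResult(mean, mean - half, mean + half, float(t_stat), p, n)


# ---------------------------------------------------------------------------
# Discordant-pair closed form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscordantTable:
    """2x2 pair table for a binary exposure: n11 both windows exposed,
    n10 case only, n01 control only, n00 neither."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_marginals(cls, n_pairs: int, n_case_exposed: int, n_control_exposed: int, n_both: int) -> "DiscordantTable":
        """Reconstruct the pair table from published marginal counts."""
        n11 = n_both
        n10 = n_case_exposed - n_both
        n01 = n_control_exposed - n_both
        n00 = n_pairs - n11 - n10 - n01
        return cls(n11=n11, n10=n10, n01=n01, n00=n00)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float


def discordant_or(table: DiscordantTable) -> OddsRatioResult:
    """Matched-pair odds ratio n10/n01 with the standard log-scale Wald
    interval, SE(log OR) = sqrt(1/n10 + 1/n01).  Concordant pairs carry
    no information and do not enter."""
    if table.n10 == 0 or table.n01 == 0:
        raise NoInformationError("a zero discordant count leaves the odds ratio undefined")
    log_or = float(np.log(table.n10 / table.n01))
    se = float(np.sqrt(1.0 / table.n10 + 1.0 / table.n01))
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        log_or=log_or,
        se_log_or=se,
    )


def discordant_table_from_pairs(pairs: Sequence[MatchedPairRecord]) -> DiscordantTable:
    """Cross-classify matched pairs by the binary any-quote exposure."""
    n11 = n10 = n01 = n00 = 0
    for p in pairs:
        if p.case.any_quote and p.control.any_quote:
            n11 += 1
        elif p.case.any_quote:
            n10 += 1
        elif p.control.any_quote:
            n01 += 1
        else:
            n00 += 1
    return DiscordantTable(n11, n10, n01, n00)


# ---------------------------------------------------------------------------
# Conditional logistic regression (1:1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClrFitResult:
    covariates: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_informative_pairs: int
    n_dropped_pairs: int
    n_iterations: int
    converged: bool

    def as_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "odds_ratios": self.odds_ratios.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "p_values": self.p_values.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_informative_pairs": self.n_informative_pairs,
            "n_dropped_pairs": self.n_dropped_pairs,
            "converged": self.converged,
        }


def pair_differences(pairs: Sequence[MatchedPairRecord], covariates: Sequence[str]) -> np.ndarray:
    """Within-pair (case minus control) differences of the named
    PeriodSummary fields, one row per pair."""
    rows = [
        [float(getattr(p.case, name)) - float(getattr(p.control, name)) for name in covariates]
        for p in pairs
    ]
    return np.asarray(rows, dtype=float).reshape(len(pairs), len(covariates))


def fit_clr_from_differences(
    diffs: np.ndarray,
    covariates: Sequence[str] | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
) -> ClrFitResult:
    """Maximise the 1:1 conditional likelihood on a matrix of within-pair
    differences (one row per pair, one column per covariate).

    Newton–Raphson from beta = 0; converged when the largest score
    component falls below ``score_tol`` or the step below ``step_tol``.
    Pairs whose difference row is all-zero are uninformative and dropped
    (counted in ``n_dropped_pairs``).
    """
    D = np.asarray(diffs, dtype=float)
    if D.ndim != 2:
        raise ValueError("differences must be a 2-d array (pairs x covariates)")
    n_total = D.shape[0]
    informative = ~np.all(D == 0.0, axis=1)
    D = D[informative]
    n_inf = D.shape[0]
    if n_inf == 0:
        raise NoInformationError("every within-pair difference is zero")
    k = D.shape[1]
    names = tuple(covariates) if covariates is not None else tuple(f"x{i}" for i in range(k))

    beta = np.zeros(k)
    score = np.full(k, np.inf)
    info = np.eye(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = D.T @ (1.0 - p)
        w = p * (1.0 - p)
        info = D.T @ (D * w[:, None])
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix: data are separated or a covariate is collinear"
            ) from None
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "diverging coefficients: complete separation, no finite estimate"
            )
        if np.max(np.abs(step)) < step_tol:
            eta = D @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            score = D.T @ (1.0 - p)
            w = p * (1.0 - p)
            info = D.T @ (D * w[:, None])
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_iter} Newton iterations", beta, score
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    eta = D @ beta
    loglik = float(-np.sum(np.log1p(np.exp(-eta))))
    if loglik > -1e-6:
        # every informative pair predicted perfectly: the likelihood has
        # no interior maximum and the "estimate" is an artefact of the
        # stopping rule
        raise SeparationError("complete separation: likelihood attains its supremum at infinity")
    z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # a huge SE legitimately gives an infinite bound
        ci_low = np.exp(beta - _Z95 * se)
        ci_high = np.exp(beta + _Z95 * se)
    return ClrFitResult(
        covariates=names,
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        ci_low=ci_low,
        ci_high=ci_high,
        p_values=p_values,
        log_likelihood=loglik,
        n_informative_pairs=n_inf,
        n_dropped_pairs=n_total - n_inf,
        n_iterations=it,
        converged=True,
    )


def fit_clr_from_table(table: DiscordantTable, exposure_name: str = "any_quote", **newton_kwargs) -> ClrFitResult:
    """Unadjusted single-binary-exposure conditional logistic fit from a
    2x2 pair table: +1 differences for case-only-exposed pairs, -1 for
    control-only, 0 for the concordant pairs."""
    diffs = np.concatenate(
        [
            np.ones(table.n10),
            -np.ones(table.n01),
            np.zeros(table.n11 + table.n00),
        ]
    ).reshape(-1, 1)
    return fit_clr_from_differences(diffs, [exposure_name], **newton_kwargs)


def conditional_logistic_fit(
    pairs: Sequence[MatchedPairRecord],
    covariates: Sequence[str],
    **newton_kwargs,
) -> ClrFitResult:
    """Fit the 1:1 conditional logistic model to matched pairs.

    ``covariates`` names PeriodSummary fields; the first entry is
    conventionally the exposure (``any_quote`` or ``quotes_per_token``),
    followed by adjustment covariates such as ``face_to_face``, ``dna``
    and ``bed_days``.
    """
    if not covariates:
        raise ValueError("at least one covariate (the exposure) is required")
    diffs = pair_differences(pairs, covariates)
    return fit_clr_from_differences(diffs, covariates, **newton_kwargs)
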