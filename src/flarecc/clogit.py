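"""Conditional logistic regression with exact multi-case strata.

Each risk set (stratum) holds m windows of which k are hazards.  Conditioning
on k removes the stratum's intercept, leaving the exact conditional
likelihood

    L_s(beta) = exp(sum_{cases} x'beta) / B(m, k),
    B(m, k)   = sum over all size-k subsets S of exp(sum_{i in S} x_i'beta),

with B computed by the standard recursion B(j, l) = B(j-1, l) +
e^{x_j beta} B(j-1, l-1) (each factor rescaled by the stratum's maximum
linear predictor for stability).  Score and observed information come from
companion recursions for the first and second derivatives of B, so both are
exact, not approximated.  No Breslow/Efron tie handling is needed: the exact
likelihood is cheap at these stratum sizes.

Newton-Raphson maximization starts at beta = 0; standard errors are reported
both model-based (inverse information) and cluster-robust (sandwich with
per-participant score outer products), the latter accounting for
within-participant correlation across multiple hazard periods.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import RiskSet

logger = logging.getLogger(__name__)

Z_95 = 1.96  # conventional two-sided 95% normal quantile

METRICS = ("mean", "isd")


@dataclass(frozen=True)
class ModelSpec:
    """One conditional-logit model: an exposure with one or both metrics."""

    definition: str
    exposure: str
    metrics: tuple[str, ...]  # ("mean",), ("isd",) or ("mean", "isd")
    mode: str = "full_stratum"

    def __post_init__(self):
        if not self.metrics or any(m not in METRICS for m in self.metrics):
            raise ValueError(f"metrics must be a nonempty subset of {METRICS}")

    @property
    def model_type(self) -> str:
        return "multivariable" if len(self.metrics) > 1 else "univariable"

    @property
    def terms(self) -> list[str]:
        return [f"{m}_{self.exposure}" for m in self.metrics]


@dataclass
class FitResult:
    spec: ModelSpec | None
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    loglik: float
    converged: bool
    n_strata: int
    n_hazards: int
    n_controls: int
    n_iter: int
    message: str = ""
    term_names: list[str] = field(default_factory=list)

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci(self, robust: bool = True) -> np.ndarray:
        """95% Wald CI bounds for the ORs, shape (p, 2)."""
        se = self.se_robust if robust else self.se_model
        lo = np.exp(self.beta - Z_95 * se)
        hi = np.exp(self.beta + Z_95 * se)
        return np.column_stack([lo, hi])


def stratum_loglik(
    x: np.ndarray, y: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact conditional log-likelihood contribution of one stratum.

    Parameters
    ----------
    x : (m, p) design values for the stratum's windows.
    y : (m,) binary outcomes (1 = hazard); k = y.sum().
    beta : (p,) coefficients.

    Returns
    -------
    (loglik, score, information) where information is the *observed*
    information contribution (negative Hessian), a p x p PSD matrix equal to
    the covariance of sum_{i in S} x_i over the size-k subset distribution.
    Concordant strata (k = 0 or k = m) contribute 0 with zero score.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    m, p = x.shape
    k = int(y.sum())
    if k == 0 or k == m:
        return 0.0, np.zeros(p), np.zeros((p, p))
    eta = x @ beta
    c = float(eta.max())
    w = np.exp(eta - c)

    # B[l], dB[l] (p,), d2B[l] (p,p): scaled by exp(-l*c); ratios are invariant
    B = np.zeros(k + 1)
    dB = np.zeros((k + 1, p))
    d2B = np.zeros((k + 1, p, p))
    B[0] = 1.0
    for j in range(m):
        xj = x[j]
        lmax = min(j + 1, k)
        for l in range(lmax, 0, -1):
            B_prev, dB_prev, d2B_prev = B[l - 1], dB[l - 1], d2B[l - 1]
            d2B[l] = d2B[l] + w[j] * (
                np.outer(xj, xj) * B_prev
                + np.outer(xj, dB_prev)
                + np.outer(dB_prev, xj)
                + d2B_prev
            )
            dB[l] = dB[l] + w[j] * (xj * B_prev + dB_prev)
            B[l] = B[l] + w[j] * B_prev

    logB = np.log(B[k]) + k * c
    case_x = x[y.astype(bool)].sum(axis=0)
    loglik = float(case_x @ beta - logB)
    ratio = dB[k] / B[k]
    score = case_x - ratio
    info = d2B[k] / B[k] - np.outer(ratio, ratio)
    return loglik, score, info


def stratum_loglik_enumerate(
    x: np.ndarray, y: np.ndarray, beta: np.ndarray
) -> float:
    """Reference log-likelihood by direct enumeration of all size-k subsets
    (exponential in m; for small strata and cross-checks only)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    m = x.shape[0]
    k = int(np.asarray(y).sum())
    if k == 0 or k == m:
        return 0.0
    eta = x @ beta
    terms = [eta[list(s)].sum() for s in itertools.combinations(range(m), k)]
    c = max(terms)
    logB = c + np.log(np.sum(np.exp(np.asarray(terms) - c)))
    return float(eta[np.asarray(y, dtype=bool)].sum() - logB)


def _design(risk_sets: list[RiskSet], spec: ModelSpec):
    """Extract (x, y, cluster id) per stratum for the requested model terms."""
    strata = []
    for rs in risk_sets:
        rows = []
        y = []
        for w in rs.windows:
            vals = []
            for metric in spec.metrics:
                src = w.means if metric == "mean" else w.isds
                vals.append(src[spec.exposure])
            rows.append(vals)
            y.append(1 if w.label == "hazard" else 0)
        strata.append((np.asarray(rows, float), np.asarray(y, int), rs.participant_id))
    return strata


BETA_DIVERGENCE = 10.0  # |beta| beyond which the likelihood is flagged separated


def fit(
    risk_sets: list[RiskSet],
    spec: ModelSpec,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    stratum_mode: str = "participant",
) -> FitResult:
    """Maximize the summed exact conditional log-likelihood.

    ``stratum_mode='participant'`` (default) keeps each participant's windows
    in one matched set; ``'hazard'`` forms one stratum per hazard window
    (that hazard vs. all the participant's controls).  Clusters for the
    robust sandwich are participants in either mode.

    Raises ``ValueError`` when no stratum is informative; non-convergence and
    separation are reported via ``converged``/``message``, not exceptions.
    """
    p = len(spec.metrics)
    strata = []
    for x, y, pid in _design(risk_sets, spec):
        if stratum_mode == "participant":
            strata.append((x, y, pid))
        elif stratum_mode == "hazard":
            controls = x[y == 0]
            for xi in x[y == 1]:
                xs = np.vstack([xi[None, :], controls])
                ys = np.zeros(len(controls) + 1, int)
                ys[0] = 1
                strata.append((xs, ys, pid))
        else:
            raise ValueError(f"unknown stratum_mode {stratum_mode!r}")

    informative = [
        (x, y, pid)
        for x, y, pid in strata
        if 0 < y.sum() < len(y) and np.ptp(x, axis=0).max() > 0
    ]
    n_strata = len(informative)
    if n_strata == 0:
        raise ValueError("no informative strata (every stratum concordant or constant)")
    n_hazards = sum(int(y.sum()) for _, y, _ in informative)
    n_controls = sum(int((1 - y).sum()) for _, y, _ in informative)

    def evaluate(beta):
        ll = 0.0
        cluster_scores: dict[object, np.ndarray] = {}
        info = np.zeros((p, p))
        for x, y, pid in informative:
            lls, s, i = stratum_loglik(x, y, beta)
            ll += lls
            info += i
            cluster_scores[pid] = cluster_scores.get(pid, np.zeros(p)) + s
        score = np.sum(list(cluster_scores.values()), axis=0)
        return ll, score, info, cluster_scores

    beta = np.zeros(p)
    ll, score, info, cluster_scores = evaluate(beta)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(score).max() < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving line search
        new = None
        for half in range(31):
            cand = beta + step / (2**half)
            ll_new, s_new, i_new, cs_new = evaluate(cand)
            if ll_new >= ll - 1e-12:
                new = (cand, ll_new, s_new, i_new, cs_new)
                break
        if new is None:
            message = "line search failed"
            break
        ll_prev = ll
        beta, ll, score, info, cluster_scores = new
        if np.abs(beta).max() > BETA_DIVERGENCE:
            message = "apparent complete separation (|beta| diverging)"
            break
        if abs(ll - ll_prev) < ll_tol * (abs(ll_prev) + 1e-12):
            converged = np.abs(score).max() < 1e-3
            if not converged:
                message = "log-likelihood stalled before score convergence"
            break
    else:
        message = f"no convergence in {max_iter} iterations"
    if converged and np.abs(beta).max() > BETA_DIVERGENCE:
        # a vanishing score at a huge |beta| is monotone likelihood, not a
        # genuine optimum
        converged = False
        message = "apparent complete separation (|beta| diverging)"

    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bread = np.full((p, p), np.nan)
        converged = False
        message = message or "singular information at optimum"
    meat = np.zeros((p, p))
    for s in cluster_scores.values():
        meat += np.outer(s, s)
    cov_robust = bread @ meat @ bread
    cov_robust = (cov_robust + cov_robust.T) / 2

    if not converged and not message:
        message = "did not converge"
    return FitResult(
        spec=spec,
        beta=beta,
        cov_model=bread,
        cov_robust=cov_robust,
        loglik=ll,
        converged=converged,
        n_strata=n_strata,
        n_hazards=n_hazards,
        n_controls=n_controls,
        n_iter=it,
        message=message,
        term_names=spec.terms,
    )


def primary_model_specs(definition: str, mode: str = "full_stratum") -> list[ModelSpec]:
    """The study's model battery for one flare definition: 24 univariable
    (12 exposures x {mean, iSD}) plus 12 multivariable (both metrics)."""
    from .preprocess import EXPOSURES

    specs = []
    for exposure in EXPOSURES:
        for metric in METRICS:
            specs.append(ModelSpec(definition, exposure, (metric,), mode))
    for exposure in EXPOSURES:
        specs.append(ModelSpec(definition, exposure, METRICS, mode))
    return specs


def or_table(fits: list[FitResult], robust: bool = True) -> pd.DataFrame:
    """Tidy OR table: one row per (definition, exposure, metric, model type,
    mode); non-converged fits are excluded and listed with their diagnostic
    in the ``converged``/``message`` columns of the returned frame."""
    rows = []
    for f in fits:
        spec = f.spec
        ses_r = f.se_robust
        ses_m = f.se_model
        cis = f.ci(robust=robust)
        ors = f.odds_ratios
        for j, metric in enumerate(spec.metrics):
            if f.converged:
                lo, hi = cis[j]
                rows.append(
                    {
                        "definition": spec.definition,
                        "exposure": spec.exposure,
                        "metric": metric,
                        "model_type": spec.model_type,
                        "mode": spec.mode,
                        "n_strata": f.n_strata,
                        "n_hazards": f.n_hazards,
                        "n_controls": f.n_controls,
                        "beta": f.beta[j],
                        "se_model": ses_m[j],
                        "se_robust": ses_r[j],
                        "or": ors[j],
                        "ci_low": lo,
                        "ci_high": hi,
                        "significant": bool(lo > 1.0 or hi < 1.0),
                        "converged": True,
                        "message": "",
                    }
                )
            else:
                rows.append(
                    {
                        "definition": spec.definition,
                        "exposure": spec.exposure,
                        "metric": metric,
                        "model_type": spec.model_type,
                        "mode": spec.mode,
                        "n_strata": f.n_strata,
                        "n_hazards": f.n_hazards,
                        "n_controls": f.n_controls,
                        "beta": np.nan,
                        "se_model": np.nan,
                        "se_robust": np.nan,
                        "or": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "converged": False,
                        "message": f.message,
                    }
                )
    return pd.DataFrame(rows)
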