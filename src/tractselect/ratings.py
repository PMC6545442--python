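"""Blinded multi-rater assessment: bookkeeping, simulation, and the
mixed-effects logistic response model.

Raters answer three binary questions per (subject, tract, method) cell —
does the tract connect the correct regions, is it morphologically correct,
are there spurious streamlines — after the three generation methods
(automated pipeline AU, human experts H1, H2) have been blinded behind
per-subject randomized set codes A/B/C.

The response model is a logistic regression with fixed effects for
generation method (reference AU) and rater, and a per-subject random
intercept capturing patient-level clustering:

    logit P(y_ij = 1) = x_ij' beta + b_i,   b_i ~ N(0, sigma^2).

The marginal likelihood is maximized with adaptive Gauss-Hermite
quadrature (Laplace approximation at one node); confidence intervals are
Wald on the log-odds scale, exponentiated to odds ratios.  Complete
separation (an empty method x response cell) is detected before fitting
and reported as a data error rather than a silently divergent fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "RatingRecord",
    "BlindingPlan",
    "GlmmFit",
    "SeparationError",
    "METHODS",
    "QUESTIONS",
    "make_blinding",
    "apply_blinding",
    "simulate_ratings",
    "fit_rating_model",
    "summarize_method_contrasts",
    "records_to_frame",
    "frame_to_records",
    "read_ratings_csv",
    "write_ratings_csv",
]

METHODS = ("AU", "H1", "H2")
SET_CODES = ("A", "B", "C")
QUESTIONS = ("q1", "q2", "q3")
DEFAULT_TRACTS = ("AF", "IFOF", "ILF", "MLF", "UF")
_QUESTION_FIELDS = {"q1": "q1_connects", "q2": "q2_morphology", "q3": "q3_spurious"}


class SeparationError(ValueError):
    """Complete separation: some level x response cell is empty."""


@dataclass
class RatingRecord:
    subject: str
    tract: str
    method: str
    rater: str
    q1_connects: bool
    q2_morphology: bool
    q3_spurious: bool
    set_code: str = ""
    free_text: dict[str, str] = field(default_factory=dict)


@dataclass
class BlindingPlan:
    """Per-subject bijection between displayed set codes and methods."""

    assignments: dict[str, dict[str, str]]  # subject -> {set_code: method}
    rng_seed: int

    def __post_init__(self) -> None:
        for subj, mapping in self.assignments.items():
            if sorted(mapping) != sorted(SET_CODES) or sorted(
                mapping.values()
            ) != sorted(METHODS):
                raise ValueError(f"subject {subj!r}: map is not an A/B/C <-> method bijection")

    def method_of(self, subject: str, set_code: str) -> str:
        return self.assignments[subject][set_code]

    def code_of(self, subject: str, method: str) -> str:
        inv = {m: c for c, m in self.assignments[subject].items()}
        return inv[method]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": s, "set_code": c, "method": m}
            for s, mapping in self.assignments.items()
            for c, m in mapping.items()
        ]
        return pd.DataFrame(rows)


def make_blinding(subjects: list[str], seed: int) -> BlindingPlan:
    """Independent uniform random code<->method bijection per subject."""
    if not subjects:
        raise ValueError("subjects must be non-empty")
    rng = np.random.default_rng(seed)
    assignments = {}
    for subj in subjects:
        perm = rng.permutation(len(METHODS))
        assignments[str(subj)] = {
            SET_CODES[i]: METHODS[perm[i]] for i in range(len(METHODS))
        }
    return BlindingPlan(assignments, seed)


def apply_blinding(records: list[RatingRecord], plan: BlindingPlan) -> list[RatingRecord]:
    """Stamp each record's set_code from the plan (methods left intact)."""
    out = []
    for r in records:
        out.append(
            RatingRecord(
                r.subject, r.tract, r.method, r.rater,
                r.q1_connects, r.q2_morphology, r.q3_spurious,
                set_code=plan.code_of(r.subject, r.method),
                free_text=dict(r.free_text),
            )
        )
    return out


def simulate_ratings(
    n_subjects: int,
    n_tracts: int,
    n_raters: int,
    method_logodds: dict[str, float] | None = None,
    rater_logodds: dict[str, float] | None = None,
    subject_sd: float = 0.8,
    seed: int = 0,
) -> list[RatingRecord]:
    """Draw ratings from the exact generative model the fit assumes.

    ``method_logodds[AU]`` acts as the baseline log-odds; other methods add
    their offsets.  Each question gets an independent per-subject normal
    intercept of SD ``subject_sd``.  Deterministic given ``seed``.
    """
    if min(n_subjects, n_tracts, n_raters) < 1:
        raise ValueError("all design sizes must be >= 1")
    if subject_sd < 0 or not np.isfinite(subject_sd):
        raise ValueError("subject_sd must be finite and non-negative")
    method_logodds = dict(method_logodds or {m: 0.0 for m in METHODS})
    raters = [f"R{i + 1}" for i in range(n_raters)]
    rater_logodds = dict(rater_logodds or {r: 0.0 for r in raters})
    tracts = [
        DEFAULT_TRACTS[i % len(DEFAULT_TRACTS)] + ("" if i < len(DEFAULT_TRACTS) else f"_{i}")
        for i in range(n_tracts)
    ]
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    rng = np.random.default_rng(seed)
    intercepts = {
        q: rng.normal(0.0, subject_sd, size=n_subjects) for q in QUESTIONS
    }
    records = []
    for si, subj in enumerate(subjects):
        for tract in tracts:
            for method in METHODS:
                # AU log-odds is the baseline; other methods add their offset
                baseline = method_logodds.get("AU", 0.0)
                eta_fixed = baseline if method == "AU" else baseline + method_logodds.get(method, 0.0)
                for rater in raters:
                    eta = eta_fixed + rater_logodds.get(rater, 0.0)
                    answers = {}
                    for q in QUESTIONS:
                        p = expit(eta + intercepts[q][si])
                        answers[q] = bool(rng.random() < p)
                    records.append(
                        RatingRecord(
                            subj, tract, method, rater,
                            answers["q1"], answers["q2"], answers["q3"],
                        )
                    )
    return records


def records_to_frame(records: list[RatingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "tract": [r.tract for r in records],
            "method": [r.method for r in records],
            "rater": [r.rater for r in records],
            "q1": [int(r.q1_connects) for r in records],
            "q2": [int(r.q2_morphology) for r in records],
            "q3": [int(r.q3_spurious) for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[RatingRecord]:
    return [
        RatingRecord(
            str(row.subject), str(row.tract), str(row.method), str(row.rater),
            bool(int(row.q1)), bool(int(row.q2)), bool(int(row.q3)),
            set_code=str(getattr(row, "set_code", "") or ""),
        )
        for row in df.itertuples()
    ]


def write_ratings_csv(records: list[RatingRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_ratings_csv(path: str) -> list[RatingRecord]:
    return frame_to_records(pd.read_csv(path))


@dataclass
class GlmmFit:
    question: str
    fixed_effects: pd.DataFrame  # columns: term, coef, se
    random_intercept_sd: float
    odds_ratios: dict[str, tuple[float, float, float]]  # method -> (OR, lo, hi)
    converged: bool
    n_obs: int
    loglik: float
    reference_method: str = "AU"


def _marginal_negloglik(theta, X, y, gi, n_subj, nodes, lognw):
    """Negative marginal loglik via adaptive Gauss-Hermite quadrature."""
    beta = theta[:-1]
    sigma = math.exp(theta[-1])
    eta0 = X @ beta
    inv_var = 1.0 / (sigma * sigma)
    # per-subject posterior mode of the random intercept (Newton)
    b = np.zeros(n_subj)
    for _ in range(50):
        p = expit(eta0 + b[gi])
        grad = np.bincount(gi, weights=y - p, minlength=n_subj) - b * inv_var
        hess = np.bincount(gi, weights=p * (1.0 - p), minlength=n_subj) + inv_var
        step = grad / hess
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta0 + b[gi])
    hess = np.bincount(gi, weights=p * (1.0 - p), minlength=n_subj) + inv_var
    scale = 1.0 / np.sqrt(hess)  # adaptive quadrature scale per subject
    # evaluate the integrand at shifted/scaled nodes
    k = nodes.shape[0]
    ll_nodes = np.empty((k, n_subj))
    const = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)
    for j in range(k):
        bj = b + math.sqrt(2.0) * scale * nodes[j]
        eta = eta0 + bj[gi]
        # Bernoulli loglik, numerically stable
        ll_obs = np.where(y > 0.5, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta))
        ll_nodes[j] = (
            np.bincount(gi, weights=ll_obs, minlength=n_subj)
            - 0.5 * bj * bj * inv_var
            + const
            + nodes[j] * nodes[j]
            + lognw[j]
        )
    per_subject = logsumexp(ll_nodes, axis=0) + 0.5 * math.log(2.0) + np.log(scale)
    return -float(per_subject.sum())


def _numeric_hessian(f, x, eps=1e-4):
    n = x.size
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * eps * eps)
    return h


def _check_separation(df: pd.DataFrame, col: str, what: str) -> None:
    tab = pd.crosstab(df[col], df["y"])
    for level in tab.index:
        for response in (0, 1):
            if response not in tab.columns or tab.loc[level, response] == 0:
                raise SeparationError(
                    f"complete separation: {what} {level!r} has no response={response} cells"
                )


def fit_rating_model(
    records: list[RatingRecord],
    question: str,
    include_tract_effect: bool = False,
    n_quadrature: int = 8,
    reference_method: str = "AU",
) -> GlmmFit:
    """Fit the random-intercept logistic model for one binary question.

    Fixed effects: method (reference ``reference_method``) and rater
    (reference = first rater in sorted order); optionally tract.  Random
    intercept per subject.  Maximum likelihood by adaptive Gauss-Hermite
    quadrature with ``n_quadrature`` nodes (1 = Laplace approximation).
    """
    if question not in QUESTIONS:
        raise ValueError(f"question must be one of {QUESTIONS}")
    df = records_to_frame(records).rename(columns={question: "y"})
    methods = sorted(df["method"].unique())
    raters = sorted(df["rater"].unique())
    subjects = sorted(df["subject"].unique())
    if len(methods) < 2 or len(raters) < 2 or len(subjects) < 2:
        raise ValueError("need >=2 methods, >=2 raters and >=2 subjects")
    if df["y"].nunique() < 2:
        raise SeparationError("responses are all identical")
    _check_separation(df, "method", "method")

    if reference_method not in methods:
        reference_method = methods[0]
    method_terms = [m for m in methods if m != reference_method]
    rater_terms = raters[1:]
    cols = [np.ones(len(df))]
    terms = ["intercept"]
    for m in method_terms:
        cols.append((df["method"] == m).to_numpy(float))
        terms.append(f"method[{m}]")
    for r in rater_terms:
        cols.append((df["rater"] == r).to_numpy(float))
        terms.append(f"rater[{r}]")
    if include_tract_effect:
        for t in sorted(df["tract"].unique())[1:]:
            cols.append((df["tract"] == t).to_numpy(float))
            terms.append(f"tract[{t}]")
    X = np.column_stack(cols)
    y = df["y"].to_numpy(float)
    gi = pd.Categorical(df["subject"], categories=subjects).codes.astype(np.int64)

    nodes, weights = np.polynomial.hermite.hermgauss(max(1, int(n_quadrature)))
    lognw = np.log(weights)
    n_subj = len(subjects)

    def objective(theta):
        return _marginal_negloglik(theta, X, y, gi, n_subj, nodes, lognw)

    # start from the pooled logistic solution at moderate sigma
    theta0 = np.zeros(X.shape[1] + 1)
    theta0[0] = math.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    theta0[-1] = math.log(0.5)
    bounds = [(None, None)] * X.shape[1] + [(math.log(1e-4), math.log(50.0))]
    res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8})
    theta = res.x
    hess = _numeric_hessian(objective, theta)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        cov_ok = np.all(np.isfinite(se_all[: X.shape[1]])) and np.all(
            se_all[: X.shape[1]] > 0
        )
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
        cov_ok = False
    fixed = pd.DataFrame(
        {"term": terms, "coef": theta[: X.shape[1]], "se": se_all[: X.shape[1]]}
    )
    z = 1.959963984540054  # 97.5% normal quantile
    odds = {}
    for m in method_terms:
        row = fixed[fixed["term"] == f"method[{m}]"].iloc[0]
        odds[m] = (
            math.exp(row.coef),
            math.exp(row.coef - z * row.se),
            math.exp(row.coef + z * row.se),
        )
    return GlmmFit(
        question=question,
        fixed_effects=fixed,
        random_intercept_sd=math.exp(theta[-1]),
        odds_ratios=odds,
        converged=bool(res.success and cov_ok),
        n_obs=len(df),
        loglik=-res.fun,
        reference_method=reference_method,
    )


def summarize_method_contrasts(fit: GlmmFit) -> pd.DataFrame:
    """OR (95% CI) per non-reference method, with a direction flag vs the
    reference: "lower"/"higher" when the CI excludes 1, else
    "indistinguishable"."""
    if not fit.converged:
        raise ValueError("cannot summarize a non-converged fit")
    rows = []
    for method, (or_, lo, hi) in sorted(fit.odds_ratios.items()):
        if hi < 1.0:
            direction = "lower"
        elif lo > 1.0:
            direction = "higher"
        else:
            direction = "indistinguishable"
        rows.append(
            {
                "method": method, "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                "direction_vs_reference": direction,
            }
        )
    return pd.DataFrame(rows)
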