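"""Risk-score survival modelling of candidate genes.

Workflow: split the cohort into training and test halves; screen each
candidate gene with a univariate Cox proportional-hazards regression on the
training half; combine the significant candidates into a per-patient risk
score

    RiskScore = sum_i r_i * Exp(i)

where r_i is the training Cox coefficient of gene i and Exp(i) the
patient's (log2-scale) expression of that gene; dichotomize at the training
median; and compare the high- and low-risk groups with Kaplan-Meier curves
and a log-rank test on training, held-out test, combined, and external
cohorts — always reusing the training coefficients and cutoff verbatim.

The univariate Cox fit maximizes the Breslow partial likelihood with
Newton-Raphson (tolerance 1e-9 on the log-partial-likelihood, at most 50
iterations, step-halving on overshoot); Kaplan-Meier and the log-rank test
come from lifelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

#: Univariate screening threshold on the Wald p-value.
DEFAULT_SCREEN_P = 0.05
NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 50


def check_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table (sample_id, time, event)."""
    required = ["sample_id", "time", "event"]
    missing = [c for c in required if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if clinical["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    if (clinical["time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("event status must be 0 (censored) or 1 (dead)")
    return clinical


def load_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t")
    clinical["sample_id"] = clinical["sample_id"].astype(str)
    return check_clinical(clinical)


# ---------------------------------------------------------------------------
# Train / test split


def split_train_test(
    clinical: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[list, list]:
    """Seeded random partition of patients into training and test ids.

    ``fraction`` is the training share; group sizes differ by at most one.
    """
    check_clinical(clinical)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ids = list(clinical["sample_id"])
    if len(ids) < 4:
        raise ValueError("need at least 4 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def split_comparability(
    clinical: pd.DataFrame, train_ids, test_ids, covariates: list[str]
) -> pd.DataFrame:
    """Chi-square comparability of categorical covariates across the split."""
    rows = []
    train = clinical[clinical["sample_id"].isin(set(train_ids))]
    test = clinical[clinical["sample_id"].isin(set(test_ids))]
    for cov in covariates:
        table = pd.crosstab(
            pd.concat([train[cov], test[cov]]),
            ["train"] * len(train) + ["test"] * len(test),
        )
        chi2, p, _, _ = stats.chi2_contingency(table)
        rows.append((cov, float(chi2), float(p)))
    return pd.DataFrame(rows, columns=["covariate", "chi_square", "p_value"])


# ---------------------------------------------------------------------------
# Univariate Cox regression (Breslow ties, Newton-Raphson)


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit for one gene."""

    gene_id: str
    coefficient: float
    se: float
    p_value: float
    converged: bool
    n: int
    n_events: int

    @property
    def hazard_ratio(self) -> float:
        return math.exp(self.coefficient)

    @property
    def ci_low(self) -> float:
        return math.exp(self.coefficient - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.coefficient + 1.959963984540054 * self.se)


def _breslow_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Breslow partial log-likelihood, score and information for one beta.

    Patients are pre-sorted by time descending so the risk set at each event
    time is a prefix cumulative sum.
    """
    eta = beta * x
    w = np.exp(eta)
    s0 = np.cumsum(w)            # sum of weights over the risk set
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    ll = grad = info = 0.0
    # group tied event times (Breslow: one risk-set denominator per time)
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j + 1) if event[k] == 1]
        if d_idx:
            d = len(d_idx)
            ll += eta[d_idx].sum() - d * math.log(s0[j])
            mean = s1[j] / s0[j]
            grad += x[d_idx].sum() - d * mean
            info += d * (s2[j] / s0[j] - mean * mean)
        i = j + 1
    return ll, grad, info


def cox_univariate(expression: pd.Series, clinical: pd.DataFrame) -> CoxFit:
    """Maximum-partial-likelihood fit of survival on one gene's expression.

    Newton-Raphson on the Breslow partial likelihood, converged when
    successive log-partial-likelihoods differ by less than 1e-9 (at most 50
    iterations, halving overshooting steps).  Monotone-likelihood or
    non-convergent fits are returned flagged ``converged=False``.
    """
    check_clinical(clinical)
    clin = clinical.set_index("sample_id")
    missing = [s for s in clin.index if s not in expression.index]
    if missing:
        raise ValueError(f"expression missing for samples: {missing[:5]}")
    if len(clin) < 10:
        raise ValueError("need at least 10 patients for a Cox fit")
    if int(clin["event"].sum()) < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    x = expression.loc[clin.index].to_numpy(dtype=float)
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    order = np.argsort(-time, kind="mergesort")
    x, time, event = x[order], time[order], event[order]
    gene = expression.name if expression.name is not None else "gene"

    beta = 0.0
    ll, grad, info = _breslow_loglik(beta, x, time, event)
    converged = False
    for _ in range(NEWTON_MAX_ITER):
        if info <= 0 or not np.isfinite(info):
            break
        step = grad / info
        # step-halving keeps the likelihood non-decreasing
        new_beta, new = beta + step, None
        for _ in range(30):
            new = _breslow_loglik(new_beta, x, time, event)
            if np.isfinite(new[0]) and new[0] >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2
        if new is None or not np.isfinite(new[0]):
            break
        delta = new[0] - ll
        beta, (ll, grad, info) = new_beta, new
        if abs(delta) < NEWTON_TOL:
            converged = True
            break
    # monotone likelihood: beta drifts to +-inf with an exploding SE
    se_est = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    if not converged or abs(beta) > 10 or se_est > 100:
        logger.warning("Cox fit for %s unreliable (beta=%.3g)", gene, beta)
        converged = False
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return CoxFit(str(gene), float(beta), float(se), float(p), converged, len(x), int(event.sum()))


def screen_candidates(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    genes=None,
    p_threshold: float = DEFAULT_SCREEN_P,
) -> pd.DataFrame:
    """Univariate Cox screening of candidate genes on a (training) cohort.

    Returns one row per gene (coefficient, HR, 95% CI, p) with a
    ``significant`` flag at ``p_threshold``.
    """
    genes = list(genes) if genes is not None else list(expression.index)
    rows = []
    for gene in genes:
        if gene not in expression.index:
            raise ValueError(f"gene {gene!r} absent from expression matrix")
        fit = cox_univariate(expression.loc[gene], clinical)
        rows.append(
            (
                gene,
                fit.coefficient,
                fit.hazard_ratio,
                fit.ci_low,
                fit.ci_high,
                fit.p_value,
                int(fit.converged),
                int(fit.converged and fit.p_value < p_threshold),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "coefficient",
            "hazard_ratio",
            "ci_low",
            "ci_high",
            "p_value",
            "converged",
            "significant",
        ],
    )


# ---------------------------------------------------------------------------
# Risk score model


@dataclass(frozen=True)
class RiskModel:
    """Linear risk score with a training-median cutoff."""

    genes: tuple
    coefficients: tuple
    cutoff: float
    n: int = field(default=0)

    def scores(self, expression: pd.DataFrame, ids) -> pd.Series:
        """RiskScore = sum_i r_i * Exp(i) per patient (matrix product)."""
        missing = [g for g in self.genes if g not in expression.index]
        if missing:
            raise ValueError(f"model genes absent from expression matrix: {missing}")
        sub = expression.loc[list(self.genes), list(ids)].to_numpy(dtype=float)
        return pd.Series(
            np.asarray(self.coefficients, dtype=float) @ sub, index=list(ids)
        )


def build_risk_model(
    fits: pd.DataFrame, expression: pd.DataFrame, train_ids
) -> RiskModel:
    """Combine training Cox coefficients into a median-cutoff risk model.

    ``fits`` is a screen_candidates frame (or any frame with ``gene_id`` and
    ``coefficient``); the cutoff is the median training risk score.
    """
    genes = tuple(fits["gene_id"])
    coefs = tuple(float(c) for c in fits["coefficient"])
    if len(genes) == 0:
        raise ValueError("risk model needs at least one gene")
    model = RiskModel(genes, coefs, cutoff=0.0, n=len(genes))
    cutoff = float(model.scores(expression, train_ids).median())
    return RiskModel(genes, coefs, cutoff=cutoff, n=len(genes))


def stratify(model: RiskModel, expression: pd.DataFrame, ids) -> pd.Series:
    """Label patients 'high' (score > cutoff) or 'low' (score <= cutoff).

    The training cutoff is reused unchanged on test and external cohorts;
    scores exactly at the cutoff are low-risk.
    """
    scores = model.scores(expression, ids)
    return pd.Series(np.where(scores > model.cutoff, "high", "low"), index=scores.index)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def kaplan_meier(clinical: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve: columns time, survival, at_risk.

    Survival is 1 at time 0 and steps down only at event times.
    """
    check_clinical(clinical)
    if len(clinical) == 0:
        raise ValueError("empty clinical subset")
    km = KaplanMeierFitter()
    km.fit(clinical["time"], clinical["event"])
    curve = km.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    at_risk = [
        int((clinical["time"] >= t).sum()) if t > 0 else len(clinical)
        for t in curve["time"]
    ]
    curve["at_risk"] = at_risk
    return curve


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p-value."""
    for g in (group_a, group_b):
        check_clinical(g)
        if len(g) == 0:
            raise ValueError("empty group in log-rank test")
    if int(group_a["event"].sum() + group_b["event"].sum()) == 0:
        return float("nan"), float("nan")
    res = _ll_logrank(
        group_a["time"], group_b["time"], group_a["event"], group_b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# End-to-end evaluation


def evaluate_signature(
    genes,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    split_fraction: float = 0.5,
    seed: int = 0,
    external: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    screen_p: float | None = None,
) -> dict:
    """Fit a risk model on a training split and evaluate per cohort.

    Screens ``genes`` with univariate Cox on the training half (optionally
    keeping only those with p < ``screen_p``), builds the risk model,
    stratifies training / held-out test / combined cohorts (and an external
    ``(expression, clinical)`` pair if given) at the training cutoff, and
    reports group sizes, log-rank statistics and Kaplan-Meier curves.
    """
    check_clinical(clinical)
    train_ids, test_ids = split_train_test(clinical, split_fraction, seed)
    clin = clinical.set_index("sample_id", drop=False)
    train_clin = clin.loc[train_ids].reset_index(drop=True)
    fits = screen_candidates(expression, train_clin, genes)
    if screen_p is not None:
        kept = fits[(fits["converged"] == 1) & (fits["p_value"] < screen_p)]
        if len(kept) == 0:
            # an all-null screen falls back to the full candidate list so the
            # (correctly non-significant) stratification is still reported
            logger.warning("no candidate passed the univariate screen; using all %d", len(fits))
        else:
            fits = kept
    model = build_risk_model(fits, expression, train_ids)
    cohorts = {
        "train": (expression, clin.loc[train_ids].reset_index(drop=True)),
        "test": (expression, clin.loc[test_ids].reset_index(drop=True)),
        "all": (expression, clinical),
    }
    if external is not None:
        cohorts["external"] = external
    report_rows = []
    curves = {}
    for name, (expr, c) in cohorts.items():
        check_clinical(c)
        labels = stratify(model, expr, list(c["sample_id"]))
        c = c.assign(group=labels.loc[c["sample_id"]].to_numpy())
        high = c[c["group"] == "high"]
        low = c[c["group"] == "low"]
        if len(high) and len(low):
            chi2, p = logrank_test(high, low)
        else:
            chi2, p = float("nan"), float("nan")
        report_rows.append((name, len(high), len(low), chi2, p))
        curves[name] = {
            grp: kaplan_meier(sub) for grp, sub in c.groupby("group") if len(sub)
        }
    report = pd.DataFrame(
        report_rows, columns=["cohort", "n_high", "n_low", "chi_square", "p_value"]
    )
    logger.info("signature evaluation:\n%s", report.to_string(index=False))
    return {
        "model": model,
        "fits": fits,
        "report": report,
        "curves": curves,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }
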