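"""ROC analysis of polypharmacy risk classifiers against outcome flags.

AUROC is estimated with the Mann–Whitney statistic using midranks for ties:
the probability that a randomly chosen case scores above a randomly chosen
control, counting equal scores as one half.  The standard error uses the
Hanley–McNeil approximation by default (a DeLong variance is available as an
alternative), the 95% CI is Wald on the AUC scale truncated to [0, 1], and
the comparison with chance is a two-sided normal test of AUC = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "CLASSIFIER_COLUMNS",
    "ROCResult",
    "auroc",
    "auroc_se_ci",
    "delong_se",
    "compare_to_chance",
    "roc_points",
    "evaluate_classifiers",
    "results_to_dataframe",
]

#: Cohort score columns evaluated side by side, in reporting order.
CLASSIFIER_COLUMNS = ("qsp_readout", "d2r_sum", "inv_k_sum", "cpz_sum")


@dataclass(frozen=True)
class ROCResult:
    """AUROC with uncertainty for one classifier on one cohort."""

    classifier_name: str
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_vs_chance: float
    n_cases: int
    n_controls: int
    roc_points: tuple[tuple[float, float], ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc outside [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI does not bracket the AUC")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-d vectors")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    cases, controls = scores[labels], scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(
            "AUROC undefined: need at least one case and one control "
            f"(got {len(cases)} cases, {len(controls)} controls)"
        )
    return cases, controls


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC with midrank tie handling.

    Equals the mean over all case–control pairs of 1 (case higher),
    ½ (tied) or 0 (control higher), computed via the rank-sum identity.
    """
    cases, controls = _split(scores, labels)
    n1, n0 = len(cases), len(controls)
    ranks = rankdata(np.concatenate([cases, controls]), method="average")
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auroc_se_ci(auc: float, n_cases: int, n_controls: int) -> tuple[float, float, float]:
    """Hanley–McNeil standard error and Wald 95% CI truncated to [0, 1].

    At AUC exactly 0 or 1 the approximation collapses; the SE is returned as
    0 with a degenerate point interval (callers flag this).
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least two cases and two controls for a standard error")
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc outside [0, 1]")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_cases - 1) * (q1 - a * a)
        + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)
    se = float(np.sqrt(max(var, 0.0)))
    half = norm.ppf(0.975) * se
    return se, max(0.0, a - half), min(1.0, a + half)


def delong_se(scores, labels) -> float:
    """DeLong (1988) standard error of the midrank AUROC.

    Structural-component estimator: V10 for cases, V01 for controls.
    """
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    if m < 2 or n < 2:
        raise ValueError("need at least two cases and two controls for a standard error")
    # placement values via midranks
    all_ranks = rankdata(np.concatenate([cases, controls]), method="average")
    case_ranks = rankdata(cases, method="average")
    control_ranks = rankdata(controls, method="average")
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(np.sqrt(var))


def compare_to_chance(auc: float, se: float) -> float:
    """Two-sided normal-approximation p-value for H₀: AUC = 0.5."""
    if se <= 0:
        raise ValueError("standard error must be > 0")
    z = (auc - 0.5) / se
    return float(2.0 * norm.sf(abs(z)))


def roc_points(scores, labels) -> tuple[tuple[float, float], ...]:
    """Tie-aware ROC curve as (FPR, TPR) pairs from (0,0) to (1,1)."""
    _split(scores, labels)  # validation
    fpr, tpr, _ = roc_curve(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float))
    pts = [(float(x), float(y)) for x, y in zip(fpr, tpr)]
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return tuple(pts)


def roc_result(name: str, scores, labels, se_method: str = "hanley") -> ROCResult:
    """Full ROC summary for one classifier's scores."""
    cases, controls = _split(scores, labels)
    a = auroc(scores, labels)
    degenerate = a in (0.0, 1.0)
    if degenerate:
        se, lo, hi = 0.0, a, a
        p = float("nan")
    else:
        if se_method == "hanley":
            se, lo, hi = auroc_se_ci(a, len(cases), len(controls))
        elif se_method == "delong":
            se = delong_se(scores, labels)
            half = norm.ppf(0.975) * se
            lo, hi = max(0.0, a - half), min(1.0, a + half)
        else:
            raise ValueError(f"unknown se_method {se_method!r}")
        p = compare_to_chance(a, se)
    return ROCResult(
        classifier_name=name,
        auc=a,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_vs_chance=p,
        n_cases=len(cases),
        n_controls=len(controls),
        roc_points=roc_points(scores, labels),
        degenerate=degenerate,
    )


def evaluate_classifiers(
    cohort: pd.DataFrame,
    classifiers: tuple[str, ...] = CLASSIFIER_COLUMNS,
    se_method: str = "hanley",
) -> list[ROCResult]:
    """One :class:`ROCResult` per score column against the outcome flags.

    ``cohort`` is a scored cohort table with an ``outcome`` column (0/1) and
    one numeric column per classifier.  Deterministic; invariant to record
    order.
    """
    if "outcome" not in cohort.columns:
        raise ValueError("cohort has no outcome column")
    missing = [c for c in classifiers if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort not scored for classifiers {missing}")
    bad = cohort[cohort[list(classifiers)].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"records with missing scores: {bad['id'].tolist()}")
    labels = cohort["outcome"].astype(int).to_numpy().astype(bool)
    return [roc_result(c, cohort[c].to_numpy(dtype=float), labels, se_method) for c in classifiers]


def results_to_dataframe(results: list[ROCResult]) -> pd.DataFrame:
    """Comparison table: one row per classifier, AUC / SE / CI / p / counts."""
    return pd.DataFrame(
        [
            {
                "classifier": r.classifier_name,
                "auc": r.auc,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_vs_chance": r.p_vs_chance,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
            for r in results
        ]
    )
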