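"""Discrimination and reclassification statistics for risk-model comparison.

AUC is the Mann–Whitney estimator (ties count one half) with standard
error from DeLong's structural components; paired AUC differences use the
covariance of the two models' components, the field-standard test for
correlated ROC curves.  IDI is the difference in discrimination slopes;
the categorical NRI counts net movement across fixed risk categories.
AIC/BIC are the usual penalized log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import ModelFit

__all__ = [
    "AUCResult",
    "DeLongResult",
    "IDIResult",
    "NRIResult",
    "ComparisonResult",
    "compute_auc",
    "delong_paired_test",
    "compute_idi",
    "compute_nri_categorical",
    "information_criteria",
    "compare_models",
    "DEFAULT_NRI_CUTS",
]

#: conventional three-category risk thresholds for the categorical NRI
DEFAULT_NRI_CUTS = (0.05, 0.15)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DeLongResult:
    delta_auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class IDIResult:
    idi: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class NRIResult:
    nri: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    case_table: np.ndarray      # old-category x new-category counts, cases
    control_table: np.ndarray   # same, controls


@dataclass(frozen=True)
class ComparisonResult:
    reference: str
    comparator: str
    auc_reference: AUCResult
    auc_comparator: AUCResult
    delta_auc: DeLongResult
    idi: IDIResult
    nri: NRIResult
    delta_aic: float
    delta_bic: float


def _check_inputs(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    return scores, labels.astype(int)


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components.

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the mean placement of
    case i against all controls and ``v01[j]`` the mean placement of
    control j against all cases (ties contribute one half).
    """
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    diff = cases[:, None] - controls[None, :]
    psi = (diff > 0).astype(float)
    psi[diff == 0] = 0.5
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def compute_auc(scores, labels) -> AUCResult:
    """Mann–Whitney AUC with DeLong standard error and Wald 95% CI."""
    scores, labels = _check_inputs(scores, labels)
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    return AUCResult(
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - 1.96 * se)),
        ci_high=float(min(1.0, auc + 1.96 * se)),
    )


def delong_paired_test(scores1, scores2, labels) -> DeLongResult:
    """Paired difference of correlated AUCs (model 2 minus model 1).

    Variance of the difference comes from the covariance matrix of the two
    models' structural components; the p-value is two-sided normal.
    Monotone transforms of a score vector leave its AUC — and hence a
    delta of zero against itself — exactly unchanged.
    """
    s1, labels = _check_inputs(scores1, labels)
    s2, labels2 = _check_inputs(scores2, labels)
    if not np.array_equal(labels, labels2):
        raise ValueError("label vectors must match")
    auc1, v10_1, v01_1 = _structural_components(s1, labels)
    auc2, v10_2, v01_2 = _structural_components(s2, labels)
    m, n = len(v10_1), len(v01_1)
    delta = auc2 - auc1
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / se))
    return DeLongResult(
        delta_auc=float(delta),
        se=se,
        ci_low=float(delta - 1.96 * se),
        ci_high=float(delta + 1.96 * se),
        p_value=p,
    )


def compute_idi(
    scores_new, scores_old, labels, n_boot: int = 0, seed: int | None = None
) -> IDIResult:
    """Integrated discrimination improvement, new model versus old.

    ``IDI = [mean(new|case) - mean(old|case)] - [mean(new|control) -
    mean(old|control)]``.  The default SE combines the paired-difference
    standard errors within cases and controls; ``n_boot > 0`` replaces the
    CI and p with a seeded nonparametric bootstrap (participants resampled
    within outcome class).
    """
    new, labels = _check_inputs(scores_new, labels)
    old, _ = _check_inputs(scores_old, labels)
    d = new - old
    d_case = d[labels == 1]
    d_ctrl = d[labels == 0]
    idi = float(d_case.mean() - d_ctrl.mean())
    se = float(
        np.sqrt(
            (np.var(d_case, ddof=1) / len(d_case) if len(d_case) > 1 else 0.0)
            + (np.var(d_ctrl, ddof=1) / len(d_ctrl) if len(d_ctrl) > 1 else 0.0)
        )
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            reps[b] = (
                rng.choice(d_case, size=len(d_case)).mean()
                - rng.choice(d_ctrl, size=len(d_ctrl)).mean()
            )
        lo, hi = np.percentile(reps, [2.5, 97.5])
        p = float(2 * min((reps <= 0).mean(), (reps >= 0).mean()))
        return IDIResult(idi, float(reps.std(ddof=1)), float(lo), float(hi), min(p, 1.0))
    if se == 0.0:
        p = 1.0 if idi == 0.0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(idi) / se))
    return IDIResult(idi, se, idi - 1.96 * se, idi + 1.96 * se, p)


def _categorize(scores: np.ndarray, cuts) -> np.ndarray:
    return np.searchsorted(np.asarray(cuts, dtype=float), scores, side="left")


def compute_nri_categorical(
    scores_new, scores_old, labels, cuts=DEFAULT_NRI_CUTS
) -> NRIResult:
    """Categorical net reclassification improvement, new versus old.

    Participants are binned by the strictly increasing risk thresholds
    ``cuts``; ``NRI = [P(up|case) - P(down|case)] + [P(down|control) -
    P(up|control)]`` with the usual asymptotic variance.  Both
    reclassification cross-tabulations (rows = old category, columns =
    new) are returned.
    """
    cuts = tuple(float(c) for c in cuts)
    if len(cuts) == 0:
        raise ValueError("at least one risk threshold is required")
    if any(not 0 < c < 1 for c in cuts) or any(
        b <= a for a, b in zip(cuts, cuts[1:])
    ):
        raise ValueError("cuts must be strictly increasing within (0, 1)")
    new, labels = _check_inputs(scores_new, labels)
    old, _ = _check_inputs(scores_old, labels)
    cat_new = _categorize(new, cuts)
    cat_old = _categorize(old, cuts)
    k = len(cuts) + 1

    def _tab(mask):
        tab = np.zeros((k, k), dtype=int)
        np.add.at(tab, (cat_old[mask], cat_new[mask]), 1)
        return tab

    case, ctrl = labels == 1, labels == 0
    case_tab, ctrl_tab = _tab(case), _tab(ctrl)

    def _rates(tab):
        n = tab.sum()
        up = np.triu(tab, 1).sum() / n
        down = np.tril(tab, -1).sum() / n
        return up, down, n

    up_c, down_c, n_case = _rates(case_tab)
    up_n, down_n, n_ctrl = _rates(ctrl_tab)
    nri = float((up_c - down_c) + (down_n - up_n))
    var = (up_c + down_c - (up_c - down_c) ** 2) / n_case + (
        up_n + down_n - (down_n - up_n) ** 2
    ) / n_ctrl
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if nri == 0.0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(nri) / se))
    return NRIResult(
        nri, se, nri - 1.96 * se, nri + 1.96 * se, p, case_tab, ctrl_tab
    )


def information_criteria(fit: ModelFit) -> tuple[float, float]:
    """AIC and BIC: ``-2 logL + 2k`` and ``-2 logL + k ln(n)``."""
    aic = -2.0 * fit.log_likelihood + 2.0 * fit.k
    bic = -2.0 * fit.log_likelihood + fit.k * np.log(fit.n)
    return float(aic), float(bic)


def compare_models(
    fits: list[ModelFit],
    reference: str,
    labels,
    cuts=DEFAULT_NRI_CUTS,
    n_boot: int = 0,
    seed: int | None = None,
) -> list[ComparisonResult]:
    """One :class:`ComparisonResult` per non-reference model vs the reference.

    All fits must be on the identical participants (same length and label
    vector).  Deterministic given inputs; bootstrap CIs, when requested,
    are seeded.
    """
    by_name = {f.spec.name: f for f in fits}
    if reference not in by_name:
        raise ValueError(f"reference model {reference!r} not among fits")
    ref = by_name[reference]
    labels = np.asarray(labels)
    if len(labels) != len(ref.predicted_risks):
        raise ValueError("labels length does not match fitted risks")
    ref_auc = compute_auc(ref.predicted_risks, labels)
    ref_aic, ref_bic = information_criteria(ref)
    out = []
    for fit in fits:
        if fit.spec.name == reference:
            continue
        if len(fit.predicted_risks) != len(labels):
            raise ValueError(
                f"model {fit.spec.name!r} fitted on different participants"
            )
        aic, bic = information_criteria(fit)
        out.append(
            ComparisonResult(
                reference=reference,
                comparator=fit.spec.name,
                auc_reference=ref_auc,
                auc_comparator=compute_auc(fit.predicted_risks, labels),
                delta_auc=delong_paired_test(
                    ref.predicted_risks, fit.predicted_risks, labels
                ),
                idi=compute_idi(
                    fit.predicted_risks, ref.predicted_risks, labels,
                    n_boot=n_boot, seed=seed,
                ),
                nri=compute_nri_categorical(
                    fit.predicted_risks, ref.predicted_risks, labels, cuts
                ),
                delta_aic=float(aic - ref_aic),
                delta_bic=float(bic - ref_bic),
            )
        )
    return out
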