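"""End-to-end analysis pipeline.

Runs the full study replication on a cohort (real delimited-text files or
the synthetic generator): eligibility filters, single-value imputation,
index computation, a baseline-characteristics table by outcome group,
crude and age/sex-adjusted Spearman correlations among indices, crude and
covariate-adjusted odds ratios per index, the discrimination model grid
(AUC/DeLong, IDI, categorical NRI, AIC/BIC against a reference model),
and sensitivity re-runs at stricter minimum visit counts.  Every table is
emitted as delimited text; a run is deterministic given its config and
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (
    CLASSICAL_COVARIATES,
    Cohort,
    apply_eligibility_filters,
    derive_comorbidity_flags,
    impute_missing_covariates,
    read_cohort,
)
from .discrimination import DEFAULT_NRI_CUTS, compare_models, compute_auc
from .indices import DEFAULT_SCALING, DEFAULT_THRESHOLD, compute_all_indices
from .models import INDEX_TERMS, ModelSpec, build_model_grid, extract_or, fit_logistic
from .simulate import GeneratorParams, generate_cohort

__all__ = [
    "RunConfig",
    "run_baseline_table",
    "run_correlation_matrix",
    "run_full_analysis",
    "analysis_frame",
]

BASELINE_CONTINUOUS = ("age", "bmi") + INDEX_TERMS
BASELINE_CATEGORICAL = (
    "female",
    "education_low",
    "income_low",
    "current_smoking",
    "current_drinking",
    "hypertension",
    "dyslipidemia",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    visits_path: str | None = None
    participants_path: str | None = None
    generator: dict = field(default_factory=dict)   # GeneratorParams overrides
    threshold: float = DEFAULT_THRESHOLD
    scaling: dict = field(default_factory=lambda: dict(DEFAULT_SCALING))
    nri_cuts: tuple = DEFAULT_NRI_CUTS
    reference_model: str = "classical+fbg_baseline"
    min_visits: int = 3
    sensitivity_min_visits: tuple = (4, 5)
    seed: int = 0
    outdir: str = "fbgrisk_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.nri_cuts, list):
            cfg.nri_cuts = tuple(cfg.nri_cuts)
        if isinstance(cfg.sensitivity_min_visits, list):
            cfg.sensitivity_min_visits = tuple(cfg.sensitivity_min_visits)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["nri_cuts"] = list(self.nri_cuts)
        d["sensitivity_min_visits"] = list(self.sensitivity_min_visits)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _fmt_ci(x: float, lo: float, hi: float, nd: int = 4) -> str:
    return f"{x:.{nd}f} ({lo:.{nd}f}, {hi:.{nd}f})"


def analysis_frame(cohort: Cohort, indices: pd.DataFrame) -> pd.DataFrame:
    """Merge participant covariates with the per-participant index table."""
    return cohort.participants.merge(indices, on="participant_id", how="inner")


def run_baseline_table(
    cohort: Cohort,
    indices: pd.DataFrame,
    continuous: tuple = BASELINE_CONTINUOUS,
    categorical: tuple = BASELINE_CATEGORICAL,
) -> pd.DataFrame:
    """Baseline characteristics by outcome group with comparison p-values.

    Continuous variables: mean (SD) per group; unpaired t-test, replaced
    by the Wilcoxon rank-sum test when normality is rejected (alpha 0.05,
    D'Agostino-Pearson) in either group.  Categorical variables: n (%)
    per group; chi-square without continuity correction, replaced by
    Fisher's exact test when any expected cell count is below 5.
    """
    df = analysis_frame(cohort, indices)
    y = pd.to_numeric(df["dr_status"], errors="coerce")
    g0, g1 = df[y == 0], df[y == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        a = pd.to_numeric(g0[var]).dropna().to_numpy()
        b = pd.to_numeric(g1[var]).dropna().to_numpy()
        normal = True
        for x in (a, b):
            if len(x) >= 20 and stats.normaltest(x).pvalue < 0.05:
                normal = False
        if normal:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            test = "t"
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            test = "wilcoxon"
        rows.append(
            {
                "variable": var,
                "no_dr": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                "dr": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                "test": test,
                "p_value": float(p),
            }
        )
    for var in categorical:
        if var not in df.columns:
            continue
        a = pd.to_numeric(g0[var]).dropna()
        b = pd.to_numeric(g1[var]).dropna()
        table = np.array(
            [[(a == 0).sum(), (a == 1).sum()], [(b == 0).sum(), (b == 1).sum()]]
        )
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            p = stats.fisher_exact(table).pvalue
            test = "fisher"
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
            test = "chi2"
        rows.append(
            {
                "variable": var,
                "no_dr": f"{int((a == 1).sum())} ({100 * (a == 1).mean():.2f}%)",
                "dr": f"{int((b == 1).sum())} ({100 * (b == 1).mean():.2f}%)",
                "test": test,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def _rank_partial_corr(x, y, controls: np.ndarray) -> float:
    """Spearman partial correlation: Pearson on rank residuals.

    All variables, covariates included, are rank-transformed first (the
    standard Spearman partial), then the index ranks are residualized on
    the covariate ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([stats.rankdata(c) for c in np.atleast_2d(controls.T)])
    Z = np.column_stack([np.ones(len(rx)), rz])
    beta_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex, ey = rx - Z @ beta_x, ry - Z @ beta_y
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        return np.nan
    return float((ex * ey).sum() / denom)


def run_correlation_matrix(
    indices: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    terms: tuple = INDEX_TERMS,
) -> dict:
    """Pairwise Spearman correlations among the indices.

    Returns ``{"crude": DataFrame, "adjusted": DataFrame}``; the adjusted
    matrix is the partial correlation on rank-transformed values
    controlling for age and sex, and requires ``participants``.  Constant
    columns yield NaN entries (flagged, not silent).
    """
    cols = [t for t in terms if t in indices.columns]
    X = indices[cols].to_numpy(dtype=float)
    crude = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.ptp(X[:, i]) == 0 or np.ptp(X[:, j]) == 0:
                r = np.nan
            else:
                r = stats.spearmanr(X[:, i], X[:, j]).statistic
            crude.iloc[i, j] = crude.iloc[j, i] = r
    out = {"crude": crude}
    if participants is not None:
        merged = indices.merge(
            participants[["participant_id", "age", "female"]], on="participant_id"
        )
        controls = merged[["age", "female"]].to_numpy(dtype=float)
        Xm = merged[cols].to_numpy(dtype=float)
        adj = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if np.ptp(Xm[:, i]) == 0 or np.ptp(Xm[:, j]) == 0:
                    r = np.nan
                else:
                    r = _rank_partial_corr(Xm[:, i], Xm[:, j], controls)
                adj.iloc[i, j] = adj.iloc[j, i] = r
        out["adjusted"] = adj
    return out


def _association_table(df: pd.DataFrame, scaling: dict) -> pd.DataFrame:
    """Crude and covariate-adjusted odds ratio per index (one model each)."""
    rows = []
    for term in INDEX_TERMS:
        if term not in df.columns:
            continue
        sc = {term: scaling.get(term, "per_unit")}
        crude = fit_logistic(df, ModelSpec(name=f"crude:{term}", terms=(term,),
                                           scaling=sc))
        adj = fit_logistic(
            df,
            ModelSpec(
                name=f"adjusted:{term}",
                terms=tuple(CLASSICAL_COVARIATES) + (term,),
                scaling=sc,
            ),
        )
        rows.append(
            {
                "term": term,
                "scaling": sc[term],
                "crude_or_95ci": _fmt_ci(*extract_or(crude, term), nd=2),
                "adjusted_or_95ci": _fmt_ci(*extract_or(adj, term), nd=2),
            }
        )
    return pd.DataFrame(rows)


def _discrimination_tables(
    df: pd.DataFrame, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fit the model grid and tabulate AUC/ΔAUC, IDI/NRI, and AIC/BIC."""
    specs = build_model_grid(scaling=cfg.scaling)
    fits = [fit_logistic(df, s) for s in specs]
    labels = pd.to_numeric(df["dr_status"]).to_numpy()
    results = compare_models(fits, cfg.reference_model, labels, cuts=cfg.nri_cuts)
    by_name = {f.spec.name: f for f in fits}
    ref = by_name[cfg.reference_model]
    ref_auc = compute_auc(ref.predicted_risks, labels)
    from .discrimination import information_criteria

    ref_aic, ref_bic = information_criteria(ref)
    t3 = [
        {
            "model": cfg.reference_model,
            "auc_95ci": _fmt_ci(ref_auc.auc, ref_auc.ci_low, ref_auc.ci_high),
            "delta_auc_95ci": "reference (0.0000)",
            "p_value": np.nan,
        }
    ]
    t4 = [
        {
            "model": cfg.reference_model,
            "idi_95ci": "reference",
            "idi_p": np.nan,
            "nri_95ci": "reference",
            "nri_p": np.nan,
        }
    ]
    ic = [
        {"model": cfg.reference_model, "aic": ref_aic, "bic": ref_bic,
         "delta_aic": 0.0, "delta_bic": 0.0}
    ]
    for res in results:
        t3.append(
            {
                "model": res.comparator,
                "auc_95ci": _fmt_ci(
                    res.auc_comparator.auc,
                    res.auc_comparator.ci_low,
                    res.auc_comparator.ci_high,
                ),
                "delta_auc_95ci": _fmt_ci(
                    res.delta_auc.delta_auc, res.delta_auc.ci_low,
                    res.delta_auc.ci_high,
                ),
                "p_value": res.delta_auc.p_value,
            }
        )
        t4.append(
            {
                "model": res.comparator,
                "idi_95ci": _fmt_ci(res.idi.idi, res.idi.ci_low, res.idi.ci_high),
                "idi_p": res.idi.p_value,
                "nri_95ci": _fmt_ci(res.nri.nri, res.nri.ci_low, res.nri.ci_high),
                "nri_p": res.nri.p_value,
            }
        )
        aic, bic = information_criteria(by_name[res.comparator])
        ic.append(
            {"model": res.comparator, "aic": aic, "bic": bic,
             "delta_aic": res.delta_aic, "delta_bic": res.delta_bic}
        )
    return pd.DataFrame(t3), pd.DataFrame(t4), pd.DataFrame(ic)


def _write(df: pd.DataFrame, path: Path, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {schema}\n")
        df.to_csv(fh, sep="\t", index=schema.endswith("matrix"))


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write every table under ``cfg.outdir``.

    Returns a dict of the in-memory artifacts keyed by table name.  Any
    stage failure raises with the stage named.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    stage = "input"
    try:
        if cfg.visits_path and cfg.participants_path:
            cohort = read_cohort(cfg.visits_path, cfg.participants_path)
        else:
            gp = GeneratorParams(**{"seed": cfg.seed, **cfg.generator})
            cohort = generate_cohort(gp).cohort

        stage = "comorbidity flags"
        cohort = Cohort(cohort.visits, derive_comorbidity_flags(cohort.participants))

        stage = "eligibility filters"
        cohort, flog = apply_eligibility_filters(cohort, min_visits=cfg.min_visits)

        stage = "imputation"
        cohort, imp_report = impute_missing_covariates(cohort)

        stage = "indices"
        indices, vim_cal = compute_all_indices(cohort.visits, threshold=cfg.threshold)
        df = analysis_frame(cohort, indices)

        stage = "baseline table"
        table1 = run_baseline_table(cohort, indices)

        stage = "correlations"
        corr = run_correlation_matrix(indices, cohort.participants)

        stage = "associations"
        table2 = _association_table(df, cfg.scaling)

        stage = "model grid"
        table3, table4, ic_table = _discrimination_tables(df, cfg)

        artifacts = {
            "filter_log": flog.to_frame(),
            "imputation_report": imp_report,
            "vim_calibration": pd.DataFrame(
                [{"beta": vim_cal.beta, "intercept": vim_cal.intercept,
                  "n_used": vim_cal.n_used}]
            ),
            "indices": indices,
            "table1_baseline": table1,
            "correlations_crude": corr["crude"],
            "correlations_adjusted": corr["adjusted"],
            "table2_associations": table2,
            "table3_discrimination": table3,
            "table4_reclassification": table4,
            "information_criteria": ic_table,
        }

        stage = "sensitivity"
        for mv in cfg.sensitivity_min_visits:
            sub, _ = apply_eligibility_filters(cohort, min_visits=mv)
            if pd.to_numeric(sub.participants["dr_status"]).nunique() < 2:
                continue
            sub_idx, _ = compute_all_indices(sub.visits, threshold=cfg.threshold)
            sub_df = analysis_frame(sub, sub_idx)
            t3, t4, ics = _discrimination_tables(sub_df, cfg)
            artifacts[f"table3_min_visits_{mv}"] = t3
            artifacts[f"table4_min_visits_{mv}"] = t4
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for name, df_out in artifacts.items():
        schema = "correlation matrix" if name.startswith("correlations") else name
        _write(df_out, outdir / f"{name}.tsv", schema)
    return artifacts


def plot_roc(fits, labels, path) -> None:
    """Write a simple ROC overlay for a list of fitted models (optional).

    Requires matplotlib (optional extra ``plots``).
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plot_roc requires matplotlib") from exc
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    for fit in fits:
        scores = fit.predicted_risks
        order = np.argsort(-scores)
        y = labels[order]
        tpr = np.concatenate([[0], np.cumsum(y) / y.sum()])
        fpr = np.concatenate([[0], np.cumsum(1 - y) / (1 - y).sum()])
        ax.plot(fpr, tpr, label=fit.spec.name, lw=1)
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=6)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
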