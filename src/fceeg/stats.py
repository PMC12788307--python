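"""Age-adjusted group comparison with FDR correction and effect sizes.

Each EEG feature (a region x band relative power, or a network AUC metric)
is compared between patients and controls with an ANCOVA: the linear model
``value ~ 1 + group + age`` fitted by least squares, with the group term
tested by a partial F-test (equivalent to the type-III test in this
two-term model) on (1, n-3) degrees of freedom.  Raw p-values are adjusted
with the Benjamini-Hochberg step-up procedure within each (task, band)
family across the five lobes; network AUC features form singleton families
and are reported with their raw p.  Effect sizes are Cohen's d with the
pooled standard deviation, signed patient minus control; |d| > 0.5 is
flagged as a medium effect.  Tests are two-sided with alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InputError

__all__ = [
    "AncovaResult",
    "ancova_group",
    "bh_fdr",
    "cohens_d",
    "run_group_comparison",
    "summary_report",
]

ALPHA = 0.05
MEDIUM_EFFECT_D = 0.5


@dataclass
class AncovaResult:
    f_stat: float
    p_value: float
    group_coef: float  # patient-minus-control adjusted mean difference
    df_num: int
    df_den: int
    age_adjusted: bool


def ancova_group(values, groups, ages) -> AncovaResult:
    """Partial F-test of the group factor with age as covariate.

    ``groups`` holds ``"patient"``/``"control"`` labels (or a 0/1
    indicator with 1 = patient).  If the design is singular (e.g. constant
    age), the model falls back to the group-only fit -- a one-way ANOVA --
    with a warning.  Zero residual variance yields p = 0 with a
    degenerate-fit warning.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    g = np.asarray(
        [1.0 if x in (1, "patient") else 0.0 for x in np.asarray(groups).ravel()]
    )
    n = len(values)
    if len(g) != n or len(ages) != n:
        raise InputError("values, groups and ages must have equal length")
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise InputError("need at least 2 subjects per group")
    if not np.all(np.isfinite(ages)):
        raise InputError("ages must be finite")

    X_full = np.column_stack([np.ones(n), g, ages])
    age_adjusted = True
    if np.linalg.matrix_rank(X_full) < 3:
        warnings.warn(
            "singular design (age carries no information); "
            "falling back to the group-only model"
        )
        X_full = X_full[:, :2]
        age_adjusted = False
    X_red = np.delete(X_full, 1, axis=1)

    def _sse(X: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        resid = values - X @ beta
        return float(resid @ resid), beta

    sse_full, beta = _sse(X_full)
    sse_red, _ = _sse(X_red)
    df_den = n - X_full.shape[1]
    if df_den <= 0:
        raise InputError("not enough subjects for the model degrees of freedom")
    if sse_full <= max(1e-12 * max(sse_red, 1.0), 0.0):
        warnings.warn("degenerate fit: zero residual variance; p reported as 0")
        return AncovaResult(np.inf, 0.0, float(beta[1]), 1, df_den, age_adjusted)
    f = (sse_red - sse_full) / (sse_full / df_den)
    f = max(f, 0.0)
    p = float(sstats.f.sf(f, 1, df_den))
    return AncovaResult(float(f), p, float(beta[1]), 1, df_den, age_adjusted)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def cohens_d(patient_values, control_values) -> float:
    """Standardized mean difference, patient minus control, pooled SD."""
    a = np.asarray(patient_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise InputError("need at least 2 values per group")
    s_pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise InputError("pooled standard deviation is zero; d undefined")
    return float((a.mean() - b.mean()) / s_pooled)


def run_group_comparison(
    features: pd.DataFrame,
    *,
    feature_column: str = "region",
    fdr_within_family: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Compare every (task, band, feature) cell between the groups.

    ``features`` is long-format with columns ``subject_id, group, age,
    task, band, <feature_column>, value``.  One ANCOVA is run per cell;
    BH-FDR is applied within each (task, band) family across the features
    (for network metrics call with ``fdr_within_family=False`` to report
    raw p, i.e. singleton families).  Families with missing cells are
    skipped with a warning.
    """
    required = {"subject_id", "group", "age", "task", "band", feature_column, "value"}
    missing = required - set(features.columns)
    if missing:
        raise InputError(f"feature table lacks columns: {sorted(missing)}")

    rows = []
    for (task, band), fam in features.groupby(["task", "band"], sort=False):
        fam_rows = []
        ok = True
        for feat, cell in fam.groupby(feature_column, sort=False):
            pat = cell.loc[cell["group"] == "patient", "value"].to_numpy()
            ctl = cell.loc[cell["group"] == "control", "value"].to_numpy()
            if len(pat) < 2 or len(ctl) < 2 or not np.all(np.isfinite(cell["value"])):
                warnings.warn(
                    f"family (task={task}, band={band}) skipped: "
                    f"feature {feat!r} has insufficient data"
                )
                ok = False
                break
            res = ancova_group(
                cell["value"].to_numpy(),
                cell["group"].to_numpy(),
                cell["age"].to_numpy(),
            )
            d = cohens_d(pat, ctl)
            fam_rows.append(
                {
                    "task": task,
                    "band": band,
                    "feature": feat,
                    "f_stat": res.f_stat,
                    "p_raw": res.p_value,
                    "cohens_d": d,
                    "medium_effect": abs(d) > MEDIUM_EFFECT_D,
                    "n_patient": len(pat),
                    "n_control": len(ctl),
                }
            )
        if not ok:
            continue
        p_raw = np.array([r["p_raw"] for r in fam_rows])
        p_adj = bh_fdr(p_raw) if fdr_within_family else p_raw.copy()
        for r, pa in zip(fam_rows, p_adj):
            r["p_fdr"] = float(pa)
            r["significant"] = pa < alpha
        rows.extend(fam_rows)
    out = pd.DataFrame(rows)
    if len(out):
        out = out[
            [
                "task", "band", "feature", "f_stat", "p_raw", "p_fdr",
                "cohens_d", "medium_effect", "significant",
                "n_patient", "n_control",
            ]
        ]
    return out


def summary_report(stats_table: pd.DataFrame, alpha: float = ALPHA) -> str:
    """Human-readable listing of notable rows.

    Stars follow the usual convention (** p < 0.01, * p < alpha on the
    FDR-adjusted p) and ``#`` marks a medium effect (|d| > 0.5); the
    significance and effect-size flags are reported independently, never
    merged.
    """
    lines = ["task | band | feature | p_fdr | d | flags"]
    for _, r in stats_table.iterrows():
        flags = ""
        if r["p_fdr"] < 0.01:
            flags += "**"
        elif r["p_fdr"] < alpha:
            flags += "*"
        if r["medium_effect"]:
            flags += "#"
        if flags:
            lines.append(
                f"{r['task']} | {r['band']} | {r['feature']} | "
                f"{r['p_fdr']:.4f} | {r['cohens_d']:+.2f} | {flags}"
            )
    if len(lines) == 1:
        lines.append("(no significant or medium-effect cells)")
    return "\n".join(lines)
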