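"""Additive subunit/compound factor model for potency and efficacy.

Each (receptor, ligand) summary mean is modelled as

    outcome = intercept + Σ_s β_s · 1[subunit s present] + Σ_c γ_c · 1[ligand = c]

with ACh the reference ligand (its dummy omitted) and the obligatory Dβ1
excluded from the covariates because it is constant across the panel.  Fitted
on the 12-receptor core panel this gives 48 samples and 40 residual degrees of
freedom.  Because every ligand is measured on every receptor the design is
balanced: each ligand coefficient equals the mean outcome difference from ACh,
orthogonal to the subunit terms.

The least-squares solve is delegated to statsmodels OLS; this module owns the
design construction, confidence intervals and the Table-2-shaped summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .receptor_data import LIGANDS, REFERENCE_LIGAND, PotencyEfficacyTable

__all__ = ["DesignSpec", "LinearModelFit", "build_design", "fit_ols", "summarize_fit"]

DEFAULT_SUBUNIT_COVARIATES = ("Da1", "Da2", "Da3", "Db2")


@dataclass(frozen=True)
class DesignSpec:
    """What to regress on what.

    outcome: "pec50" or "imax"; subunit_covariates must exclude any subunit
    constant across the panel (Dβ1).
    """

    outcome: str = "pec50"
    subunit_covariates: tuple = DEFAULT_SUBUNIT_COVARIATES
    reference_ligand: str = REFERENCE_LIGAND
    include_intercept: bool = True

    def __post_init__(self):
        if self.outcome not in ("pec50", "imax"):
            raise ValueError(f"outcome must be 'pec50' or 'imax', got {self.outcome!r}")


@dataclass
class LinearModelFit:
    """OLS fit with per-term inference and fit-quality statistics.

    coefficients: DataFrame indexed by term with columns estimate, se,
    ci_low, ci_high, t, p.  aic / aic_const are the Gaussian-likelihood
    information criterion without (n·ln(RSS/n) + 2k) and with the additive
    constant (statsmodels convention).
    """

    coefficients: pd.DataFrame
    n: int
    df_resid: int
    r2: float
    r2_adj: float
    aic: float
    aic_const: float
    rss: float
    outcome: str

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def ci(self, term: str) -> tuple:
        row = self.coefficients.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def significant(self, term: str) -> bool:
        lo, hi = self.ci(term)
        return not (lo <= 0.0 <= hi)


def build_design(table: PotencyEfficacyTable, spec: Optional[DesignSpec] = None):
    """Design matrix and outcome vector from a core-panel potency table.

    Returns ``(X, y)``: X a DataFrame with an intercept column, one binary
    column per subunit covariate and one dummy per non-reference ligand;
    y the chosen outcome.  One row per (receptor, ligand), ordered by receptor
    then ligand.  Raises on missing cells or a constant covariate column.
    """
    spec = spec or DesignSpec()
    frame = table.frame
    receptors = table.receptors
    ligands = [spec.reference_ligand] + [l for l in LIGANDS if l in set(frame["ligand"])
                                         and l != spec.reference_ligand]
    present = {(r, l) for r, l in zip(frame["receptor"], frame["ligand"])}
    gaps = [(r.canonical, l) for r in receptors for l in ligands if (r, l) not in present]
    if gaps:
        raise ValueError(f"missing (receptor, ligand) cells: {gaps}")

    outcome_col = "pec50_mean" if spec.outcome == "pec50" else "imax_mean"
    rows, y = [], []
    for r in receptors:
        for l in ligands:
            rec = table.lookup(r, l)
            row = {}
            if spec.include_intercept:
                row["intercept"] = 1.0
            for s in spec.subunit_covariates:
                row[s] = float(s in r)
            for l2 in ligands[1:]:
                row[l2] = float(l == l2)
            rows.append(row)
            y.append(float(rec[outcome_col]))
    X = pd.DataFrame(rows)
    yv = pd.Series(y, name=spec.outcome)
    for s in spec.subunit_covariates:
        if X[s].nunique() < 2:
            raise ValueError(f"covariate {s!r} is constant across the panel")
    return X, yv


def fit_ols(X: pd.DataFrame, y: pd.Series, alpha: float = 0.05) -> LinearModelFit:
    """Exact least squares with t-based 100(1−alpha)% confidence intervals."""
    Xv = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify a minimal set of columns that complete the rank deficiency
        bad = []
        cols = list(X.columns)
        kept: list = []
        for j, c in enumerate(cols):
            trial = kept + [j]
            if np.linalg.matrix_rank(Xv[:, trial]) < len(trial):
                bad.append(c)
            else:
                kept = trial
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")

    res = sm.OLS(np.asarray(y, dtype=float), Xv).fit()
    n, k = Xv.shape
    df_resid = n - k
    tq = stats.t.ppf(1.0 - alpha / 2.0, df_resid)
    est = res.params
    se = res.bse
    coeffs = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - tq * se,
            "ci_high": est + tq * se,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=list(X.columns),
    )
    rss = float(res.ssr)
    r2 = float(res.rsquared)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    aic = n * np.log(rss / n) + 2 * k
    return LinearModelFit(
        coefficients=coeffs, n=n, df_resid=df_resid, r2=r2, r2_adj=r2_adj,
        aic=float(aic), aic_const=float(res.aic), rss=rss, outcome=str(y.name),
    )


def fit_factor_model(table: PotencyEfficacyTable, spec: Optional[DesignSpec] = None) -> LinearModelFit:
    """Convenience: build the design from a core panel and fit it."""
    spec = spec or DesignSpec()
    X, y = build_design(table, spec)
    return fit_ols(X, y)


def summarize_fit(fit: LinearModelFit) -> pd.DataFrame:
    """Publication-shaped coefficient table.

    Columns: estimate, 95% CI bounds, and a significance star when the CI
    excludes zero (equivalent to the two-sided t-test at α = 0.05).
    """
    out = fit.coefficients.copy()
    out["significant"] = [
        "*" if not (lo <= 0.0 <= hi) else ""
        for lo, hi in zip(out["ci_low"], out["ci_high"])
    ]
    out.attrs.update(
        r2=fit.r2, r2_adj=fit.r2_adj, aic=fit.aic, n=fit.n, df_resid=fit.df_resid
    )
    return out
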