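"""Hill concentration–response fitting and potency arithmetic.

The agonist model is the three-parameter Hill (logistic in log-concentration)
curve

    Y = Imax / (1 + 10^((logEC50 − X) · nH)),   X = log10[ligand (M)]

with Imax the maximal normalized response (fraction of the maximal ACh
response), EC50 the half-maximal concentration and nH the Hill coefficient.
pEC50 = −log10(EC50).  Fits are nonlinear least squares with a multistart
over a pEC50 grid, because on sparse 6–8-point curves the RSS surface can be
multimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FitConfig",
    "HillFit",
    "hill_response",
    "fit_hill",
    "normalize_responses",
    "NormalizationError",
    "pec50_to_ec50",
    "ec50_nanomolar",
    "fold_change",
]


class NormalizationError(ValueError):
    """Raised when raw currents cannot be normalized (missing/invalid reference)."""


def hill_response(concentration, pec50: float, imax: float, nh: float):
    """Normalized response at molar *concentration* under the Hill model."""
    x = np.log10(np.asarray(concentration, dtype=float))
    return imax / (1.0 + 10.0 ** ((-pec50 - x) * nh))


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for :func:`fit_hill`.

    nh_bounds keeps slopes physical on non-plateau curves; imax_max = 2 allows
    super-maximal responses without letting the plateau run away.  The pEC50
    multistart grid spans the observed concentration range ± grid_margin log
    units at grid_step spacing.
    """

    nh_bounds: tuple = (0.3, 5.0)
    imax_max: float = 2.0
    grid_margin: float = 1.0
    grid_step: float = 0.5
    ftol: float = 1e-10
    plateau_fraction: float = 0.9  # top response below this × Imax ⇒ extrapolated plateau


@dataclass
class HillFit:
    """Estimated Hill parameters with asymptotic standard errors."""

    pec50: float
    imax: float
    nh: float
    se_pec50: float
    se_imax: float
    se_nh: float
    rss: float
    converged: bool
    n_points: int
    extrapolated_plateau: bool = False

    def predict(self, concentration):
        return hill_response(concentration, self.pec50, self.imax, self.nh)

    @property
    def ec50(self) -> float:
        return pec50_to_ec50(self.pec50)


def _start_points(conc: np.ndarray, resp: np.ndarray, cfg: FitConfig):
    logc = np.log10(conc)
    lo, hi = logc.min() - cfg.grid_margin, logc.max() + cfg.grid_margin
    pec_grid = -np.arange(lo, hi + 1e-9, cfg.grid_step)[::-1]
    imax0 = float(np.clip(resp.max(), 0.01, cfg.imax_max))
    return [(p, imax0, 1.0) for p in pec_grid]


def fit_hill(
    concentrations: Sequence[float],
    responses: Sequence[float],
    config: Optional[FitConfig] = None,
) -> HillFit:
    """Least-squares Hill fit of normalized responses vs molar concentrations.

    Requires at least 4 distinct concentrations.  Deterministic: the
    multistart grid is derived from the data, not from randomness.  If no
    start converges the best candidate is still returned with
    ``converged=False`` rather than raising.
    """
    cfg = config or FitConfig()
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (molar)")
    if np.any(resp < 0):
        raise ValueError("responses must be non-negative")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit 3 parameters")

    logc = np.log10(conc)
    # pec50 confined to one decade beyond the multistart grid: an EC50
    # further outside the tested window is pure extrapolation
    pec_lo = -logc.max() - cfg.grid_margin - 1.0
    pec_hi = -logc.min() + cfg.grid_margin + 1.0
    bounds = ([pec_lo, 1e-6, cfg.nh_bounds[0]], [pec_hi, cfg.imax_max, cfg.nh_bounds[1]])

    def residuals(theta):
        return hill_response(conc, *theta) - resp

    best = None
    for theta0 in _start_points(conc, resp, cfg):
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            sol = least_squares(residuals, theta0, bounds=bounds, ftol=cfg.ftol,
                                xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("all multistart fits failed")
    rss, sol = best

    n, p = len(resp), 3
    ses = np.full(3, np.nan)
    if n > p:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / (n - p))
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            pass

    pec50, imax, nh = (float(v) for v in sol.x)
    # mean response at the top concentration, vs fitted plateau
    top = conc == conc.max()
    extrapolated = bool(resp[top].mean() < cfg.plateau_fraction * imax)
    return HillFit(
        pec50=pec50, imax=imax, nh=nh,
        se_pec50=float(ses[0]), se_imax=float(ses[1]), se_nh=float(ses[2]),
        rss=rss, converged=bool(sol.success), n_points=int(n),
        extrapolated_plateau=extrapolated,
    )


def normalize_responses(
    records: pd.DataFrame,
    ach_reference: Mapping[str, float],
) -> pd.DataFrame:
    """Divide each oocyte's raw peak currents by its maximal ACh current.

    *records* is a concentration–response frame with columns ``oocyte_id``,
    ``response`` and ``response_kind``; rows flagged ``raw_uA`` are divided by
    ``ach_reference[oocyte_id]`` (the plateau ACh response of that oocyte) and
    re-flagged ``normalized``.  Raises :class:`NormalizationError` naming every
    oocyte that lacks a positive reference.
    """
    out = records.copy()
    raw = out["response_kind"] == "raw_uA"
    ids = out.loc[raw, "oocyte_id"].unique()
    bad = [str(i) for i in ids
           if i not in ach_reference or not ach_reference[i] > 0]
    if bad:
        raise NormalizationError(
            f"missing or non-positive ACh reference for oocytes: {sorted(bad)}"
        )
    refs = out.loc[raw, "oocyte_id"].map(ach_reference).astype(float)
    out.loc[raw, "response"] = out.loc[raw, "response"].astype(float) / refs
    out.loc[raw, "response_kind"] = "normalized"
    return out


def pec50_to_ec50(pec50: float) -> float:
    """EC50 in molar from pEC50 = −log10(EC50)."""
    if not np.isfinite(pec50):
        raise ValueError("pEC50 must be finite")
    return 10.0 ** (-float(pec50))


def ec50_nanomolar(pec50: float) -> float:
    """Convenience nanomolar rendering of the EC50."""
    return pec50_to_ec50(pec50) * 1e9


def fold_change(pec50_high: float, pec50_low: float) -> float:
    """EC50 ratio 10^(pEC50_high − pEC50_low): how many-fold more potent."""
    if not (np.isfinite(pec50_high) and np.isfinite(pec50_low)):
        raise ValueError("pEC50 values must be finite")
    return 10.0 ** (float(pec50_high) - float(pec50_low))
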