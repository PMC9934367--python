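"""Ground-truth-known synthetic electrophysiology data.

The generator mirrors the study design in reverse: a subunit-additive pEC50
surface (the generative inverse of the factor model), compound-specific true
efficacies, and Hill-shaped per-oocyte concentration–response curves with
Gaussian response noise, five oocytes per curve.  Every pipeline stage —
Hill fitting, factor model, CHAID, lattice — can therefore be checked against
configured truth without any external data.

Defaults are the study's own conditions: subunit effects and compound offsets
from the fitted potency factor model, compound efficacies at the panel means,
σ = 0.03 on the normalized response (the scale of the published standard
errors), n = 5 oocytes, and 8 half-log-spaced concentrations bracketing each
curve's EC50 (as the measured dilution series did; a shared panel-wide grid
is available instead via ``NoiseConfig.concentrations``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import factor_model, hill
from .receptor_data import (
    LIGANDS,
    REFERENCE_LIGAND,
    PotencyEfficacyTable,
    SubunitSet,
    parse_subunit_set,
)

__all__ = [
    "CORE_PANEL_RECEPTORS",
    "TruthConfig",
    "NoiseConfig",
    "generate_truth",
    "simulate_curves",
    "fit_panel",
    "recovery_experiment",
]

#: The 12 functional receptors of the core panel: every non-empty combination
#: of Dα1/Dα2/Dα3 observed in the study (Dα2 never expresses without another
#: alpha), with obligatory Dβ1, with and without Dβ2.
CORE_PANEL_RECEPTORS = tuple(
    parse_subunit_set(s)
    for alpha in ("Da1", "Da3", "Da1/Da3", "Da1/Da2", "Da2/Da3", "Da1/Da2/Da3")
    for s in (f"{alpha}/Db1", f"{alpha}/Db1/Db2")
)


def _default_subunit_effects() -> dict:
    return {
        "Da1": -0.306, "Da2": -0.754, "Da3": 0.524, "Db2": 0.092,
        "Db1": 0.0,  # obligatory, constant across the panel
    }


def _default_compound_offsets() -> dict:
    return {"imidacloprid": 1.414, "thiacloprid": 1.785, "clothianidin": 2.229}


def _default_compound_imax() -> dict:
    # reference ligand 1 by normalization; neonicotinoids at the panel means
    return {REFERENCE_LIGAND: 1.0, "imidacloprid": 0.119,
            "thiacloprid": 0.049, "clothianidin": 0.667}


@dataclass
class TruthConfig:
    """True additive potency surface and per-compound efficacy."""

    subunit_effects: dict = field(default_factory=_default_subunit_effects)
    intercept: float = 6.96
    compound_offsets: dict = field(default_factory=_default_compound_offsets)
    compound_imax: dict = field(default_factory=_default_compound_imax)
    nh_range: tuple = (1.0, 2.0)
    receptors: tuple = CORE_PANEL_RECEPTORS
    seed: int = 0

    def __post_init__(self):
        if self.compound_offsets.get(REFERENCE_LIGAND, 0.0) != 0.0:
            raise ValueError("reference ligand offset must be 0")
        if self.compound_imax.get(REFERENCE_LIGAND, 1.0) != 1.0:
            raise ValueError("reference ligand Imax must be 1")
        nonfunc = [r.canonical for r in self.receptors if not r.is_functional]
        if nonfunc:
            raise ValueError(f"receptors lacking the essential Db1: {nonfunc}")


@dataclass
class NoiseConfig:
    """Measurement model: replicate oocytes and Gaussian response noise."""

    response_sigma: float = 0.03
    n_oocytes: int = 5
    #: explicit shared molar grid; None = 8 half-log steps bracketing each
    #: curve's own true EC50, as the measured concentration ranges did
    concentrations: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.response_sigma < 0:
            raise ValueError("response_sigma must be >= 0")
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")


def generate_truth(config: Optional[TruthConfig] = None) -> PotencyEfficacyTable:
    """Deterministic truth panel: pEC50 = intercept + Σ subunit effects + offset.

    The returned table has SE columns of 0 and an extra ``nh`` column with the
    true Hill slope of each curve, drawn reproducibly from ``nh_range`` using
    the config seed.
    """
    cfg = config or TruthConfig()
    ligands = [REFERENCE_LIGAND] + list(cfg.compound_offsets)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rec in cfg.receptors:
        missing = [s for s in sorted(rec.members) if s not in cfg.subunit_effects]
        if missing:
            raise ValueError(f"no configured effect for subunits {missing} in {rec.canonical}")
        base = cfg.intercept + sum(cfg.subunit_effects[s] for s in rec.members)
        for lig in ligands:
            offset = 0.0 if lig == REFERENCE_LIGAND else cfg.compound_offsets[lig]
            if lig not in cfg.compound_imax:
                raise ValueError(f"no configured Imax for ligand {lig!r}")
            rows.append({
                "receptor": rec, "ligand": lig,
                "pec50_mean": base + offset, "pec50_se": 0.0,
                "imax_mean": cfg.compound_imax[lig], "imax_se": 0.0,
                "n": 0, "core_panel": True,
                "nh": float(rng.uniform(*cfg.nh_range)),
            })
    return PotencyEfficacyTable(pd.DataFrame(rows))


_GRID_OFFSETS = np.arange(-1.75, 1.76, 0.5)  # 8 half-log steps


def curve_grid(pec50: float) -> np.ndarray:
    """8 half-log-spaced molar concentrations bracketing one curve's EC50."""
    return 10.0 ** (-float(pec50) + _GRID_OFFSETS)


def shared_median_grid(truth: PotencyEfficacyTable) -> np.ndarray:
    """One shared grid centered on the panel's median EC50.

    Convenience for emulating a fixed dilution series across the whole panel;
    note that on panels spanning several potency decades the extreme curves
    are then poorly covered and their fits degrade accordingly.
    """
    med = float(np.median(truth.frame["pec50_mean"]))
    return curve_grid(med)


def simulate_curves(
    truth: PotencyEfficacyTable,
    noise: Optional[NoiseConfig] = None,
) -> pd.DataFrame:
    """Per-oocyte normalized responses on the Hill curves of a truth panel.

    response = Hill(pEC50, Imax, nH) + N(0, σ), truncated at 0 (currents are
    not negative).  Fully reproducible from ``noise.seed``.
    """
    cfg = noise or NoiseConfig()
    shared = (np.asarray(cfg.concentrations, dtype=float)
              if cfg.concentrations is not None else None)
    rng = np.random.default_rng(cfg.seed)
    has_nh = "nh" in truth.frame.columns
    rows = []
    for _, rec in truth.frame.iterrows():
        nh = float(rec["nh"]) if has_nh else 1.5
        conc = shared if shared is not None else curve_grid(rec["pec50_mean"])
        clean = hill.hill_response(conc, float(rec["pec50_mean"]),
                                   float(rec["imax_mean"]), nh)
        for k in range(cfg.n_oocytes):
            noisy = clean + rng.normal(0.0, cfg.response_sigma, size=clean.shape) \
                if cfg.response_sigma > 0 else clean.copy()
            noisy = np.clip(noisy, 0.0, None)
            for c, y in zip(conc, noisy):
                rows.append({
                    "oocyte_id": f"{rec['receptor'].canonical}|{rec['ligand']}|oo{k + 1}",
                    "receptor": rec["receptor"].canonical,
                    "ligand": rec["ligand"],
                    "concentration_molar": float(c),
                    "response": float(y),
                    "response_kind": "normalized",
                })
    return pd.DataFrame(rows)


def fit_panel(
    records: pd.DataFrame,
    fit_config: Optional[hill.FitConfig] = None,
    n: Optional[int] = None,
) -> PotencyEfficacyTable:
    """Pool each (receptor, ligand)'s oocytes and Hill-fit every curve.

    Reference-ligand Imax is entered as 1.0 in the resulting panel, as the
    normalization rule defines; all other summaries come from the fits.
    """
    rows = []
    for (rec, lig), grp in records.groupby(["receptor", "ligand"], sort=True):
        fit = hill.fit_hill(grp["concentration_molar"], grp["response"], fit_config)
        rows.append({
            "receptor": rec, "ligand": lig,
            "pec50_mean": fit.pec50, "pec50_se": fit.se_pec50,
            "imax_mean": 1.0 if lig == REFERENCE_LIGAND else fit.imax,
            "imax_se": 0.0 if lig == REFERENCE_LIGAND else fit.se_imax,
            "n": n if n is not None else grp["oocyte_id"].nunique(),
            "core_panel": True,
            "nh": fit.nh,
        })
    return PotencyEfficacyTable(pd.DataFrame(rows))


def recovery_experiment(
    truth_cfg: Optional[TruthConfig] = None,
    noise_cfg: Optional[NoiseConfig] = None,
    n_reps: int = 1,
    fit_config: Optional[hill.FitConfig] = None,
) -> dict:
    """Simulate → Hill-fit → factor-model, repeatedly; score parameter recovery.

    Returns a dict with per-subunit bias, RMSE and 95% CI coverage of the
    configured effects, plus the overall pEC50 bias/RMSE of the Hill stage.
    Replicate r uses noise seed ``noise_cfg.seed + r``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tcfg = truth_cfg or TruthConfig()
    ncfg = noise_cfg or NoiseConfig()
    truth = generate_truth(tcfg)
    true_pec50 = {
        (r["receptor"], r["ligand"]): float(r["pec50_mean"])
        for _, r in truth.frame.iterrows()
    }
    subunits = [s for s in factor_model.DEFAULT_SUBUNIT_COVARIATES
                if s in tcfg.subunit_effects]
    est = {s: [] for s in subunits}
    covered = {s: [] for s in subunits}
    pec50_errors = []
    pec50_errors_by_ligand: dict = {}
    for rep in range(n_reps):
        rep_noise = NoiseConfig(
            response_sigma=ncfg.response_sigma, n_oocytes=ncfg.n_oocytes,
            concentrations=ncfg.concentrations, seed=ncfg.seed + rep,
        )
        records = simulate_curves(truth, rep_noise)
        fitted = fit_panel(records, fit_config)
        for _, r in fitted.frame.iterrows():
            err = float(r["pec50_mean"]) - true_pec50[(r["receptor"], r["ligand"])]
            pec50_errors.append(err)
            pec50_errors_by_ligand.setdefault(r["ligand"], []).append(err)
        lm = factor_model.fit_factor_model(fitted, factor_model.DesignSpec("pec50"))
        for s in subunits:
            est[s].append(lm.coef(s))
            lo, hi = lm.ci(s)
            covered[s].append(lo <= tcfg.subunit_effects[s] <= hi)
    report = {"n_reps": n_reps, "subunits": {}}
    for s in subunits:
        e = np.array(est[s])
        truth_s = tcfg.subunit_effects[s]
        report["subunits"][s] = {
            "truth": truth_s,
            "bias": float(e.mean() - truth_s),
            "rmse": float(np.sqrt(((e - truth_s) ** 2).mean())),
            "ci_coverage": float(np.mean(covered[s])),
        }
    err = np.array(pec50_errors)
    report["hill_pec50"] = {
        "bias": float(err.mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
    }
    report["hill_pec50_by_ligand"] = {
        lig: {
            "bias": float(np.mean(e)),
            "rmse": float(np.sqrt(np.mean(np.square(e)))),
            "true_imax": float(tcfg.compound_imax.get(lig, 1.0)),
        }
        for lig, e in sorted(pec50_errors_by_ligand.items())
    }
    return report
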