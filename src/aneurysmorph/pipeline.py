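"""End-to-end study replication on any cohort table.

Stages: sphericity screen -> per-record morphometric indices (uncorrected and
height-corrected) -> per-index ROC / likelihood-ratio analysis -> all-site and
per-site logistic fits on WTR and WTR' -> inversion to the critical value and
comparison against the theoretical rupture threshold WTR = 6.1e-3 predicted by
the thin-spherical-shell mechanical model.

The height-corrected ("primed") analysis divides the measured height of
ruptured records by 1.149, removing average post-rupture inflation; unruptured
heights are never touched.  BF has no corrected variant (it does not involve
height).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import stats
from .cohort_io import CohortTable, SITES, per_record_indices
from .morphometrics import (
    DEFAULT_WALL_MODEL,
    SPHERICITY_THRESHOLD,
    VesselWallModel,
    screen_spherical,
)
from .stats import GroupComparison, LogisticModel, RocAnalysis

__all__ = [
    "THEORETICAL_CRITICAL_WTR",
    "THEORETICAL_CRITICAL_WTR_NOTE",
    "AnalysisConfig",
    "LogisticFit",
    "AnalysisReport",
    "run_analysis",
    "compare_to_theory",
    "wall_thickness_at",
]

#: Critical wall-thickness-to-radius ratio at which a thin spherical shell
#: with Fung-type wall material at ~1 MPa rupture stress is predicted to fail
#: (Chaudhry et al.'s mechanical derivation; imported here as a reference
#: constant, not re-derived).
THEORETICAL_CRITICAL_WTR = 6.1e-3
THEORETICAL_CRITICAL_WTR_NOTE = (
    "Theoretical rupture threshold for a thin spherical shell "
    "(Fung strain-energy wall model, rupture stress ~1 MPa); "
    "used as an external reference value."
)

#: ROC orientation per index: rupture associates with LOWER WTR-family values
#: and HIGHER aspect-ratio-family values.
INDEX_ORIENTATIONS: dict[str, str] = {
    "WTR": "lower_is_ruptured",
    "AR": "higher_is_ruptured",
    "BF": "higher_is_ruptured",
    "SR": "higher_is_ruptured",
    "WTR_prime": "lower_is_ruptured",
    "AR_prime": "higher_is_ruptured",
    "SR_prime": "higher_is_ruptured",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline."""

    sphericity_threshold: float = SPHERICITY_THRESHOLD
    wall_model: VesselWallModel = DEFAULT_WALL_MODEL
    #: user-supplied operating cutoffs per index (raw index scale); indices
    #: absent here use the Youden-optimal cutoff.
    cutoffs: dict = field(default_factory=dict)
    auc_ci_method: str = "delong"
    n_boot: int = 2000
    or_delta: float = 0.001
    theoretical_wtr: float = THEORETICAL_CRITICAL_WTR
    seed: int = 0


@dataclass(frozen=True)
class LogisticFit:
    """One logistic fit slot (an index on all sites or one site)."""

    index_name: str
    site: str  # "all" or a site label
    status: str  # "ok", "insufficient", "separated", "failed"
    model: Optional[LogisticModel] = None
    critical_value: float = math.nan
    or_per_delta: float = math.nan
    delta: float = 0.001


@dataclass
class AnalysisReport:
    """Everything the replication computes on one cohort."""

    cohort_summary: dict
    group_comparisons: list[GroupComparison]
    roc: dict[str, RocAnalysis]
    logistic: list[LogisticFit]
    theoretical_reference: float
    theoretical_note: str
    percent_differences: dict[str, float]
    indices: pd.DataFrame
    n_excluded_by_screen: int = 0

    def logistic_fit(self, index_name: str, site: str = "all") -> LogisticFit:
        for f in self.logistic:
            if f.index_name == index_name and f.site == site:
                return f
        raise KeyError(f"no logistic fit for {index_name!r} at site {site!r}")

    def logistic_table(self) -> pd.DataFrame:
        rows = []
        for f in self.logistic:
            m = f.model
            rows.append(
                {
                    "index_name": f.index_name,
                    "site": f.site,
                    "status": f.status,
                    "beta0": m.beta0 if m else math.nan,
                    "beta1": m.beta1 if m else math.nan,
                    "se_beta0": m.se_beta0 if m else math.nan,
                    "se_beta1": m.se_beta1 if m else math.nan,
                    "critical_value": f.critical_value,
                    f"or_per_{f.delta:g}": f.or_per_delta,
                    "p_value": m.p_value if m else math.nan,
                    "n": m.n if m else 0,
                    "n_iter": m.n_iter if m else 0,
                }
            )
        return pd.DataFrame(rows)

    def comparisons_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    "test": c.test,
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_value": c.p_value,
                    "n": c.n,
                }
                for c in self.group_comparisons
            ]
        )

    def summary_dict(self) -> dict:
        """Headline numbers for the human-readable JSON summary."""
        out = {
            "screen_excluded": self.n_excluded_by_screen,
            "theoretical_wtr": self.theoretical_reference,
            "percent_difference_vs_theory": dict(self.percent_differences),
            "roc": {
                name: {
                    "auc": r.auc,
                    "auc_ci": list(r.auc_ci),
                    "cutoff": r.chosen_cutoff,
                    "sensitivity": r.sens,
                    "specificity": r.spec,
                    "positive_lr": r.positive_lr,
                    "lr_ci": list(r.lr_ci),
                }
                for name, r in self.roc.items()
            },
            "logistic": {
                f"{f.index_name}[{f.site}]": {
                    "status": f.status,
                    "beta0": f.model.beta0 if f.model else None,
                    "beta1": f.model.beta1 if f.model else None,
                    "critical_value": f.critical_value if f.model else None,
                    "p_value": f.model.p_value if f.model else None,
                }
                for f in self.logistic
            },
        }
        return out


def _fit_slot(index_name, site, x, y, delta) -> LogisticFit:
    y = np.asarray(y, dtype=bool)
    if len(y) < 4 or y.sum() < 2 or (~y).sum() < 2:
        return LogisticFit(index_name, site, "insufficient")
    try:
        model = stats.fit_logistic(x, y.astype(float), index_name=index_name)
    except stats.SeparationError:
        return LogisticFit(index_name, site, "separated")
    except (stats.ConvergenceError, ValueError):
        return LogisticFit(index_name, site, "failed")
    return LogisticFit(
        index_name,
        site,
        "ok",
        model=model,
        critical_value=stats.critical_value(model),
        or_per_delta=stats.odds_ratio_per_delta(model, delta),
        delta=delta,
    )


def _group_comparisons(kept: CohortTable, indices: pd.DataFrame) -> list[GroupComparison]:
    out: list[GroupComparison] = []
    df = kept.to_dataframe()
    df["neck_mm"] = np.sqrt(df["d1_mm"] * df["d2_mm"])
    rupt = df["ruptured"] == 1
    for col, label in [
        ("h_mm", "h"), ("w_mm", "w"), ("r_mm", "r"), ("neck_mm", "neck_geometric_mean"),
    ]:
        a, b = df.loc[rupt, col], df.loc[~rupt, col]
        if len(a) >= 2 and len(b) >= 2:
            out.append(stats.welch_t_test(a, b, variable=label))
    # categorical: site, modality, smoking, hypertension vs rupture status
    for col in ("site", "modality", "smoking", "hypertension"):
        sub = df[[col, "ruptured"]].dropna()
        if sub.empty:
            continue
        table = pd.crosstab(sub["ruptured"], sub[col])
        table = table.loc[:, (table.sum(axis=0) > 0)]
        if table.shape[0] == 2 and table.shape[1] >= 2:
            try:
                out.append(stats.chi_squared_test(table.to_numpy(), variable=col))
            except ValueError:
                pass
    return out


def run_analysis(cohort: CohortTable, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full replication on a cohort table.

    Raises if, after the sphericity screen, fewer than 2 ruptured or 2
    unruptured records remain (nothing can be discriminated); a single-class
    *site* is merely flagged "insufficient" in its per-site logistic slot.
    """
    cfg = config or AnalysisConfig()
    kept, excluded = screen_spherical(cohort, cfg.sphericity_threshold)
    n_r, n_u = kept.n_ruptured, kept.n_unruptured
    if n_r < 2 or n_u < 2:
        raise ValueError(
            f"cohort must retain >= 2 records of each rupture status after the "
            f"sphericity screen (got {n_r} ruptured / {n_u} unruptured)"
        )

    indices = per_record_indices(kept, model=cfg.wall_model)
    y = indices["ruptured"].to_numpy(dtype=bool)

    roc: dict[str, RocAnalysis] = {}
    for name, orientation in INDEX_ORIENTATIONS.items():
        roc[name] = stats.roc_analysis(
            name,
            indices[name].to_numpy(),
            y,
            orientation,  # type: ignore[arg-type]
            cutoff=cfg.cutoffs.get(name),
            ci_method=cfg.auc_ci_method,  # type: ignore[arg-type]
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )

    fits: list[LogisticFit] = []
    for name in ("WTR", "WTR_prime"):
        x = indices[name].to_numpy()
        fits.append(_fit_slot(name, "all", x, y, cfg.or_delta))
        for site in SITES:
            mask = (indices["site"] == site).to_numpy()
            fits.append(_fit_slot(name, site, x[mask], y[mask], cfg.or_delta))

    pct: dict[str, float] = {}
    for name in ("WTR", "WTR_prime"):
        f = next(f for f in fits if f.index_name == name and f.site == "all")
        if f.status == "ok":
            pct[name] = stats.percent_difference(cfg.theoretical_wtr, f.critical_value)

    summary = {
        "n_records": len(kept),
        "n_ruptured": n_r,
        "n_unruptured": n_u,
        "by_site": {
            site: {
                "ruptured": sum(1 for rec in kept if rec.site == site and rec.ruptured),
                "unruptured": sum(1 for rec in kept if rec.site == site and not rec.ruptured),
            }
            for site in SITES
        },
    }

    return AnalysisReport(
        cohort_summary=summary,
        group_comparisons=_group_comparisons(kept, indices),
        roc=roc,
        logistic=fits,
        theoretical_reference=cfg.theoretical_wtr,
        theoretical_note=THEORETICAL_CRITICAL_WTR_NOTE,
        percent_differences=pct,
        indices=indices,
        n_excluded_by_screen=len(excluded),
    )


def compare_to_theory(
    model: LogisticModel, reference: float = THEORETICAL_CRITICAL_WTR
) -> tuple[float, str]:
    """Percent difference between the theoretical threshold and the fitted
    critical value, with a one-line narrative."""
    crit = stats.critical_value(model)
    pct = stats.percent_difference(reference, crit)
    verdict = (
        f"fitted critical {model.index_name} = {crit:.3g}; the theoretical "
        f"threshold {reference:.3g} differs from it by {pct:.1f}%"
    )
    return pct, verdict


def wall_thickness_at(critical_wtr: float, R_dome_mm: float) -> float:
    """Dome wall thickness t_A = WTR x R_dome implied by a critical ratio,
    for a dome of the given radius; returned in micrometres."""
    if critical_wtr <= 0 or R_dome_mm <= 0:
        raise ValueError("critical WTR and dome radius must be positive")
    return critical_wtr * R_dome_mm * 1000.0
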