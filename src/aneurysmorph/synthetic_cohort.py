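"""Synthetic measurement cohorts with the statistical structure the analysis
assumes.

The study's patient measurements are not publicly deposited, so downstream
stages are exercised on generated cohorts that emulate their documented
structure: millimetre-scale log-normal morphometry, near-spherical domes
(|h - w| / (h + w) < 0.2 by construction), rupture labels Bernoulli-linked to
WTR through a logistic model, optional 14.9% post-rupture height inflation of
ruptured records, and site / covariate mixes.

Two sampling schemes are provided:

* :func:`generate_cohort` — case-control style: records are drawn and labelled
  until configured group sizes (default 52 unruptured / 28 ruptured) are met,
  mirroring a pre-stratified retrospective design.
* :func:`generate_prospective_cohort` — a fixed number of records, each
  labelled by a Bernoulli draw from the link.  This is the scheme under which
  the logistic intercept (and hence the critical value) is directly
  identifiable, so parameter-recovery and null-behaviour experiments use it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cohort_io import AneurysmRecord, CohortTable, SITES
from .morphometrics import (
    DEFAULT_WALL_MODEL,
    HEIGHT_INFLATION_FACTOR,
    VesselWallModel,
)

__all__ = [
    "LogNormalLaw",
    "CohortConfig",
    "generate_cohort",
    "generate_prospective_cohort",
    "generate_confusion_cohort",
]


@dataclass(frozen=True)
class LogNormalLaw:
    """Log-normal law parameterized by median (mm) and geometric SD (>= 1)."""

    median: float
    gsd: float

    def __post_init__(self):
        if self.median <= 0:
            raise ValueError("median must be positive")
        if self.gsd < 1:
            raise ValueError("geometric SD must be >= 1")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.gsd == 1.0:
            return np.full(size, self.median)
        return rng.lognormal(math.log(self.median), math.log(self.gsd), size)


@dataclass(frozen=True)
class CohortConfig:
    """Free parameters of the cohort generator.

    Defaults: group sizes 52 unruptured / 28 ruptured (the study cohort);
    site mix matching the study's 51/15/14 BT/Acom/Pcom split; morphometry
    medians h = 6 mm, neck = 4 mm, r = 1.3 mm (plausible-scale choices that
    put the WTR distribution in the regime of the fitted rupture models and
    keep r far below the vessel-wall model's validity bound); width coupling
    w = h (1 + u), u ~ U(-0.18, 0.18), so every record passes the sphericity
    screen; link (0.577, -72.8), the all-site fitted rupture model on WTR.
    """

    n_unruptured: int = 52
    n_ruptured: int = 28
    site_mix: tuple[float, float, float] = (51 / 80, 15 / 80, 14 / 80)  # BT, Acom, Pcom
    height_law: LogNormalLaw = LogNormalLaw(6.0, 1.35)
    neck_law: LogNormalLaw = LogNormalLaw(4.0, 1.25)
    radius_law: LogNormalLaw = LogNormalLaw(1.3, 1.2)
    width_coupling: float = 0.18  # u ~ U(-c, c), w = h (1 + u)
    neck_eccentricity_max: float = 1.3  # d1/d2 <= max^2
    link_beta0: float = 0.577
    link_beta1: float = -72.8
    apply_rupture_inflation: bool = True
    smoking_prevalence: float = 0.80
    hypertension_prevalence: float = 0.79
    modality_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # CTA, MRA, DSA
    wall_model: VesselWallModel = DEFAULT_WALL_MODEL
    seed: int = 0

    def __post_init__(self):
        if self.n_unruptured < 0 or self.n_ruptured < 0:
            raise ValueError("group sizes must be non-negative")
        for name, mix in (("site_mix", self.site_mix), ("modality_mix", self.modality_mix)):
            if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 3 non-negative probabilities summing to 1")
        if not 0 <= self.width_coupling < 1:
            raise ValueError("width_coupling must lie in [0, 1)")
        if self.neck_eccentricity_max < 1:
            raise ValueError("neck_eccentricity_max must be >= 1")


def _draw_morphometry(rng: np.random.Generator, cfg: CohortConfig, size: int):
    """Vector draw of (h, w, d1, d2, r); r is redrawn while outside the
    wall-model validity bound so every record passes the t_V guard."""
    h = cfg.height_law.sample(rng, size)
    neck = cfg.neck_law.sample(rng, size)
    r = cfg.radius_law.sample(rng, size)
    bound = cfg.wall_model.max_radius
    for _ in range(100):
        bad = r >= bound
        if not bad.any():
            break
        r[bad] = cfg.radius_law.sample(rng, int(bad.sum()))
    else:
        raise RuntimeError("radius law places too much mass beyond the wall-model bound")
    u = rng.uniform(-cfg.width_coupling, cfg.width_coupling, size)
    w = h * (1.0 + u)
    ecc = rng.uniform(1.0, cfg.neck_eccentricity_max, size)
    d1, d2 = neck * ecc, neck / ecc
    return h, w, d1, d2, r


def _wtr(h, w, d1, d2, r, model: VesselWallModel):
    t_v = (model.slope * r + model.intercept) * (2.0 * r)
    t_a = d1 * d2 / (4.0 * h * w) * t_v
    return t_a / (np.sqrt(h * w) / 2.0)


def _records_from_arrays(rng, cfg, h, w, d1, d2, r, ruptured, id_offset=0):
    sites = rng.choice(np.array(SITES), size=len(h), p=np.array(cfg.site_mix))
    modalities = rng.choice(
        np.array(["CTA", "MRA", "DSA"]), size=len(h), p=np.array(cfg.modality_mix)
    )
    smoking = rng.random(len(h)) < cfg.smoking_prevalence
    hypertension = rng.random(len(h)) < cfg.hypertension_prevalence
    recs = []
    for i in range(len(h)):
        hi = h[i] * HEIGHT_INFLATION_FACTOR if (ruptured[i] and cfg.apply_rupture_inflation) else h[i]
        recs.append(
            AneurysmRecord(
                id=f"s{id_offset + i + 1:05d}",
                h=float(hi),
                w=float(w[i]),
                d1=float(d1[i]),
                d2=float(d2[i]),
                r=float(r[i]),
                site=str(sites[i]),
                ruptured=bool(ruptured[i]),
                modality=str(modalities[i]),
                smoking=bool(smoking[i]),
                hypertension=bool(hypertension[i]),
            )
        )
    return recs


def generate_cohort(config: CohortConfig | None = None, **overrides) -> CohortTable:
    """Case-control cohort with exact group sizes, deterministic given the seed.

    Morphometry is drawn from the configured laws, WTR computed, and a
    provisional rupture label drawn ~ Bernoulli(link(WTR)); records are
    accepted into the ruptured / unruptured group until each configured size
    is met (rejection within fixed margins, mirroring a pre-stratified
    design).  If ``apply_rupture_inflation``, the measured height of ruptured
    records is then multiplied by 1.149 to emulate post-rupture measurement.
    """
    cfg = replace(config, **overrides) if config is not None else CohortConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)
    need_r, need_u = cfg.n_ruptured, cfg.n_unruptured
    got = {True: [], False: []}
    total_needed = need_r + need_u
    max_rounds = 200
    for _ in range(max_rounds):
        if len(got[True]) >= need_r and len(got[False]) >= need_u:
            break
        batch = max(64, 2 * total_needed)
        h, w, d1, d2, r = _draw_morphometry(rng, cfg, batch)
        wtr = _wtr(h, w, d1, d2, r, cfg.wall_model)
        p = 1.0 / (1.0 + np.exp(-(cfg.link_beta0 + cfg.link_beta1 * wtr)))
        y = rng.random(batch) < p
        for i in range(batch):
            got[bool(y[i])].append((h[i], w[i], d1[i], d2[i], r[i]))
    else:
        raise RuntimeError(
            "could not reach the configured group sizes: the link is too extreme "
            "for the morphometry laws"
        )
    rows = [got[False][i] for i in range(need_u)] + [got[True][i] for i in range(need_r)]
    ruptured = np.array([False] * need_u + [True] * need_r)
    arr = np.array(rows, dtype=float).reshape(len(rows), 5)
    recs = _records_from_arrays(
        rng, cfg, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4], ruptured
    )
    return CohortTable(records=recs, provenance=f"synthetic case-control (seed={cfg.seed})")


def generate_prospective_cohort(n: int, config: CohortConfig | None = None, **overrides) -> CohortTable:
    """Cohort of ``n`` records with rupture labels drawn directly from the link.

    Unlike :func:`generate_cohort` the class sizes are random; the logistic
    intercept is identifiable without a case-control offset, so use this for
    parameter-recovery experiments.
    """
    cfg = replace(config, **overrides) if config is not None else CohortConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)
    h, w, d1, d2, r = _draw_morphometry(rng, cfg, n)
    wtr = _wtr(h, w, d1, d2, r, cfg.wall_model)
    p = 1.0 / (1.0 + np.exp(-(cfg.link_beta0 + cfg.link_beta1 * wtr)))
    y = rng.random(n) < p
    recs = _records_from_arrays(rng, cfg, h, w, d1, d2, r, y)
    return CohortTable(records=recs, provenance=f"synthetic prospective (seed={cfg.seed})")


def generate_confusion_cohort(
    tp: int, fn: int, tn: int, fp: int, cutoff: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic labelled scores realizing exact confusion counts.

    Under the ``lower_is_ruptured`` convention (score <= cutoff is called
    positive): tp cases and fp controls are placed just below the cutoff, fn
    cases and tn controls just above.  Returns ``(scores, labels)`` suitable
    for :func:`aneurysmorph.stats.sens_spec_at_cutoff` and friends.
    """
    for name, c in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if c < 0:
            raise ValueError(f"{name} must be non-negative")
    eps = max(abs(cutoff), 1.0) * 1e-3
    scores = np.concatenate(
        [
            np.full(tp, cutoff - eps),
            np.full(fn, cutoff + eps),
            np.full(tn, cutoff + eps),
            np.full(fp, cutoff - eps),
        ]
    )
    labels = np.concatenate(
        [np.ones(tp + fn, dtype=bool), np.zeros(tn + fp, dtype=bool)]
    )
    return scores, labels
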