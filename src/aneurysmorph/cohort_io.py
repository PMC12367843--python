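"""Reading, validating and writing per-aneurysm measurement tables.

The on-disk format is one bit-exact CSV dialect: comma-separated, UTF-8, dot
decimal, one header row with columns

    id,h_mm,w_mm,d1_mm,d2_mm,r_mm,site,ruptured,modality,smoking,hypertension

(``modality``, ``smoking`` and ``hypertension`` optional, plus an optional
``vessel_choice`` column recording which candidate vessel supplied r).  All
lengths are millimetres.  The reader canonicalizes the two perpendicular neck
diameters so that ``d1`` is the major axis; every downstream formula is
symmetric in (d1, d2), so this is cosmetic but stabilizes output.

The parent-vessel selection rule — when an aneurysm arises at least partially
from a branch vessel, the smaller of the two candidate vessels is the parent —
is applied at data-preparation time through :func:`resolve_parent_radius`, so
the morphometry layer always receives a single radius.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SITES",
    "MODALITIES",
    "AneurysmRecord",
    "CohortTable",
    "CohortSchemaError",
    "RecordValidationError",
    "read_cohort",
    "write_cohort",
    "resolve_parent_radius",
    "write_results",
]

#: The three study locations: basilar terminus, anterior communicating artery,
#: posterior communicating artery.
SITES = ("BT", "Acom", "Pcom")
MODALITIES = ("CTA", "MRA", "DSA", "unknown")

REQUIRED_COLUMNS = ("id", "h_mm", "w_mm", "d1_mm", "d2_mm", "r_mm", "site", "ruptured")
OPTIONAL_COLUMNS = ("modality", "smoking", "hypertension", "vessel_choice")

_DIMENSIONS = ("h", "w", "d1", "d2", "r")


class CohortSchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


class RecordValidationError(ValueError):
    """A row violates a record invariant (identified by record id)."""


@dataclass(frozen=True)
class AneurysmRecord:
    """One measured aneurysm: raw 2D dimensions plus clinical labels.

    Lengths in mm: dome height ``h``, dome width ``w``, perpendicular neck
    diameters ``d1 >= d2``, parent-vessel radius ``r``.
    """

    id: str
    h: float
    w: float
    d1: float
    d2: float
    r: float
    site: str
    ruptured: bool
    modality: str = "unknown"
    smoking: Optional[bool] = None
    hypertension: Optional[bool] = None
    vessel_choice: Optional[str] = None

    def __post_init__(self):
        for name in _DIMENSIONS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
                raise RecordValidationError(
                    f"record {self.id!r}: {name} must be a positive finite mm "
                    f"value, got {v!r}"
                )
        if self.d1 < self.d2:
            raise RecordValidationError(
                f"record {self.id!r}: d1 must be the major neck axis "
                f"(d1={self.d1} < d2={self.d2}); canonicalize before construction"
            )
        if self.site not in SITES:
            raise RecordValidationError(
                f"record {self.id!r}: site {self.site!r} not one of {SITES}"
            )
        if self.modality not in MODALITIES:
            raise RecordValidationError(
                f"record {self.id!r}: modality {self.modality!r} not one of {MODALITIES}"
            )


@dataclass
class CohortTable:
    """Ordered collection of :class:`AneurysmRecord` with unique ids."""

    records: list[AneurysmRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValidationError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_ruptured(self) -> int:
        return sum(r.ruptured for r in self.records)

    @property
    def n_unruptured(self) -> int:
        return len(self.records) - self.n_ruptured

    def to_dataframe(self) -> pd.DataFrame:
        """Table in the on-disk column layout (booleans as 0/1, NA for missing)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "id": r.id,
                    "h_mm": r.h,
                    "w_mm": r.w,
                    "d1_mm": r.d1,
                    "d2_mm": r.d2,
                    "r_mm": r.r,
                    "site": r.site,
                    "ruptured": int(r.ruptured),
                    "modality": r.modality,
                    "smoking": None if r.smoking is None else int(r.smoking),
                    "hypertension": None if r.hypertension is None else int(r.hypertension),
                    "vessel_choice": r.vessel_choice,
                }
            )
        cols = list(REQUIRED_COLUMNS[:7]) + ["ruptured"] + list(OPTIONAL_COLUMNS)
        return pd.DataFrame(rows, columns=cols)


def _parse_bool(value, what: str, rec_id: str) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "t"}:
        return True
    if s in {"0", "false", "no", "f"}:
        return False
    raise RecordValidationError(f"record {rec_id!r}: {what} must be boolean-like, got {value!r}")


def _row_to_record(row: pd.Series) -> AneurysmRecord:
    rec_id = str(row["id"])
    dims = {}
    for name in _DIMENSIONS:
        raw = row[f"{name}_mm"]
        try:
            dims[name] = float(raw)
        except (TypeError, ValueError):
            raise RecordValidationError(
                f"record {rec_id!r}: non-numeric {name}_mm value {raw!r}"
            ) from None
    # canonicalize: d1 is the major neck axis
    d1, d2 = max(dims["d1"], dims["d2"]), min(dims["d1"], dims["d2"])

    def opt_bool(col: str) -> Optional[bool]:
        if col not in row.index or pd.isna(row[col]) or str(row[col]).strip() == "":
            return None
        return _parse_bool(row[col], col, rec_id)

    modality = "unknown"
    if "modality" in row.index and not pd.isna(row["modality"]) and str(row["modality"]).strip():
        modality = str(row["modality"]).strip()

    vessel_choice = None
    if "vessel_choice" in row.index and not pd.isna(row["vessel_choice"]):
        vc = str(row["vessel_choice"]).strip()
        vessel_choice = vc or None

    return AneurysmRecord(
        id=rec_id,
        h=dims["h"],
        w=dims["w"],
        d1=d1,
        d2=d2,
        r=dims["r"],
        site=str(row["site"]).strip(),
        ruptured=_parse_bool(row["ruptured"], "ruptured", rec_id),
        modality=modality,
        smoking=opt_bool("smoking"),
        hypertension=opt_bool("hypertension"),
        vessel_choice=vessel_choice,
    )


def read_cohort(path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV into validated records.

    In strict mode any invariant violation aborts with the offending row's id;
    in lenient mode offending rows are dropped and logged with reasons.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records = []
    for _, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except RecordValidationError as exc:
            if strict:
                raise
            logger.warning("dropping row: %s", exc)
    return CohortTable(records=records, provenance=str(path))


def write_cohort(cohort: CohortTable, path) -> Path:
    """Write a cohort back to the documented CSV layout (full precision)."""
    path = Path(path)
    cohort.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def resolve_parent_radius(
    candidates: Sequence[tuple[str, float]], arises_from_branch: bool
) -> tuple[float, str]:
    """Select the parent-vessel radius among 1-2 candidate vessels.

    The wall-conservation model assumes the dome is stretched parent-vessel
    wall, so when an aneurysm arises at least partially from a branch the
    thinner-walled (smaller) vessel governs: the smaller radius is returned.
    If it arises entirely from the trunk, the trunk (first-listed) vessel is
    returned.  Returns ``(radius_mm, vessel_label)``.
    """
    if not candidates:
        raise ValueError("no candidate parent vessels supplied")
    if len(candidates) > 2:
        raise ValueError("at most two candidate parent vessels are supported")
    for label, radius in candidates:
        if not radius > 0:
            raise ValueError(f"candidate vessel {label!r} has non-positive radius {radius!r}")
    if len(candidates) == 1 or not arises_from_branch:
        label, radius = candidates[0]
        return radius, label
    label, radius = min(candidates, key=lambda c: c[1])
    return radius, label


def _round_sig(x, sig: int = 3):
    """Round to ``sig`` significant figures for the human-readable summary."""
    if x is None or isinstance(x, bool):
        return x
    if isinstance(x, (int,)) :
        return x
    if not isinstance(x, float):
        return x
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _round_tree(obj, sig: int = 3):
    if isinstance(obj, dict):
        return {k: _round_tree(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, sig) for v in obj]
    return _round_sig(obj, sig)


def write_results(outdir, cohort: CohortTable, report=None) -> list[Path]:
    """Emit analysis outputs to ``outdir`` and return the file manifest.

    Always writes ``summary.json`` (numbers at 3 significant figures).  With a
    non-empty cohort, writes the per-record index table ``indices.csv``; with a
    full :class:`~aneurysmorph.pipeline.AnalysisReport`, also writes
    ``roc_points_<index>.csv`` per analyzed index, ``logistic_fits.csv`` and
    ``group_comparisons.csv``, all at full precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    summary: dict = {
        "n_records": len(cohort),
        "n_ruptured": cohort.n_ruptured,
        "n_unruptured": cohort.n_unruptured,
        "by_site": {
            site: {
                "ruptured": sum(1 for r in cohort if r.site == site and r.ruptured),
                "unruptured": sum(1 for r in cohort if r.site == site and not r.ruptured),
            }
            for site in SITES
        },
        "provenance": cohort.provenance,
    }

    if len(cohort) > 0:
        if report is not None:
            indices_df = report.indices
        else:
            indices_df = per_record_indices(cohort)
        p = outdir / "indices.csv"
        indices_df.to_csv(p, index=False, float_format="%.17g")
        manifest.append(p)

    if report is not None:
        for name, roc in report.roc.items():
            p = outdir / f"roc_points_{name}.csv"
            pts = pd.DataFrame(roc.points, columns=["cutoff", "sens", "spec"])
            pts["one_minus_spec"] = 1.0 - pts["spec"]
            pts.to_csv(p, index=False, float_format="%.17g")
            manifest.append(p)
        p = outdir / "logistic_fits.csv"
        report.logistic_table().to_csv(p, index=False, float_format="%.17g")
        manifest.append(p)
        p = outdir / "group_comparisons.csv"
        report.comparisons_table().to_csv(p, index=False, float_format="%.17g")
        manifest.append(p)
        summary.update(report.summary_dict())

    p = outdir / "summary.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(_round_tree(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.append(p)
    return manifest


def per_record_indices(cohort: CohortTable, model=None) -> pd.DataFrame:
    """Uncorrected and (for ruptured records) corrected indices per record.

    Corrected columns for unruptured records repeat the uncorrected values:
    the correction removes post-rupture inflation, which unruptured
    measurements never had.
    """
    from .morphometrics import DEFAULT_WALL_MODEL, compute_indices

    model = model or DEFAULT_WALL_MODEL
    rows = []
    for rec in cohort:
        raw = compute_indices(rec, correct_for_rupture=False, model=model)
        cor = (
            compute_indices(rec, correct_for_rupture=True, model=model)
            if rec.ruptured
            else raw
        )
        rows.append(
            {
                "id": rec.id,
                "site": rec.site,
                "ruptured": int(rec.ruptured),
                "t_V_mm": raw.t_V,
                "t_A_mm": raw.t_A,
                "R_dome_mm": raw.R_dome,
                "sphericity": raw.sphericity,
                "WTR": raw.WTR,
                "AR": raw.AR,
                "BF": raw.BF,
                "SR": raw.SR,
                "WTR_prime": cor.WTR,
                "AR_prime": cor.AR,
                "SR_prime": cor.SR,
            }
        )
    cols = [
        "id", "site", "ruptured", "t_V_mm", "t_A_mm", "R_dome_mm", "sphericity",
        "WTR", "AR", "BF", "SR", "WTR_prime", "AR_prime", "SR_prime",
    ]
    return pd.DataFrame(rows, columns=cols)
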