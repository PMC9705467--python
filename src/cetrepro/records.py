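"""Necropsy-record data model, CSV I/O and reproductive-status classification.

One :class:`NecropsyRecord` holds the post-mortem observations for a single
female: morphometrics (total body length, TBL), tooth-derived age (possibly a
censored lower bound such as "≥9"), ovarian corpora counts per side, corpus
luteum (CL) presence/diameter, mammary lactation evidence, and any foetus.

Classification follows the standard necropsy convention for delphinids: a
female is sexually mature iff she carries at least one ovarian corpus (CA or
CL) and/or is pregnant and/or lactating; mature females are then partitioned
into pregnant / pregnant+lactating / lactating / resting / indeterminate.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
import re
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml


class EventType(str, enum.Enum):
    stranding = "stranding"
    bycatch = "bycatch"


class FoetusSex(str, enum.Enum):
    F = "F"
    M = "M"
    unknown = "unknown"


class Decomposition(str, enum.Enum):
    fresh = "fresh"
    mild = "mild"
    moderate = "moderate"


class Maturity(str, enum.Enum):
    immature = "immature"
    mature = "mature"
    undetermined = "undetermined"


class ReproductiveClass(str, enum.Enum):
    immature = "immature"
    pregnant = "pregnant"
    lactating = "lactating"
    pregnant_lactating = "pregnant_lactating"
    resting_mature = "resting_mature"
    indeterminate_mature = "indeterminate_mature"


#: mature subclasses; together with ``immature`` they partition classified records
MATURE_CLASSES = (
    ReproductiveClass.pregnant,
    ReproductiveClass.lactating,
    ReproductiveClass.pregnant_lactating,
    ReproductiveClass.resting_mature,
    ReproductiveClass.indeterminate_mature,
)


class RecordError(ValueError):
    """A CSV row violated the record invariants (carries row diagnostics)."""


@dataclass
class NecropsyRecord:
    """One female's necropsy observations. Missing values are ``None``."""

    id: str
    event_date: _dt.date
    event_type: EventType = EventType.stranding
    tbl_cm: float | None = None
    age_years: float | None = None
    age_censored: bool = False  # True: age_years is a lower bound, not a point value
    corpora_left: int | None = None
    corpora_right: int | None = None
    cl_left: bool | None = None
    cl_right: bool | None = None
    cl_diameter_mm: float | None = None
    ovary_weight_left_g: float | None = None
    ovary_weight_right_g: float | None = None
    lactating: bool | None = None
    foetus_tbl_cm: float | None = None
    foetus_sex: FoetusSex | None = None
    largest_follicle_mm: float | None = None
    decomposition: Decomposition | None = None

    @property
    def corpora_total(self) -> int | None:
        if self.corpora_left is None and self.corpora_right is None:
            return None
        return (self.corpora_left or 0) + (self.corpora_right or 0)

    @property
    def cl_present(self) -> bool | None:
        if self.cl_left is None and self.cl_right is None:
            return None
        return bool(self.cl_left) or bool(self.cl_right)

    @property
    def julian_day(self) -> int:
        """1-based day of year of the stranding/bycatch event."""
        return self.event_date.timetuple().tm_yday


_AGE_BOUND_RE = re.compile(r"^\s*(?:>=|≥|>)\s*(\d+(?:\.\d+)?)\s*$")

#: canonical CSV column order
COLUMNS = [
    "id", "event_date", "event_type", "tbl_cm", "age_years",
    "corpora_left", "corpora_right", "cl_left", "cl_right", "cl_diameter_mm",
    "ovary_weight_left_g", "ovary_weight_right_g", "lactating",
    "foetus_tbl_cm", "foetus_sex", "largest_follicle_mm", "decomposition",
]


def parse_age(cell: str | None) -> tuple[float | None, bool]:
    """Parse an age cell into ``(value, censored)``.

    ``"8.5"`` -> (8.5, False); ``"≥9"``/``">=9"``/``">20"`` -> (bound, True);
    empty -> (None, False).
    """
    if cell is None or str(cell).strip() == "":
        return None, False
    s = str(cell).strip()
    m = _AGE_BOUND_RE.match(s)
    if m:
        return float(m.group(1)), True
    return float(s), False


def _parse_bool(cell: str) -> bool:
    s = str(cell).strip().lower()
    if s in {"true", "t", "1", "yes", "y"}:
        return True
    if s in {"false", "f", "0", "no", "n"}:
        return False
    raise ValueError(f"cannot parse boolean {cell!r}")


def _blank(cell) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == ""


def read_records(path, schema_config: dict | str | None = None) -> list[NecropsyRecord]:
    """Read and validate a necropsy CSV into :class:`NecropsyRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row; dates ISO-8601; missing cells empty.
    schema_config
        Optional mapping ``{canonical_name: csv_column_name}`` (or a path to a
        YAML file holding one) for data that uses different column names.

    Raises
    ------
    RecordError
        Listing every offending row (1-based data row number) if any row
        fails to parse or violates an invariant, or if ids are duplicated.
    """
    if isinstance(schema_config, (str, bytes)) or hasattr(schema_config, "read"):
        with open(schema_config) as fh:  # type: ignore[arg-type]
            schema_config = yaml.safe_load(fh)
    mapping = dict(schema_config or {})

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})

    records: list[NecropsyRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            records.append(_parse_row(row))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    ids = [r.id for r in records]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        errors.append(f"duplicate id(s): {sorted(dupes)}")
    if errors:
        raise RecordError("; ".join(errors))
    return records


def _parse_row(row: dict) -> NecropsyRecord:
    def get(name):
        return None if _blank(row.get(name)) else str(row[name]).strip()

    rid = get("id")
    if not rid:
        raise ValueError("missing id")
    date_s = get("event_date")
    if not date_s:
        raise ValueError("missing event_date")
    event_date = _dt.date.fromisoformat(date_s)

    age, censored = parse_age(get("age_years"))
    if age is not None and age < 0:
        raise ValueError(f"negative age {age}")

    def fnum(name, lo=None, hi=None, strict_lo=False):
        s = get(name)
        if s is None:
            return None
        v = float(s)
        if lo is not None and (v < lo or (strict_lo and v <= lo)):
            raise ValueError(f"{name}={v} out of range")
        if hi is not None and v >= hi:
            raise ValueError(f"{name}={v} out of range")
        return v

    def inum(name):
        s = get(name)
        if s is None:
            return None
        v = int(float(s))
        if v < 0:
            raise ValueError(f"{name}={v} negative")
        return v

    def boolean(name):
        s = get(name)
        return None if s is None else _parse_bool(s)

    return NecropsyRecord(
        id=rid,
        event_date=event_date,
        event_type=EventType(get("event_type") or "stranding"),
        tbl_cm=fnum("tbl_cm", lo=0, hi=400, strict_lo=True),
        age_years=age,
        age_censored=censored,
        corpora_left=inum("corpora_left"),
        corpora_right=inum("corpora_right"),
        cl_left=boolean("cl_left"),
        cl_right=boolean("cl_right"),
        cl_diameter_mm=fnum("cl_diameter_mm", lo=0, strict_lo=True),
        ovary_weight_left_g=fnum("ovary_weight_left_g", lo=0),
        ovary_weight_right_g=fnum("ovary_weight_right_g", lo=0),
        lactating=boolean("lactating"),
        foetus_tbl_cm=fnum("foetus_tbl_cm", lo=0, strict_lo=True),
        foetus_sex=FoetusSex(get("foetus_sex")) if get("foetus_sex") else None,
        largest_follicle_mm=fnum("largest_follicle_mm", lo=0),
        decomposition=Decomposition(get("decomposition")) if get("decomposition") else None,
    )


def records_to_frame(records: list[NecropsyRecord]) -> pd.DataFrame:
    """Tabulate records, with censored ages serialised back to "≥bound"."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(r)}
        if r.age_censored and r.age_years is not None:
            d["age_years"] = f"≥{r.age_years:g}"
        else:
            d["age_years"] = "" if r.age_years is None else f"{r.age_years:g}"
        d.pop("age_censored")
        for k, v in list(d.items()):
            if isinstance(v, enum.Enum):
                d[k] = v.value
            elif isinstance(v, _dt.date):
                d[k] = v.isoformat()
            elif v is None:
                d[k] = ""
        rows.append(d)
    return pd.DataFrame(rows, columns=COLUMNS)


def write_records(records: list[NecropsyRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def classify_maturity(rec: NecropsyRecord) -> Maturity:
    """Mature iff ≥1 corpus (CA or CL) and/or pregnant and/or lactating.

    If every line of evidence (corpora, CL, foetus, lactation) is missing the
    status is ``undetermined`` rather than a silent ``immature``.
    """
    evidence_seen = False
    if rec.corpora_total is not None:
        evidence_seen = True
        if rec.corpora_total >= 1:
            return Maturity.mature
    if rec.cl_present is not None:
        evidence_seen = True
        if rec.cl_present:
            return Maturity.mature
    if rec.foetus_tbl_cm is not None:
        return Maturity.mature
    if rec.lactating is not None:
        evidence_seen = True
        if rec.lactating:
            return Maturity.mature
    return Maturity.immature if evidence_seen else Maturity.undetermined


def classify_reproductive_class(rec: NecropsyRecord) -> ReproductiveClass:
    """Partition a *mature* female into the standard reproductive classes.

    pregnant (foetus present), pregnant+lactating, lactating, resting
    (corpora/CL evidence but neither pregnant nor lactating), or
    indeterminate when the mammary state could not be assessed.
    """
    if classify_maturity(rec) is not Maturity.mature:
        raise ValueError(f"record {rec.id}: reproductive class is defined for mature females only")
    pregnant = rec.foetus_tbl_cm is not None
    if pregnant and rec.lactating:
        return ReproductiveClass.pregnant_lactating
    if pregnant:
        return ReproductiveClass.pregnant
    if rec.lactating:
        return ReproductiveClass.lactating
    if rec.lactating is None:
        # mammary glands unassessable and no foetus observed: cannot separate
        # lactating from resting
        return ReproductiveClass.indeterminate_mature
    return ReproductiveClass.resting_mature


def classify_records(records: list[NecropsyRecord]) -> pd.DataFrame:
    """Classify every record; returns id, maturity, reproductive class."""
    rows = []
    for r in records:
        mat = classify_maturity(r)
        if mat is Maturity.mature:
            cls = classify_reproductive_class(r).value
        elif mat is Maturity.immature:
            cls = ReproductiveClass.immature.value
        else:
            cls = None
        rows.append({"id": r.id, "maturity": mat.value, "repro_class": cls})
    return pd.DataFrame(rows)


_SUMMARY_VARS = {
    "tbl_cm": lambda r: r.tbl_cm,
    "age_years": lambda r: r.age_years if not r.age_censored else None,
    "ovary_weight_left_g": lambda r: r.ovary_weight_left_g,
    "ovary_weight_right_g": lambda r: r.ovary_weight_right_g,
    "corpora_left": lambda r: r.corpora_left,
    "corpora_right": lambda r: r.corpora_right,
}


def summarize_by_class(records: list[NecropsyRecord]) -> pd.DataFrame:
    """Per-class n, mean, SE (sd/√n) and range for TBL, age, ovary weights and corpora.

    Missing values are excluded per variable with the per-variable n reported
    (sample sizes therefore vary across variables, as they do in necropsy
    datasets). Censored ages never enter means. Aggregate rows ``all_mature``
    and ``total`` are appended.
    """
    cls_df = classify_records(records)
    by_id = dict(zip(cls_df["id"], cls_df["repro_class"]))
    groups: dict[str, list[NecropsyRecord]] = {c.value: [] for c in ReproductiveClass}
    for r in records:
        c = by_id.get(r.id)
        if c is not None:
            groups[c].append(r)
    groups["all_mature"] = [r for c in MATURE_CLASSES for r in groups[c.value]]
    groups["total"] = [r for g in (c.value for c in ReproductiveClass) for r in groups[g]]

    rows = []
    for cls, recs in groups.items():
        for var, getter in _SUMMARY_VARS.items():
            vals = np.array([v for r in recs if (v := getter(r)) is not None], dtype=float)
            n = len(vals)
            rows.append({
                "repro_class": cls,
                "variable": var,
                "n_class": len(recs),
                "n": n,
                "mean": vals.mean() if n else np.nan,
                "se": vals.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan,
                "min": vals.min() if n else np.nan,
                "max": vals.max() if n else np.nan,
            })
    return pd.DataFrame(rows)
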