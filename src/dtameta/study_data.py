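"""Study-level 2x2 data: domain types, CSV I/O, validation and subgrouping.

A diagnostic-accuracy meta-analysis consumes one 2x2 confusion table per
study arm (TP/FP/FN/TN against a reference standard) together with
study-level covariates used for subgrouping and meta-regression.  This
module defines the row type (:class:`Study2x2`), the ordered collection
(:class:`StudyPanel`), a strict CSV reader/writer, descriptive per-study
rates, and dichotomisation rules for subgroup selection.

The package ships a 29-row panel of published prostate-cancer DWI studies
(high diffusion-weighting, b >= 2000 s/mm^2) as ``dtameta/data/table3.csv``;
load it with :func:`load_fixture_panel`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import logit

logger = logging.getLogger(__name__)

__all__ = [
    "Study2x2",
    "StudyPanel",
    "ValidationError",
    "read_panel",
    "write_panel",
    "load_fixture_panel",
    "observed_rates",
    "select_subgroup",
    "subgroup_levels",
    "covariate_level",
    "SUBGROUP_VARIABLES",
]

_DESIGNS = {"prospective", "retrospective"}
_MEASURES = {"ADC", "visual"}
_POPULATIONS = {"PCa", "suspected"}
_BIOPSY_TYPES = {"prostatectomy", "systematic", "targeted", "mixed"}
_B_METHODS = {"signal_extrapolation", "motion_probing_gradients", "both"}
_FIELD_STRENGTHS = {1.5, 3.0}

CSV_COLUMNS = [
    "study_id", "author", "year", "b_value", "tp", "fp", "fn", "tn",
    "design", "n_patients", "mean_age", "field_strength", "measure",
    "supplier", "population", "biopsy_type", "b_method",
]


class ValidationError(ValueError):
    """Raised when a row or panel violates the data contract."""


@dataclass(frozen=True)
class Study2x2:
    """One study arm's 2x2 confusion counts plus covariates.

    ``tp``/``fn`` are counts among reference-standard positives (diseased
    arm), ``tn``/``fp`` among negatives.  Optional covariates are ``None``
    when the source publication did not report them; they are never imputed.
    """

    study_id: str
    author: str
    year: int
    b_value: int
    tp: int
    fp: int
    fn: int
    tn: int
    design: str
    n_patients: Optional[int] = None
    mean_age: Optional[float] = None
    field_strength: Optional[float] = None
    measure: Optional[str] = None
    supplier: Optional[str] = None
    population: Optional[str] = None
    biopsy_type: Optional[str] = None
    b_method: Optional[str] = None

    def __post_init__(self) -> None:
        for cell in ("tp", "fp", "fn", "tn"):
            v = getattr(self, cell)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(
                    f"study {self.study_id!r}: count {cell}={v!r} must be a "
                    "non-negative integer"
                )
        if self.tp + self.fn < 1:
            raise ValidationError(
                f"study {self.study_id!r}: empty diseased arm (tp+fn=0)"
            )
        if self.tn + self.fp < 1:
            raise ValidationError(
                f"study {self.study_id!r}: empty non-diseased arm (tn+fp=0)"
            )
        if self.b_value < 2000:
            raise ValidationError(
                f"study {self.study_id!r}: b_value={self.b_value} below the "
                "inclusion threshold of 2000 s/mm^2"
            )
        if self.design not in _DESIGNS:
            raise ValidationError(
                f"study {self.study_id!r}: design={self.design!r} not in "
                f"{sorted(_DESIGNS)}"
            )
        for name, allowed in (
            ("measure", _MEASURES),
            ("population", _POPULATIONS),
            ("biopsy_type", _BIOPSY_TYPES),
            ("b_method", _B_METHODS),
        ):
            v = getattr(self, name)
            if v is not None and v not in allowed:
                raise ValidationError(
                    f"study {self.study_id!r}: {name}={v!r} not in {sorted(allowed)}"
                )
        if self.field_strength is not None and self.field_strength not in _FIELD_STRENGTHS:
            raise ValidationError(
                f"study {self.study_id!r}: field_strength={self.field_strength!r} "
                "must be 1.5 or 3.0 tesla"
            )
        if self.n_patients is not None and self.n_patients <= 0:
            raise ValidationError(
                f"study {self.study_id!r}: n_patients must be positive"
            )

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.tn + self.fp


@dataclass
class StudyPanel:
    """Ordered collection of :class:`Study2x2` rows with unique ids."""

    rows: list[Study2x2]
    label: str = ""
    #: latent (logit sens, logit spec) per row; set by the synthetic
    #: generator as a test-only channel, absent for real data.
    latents: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.rows]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate study_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[Study2x2]:
        return iter(self.rows)

    def __getitem__(self, i: int) -> Study2x2:
        return self.rows[i]

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(tp, fp, fn, tn) as float arrays in row order."""
        tp = np.array([r.tp for r in self.rows], float)
        fp = np.array([r.fp for r in self.rows], float)
        fn = np.array([r.fn for r in self.rows], float)
        tn = np.array([r.tn for r in self.rows], float)
        return tp, fp, fn, tn

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({f.name: getattr(r, f.name) for f in fields(Study2x2)})
        return pd.DataFrame.from_records(recs, columns=CSV_COLUMNS)

    def subset(self, keep: Iterable[bool] | Iterable[int], label: str = "") -> "StudyPanel":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            rows = [r for r, k in zip(self.rows, keep) if k]
        else:
            rows = [self.rows[i] for i in keep]
        return StudyPanel(rows, label=label or self.label)

    def drop(self, study_id: str) -> "StudyPanel":
        rows = [r for r in self.rows if r.study_id != study_id]
        if len(rows) == len(self.rows):
            raise KeyError(study_id)
        return StudyPanel(rows, label=self.label)


def _parse_row(raw: dict, line_no: int) -> Study2x2:
    def req(col: str) -> str:
        v = (raw.get(col) or "").strip()
        if v == "":
            raise ValidationError(f"row {line_no}: column {col!r} is required")
        return v

    def opt(col: str) -> Optional[str]:
        v = (raw.get(col) or "").strip()
        return v or None

    def to_int(col: str, v: str) -> int:
        try:
            return int(v)
        except ValueError:
            raise ValidationError(
                f"row {line_no}: column {col!r} value {v!r} is not an integer"
            ) from None

    def to_float(col: str, v: str) -> float:
        try:
            return float(v)
        except ValueError:
            raise ValidationError(
                f"row {line_no}: column {col!r} value {v!r} is not a number"
            ) from None

    npat = opt("n_patients")
    age = opt("mean_age")
    fs = opt("field_strength")
    try:
        return Study2x2(
            study_id=req("study_id"),
            author=req("author"),
            year=to_int("year", req("year")),
            b_value=to_int("b_value", req("b_value")),
            tp=to_int("tp", req("tp")),
            fp=to_int("fp", req("fp")),
            fn=to_int("fn", req("fn")),
            tn=to_int("tn", req("tn")),
            design=req("design"),
            n_patients=to_int("n_patients", npat) if npat else None,
            mean_age=to_float("mean_age", age) if age else None,
            field_strength=to_float("field_strength", fs) if fs else None,
            measure=opt("measure"),
            supplier=opt("supplier"),
            population=opt("population"),
            biopsy_type=opt("biopsy_type"),
            b_method=opt("b_method"),
        )
    except ValidationError as e:
        raise ValidationError(f"row {line_no}: {e}") from None


def read_panel(path: str | Path, strict: bool = True, label: str = "") -> StudyPanel:
    """Read a panel from CSV, validating every row.

    The header must list exactly the documented columns.  With
    ``strict=False`` extra columns are tolerated (and ignored).
    Missing covariates are empty cells, preserved as ``None``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        header = [c.strip() for c in reader.fieldnames]
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {missing}")
        if strict:
            extra = [c for c in header if c not in CSV_COLUMNS]
            if extra:
                raise ValidationError(f"{path}: unexpected column(s) {extra}")
        rows = [_parse_row(raw, i) for i, raw in enumerate(reader, start=2)]
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    return StudyPanel(rows, label=label or path.stem)


def write_panel(panel: StudyPanel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in panel.rows:
            w.writerow(
                ["" if getattr(r, c) is None else getattr(r, c) for c in CSV_COLUMNS]
            )


def load_fixture_panel() -> StudyPanel:
    """The bundled 29-row prostate-cancer high-b-value DWI panel."""
    ref = resources.files("dtameta.data") / "table3.csv"
    with resources.as_file(ref) as p:
        return read_panel(p, label="table3")


def observed_rates(
    s: Study2x2, cc: float = 0.5
) -> tuple[float, float, float, float, float]:
    """Per-study observed (sens, spec, logit sens, logit spec, lnDOR).

    Sensitivity and specificity are the raw proportions.  When any of the
    four cells is zero, a continuity correction ``cc`` is added to *all
    four* cells before forming logits and the log diagnostic odds ratio so
    that they stay finite; the uncorrected proportions are still reported
    when no cell is zero.
    """
    if cc < 0:
        raise ValueError("continuity correction must be >= 0")
    tp, fp, fn, tn = float(s.tp), float(s.fp), float(s.fn), float(s.tn)
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + cc, fp + cc, fn + cc, tn + cc
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lsens = float(logit(sens))
    lspec = float(logit(spec))
    lndor = math.log(tp * tn / (fp * fn))
    return sens, spec, lsens, lspec, lndor


# --- subgrouping -----------------------------------------------------------

def _dichotomy(value: Optional[float], cut: float, lo: str, hi: str) -> Optional[str]:
    if value is None:
        return None
    return lo if value <= cut else hi


_LEVEL_RULES: dict[str, Callable[[Study2x2], Optional[str]]] = {
    "design": lambda r: r.design,
    "n_patients": lambda r: _dichotomy(r.n_patients, 50, "<=50", ">50"),
    "mean_age": lambda r: _dichotomy(r.mean_age, 65, "<=65", ">65"),
    "field_strength": lambda r: None if r.field_strength is None else f"{r.field_strength:.1f}",
    "b_value": lambda r: "high" if r.b_value == 2000 else "ultra_high",
    "measure": lambda r: r.measure,
    "population": lambda r: r.population,
    "biopsy_type": lambda r: r.biopsy_type,
    "b_method": lambda r: r.b_method,
    "supplier": lambda r: r.supplier,
}

SUBGROUP_VARIABLES = tuple(_LEVEL_RULES)

# aliases so callers may pass the cut-point spelling of a level
_LEVEL_ALIASES = {
    ("b_value", "=2000"): "high",
    ("b_value", "2000"): "high",
    ("b_value", ">2000"): "ultra_high",
}


def covariate_level(row: Study2x2, variable: str) -> Optional[str]:
    """Dichotomised level label of ``row`` for ``variable`` (None = missing)."""
    try:
        rule = _LEVEL_RULES[variable]
    except KeyError:
        raise ValueError(
            f"unknown subgroup variable {variable!r}; valid: {sorted(_LEVEL_RULES)}"
        ) from None
    return rule(row)


def select_subgroup(panel: StudyPanel, variable: str, level: str) -> StudyPanel:
    """Rows of ``panel`` whose dichotomised ``variable`` equals ``level``.

    Rows with the covariate missing are dropped (and counted in the log).
    """
    level = _LEVEL_ALIASES.get((variable, level), level)
    kept, missing = [], 0
    for r in panel.rows:
        lv = covariate_level(r, variable)
        if lv is None:
            missing += 1
        elif lv == level:
            kept.append(r)
    if missing:
        logger.info(
            "select_subgroup(%s=%s): dropped %d row(s) with missing covariate",
            variable, level, missing,
        )
    return StudyPanel(kept, label=f"{panel.label}[{variable}={level}]")


def subgroup_levels(panel: StudyPanel, variable: str) -> tuple[dict[str, StudyPanel], list[str]]:
    """Partition ``panel`` by ``variable``.

    Returns ``(levels, dropped)`` where ``levels`` maps each observed level
    (sorted) to its sub-panel and ``dropped`` lists study_ids with the
    covariate missing.
    """
    buckets: dict[str, list[Study2x2]] = {}
    dropped: list[str] = []
    for r in panel.rows:
        lv = covariate_level(r, variable)
        if lv is None:
            dropped.append(r.study_id)
        else:
            buckets.setdefault(lv, []).append(r)
    return (
        {
            lv: StudyPanel(rows, label=f"{panel.label}[{variable}={lv}]")
            for lv, rows in sorted(buckets.items())
        },
        dropped,
    )
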