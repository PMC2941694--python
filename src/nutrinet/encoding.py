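"""Categorical encoding of nutrigenetic cohort data.

Raw subject measurements — continuous nutrient intakes, tri-allelic
genotypes, gender and BMI — become a table of small categorical factors,
then a numeric matrix in [-1, +1] suitable for a tanh-hidden-layer
network:

* "intake in food" and "total intake" nutrition variables are binned at
  their sample quartiles into four classes;
* "intake in supplement" variables put exact zeros into class 1 and split
  the non-zero values at their tertiles into classes 2-4;
* genotypes are three-class (two homozygote forms + heterozygote),
  gender two-class;
* class j of a k-class factor is encoded as the equispaced symmetric
  value -1 + 2*(j-1)/(k-1), e.g. a 4-class variable maps to
  [-1.000, -0.333, +0.333, +1.000];
* BMI is dichotomised at 25 kg/m^2 into C1 (normal, BMI <= 25) and
  C2 (overweight, BMI > 25).  C2 is the positive class throughout.

Quantile estimator: linear-interpolation sample quantiles, with ties
broken to the LOWER class via half-open, upper-closed intervals
(-inf, q1], (q1, q2], ...  Missing values are rejected by default; an
opt-in policy drops the affected subjects instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FactorMeta",
    "Cohort",
    "EncodedMatrix",
    "quartile_bin",
    "supplement_bin",
    "encode_labels",
    "bmi_class",
    "encode",
    "load_cohort",
    "save_cohort",
]

#: factor kind -> required number of classes
KIND_CLASSES = {
    "genotype": 3,
    "gender": 2,
    "nutrition_food": 4,
    "nutrition_supplement": 4,
    "nutrition_total": 4,
}

C1 = "C1"  # normal, BMI <= 25 (negative class)
C2 = "C2"  # overweight, BMI > 25 (positive class)


@dataclass(frozen=True)
class FactorMeta:
    """Name, kind and ordered class labels of one categorical factor."""

    name: str
    kind: str
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in KIND_CLASSES:
            raise ValueError(
                f"factor {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {sorted(KIND_CLASSES)}"
            )
        object.__setattr__(self, "class_order", tuple(str(c) for c in self.class_order))
        expected = KIND_CLASSES[self.kind]
        if len(self.class_order) != expected:
            raise ValueError(
                f"factor {self.name!r}: kind {self.kind!r} requires "
                f"{expected} classes, got {len(self.class_order)}"
            )
        if len(set(self.class_order)) != len(self.class_order):
            raise ValueError(f"factor {self.name!r}: duplicate class labels")

    @property
    def n_classes(self) -> int:
        return len(self.class_order)


@dataclass
class Cohort:
    """Subjects-by-factors table of class indices plus a binary outcome.

    ``values[i, j]`` is the 1-based class index of subject i on factor j;
    ``outcome[i]`` is ``"C1"`` or ``"C2"``.
    """

    factors: list[FactorMeta]
    values: np.ndarray  # (n_subjects, n_factors) int, entries 1..n_classes
    outcome: np.ndarray  # (n_subjects,) of {"C1", "C2"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=object)
        self.validate()

    def validate(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicated factor names: {dupes}")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.factors):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.factors)} factors"
            )
        if self.outcome.shape != (self.values.shape[0],):
            raise ValueError("outcome must have one entry per subject")
        for j, f in enumerate(self.factors):
            col = self.values[:, j]
            if col.min(initial=1) < 1 or col.max(initial=1) > f.n_classes:
                bad = np.where((col < 1) | (col > f.n_classes))[0][0]
                raise ValueError(
                    f"factor {f.name!r}: class index {col[bad]} at subject "
                    f"{bad} outside 1..{f.n_classes}"
                )
        bad = [i for i, o in enumerate(self.outcome) if o not in (C1, C2)]
        if bad:
            raise ValueError(f"outcome must be C1/C2; bad subjects: {bad[:5]}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.factors == other.factors
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.outcome, other.outcome)
        )


@dataclass
class EncodedMatrix:
    """Real-valued design matrix in [-1, +1] with 0/1 targets (C2 -> 1)."""

    X: np.ndarray  # (n_subjects, n_factors) float64
    y: np.ndarray  # (n_subjects,) int, 0 = C1, 1 = C2
    factor_names: list[str]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# binning


def _bin_by_cuts(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    # half-open upper-closed intervals: value == cut goes to the lower class
    return 1 + np.searchsorted(cuts, values, side="left")


def quartile_bin(values: Sequence[float]) -> np.ndarray:
    """Bin non-negative intakes into four classes at the sample quartiles.

    Classes are (-inf, q1], (q1, q2], (q2, q3], (q3, inf) with q1..q3 the
    linear-interpolation sample quartiles, so each class holds ~25% of
    subjects up to ties.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 values to form quartiles, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: quartiles are degenerate")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    return _bin_by_cuts(v, cuts)


def supplement_bin(values: Sequence[float]) -> np.ndarray:
    """Bin supplement intakes: zeros to class 1, non-zero tertiles to 2-4.

    All-zero input maps every subject to class 1.  Fewer than 3 distinct
    non-zero values (with at least one non-zero) leaves the tertiles
    degenerate and raises.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    if np.any(v < 0):
        raise ValueError("supplement intakes must be non-negative")
    out = np.ones(v.shape, dtype=np.int64)
    nz = v > 0
    if not nz.any():
        return out
    nonzero = v[nz]
    if np.unique(nonzero).size < 3:
        raise ValueError(
            "need >= 3 distinct non-zero values to form tertiles "
            f"(got {np.unique(nonzero).size})"
        )
    cuts = np.quantile(nonzero, [1 / 3, 2 / 3])
    out[nz] = 1 + _bin_by_cuts(nonzero, cuts)
    return out


def encode_labels(n_classes: int) -> np.ndarray:
    """Equispaced symmetric class values in [-1, +1].

    Class j (1-based) of a k-class factor maps to -1 + 2*(j-1)/(k-1);
    a 4-class factor therefore maps to [-1.000, -0.333, +0.333, +1.000].
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    return -1.0 + 2.0 * np.arange(n_classes) / (n_classes - 1)


def bmi_class(bmi: float) -> str:
    """Dichotomise BMI (kg/m^2) at 25: C1 if bmi <= 25, else C2."""
    b = float(bmi)
    if not np.isfinite(b) or b <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    return C1 if b <= 25.0 else C2


def encode(cohort: Cohort) -> EncodedMatrix:
    """Map a Cohort's class indices to the symmetric [-1, +1] encoding."""
    X = np.empty((cohort.n_subjects, cohort.n_factors), dtype=float)
    for j, f in enumerate(cohort.factors):
        X[:, j] = encode_labels(f.n_classes)[cohort.values[:, j] - 1]
    y = (cohort.outcome == C2).astype(np.int64)
    return EncodedMatrix(X=X, y=y, factor_names=cohort.factor_names)


# ---------------------------------------------------------------------------
# file I/O
#
# Cohort file format: a CSV/TSV with one row per subject, a header row of
# factor names holding class LABELS (not indices), plus one outcome column
# (either precomputed C1/C2 classes or a raw BMI column to dichotomise),
# and a YAML sidecar declaring each factor's kind and class order.

OUTCOME_COLUMN = "bmi_class"


def _meta_path_for(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def save_cohort(
    cohort: Cohort, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write the cohort CSV (class labels) and its YAML metadata sidecar."""
    path = Path(path)
    meta_path = _meta_path_for(path) if meta_path is None else Path(meta_path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cols = {}
    for j, f in enumerate(cohort.factors):
        labels = np.asarray(f.class_order, dtype=object)
        cols[f.name] = labels[cohort.values[:, j] - 1]
    cols[OUTCOME_COLUMN] = cohort.outcome
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
    meta = {
        "outcome_column": OUTCOME_COLUMN,
        "factors": [
            {"name": f.name, "kind": f.kind, "class_order": list(f.class_order)}
            for f in cohort.factors
        ],
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))


def load_cohort(
    path: str | Path,
    meta_path: str | Path | None = None,
    on_missing: Literal["error", "drop"] = "error",
) -> Cohort:
    """Load a cohort CSV/TSV plus metadata sidecar into a validated Cohort.

    The metadata's ``outcome_column`` may hold C1/C2 classes directly or,
    if ``outcome_is_bmi: true``, raw BMI values dichotomised at 25.
    Missing cells raise by default (listing row and column); pass
    ``on_missing="drop"`` to drop the affected subjects instead.
    """
    path = Path(path)
    meta_path = _meta_path_for(path) if meta_path is None else Path(meta_path)
    meta = yaml.safe_load(Path(meta_path).read_text())
    factors = [
        FactorMeta(f["name"], f["kind"], tuple(f["class_order"]))
        for f in meta["factors"]
    ]
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicated factor names in metadata: {dupes}")

    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    outcome_col = meta.get("outcome_column", OUTCOME_COLUMN)
    needed = names + [outcome_col]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns missing from {path}: {missing_cols}")
    df = df[needed]

    na_mask = df.isna().any(axis=1)
    if na_mask.any():
        if on_missing == "error":
            r = int(np.where(na_mask)[0][0])
            c = df.columns[df.iloc[r].isna()].tolist()
            raise ValueError(
                f"missing cell(s) at data row {r} (columns {c}) in {path}; "
                "pass on_missing='drop' to drop affected subjects"
            )
        df = df.loc[~na_mask]

    values = np.empty((len(df), len(factors)), dtype=np.int64)
    for j, f in enumerate(factors):
        index_of = {label: k + 1 for k, label in enumerate(f.class_order)}
        col = df[f.name].to_numpy()
        try:
            values[:, j] = [index_of[x] for x in col]
        except KeyError as e:
            raise ValueError(
                f"factor {f.name!r}: unknown class label {e.args[0]!r} "
                f"(expected one of {list(f.class_order)})"
            ) from None

    raw_outcome = df[outcome_col].to_numpy()
    if meta.get("outcome_is_bmi", False):
        outcome = np.array([bmi_class(float(b)) for b in raw_outcome], dtype=object)
    else:
        bad = [x for x in raw_outcome if x not in (C1, C2)]
        if bad:
            raise ValueError(
                f"outcome column {outcome_col!r}: unknown label {bad[0]!r} "
                "(expected C1/C2; set outcome_is_bmi for raw BMI values)"
            )
        outcome = raw_outcome.astype(object)
    return Cohort(factors=factors, values=values, outcome=outcome)
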