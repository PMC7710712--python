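"""Reading, validating and writing the tabular and tree inputs of the pipeline.

The pipeline consumes three kinds of input:

* a *study table*: one row per study x host species x parasite category,
  holding the sex-specific 2x2 prevalence counts;
* a *trait table*: one row per species with sex-specific body mass, annual
  mortality and polygamy scores;
* a set of candidate phylogenies (Newick or Nexus) sharing one tip set.

All species-name joins in the pipeline go through :func:`canonical_name`:
underscores become spaces, whitespace is collapsed, and matching is
case-insensitive.  Synonym resolution is deliberately out of scope — an
unmatched name is reported, never silently joined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "PARASITE_CLASSES",
    "PARASITE_CATEGORIES",
    "BLOOD_CATEGORIES",
    "GI_CATEGORIES",
    "PERIODS",
    "DETECTIONS",
    "StudyRecord",
    "SpeciesTraits",
    "TreeSet",
    "ValidationReport",
    "SchemaError",
    "ValidationError",
    "canonical_name",
    "read_study_table",
    "read_trait_table",
    "read_trees",
    "write_trees",
    "write_results_table",
    "write_study_table",
    "write_trait_table",
    "RESULTS_COLUMNS",
]

PARASITE_CLASSES = ("blood", "gastrointestinal", "ectoparasite")
BLOOD_CATEGORIES = (
    "Haemoproteus",
    "Leucocytozoon",
    "Plasmodium",
    "Trypanosoma",
    "Microfilaria",
)
GI_CATEGORIES = ("Cestoda", "Acanthocephala", "Nematoda", "Trematoda", "Protozoa")
PARASITE_CATEGORIES = BLOOD_CATEGORIES + GI_CATEGORIES + ("Combined",)
PERIODS = ("breeding", "nonbreeding", "year_round")
DETECTIONS = ("molecular", "microscopy", "both", "not_applicable")


class SchemaError(ValueError):
    """A required column is missing or the header does not match the schema."""


class ValidationError(ValueError):
    """A row violates a field-level or cross-field invariant."""


def canonical_name(name: str) -> str:
    """Normalize a species name to the canonical join key.

    Underscores are treated as spaces and runs of whitespace collapse to a
    single space.  Comparisons elsewhere use ``canonical_name(x).casefold()``.
    """
    return " ".join(str(name).replace("_", " ").split())


def _name_key(name: str) -> str:
    return canonical_name(name).casefold()


@dataclass(frozen=True)
class StudyRecord:
    """One study x species x parasite-category row of sex-specific counts."""

    study_id: str
    species: str
    parasite_class: str
    parasite_category: str
    males_examined: int
    males_infected: int
    females_examined: int
    females_infected: int
    period: str
    detection: str

    def validate(self) -> None:
        if self.parasite_class not in PARASITE_CLASSES:
            raise ValidationError(
                f"unknown parasite_class {self.parasite_class!r}; "
                f"allowed: {PARASITE_CLASSES}"
            )
        if self.parasite_category not in PARASITE_CATEGORIES:
            raise ValidationError(
                f"unknown parasite_category {self.parasite_category!r}; "
                f"allowed: {PARASITE_CATEGORIES}"
            )
        if self.period not in PERIODS:
            raise ValidationError(
                f"unknown period {self.period!r}; allowed: {PERIODS}"
            )
        if self.detection not in DETECTIONS:
            raise ValidationError(
                f"unknown detection {self.detection!r}; allowed: {DETECTIONS}"
            )
        if self.males_examined < 1 or self.females_examined < 1:
            raise ValidationError(
                "both sexes must have at least one examined individual"
            )
        if not (0 <= self.males_infected <= self.males_examined):
            raise ValidationError(
                f"males_infected={self.males_infected} outside "
                f"[0, males_examined={self.males_examined}]"
            )
        if not (0 <= self.females_infected <= self.females_examined):
            raise ValidationError(
                f"females_infected={self.females_infected} outside "
                f"[0, females_examined={self.females_examined}]"
            )
        if self.parasite_class == "blood":
            if self.detection == "not_applicable":
                raise ValidationError(
                    "blood-parasite rows need detection in "
                    "{molecular, microscopy, both}"
                )
        elif self.detection != "not_applicable":
            raise ValidationError(
                f"{self.parasite_class} rows must have detection=not_applicable "
                "(non-blood surveys use taxonomic-key diagnosis)"
            )

    @property
    def species_key(self) -> str:
        return _name_key(self.species)


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-level sex-specific traits; missing fields are None, never 0."""

    species: str
    male_mass: float | None
    female_mass: float | None
    male_mortality: float | None
    female_mortality: float | None
    male_polygamy: int | None
    female_polygamy: int | None

    def validate(self) -> None:
        for label, mass in (("male_mass", self.male_mass), ("female_mass", self.female_mass)):
            if mass is not None and not mass > 0:
                raise ValidationError(f"{label}={mass} must be > 0")
        for label, mort in (
            ("male_mortality", self.male_mortality),
            ("female_mortality", self.female_mortality),
        ):
            if mort is not None and not (0.0 < mort < 1.0):
                raise ValidationError(
                    f"{label}={mort} must lie strictly inside (0, 1) "
                    "(logit transform undefined at the boundary)"
                )
        for label, score in (
            ("male_polygamy", self.male_polygamy),
            ("female_polygamy", self.female_polygamy),
        ):
            if score is not None and score not in (0, 1, 2, 3, 4):
                raise ValidationError(f"{label}={score} must be an integer in 0..4")

    @property
    def missing_fields(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in (
                "male_mass",
                "female_mass",
                "male_mortality",
                "female_mortality",
                "male_polygamy",
                "female_polygamy",
            )
            if getattr(self, name) is None
        )

    @property
    def complete(self) -> bool:
        return not self.missing_fields

    @property
    def species_key(self) -> str:
        return _name_key(self.species)


@dataclass
class ValidationReport:
    """Bookkeeping attached to every table read: accepted + rejected = total."""

    n_read: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)
    flagged_incomplete: list[str] = field(default_factory=list)

    def reject(self, row: int, reason: str) -> None:
        self.n_rejected += 1
        self.errors.append((row, reason))

    def summary(self) -> str:
        lines = [
            f"rows read: {self.n_read}, accepted: {self.n_accepted}, "
            f"rejected: {self.n_rejected}"
        ]
        lines += [f"  row {row}: {reason}" for row, reason in self.errors]
        if self.flagged_incomplete:
            lines.append(
                "incomplete (flagged, retained): "
                + ", ".join(self.flagged_incomplete)
            )
        return "\n".join(lines)


@dataclass
class TreeSet:
    """An ordered collection of rooted trees over one shared tip-label set."""

    trees: dendropy.TreeList

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(t.label for t in self.trees.taxon_namespace)

    def validate(self) -> None:
        if len(self.trees) == 0:
            raise ValidationError("tree set is empty")
        ref = None
        for idx, tree in enumerate(self.trees):
            tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
            if ref is None:
                ref = tips
            elif tips != ref:
                missing = sorted(ref - tips)
                extra = sorted(tips - ref)
                raise ValidationError(
                    f"tree {idx} tip set differs from tree 0: "
                    f"missing={missing}, extra={extra}"
                )
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    raise ValidationError(f"tree {idx} has a negative branch length")


_STUDY_COLUMNS = (
    "study_id",
    "species",
    "parasite_class",
    "parasite_category",
    "males_examined",
    "males_infected",
    "females_examined",
    "females_infected",
    "period",
    "detection",
)

_TRAIT_COLUMNS = (
    "species",
    "male_mass",
    "female_mass",
    "male_mortality",
    "female_mortality",
    "male_polygamy",
    "female_polygamy",
)

# case-insensitive category token -> canonical spelling
_CATEGORY_LOOKUP = {c.casefold(): c for c in PARASITE_CATEGORIES}


def _check_header(df: pd.DataFrame, required: Sequence[str], what: str) -> pd.DataFrame:
    df = df.rename(columns={c: str(c).strip().casefold() for c in df.columns})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")
    return df


def _parse_count(token, label: str) -> int:
    value = float(token)
    if not value.is_integer() or value < 0:
        raise ValidationError(f"{label}={token!r} is not a non-negative integer")
    return int(value)


def read_study_table(path, **dialect) -> tuple[list[StudyRecord], ValidationReport]:
    """Read and validate a study-level prevalence table.

    Returns the accepted records in file order plus a :class:`ValidationReport`
    whose accepted + rejected counts always equal the rows read.  Rows that
    violate an invariant are rejected individually with a row number; a bad
    header raises :class:`SchemaError` instead.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **dialect)
    df = _check_header(df, _STUDY_COLUMNS, "study table")
    report = ValidationReport(n_read=len(df))
    records: list[StudyRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = StudyRecord(
                study_id=str(row.study_id).strip(),
                species=canonical_name(row.species),
                parasite_class=str(row.parasite_class).strip().casefold(),
                parasite_category=_CATEGORY_LOOKUP.get(
                    str(row.parasite_category).strip().casefold(),
                    str(row.parasite_category).strip(),
                ),
                males_examined=_parse_count(row.males_examined, "males_examined"),
                males_infected=_parse_count(row.males_infected, "males_infected"),
                females_examined=_parse_count(row.females_examined, "females_examined"),
                females_infected=_parse_count(row.females_infected, "females_infected"),
                period=str(row.period).strip().casefold(),
                detection=str(row.detection).strip().casefold(),
            )
            rec.validate()
        except (ValidationError, ValueError) as exc:
            report.reject(pos, str(exc))
            continue
        records.append(rec)
        report.n_accepted += 1
    return records, report


def _parse_optional_float(token) -> float | None:
    token = str(token).strip()
    if token == "":
        return None
    return float(token)


def _parse_optional_int(token) -> int | None:
    value = _parse_optional_float(token)
    if value is None:
        return None
    if not float(value).is_integer():
        raise ValidationError(f"polygamy score {token!r} is not an integer")
    return int(value)


def read_trait_table(path, **dialect) -> tuple[list[SpeciesTraits], ValidationReport]:
    """Read the species-level trait table.

    Species with missing fields are *retained* and flagged (downstream models
    apply listwise deletion); out-of-range values reject the row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **dialect)
    df = _check_header(df, _TRAIT_COLUMNS, "trait table")
    report = ValidationReport(n_read=len(df))
    records: list[SpeciesTraits] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = SpeciesTraits(
                species=canonical_name(row.species),
                male_mass=_parse_optional_float(row.male_mass),
                female_mass=_parse_optional_float(row.female_mass),
                male_mortality=_parse_optional_float(row.male_mortality),
                female_mortality=_parse_optional_float(row.female_mortality),
                male_polygamy=_parse_optional_int(row.male_polygamy),
                female_polygamy=_parse_optional_int(row.female_polygamy),
            )
            rec.validate()
        except (ValidationError, ValueError) as exc:
            report.reject(pos, str(exc))
            continue
        records.append(rec)
        report.n_accepted += 1
        if not rec.complete:
            report.flagged_incomplete.append(rec.species)
    return records, report


def read_trees(path, format: str = "newick") -> TreeSet:
    """Read a set of rooted trees and normalize tip labels.

    All trees must share one tip set; a mismatch raises
    :class:`ValidationError` listing the offending tips.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    trees = dendropy.TreeList.get(path=str(path), schema=format)
    for taxon in trees.taxon_namespace:
        taxon.label = canonical_name(taxon.label)
    for tree in trees:
        tree.is_rooted = True
    ts = TreeSet(trees=trees)
    ts.validate()
    return ts


def write_trees(treeset: TreeSet | Iterable[dendropy.Tree], path) -> None:
    if isinstance(treeset, TreeSet):
        trees = treeset.trees
    else:
        trees = dendropy.TreeList(list(treeset))
    trees.write(path=str(path), schema="newick", suppress_rooting=True,
                real_value_format_specifier=".12g")


def write_study_table(records: Iterable[StudyRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(_STUDY_COLUMNS))
    df.to_csv(path, index=False)


def write_trait_table(records: Iterable[SpeciesTraits], path) -> None:
    df = pd.DataFrame(
        [
            {c: ("" if getattr(r, c) is None else getattr(r, c)) for c in _TRAIT_COLUMNS}
            for r in records
        ],
        columns=list(_TRAIT_COLUMNS),
    )
    df.to_csv(path, index=False)


RESULTS_COLUMNS = (
    "analysis",
    "group",
    "k",
    "n_species",
    "n_studies",
    "estimate",
    "ci_low",
    "ci_high",
    "Z_or_t",
    "P",
    "Q",
    "Q_df",
    "Q_P",
    "lambda",
    "adj_R2",
)


def write_results_table(rows: Iterable[dict], path) -> pd.DataFrame:
    """Write fit summaries as a CSV with the fixed results schema.

    `rows` are dicts keyed by (a subset of) :data:`RESULTS_COLUMNS`;
    inapplicable cells stay empty.  Numbers keep >= 6 significant digits.
    """
    df = pd.DataFrame(list(rows), columns=RESULTS_COLUMNS)
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_format_cell)
    out.to_csv(path, index=False)
    return df


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return f"{value:.8g}"
    return str(value)
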