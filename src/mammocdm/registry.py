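"""Common data model (CDM) registry: coded concepts, value sets, validation.

The registry is the heart of the harmonization scheme: a fixed list of
clinical concepts, each mapped to an OMOP standardized-vocabulary concept
ID, with either a numeric domain or a closed, coded value set.  Every cell
of a harmonized table must be either a number or a registered value code,
so the harmonized dataset carries its semantics with it and contains no
free text and no empty cells.  Missingness is itself coded, with the OMOP
concept "Not provided" (763013).

The shipped registry lives in ``data/cdm_registry.yaml`` and describes 38
breast-cancer concepts curated from five public TCIA collections.  It is
deliberately plain YAML under version control so the concept-by-concept
mapping can be reviewed like any other source file.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "NOT_PROVIDED",
    "ConceptGroup",
    "ValueDomain",
    "Granularity",
    "ValueDef",
    "ConceptDef",
    "CDMDefinition",
    "VocabularyUsage",
    "ValidationReport",
    "RegistryFormatError",
    "RegistryValidationError",
    "load_registry",
    "save_registry",
    "default_registry",
    "vocabulary_usage",
    "validate_record",
]

#: OMOP concept ID of "Not provided", the coded missing value.
NOT_PROVIDED = 763013

#: Cell string used for missing values (single and multi fields alike).
NOT_PROVIDED_CELL = str(NOT_PROVIDED)

_NOT_PROVIDED_VOCABULARY = "PPI"


class ConceptGroup(str, enum.Enum):
    DEMOGRAPHIC = "demographic"
    PATHOLOGY = "pathology"
    TREATMENT = "treatment"
    OUTCOME = "outcome"
    IMAGING_CONTEXT = "imaging_context"


class ValueDomain(str, enum.Enum):
    SCALAR_NUMERIC = "scalar_numeric"
    CODED_SINGLE = "coded_single"
    CODED_MULTI = "coded_multi"


class Granularity(str, enum.Enum):
    GENERIC = "generic"
    DETAILED = "detailed"


class RegistryFormatError(ValueError):
    """Raised when a registry file cannot be parsed as the documented format."""


class RegistryValidationError(ValueError):
    """Raised when a parsed registry violates a structural invariant."""


@dataclass(frozen=True)
class ValueDef:
    """One registered coded value of a concept's value set.

    ``generic_parent`` links a detailed code (e.g. pN1a) to its generic
    parent (pN1) so a field can be recoded to the coarse value set on
    demand without losing the detailed information in the shipped data.
    """

    omop_id: int
    vocabulary: str
    label: str
    granularity: Granularity = Granularity.GENERIC
    generic_parent: int | None = None

    def __post_init__(self) -> None:
        if self.omop_id <= 0:
            raise RegistryValidationError(
                f"value {self.label!r}: omop_id must be positive, got {self.omop_id}"
            )


#: The reserved "Not provided" value, present in every coded value set.
NOT_PROVIDED_VALUE = ValueDef(
    omop_id=NOT_PROVIDED,
    vocabulary=_NOT_PROVIDED_VOCABULARY,
    label="Not provided",
)


@dataclass(frozen=True)
class ConceptDef:
    field_name: str
    omop_id: int
    vocabulary: str
    concept_group: ConceptGroup
    value_domain: ValueDomain
    value_set: tuple[ValueDef, ...] = ()
    units: str | None = None

    def __post_init__(self) -> None:
        if self.omop_id <= 0:
            raise RegistryValidationError(
                f"concept {self.field_name!r}: omop_id must be positive"
            )
        ids = [v.omop_id for v in self.value_set]
        dupes = [i for i, n in Counter(ids).items() if n > 1]
        if dupes:
            raise RegistryValidationError(
                f"concept {self.field_name!r}: duplicate value omop_id(s) {dupes}"
            )
        if self.value_domain is ValueDomain.SCALAR_NUMERIC:
            if self.value_set:
                raise RegistryValidationError(
                    f"scalar concept {self.field_name!r} must have an empty value set"
                )
        else:
            if not self.value_set:
                raise RegistryValidationError(
                    f"coded concept {self.field_name!r} has an empty value set"
                )
            if NOT_PROVIDED not in ids:
                raise RegistryValidationError(
                    f"coded concept {self.field_name!r} is missing the "
                    f"'Not provided' value ({NOT_PROVIDED})"
                )

    @property
    def is_coded(self) -> bool:
        return self.value_domain is not ValueDomain.SCALAR_NUMERIC

    def value(self, omop_id: int) -> ValueDef:
        for v in self.value_set:
            if v.omop_id == omop_id:
                return v
        raise KeyError(
            f"value {omop_id} is not registered for concept {self.field_name!r}"
        )

    def value_ids(self) -> frozenset[int]:
        return frozenset(v.omop_id for v in self.value_set)


@dataclass(frozen=True)
class CDMDefinition:
    """An ordered, validated collection of concept definitions."""

    concepts: tuple[ConceptDef, ...]
    version: str = "0"

    def __post_init__(self) -> None:
        names = [c.field_name for c in self.concepts]
        dupes = sorted(n for n, k in Counter(names).items() if k > 1)
        if dupes:
            raise RegistryValidationError(f"duplicate field_name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    def field_names(self) -> list[str]:
        return [c.field_name for c in self.concepts]

    def __getitem__(self, field_name: str) -> ConceptDef:
        for c in self.concepts:
            if c.field_name == field_name:
                return c
        raise KeyError(field_name)

    def __contains__(self, field_name: object) -> bool:
        return any(c.field_name == field_name for c in self.concepts)

    def distinct_values(self) -> dict[int, ValueDef]:
        """All distinct coded values across value sets, keyed by omop_id.

        A value shared by several concepts (yes/no, Not provided) counts
        once; this is the convention under which the shipped registry's
        composition statistics are computed.
        """
        out: dict[int, ValueDef] = {}
        for c in self.concepts:
            for v in c.value_set:
                out.setdefault(v.omop_id, v)
        return out

    def vocabularies(self) -> set[str]:
        vocs = {c.vocabulary for c in self.concepts}
        vocs.update(v.vocabulary for v in self.distinct_values().values())
        return vocs


@dataclass(frozen=True)
class VocabularyUsage:
    """Marginal vocabulary counts: concept mapping vs. value-set mapping."""

    concept_counts: Mapping[str, int]
    value_counts: Mapping[str, int]

    @property
    def n_concepts(self) -> int:
        return sum(self.concept_counts.values())

    @property
    def n_values(self) -> int:
        return sum(self.value_counts.values())

    @property
    def n_vocabularies(self) -> int:
        return len(set(self.concept_counts) | set(self.value_counts))


@dataclass(frozen=True)
class Violation:
    field_name: str
    cell: str
    reason: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, field_name: str, cell: object, reason: str) -> None:
        self.violations.append(Violation(field_name, str(cell), reason))


# ---------------------------------------------------------------------------
# serialization


def _value_from_dict(raw: Mapping, where: str) -> ValueDef:
    try:
        return ValueDef(
            omop_id=int(raw["omop_id"]),
            vocabulary=str(raw["vocabulary"]),
            label=str(raw["label"]),
            granularity=Granularity(raw.get("granularity", "generic")),
            generic_parent=(
                int(raw["generic_parent"]) if raw.get("generic_parent") else None
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RegistryFormatError(f"{where}: bad value entry {raw!r}: {exc}") from exc


def _concept_from_dict(raw: Mapping, where: str) -> ConceptDef:
    if not isinstance(raw, Mapping) or "field" not in raw:
        raise RegistryFormatError(f"{where}: concept entry must be a mapping with 'field'")
    name = str(raw["field"])
    try:
        domain = ValueDomain(raw["domain"])
        group = ConceptGroup(raw["group"])
        omop_id = int(raw["omop_id"])
        vocabulary = str(raw["vocabulary"])
    except (KeyError, ValueError) as exc:
        raise RegistryFormatError(f"{where}: concept {name!r}: {exc}") from exc
    values = [
        _value_from_dict(v, f"{where}: concept {name!r}")
        for v in raw.get("values", []) or []
    ]
    if domain is not ValueDomain.SCALAR_NUMERIC:
        if all(v.omop_id != NOT_PROVIDED for v in values):
            values.append(NOT_PROVIDED_VALUE)
    return ConceptDef(
        field_name=name,
        omop_id=omop_id,
        vocabulary=vocabulary,
        concept_group=group,
        value_domain=domain,
        value_set=tuple(values),
        units=raw.get("units"),
    )


def load_registry(path: str | Path) -> CDMDefinition:
    """Load and validate a CDM registry from its YAML file.

    The "Not provided" value (763013) is injected into every coded value
    set if the file omits it, so the on-disk file only lists the
    substantive codes.  Concept order in the file is preserved.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise RegistryFormatError(f"cannot read registry {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise RegistryFormatError(f"registry {path} is not valid YAML{line}") from exc
    if not isinstance(doc, Mapping) or "concepts" not in doc:
        raise RegistryFormatError(f"registry {path} must be a mapping with 'concepts'")
    concepts = [
        _concept_from_dict(c, f"{path}") for c in doc["concepts"]
    ]
    return CDMDefinition(concepts=tuple(concepts), version=str(doc.get("version", "0")))


def save_registry(cdm: CDMDefinition, path: str | Path) -> Path:
    """Write a registry back to YAML (inverse of :func:`load_registry`)."""
    out = {"version": cdm.version, "concepts": []}
    for c in cdm.concepts:
        entry: dict = {
            "field": c.field_name,
            "omop_id": c.omop_id,
            "vocabulary": c.vocabulary,
            "group": c.concept_group.value,
            "domain": c.value_domain.value,
        }
        if c.units:
            entry["units"] = c.units
        values = []
        for v in c.value_set:
            if v.omop_id == NOT_PROVIDED:
                continue  # implied; re-injected at load time
            vd: dict = {
                "omop_id": v.omop_id,
                "vocabulary": v.vocabulary,
                "label": v.label,
                "granularity": v.granularity.value,
            }
            if v.generic_parent is not None:
                vd["generic_parent"] = v.generic_parent
            values.append(vd)
        if values:
            entry["values"] = values
        out["concepts"].append(entry)
    path = Path(path)
    path.write_text(
        yaml.safe_dump(out, sort_keys=False, allow_unicode=True, width=100)
    )
    return path


def default_registry_path() -> Path:
    return Path(resources.files("mammocdm").joinpath("data/cdm_registry.yaml"))


def default_registry() -> CDMDefinition:
    """The shipped 38-concept breast-cancer registry."""
    return load_registry(default_registry_path())


def registry_to_csv(cdm: CDMDefinition, path: str | Path) -> Path:
    """Flat CSV export of the registry, for documentation/review."""
    import csv

    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["field", "concept_omop_id", "concept_vocabulary", "group", "domain",
             "value_omop_id", "value_vocabulary", "value_label", "granularity"]
        )
        for c in cdm.concepts:
            if not c.value_set:
                w.writerow([c.field_name, c.omop_id, c.vocabulary,
                            c.concept_group.value, c.value_domain.value,
                            "", "", "", ""])
            for v in c.value_set:
                w.writerow([c.field_name, c.omop_id, c.vocabulary,
                            c.concept_group.value, c.value_domain.value,
                            v.omop_id, v.vocabulary, v.label, v.granularity.value])
    return path


# ---------------------------------------------------------------------------
# composition statistics and record validation


def vocabulary_usage(cdm: CDMDefinition) -> VocabularyUsage:
    """Vocabulary marginals: concepts (inner arc) vs. coded values (outer arc).

    Each concept counts once under its vocabulary.  Each *distinct* coded
    value (by omop_id) counts once under its vocabulary, so values shared
    across concepts — yes/no, "Not provided" — contribute a single count.
    """
    concept_counts = Counter(c.vocabulary for c in cdm.concepts)
    value_counts = Counter(v.vocabulary for v in cdm.distinct_values().values())
    return VocabularyUsage(dict(concept_counts), dict(value_counts))


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def validate_record(record: Mapping[str, object], cdm: CDMDefinition) -> ValidationReport:
    """Check one harmonized row against the registry, cell by cell.

    Violations are collected, never raised: a coded_single cell must be a
    registered value ID, a coded_multi cell a ``|``-joined sequence of
    registered IDs, a scalar cell numeric.  Empty cells are violations —
    missingness must be coded as 763013.
    """
    report = ValidationReport()
    for name, raw in record.items():
        if name not in cdm:
            report.add(name, raw, "unknown field")
            continue
        concept = cdm[name]
        cell = "" if raw is None else str(raw).strip()
        if cell == "":
            report.add(name, raw, "empty cell")
            continue
        if concept.value_domain is ValueDomain.SCALAR_NUMERIC:
            if not _is_number(cell):
                report.add(name, cell, "not numeric")
            continue
        tokens = cell.split("|") if concept.value_domain is ValueDomain.CODED_MULTI else [cell]
        registered = concept.value_ids()
        for tok in tokens:
            tok = tok.strip()
            if not tok.isdigit() or int(tok) not in registered:
                report.add(name, cell, f"unregistered value {tok!r}")
    return report


def random_registry(rng, n_concepts: int = 5, max_values: int = 6) -> CDMDefinition:
    """A small random-but-valid registry (property-test helper)."""
    vocabs = ["SNOMED", "LOINC", "Cancer Modifier", "RxNorm", "HemOnc"]
    concepts = []
    next_id = 10_000
    for i in range(n_concepts):
        domain = rng.choice(
            [ValueDomain.SCALAR_NUMERIC, ValueDomain.CODED_SINGLE, ValueDomain.CODED_MULTI]
        )
        values: list[ValueDef] = []
        if domain is not ValueDomain.SCALAR_NUMERIC:
            for j in range(int(rng.integers(1, max_values + 1))):
                next_id += 1
                values.append(
                    ValueDef(next_id, str(rng.choice(vocabs)), f"value {next_id}")
                )
            values.append(NOT_PROVIDED_VALUE)
        next_id += 1
        concepts.append(
            ConceptDef(
                field_name=f"field_{i}",
                omop_id=next_id,
                vocabulary=str(rng.choice(vocabs)),
                concept_group=ConceptGroup(
                    str(rng.choice([g.value for g in ConceptGroup]))
                ),
                value_domain=domain,
                value_set=tuple(values),
            )
        )
    return CDMDefinition(concepts=tuple(concepts), version="random")
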