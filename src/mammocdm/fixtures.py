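"""Seeded synthetic fixtures: source clinical CSVs and DICOM tag records.

Every other module is testable offline through this one.  The clinical
generator draws, per subject, ground-truth CDM codes and then *renders*
them into each dataset's source conventions — 0/1 binaries, drug-name
arms, free-text clock positions, detailed pN subcategories — so the ETL
can be checked for exact ground-truth recovery.  A ``mess_rate`` fraction
of eligible cells is additionally perturbed with realistic,
semantics-preserving noise (case changes, stray whitespace, trailing
text such as "with calcs"), i.e. exactly the dirtiness the harmonization
rules must tolerate; the recorded truth never changes under noise.

The series generator emits tag maps realizing each MRI technique,
optionally in "anonymized" variants that drop the most direct tag and
must still classify correctly through the fallback rules.

Everything is deterministic under a fixed seed.  Fixture sizes default
to small (tens of subjects); these fixtures validate mechanics, not
epidemiology — no attempt is made to match the real cohorts' joint
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dicom import (
    Orientation,
    SeriesMetadata,
    Technique,
)
from .etl import (
    DatasetId,
    MappingRule,
    MappingSpec,
    RuleKind,
    default_mapping_spec,
    encode_multivalue,
    format_scalar,
    load_clock_table,
    normalize_token,
)
from .registry import NOT_PROVIDED_CELL, CDMDefinition, default_registry

__all__ = [
    "FixtureConfig",
    "SeriesComposition",
    "GeneratedSeries",
    "generate_source_csv",
    "generate_series_metadata",
    "write_series_json",
    "NOISE_SUFFIXES",
]

#: Semantics-preserving trailing noise drawn from the kinds of free-text
#: additions the public CSVs contain ("L 2 with calcs", ...).
NOISE_SUFFIXES = (
    "with calcs",
    "with marker",
    "with clip",
    "anterior",
    "posterior",
    "see notes",
)

_BLANK_P = 0.10  # baseline missingness of optional source cells

_DATASET_SEED = {d: i + 1 for i, d in enumerate(DatasetId)}


@dataclass(frozen=True)
class FixtureConfig:
    dataset_id: DatasetId
    n_subjects: int = 20
    mess_rate: float = 0.0
    seed: int = 0
    out_dir: Path = Path("fixtures")

    def __post_init__(self) -> None:
        object.__setattr__(self, "dataset_id", DatasetId(self.dataset_id))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.mess_rate <= 1.0:
            raise ValueError("mess_rate must be in [0, 1]")


def _subject_id(dataset: DatasetId, i: int) -> str:
    return {
        DatasetId.ISPY2: f"{100001 + i}",
        DatasetId.DUKE: f"Breast_MRI_{i + 1:03d}",
        DatasetId.ISPY1: f"{1001 + i}",
        DatasetId.TCGA_BRCA: f"TCGA-A1-{i + 1:04d}",
        DatasetId.NACT: f"{i + 1}",
    }[dataset]


_SCALAR_RANGES = {
    "age": (25, 85, 0),
    "ki67_percent": (1, 95, 0),
    "tumor_size_mm": (4, 95, 0),
    "followup_months": (6, 120, 1),
}


def _vary_case(token: str, rng: np.random.Generator) -> str:
    op = rng.integers(0, 4)
    if op == 0:
        return token.upper()
    if op == 1:
        return token.capitalize()
    if op == 2:
        return f" {token} "
    return token.lower()


class _ClinicalGenerator:
    """Renders one dataset's fixture from its shipped mapping spec."""

    def __init__(self, config: FixtureConfig, spec: MappingSpec, cdm: CDMDefinition):
        self.config = config
        self.spec = spec
        self.cdm = cdm
        self.rng = np.random.default_rng(
            [config.seed, _DATASET_SEED[config.dataset_id]]
        )
        self.clock = load_clock_table()

    # -- cell helpers ------------------------------------------------------

    def _maybe_blank(self) -> bool:
        return bool(self.rng.random() < _BLANK_P)

    def _mess(self, token: str) -> str:
        if token and self.rng.random() < self.config.mess_rate:
            return _vary_case(token, self.rng)
        return token

    def _draw_mapped(self, rule: MappingRule) -> tuple[str, str]:
        """(source token, truth cell) for a direct_recode rule."""
        if self._maybe_blank():
            return "", NOT_PROVIDED_CELL
        keys = sorted((rule.value_map or {}).keys())
        token = str(self.rng.choice(keys))
        ids = rule.value_map[token]  # type: ignore[index]
        return self._mess(token), str(ids[0])

    def _draw_scalar(self, field_name: str) -> tuple[str, str]:
        if self._maybe_blank():
            return "", NOT_PROVIDED_CELL
        lo, hi, decimals = _SCALAR_RANGES.get(field_name, (1, 100, 0))
        if decimals:
            value = round(float(self.rng.uniform(lo, hi)), decimals)
        else:
            value = int(self.rng.integers(lo, hi + 1))
        cell = format_scalar(value)
        return self._mess(cell) if " " not in cell else cell, format_scalar(value)

    def _draw_position(self) -> tuple[str, str, str]:
        """(source text, truth topography cell, truth laterality cell)."""
        if self._maybe_blank():
            return "", NOT_PROVIDED_CELL, NOT_PROVIDED_CELL
        side = str(self.rng.choice(["left", "right"]))
        side_token = str(self.rng.choice([side[0].upper(), side[0], side.capitalize()]))
        lat_truth = str(self.clock.laterality_codes[side])
        style = int(self.rng.integers(0, 5))
        if style == 0:  # laterality only -> breast NOS
            return side_token, str(self.clock.nos_code), lat_truth
        hour = int(self.rng.integers(1, 13))
        if style == 1:  # plain "L 2"
            text = f"{side_token} {hour}"
            semantic = float(hour % 12)
        elif style == 2:  # no space "R4"
            text = f"{side_token}{hour}"
            semantic = float(hour % 12)
        elif style == 3:  # half hour "L 11:30"
            text = f"{side_token} {hour}:30"
            semantic = (hour % 12) + 0.5
        else:  # range "R4-5" -> midpoint
            nxt = hour % 12 + 1
            text = f"{side_token}{hour}-{nxt}"
            semantic = ((hour % 12) + 0.5) % 12
        if self.rng.random() < self.config.mess_rate:
            text = f"{text} {self.rng.choice(NOISE_SUFFIXES)}"
        return text, str(self.clock.quadrant_for(side, semantic)), lat_truth

    # -- one subject -------------------------------------------------------

    def subject_rows(self, i: int) -> tuple[dict[str, str], dict[str, str]]:
        sid = _subject_id(self.config.dataset_id, i)
        source: dict[str, str] = {self.spec.subject_column: sid}
        truth: dict[str, str] = {f: NOT_PROVIDED_CELL for f in self.cdm.field_names()}
        drawn_tokens: dict[str, str] = {}  # source column -> normalized token

        for rule in self.spec.rules:
            f = rule.target_field
            if rule.kind is RuleKind.CONSTANT:
                truth[f] = str(rule.constant_value)
                continue
            if rule.derivation_id == "hr_from_er_pr":
                continue  # resolved after ER/PR below
            if rule.derivation_id in ("tumor_position", "laterality_from_position"):
                col = rule.source_columns[0]
                if col not in source:
                    text, topo, lat = self._draw_position()
                    source[col] = text
                    drawn_tokens[col + "#topo"] = topo
                    drawn_tokens[col + "#lat"] = lat
                truth[f] = drawn_tokens[
                    col + ("#topo" if rule.derivation_id == "tumor_position" else "#lat")
                ]
                continue
            if rule.derivation_id == "numeric" or (
                rule.kind is RuleKind.DIRECT_RECODE
                and not self.cdm[f].is_coded
            ):
                cell, t = self._draw_scalar(f)
                source[rule.source_columns[0]] = cell
                truth[f] = t
                continue
            if rule.derivation_id == "months_from_days":
                if self._maybe_blank():
                    source[rule.source_columns[0]] = ""
                    continue
                days = int(self.rng.integers(30, 3000))
                source[rule.source_columns[0]] = str(days)
                truth[f] = format_scalar(round(days / 30.4375, 1))
                continue
            if rule.derivation_id == "map_multi_always":
                col = rule.source_columns[0]
                always = [int(v) for v in rule.params.get("always", [])]
                if self._maybe_blank():
                    source[col] = ""
                    truth[f] = encode_multivalue(always) if always else NOT_PROVIDED_CELL
                    continue
                keys = sorted((rule.value_map or {}).keys())
                token = str(self.rng.choice(keys))
                source[col] = self._mess(token)
                truth[f] = encode_multivalue(list(rule.value_map[token]) + always)  # type: ignore[index]
                continue
            if rule.derivation_id == "meds_from_flags":
                chosen: list[int] = []
                for col in rule.source_columns:
                    on = bool(self.rng.random() < 0.4)
                    source[col] = "1" if on else "0"
                    if on:
                        chosen.extend(rule.value_map[normalize_token(col)])  # type: ignore[index]
                truth[f] = encode_multivalue(chosen)
                continue
            # plain direct_recode on a coded field
            col = rule.source_columns[0]
            if col in source:  # second rule over an already-rendered column
                tok = normalize_token(source[col])
                ids = (rule.value_map or {}).get(tok)
                truth[f] = str(ids[0]) if ids else NOT_PROVIDED_CELL
                continue
            cell, t = self._draw_mapped(rule)
            source[col] = cell
            truth[f] = t

        # HR status from the ER/PR truth, by the documented disjunction
        for rule in self.spec.rules:
            if rule.derivation_id == "hr_from_er_pr":
                from .etl import derive_hr_status

                truth[rule.target_field] = str(
                    derive_hr_status(int(truth["er_status"]), int(truth["pr_status"]))
                )

        # overrides win over every rule
        for ov in self.spec.overrides:
            if ov.subject_id == sid:
                truth[ov.field_name] = str(ov.value_id)

        # unmapped decoy columns, never read by any rule
        source["Comments"] = ""
        source["Acquisition Notes"] = str(self.rng.integers(0, 999))
        return source, truth


def generate_source_csv(
    config: FixtureConfig, cdm: CDMDefinition | None = None
) -> tuple[Path, Path]:
    """Write one dataset's synthetic source CSV and its truth CSV.

    Returns ``(source_path, truth_path)``.  The truth file records, per
    subject, the CDM cell every field must harmonize to; the source file
    follows the dataset's column conventions, including the decorative
    top row the real DUKE spreadsheet carries.
    """
    cdm = cdm or default_registry()
    spec = default_mapping_spec(config.dataset_id)
    gen = _ClinicalGenerator(config, spec, cdm)

    source_rows, truth_rows = [], []
    for i in range(config.n_subjects):
        s, t = gen.subject_rows(i)
        source_rows.append(s)
        truth_rows.append({spec.subject_column: s[spec.subject_column], **t})

    config.out_dir.mkdir(parents=True, exist_ok=True)
    name = config.dataset_id.value.lower()
    source_path = config.out_dir / f"{name}_source.csv"
    truth_path = config.out_dir / f"{name}_truth.csv"

    frame = pd.DataFrame(source_rows)
    csv_text = frame.to_csv(index=False, lineterminator="\n")
    # the real DUKE spreadsheet carries decorative rows above the header
    for _ in range(spec.skip_rows):
        banner = ",".join(
            ["Synthetic clinical export"] + [""] * (len(frame.columns) - 1)
        )
        csv_text = banner + "\n" + csv_text
    source_path.write_text(csv_text)
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False, lineterminator="\n")
    return source_path, truth_path


# ---------------------------------------------------------------------------
# imaging series fixtures


@dataclass(frozen=True)
class SeriesComposition:
    counts: Mapping[str, int]
    orientation_mix: Mapping[str, float] = dc_field(
        default_factory=lambda: {"AXIAL": 0.6, "SAGITTAL": 0.3, "CORONAL": 0.1}
    )
    anonymized_fraction: float = 0.25
    collection: str = "SYNTH-BREAST-MRI"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("technique counts must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError("series composition is empty")


@dataclass(frozen=True)
class GeneratedSeries:
    meta: SeriesMetadata
    technique: Technique
    orientation: Orientation


_IOP = {
    Orientation.AXIAL: "1\\0\\0\\0\\1\\0",
    Orientation.SAGITTAL: "0\\1\\0\\0\\0\\-1",
    Orientation.CORONAL: "1\\0\\0\\0\\0\\-1",
    Orientation.OBLIQUE: "0.7071\\0.7071\\0\\0\\0\\-1",
}


def _series_tags(
    technique: Technique,
    orientation: Orientation,
    rng: np.random.Generator,
    anonymized: bool,
) -> tuple[dict, Orientation]:
    if technique is Technique.UNKNOWN:
        return {}, Orientation.UNKNOWN
    tags: dict[str, object] = {"(0020,0037)": _IOP[orientation]}
    if technique is Technique.DCE:
        flip = int(rng.integers(8, 16))
        tags.update({
            "(0018,0020)": "GR",
            "(0018,0023)": "3D",
            "(0018,1314)": str(flip),
            "(0008,103E)": f"dyn 3d vibrant ph{int(rng.integers(1, 7))}",
            "(0020,0105)": str(int(rng.integers(40, 90))),
        })
        if anonymized:
            del tags["(0020,0105)"]  # fallback: GR + 3D + low flip angle
    elif technique is Technique.DWI:
        b = int(rng.choice([0, 50, 400, 600, 800, 1000]))
        tags.update({
            "(0018,0020)": "EP\\SE",
            "(0018,0023)": "2D",
            "(0008,103E)": f"ax dwi b{b}",
            "(0018,9075)": "ISOTROPIC",
        })
        if rng.random() < 0.5:
            tags["(0018,9087)"] = str(b)
        else:  # GE private encoding with the 10^9 ordering offset
            tags["(0043,1039)"] = [1_000_000_000 + b, 8, 0, 0]
        if anonymized:
            del tags["(0008,103E)"]  # still EP + diffusion tags
    elif technique is Technique.T1W:
        tags.update({
            "(0018,0020)": "SE",
            "(0018,0023)": "2D",
            "(0018,1314)": "90",
            "(0008,103E)": "sag t1 fse",
        })
        if anonymized:
            del tags["(0008,103E)"]  # still spin echo
    elif technique is Technique.T2W:
        tags.update({
            "(0018,0020)": "SE",
            "(0018,0023)": "2D",
            "(0008,103E)": str(rng.choice(["ax t2 fat sat", "stir cor", "t2 tirm"])),
        })
        if anonymized:
            del tags["(0018,0020)"]  # description keywords still decide
    else:  # OTHER: technically complete tags that fire no technique rule
        tags.update({
            "(0018,0020)": "GR",
            "(0018,0023)": "2D",
            "(0018,1314)": "70",
            "(0008,103E)": "cal body localizer",
        })
    return tags, orientation


def generate_series_metadata(comp: SeriesComposition) -> list[GeneratedSeries]:
    """Generate series tag records realizing the requested composition.

    Each series carries tags sufficient for its ground-truth technique;
    an ``anonymized_fraction`` of them drop the most direct tag and must
    classify correctly via the fallback path.
    """
    rng = np.random.default_rng([comp.seed, 97])
    orientations = sorted(comp.orientation_mix.keys())
    weights = np.array([comp.orientation_mix[o] for o in orientations], dtype=float)
    weights = weights / weights.sum()
    out: list[GeneratedSeries] = []
    n = 0
    for tech_name in sorted(comp.counts):
        technique = Technique(tech_name)
        for _ in range(comp.counts[tech_name]):
            n += 1
            orient = Orientation(str(rng.choice(orientations, p=weights)))
            anonymized = bool(rng.random() < comp.anonymized_fraction)
            tags, truth_orient = _series_tags(technique, orient, rng, anonymized)
            meta = SeriesMetadata(
                series_uid=f"1.2.826.0.1.{comp.seed % 10_000}.{n}",
                collection=comp.collection,
                subject_id=f"SYN-{1 + n % 25:03d}",
                tags=tags,
            )
            out.append(GeneratedSeries(meta, technique, truth_orient))
    return out


def write_series_json(series: Sequence[GeneratedSeries], path: str | Path) -> Path:
    """Dump generated series (with their truth labels) as a JSON fixture
    readable by :func:`mammocdm.dicom.load_series_json`."""
    import json

    doc = []
    for gs in series:
        doc.append({
            "series_uid": gs.meta.series_uid,
            "collection": gs.meta.collection,
            "subject_id": gs.meta.subject_id,
            "tags": {f"({g},{e})": v for (g, e), v in gs.meta.tags.items()},
            "truth_technique": gs.technique.value,
            "truth_orientation": gs.orientation.value,
        })
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path
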