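"""DICOM series metadata: acquisition, technique classification, statistics.

Works on per-series *tag maps* — ``(group, element)`` hex pairs to raw
values — as served by the NBIA Advanced REST API or dumped from local
headers, never on pixel data.  Public collections are anonymized
unevenly, so classification is total over arbitrarily sparse tag maps
and falls back to technical-setup tags (gradient-echo + 3D + low flip
angle reads as dynamic contrast-enhanced) when the direct evidence
(number of temporal positions) has been stripped.

Diffusion series are recognized as echo-planar acquisitions carrying
diffusion evidence; the b-value is read from the standard tag
(0018,9087) or, on GE scanners, from the private tag (0043,1039), whose
first element encodes the b-value with an offset of 10^9 used by the
vendor to flag its b-value ordering scheme.
"""

from __future__ import annotations

import enum
import json
import logging
import math
import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import yaml

__all__ = [
    "TagKey",
    "Technique",
    "Orientation",
    "SeriesMetadata",
    "SeriesLabel",
    "TechniqueStats",
    "ClassifierRules",
    "MetadataClient",
    "NBIAClient",
    "normalize_tag_key",
    "normalize_tags",
    "orientation_from_cosines",
    "parse_diffusion_bvalue",
    "classify_series",
    "technique_statistics",
    "fetch_collection_series",
    "load_series_json",
    "read_dicom_file_tags",
]

log = logging.getLogger(__name__)

TagKey = tuple[str, str]

TAG_SCANNING_SEQUENCE: TagKey = ("0018", "0020")
TAG_ACQUISITION_TYPE: TagKey = ("0018", "0023")
TAG_ORIENTATION: TagKey = ("0020", "0037")
TAG_SEQUENCE_NAME: TagKey = ("0018", "0024")
TAG_SERIES_DESCRIPTION: TagKey = ("0008", "103E")
TAG_IMAGE_TYPE: TagKey = ("0008", "0008")
TAG_FLIP_ANGLE: TagKey = ("0018", "1314")
TAG_DIFFUSION_DIRECTIONALITY: TagKey = ("0018", "9075")
TAG_GE_BVALUE: TagKey = ("0043", "1039")
TAG_BVALUE: TagKey = ("0018", "9087")
TAG_TEMPORAL_POSITIONS: TagKey = ("0020", "0105")

#: GE stores the b-value in the first element of (0043,1039) with 10^9
#: added when the scanner's b-value ordering scheme is in effect.
GE_BVALUE_OFFSET = 1_000_000_000


class Technique(str, enum.Enum):
    DCE = "DCE"
    DWI = "DWI"
    T1W = "T1W"
    T2W = "T2W"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Orientation(str, enum.Enum):
    AXIAL = "AXIAL"
    SAGITTAL = "SAGITTAL"
    CORONAL = "CORONAL"
    OBLIQUE = "OBLIQUE"
    UNKNOWN = "UNKNOWN"


_TAG_RE = re.compile(r"^\(?\s*([0-9a-fA-F]{4})\s*,\s*([0-9a-fA-F]{4})\s*\)?$")


def normalize_tag_key(key: object) -> TagKey:
    """Coerce any common tag spelling to an uppercase hex pair.

    Accepts ``("0020", "0105")``, ``"(0020,0105)"``, ``"0020,0105"`` and
    ``"00200105"`` — keeps round-tripping between API JSON and local
    header dumps dialect-proof.
    """
    if isinstance(key, (tuple, list)) and len(key) == 2:
        g, e = str(key[0]), str(key[1])
        return (g.zfill(4).upper(), e.zfill(4).upper())
    s = str(key).strip()
    m = _TAG_RE.match(s)
    if m:
        return (m.group(1).upper(), m.group(2).upper())
    compact = s.replace("(", "").replace(")", "").replace(",", "").replace(" ", "")
    if re.fullmatch(r"[0-9a-fA-F]{8}", compact):
        return (compact[:4].upper(), compact[4:].upper())
    raise ValueError(f"not a DICOM tag key: {key!r}")


def normalize_tags(raw: object) -> dict[TagKey, object]:
    """Normalize a raw tag record (mapping, or NBIA-style list of
    ``{"element": ..., "data": ...}`` entries) to a tag map."""
    out: dict[TagKey, object] = {}
    if isinstance(raw, Mapping):
        items: Iterable = raw.items()
        for k, v in items:
            out[normalize_tag_key(k)] = v
    elif isinstance(raw, Sequence) and not isinstance(raw, (str, bytes)):
        for entry in raw:
            if not isinstance(entry, Mapping) or "element" not in entry:
                raise ValueError(f"malformed tag entry: {entry!r}")
            out[normalize_tag_key(entry["element"])] = entry.get("data")
    else:
        raise ValueError(f"cannot interpret tag record of type {type(raw).__name__}")
    return out


@dataclass
class SeriesMetadata:
    series_uid: str
    collection: str
    subject_id: str = ""
    tags: dict[TagKey, object] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.series_uid:
            raise ValueError("series_uid must be non-empty")
        self.tags = {normalize_tag_key(k): v for k, v in self.tags.items()}

    def tag_str(self, key: TagKey) -> str | None:
        v = self.tags.get(key)
        if v is None:
            return None
        if isinstance(v, (list, tuple)):
            return "\\".join(str(x) for x in v)
        return str(v)


@dataclass(frozen=True)
class SeriesLabel:
    technique: Technique
    orientation: Orientation
    evidence: tuple[tuple[str, str], ...] = ()
    b_values: tuple[float, ...] | None = None


@dataclass(frozen=True)
class TechniqueStats:
    collection: str
    counts: Mapping[str, int]
    total: int


@dataclass(frozen=True)
class ClassifierRules:
    dce_flip_angle_threshold: float = 20.0
    obliquity_threshold: float = 0.8
    diffusion_description_patterns: tuple[str, ...] = (
        "dwi", "diffusion", "adc", "trace", r"\bdif\b",
    )
    t2_description_patterns: tuple[str, ...] = ("t2", "stir", "tirm")
    t1_description_patterns: tuple[str, ...] = ("t1",)

    @staticmethod
    def load(path: str | Path | None = None) -> "ClassifierRules":
        if path is None:
            path = resources.files("mammocdm").joinpath("data/dicom_rules.yaml")
        doc = yaml.safe_load(Path(str(path)).read_text())
        return ClassifierRules(
            dce_flip_angle_threshold=float(doc["dce_flip_angle_threshold"]),
            obliquity_threshold=float(doc["obliquity_threshold"]),
            diffusion_description_patterns=tuple(doc["diffusion_description_patterns"]),
            t2_description_patterns=tuple(doc["t2_description_patterns"]),
            t1_description_patterns=tuple(doc["t1_description_patterns"]),
        )


_DEFAULT_RULES: ClassifierRules | None = None


def default_rules() -> ClassifierRules:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = ClassifierRules.load()
    return _DEFAULT_RULES


# ---------------------------------------------------------------------------
# orientation


def _floats(value: object) -> list[float] | None:
    if value is None:
        return None
    if isinstance(value, (list, tuple)):
        parts = [str(p) for p in value]
    else:
        parts = re.split(r"[\\/,;\s]+", str(value).strip())
    try:
        return [float(p) for p in parts if p != ""]
    except ValueError:
        return None


def orientation_from_cosines(
    iop: object, obliquity_threshold: float = 0.8
) -> Orientation:
    """Acquisition plane from the six Image Orientation (Patient) cosines.

    The slice normal is the cross product of the row and column direction
    vectors; the plane is named after the patient axis the normal mostly
    points along (x: sagittal, y: coronal, z: axial).  If no component of
    the unit normal reaches the obliquity threshold the plane is OBLIQUE;
    a missing or malformed tag yields UNKNOWN.
    """
    vals = _floats(iop)
    if vals is None or len(vals) != 6 or not all(math.isfinite(v) for v in vals):
        return Orientation.UNKNOWN
    r, c = vals[:3], vals[3:]
    n = [
        r[1] * c[2] - r[2] * c[1],
        r[2] * c[0] - r[0] * c[2],
        r[0] * c[1] - r[1] * c[0],
    ]
    norm = math.sqrt(sum(v * v for v in n))
    if norm < 1e-9:
        return Orientation.UNKNOWN
    n = [v / norm for v in n]
    axis = max(range(3), key=lambda i: abs(n[i]))
    if abs(n[axis]) < obliquity_threshold:
        return Orientation.OBLIQUE
    return (Orientation.SAGITTAL, Orientation.CORONAL, Orientation.AXIAL)[axis]


# ---------------------------------------------------------------------------
# diffusion b-value


def parse_diffusion_bvalue(tags: Mapping[TagKey, object]) -> float | None:
    """Diffusion b-value (s/mm²) from the standard or the GE private tag.

    The standard tag (0018,9087) wins.  Otherwise the first element of GE
    (0043,1039) is used, reduced by 10^9 when the vendor offset is
    present.  Returns None if neither tag parses.
    """
    std = tags.get(TAG_BVALUE)
    if std is not None:
        vals = _floats(std)
        if vals:
            return vals[0]
        log.warning("non-numeric diffusion b-value tag content: %r", std)
    ge = tags.get(TAG_GE_BVALUE)
    if ge is not None:
        vals = _floats(ge)
        if vals:
            b = vals[0]
            if b >= GE_BVALUE_OFFSET:
                b -= GE_BVALUE_OFFSET
            return b
        log.warning("non-numeric GE b-value tag content: %r", ge)
    return None


# ---------------------------------------------------------------------------
# classification


def _matches_any(text: str | None, patterns: Sequence[str]) -> str | None:
    if not text:
        return None
    for pat in patterns:
        if re.search(pat, text, re.IGNORECASE):
            return pat
    return None


def _parse_float(token: str | None) -> float | None:
    vals = _floats(token) if token is not None else None
    return vals[0] if vals else None


def classify_series(
    meta: SeriesMetadata, rules: ClassifierRules | None = None
) -> SeriesLabel:
    """Assign an MRI technique and acquisition plane to one series.

    Total and deterministic over sparse tag maps.  Rule precedence is
    DWI > DCE > T2W/T1W > OTHER, most-specific evidence first: diffusion
    b-value tags are unambiguous, temporal positions nearly so, while
    anatomical contrasts rest on free-text description keywords.  An
    empty tag map is UNKNOWN.
    """
    rules = rules or default_rules()
    if not meta.tags:
        return SeriesLabel(Technique.UNKNOWN, Orientation.UNKNOWN)

    evidence: list[tuple[str, str]] = []
    orientation = orientation_from_cosines(
        meta.tags.get(TAG_ORIENTATION), rules.obliquity_threshold
    )
    if orientation is not Orientation.UNKNOWN:
        evidence.append(("(0020,0037)", f"orientation={orientation.value}"))

    seq = (meta.tag_str(TAG_SCANNING_SEQUENCE) or "").upper()
    seq_tokens = set(re.split(r"[\\\s,]+", seq)) - {""}
    desc = meta.tag_str(TAG_SERIES_DESCRIPTION) or ""
    seq_name = meta.tag_str(TAG_SEQUENCE_NAME) or ""

    # --- DWI: echo-planar (or diffusion-named) + diffusion evidence
    epi = "EP" in seq_tokens
    diff_pat = _matches_any(desc, rules.diffusion_description_patterns) or _matches_any(
        seq_name, rules.diffusion_description_patterns
    )
    diff_tags = [
        t for t in (TAG_BVALUE, TAG_DIFFUSION_DIRECTIONALITY, TAG_GE_BVALUE)
        if t in meta.tags
    ]
    if (epi or diff_pat) and diff_tags:
        if epi:
            evidence.append(("(0018,0020)", "echo-planar scanning sequence"))
        if diff_pat:
            evidence.append(("(0008,103E)/(0018,0024)", f"matches /{diff_pat}/"))
        for t in diff_tags:
            evidence.append((f"({t[0]},{t[1]})", "diffusion tag present"))
        b = parse_diffusion_bvalue(meta.tags)
        return SeriesLabel(
            Technique.DWI,
            orientation,
            tuple(evidence),
            (b,) if b is not None else None,
        )

    # --- DCE: repeated temporal positions, else GR/3D/low-flip fallback
    ntp = _parse_float(meta.tag_str(TAG_TEMPORAL_POSITIONS))
    if ntp is not None and ntp > 1:
        evidence.append(("(0020,0105)", f"temporal positions = {int(ntp)} > 1"))
        return SeriesLabel(Technique.DCE, orientation, tuple(evidence))
    flip = _parse_float(meta.tag_str(TAG_FLIP_ANGLE))
    acq = (meta.tag_str(TAG_ACQUISITION_TYPE) or "").strip().upper()
    if (
        "GR" in seq_tokens
        and acq == "3D"
        and flip is not None
        and flip < rules.dce_flip_angle_threshold
    ):
        evidence.append(("(0018,0020)", "gradient echo"))
        evidence.append(("(0018,0023)", "3D acquisition"))
        evidence.append(("(0018,1314)", f"flip angle {flip:g} < "
                                        f"{rules.dce_flip_angle_threshold:g}"))
        return SeriesLabel(Technique.DCE, orientation, tuple(evidence))

    # --- anatomical contrasts from description keywords / spin echo
    t2 = _matches_any(desc, rules.t2_description_patterns)
    if t2:
        evidence.append(("(0008,103E)", f"matches /{t2}/"))
        return SeriesLabel(Technique.T2W, orientation, tuple(evidence))
    t1 = _matches_any(desc, rules.t1_description_patterns)
    if t1 or "SE" in seq_tokens:
        if t1:
            evidence.append(("(0008,103E)", f"matches /{t1}/"))
        if "SE" in seq_tokens:
            evidence.append(("(0018,0020)", "spin echo"))
        return SeriesLabel(Technique.T1W, orientation, tuple(evidence))

    evidence.append(("*", "tags present but no technique rule fired"))
    return SeriesLabel(Technique.OTHER, orientation, tuple(evidence))


def technique_statistics(
    series: Sequence[SeriesMetadata], rules: ClassifierRules | None = None
) -> TechniqueStats:
    """Classify a collection's series and tally techniques."""
    collections = {s.collection for s in series}
    if len(collections) > 1:
        raise ValueError(f"mixed collections in one tally: {sorted(collections)}")
    counts = {t.value: 0 for t in Technique}
    for s in series:
        counts[classify_series(s, rules).technique.value] += 1
    return TechniqueStats(
        collection=collections.pop() if collections else "",
        counts=counts,
        total=len(series),
    )


# ---------------------------------------------------------------------------
# metadata acquisition (injectable client + write-through cache)


class MetadataClient(Protocol):
    """Source of series metadata: the NBIA Advanced REST API or any local
    stand-in (tests use recorded/synthetic fixtures)."""

    def list_series(self, collection: str) -> list[dict]:
        """Return one record per series; each must carry 'SeriesInstanceUID'
        and may carry 'PatientID'."""
        ...

    def get_series_tags(self, series_uid: str) -> object:
        """Return the raw per-series DICOM tag record."""
        ...


class NBIAClient:
    """Thin live client for the NBIA Advanced REST API (stdlib urllib)."""

    def __init__(self, base_url: str = "https://services.cancerimagingarchive.net/nbia-api/services/v1"):
        self.base_url = base_url.rstrip("/")

    def _get_json(self, path: str, **params: str) -> object:
        import urllib.parse
        import urllib.request

        url = f"{self.base_url}/{path}"
        if params:
            url += "?" + urllib.parse.urlencode(params)
        with urllib.request.urlopen(url, timeout=60) as resp:  # noqa: S310
            return json.load(resp)

    def list_series(self, collection: str) -> list[dict]:
        data = self._get_json("getSeries", Collection=collection)
        return list(data)  # type: ignore[arg-type]

    def get_series_tags(self, series_uid: str) -> object:
        return self._get_json("getDicomTags", SeriesUID=series_uid)


def _cache_paths(cache_dir: Path, collection: str) -> tuple[Path, Path]:
    cdir = cache_dir / collection
    return cdir, cdir / "_index.json"


def fetch_collection_series(
    collection: str,
    client: MetadataClient | None,
    cache_dir: str | Path,
) -> list[SeriesMetadata]:
    """All series metadata for one collection, through a write-through cache.

    Cold cache: one listing request plus one tag request per series, each
    written to the cache (one JSON document per series UID) before the
    collection index is committed.  Warm cache: everything is served from
    disk and zero per-series requests are issued, so repeated runs are
    fast and byte-identical.
    """
    cache_dir = Path(cache_dir)
    cdir, index_path = _cache_paths(cache_dir, collection)
    if index_path.exists():
        index = json.loads(index_path.read_text())
        out = []
        for entry in index:
            uid = entry["series_uid"]
            tag_doc = json.loads((cdir / f"{uid}.json").read_text())
            out.append(
                SeriesMetadata(
                    series_uid=uid,
                    collection=collection,
                    subject_id=entry.get("subject_id", ""),
                    tags=normalize_tags(tag_doc),
                )
            )
        return out

    if client is None:
        raise ConnectionError(
            f"cold cache for collection {collection!r} and no client provided"
        )
    try:
        listing = client.list_series(collection)
    except OSError as exc:
        raise ConnectionError(f"listing series for {collection!r} failed: {exc}") from exc
    cdir.mkdir(parents=True, exist_ok=True)
    out = []
    index = []
    for rec in listing:
        uid = str(rec.get("SeriesInstanceUID", "")).strip()
        if not uid:
            raise ValueError(f"listing entry without SeriesInstanceUID: {rec!r}")
        try:
            raw = client.get_series_tags(uid)
            tags = normalize_tags(raw)
        except OSError as exc:
            raise ConnectionError(f"tag fetch for {uid} failed: {exc}") from exc
        except ValueError as exc:
            raise ValueError(f"malformed tag response for series {uid}: {exc}") from exc
        subject = str(rec.get("PatientID", "") or "")
        (cdir / f"{uid}.json").write_text(
            json.dumps({f"({g},{e})": v for (g, e), v in tags.items()}, sort_keys=True)
        )
        index.append({"series_uid": uid, "subject_id": subject})
        out.append(
            SeriesMetadata(
                series_uid=uid, collection=collection, subject_id=subject, tags=tags
            )
        )
    index_path.write_text(json.dumps(index, indent=0))
    return out


def load_series_json(path: str | Path) -> list[SeriesMetadata]:
    """Load series metadata from a local JSON dump (the synthetic-fixture
    format: a list of records with series_uid/collection/subject_id/tags)."""
    doc = json.loads(Path(path).read_text())
    return [
        SeriesMetadata(
            series_uid=rec["series_uid"],
            collection=rec.get("collection", ""),
            subject_id=rec.get("subject_id", ""),
            tags=normalize_tags(rec.get("tags", {})),
        )
        for rec in doc
    ]


def read_dicom_file_tags(path: str | Path, collection: str = "") -> SeriesMetadata:
    """Read the header of a DICOM part-10 file into a SeriesMetadata
    (pixel data is never touched)."""
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    tags: dict[TagKey, object] = {}
    for elem in ds:
        key = (f"{elem.tag.group:04X}", f"{elem.tag.element:04X}")
        if elem.VR == "SQ":
            continue
        value = elem.value
        if isinstance(value, (list, tuple)) or type(value).__name__ == "MultiValue":
            tags[key] = [str(v) for v in value]
        else:
            tags[key] = str(value)
    return SeriesMetadata(
        series_uid=str(getattr(ds, "SeriesInstanceUID", "")) or "unknown",
        collection=collection,
        subject_id=str(getattr(ds, "PatientID", "")),
        tags=tags,
    )
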