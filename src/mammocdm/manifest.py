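"""NBIA Retriever manifest (.tcia) files: write and re-read.

The manifest is a plain-text handoff format: a fixed block of
``key=value`` header lines, the literal marker line
``ListOfSeriesToDownload=``, then one series instance UID per line.  The
writer is byte-stable so manifests can be regression-tested; the reader
exists as the writer's inverse (and to ingest manifests produced by
other tools).  The header defaults mirror current NBIA Retriever
conventions, including the tool's historical key spelling ``noOfrRetry``,
kept verbatim for bit-compatibility with the consumer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = ["ManifestSpec", "ManifestError", "write_manifest", "read_manifest"]

DEFAULT_SERVER_URL = "https://services.cancerimagingarchive.net/nbia-download/servlet/DownloadServlet"
DEFAULT_MANIFEST_VERSION = "3.0"
DEFAULT_RETRIES = 4

MARKER_LINE = "ListOfSeriesToDownload="

_HEADER_KEYS = (
    "downloadServerUrl",
    "includeAnnotation",
    "noOfrRetry",
    "databasketId",
    "manifestVersion",
)


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class ManifestSpec:
    series_uids: tuple[str, ...]
    server_url: str = DEFAULT_SERVER_URL
    include_annotation: bool = True
    retries: int = DEFAULT_RETRIES
    basket_id: str = "manifest"
    manifest_version: str = DEFAULT_MANIFEST_VERSION
    #: unknown header lines found by the reader, preserved verbatim
    extra_headers: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "series_uids", tuple(self.series_uids))
        if not self.series_uids:
            raise ManifestError("a manifest must list at least one series UID")
        seen = set()
        for uid in self.series_uids:
            if not uid or uid != uid.strip():
                raise ManifestError(f"bad series UID: {uid!r}")
            if uid in seen:
                raise ManifestError(f"duplicate series UID: {uid}")
            seen.add(uid)
        if self.retries < 0:
            raise ManifestError("retries must be non-negative")


def write_manifest(spec: ManifestSpec, path: str | Path) -> Path:
    """Write the manifest; identical specs produce byte-identical files."""
    lines = [
        f"downloadServerUrl={spec.server_url}",
        f"includeAnnotation={'true' if spec.include_annotation else 'false'}",
        f"noOfrRetry={spec.retries}",
        f"databasketId={spec.basket_id}",
        f"manifestVersion={spec.manifest_version}",
        MARKER_LINE,
        *spec.series_uids,
    ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", newline="\n")
    return path


def read_manifest(path: str | Path) -> ManifestSpec:
    """Inverse of :func:`write_manifest` on its image.

    Unknown header keys are warned about and preserved in
    ``extra_headers``; a file without the marker line is rejected.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if MARKER_LINE not in lines:
        raise ManifestError(f"{path}: missing marker line {MARKER_LINE!r}")
    marker_at = lines.index(MARKER_LINE)
    headers: dict[str, str] = {}
    extra: dict[str, str] = {}
    for line in lines[:marker_at]:
        if not line.strip():
            continue
        if "=" not in line:
            raise ManifestError(f"{path}: malformed header line {line!r}")
        key, _, value = line.partition("=")
        if key in _HEADER_KEYS:
            headers[key] = value
        else:
            log.warning("%s: unknown manifest header %r preserved", path, key)
            extra[key] = value
    uids = [ln.strip() for ln in lines[marker_at + 1 :] if ln.strip()]
    return ManifestSpec(
        series_uids=tuple(uids),
        server_url=headers.get("downloadServerUrl", DEFAULT_SERVER_URL),
        include_annotation=headers.get("includeAnnotation", "true").lower() == "true",
        retries=int(headers.get("noOfrRetry", DEFAULT_RETRIES)),
        basket_id=headers.get("databasketId", "manifest"),
        manifest_version=headers.get("manifestVersion", DEFAULT_MANIFEST_VERSION),
        extra_headers=extra,
    )
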