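"""Cherry-pick series and write an NBIA Retriever manifest.

Filters a synthetic collection down to axial DWI series and writes the
.tcia manifest NBIA Retriever consumes to download exactly those series
— the final step of selecting a technique-specific imaging subset
without downloading anything else first.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from mammocdm import (
    ManifestSpec,
    SeriesComposition,
    classify_series,
    read_manifest,
    write_manifest,
)
from mammocdm.fixtures import generate_series_metadata

comp = SeriesComposition(
    counts={"DCE": 6, "DWI": 4, "T2W": 3},
    orientation_mix={"AXIAL": 0.7, "SAGITTAL": 0.3},
    seed=5,
)
series = [gs.meta for gs in generate_series_metadata(comp)]

selected = [
    s.series_uid
    for s in series
    if (label := classify_series(s)).technique.value == "DWI"
    and label.orientation.value == "AXIAL"
]
print(f"{len(series)} series in collection; {len(selected)} match "
      "technique=DWI AND orientation=AXIAL")

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "dwi_axial.tcia"
    write_manifest(ManifestSpec(series_uids=tuple(selected),
                                basket_id="dwi-axial-demo"), path)
    print(f"\nmanifest ({path.name}):")
    print(path.read_text())
    assert read_manifest(path).series_uids == tuple(selected)
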