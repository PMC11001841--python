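# mammocdm

Harmonization of public breast-cancer clinical and MRI metadata into a
single, fully coded common data model (CDM), plus DICOM-header-based
cherry-picking of MRI series.

## The problem

Public breast-cancer collections (ISPY2, Duke-Breast-Cancer-MRI, ISPY1,
TCGA-BRCA, Breast-MRI-NACT-Pilot) each ship a clinical table with its own
schema and conventions — 0/1 binaries, drug names in an "Arm" column,
free-text tumor clock positions like `"L 2 with calcs"`, numeric pN
staging with `-1` meaning NX — and MRI series whose technique (dynamic
contrast-enhanced, diffusion-weighted, T1/T2-weighted) is only
discoverable from DICOM header tags, many of which anonymization has
stripped. Neither half can be used directly to assemble an AI-ready
cohort.

`mammocdm` addresses both halves:

* **A CDM registry** of 38 clinical concepts, each mapped to an OMOP
  standardized-vocabulary concept ID, with closed coded value sets (135
  distinct values from 12 vocabularies). Cells are numbers or registered
  codes — never free text, never empty: missingness is itself coded as
  OMOP 763013 ("Not provided").
* **A declarative ETL**: one mapping spec per dataset (YAML, reviewable,
  re-runnable) with four rule kinds — direct recodes, constants encoding
  study-design knowledge (e.g. every neoadjuvant-trial subject received
  neoadjuvant chemotherapy), named derivations (hormone-receptor status
  as the disjunction of ER and PR), and parsers (breast clock position →
  ICD-O-3 quadrant, tolerating half hours, hour ranges and trailing
  noise). Per-subject overrides curated from comment fields are applied
  last. The run is deterministic: byte-identical output on re-run.
* **A DICOM series classifier** over per-series tag maps (from the NBIA
  Advanced REST API, cached write-through, or local dumps): DWI from
  echo-planar acquisition plus diffusion tags — including the GE private
  b-value tag (0043,1039) with its 10⁹ offset; DCE from repeated
  temporal positions, falling back to gradient-echo + 3D + low flip
  angle when anonymized; orientation from the image-orientation cosines.
* **NBIA Retriever manifests** (`.tcia`) for exactly the selected series.
* **Seeded synthetic fixtures** emulating each dataset's schema and
  messiness with known ground truth, so the whole pipeline is testable
  offline.

## Worked example

```bash
python examples/harmonize_fixture.py
```

```
DUKE: 8/8 subjects, 36 CDM concepts mapped (49% of the source's 74 concepts)

subject Breast_MRI_001:
  source 'Tumor Location' = 'l 12:30 posterior'
  -> tumor_position = 36402335 (ICD-O-3 quadrant code)
  -> laterality     = 4300877
  source ER='1', PR='1'
  -> hr_status      = 9191 (9191 positive / 9189 negative / 763013 not provided)

empty cells in harmonized output: 0
```

Reading the output: the messy clock position `l 12:30 posterior` parses
to 12:30 on the left breast, which falls in the upper-outer quadrant —
code 36402335 (ICD-O-3 C50.4); laterality is recorded separately as
4300877 (left). ER and PR are both positive, so the derived
hormone-receptor status is 9191 (positive). Every one of the 38 CDM
cells per subject is filled.

The other examples summarize the registry (`registry_summary.py`),
classify a synthetic series collection and decode a GE b-value
(`classify_series.py`), and write a download manifest for axial DWI
series only (`build_manifest.py`).

There is also a CLI for the full workflow:

```bash
mammocdm fixtures --n 20 --seed 1 --out-dir fx --series "DWI=5,DCE=7"
mammocdm harmonize --all fx --out harmonized.csv --coverage-out coverage.csv
mammocdm stats --fixtures fx/series_metadata.json
mammocdm manifest --fixtures fx/series_metadata.json --filter technique=DWI --out dwi.tcia
```

Exit codes: 0 success, 2 configuration error, 3 empty selection,
1 unexpected failure.

## Layout

```
src/mammocdm/
  registry.py   CDM concepts, value sets, validation
  etl.py        mapping specs, harmonization engine, value normalizers
  dicom.py      series metadata, technique/orientation classification, cache
  manifest.py   NBIA Retriever .tcia files
  fixtures.py   seeded synthetic sources and series
  cli.py        command-line wrapper
  data/         the shipped registry, per-dataset mapping specs,
                clock-quadrant table, classifier rule config
```

See `docs/methods.md` for the modelling decisions and their rationale.
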