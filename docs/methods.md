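# Methods

This note documents the modelling and design decisions behind
`mammocdm`: what the common data model commits to, how the ETL rules are
defined where the source conventions are ambiguous, how MRI series are
classified from incomplete headers, and what the synthetic fixtures do
and do not demonstrate.

## The common data model

The registry (`data/cdm_registry.yaml`) defines 38 clinical concepts in
four groups (demographic, pathology, treatment, outcome). Each concept
carries an OMOP standardized-vocabulary concept ID and is either

* `scalar_numeric` — a number with documented units (age in years,
  tumor size in mm, Ki-67 in percent, follow-up in months), or
* `coded_single` / `coded_multi` — a closed value set of OMOP-coded
  values.

Design commitments:

* **Coded missingness.** Every coded value set contains "Not provided"
  (OMOP 763013). The harmonized table therefore has no empty cells by
  construction; consumers never need a sentinel convention. The loader
  injects 763013 into every coded set so the data file lists only
  substantive codes.
* **Detailed + generic retention.** Where sources disagree in
  granularity, both levels exist. Two distinct fields may share one
  concept ID (`neoadjuvant_chemotherapy` yes/no and
  `neoadjuvant_chemo_medication` as a drug-code list both map to OMOP
  44808409; likewise adjuvant hormone therapy and its medication list).
  Field-name uniqueness, not concept-ID uniqueness, is the registry
  invariant. Detailed values (pN1a, Stage IIA, pT4b) carry a
  `generic_parent` link so `recode_generic` can coarsen a column on
  demand; the operation is idempotent and exhaustively enumerated in the
  tests.
* **Counting conventions.** Composition statistics count each concept
  once under its vocabulary and each *distinct* coded value (by OMOP ID)
  once under its vocabulary; values shared across concepts (yes/no,
  763013) count once globally, with 763013 counted under its OMOP
  source vocabulary (PPI). Under these conventions the shipped registry
  measures 38 concepts, 135 values and 12 vocabularies, with SNOMED
  carrying 31 concepts and Cancer Modifier/SNOMED carrying 60/26 values.
* **Provenance of the registry content.** The registry is a curated
  artifact. Concept and value IDs that the harmonization scheme pivots
  on (ER/PR/HR status, neoadjuvant chemotherapy, anatomic location, pN
  category, yes/no, Not provided) are genuine OMOP IDs; the remaining
  entries are curated placeholders with realistic structure. Re-curating
  an entry is a data-file edit, not a code change.

## The ETL

One YAML mapping spec per dataset declares, per CDM field, exactly one
rule. Rule kinds:

* `direct_recode` — token lookup after normalization (strip, casefold,
  collapse whitespace), which absorbs the case/spacing noise real
  exports contain. Unmapped tokens demote the cell to 763013 with a
  logged warning rather than aborting: the sources are messy by design
  and the ETL must be re-runnable over them. A rule *emitting* an
  unregistered code, by contrast, is a hard error — that is a spec bug.
* `constant` — study-design knowledge with no source column: every
  ISPY1/ISPY2/NACT subject received neoadjuvant chemotherapy; every
  NACT subject received adjuvant radiotherapy per protocol; cohorts are
  female.
* `derived`/`parser` — named derivations. Cross-field logic may read
  already-harmonized cells (HR from ER/PR), so rule order within a spec
  matters and the specs list ER/PR before HR.
* **Overrides** — per-subject (subject, field, value) triples curated
  from comment fields, applied after all rules; e.g. NACT subject 27,
  whose comment records declining post-surgery radiation and hormonal
  treatment, gets both adjuvant fields forced to "No".

Decisions where the source semantics were open:

* **HR derivation.** HR-positive iff ER-positive or PR-positive;
  HR-negative iff both known negative; otherwise 763013. This is the
  standard clinical disjunction; the full 9-case truth table is frozen
  in the tests.
* **Clock → quadrant.** Patient-facing clock; on the left breast the
  sectors [12,3), [3,6), [6,9), [9,12) map to upper-outer, lower-outer,
  lower-inner, upper-inner; the right breast mirrors. Boundary hours
  belong to the clockwise-following sector (the half-open intervals make
  this deterministic). Half hours are taken literally, hour ranges by
  their wrap-aware midpoint ("R4-5" → 4:30). A parsable laterality with
  no parsable clock yields breast-NOS (C50.9); nothing parsable yields
  763013. The sector table is shipped config
  (`data/clock_quadrants.yaml`) so it can be re-curated without code
  changes; all 24 (hour, side) pairs are enumerated in the tests.
* **DUKE numeric pN.** The source codes the pN category as −1…4 with −1
  meaning NX. 0–3 map to pN0–pN3; code 4, which has no TNM counterpart,
  is mapped to pN3 (ceiling) rather than dropped.
* **Multi-valued cells.** Deduplicated, sorted ascending by OMOP ID,
  joined with `|`; the empty list encodes as `763013`, and 763013 mixed
  with substantive codes is dropped. The canonical form makes harmonized
  output byte-stable and regression-testable.
* **Follow-up conversion.** TCGA reports days; months are computed as
  `round(days / 30.4375, 1)` (the mean Gregorian month).
* **Subject exclusion.** Exclusion is an explicit spec predicate
  (default: drop blank subject IDs; duplicate IDs are a load error),
  never an implicit side effect.
* **Coverage percentages.** `concepts_mapped / source concept count`,
  with the source counts (9, 74, 17, 110, 41) shipped as spec metadata.
  The ratio may exceed 100% because one source concept can feed several
  CDM fields (ISPY2: 12 from 9, 133%). Display values round half-up;
  stored values are unrounded.

## Series classification

Classification is total and deterministic over arbitrarily sparse tag
maps. Precedence runs from the most specific evidence to the least:

1. **DWI** — scanning sequence (0018,0020) contains `EP`, or the series
   description/sequence name matches a diffusion pattern, *and* at least
   one diffusion tag is present: b-value (0018,9087), directionality
   (0018,9075), or GE private (0043,1039). The b-value is read from the
   standard tag first; the GE private tag's first element is reduced by
   10⁹ when the vendor's b-value-ordering offset is present — ignoring
   that offset corrupts downstream ADC computation, so the rule is
   isolated in one unit-tested function.
2. **DCE** — number of temporal positions (0020,0105) > 1; if
   anonymization removed it, the fallback is gradient-echo (`GR`) + 3D
   acquisition (0018,0023) + flip angle (0018,1314) below 20°. The
   threshold is configuration (`data/dicom_rules.yaml`) with that
   documented default: dynamic T1-weighted 3D acquisitions use low flip
   angles, spoiled anatomical gradient-echo typically does not.
3. **T2W/T1W** — free-text description keywords (`t2`, `stir`, `tirm`
   vs. `t1`), with spin-echo scanning sequence defaulting to T1W. T2
   keywords are checked first so a `t2 fse` spin echo is not claimed by
   the T1 rule.
4. **OTHER** if tags are present but no rule fires; **UNKNOWN** only for
   an empty tag map. Every fired predicate is recorded as evidence.

Orientation comes from the image-orientation cosines (0020,0037): the
slice normal is the row×column cross product and the plane is the axis
of its largest absolute component (x sagittal, y coronal, z axial),
provided that component reaches 0.8 — below that the series is OBLIQUE.
The 0.8 threshold is configuration; the implementation is checked
against an independent cross-product oracle on 1,000 random orthonormal
frames.

Tag keys are normalized to uppercase zero-padded hex pairs, accepting
the spellings found in API JSON and local dumps; multi-valued tags stay
lists.

Metadata acquisition is a two-step, cached procedure: one collection
listing, then one tag request per series, written through to one JSON
document per series UID with the collection index committed last. A warm
cache serves byte-identical results with zero requests. The client is an
injectable interface; the live NBIA implementation uses stdlib HTTP and
is exercised in tests only through counting fakes.

## Manifests

The `.tcia` writer emits the five `key=value` header lines (including
NBIA's historical spelling `noOfrRetry`, preserved verbatim for
bit-compatibility with NBIA Retriever), the marker
`ListOfSeriesToDownload=`, then one UID per line with `\n` endings —
byte-stable for identical specs. The reader is the writer's inverse;
unknown headers are preserved with a warning. Header defaults mirror
current NBIA Retriever conventions and are not pinned to a specific
consumer version.

## Synthetic fixtures

The clinical generator draws, per subject, ground-truth CDM codes and
renders them into each dataset's source conventions — including the
decorative top row of the DUKE spreadsheet, per-drug 0/1 medication
flags, detailed pN text subcategories, and clock positions in four
notations (plain, space-free, half hour, range). `mess_rate` controls
the fraction of cells additionally perturbed with semantics-preserving
noise only: case changes, stray whitespace, and the trailing-text
vocabulary ("with calcs", "with marker", …). Because the noise is
tolerable by construction, exact truth recovery is expected at any mess
rate up to 1.0; a baseline 10% of optional cells are blank to exercise
imputation. The series generator realizes each technique's tag
signature, with an `anonymized_fraction` of series dropping their most
direct tag and relying on the fallback path (DCE without temporal
positions, DWI without description, T2W without scanning sequence).

What passing fixture tests shows: the mechanics — parsing, recoding,
imputation, override application, canonical encoding, classification
logic — are correct and deterministic. What they do not show: fidelity
to the real cohorts' joint distributions (ages, stage frequencies,
arm–drug pairings) or to source-file pathologies beyond the emulated
noise vocabulary; real datasets may contain token spellings absent from
the shipped value maps, which the ETL demotes to 763013 with a warning
rather than silently recoding.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small
problems chosen as adequate for their purpose: 50 subjects per dataset
for ETL recovery (≈9,500 scored cells), 100 seeded compositions for the
classifier (800 series), 1,000 random frames for orientation, 200
random manifest specs. Determinism everywhere: NumPy `default_rng`
seeded per run, per-dataset stream separation via seed sequences, stable
text renderings for numeric cells (integers without `.0`, `%.10g`
otherwise), `\n` line endings on all outputs.

## Known limitations

* The registry's non-pivotal OMOP IDs are curated placeholders (see
  above); swap in verified IDs before using the output for cross-study
  interoperation with other OMOP resources.
* The classifier's keyword lists and thresholds are a reconstruction;
  against a new collection they should be reviewed, which is why they
  ship as configuration.
* The ETL deliberately refuses schema inference: a new dataset requires
  a new mapping spec. That is the extensibility mechanism, not a gap.
* Real ISPY2 and TCGA releases exclude a handful of subjects for
  reasons not recoverable from the distributed files; the shipped specs
  implement only the explicit, documented exclusion predicate.
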