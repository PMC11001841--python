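"""Summarize the shipped common data model.

Loads the 38-concept breast-cancer registry and prints its composition:
how many concepts and distinct coded values it defines and which OMOP
standardized vocabularies they come from.  The counts are the shape of
the harmonized dataset's semantics — every cell of a harmonized table is
one of these codes or a number.
"""

from mammocdm import default_registry, vocabulary_usage

cdm = default_registry()
usage = vocabulary_usage(cdm)

print(f"concepts:           {usage.n_concepts}")
print(f"distinct values:    {usage.n_values}")
print(f"vocabularies:       {usage.n_vocabularies}")
print("\nconcept mapping (per vocabulary):")
for vocab, n in sorted(usage.concept_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {vocab:16s} {n}")
print("\nvalue-set mapping (per vocabulary):")
for vocab, n in sorted(usage.value_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {vocab:16s} {n}")
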