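"""Generate a synthetic multi-omics cohort with planted module structure.

Builds a 10-patient, 60-gene cohort with 3 planted modules per patient
(one activated, one suppressed, one neutral) across four omics layers, and
writes the tab-delimited inputs an analysis run would consume.
"""

from gmiec import generate_cohort, write_cohort

bundle, drug_map, truth = generate_cohort(
    n_patients=10, n_genes=60, n_modules=3, effect="strong",
    druggable_fraction=0.3, seed=7,
)
write_cohort(bundle, drug_map, truth, "scratch/example_cohort")

print(f"layers:   {bundle.layer_kinds}")
print(f"genes:    {len(bundle.genes)}  samples: {len(bundle.samples)}")
print(f"drug associations: {len(drug_map.associations)} over {len(drug_map.genes)} genes")
p = bundle.samples[0]
print(f"patient {p} module states: {truth.states[p]}")
print(f"activated-druggable patients: {len(truth.activated_druggable_patients())}/10")
# Each patient carries one activated module (over-expressed, copy-gain,
# hypomethylated, recurrently mutated) — the signal the pipeline must find.
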