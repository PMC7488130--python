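"""M2 strategy: logic-rule binarization + k-modes clustering.

Shows the seven default alteration rules, the binary gene-by-rule matrix
they produce for one patient, and the modules k-modes finds in it.
"""

from sklearn.metrics import adjusted_rand_score

from gmiec import (
    assemble_patient_matrix,
    binarize_rules,
    default_rules,
    generate_cohort,
    kmodes_cluster,
)

rules = default_rules()
print("default rules:")
for r in rules:
    op = {"above": ">", "below": "<", "at_least": ">="}[r.direction]
    print(f"  {r.name:17s} {r.layer:12s} value {op} {r.threshold:+.1f}  ({r.effect})")

bundle, _, truth = generate_cohort(n_patients=1, n_genes=60, n_modules=3, seed=5)
patient = bundle.samples[0]
rm = binarize_rules(assemble_patient_matrix(bundle, patient), rules)
print(f"\nrule matrix M_i: {rm.values.shape[0]} genes x {rm.values.shape[1]} rules")
print(rm.to_frame().head(6).to_string())

assignment = kmodes_cluster(rm, k=3, n_init=10, seed=5)
true_lab = [truth.labels[patient][g] for g in bundle.genes]
pred_lab = [assignment.labels[g] for g in bundle.genes]
print(f"\nk-modes modules: {assignment.k}")
for j in range(1, assignment.k + 1):
    genes = assignment.module_genes(j)
    print(f"  module {j}: {len(genes)} genes")
print(f"adjusted Rand index vs planted modules: {adjusted_rand_score(true_lab, pred_lab):.3f}")
# Genes sharing the same alteration pattern (e.g. copy-gain + hypomethylated)
# land in the same module; recovery should be near-perfect at strong effect.
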