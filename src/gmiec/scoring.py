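"""Drug attachment and module scoring.

Every gene module (GM) is merged with the gene-drug association table to
form its drug module (DM), then scored on three axes:

* ``score_genes`` — alteration density: the mean of the binary rule matrix
  over the module's genes and every applied rule, in [0, 1];
* ``score_drugs`` — druggability: the fraction of module genes with at
  least one associated drug, in [0, 1];
* ``s_score`` — signed activation balance in [-1, 1]: the mean of the
  activating per-rule sub-scores minus the mean of the suppressing ones,
  each mean taken over the sub-scores whose rule columns are present.

Per-rule sub-scores (the fraction of module genes satisfying each rule) are
kept alongside, so a module's character — amplified, silenced, mutated —
stays inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import DrugGeneMap, ModuleRecord, ResultTable, ValidationError
from .m1 import ModuleAssignment
from .m2 import RuleMatrix


@dataclass
class GeneModule:
    patient: str
    index: int
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene module must be non-empty")


@dataclass
class DrugModule:
    module: GeneModule
    gene_drugs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return sorted({d for ds in self.gene_drugs.values() for d in ds})


@dataclass
class ModuleScores:
    score_genes: float
    score_drugs: float
    s_score: float
    sub_scores: dict[str, float]


def attach_drugs(module: GeneModule, drug_map: DrugGeneMap) -> DrugModule:
    """Restrict the gene-drug relation to the module's genes.

    A drug appears iff one of the module's genes carries it in the map;
    genes without associations contribute nothing and an empty drug set is
    a perfectly valid (just undruggable) module.
    """
    gene_drugs = {}
    for gene in module.genes:
        drugs = drug_map.drugs_for(gene)
        if drugs:
            gene_drugs[gene] = drugs
    return DrugModule(module=module, gene_drugs=gene_drugs)


def score_module(
    module: GeneModule, rule_matrix: RuleMatrix, drug_module: DrugModule
) -> ModuleScores:
    """Score one module from its rule-matrix rows and attached drugs."""
    index = {g: i for i, g in enumerate(rule_matrix.genes)}
    missing = [g for g in module.genes if g not in index]
    if missing:
        raise ValidationError(f"module genes absent from rule matrix: {missing}")
    rows = rule_matrix.values[[index[g] for g in module.genes]]
    score_genes = float(rows.mean())
    score_drugs = len(drug_module.gene_drugs) / len(module.genes)
    sub = {
        rule.name: float(rows[:, j].mean())
        for j, rule in enumerate(rule_matrix.rules)
    }
    activating = [sub[r.name] for r in rule_matrix.rules if r.effect == "activating"]
    suppressing = [sub[r.name] for r in rule_matrix.rules if r.effect == "suppressing"]
    act = sum(activating) / len(activating) if activating else 0.0
    sup = sum(suppressing) / len(suppressing) if suppressing else 0.0
    return ModuleScores(
        score_genes=score_genes,
        score_drugs=score_drugs,
        s_score=act - sup,
        sub_scores=sub,
    )


def score_all(
    assignments: list[ModuleAssignment],
    rule_matrices: dict[str, RuleMatrix],
    drug_map: DrugGeneMap,
    clinical=None,
) -> ResultTable:
    """Score every patient's modules into the wide results table.

    One rule matrix per patient is required; for M1 runs it is computed from
    the same bundle with the default rules purely for scoring, so both
    strategies share a single scoring path. Clinical columns, when provided,
    are appended by sample id and never influence any score.
    """
    modules: dict[str, list[ModuleRecord]] = {}
    for assignment in assignments:
        rm = rule_matrices[assignment.patient]
        recs = []
        for j in range(1, assignment.k + 1):
            genes = assignment.module_genes(j)
            if not genes:
                continue
            gm = GeneModule(patient=assignment.patient, index=j, genes=genes)
            dm = attach_drugs(gm, drug_map)
            scores = score_module(gm, rm, dm)
            recs.append(
                ModuleRecord(
                    index=j,
                    genes=genes,
                    drugs=dm.drugs,
                    score_genes=scores.score_genes,
                    score_drugs=scores.score_drugs,
                    s_score=scores.s_score,
                    sub_scores=scores.sub_scores,
                )
            )
        modules[assignment.patient] = recs
    clin = clinical.values if clinical is not None else None
    return ResultTable(modules=modules, clinical=clin)
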