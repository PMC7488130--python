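"""M2 strategy: logic-rule binarization + k-modes per patient.

Each patient's genomic profile is reduced to a binary matrix M_i = (g x r):
cell (gene, rule) is 1 when the gene's value in the rule's omics layer
satisfies the rule threshold, 0 otherwise. Only rules whose layer is present
in the data are applied. Genes are then grouped with k-modes so that genes
sharing the same pattern of alterations fall in the same module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsBundle, ValidationError
from .kmodes import kmodes
from .m1 import ModuleAssignment, PatientFeatureMatrix, _canonical_relabel, assemble_patient_matrix

DIRECTIONS = ("above", "below", "at_least")
EFFECTS = ("activating", "suppressing", "neutral")


@dataclass(frozen=True)
class Rule:
    """One crisp threshold rule on a single omics layer.

    ``direction``: above (strict >), below (strict <), at_least (>=).
    ``on_zscore`` rules evaluate on the within-patient z-scored column
    (scale-free, used for expression); others use raw values so absolute
    conventions like a 0.3 copy-ratio threshold keep their meaning.
    ``effect`` says whether satisfying the rule signals activation or
    suppression of the gene, which feeds the signed module S-score.
    """

    name: str
    layer: str
    direction: str
    threshold: float
    effect: str = "activating"
    on_zscore: bool = False

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"rule {self.name!r}: unknown direction {self.direction!r}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"rule {self.name!r}: unknown effect {self.effect!r}")
        try:
            float(self.threshold)
        except (TypeError, ValueError):
            raise ValidationError(
                f"rule {self.name!r}: threshold {self.threshold!r} is not numeric"
            ) from None

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        t = float(self.threshold)
        if self.direction == "above":
            return (values > t).astype(np.int8)
        if self.direction == "below":
            return (values < t).astype(np.int8)
        return (values >= t).astype(np.int8)


@dataclass
class RuleSet:
    rules: list[Rule]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValidationError("rule names must be unique")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)


_DEFAULTS: list[tuple[str, str, str, float, str, bool]] = [
    ("over_expressed", "expression", "above", 1.0, "activating", True),
    ("under_expressed", "expression", "below", -1.0, "suppressing", True),
    ("cn_gain", "copy_number", "above", 0.3, "activating", False),
    ("cn_loss", "copy_number", "below", -0.3, "suppressing", False),
    ("hyper_methylated", "methylation", "above", 0.7, "suppressing", False),
    ("hypo_methylated", "methylation", "below", 0.3, "activating", False),
    ("mutated", "mutation", "at_least", 1.0, "activating", False),
]


def default_rules(overrides: dict[str, float] | None = None) -> RuleSet:
    """The seven default alteration rules, thresholds individually overridable.

    Expression rules act on within-patient z-scores (|z| > 1); copy number
    uses the conventional +/-0.3 log-ratio cut, methylation the 0.3/0.7 beta
    conventions, and any mutation count >= 1 marks a gene as mutated.
    """
    overrides = dict(overrides or {})
    rules = []
    for name, layer, direction, threshold, effect, on_z in _DEFAULTS:
        if name in overrides:
            value = overrides.pop(name)
            try:
                threshold = float(value)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"override for rule {name!r}: threshold {value!r} is not numeric"
                ) from None
        rules.append(Rule(name, layer, direction, threshold, effect, on_z))
    if overrides:
        raise ValidationError(f"unknown rule overrides: {sorted(overrides)}")
    return RuleSet(rules=rules)


def read_rules(path) -> RuleSet:
    """Read a custom rule table: name, layer, direction, threshold[, effect].

    A missing effect column defaults to activating for above/at_least rules
    and suppressing for below rules. Expression rules read from a file are
    evaluated on z-scores, matching the defaults.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: rules file needs columns name, layer, direction, threshold")
    rules = []
    for _, row in df.iterrows():
        direction = row.iloc[2]
        effect = row.iloc[4] if df.shape[1] > 4 and row.iloc[4] else (
            "suppressing" if direction == "below" else "activating"
        )
        try:
            threshold = float(row.iloc[3])
        except ValueError:
            raise ValidationError(
                f"{path}: rule {row.iloc[0]!r} threshold {row.iloc[3]!r} is not numeric"
            ) from None
        rules.append(
            Rule(
                name=row.iloc[0],
                layer=row.iloc[1],
                direction=direction,
                threshold=threshold,
                effect=effect,
                on_zscore=row.iloc[1] == "expression",
            )
        )
    return RuleSet(rules=rules)


@dataclass
class RuleMatrix:
    """Binary per-patient matrix M_i = (g x r): genes by applied rules."""

    patient: str
    genes: list[str]
    rules: list[Rule] = field(repr=False, default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int8))

    @property
    def rule_names(self) -> list[str]:
        return [r.name for r in self.rules]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.rule_names)


def binarize_rules(matrix: PatientFeatureMatrix, rules: RuleSet) -> RuleMatrix:
    """Apply every rule whose layer exists in the patient matrix.

    The rule column order follows the rule set; cells are 1 iff the gene's
    layer value satisfies the rule (strict inequality for above/below).
    Raises when no rule matches any provided layer, because an all-empty
    rule matrix cannot be clustered.
    """
    applied = [r for r in rules if r.layer in matrix.layers]
    if not applied:
        raise ValidationError(
            f"no rule applies to layers {matrix.layers}; provide matching rules"
        )
    cols = [
        r.evaluate(matrix.column(r.layer, raw=not r.on_zscore)) for r in applied
    ]
    return RuleMatrix(
        patient=matrix.patient,
        genes=list(matrix.genes),
        rules=applied,
        values=np.column_stack(cols).astype(np.int8),
    )


def kmodes_cluster(
    rule_matrix: RuleMatrix, k: int, n_init: int = 10, seed: int = 0
) -> ModuleAssignment:
    """Cluster genes by their binary alteration patterns with Huang k-modes.

    The best of ``n_init`` seeded restarts (by total within-cluster Hamming
    cost) is kept; empty clusters collapse, so the assignment's ``k`` is the
    effective number of non-empty modules. Labels are renumbered so module 1
    holds the lexicographically first gene.
    """
    res = kmodes(rule_matrix.values, k=k, n_init=n_init, seed=seed)
    labels, k_eff = _canonical_relabel(rule_matrix.genes, res.labels)
    return ModuleAssignment(patient=rule_matrix.patient, labels=labels, k=k_eff)


def run_m2(
    bundle: OmicsBundle,
    k: int,
    rules: RuleSet | None = None,
    n_init: int = 10,
    seed: int = 0,
) -> list[ModuleAssignment]:
    """Full M2 pipeline: binarize and cluster every patient independently.

    Per-patient seeds derive as ``seed + patient_index``, mirroring M1, so
    outputs are order-independent and reproducible.
    """
    if rules is None:
        rules = default_rules()
    assignments = []
    for idx, patient in enumerate(bundle.samples):
        pfm = assemble_patient_matrix(bundle, patient, standardize=True)
        rm = binarize_rules(pfm, rules)
        assignment = kmodes_cluster(rm, k=k, n_init=n_init, seed=seed + idx)
        assignments.append(assignment)
    return assignments


def rule_matrices(bundle: OmicsBundle, rules: RuleSet | None = None) -> dict[str, RuleMatrix]:
    """Binary rule matrix per patient (used for scoring under both M1 and M2)."""
    if rules is None:
        rules = default_rules()
    out = {}
    for patient in bundle.samples:
        pfm = assemble_patient_matrix(bundle, patient, standardize=True)
        out[patient] = binarize_rules(pfm, rules)
    return out
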