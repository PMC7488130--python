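"""Synthetic multi-omics cohorts with planted, drug-annotated module structure.

The generator emulates the analysis conditions of a tumor cohort: four
omics layers (expression, copy number log-ratio, methylation beta, mutation
indicator) over a shared gene set, with each patient carrying one activated
module (up-regulated, copy-gain, hypomethylated, recurrently mutated), one
suppressed module (the mirror image) and neutral background modules. Every
draw is seeded, and the planted truth — per-patient gene labels, module
states and the druggable gene set — is returned so recovery can be measured
with the adjusted Rand index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import DrugGeneMap, OmicsBundle, OmicsDataset, ValidationError, align_bundle
from .m1 import run_m1
from .m2 import default_rules, rule_matrices, run_m2
from .scoring import score_all
from .selection import select_active

EFFECT_DELTA = {"strong": 3.0, "moderate": 1.5, "weak": 0.5}

#: (expression mean shift factor, cn mean, cn sd, methylation beta mean, mutation rate)
STATE_PARAMS = {
    "activated": (+1.0, +0.6, 0.15, 0.2, 0.30),
    "suppressed": (-1.0, -0.6, 0.15, 0.8, 0.02),
    "neutral": (0.0, 0.0, 0.10, 0.5, 0.02),
}

#: Beta concentration for methylation draws; keeps values strictly in [0, 1]
METH_CONCENTRATION = 10.0


@dataclass
class CohortTruth:
    """Planted ground truth: labels, per-module states, druggable genes."""

    labels: dict[str, dict[str, int]]  # patient -> gene -> module index (1-based)
    states: dict[str, dict[int, str]]  # patient -> module index -> state
    druggable_genes: list[str]

    def activated_druggable_patients(self) -> list[str]:
        """Patients whose activated module contains >= 1 druggable gene."""
        druggable = set(self.druggable_genes)
        out = []
        for patient, states in self.states.items():
            activated = {m for m, s in states.items() if s == "activated"}
            genes = {
                g for g, lab in self.labels[patient].items() if lab in activated
            }
            if genes & druggable:
                out.append(patient)
        return out


def generate_cohort(
    n_patients: int = 10,
    n_genes: int = 60,
    n_modules: int = 3,
    effect: str = "strong",
    druggable_fraction: float = 0.3,
    seed: int = 0,
    per_patient_modules: bool = False,
) -> tuple[OmicsBundle, DrugGeneMap, CohortTruth]:
    """Generate a four-layer cohort with planted module structure.

    Module composition is shared cohort-wide by default (each patient gets
    its own shuffle of module *states*); ``per_patient_modules`` randomizes
    the gene partition per patient as well. Effect size delta scales the
    expression shift of altered modules: 3 / 1.5 / 0.5 standard deviations
    for strong / moderate / weak. ``druggable_fraction`` of genes receive
    one to three synthetic drug names.
    """
    if effect not in EFFECT_DELTA:
        raise ValidationError(f"unknown effect size {effect!r}")
    if n_modules < 1 or n_patients < 1:
        raise ValidationError("n_patients and n_modules must be positive")
    if n_genes < 3 * n_modules:
        raise ValidationError("need n_genes >= 3 * n_modules")
    if not 0.0 <= druggable_fraction <= 1.0:
        raise ValidationError("druggable_fraction must lie in [0, 1]")
    delta = EFFECT_DELTA[effect]
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    patients = [f"P{i:03d}" for i in range(1, n_patients + 1)]

    def partition() -> dict[str, int]:
        perm = rng.permutation(n_genes)
        labels = {}
        for pos, gi in enumerate(perm):
            labels[genes[gi]] = (pos % n_modules) + 1
        return labels

    shared = partition()
    layers = {
        kind: pd.DataFrame(0.0, index=genes, columns=patients)
        for kind in ("expression", "copy_number", "methylation", "mutation")
    }
    truth_labels: dict[str, dict[str, int]] = {}
    truth_states: dict[str, dict[int, str]] = {}
    for patient in patients:
        labels = partition() if per_patient_modules else dict(shared)
        # one activated, one suppressed (when possible), rest neutral
        states = ["activated"] + (["suppressed"] if n_modules > 1 else [])
        states += ["neutral"] * (n_modules - len(states))
        state_of = {
            m + 1: str(s) for m, s in enumerate(rng.permutation(states))
        }
        truth_labels[patient] = labels
        truth_states[patient] = state_of
        for gene in genes:
            expr_sign, cn_mu, cn_sd, meth_mu, mut_p = STATE_PARAMS[state_of[labels[gene]]]
            layers["expression"].loc[gene, patient] = rng.normal(expr_sign * delta, 1.0)
            layers["copy_number"].loc[gene, patient] = rng.normal(cn_mu, cn_sd)
            a = meth_mu * METH_CONCENTRATION
            b = (1.0 - meth_mu) * METH_CONCENTRATION
            layers["methylation"].loc[gene, patient] = rng.beta(a, b)
            layers["mutation"].loc[gene, patient] = float(rng.random() < mut_p)

    n_druggable = int(round(druggable_fraction * n_genes))
    druggable = sorted(rng.choice(genes, size=n_druggable, replace=False).tolist())
    associations = set()
    for gene in druggable:
        for d in range(int(rng.integers(1, 4))):
            associations.add((gene, f"drug_{gene}_{d}"))
    drug_map = DrugGeneMap(associations=associations)

    datasets = [OmicsDataset(kind, df) for kind, df in layers.items()]
    bundle = align_bundle(datasets)
    truth = CohortTruth(
        labels=truth_labels, states=truth_states, druggable_genes=druggable
    )
    return bundle, drug_map, truth


def write_cohort(
    bundle: OmicsBundle, drug_map: DrugGeneMap, truth: CohortTruth, out_dir
) -> None:
    """Write the four omics TSVs, the drug table and the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for d in bundle.datasets:
        df = d.values.copy()
        df.index.name = "gene"
        df.to_csv(out / f"{d.layer_kind}.tsv", sep="\t")
    pd.DataFrame(
        sorted(drug_map.associations), columns=["gene", "drug"]
    ).to_csv(out / "drugs.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "labels": truth.labels,
                "states": {
                    p: {str(m): s for m, s in st.items()}
                    for p, st in truth.states.items()
                },
                "druggable_genes": truth.druggable_genes,
            },
            fh,
            indent=1,
        )


@dataclass
class RecoveryResult:
    method: str
    effect: str
    mean_ari: float
    per_patient_ari: list[float]
    aomd_rate: float  # fraction of planted activated-druggable patients flagged AOMD
    n_planted: int


def recovery_experiment(
    method: str = "m2",
    effect: str = "strong",
    n_reps: int = 5,
    seed: int = 0,
    n_patients: int = 10,
    n_genes: int = 60,
    n_modules: int = 3,
    druggable_fraction: float = 0.3,
    n_trees: int = 500,
    n_init: int = 10,
) -> RecoveryResult:
    """Measure module recovery and AOMD detection on generated cohorts.

    Runs the full pipeline (generate, cluster with the chosen strategy at
    k = n_modules, score, select) on ``n_reps`` cohorts and reports the mean
    per-patient adjusted Rand index against the planted partition, and the
    fraction of planted activated-druggable patients that come out AOMD.
    """
    if method not in ("m1", "m2"):
        raise ValidationError(f"method must be m1|m2, got {method!r}")
    aris: list[float] = []
    flagged = 0
    planted_total = 0
    for rep in range(n_reps):
        gseed = (seed + 100_003 * rep) % (2**31)
        bundle, drug_map, truth = generate_cohort(
            n_patients=n_patients,
            n_genes=n_genes,
            n_modules=n_modules,
            effect=effect,
            druggable_fraction=druggable_fraction,
            seed=gseed,
        )
        if method == "m1":
            assignments = run_m1(
                bundle, k=n_modules, n_trees=n_trees, seed=gseed + 1, n_init=n_init
            )
        else:
            assignments = run_m2(bundle, k=n_modules, seed=gseed + 1, n_init=n_init)
        for assignment in assignments:
            true_lab = [truth.labels[assignment.patient][g] for g in bundle.genes]
            pred_lab = [assignment.labels[g] for g in bundle.genes]
            aris.append(adjusted_rand_score(true_lab, pred_lab))
        rms = rule_matrices(bundle, default_rules())
        result = score_all(assignments, rms, drug_map)
        selections = select_active(result, direction="active", min_drugs=1)
        flagged_patients = {s.patient for s in selections if s.category == "AOMD"}
        planted = truth.activated_druggable_patients()
        planted_total += len(planted)
        flagged += sum(1 for p in planted if p in flagged_patients)
    return RecoveryResult(
        method=method,
        effect=effect,
        mean_ari=float(np.mean(aris)),
        per_patient_ari=aris,
        aomd_rate=flagged / planted_total if planted_total else float("nan"),
        n_planted=planted_total,
    )
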