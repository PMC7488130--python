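import numpy as np
import pytest

from gmiec import (
    RuleMatrix,
    ValidationError,
    align_bundle,
    assemble_patient_matrix,
    binarize_rules,
    default_rules,
    kmodes_cluster,
    run_m2,
)
from gmiec.kmodes import kmodes

from conftest import brute_kmodes_cost, make_dataset


def naive_binarize(pfm, rules):
    """Per-cell re-evaluation of every applicable rule, the independent oracle."""
    applied = [r for r in rules if r.layer in pfm.layers]
    out = np.zeros((len(pfm.genes), len(applied)), dtype=int)
    for i in range(len(pfm.genes)):
        for j, rule in enumerate(applied):
            col = pfm.layers.index(rule.layer)
            v = (pfm.values if rule.on_zscore else pfm.raw)[i, col]
            t = rule.threshold
            if rule.direction == "above":
                out[i, j] = 1 if v > t else 0
            elif rule.direction == "below":
                out[i, j] = 1 if v < t else 0
            else:
                out[i, j] = 1 if v >= t else 0
    return [r.name for r in applied], out


def random_bundle(rng, n_genes=20, kinds=("expression", "copy_number", "methylation", "mutation")):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    datasets = []
    for kind in kinds:
        if kind == "methylation":
            vals = rng.uniform(0, 1, size=(n_genes, 1))
        elif kind == "mutation":
            vals = rng.integers(0, 3, size=(n_genes, 1)).astype(float)
        else:
            vals = rng.normal(0, 1.5, size=(n_genes, 1))
        datasets.append(make_dataset(kind, genes, ["s1"], vals))
    return align_bundle(datasets)


class TestDefaultRules:
    def test_seven_rules_with_documented_thresholds(self):
        rules = {r.name: r for r in default_rules()}
        assert len(rules) == 7
        assert rules["over_expressed"].threshold == 1.0
        assert rules["cn_gain"].threshold == 0.3
        assert rules["hyper_methylated"].threshold == 0.7
        assert rules["mutated"].direction == "at_least"

    def test_threshold_override(self):
        rules = {r.name: r for r in default_rules({"cn_gain": 0.5})}
        assert rules["cn_gain"].threshold == 0.5

    def test_non_numeric_override_rejected(self):
        with pytest.raises(ValidationError, match="not numeric"):
            default_rules({"cn_gain": "high"})

    def test_unknown_override_rejected(self):
        with pytest.raises(ValidationError, match="unknown rule"):
            default_rules({"nonsense": 1})


class TestBinarize:
    def test_direct_threshold_application(self):
        rng = np.random.default_rng(0)
        bundle = random_bundle(rng, n_genes=8, kinds=("expression", "copy_number"))
        pfm = assemble_patient_matrix(bundle, "s1")
        rm = binarize_rules(pfm, default_rules())
        i = 0
        z = pfm.values[i, 0]
        cn = pfm.raw[i, 1]
        row = dict(zip(rm.rule_names, rm.values[i]))
        assert row["over_expressed"] == int(z > 1.0)
        assert row["under_expressed"] == int(z < -1.0)
        assert row["cn_gain"] == int(cn > 0.3)
        assert row["cn_loss"] == int(cn < -0.3)

    def test_columns_restricted_to_present_layers(self):
        rng = np.random.default_rng(1)
        bundle = random_bundle(rng, n_genes=6, kinds=("expression", "mutation"))
        rm = binarize_rules(assemble_patient_matrix(bundle, "s1"), default_rules())
        assert rm.rule_names == ["over_expressed", "under_expressed", "mutated"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_per_cell_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bundle = random_bundle(rng)
        pfm = assemble_patient_matrix(bundle, "s1")
        rm = binarize_rules(pfm, default_rules())
        names, expected = naive_binarize(pfm, default_rules())
        assert rm.rule_names == names
        np.testing.assert_array_equal(rm.values, expected)

    def test_layer_removal_removes_exactly_its_rules(self):
        rng = np.random.default_rng(2)
        full = random_bundle(rng)
        sub = align_bundle([d for d in full.datasets if d.layer_kind != "methylation"])
        cols_full = set(binarize_rules(assemble_patient_matrix(full, "s1"), default_rules()).rule_names)
        cols_sub = set(binarize_rules(assemble_patient_matrix(sub, "s1"), default_rules()).rule_names)
        assert cols_full - cols_sub == {"hyper_methylated", "hypo_methylated"}
        assert cols_sub <= cols_full

    def test_no_applicable_rule_fatal(self):
        rng = np.random.default_rng(3)
        bundle = random_bundle(rng, kinds=("expression", "copy_number"))
        pfm = assemble_patient_matrix(bundle, "s1")
        meth_only = [r for r in default_rules() if r.layer == "methylation"]
        from gmiec import RuleSet

        with pytest.raises(ValidationError, match="no rule applies"):
            binarize_rules(pfm, RuleSet(rules=meth_only))


class TestKModes:
    def test_perfectly_separated_rows(self):
        X = np.array([[1, 0, 0]] * 3 + [[0, 1, 1]] * 3)
        res = kmodes(X, 2, n_init=10, seed=0)
        assert res.cost == 0
        assert len(set(res.labels[:3])) == 1 and len(set(res.labels[3:])) == 1
        assert res.labels[0] != res.labels[3]

    def test_identical_rows_k1(self):
        X = np.tile([1, 0, 1], (6, 1))
        res = kmodes(X, 1, n_init=5, seed=0)
        assert res.cost == 0
        np.testing.assert_array_equal(res.centroids[0], [1, 0, 1])

    def test_duplicate_rows_reduce_effective_k(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        res = kmodes(X, 3, n_init=10, seed=0)
        assert res.k_effective == 2
        assert res.cost == 0

    def test_cost_history_monotone_non_increasing(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            X = rng.integers(0, 2, size=(15, 6))
            res = kmodes(X, 3, n_init=5, seed=trial)
            assert all(a >= b for a, b in zip(res.cost_history, res.cost_history[1:]))

    @pytest.mark.parametrize("seed", range(15))
    def test_attains_exhaustive_optimum_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        g, r = int(rng.integers(4, 9)), int(rng.integers(2, 6))
        X = rng.integers(0, 2, size=(g, r))
        k = int(rng.integers(2, 4))
        assert kmodes(X, k, n_init=50, seed=seed).cost == brute_kmodes_cost(X, k)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValidationError, match="binary"):
            kmodes(np.array([[0, 2], [1, 0]]), 2)


@pytest.fixture(scope="module")
def m2_cohort():
    from gmiec import generate_cohort

    return generate_cohort(n_patients=3, n_genes=24, n_modules=2, seed=8)


class TestRunM2:
    def test_independent_assignments_per_patient(self, m2_cohort):
        bundle, _, _ = m2_cohort
        assignments = run_m2(bundle, k=2, seed=5)
        assert [a.patient for a in assignments] == bundle.samples
        for a in assignments:
            assert sorted(a.labels) == bundle.genes

    def test_deterministic_given_seed(self, m2_cohort):
        bundle, _, _ = m2_cohort
        a1 = run_m2(bundle, k=2, seed=5)
        a2 = run_m2(bundle, k=2, seed=5)
        assert [x.labels for x in a1] == [x.labels for x in a2]

    def test_kmodes_cluster_canonical_first_gene(self, m2_cohort):
        bundle, _, _ = m2_cohort
        pfm = assemble_patient_matrix(bundle, bundle.samples[0])
        rm = binarize_rules(pfm, default_rules())
        asg = kmodes_cluster(rm, k=2, seed=1)
        assert asg.labels[sorted(bundle.genes)[0]] == 1
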