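import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmiec import (
    DrugGeneMap,
    GeneModule,
    Rule,
    RuleMatrix,
    ValidationError,
    attach_drugs,
    score_all,
    score_module,
)

RULES = [
    Rule("over_expressed", "expression", "above", 1.0, "activating", True),
    Rule("under_expressed", "expression", "below", -1.0, "suppressing", True),
    Rule("cn_gain", "copy_number", "above", 0.3, "activating"),
    Rule("hyper_methylated", "methylation", "above", 0.7, "suppressing"),
]


def make_rule_matrix(values, genes=None, rules=None):
    values = np.asarray(values, dtype=np.int8)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    rules = rules or RULES[: values.shape[1]]
    return RuleMatrix(patient="p", genes=genes, rules=rules, values=values)


def oracle_scores(module_genes, rm, drug_map):
    """Independent recomputation of every score from its definition."""
    idx = {g: i for i, g in enumerate(rm.genes)}
    cells = [rm.values[idx[g], j] for g in module_genes for j in range(len(rm.rules))]
    score_genes = sum(cells) / len(cells)
    druggable = sum(1 for g in module_genes if drug_map.drugs_for(g))
    sub = {}
    for j, rule in enumerate(rm.rules):
        sub[rule.name] = sum(rm.values[idx[g], j] for g in module_genes) / len(module_genes)
    act = [sub[r.name] for r in rm.rules if r.effect == "activating"]
    sup = [sub[r.name] for r in rm.rules if r.effect == "suppressing"]
    s = (sum(act) / len(act) if act else 0.0) - (sum(sup) / len(sup) if sup else 0.0)
    return score_genes, druggable / len(module_genes), s, sub


class TestAttachDrugs:
    def test_single_gene_single_drug(self):
        dm = DrugGeneMap({("ERCC6", "cisplatin")})
        module = GeneModule("p", 1, ["ERCC6"])
        assert attach_drugs(module, dm).drugs == ["cisplatin"]

    def test_gene_with_two_drugs(self):
        dm = DrugGeneMap({("ATR", "olaparib"), ("ATR", "temozolomide")})
        module = GeneModule("p", 1, ["ATR"])
        assert attach_drugs(module, dm).drugs == ["olaparib", "temozolomide"]

    def test_empty_map_gives_empty_drug_set(self):
        module = GeneModule("p", 1, ["XYZ"])
        assert attach_drugs(module, DrugGeneMap(set())).drugs == []

    def test_is_relation_restriction(self):
        dm = DrugGeneMap({("A", "d1"), ("B", "d2"), ("C", "d3")})
        module = GeneModule("p", 1, ["A", "C"])
        attached = attach_drugs(module, dm)
        assert attached.gene_drugs == {"A": ["d1"], "C": ["d3"]}


class TestScoreModule:
    def test_alteration_density_example(self):
        rm = make_rule_matrix([[1, 0, 1, 0], [1, 0, 0, 0]])
        module = GeneModule("p", 1, ["G0", "G1"])
        scores = score_module(module, rm, attach_drugs(module, DrugGeneMap(set())))
        assert scores.score_genes == pytest.approx(3 / 8)

    def test_druggable_fraction(self):
        rm = make_rule_matrix(np.zeros((4, 2)))
        module = GeneModule("p", 1, ["G0", "G1", "G2", "G3"])
        dm = DrugGeneMap({("G0", "d"), ("G2", "e")})
        scores = score_module(module, rm, attach_drugs(module, dm))
        assert scores.score_drugs == 0.5

    def test_missing_gene_rejected(self):
        rm = make_rule_matrix(np.zeros((2, 2)))
        module = GeneModule("p", 1, ["G0", "NOT_THERE"])
        with pytest.raises(ValidationError, match="NOT_THERE"):
            score_module(module, rm, attach_drugs(module, DrugGeneMap(set())))

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_oracle_and_bounds(self, data):
        n = data.draw(st.integers(3, 10))
        r = data.draw(st.integers(1, 4))
        bits = data.draw(
            st.lists(st.lists(st.integers(0, 1), min_size=r, max_size=r), min_size=n, max_size=n)
        )
        rm = make_rule_matrix(bits)
        size = data.draw(st.integers(1, n))
        module = GeneModule("p", 1, [f"G{i}" for i in range(size)])
        druggable = data.draw(st.sets(st.integers(0, n - 1)))
        dm = DrugGeneMap({(f"G{i}", f"d{i}") for i in druggable} or {("ZZ", "zz")})
        scores = score_module(module, rm, attach_drugs(module, dm))
        exp_g, exp_d, exp_s, exp_sub = oracle_scores(module.genes, rm, dm)
        assert scores.score_genes == pytest.approx(exp_g)
        assert scores.score_drugs == pytest.approx(exp_d)
        assert scores.s_score == pytest.approx(exp_s)
        assert scores.sub_scores == pytest.approx(exp_sub)
        assert 0.0 <= scores.score_genes <= 1.0
        assert 0.0 <= scores.score_drugs <= 1.0
        assert -1.0 <= scores.s_score <= 1.0

    def test_adding_association_never_decreases_score_drugs(self):
        rm = make_rule_matrix(np.zeros((3, 2)))
        module = GeneModule("p", 1, ["G0", "G1", "G2"])
        base = DrugGeneMap({("G0", "d")})
        more = DrugGeneMap({("G0", "d"), ("G1", "e")})
        s0 = score_module(module, rm, attach_drugs(module, base)).score_drugs
        s1 = score_module(module, rm, attach_drugs(module, more)).score_drugs
        assert s1 >= s0

    def test_activating_flip_raises_suppressing_flip_lowers_s_score(self):
        values = np.zeros((3, 4), dtype=int)
        rm = make_rule_matrix(values.copy())
        module = GeneModule("p", 1, ["G0", "G1", "G2"])
        dm = DrugGeneMap(set())
        base = score_module(module, rm, attach_drugs(module, dm)).s_score
        up = values.copy()
        up[0, 0] = 1  # over_expressed is activating
        s_up = score_module(module, make_rule_matrix(up), attach_drugs(module, dm)).s_score
        down = values.copy()
        down[0, 1] = 1  # under_expressed is suppressing
        s_down = score_module(module, make_rule_matrix(down), attach_drugs(module, dm)).s_score
        assert s_up >= base >= s_down


class TestScoreAll:
    def test_every_module_scored(self):
        from gmiec import ModuleAssignment

        rm = make_rule_matrix([[1, 0], [0, 1], [1, 1], [0, 0]])
        asg = ModuleAssignment("p", {"G0": 1, "G1": 1, "G2": 2, "G3": 2}, 2)
        result = score_all([asg], {"p": rm}, DrugGeneMap({("G2", "dx")}))
        recs = result.modules["p"]
        assert [r.index for r in recs] == [1, 2]
        assert recs[1].drugs == ["dx"]
        assert recs[0].drugs == []
        for r in recs:
            assert 0.0 <= r.score_genes <= 1.0 and -1.0 <= r.s_score <= 1.0
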