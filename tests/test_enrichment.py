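"""DAG propagation, hypergeometric/KS enrichment, elim decorrelation."""

from math import comb

import networkx as nx
import numpy as np
import pytest

from pufgba.diffexpr import bh_adjust
from pufgba.enrichment import (
    EnrichConfig,
    fisher_term,
    kegg_overrep,
    ks_enrichment,
    propagate,
    run_go_enrichment,
)
from pufgba.simulate import sim_go


def chain_dag():
    dag = nx.MultiDiGraph()
    for t in ("GO:3", "GO:2", "GO:1"):
        dag.add_node(t, name=t, namespace="biological_process")
    dag.add_edge("GO:3", "GO:2", key="is_a")
    dag.add_edge("GO:2", "GO:1", key="is_a")
    return dag


class TestPropagate:
    def test_leaf_annotation_reaches_all_ancestors(self):
        ann = propagate(chain_dag(), {"g": {"GO:3"}})
        assert ann["g"] == {"GO:1", "GO:2", "GO:3"}

    def test_idempotent(self):
        dag, raw = sim_go(25, 4, [f"g{i}" for i in range(30)], seed=3)
        once = propagate(dag, raw)
        twice = propagate(dag, once)
        assert once == twice

    def test_matches_reachability_oracle(self):
        dag, raw = sim_go(30, 4, [f"g{i}" for i in range(20)], seed=9)
        ann = propagate(dag, raw)
        for gene, terms in raw.items():
            expected = set()
            for t in terms:
                expected.add(t)
                stack = [t]
                while stack:
                    node = stack.pop()
                    for parent in dag.successors(node):
                        if parent not in expected:
                            expected.add(parent)
                            stack.append(parent)
            assert ann[gene] == expected

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            propagate(chain_dag(), {"g": {"GO:99"}})


class TestFisher:
    def test_matches_exhaustive_tail_enumeration(self):
        background = {f"g{i}" for i in range(50)}
        annotated = {f"g{i}" for i in range(10)}
        study = {"g0", "g1", "g2", "g3", "g40"}
        ann = {g: ({"T"} if g in annotated else set()) for g in background}
        p, k, K = fisher_term(study, background, "T", ann)
        assert (k, K) == (4, 10)
        expected = sum(comb(10, j) * comb(40, 5 - j) for j in range(4, 6)) / comb(50, 5)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_study_equal_background_p_one(self):
        background = {f"g{i}" for i in range(20)}
        ann = {g: ({"T"} if int(g[1:]) < 5 else set()) for g in background}
        p, *_ = fisher_term(background, background, "T", ann)
        assert p == pytest.approx(1.0)

    def test_all_background_annotated_p_one(self):
        background = {f"g{i}" for i in range(20)}
        ann = {g: {"T"} for g in background}
        p, *_ = fisher_term({"g0", "g1"}, background, "T", ann)
        assert p == pytest.approx(1.0)

    def test_unannotated_term_skipped(self):
        background = {"a", "b"}
        assert fisher_term({"a"}, background, "T", {"a": set(), "b": set()}) is None


class TestElim:
    def _leaf_signal_fixture(self):
        """Genes annotated at the leaf; signal concentrated there."""
        dag = chain_dag()
        background = {f"g{i}" for i in range(60)}
        raw = {}
        for i, g in enumerate(sorted(background)):
            raw[g] = {"GO:3"} if i < 20 else set()
        ann = propagate(dag, raw)
        study = set(sorted(background)[:15])  # 15 of 20 leaf genes
        return dag, background, ann, study

    def test_elim_weakens_ancestors_not_leaf(self):
        dag, background, ann, study = self._leaf_signal_fixture()
        classic = run_go_enrichment(study, background, dag, ann,
                                    EnrichConfig(algorithm="classic"))
        elim = run_go_enrichment(study, background, dag, ann,
                                 EnrichConfig(algorithm="elim", elim_cutoff=0.01))
        c = classic.set_index("term")["p"]
        e = elim.set_index("term")["p"]
        assert e["GO:3"] == pytest.approx(c["GO:3"])
        assert e["GO:2"] >= c["GO:2"]
        assert e["GO:1"] >= c["GO:1"]
        # study-annotated count for ancestors never larger under elim
        ca = classic.set_index("term")["study_annotated"]
        ea = elim.set_index("term")["study_annotated"]
        assert ea["GO:1"] <= ca["GO:1"]

    def test_elim_cutoff_zero_reduces_to_classic(self):
        dag, background, ann, study = self._leaf_signal_fixture()
        classic = run_go_enrichment(study, background, dag, ann,
                                    EnrichConfig(algorithm="classic"))
        elim0 = run_go_enrichment(study, background, dag, ann,
                                  EnrichConfig(algorithm="elim", elim_cutoff=0.0))
        assert np.allclose(classic["p"].to_numpy(), elim0["p"].to_numpy())

    def test_planted_term_has_minimum_p_under_both(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        dag, raw = sim_go(20, 3, genes, seed=11)
        target = "GO:0000015"
        study = set(rng.choice(genes, 20, replace=False))
        for g in genes:
            raw[g].discard(target)
        for g in sorted(study)[:16]:      # 80% of study annotated
            raw[g].add(target)
        for g in sorted(set(genes) - study)[:18]:  # ~10% of background
            raw[g].add(target)
        ann = propagate(dag, raw)
        for algo in ("classic", "elim"):
            res = run_go_enrichment(study, set(genes), dag, ann,
                                    EnrichConfig(algorithm=algo))
            best = res.iloc[0]
            assert best["p"] < 1e-6
            # the winner must sit on the planted leaf's propagation path
            assert target in {best["term"]} | set(nx.descendants(dag, target))

    def test_empty_study_rejected(self):
        dag, background, ann, _ = self._leaf_signal_fixture()
        with pytest.raises(ValueError):
            run_go_enrichment(set(), background, dag, ann)


class TestKs:
    def test_extreme_separation_matches_exact_tail(self):
        dag = chain_dag()
        genes = [f"g{i}" for i in range(50)]
        raw = {g: ({"GO:3"} if i < 10 else set()) for i, g in enumerate(genes)}
        ann = propagate(dag, raw)
        scores = {g: (float(i) if i < 10 else 100.0 + i) for i, g in enumerate(genes)}
        res = run_go_enrichment(set(genes[:10]), set(genes), dag, ann,
                                EnrichConfig(test="ks", algorithm="classic"),
                                scores=scores)
        from scipy.stats import ks_2samp
        expected = ks_2samp([0.0] * 10, [1.0] * 40, alternative="greater").pvalue
        p3 = res.set_index("term")["p"]["GO:3"]
        assert p3 == pytest.approx(expected, rel=1e-9)
        assert p3 < 1e-6

    def test_null_scores_near_uniform(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        dag = nx.MultiDiGraph()
        dag.add_node("GO:root", name="r", namespace="bp")
        pvals = []
        for rep in range(300):
            term = f"GO:{rep}"
            dag.add_node(term, name=term, namespace="bp")
            dag.add_edge(term, "GO:root", key="is_a")
            members = set(rng.choice(genes, 15, replace=False))
            raw = {g: ({term} if g in members else set()) for g in genes}
            ann = propagate(dag, raw)
            scores = {g: float(s) for g, s in zip(genes, rng.normal(size=60))}
            res = ks_enrichment(scores, dag, ann,
                                EnrichConfig(algorithm="classic", min_term_size=3))
            sub = res[res["term"] == term]
            pvals.append(float(sub["p"].iloc[0]))
            dag.remove_node(term)
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").statistic < 0.1

    def test_term_covering_background_skipped(self):
        dag = chain_dag()
        genes = [f"g{i}" for i in range(10)]
        ann = propagate(dag, {g: {"GO:3"} for g in genes})
        scores = {g: float(i) for i, g in enumerate(genes)}
        res = run_go_enrichment(set(genes[:3]), set(genes), dag, ann,
                                EnrichConfig(test="ks", algorithm="classic"),
                                scores=scores)
        assert res.empty  # every term covers the whole background


class TestKegg:
    def test_single_pathway_q_equals_p(self):
        background = {f"g{i}" for i in range(30)}
        pmap = {g: ({"path1"} if int(g[1:]) < 8 else set()) for g in background}
        res = kegg_overrep({"g0", "g1", "g2"}, background, pmap)
        assert len(res) == 1
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_planted_pathway_minimum_q(self, rng):
        background = {f"g{i}" for i in range(100)}
        pmap = {g: set() for g in background}
        study = {f"g{i}" for i in range(20)}
        for g in list(study)[:16]:
            pmap[g].add("hit")
        for g in [f"g{i}" for i in range(30, 40)]:
            pmap[g].add("hit")
        for j in range(5):
            for g in rng.choice(sorted(background), 20, replace=False):
                pmap[g].add(f"bg{j}")
        res = kegg_overrep(study, background, pmap)
        assert res.iloc[0]["term"] == "hit"

    def test_q_is_bh_of_p(self, rng):
        background = {f"g{i}" for i in range(80)}
        pmap = {g: set() for g in background}
        for j in range(6):
            for g in rng.choice(sorted(background), 25, replace=False):
                pmap[g].add(f"p{j}")
        study = set(rng.choice(sorted(background), 15, replace=False))
        res = kegg_overrep(study, background, pmap)
        assert np.allclose(res["q"].to_numpy(),
                           bh_adjust(res["p"].to_numpy()))
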