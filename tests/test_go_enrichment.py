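"""OBO parsing, true-path propagation and Fisher term enrichment."""

import io
import math

import networkx as nx
import numpy as np
import pytest

from ddiscreen import (
    ParseError,
    ProteinRecord,
    ScreenResult,
    enrich,
    fisher_term_test,
    parse_obo,
    propagate_true_path,
)
from ddiscreen.go_enrichment import write_enrichment_tsv
from ddiscreen.virtual_proteome import VirtualProteome

CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: middle
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: leaf
namespace: molecular_function
is_a: GO:0000002 ! middle

[Term]
id: GO:0000009
name: gone
namespace: molecular_function
is_obsolete: true
"""


def hypergeom_upper_tail_exact(k, n, K, N):
    """Oracle: exact integer enumeration of all 2x2 tables with these margins."""
    den = math.comb(N, n)
    num = sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    )
    return num / den


class TestOboParsing:
    def test_three_term_chain(self):
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        assert len(dag) == 4
        assert dag.n_edges == 2
        assert dag.ancestors("GO:0000003") == {"GO:0000002", "GO:0000001"}
        assert dag.namespace("GO:0000002") == "molecular_function"

    def test_obsolete_term_present_but_unannotatable(self, caplog):
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        assert dag.is_obsolete("GO:0000009")
        with caplog.at_level("WARNING"):
            ann = propagate_true_path(dag, {"P1": {"GO:0000009"}})
        assert ann.propagated["P1"] == frozenset()

    def test_cycle_is_parse_error(self):
        cyclic = CHAIN_OBO.replace(
            "id: GO:0000001\nname: root\nnamespace: molecular_function",
            "id: GO:0000001\nname: root\nnamespace: molecular_function\n"
            "is_a: GO:0000003 ! back edge",
        )
        with pytest.raises(ParseError, match="cycle"):
            parse_obo(io.StringIO(cyclic))

    def test_synthetic_dag_edge_count_matches_generator_record(self, small_sim):
        _, out = small_sim
        with open(out.obo, encoding="utf-8") as fh:
            dag = parse_obo(fh)
        assert len(dag) == out.truth["go_dag"]["n_terms"]
        assert dag.n_edges == out.truth["go_dag"]["n_edges"]


class TestPropagation:
    def test_leaf_annotation_closes_full_chain(self):
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        ann = propagate_true_path(dag, {"P1": {"GO:0000003"}})
        assert ann.propagated["P1"] == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_idempotence_on_closed_input(self):
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        once = propagate_true_path(dag, {"P1": {"GO:0000003"}})
        twice = propagate_true_path(dag, dict(once.propagated))
        assert twice.propagated == once.propagated

    def test_unknown_term_error_mode(self):
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        with pytest.raises(ValueError, match="GO:0099999"):
            propagate_true_path(dag, {"P1": {"GO:0099999"}}, on_unknown="error")

    def test_random_dag_matches_bfs_ancestor_oracle(self, rng):
        n = 40
        graph = nx.DiGraph()
        ids = [f"GO:{i:07d}" for i in range(1, n + 1)]
        graph.add_nodes_from(ids)
        for i in range(1, n):
            for parent in rng.choice(i, size=min(i, 2), replace=False):
                graph.add_edge(ids[i], ids[int(parent)])
        lines = ["format-version: 1.2", ""]
        for i, t in enumerate(ids):
            lines += [f"[Term]", f"id: {t}", f"name: t{i}",
                      "namespace: biological_process"]
            lines += [f"is_a: {p} ! x" for _, p in graph.out_edges(t)]
            lines.append("")
        dag = parse_obo(io.StringIO("\n".join(lines)))
        chosen = {f"P{j}": {ids[int(k)] for k in rng.integers(0, n, size=3)}
                  for j in range(25)}
        ann = propagate_true_path(dag, chosen)
        for protein, terms in chosen.items():
            # breadth-first ancestor closure, independently of the package path
            seen = set(terms)
            frontier = list(terms)
            while frontier:
                t = frontier.pop()
                for _, parent in graph.out_edges(t):
                    if parent not in seen:
                        seen.add(parent)
                        frontier.append(parent)
            assert ann.propagated[protein] == seen

    def test_parent_dominance_after_propagation(self, rng):
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        direct = {f"P{i}": {"GO:0000003"} if rng.random() < 0.5 else {"GO:0000002"}
                  for i in range(30)}
        ann = propagate_true_path(dag, direct)
        carriers = {}
        for protein, terms in ann.propagated.items():
            for t in terms:
                carriers.setdefault(t, set()).add(protein)
        for child, parent in dag.graph.edges:
            assert carriers.get(child, set()) <= carriers.get(parent, set())


class TestFisher:
    def test_study_equals_universe_gives_p_one(self):
        assert fisher_term_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_zero_observed_gives_p_one(self):
        assert fisher_term_test(0, 10, 5, 20) == pytest.approx(1.0)

    def test_example_matches_exhaustive_enumeration(self):
        p = fisher_term_test(5, 10, 5, 20)
        assert p == pytest.approx(hypergeom_upper_tail_exact(5, 10, 5, 20),
                                  rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_term_test(6, 5, 10, 20)
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_term_test(0, 10, 15, 20)  # k below K + n - N

    def test_agrees_with_enumeration_on_sampled_margins(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            p = fisher_term_test(k, n, K, N)
            assert p == pytest.approx(
                hypergeom_upper_tail_exact(k, n, K, N), rel=1e-9, abs=1e-12
            )


def _annotated_proteome(rng, n, leaf_rates, extra_terms=()):
    """Proteome whose proteins carry leaf GO:0000003 at given per-protein rate."""
    records = []
    for i in range(n):
        terms = set()
        if rng.random() < leaf_rates:
            terms.add("GO:0000003")
        else:
            terms.add("GO:0000002")
        terms |= set(extra_terms)
        records.append(ProteinRecord(
            accession=f"P{i:05d}", genus="G", domains=("PF00001",),
            go_terms=frozenset(terms),
        ))
    return VirtualProteome(group="CT", records=tuple(records))


class TestEnrich:
    def test_empty_study_returns_no_rows(self, rng, caplog):
        proteome = _annotated_proteome(rng, 20, 0.5)
        screen = ScreenResult(group="CT", retained=frozenset(),
                              partner_set_used=frozenset())
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        with caplog.at_level("WARNING"):
            rows = enrich(screen, proteome, dag)
        assert all(not v for v in rows.values())

    def test_study_equals_universe_all_p_one(self, rng):
        proteome = _annotated_proteome(rng, 30, 0.5)
        screen = ScreenResult(group="CT", retained=proteome.accessions,
                              partner_set_used=frozenset())
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        rows = enrich(screen, proteome, dag)
        assert rows["molecular_function"]
        assert all(r.p == pytest.approx(1.0) for r in rows["molecular_function"])

    def test_planted_term_ranks_first_and_passes_q(self, rng):
        n = 2500
        proteome = _annotated_proteome(rng, n, 0.05)
        # study: random 40% of proteins, plus enforced 3x carriage of the leaf
        study = set()
        for r in proteome.records:
            is_carrier = "GO:0000003" in r.go_terms
            p_in = 0.8 if is_carrier else 0.35
            if rng.random() < p_in:
                study.add(r.accession)
        screen = ScreenResult(group="CT", retained=frozenset(study),
                              partner_set_used=frozenset())
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        rows = enrich(screen, proteome, dag)["molecular_function"]
        assert rows[0].go_id == "GO:0000003"
        assert rows[0].significant_q
        assert rows[0].observed > rows[0].expected

    def test_bh_q_monotone_and_bounded(self, rng):
        proteome = _annotated_proteome(rng, 400, 0.3)
        study = {r.accession for r in proteome.records if rng.random() < 0.3}
        screen = ScreenResult(group="CT", retained=frozenset(study),
                              partner_set_used=frozenset())
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        rows = enrich(screen, proteome, dag)["molecular_function"]
        assert rows == sorted(rows, key=lambda r: (r.p, r.go_id))
        for r in rows:
            assert r.p <= r.q <= 1.0
        qs = [r.q for r in rows]
        assert qs == sorted(qs)

    def test_parent_dominance_in_annotated_counts(self, rng):
        proteome = _annotated_proteome(rng, 200, 0.4)
        study = {r.accession for r in proteome.records if rng.random() < 0.5}
        screen = ScreenResult(group="CT", retained=frozenset(study),
                              partner_set_used=frozenset())
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        rows = {r.go_id: r for r in
                enrich(screen, proteome, dag)["molecular_function"]}
        for child, parent in dag.graph.edges:
            if child in rows and parent in rows:
                assert rows[parent].annotated >= rows[child].annotated
                assert rows[parent].observed >= rows[child].observed

    def test_raw_p_calibration_under_uniform_null(self, rng):
        """Random study subsets: about alpha of the term tests fall below alpha."""
        alpha = 0.05
        hits = trials = 0
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        for _ in range(200):
            proteome = _annotated_proteome(rng, 120, 0.5)
            study = {r.accession for r in proteome.records if rng.random() < 0.4}
            if not study:
                continue
            screen = ScreenResult(group="CT", retained=frozenset(study),
                                  partner_set_used=frozenset())
            rows = enrich(screen, proteome, dag)["molecular_function"]
            for r in rows:
                if r.go_id == "GO:0000003":  # one genuinely random term per rep
                    trials += 1
                    hits += r.p < alpha
        from scipy.stats import binom

        lo, hi = binom.interval(0.999, trials, alpha)
        # one-sided discreteness makes Fisher conservative: no excess allowed
        assert hits <= hi

    def test_writer_is_deterministic_tsv(self, rng):
        proteome = _annotated_proteome(rng, 50, 0.4)
        screen = ScreenResult(group="CT",
                              retained=frozenset(list(proteome.accessions)[:20]),
                              partner_set_used=frozenset())
        dag = parse_obo(io.StringIO(CHAIN_OBO))
        rows = enrich(screen, proteome, dag)
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_enrichment_tsv(rows, buf1)
        write_enrichment_tsv(enrich(screen, proteome, dag), buf2)
        assert buf1.getvalue() == buf2.getvalue()
        assert buf1.getvalue().startswith("namespace\tgo_id")
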