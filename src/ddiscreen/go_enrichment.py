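"""GO term enrichment of screened interactor sets (classic Fisher on a DAG).

The study set is a group's screened interactors and the universe is that
group's virtual proteome restricted to proteins with at least one annotation
in the namespace under test.  Direct annotations are first propagated to all
``is_a`` ancestors (the true-path rule), then every term with >= 1 annotated
universe protein is tested with a one-sided Fisher exact test (hypergeometric
upper tail) and Benjamini-Hochberg adjusted within its namespace.

This is the "classic" algorithm: each term is tested independently on the
propagated annotations; DAG-decorrelating schemes (weight/elim) are out of
scope.  Both the raw-p and the q-value significance filters are reported,
since either convention is used for this kind of screen.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import obonet
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interaction_map import ParseError
from .virtual_proteome import ScreenResult, VirtualProteome

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
DEFAULT_Q_MAX = 0.01


class GoDag:
    """Gene Ontology ``is_a`` DAG with term metadata.

    Wraps a :class:`networkx.DiGraph` whose edges point child -> parent, so
    graph descendants of a node are its ontology ancestors.
    """

    def __init__(self, graph: nx.DiGraph,
                 meta: Mapping[str, dict],
                 obsolete: frozenset[str]):
        self.graph = graph
        self.meta = dict(meta)
        self.obsolete = obsolete

    def __contains__(self, term: str) -> bool:
        return term in self.meta

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def name(self, term: str) -> str:
        return self.meta[term].get("name", "")

    def namespace(self, term: str) -> str:
        return self.meta[term].get("namespace", "")

    def is_obsolete(self, term: str) -> bool:
        return term in self.obsolete

    @functools.lru_cache(maxsize=None)
    def ancestors(self, term: str) -> frozenset[str]:
        """All ``is_a`` ancestors of a term (excluding the term itself)."""
        return frozenset(nx.descendants(self.graph, term))

    def roots(self) -> frozenset[str]:
        return frozenset(
            t for t in self.graph.nodes if self.graph.out_degree(t) == 0
            and t not in self.obsolete
        )


@dataclasses.dataclass
class AnnotationMap:
    """Direct and true-path propagated protein -> GO annotations."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]


@dataclasses.dataclass
class EnrichmentRow:
    """One tested GO term: counts, Fisher p and BH q."""

    go_id: str
    namespace: str
    name: str
    annotated: int   # universe proteins carrying the term (after propagation)
    observed: int    # study proteins carrying the term
    expected: float  # annotated * |study| / |universe|
    p: float
    q: float
    significant_q: bool
    significant_p: bool


def parse_obo(stream: IO[str] | str) -> GoDag:
    """Parse an OBO 1.2 subset into a :class:`GoDag`.

    Only ``[Term]`` stanzas with ``id``, ``name``, ``namespace``, ``is_a`` and
    ``is_obsolete`` are interpreted; unknown tags are ignored.  Obsolete terms
    are present but carry no edges and cannot be annotated.  A cycle among
    ``is_a`` edges is an error naming one cycle.
    """
    multigraph = obonet.read_obo(stream, ignore_obsolete=False)
    graph = nx.DiGraph()
    meta: dict[str, dict] = {}
    obsolete = set()
    for term, data in multigraph.nodes(data=True):
        meta[term] = {
            "name": data.get("name", ""),
            "namespace": data.get("namespace", ""),
        }
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
        graph.add_node(term)
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if child in obsolete or parent in obsolete:
            continue
        graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise ParseError(f"cycle in is_a graph: {path}")
    return GoDag(graph=graph, meta=meta, obsolete=frozenset(obsolete))


def propagate_true_path(
    dag: GoDag,
    direct: Mapping[str, Iterable[str]],
    on_unknown: str = "warn",
) -> AnnotationMap:
    """Close each protein's annotation set under ``is_a`` ancestry.

    Annotations to unknown or obsolete terms are skipped with a warning
    (``on_unknown="error"`` raises instead).
    """
    if on_unknown not in ("warn", "error"):
        raise ValueError("on_unknown must be 'warn' or 'error'")
    direct_out: dict[str, frozenset[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    bad_seen: set[str] = set()
    for protein, terms in direct.items():
        kept: set[str] = set()
        closed: set[str] = set()
        for t in terms:
            if t not in dag or dag.is_obsolete(t):
                if on_unknown == "error":
                    raise ValueError(
                        f"annotation of {protein} to unknown/obsolete term {t}"
                    )
                if t not in bad_seen:
                    log.warning("skipping annotation to unknown/obsolete term %s", t)
                    bad_seen.add(t)
                continue
            kept.add(t)
            closed.add(t)
            closed |= dag.ancestors(t)
        direct_out[protein] = frozenset(kept)
        propagated[protein] = frozenset(closed)
    return AnnotationMap(direct=direct_out, propagated=propagated)


def fisher_term_test(
    annotated_in_study: int,
    study_size: int,
    annotated_in_universe: int,
    universe_size: int,
) -> float:
    """One-sided (enrichment) Fisher exact p = hypergeometric upper tail.

    P(X >= annotated_in_study) for X ~ Hypergeom(universe_size,
    annotated_in_universe, study_size).
    """
    k, n, K, N = annotated_in_study, study_size, annotated_in_universe, universe_size
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, study={n}, annotated={K}, universe={N}"
        )
    if k < K + n - N:
        raise ValueError(
            f"inconsistent counts: k={k} below max(0, K+n-N)={K + n - N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    screen: ScreenResult,
    proteome: VirtualProteome,
    dag: GoDag,
    annotations: AnnotationMap | None = None,
    q_max: float = DEFAULT_Q_MAX,
    p_max: float = DEFAULT_Q_MAX,
    universe: str = "proteome",
) -> dict[str, list[EnrichmentRow]]:
    """Per-namespace GO enrichment of the screened interactors.

    ``annotations=None`` builds the map from the proteome records' direct GO
    terms.  ``universe="proteome"`` (default) tests against all annotated
    proteins of the group's virtual proteome; ``universe="screen"`` restricts
    the universe to the screened set itself (then every p is 1).
    Rows are sorted by (p, go_id); BH adjustment is within namespace.
    """
    if universe not in ("proteome", "screen"):
        raise ValueError("universe must be 'proteome' or 'screen'")
    if annotations is None:
        annotations = propagate_true_path(
            dag, {r.accession: r.go_terms for r in proteome.records}
        )
    prop = annotations.propagated
    results: dict[str, list[EnrichmentRow]] = {ns: [] for ns in NAMESPACES}
    if not screen.retained:
        log.warning("empty study set for group %s: no enrichment rows", screen.group)
        return results
    for ns in NAMESPACES:
        carriers: dict[str, set[str]] = {}
        universe_ns: set[str] = set()
        pool = (proteome.accessions if universe == "proteome"
                else frozenset(screen.retained) & proteome.accessions)
        for acc in pool:
            terms = [t for t in prop.get(acc, ()) if dag.namespace(t) == ns]
            if not terms:
                continue
            universe_ns.add(acc)
            for t in terms:
                carriers.setdefault(t, set()).add(acc)
        study_ns = universe_ns & screen.retained
        if not universe_ns or not study_ns:
            continue
        rows = []
        for term in sorted(carriers):
            annotated = len(carriers[term])
            observed = len(carriers[term] & study_ns)
            expected = annotated * len(study_ns) / len(universe_ns)
            p = fisher_term_test(observed, len(study_ns), annotated, len(universe_ns))
            rows.append((term, annotated, observed, expected, p))
        qvals = multipletests([r[4] for r in rows], method="fdr_bh")[1]
        out = [
            EnrichmentRow(
                go_id=term, namespace=ns, name=dag.name(term),
                annotated=annotated, observed=observed, expected=expected,
                p=p, q=float(q),
                significant_q=bool(q <= q_max), significant_p=bool(p < p_max),
            )
            for (term, annotated, observed, expected, p), q in zip(rows, qvals)
        ]
        out.sort(key=lambda r: (r.p, r.go_id))
        results[ns] = out
    return results


def write_enrichment_tsv(
    results: Mapping[str, Sequence[EnrichmentRow]], stream: IO[str]
) -> None:
    stream.write(
        "namespace\tgo_id\tname\tannotated\tobserved\texpected\tp\tq\t"
        "sig_q\tsig_p\n"
    )
    for ns in NAMESPACES:
        for r in results.get(ns, []):
            stream.write(
                f"{ns}\t{r.go_id}\t{r.name}\t{r.annotated}\t{r.observed}\t"
                f"{r.expected:.6g}\t{r.p:.6g}\t{r.q:.6g}\t"
                f"{int(r.significant_q)}\t{int(r.significant_p)}\n"
            )
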