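"""Seeded synthetic microbiome/proteome fixtures with known ground truth.

The generator emulates the study design the pipeline targets: three sample
groups (healthy controls CT and the two IBD groups CD/UC) whose genus sets
partially overlap (by default 15 genera shared by all three, plus 13 CT-only,
9 CD-only and 8 UC-only genera), a per-genus collection of proteins whose
Pfam-domain content follows configurable background carriage rates with
group-specific enrichment/depletion factors, and a small single-rooted-per-
namespace GO DAG with true-path-consistent annotations.

Proteins belong to genera, and groups sharing a genus share its proteins as
identical records — exactly how overlap arises in a real virtual
metaproteome.  A per-(domain, group) rate effect therefore applies to the
proteins of genera *exclusive* to that group; the truth record stores the
resulting effective per-group rates alongside the exact empirical counts that
were sampled, so parameter-recovery tests can compare pipeline output against
what was actually generated, not just against the parameters.

One integer seed determines every draw; two runs with the same configuration
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
_LOCATIONS = ("cytoplasm", "membrane", "secreted")

#: synthetic query domains used in the emitted interaction table
QUERY_DOMAINS = ("PF98001", "PF98002")


def default_domain_catalogue(
    n_domains: int = 50, rate: float = 0.01
) -> dict[str, float]:
    """Catalogue of synthetic Pfam-like accessions at a uniform carriage rate."""
    return {f"PF9{i:04d}": rate for i in range(n_domains)}


@dataclasses.dataclass
class SimulationConfig:
    """Everything the generator needs; the seed fixes all randomness.

    ``effects`` maps ``(domain_accession, group)`` to a multiplicative rate
    factor applied to proteins of genera exclusive to that group.
    ``planted_enriched_terms`` is a sequence of ``(go_id, group, factor)``:
    each such GO term is created as a dedicated molecular_function leaf,
    annotated at ``planted_go_base_rate`` everywhere and at ``factor`` times
    that rate on the group-exclusive interactor proteins.
    """

    seed: int = 0
    groups: tuple[str, ...] = ("CT", "CD", "UC")
    shared_genera: int = 15
    specific_genera: tuple[int, ...] = (13, 9, 8)
    proteins_per_genus: int = 50
    domain_catalogue: Mapping[str, float] | None = None
    n_partner_domains: int = 20
    effects: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=dict
    )
    go_dag_size: int = 30
    go_branching: int = 2
    go_terms_per_protein: int = 3
    planted_enriched_terms: tuple[tuple[str, str, float], ...] = ()
    planted_go_base_rate: float = 0.05

    def catalogue(self) -> dict[str, float]:
        if self.domain_catalogue is None:
            return default_domain_catalogue()
        return dict(self.domain_catalogue)

    def validate(self) -> None:
        if len(self.specific_genera) != len(self.groups):
            raise ValueError("specific_genera must align with groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        cat = self.catalogue()
        if self.n_partner_domains > len(cat):
            raise ValueError("n_partner_domains exceeds catalogue size")
        for (dom, group), factor in self.effects.items():
            if dom not in cat:
                raise ValueError(f"effect on unknown domain {dom}")
            if group not in self.groups:
                raise ValueError(f"effect on unknown group {group}")
            if not 0 <= cat[dom] * factor <= 1:
                raise ValueError(
                    f"infeasible rate for {dom} in {group}: "
                    f"{cat[dom]} * {factor} outside [0, 1]"
                )
        for term, group, factor in self.planted_enriched_terms:
            if group not in self.groups:
                raise ValueError(f"planted term {term} on unknown group {group}")
            if not 0 <= self.planted_go_base_rate * factor <= 1:
                raise ValueError(f"infeasible planted rate for {term}")
        if self.go_dag_size < 2 * len(GO_NAMESPACES):
            raise ValueError("go_dag_size too small for three rooted namespaces")


@dataclasses.dataclass
class SimulationOutput:
    """Paths of the emitted files plus the in-memory truth record."""

    proteins: Path
    taxa: Path
    interactions: Path
    obo: Path
    truth_path: Path
    truth: dict


def _genus_layout(config: SimulationConfig) -> tuple[dict[str, list[str]], dict[str, str | None]]:
    """Genus name lists per group and genus -> exclusive-group map."""
    shared = [f"Genus{i:03d}" for i in range(1, config.shared_genera + 1)]
    nxt = config.shared_genera + 1
    per_group: dict[str, list[str]] = {g: list(shared) for g in config.groups}
    exclusive: dict[str, str | None] = {g: None for g in shared}
    for group, n_spec in zip(config.groups, config.specific_genera):
        for _ in range(n_spec):
            name = f"Genus{nxt:03d}"
            nxt += 1
            per_group[group].append(name)
            exclusive[name] = group
    return per_group, exclusive


def _build_go_dag(config: SimulationConfig, rng: np.random.Generator):
    """Random rooted DAG per namespace; returns (terms, edges, leaf pool).

    ``terms`` maps id -> namespace; ``edges`` is a sorted list of (child,
    parent) is_a pairs.  Planted terms become dedicated molecular_function
    leaves hanging off the MF root.
    """
    terms: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    roots = {}
    tid = 1
    for ns in GO_NAMESPACES:
        term = f"GO:90000{tid:02d}"
        terms[term] = ns
        roots[ns] = term
        tid += 1
    n_extra = config.go_dag_size - len(GO_NAMESPACES)
    by_ns: dict[str, list[str]] = {ns: [roots[ns]] for ns in GO_NAMESPACES}
    for i in range(n_extra):
        ns = GO_NAMESPACES[int(rng.integers(0, len(GO_NAMESPACES)))]
        term = f"GO:90000{tid:02d}" if tid < 100 else f"GO:9000{tid:03d}"
        tid += 1
        pool = by_ns[ns]
        n_parents = int(rng.integers(1, config.go_branching + 1))
        n_parents = min(n_parents, len(pool))
        parents = rng.choice(len(pool), size=n_parents, replace=False)
        for pi in sorted(int(x) for x in parents):
            edges.append((term, pool[pi]))
        terms[term] = ns
        by_ns[ns].append(term)
    for term, group, factor in config.planted_enriched_terms:
        if term in terms:
            raise ValueError(f"planted term id collides: {term}")
        terms[term] = "molecular_function"
        edges.append((term, roots["molecular_function"]))
    has_children = {parent for _, parent in edges}
    planted = {t for t, _, _ in config.planted_enriched_terms}
    leaf_pool = sorted(
        t for t in terms
        if t not in has_children and t not in roots.values() and t not in planted
    )
    return terms, sorted(edges), leaf_pool


def _write_obo(path: Path, terms: dict[str, str], edges: list[tuple[str, str]]) -> None:
    parent_of: dict[str, list[str]] = {}
    for child, parent in edges:
        parent_of.setdefault(child, []).append(parent)
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(terms):
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: synthetic term {term.split(':')[1]}",
            f"namespace: {terms[term]}",
        ]
        for parent in sorted(parent_of.get(term, [])):
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def simulate(config: SimulationConfig, outdir: str | Path) -> SimulationOutput:
    """Generate all pipeline inputs plus a truth record under ``outdir``.

    Emits ``proteins.tsv``, ``taxa.tsv``, ``interactions.tsv``, ``go.obo``
    and ``truth.json`` in the exact dialects the pipeline readers consume.
    Raises before writing anything if the configuration is infeasible.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    catalogue = config.catalogue()
    domains = sorted(catalogue)
    base_rates = np.array([catalogue[d] for d in domains])
    partner_set = sorted(domains)[: config.n_partner_domains]
    partner_idx = np.array([domains.index(d) for d in partner_set])

    per_group, exclusive = _genus_layout(config)
    genus_order: list[str] = []
    for genus in sorted(exclusive):
        genus_order.append(genus)

    terms, edges, leaf_pool = _build_go_dag(config, rng)

    # --- sample proteins genus by genus -----------------------------------
    accessions: list[str] = []
    genus_col: list[str] = []
    domain_strings: list[str] = []
    go_sets: list[set[str]] = []
    loc_col: list[str] = []
    is_interactor = []
    excl_group_col: list[str | None] = []
    genus_carriers: dict[str, np.ndarray] = {}

    acc_no = 1
    n = config.proteins_per_genus
    for genus in genus_order:
        excl = exclusive[genus]
        rates = base_rates.copy()
        if excl is not None:
            for j, d in enumerate(domains):
                factor = config.effects.get((d, excl), 1.0)
                rates[j] = base_rates[j] * factor
        present = rng.random((n, len(domains))) < rates[None, :]
        duplicate = rng.random((n, len(domains))) < 0.05
        genus_carriers[genus] = present.sum(axis=0).astype(int)
        go_idx = rng.integers(0, len(leaf_pool), size=(n, config.go_terms_per_protein))
        locs = rng.choice(len(_LOCATIONS), size=n)
        for i in range(n):
            acc = f"B{acc_no:07d}"
            acc_no += 1
            accessions.append(acc)
            genus_col.append(genus)
            toks: list[str] = []
            for j in np.nonzero(present[i])[0]:
                toks.append(domains[j])
                if duplicate[i, j]:
                    toks.append(domains[j])
            domain_strings.append("|".join(toks))
            go_sets.append({leaf_pool[k] for k in go_idx[i]})
            loc_col.append(_LOCATIONS[locs[i]])
            is_interactor.append(bool(present[i, partner_idx].any()))
            excl_group_col.append(excl)

    n_proteins = len(accessions)
    is_interactor = np.array(is_interactor)

    # --- planted GO enrichment on group-exclusive interactors -------------
    base = config.planted_go_base_rate
    for term, group, factor in config.planted_enriched_terms:
        eligible = np.array(
            [eg == group for eg in excl_group_col]
        ) & is_interactor
        prob = np.where(eligible, base * factor, base)
        hit = rng.random(n_proteins) < prob
        for i in np.nonzero(hit)[0]:
            go_sets[int(i)].add(term)

    # --- abundances per group ---------------------------------------------
    abundances: dict[str, dict[str, float]] = {}
    for group in config.groups:
        genera = per_group[group]
        ab = rng.dirichlet(np.ones(len(genera)))
        abundances[group] = {g: float(a) for g, a in zip(genera, ab)}

    # --- truth bookkeeping -------------------------------------------------
    group_sizes = {g: n * len(per_group[g]) for g in config.groups}
    observed_counts = {
        g: {
            d: int(sum(genus_carriers[genus][j] for genus in per_group[g]))
            for j, d in enumerate(domains)
        }
        for g in config.groups
    }
    effective_rates = {}
    for g in config.groups:
        n_shared = sum(1 for genus in per_group[g] if exclusive[genus] is None)
        n_excl = len(per_group[g]) - n_shared
        effective_rates[g] = {}
        for d in domains:
            factor = config.effects.get((d, g), 1.0)
            effective_rates[g][d] = catalogue[d] * (
                (n_shared + n_excl * factor) / len(per_group[g])
            )
    group_of_protein = {
        g: {i for i, genus in enumerate(genus_col) if genus in set(per_group[g])}
        for g in config.groups
    }
    planted_truth = []
    for term, group, factor in config.planted_enriched_terms:
        per_group_counts = {}
        for g in config.groups:
            idx = group_of_protein[g]
            carriers = {i for i in idx if term in go_sets[i]}
            study = {i for i in idx if is_interactor[i]}
            per_group_counts[g] = {
                "universe": len(idx),
                "annotated": len(carriers),
                "study": len(study),
                "observed": len(carriers & study),
            }
        planted_truth.append(
            {"term": term, "group": group, "factor": factor,
             "counts": per_group_counts}
        )

    truth = {
        "seed": config.seed,
        "groups": list(config.groups),
        "genera_per_group": {g: sorted(per_group[g]) for g in config.groups},
        "group_sizes": group_sizes,
        "domain_rates": {d: catalogue[d] for d in domains},
        "effective_rates": effective_rates,
        "observed_domain_counts": observed_counts,
        "partner_set": partner_set,
        "query_domains": list(QUERY_DOMAINS),
        "effects": {f"{d}|{g}": f for (d, g), f in sorted(config.effects.items())},
        "planted_enriched_terms": planted_truth,
        "n_interactors_total": int(is_interactor.sum()),
        "go_dag": {"n_terms": len(terms), "n_edges": len(edges),
                   "leaf_pool_size": len(leaf_pool)},
    }

    # --- write files (validation passed; deterministic formatting) --------
    proteins_path = outdir / "proteins.tsv"
    with proteins_path.open("w", encoding="utf-8") as fh:
        fh.write("accession\tgenus\tdomains\tgo\tlocation\n")
        for i in range(n_proteins):
            go = "|".join(sorted(go_sets[i]))
            fh.write(
                f"{accessions[i]}\t{genus_col[i]}\t{domain_strings[i]}\t"
                f"{go}\t{loc_col[i]}\n"
            )

    taxa_path = outdir / "taxa.tsv"
    with taxa_path.open("w", encoding="utf-8") as fh:
        fh.write("group\tgenus\tabundance\n")
        for group in config.groups:
            for genus in sorted(per_group[group]):
                fh.write(f"{group}\t{genus}\t{abundances[group][genus]:.6f}\n")

    inter_path = outdir / "interactions.tsv"
    with inter_path.open("w", encoding="utf-8") as fh:
        fh.write("# domain_acc\tpartner_acc\tdescription\n")
        half = (len(partner_set) + 1) // 2
        for q, chunk in zip(QUERY_DOMAINS, (partner_set[:half], partner_set[half:])):
            for p in chunk:
                fh.write(f"{q}\t{p}\tsynthetic partner domain\n")

    obo_path = outdir / "go.obo"
    _write_obo(obo_path, terms, edges)

    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return SimulationOutput(
        proteins=proteins_path, taxa=taxa_path, interactions=inter_path,
        obo=obo_path, truth_path=truth_path, truth=truth,
    )
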