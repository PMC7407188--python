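"""Query-protein domain architecture and domain-domain interaction expansion.

A candidate secreted protein (the reference case is human S100B, UniProt
P04271) is decomposed into its Pfam domains, and each domain is expanded into
the set of Pfam domains it is known to contact in solved structures (an
iPfam-style partner table).  The union of the partner sets over the query's
domains is the *partner set*: any protein carrying at least one of these
domains is a putative structural interactor of the query.

Two inputs are handled here:

* ``hmmscan --domtblout`` output for the query protein (profile-HMM search is
  *not* re-run here; only its tabular output is parsed), and
* a two-column TSV of known domain-domain interactions.

A curated partner table for S100B's two domains (S_100, PF01023, and
EF-hand_1, PF00036) ships with the package, together with a synthetic
domtblout fixture carrying the published S100B architecture.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from importlib import resources
from typing import IO, Iterable, Mapping

log = logging.getLogger(__name__)

PFAM_ACC_RE = re.compile(r"^PF\d{5}$")

#: default retention threshold on the per-domain independent e-value
DEFAULT_EVALUE_MAX = 0.01


class ParseError(ValueError):
    """Malformed input file (wrong column count, bad token, bad coordinate)."""


def _normalise_pfam(token: str) -> str:
    """Strip a Pfam version suffix (``PF01023.24`` -> ``PF01023``)."""
    return token.split(".", 1)[0]


@dataclasses.dataclass(frozen=True)
class DomainHit:
    """One retained domain row from an hmmscan domtblout file.

    Coordinates are 1-based inclusive envelope coordinates on the query
    sequence.
    """

    query_id: str
    domain_accession: str
    domain_name: str
    env_start: int
    env_end: int
    independent_evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not PFAM_ACC_RE.match(self.domain_accession):
            raise ValueError(
                f"not a Pfam accession: {self.domain_accession!r}"
            )
        if self.env_start < 1 or self.env_start > self.env_end:
            raise ValueError(
                f"invalid envelope {self.env_start}-{self.env_end} "
                f"for {self.domain_accession}"
            )
        if self.independent_evalue < 0:
            raise ValueError("independent e-value must be non-negative")


@dataclasses.dataclass
class DomainInteractionMap:
    """Partner-domain lookup: Pfam accession -> set of partner accessions.

    Self-partners are permitted (the S_100 domain homo-multimerises).  The map
    is directional as parsed; :meth:`symmetric_closure` adds the reverse
    edges when an undirected view is wanted.
    """

    edges: dict[str, set[str]]
    source: str = ""
    version: str = ""
    labels: dict[str, str] = dataclasses.field(default_factory=dict)

    def partners(self, accession: str) -> frozenset[str]:
        return frozenset(self.edges.get(accession, set()))

    def __contains__(self, accession: str) -> bool:
        return accession in self.edges

    def symmetric_closure(self) -> "DomainInteractionMap":
        """Return a new map where a in partners(b) <=> b in partners(a)."""
        edges: dict[str, set[str]] = {k: set(v) for k, v in self.edges.items()}
        for dom, parts in self.edges.items():
            for p in parts:
                edges.setdefault(p, set()).add(dom)
        return DomainInteractionMap(
            edges=edges, source=self.source, version=self.version,
            labels=dict(self.labels),
        )


def parse_hmmscan_domtblout(
    stream: IO[str] | Iterable[str], evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[DomainHit]:
    """Parse hmmscan ``--domtblout`` output into :class:`DomainHit` rows.

    Rows whose per-domain independent e-value exceeds ``evalue_max`` are
    dropped; order of appearance is preserved.  The dialect is
    space-delimited with ``#`` comment lines and 22+ columns (the trailing
    free-text description may contain spaces).
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(maxsplit=22)
        if len(fields) < 22:
            raise ParseError(
                f"line {lineno}: expected >= 22 columns in domtblout row, "
                f"got {len(fields)}"
            )
        try:
            ievalue = float(fields[12])
            score = float(fields[13])
            env_start = int(fields[19])
            env_end = int(fields[20])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field: {exc}") from None
        if ievalue > evalue_max:
            continue
        try:
            hit = DomainHit(
                query_id=fields[3],
                domain_accession=_normalise_pfam(fields[1]),
                domain_name=fields[0],
                env_start=env_start,
                env_end=env_end,
                independent_evalue=ievalue,
                bit_score=score,
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        hits.append(hit)
    return hits


def parse_interaction_table(
    stream: IO[str] | Iterable[str],
    source: str = "",
    version: str = "",
    symmetric: bool = False,
) -> DomainInteractionMap:
    """Parse a two-column TSV of domain-domain interactions.

    Columns are ``domain_acc``, ``partner_acc`` and an optional free-text
    description; ``#`` lines are comments.  Duplicate pairs collapse; a
    non-Pfam token in either accession column is a :class:`ParseError`.
    """
    edges: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(
                f"line {lineno}: expected >= 2 tab-separated columns"
            )
        dom = _normalise_pfam(parts[0].strip())
        partner = _normalise_pfam(parts[1].strip())
        for token in (dom, partner):
            if not PFAM_ACC_RE.match(token):
                raise ParseError(
                    f"line {lineno}: not a Pfam accession: {token!r}"
                )
        edges.setdefault(dom, set()).add(partner)
        if len(parts) >= 3 and parts[2].strip():
            labels[partner] = parts[2].strip()
    dmap = DomainInteractionMap(
        edges=edges, source=source, version=version, labels=labels
    )
    return dmap.symmetric_closure() if symmetric else dmap


def expand_partner_domains(
    query_domains: Iterable[str], dmap: DomainInteractionMap
) -> set[str]:
    """Union of the partner sets over all query domains.

    A query domain absent from the map contributes nothing (a warning is
    logged, not an error): an interaction table never covers all of Pfam.
    """
    expanded: set[str] = set()
    for dom in sorted(set(query_domains)):
        if dom not in dmap:
            log.warning("query domain %s absent from interaction map", dom)
            continue
        expanded |= dmap.edges[dom]
    return expanded


def partner_provenance(
    query_domains: Iterable[str], dmap: DomainInteractionMap
) -> dict[str, list[str]]:
    """Map each expanded partner to the sorted query domains contributing it."""
    prov: dict[str, list[str]] = {}
    for dom in sorted(set(query_domains)):
        for p in dmap.partners(dom):
            prov.setdefault(p, []).append(dom)
    return {p: sorted(qs) for p, qs in sorted(prov.items())}


def write_partner_table(
    query_domains: Iterable[str], dmap: DomainInteractionMap, stream: IO[str]
) -> None:
    """Write the expanded partner set as TSV with a provenance column."""
    stream.write("partner_acc\tfrom_query_domains\tdescription\n")
    for partner, queries in partner_provenance(query_domains, dmap).items():
        desc = dmap.labels.get(partner, "")
        stream.write(f"{partner}\t{','.join(queries)}\t{desc}\n")


def write_interaction_table(dmap: DomainInteractionMap, stream: IO[str]) -> None:
    """Serialise a map back to the TSV dialect (lexicographic order)."""
    stream.write("# domain_acc\tpartner_acc\tdescription\n")
    for dom in sorted(dmap.edges):
        for partner in sorted(dmap.edges[dom]):
            desc = dmap.labels.get(partner, "")
            stream.write(f"{dom}\t{partner}\t{desc}\n")


# ---------------------------------------------------------------------------
# packaged S100B reference fixtures


def load_s100b_interaction_map() -> DomainInteractionMap:
    """The curated S100B partner-domain table shipped with the package."""
    ref = resources.files("ddiscreen.data").joinpath("s100b_interactions.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return parse_interaction_table(fh, source="curated S100B table", version="1")


def load_s100b_query_hits(
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[DomainHit]:
    """Domain hits for S100B from the packaged synthetic domtblout fixture."""
    ref = resources.files("ddiscreen.data").joinpath(
        "s100b_hits_synthetic.domtblout"
    )
    with ref.open("r", encoding="utf-8") as fh:
        return parse_hmmscan_domtblout(fh, evalue_max=evalue_max)


def query_domains_from_hits(hits: Iterable[DomainHit]) -> set[str]:
    """Distinct Pfam accessions present in a hit list."""
    return {h.domain_accession for h in hits}
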