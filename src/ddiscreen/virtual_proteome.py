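"""Virtual metaproteomes: genus filtering, interactor screening, partitioning.

A *virtual metaproteome* is the set of database proteins attributable to the
genera observed in a community profile — a proxy proteome inferred from
taxonomy rather than measured.  For each sample group (e.g. healthy controls
CT and the two IBD groups CD/UC) the annotated protein table is filtered to
the group's genera, then screened for proteins carrying at least one domain
from the query's partner set.  The retained accession sets are finally
partitioned across groups (the 7 Venn regions for three groups).

Genus matching is case-insensitive exact string equality; proteins contribute
to the screen by domain *presence*, not occurrence; relative abundances are
carried on the profile but do not weight the screen.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .interaction_map import ParseError

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A minimally annotated bacterial protein.

    ``domains`` is a multiset (tuple with repeats) of Pfam accessions;
    ``go_terms`` are the *direct* GO annotations.
    """

    accession: str
    genus: str
    domains: tuple[str, ...]
    go_terms: frozenset[str] = frozenset()
    localisation: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if not self.genus:
            raise ValueError(f"record {self.accession}: empty genus")


@dataclasses.dataclass
class TaxonProfile:
    """Genus-level composition of one sample group."""

    group: str
    genera: frozenset[str]
    abundances: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.abundances is not None:
            if set(self.abundances) != set(self.genera):
                raise ValueError(
                    f"profile {self.group}: abundances do not cover exactly "
                    "the listed genera"
                )
            if any(v < 0 for v in self.abundances.values()):
                raise ValueError(f"profile {self.group}: negative abundance")


@dataclasses.dataclass
class VirtualProteome:
    """Per-group genus-filtered collection of protein records."""

    group: str
    records: tuple[ProteinRecord, ...]

    @property
    def n_proteins(self) -> int:
        return len(self.records)

    @property
    def n_genera(self) -> int:
        return len({r.genus.lower() for r in self.records})

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(r.accession for r in self.records)


@dataclasses.dataclass
class ScreenResult:
    """Accessions retained by the partner-domain screen for one group."""

    group: str
    retained: frozenset[str]
    partner_set_used: frozenset[str]


@dataclasses.dataclass
class GroupPartition:
    """Venn partition of retained accession sets over the groups.

    ``region_counts`` is keyed by '&'-joined group labels (e.g. ``CT``,
    ``CT&CD``, ``CT&CD&UC``) — for three groups, the 7 Venn regions.
    """

    labels: tuple[str, ...]
    region_counts: dict[str, int]
    union_size: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.union_size == 0:
            return {k: 0.0 for k in self.region_counts}
        return {k: v / self.union_size for k, v in self.region_counts.items()}


# ---------------------------------------------------------------------------
# readers

_MANDATORY_COLUMNS = ("accession", "genus", "domains", "go")


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(tok for tok in cell.split("|") if tok) if cell else ()


def load_protein_table(stream: IO[str] | str) -> list[ProteinRecord]:
    """Read the protein annotation TSV.

    Header columns: ``accession genus domains go`` plus optional ``location``;
    ``domains`` and ``go`` are pipe-separated lists (empty allowed).
    Duplicate accessions are an error.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"protein table missing column(s): {', '.join(missing)}")
    dup = df["accession"][df["accession"].duplicated()]
    if not dup.empty:
        raise ParseError(f"duplicate accession(s): {', '.join(sorted(set(dup)))}")
    has_loc = "location" in df.columns
    records = []
    for row in df.itertuples(index=False):
        loc = _split_list(getattr(row, "location")) if has_loc else None
        records.append(
            ProteinRecord(
                accession=row.accession,
                genus=row.genus,
                domains=_split_list(row.domains),
                go_terms=frozenset(_split_list(row.go)),
                localisation=frozenset(loc) if loc else None,
            )
        )
    return records


def load_taxa_profiles(stream: IO[str] | str) -> dict[str, TaxonProfile]:
    """Read per-group genus profiles: TSV ``group genus abundance?``.

    Returns profiles keyed by group label, in order of first appearance.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    for col in ("group", "genus"):
        if col not in df.columns:
            raise ParseError(f"taxa profile missing column: {col}")
    has_ab = "abundance" in df.columns
    profiles: dict[str, TaxonProfile] = {}
    for group, sub in df.groupby("group", sort=False):
        genera = frozenset(g for g in sub["genus"] if g)
        abundances = None
        if has_ab and (sub["abundance"] != "").all():
            abundances = {
                g: float(a) for g, a in zip(sub["genus"], sub["abundance"]) if g
            }
        profiles[str(group)] = TaxonProfile(
            group=str(group), genera=genera, abundances=abundances
        )
    return profiles


# ---------------------------------------------------------------------------
# core operations


def build_virtual_proteome(
    records: Iterable[ProteinRecord], profile: TaxonProfile
) -> VirtualProteome:
    """Retain exactly the records whose genus matches a profile genus.

    Matching is case-insensitive exact string equality.  An empty result is
    legal (empty profile, or no annotated proteins for the genera).
    """
    wanted = {g.lower() for g in profile.genera}
    kept = tuple(r for r in records if r.genus.lower() in wanted)
    return VirtualProteome(group=profile.group, records=kept)


def screen_interactors(
    proteome: VirtualProteome, partner_set: Iterable[str]
) -> ScreenResult:
    """Retain proteins carrying >= 1 domain from the partner set (presence)."""
    partners = frozenset(partner_set)
    retained = frozenset(
        r.accession for r in proteome.records if partners.intersection(r.domains)
    )
    return ScreenResult(
        group=proteome.group, retained=retained, partner_set_used=partners
    )


def partition_groups(screens: Sequence[ScreenResult]) -> GroupPartition:
    """Accession-identity Venn partition of the retained sets.

    For three groups this yields the 7 exclusive regions; the generalisation
    to k groups enumerates all non-empty label subsets.
    """
    labels = tuple(s.group for s in screens)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    sets = {s.group: s.retained for s in screens}
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(set(sets[g]) for g in combo))
            for other in labels:
                if other not in combo:
                    inside -= sets[other]
            regions["&".join(combo)] = len(inside)
    union = len(frozenset().union(*sets.values())) if sets else 0
    return GroupPartition(labels=labels, region_counts=regions, union_size=union)


# ---------------------------------------------------------------------------
# writers (deterministic: lexicographic sort everywhere)


def write_screen_tsv(screen: ScreenResult, stream: IO[str]) -> None:
    stream.write(f"# group={screen.group}\n")
    stream.write(
        f"# partner_set={','.join(sorted(screen.partner_set_used))}\n"
    )
    stream.write("accession\n")
    for acc in sorted(screen.retained):
        stream.write(acc + "\n")


def read_screen_tsv(stream: IO[str] | Iterable[str]) -> ScreenResult:
    """Read back a screen TSV written by :func:`write_screen_tsv`."""
    group = ""
    partners: frozenset[str] = frozenset()
    retained: set[str] = set()
    for line in stream:
        line = line.rstrip("\n")
        if line.startswith("# group="):
            group = line.split("=", 1)[1]
        elif line.startswith("# partner_set="):
            val = line.split("=", 1)[1]
            partners = frozenset(v for v in val.split(",") if v)
        elif line and not line.startswith("#") and line != "accession":
            retained.add(line)
    if not group:
        raise ParseError("screen TSV lacks '# group=' header")
    return ScreenResult(group=group, retained=frozenset(retained),
                        partner_set_used=partners)


def write_partition_tsv(partition: GroupPartition, stream: IO[str]) -> None:
    """Partition report; percents rendered to 1 decimal place."""
    stream.write("region\tcount\tpercent\n")
    fr = partition.fractions
    for region in sorted(partition.region_counts):
        stream.write(
            f"{region}\t{partition.region_counts[region]}\t"
            f"{100.0 * fr[region]:.1f}\n"
        )
    stream.write(f"union\t{partition.union_size}\t100.0\n")


def partition_to_json(partition: GroupPartition) -> str:
    payload = {
        "labels": list(partition.labels),
        "region_counts": dict(sorted(partition.region_counts.items())),
        "union_size": partition.union_size,
        "fractions": {k: round(v, 6) for k, v in sorted(partition.fractions.items())},
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def write_proteome_summary(
    proteomes: Sequence[VirtualProteome],
    screens: Mapping[str, ScreenResult],
    stream: IO[str],
) -> None:
    """Per-group summary: proteome size, genera represented, interactors."""
    stream.write("group\tn_proteins\tn_genera\tn_interacting\n")
    for p in proteomes:
        n_int = len(screens[p.group].retained) if p.group in screens else 0
        stream.write(f"{p.group}\t{p.n_proteins}\t{p.n_genera}\t{n_int}\n")
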