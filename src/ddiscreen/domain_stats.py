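"""Per-domain observed/expected occurrence statistics across sample groups.

For each partner domain *d* and group *c*, O(d,c) counts the proteins in the
group's virtual proteome carrying at least one copy of *d* (presence, not
occurrence).  The expected count under the chance model is

    E(d,c) = f(d) * N(c),

where N(c) is the group's proteome size and f(d) a per-domain background
carriage rate.  By default f(d) is estimated from the pooled groups
(f = sum_c O(d,c) / sum_c N(c)), which makes the row test the classical
chi-squared homogeneity test on carrier counts; alternatively f(d) can come
from an external reference corpus (``background_mode="external"``), in which
case the expectations are externally fixed.

Each domain row is tested with Pearson's chi-squared, X2 = sum_c (O-E)^2 / E,
against the upper tail of the chi-squared distribution with df = k-1 (default,
appropriate for pooled rates) or df = k (externally fixed expectations).
Domains are classified as ``absent`` (no carrier anywhere), ``near_zero``
(too few carriers to test), ``significant`` (p below ``alpha_sig``),
``not_significant`` (p above ``ns_threshold``) or ``intermediate``, and each
tested domain carries a per-group direction profile sign(O - E).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .virtual_proteome import VirtualProteome

DEFAULT_ALPHA_SIG = 0.01
DEFAULT_NS_THRESHOLD = 0.5
DEFAULT_NEAR_ZERO_MIN = 10
DF_MODES = ("k-1", "k")


@dataclasses.dataclass
class DomainOccurrenceTable:
    """Observed counts, group sizes and background rates for a domain set."""

    domains: tuple[str, ...]
    groups: tuple[str, ...]
    observed: np.ndarray        # shape (n_domains, n_groups), int
    group_sizes: np.ndarray     # shape (n_groups,), int
    background_rates: np.ndarray  # shape (n_domains,), float

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=int)
        self.group_sizes = np.asarray(self.group_sizes, dtype=int)
        self.background_rates = np.asarray(self.background_rates, dtype=float)
        if self.observed.shape != (len(self.domains), len(self.groups)):
            raise ValueError("observed matrix shape mismatch")
        if np.any(self.observed > self.group_sizes[None, :]):
            raise ValueError("observed count exceeds group size")
        if np.any(self.background_rates < 0):
            raise ValueError("negative background rate")

    @property
    def expected(self) -> np.ndarray:
        return compute_expected(self.background_rates, self.group_sizes)


@dataclasses.dataclass
class DomainTestResult:
    """Chi-squared test outcome and classification for one domain row."""

    domain: str
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float | None
    df: int | None
    p: float | None
    class_label: str  # absent | near_zero | significant | not_significant | intermediate
    direction: tuple[str, ...] | None  # per-group '+', '-', '0'


def count_domain_occurrence(
    proteome: VirtualProteome, domain_set: Iterable[str]
) -> dict[str, int]:
    """O(d,c) for one group: proteins carrying >= 1 copy of each domain d."""
    wanted = frozenset(domain_set)
    counts = dict.fromkeys(sorted(wanted), 0)
    for record in proteome.records:
        for d in wanted.intersection(record.domains):
            counts[d] += 1
    return counts


def estimate_background_rate(reference_observed: float, reference_size: float) -> float:
    """f(d) = carriers / corpus size in a reference corpus."""
    if reference_size <= 0:
        raise ValueError("reference size must be positive")
    return reference_observed / reference_size


def compute_expected(
    background_rates: np.ndarray | Sequence[float],
    group_sizes: np.ndarray | Sequence[float],
) -> np.ndarray:
    """E(d,c) = f(d) * N(c); full precision, rounding is display-only."""
    f = np.asarray(background_rates, dtype=float)
    n = np.asarray(group_sizes, dtype=float)
    if np.any(f < 0):
        raise ValueError("negative background rate")
    if np.any(n < 0):
        raise ValueError("group sizes must be non-negative")
    return np.atleast_1d(f)[:, None] * np.atleast_1d(n)[None, :]


def build_occurrence_table(
    proteomes: Sequence[VirtualProteome],
    domain_set: Iterable[str],
    background_rates: Mapping[str, float] | None = None,
) -> DomainOccurrenceTable:
    """Tabulate O(d,c) over groups and attach background rates.

    ``background_rates=None`` selects the pooled estimate
    f(d) = sum_c O(d,c) / sum_c N(c).  Passing an explicit mapping (domain ->
    rate) emulates an external reference corpus; domains missing from the
    mapping get rate 0.
    """
    domains = tuple(sorted(set(domain_set)))
    groups = tuple(p.group for p in proteomes)
    if len(set(groups)) != len(groups):
        raise ValueError(f"duplicate group labels: {groups}")
    observed = np.zeros((len(domains), len(groups)), dtype=int)
    for j, proteome in enumerate(proteomes):
        counts = count_domain_occurrence(proteome, domains)
        observed[:, j] = [counts[d] for d in domains]
    sizes = np.array([p.n_proteins for p in proteomes], dtype=int)
    if background_rates is None:
        total = sizes.sum()
        rates = observed.sum(axis=1) / total if total > 0 else np.zeros(len(domains))
    else:
        rates = np.array([background_rates.get(d, 0.0) for d in domains])
    return DomainOccurrenceTable(
        domains=domains, groups=groups, observed=observed,
        group_sizes=sizes, background_rates=rates,
    )


def chisq_row_test(
    observed: Sequence[float],
    expected: Sequence[float],
    df_mode: str = "k-1",
) -> tuple[float, int, float]:
    """Pearson chi-squared goodness-of-fit for one domain row.

    Returns ``(chi2, df, p)`` with p the upper tail of the chi-squared
    distribution.  ``df_mode="k-1"`` (default) fits expectations derived from
    the pooled data; ``"k"`` fits externally fixed expectations.  Any
    expected count <= 0 is an error: such domains must be excluded upstream.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1 or o.size < 2:
        raise ValueError("observed and expected must be equal-length rows, k >= 2")
    if np.any(e <= 0):
        raise ValueError(
            "expected count <= 0; exclude this domain from testing"
        )
    if df_mode not in DF_MODES:
        raise ValueError(f"df_mode must be one of {DF_MODES}")
    chi2 = float(np.sum((o - e) ** 2 / e))
    df = o.size - 1 if df_mode == "k-1" else o.size
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _direction(o: np.ndarray, e: np.ndarray) -> tuple[str, ...]:
    return tuple("+" if oo > ee else "-" if oo < ee else "0" for oo, ee in zip(o, e))


def classify_domain_rows(
    table: DomainOccurrenceTable,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
    ns_threshold: float = DEFAULT_NS_THRESHOLD,
    near_zero_min: int = DEFAULT_NEAR_ZERO_MIN,
    df_mode: str = "k-1",
) -> list[DomainTestResult]:
    """Test and classify every domain row of an occurrence table.

    Rows with no carriers anywhere are ``absent``; rows with fewer than
    ``near_zero_min`` total carriers are ``near_zero`` and excluded from
    testing (mirroring the exclusion of domains observed at a frequency close
    to zero); remaining rows are chi-squared tested and labelled by p-value.
    """
    expected = table.expected
    results: list[DomainTestResult] = []
    for i, domain in enumerate(table.domains):
        o = table.observed[i]
        e = expected[i]
        total = int(o.sum())
        if total == 0:
            results.append(DomainTestResult(
                domain=domain, observed=tuple(int(x) for x in o),
                expected=tuple(float(x) for x in e),
                chi2=None, df=None, p=None, class_label="absent", direction=None,
            ))
            continue
        if total < near_zero_min or np.any(e <= 0):
            # too few carriers to test, or a degenerate zero-expectation
            # column (empty group): excluded from testing either way
            results.append(DomainTestResult(
                domain=domain, observed=tuple(int(x) for x in o),
                expected=tuple(float(x) for x in e),
                chi2=None, df=None, p=None, class_label="near_zero", direction=None,
            ))
            continue
        chi2, df, p = chisq_row_test(o, e, df_mode=df_mode)
        if p < alpha_sig:
            label = "significant"
        elif p > ns_threshold:
            label = "not_significant"
        else:
            label = "intermediate"
        results.append(DomainTestResult(
            domain=domain, observed=tuple(int(x) for x in o),
            expected=tuple(float(x) for x in e),
            chi2=chi2, df=df, p=p, class_label=label,
            direction=_direction(o, e),
        ))
    return results


def write_domain_table(
    results: Sequence[DomainTestResult],
    groups: Sequence[str],
    stream: IO[str],
) -> None:
    """TSV report: per-group O and E (integer display + full-precision sidecar),
    chi2, df, p, class and direction profile."""
    obs_cols = [f"obs_{g}" for g in groups]
    exp_cols = [f"exp_{g}" for g in groups]
    exp_full = [f"exp_{g}_full" for g in groups]
    header = (["domain"] + obs_cols + exp_cols + exp_full
              + ["chi2", "df", "p", "class", "direction"])
    stream.write("\t".join(header) + "\n")
    for r in sorted(results, key=lambda r: r.domain):
        row = [r.domain]
        row += [str(o) for o in r.observed]
        row += [str(int(round(e))) for e in r.expected]
        row += [f"{e:.6g}" for e in r.expected]
        row += [
            f"{r.chi2:.6g}" if r.chi2 is not None else "NA",
            str(r.df) if r.df is not None else "NA",
            f"{r.p:.6g}" if r.p is not None else "NA",
            r.class_label,
            "".join(r.direction) if r.direction is not None else "NA",
        ]
        stream.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# packaged S100B reference tables


def load_s100b_occurrence_reference() -> pd.DataFrame:
    """Published per-domain observed/expected counts for the S100B screen.

    Columns: domain, obs_CT, exp_CT, obs_CD, exp_CD, obs_UC, exp_UC,
    description.
    """
    ref = resources.files("ddiscreen.data").joinpath("s100b_domain_occurrence.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_s100b_group_sizes() -> pd.DataFrame:
    """Published virtual-proteome sizes per group (CT/CD/UC)."""
    ref = resources.files("ddiscreen.data").joinpath("s100b_group_sizes.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
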