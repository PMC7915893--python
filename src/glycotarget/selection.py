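"""Downstream selection logic of the first database search.

Reproduces the funnel applied to search-engine protein exports: restrict to
plasma-membrane proteins (GO-derived registry), rank by posterior error
probability (PEP; smaller = more confident), keep the top N per
fractionation method, and intersect methods to find shared signatures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ProteinIdentification",
    "MembraneRegistry",
    "filter_membrane",
    "top_by_pep",
    "intersect_methods",
    "deduplicate",
    "select_common",
    "read_identifications",
    "read_registry",
]

_ISOFORM_RE = re.compile(r"-\d+$")


@dataclass(frozen=True)
class ProteinIdentification:
    """One protein record from a search-engine export."""

    accession: str
    pep_score: float
    method_tag: str = "other"  # RPS | SCX | other
    gene_symbol: str | None = None
    n_psms: int | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not 0.0 <= self.pep_score <= 1.0:
            raise ValueError(f"pep_score must be in [0, 1], got {self.pep_score}")


def canonical_accession(acc: str, collapse_isoforms: bool = True) -> str:
    """Strip an isoform suffix ('-2') so GO registries keyed on canonical
    accessions match."""
    return _ISOFORM_RE.sub("", acc) if collapse_isoforms else acc


@dataclass(frozen=True)
class MembraneRegistry:
    """Set of accessions annotated to the plasma membrane."""

    accessions: frozenset[str]

    @classmethod
    def from_iterable(cls, accs: Iterable[str]) -> "MembraneRegistry":
        return cls(frozenset(a.strip() for a in accs if a.strip()))

    def __contains__(self, acc: str) -> bool:
        return acc in self.accessions

    def __len__(self) -> int:
        return len(self.accessions)


def filter_membrane(
    ids: Sequence[ProteinIdentification],
    registry: MembraneRegistry,
    *,
    collapse_isoforms: bool = True,
) -> list[ProteinIdentification]:
    """Keep records whose (canonical) accession is in the registry; order
    preserved."""
    if len(registry) == 0:
        raise ValueError("membrane registry is empty; cannot filter")
    return [
        r
        for r in ids
        if canonical_accession(r.accession, collapse_isoforms) in registry
    ]


def deduplicate(ids: Sequence[ProteinIdentification]) -> list[ProteinIdentification]:
    """One record per accession: the best (lowest-PEP) one, original order of
    first occurrence."""
    best: dict[str, ProteinIdentification] = {}
    order: list[str] = []
    for r in ids:
        if r.accession not in best:
            order.append(r.accession)
            best[r.accession] = r
        elif r.pep_score < best[r.accession].pep_score:
            best[r.accession] = r
    return [best[a] for a in order]


def _rank_key(r: ProteinIdentification) -> tuple:
    # PEP ascending; ties by more PSMs, then accession.
    n = r.n_psms if r.n_psms is not None else 0
    return (r.pep_score, -n, r.accession)


def top_by_pep(
    ids: Sequence[ProteinIdentification], n: int
) -> list[ProteinIdentification]:
    """The n most confident identifications, PEP ascending (ties: n_psms
    descending, then accession)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(ids, key=_rank_key)[:n]


def intersect_methods(
    list_a: Sequence[ProteinIdentification],
    list_b: Sequence[ProteinIdentification],
) -> list[str]:
    """Accessions present in both ranked lists.

    Output is ordered by the better (smaller) of the two per-list PEP ranks,
    ties by accession. Each input must already be deduplicated.
    """
    for name, lst in (("A", list_a), ("B", list_b)):
        accs = [r.accession for r in lst]
        if len(accs) != len(set(accs)):
            dup = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"list {name} contains duplicate accessions: {dup[:5]}")
    rank_a = {r.accession: i for i, r in enumerate(list_a)}
    rank_b = {r.accession: i for i, r in enumerate(list_b)}
    common = set(rank_a) & set(rank_b)
    return sorted(common, key=lambda a: (min(rank_a[a], rank_b[a]), a))


def select_common(
    ids: Sequence[ProteinIdentification],
    registry: MembraneRegistry,
    top_n: int = 250,
    methods: tuple[str, str] = ("RPS", "SCX"),
) -> pd.DataFrame:
    """Full funnel: per method, filter to membrane -> dedupe -> top-N by PEP;
    then intersect the two methods.

    The order is fixed as filter -> rank -> top, matching the published
    workflow (membrane restriction happens at the database level, before
    ranking).

    Returns a DataFrame with accession and the per-method 1-based ranks.
    """
    tops: dict[str, list[ProteinIdentification]] = {}
    for m in methods:
        sub = [r for r in ids if r.method_tag == m]
        sub = filter_membrane(sub, registry)
        sub = deduplicate(sub)
        tops[m] = top_by_pep(sub, top_n)
    a, b = (tops[m] for m in methods)
    common = intersect_methods(a, b)
    rank_a = {r.accession: i + 1 for i, r in enumerate(a)}
    rank_b = {r.accession: i + 1 for i, r in enumerate(b)}
    return pd.DataFrame(
        {
            "accession": common,
            f"rank_{methods[0]}": [rank_a[x] for x in common],
            f"rank_{methods[1]}": [rank_b[x] for x in common],
        }
    )


def read_identifications(path) -> list[ProteinIdentification]:
    """Read an identification TSV (accession, gene, pep, method, n_psms)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            ProteinIdentification(
                accession=str(row["accession"]),
                pep_score=float(row["pep"]),
                method_tag=str(row.get("method", "other")),
                gene_symbol=str(row["gene"]) if "gene" in df.columns else None,
                n_psms=int(row["n_psms"]) if "n_psms" in df.columns else None,
            )
        )
    return out


def read_registry(path) -> MembraneRegistry:
    """Read a one-accession-per-line registry file."""
    with open(path) as fh:
        return MembraneRegistry.from_iterable(fh)
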