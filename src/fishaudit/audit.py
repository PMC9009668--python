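"""Per-name mislabeling/substitutability audits and the substitution network.

For each focal commercial name the audit tabulates how often samples sold
under it were mislabeled (and by how many distinct species), how often the
species accepted for that name was itself used as a concealed substitute
for other names, and the resulting net availability:

    correctly_labeled  = verbal_sample_number − mislabeling_frequency
    confirmed_samples  = correctly_labeled + substitutability_frequency
    over/sub-representation = verbal_sample_number − confirmed_samples

A positive over-representation means the name is advertised more often than
the species is actually present in the market.  Mislabeled calls also form
a bipartite substitution network (substitute species → commercial name)
whose in-/out-degrees reproduce the diversity columns of the audit.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .labeling import Catalog, CallStatus, normalize_name

__all__ = [
    "NameAudit",
    "SubstitutionEdge",
    "round_half_up",
    "audit_name",
    "audit_all",
    "build_network",
    "network_graph",
    "category_matrix",
    "filter_focal_names",
    "conservation_report",
]

_CALLED = (CallStatus.CORRECT.value, CallStatus.MISLABELED.value)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 → 0.13 at 2 digits), used for reporting."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class NameAudit:
    """One audit row for a focal commercial name (exact integer arithmetic)."""

    commercial_name: str
    verbal_sample_number: int
    correctly_labeled: int
    mislabeling_frequency: int
    mislabeling_diversity: int
    substitutability_frequency: int
    substitutability_diversity: int

    def __post_init__(self) -> None:
        for f in (
            self.verbal_sample_number, self.correctly_labeled,
            self.mislabeling_frequency, self.mislabeling_diversity,
            self.substitutability_frequency, self.substitutability_diversity,
        ):
            if f < 0:
                raise ValueError("audit counts must be non-negative")
        if self.verbal_sample_number != self.correctly_labeled + self.mislabeling_frequency:
            raise ValueError(
                "verbal sample number must equal correctly labeled + mislabeling frequency"
            )

    @property
    def mislabeling_percentage(self) -> float:
        if self.verbal_sample_number == 0:
            return 0.0
        return 100.0 * self.mislabeling_frequency / self.verbal_sample_number

    @property
    def confirmed_samples(self) -> int:
        return self.correctly_labeled + self.substitutability_frequency

    @property
    def over_sub_representation(self) -> int:
        return self.verbal_sample_number - self.confirmed_samples

    @property
    def over_sub_representation_percentage(self) -> float | None:
        """Signed percent of over/sub-representation; None when nothing confirmed."""
        if self.confirmed_samples == 0:
            return None
        return 100.0 * self.over_sub_representation / self.confirmed_samples

    @classmethod
    def from_counts(
        cls,
        commercial_name: str,
        verbal: int,
        correct: int,
        mislabeling_diversity: int = 0,
        substitutability_frequency: int = 0,
        substitutability_diversity: int = 0,
    ) -> "NameAudit":
        """Build an audit from primitive counts, deriving the dependent cells."""
        return cls(
            commercial_name=commercial_name,
            verbal_sample_number=verbal,
            correctly_labeled=correct,
            mislabeling_frequency=verbal - correct,
            mislabeling_diversity=mislabeling_diversity,
            substitutability_frequency=substitutability_frequency,
            substitutability_diversity=substitutability_diversity,
        )

    def as_row(self) -> dict:
        pct = self.over_sub_representation_percentage
        return {
            "commercial_name": self.commercial_name,
            "verbal_sample_number": self.verbal_sample_number,
            "correctly_labeled": self.correctly_labeled,
            "mislabeling_frequency": self.mislabeling_frequency,
            "mislabeling_percentage": round_half_up(self.mislabeling_percentage),
            "mislabeling_diversity": self.mislabeling_diversity,
            "substitutability_frequency": self.substitutability_frequency,
            "substitutability_diversity": self.substitutability_diversity,
            "confirmed_samples": self.confirmed_samples,
            "over_sub_representation": self.over_sub_representation,
            "over_sub_representation_percentage": (
                None if pct is None else round_half_up(pct)
            ),
        }


@dataclass(frozen=True)
class SubstitutionEdge:
    """(substitute species → commercial name) with its event count."""

    species: str
    commercial_name: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("edge count must be >= 1")


def _called(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[calls["status"].isin(_CALLED)]


def _substitution_credit(
    calls: pd.DataFrame,
    catalogs: Sequence[Catalog],
    credit: str = "largest",
) -> tuple[dict[str, int], dict[str, set[str]]]:
    """Substitutability frequency/diversity per focal name.

    A mislabeled call's substitute species maps to focal commercial names
    through the catalogs' accepted-species sets.  With ``credit="largest"``
    (default) each substitution event is credited once, to the accepted
    name with the most samples in the survey (ties alphabetical); with
    ``credit="all"`` every accepted name is credited.
    """
    if credit not in ("largest", "all"):
        raise ValueError("credit must be 'largest' or 'all'")
    species_to_names: dict[str, set[str]] = {}
    for catalog in catalogs:
        for cname, species_set in catalog.mapping.items():
            for sp in species_set:
                species_to_names.setdefault(sp, set()).add(cname)
    verbal = calls[calls["status"].isin(_CALLED)]["commercial_name"].value_counts()
    freq: dict[str, int] = {}
    diversity: dict[str, set[str]] = {}
    mislabeled = calls[calls["status"] == CallStatus.MISLABELED.value]
    for _, rec in mislabeled.iterrows():
        species = rec["substitute"]
        focal_names = species_to_names.get(species, set())
        if not focal_names:
            continue  # substitute accepted under no audited name
        if credit == "largest":
            focal_names = {
                min(focal_names, key=lambda n: (-int(verbal.get(n, 0)), n))
            }
        for focal in focal_names:
            if focal == rec["commercial_name"]:
                continue  # a species cannot substitute its own name
            freq[focal] = freq.get(focal, 0) + 1
            diversity.setdefault(focal, set()).add(rec["commercial_name"])
    return freq, diversity


def audit_all(
    calls: pd.DataFrame,
    catalogs: Sequence[Catalog],
    credit: str = "largest",
) -> list[NameAudit]:
    """Audit every commercial name appearing in the (non-excluded) calls."""
    called = _called(calls)
    freq, diversity = _substitution_credit(calls, catalogs, credit)
    audits = []
    names = sorted(set(called["commercial_name"]) | set(freq))
    for name in names:
        sub = called[called["commercial_name"] == name]
        mislabeled = sub[sub["status"] == CallStatus.MISLABELED.value]
        audits.append(
            NameAudit(
                commercial_name=name,
                verbal_sample_number=len(sub),
                correctly_labeled=int((sub["status"] == CallStatus.CORRECT.value).sum()),
                mislabeling_frequency=len(mislabeled),
                mislabeling_diversity=mislabeled["substitute"].nunique(),
                substitutability_frequency=freq.get(name, 0),
                substitutability_diversity=len(diversity.get(name, set())),
            )
        )
    return audits


def audit_name(
    focal: str,
    calls: pd.DataFrame,
    catalogs: Sequence[Catalog],
    credit: str = "largest",
) -> NameAudit:
    """Audit a single focal name (zeros, not an error, when absent)."""
    focal = normalize_name(focal)
    for audit in audit_all(calls, catalogs, credit):
        if audit.commercial_name == focal:
            return audit
    return NameAudit.from_counts(focal, 0, 0)


def audits_frame(audits: Sequence[NameAudit]) -> pd.DataFrame:
    columns = list(NameAudit.from_counts("x", 0, 0).as_row())
    return pd.DataFrame([a.as_row() for a in audits], columns=columns)


def build_network(calls: pd.DataFrame):
    """Edge list of the substitution network and its summary counts.

    Returns ``(edges, n_substitute_species, n_substituted_names,
    n_unique_combinations)`` with one :class:`SubstitutionEdge` per
    (species, commercial name) pair observed among mislabeled calls.
    """
    mislabeled = calls[calls["status"] == CallStatus.MISLABELED.value]
    if mislabeled.empty:
        return [], 0, 0, 0
    counts = (
        mislabeled.groupby(["substitute", "commercial_name"]).size().reset_index(name="count")
    )
    edges = [
        SubstitutionEdge(r["substitute"], r["commercial_name"], int(r["count"]))
        for _, r in counts.iterrows()
    ]
    return (
        edges,
        counts["substitute"].nunique(),
        counts["commercial_name"].nunique(),
        len(edges),
    )


def network_graph(edges: Sequence[SubstitutionEdge]) -> nx.DiGraph:
    """Directed bipartite graph (species → commercial name, weight=count)."""
    graph = nx.DiGraph()
    for edge in edges:
        graph.add_node(edge.species, kind="species")
        graph.add_node(f"name:{edge.commercial_name}", kind="commercial_name")
        graph.add_edge(edge.species, f"name:{edge.commercial_name}", weight=edge.count)
    return graph


def category_matrix(
    edges: Sequence[SubstitutionEdge],
    species_category: Mapping[str, str],
    name_category: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3×3 counts and percentages over origin groups.

    Cell (c1, c2) sums edge counts whose substitute species has category c1
    and whose labeled commercial name has category c2.  Percentages are
    over the total count.  Unmapped species or names raise with the full
    offender list.
    """
    from .simulate import CATEGORIES

    missing_sp = sorted({e.species for e in edges} - set(species_category))
    missing_nm = sorted({e.commercial_name for e in edges} - set(name_category))
    if missing_sp or missing_nm:
        raise ValueError(
            f"unmapped species: {missing_sp}; unmapped commercial names: {missing_nm}"
        )
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for edge in edges:
        counts.loc[species_category[edge.species], name_category[edge.commercial_name]] += (
            edge.count
        )
    total = counts.values.sum()
    percentages = 100.0 * counts / total if total else counts.astype(float)
    return counts, percentages


def filter_focal_names(
    audits: Sequence[NameAudit], min_verbal: int = 6
) -> list[NameAudit]:
    """Names with enough samples for rate estimation, by verbal count descending."""
    kept = [a for a in audits if a.verbal_sample_number >= min_verbal]
    return sorted(kept, key=lambda a: (-a.verbal_sample_number, a.commercial_name))


def conservation_report(
    calls: pd.DataFrame,
    status_table: pd.DataFrame,
) -> pd.DataFrame:
    """Sample and mislabel tallies per identified species joined to status.

    ``status_table`` has columns ``species``, ``iucn`` (Red List category)
    and ``cites`` (appendix or empty).  Species absent from the table are
    reported with status ``unclassified``.  The identified species of a
    call is its representative candidate (the substitute for mislabeled
    calls).
    """
    for col in ("species", "iucn", "cites"):
        if col not in status_table.columns:
            raise ValueError(f"status table lacks column {col!r}")
    called = _called(calls).copy()
    if called.empty:
        return pd.DataFrame(
            columns=["species", "iucn", "cites", "n_samples", "n_mislabeled"]
        )
    called["species"] = np.where(
        called["status"] == CallStatus.MISLABELED.value,
        called["substitute"],
        called["candidates"].str.split(";").str[0],
    )
    tallies = (
        called.groupby("species")
        .agg(
            n_samples=("sample_id", "size"),
            n_mislabeled=("status", lambda s: int((s == CallStatus.MISLABELED.value).sum())),
        )
        .reset_index()
    )
    status = status_table.set_index("species")[["iucn", "cites"]]
    report = tallies.join(status, on="species")
    report["iucn"] = report["iucn"].fillna("unclassified")
    report["cites"] = report["cites"].fillna("")
    return report[["species", "iucn", "cites", "n_samples", "n_mislabeled"]].sort_values(
        "species", ignore_index=True
    )
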