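"""Correct/mislabeled calls from commercial names and genetic identities.

A sample is mislabeled when the commercial name the vendor provided does not
list the genetically identified species in ANY of the supplied catalogs
(union semantics: one listing anywhere makes the label correct).  Samples
sold under generic names ("pescado") and samples whose barcode could not be
identified are excluded from rate denominators rather than called.
"""

from __future__ import annotations

import enum
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .identify import IdentificationResult

__all__ = [
    "Catalog",
    "LabelCall",
    "CallStatus",
    "MatchOutcome",
    "normalize_name",
    "match_catalogs",
    "call_sample",
    "call_all",
]


class CallStatus(str, enum.Enum):
    CORRECT = "correct"
    MISLABELED = "mislabeled"
    EXCLUDED_GENERIC = "excluded_generic"
    EXCLUDED_UNIDENTIFIED = "excluded_unidentified"
    # a name found in no catalog is reported separately, never auto-mislabeled
    EXCLUDED_UNKNOWN_NAME = "excluded_unknown_name"


class MatchOutcome(enum.Enum):
    ACCEPTED = "accepted"
    NOT_ACCEPTED = "not_accepted"
    UNKNOWN_NAME = "unknown_name"


def normalize_name(raw: str) -> str:
    """Case-fold, strip diacritics and collapse whitespace ("Róbalo " → "robalo")."""
    if raw is None or not str(raw).strip():
        raise ValueError("commercial name is empty or whitespace-only")
    decomposed = unicodedata.normalize("NFKD", str(raw))
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


@dataclass(frozen=True)
class Catalog:
    """One commercial-name catalog: normalized name → accepted species set."""

    tag: str
    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, species_set in self.mapping.items():
            if name != normalize_name(name):
                raise ValueError(f"catalog {self.tag!r}: name {name!r} is not normalized")
            for sp in species_set:
                if len(sp.split()) != 2:
                    raise ValueError(
                        f"catalog {self.tag!r}: species {sp!r} is not 'Genus epithet'"
                    )

    def accepts(self, name: str, species: str) -> bool:
        return species in self.mapping.get(name, frozenset())


def match_catalogs(
    name: str, species: str, catalogs: Sequence[Catalog]
) -> MatchOutcome:
    """Union-of-catalogs acceptance of a (name, species) pair.

    ``ACCEPTED`` if any catalog lists the species under the name,
    ``NOT_ACCEPTED`` if the name is known somewhere but never with this
    species, ``UNKNOWN_NAME`` if no catalog knows the name at all.
    """
    if not catalogs:
        raise ValueError("at least one catalog is required")
    known = False
    for catalog in catalogs:
        if name in catalog.mapping:
            known = True
            if catalog.accepts(name, species):
                return MatchOutcome.ACCEPTED
    return MatchOutcome.NOT_ACCEPTED if known else MatchOutcome.UNKNOWN_NAME


@dataclass(frozen=True)
class LabelCall:
    """Verdict for one sample.

    ``substitute`` is present iff the status is mislabeled and holds the
    representative (highest-identity, then alphabetical) candidate species.
    """

    sample_id: str
    commercial_name: str
    status: CallStatus
    candidates: tuple[str, ...]
    substitute: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if (self.substitute is not None) != (self.status is CallStatus.MISLABELED):
            raise ValueError("substitute must be present iff status is mislabeled")


def call_sample(
    commercial_name: str,
    identification: IdentificationResult,
    catalogs: Sequence[Catalog],
    generic_names: Iterable[str] = ("pescado",),
) -> LabelCall:
    """Call one sample against the catalogs.

    Generic names are excluded outright; unidentified barcodes are excluded;
    genus-level identifications are called through their representative
    candidate and flagged in the notes; a multi-species (tied) candidate set
    is correct when ANY candidate is accepted for the name.
    """
    name = normalize_name(commercial_name)
    generic = {normalize_name(g) for g in generic_names}
    sid = identification.sample_id
    if name in generic:
        return LabelCall(sid, name, CallStatus.EXCLUDED_GENERIC, identification.candidates)
    if identification.confidence == "unidentified" or not identification.candidates:
        return LabelCall(
            sid, name, CallStatus.EXCLUDED_UNIDENTIFIED, (),
            notes=identification.notes,
        )
    notes = []
    if identification.confidence == "genus":
        notes.append("genus-level identification")
    outcomes = {
        candidate: match_catalogs(name, candidate, catalogs)
        for candidate in identification.candidates
    }
    if all(o is MatchOutcome.UNKNOWN_NAME for o in outcomes.values()):
        notes.append("commercial name in no catalog")
        return LabelCall(
            sid, name, CallStatus.EXCLUDED_UNKNOWN_NAME,
            identification.candidates, notes="; ".join(notes),
        )
    if any(o is MatchOutcome.ACCEPTED for o in outcomes.values()):
        return LabelCall(
            sid, name, CallStatus.CORRECT, identification.candidates,
            notes="; ".join(notes),
        )
    # representative = first candidate (ordered by identity desc, then name)
    return LabelCall(
        sid, name, CallStatus.MISLABELED, identification.candidates,
        substitute=identification.candidates[0], notes="; ".join(notes),
    )


def call_all(
    samples,
    identifications: Sequence[IdentificationResult],
    catalogs: Sequence[Catalog],
    generic_names: Iterable[str] = ("pescado",),
):
    """Call every sample; returns a pandas DataFrame of LabelCall fields.

    ``samples`` is the survey table (needs ``sample_id`` and
    ``commercial_name``; stratification columns are carried through when
    present).
    """
    import pandas as pd

    by_id = {r.sample_id: r for r in identifications}
    missing = [s for s in samples["sample_id"] if s not in by_id]
    if missing:
        raise ValueError(f"no identification for samples: {missing[:5]}")
    rows = []
    carry = [c for c in ("city", "vendor_type", "name_source") if c in samples.columns]
    for _, rec in samples.iterrows():
        call = call_sample(rec["commercial_name"], by_id[rec["sample_id"]],
                           catalogs, generic_names)
        rows.append(
            {
                "sample_id": call.sample_id,
                "commercial_name": call.commercial_name,
                "status": call.status.value,
                "candidates": ";".join(call.candidates),
                "substitute": call.substitute or "",
                "notes": call.notes,
                **{c: rec[c] for c in carry},
            }
        )
    return pd.DataFrame(rows)
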