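"""Species assignment of COI barcode queries against reference libraries.

A query sequence (typically a 550–655 bp fragment of the mitochondrial
cytochrome c oxidase subunit I gene) is compared against one or more
reference libraries of species-annotated barcodes.  Assignment follows the
standard market-survey identification rule: the best match in each library
identifies the species when its percent identity reaches a threshold
(default 98%); when libraries agree only at the genus, the single highest
identity across libraries decides; exact ties at the top are reported as a
multi-species candidate set; identities below the threshold but above a
genus floor (default 90%) yield a genus-level call, and anything below that
is unidentified.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from sklearn.base import BaseEstimator

__all__ = [
    "STOP_CODONS",
    "ReferenceLibrary",
    "Hit",
    "IdentificationResult",
    "check_reading_frame",
    "pairwise_identity",
    "reverse_complement",
    "search_library",
    "consensus_assign",
    "identify_all",
    "BarcodeIdentifier",
]

#: Stop codons of the vertebrate mitochondrial genetic code (NCBI table 2).
STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_IUPAC = set("ACGTUNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def _validate_dna(sequence: str, *, minimum_length: int = 1) -> str:
    seq = sequence.strip().upper()
    if len(seq) < minimum_length:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than required {minimum_length}"
        )
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class ReferenceLibrary:
    """A tagged collection of species-annotated barcode records.

    Emulates one species-level reference database (e.g. a GenBank- or
    BOLD-like source).  ``entries`` holds ``(accession, species, sequence)``
    triples; accessions are unique within a library and species names are
    binomials ("Genus epithet").
    """

    tag: str
    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        accessions = [a for a, _, _ in self.entries]
        if len(set(accessions)) != len(accessions):
            raise ValueError(f"duplicate accessions in library {self.tag!r}")
        for accession, species, seq in self.entries:
            if not seq:
                raise ValueError(f"empty sequence for {accession}")
            _validate_dna(seq)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def species(self) -> set[str]:
        return {s for _, s, _ in self.entries}

    def kmer_index(self, k: int) -> dict[str, set[int]]:
        """Map every k-mer occurring in the library to entry indices."""
        cache = self.__dict__.setdefault("_kmer_cache", {})
        if k not in cache:
            index: dict[str, set[int]] = {}
            for i, (_, _, seq) in enumerate(self.entries):
                for j in range(len(seq) - k + 1):
                    index.setdefault(seq[j : j + k], set()).add(i)
            cache[k] = index
        return cache[k]

    @classmethod
    def from_fasta(cls, path, tag: str | None = None) -> "ReferenceLibrary":
        """Read a library from FASTA with ``>lib|accession|Genus_epithet`` headers."""
        entries = []
        tags = set()
        for record in SeqIO.parse(str(path), "fasta"):
            parts = record.id.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"header {record.id!r} not in 'lib|accession|Genus_epithet' form"
                )
            lib, accession, species = parts
            tags.add(lib)
            entries.append((accession, species.replace("_", " "), str(record.seq)))
        if not entries:
            raise ValueError(f"no records in {path}")
        if tag is None:
            if len(tags) != 1:
                raise ValueError(f"multiple library tags in {path}: {sorted(tags)}")
            tag = tags.pop()
        return cls(tag=tag, entries=tuple(entries))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for accession, species, seq in self.entries:
                fh.write(f">{self.tag}|{accession}|{species.replace(' ', '_')}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True, order=True)
class Hit:
    """One library match: accession, species, percent identity and strand."""

    sort_index: tuple = field(init=False, repr=False)
    accession: str
    species: str
    identity: float
    library: str
    strand: str = "forward"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.strand not in ("forward", "reverse-complement"):
            raise ValueError(f"unknown strand {self.strand!r}")
        object.__setattr__(self, "sort_index", (-self.identity, self.accession))


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of consensus assignment for one query.

    ``candidates`` is ordered by decreasing supporting identity (ties
    alphabetical); the first element is the representative species used by
    downstream label calling.  ``confidence`` is ``"species"``, ``"genus"``
    or ``"unidentified"``.
    """

    sample_id: str
    candidates: tuple[str, ...]
    best_identity: float
    confidence: str
    per_library_best: Mapping[str, Hit]
    notes: str = ""

    @property
    def representative(self) -> str | None:
        return self.candidates[0] if self.candidates else None

    @property
    def genus(self) -> str | None:
        rep = self.representative
        return rep.split()[0] if rep else None


def check_reading_frame(sequence: str) -> tuple[bool, int | None]:
    """Screen a barcode for an uninterrupted open reading frame.

    Returns ``(True, frame)`` with the lowest forward frame (1-based) whose
    complete codons contain no vertebrate-mitochondrial stop codon,
    otherwise ``(False, None)``.  COI barcodes sit mid-gene, so no start
    codon is required and only forward frames are scanned.
    """
    seq = _validate_dna(sequence, minimum_length=100)
    for frame in (1, 2, 3):
        sub = seq[frame - 1 :]
        codons = (sub[i : i + 3] for i in range(0, len(sub) - len(sub) % 3, 3))
        if not any(c in STOP_CODONS for c in codons):
            return True, frame
    return False, None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # terminal gaps are free: queries are partial-length fragments
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


@functools.lru_cache(maxsize=200_000)
def _identity_one_strand(a: str, b: str) -> float:
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    start, end = _trim_terminal(row_a, row_b)
    columns = end - start
    if columns <= 0:
        return 0.0
    matches = sum(
        1
        for i in range(start, end)
        if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    # The optimal free-end-gap alignment of two unrelated sequences is a
    # short perfect overlap, which would score 100% under the bare
    # matches/columns formula.  Requiring the overlap to cover at least
    # half of the shorter sequence (a denominator floor) down-weights such
    # fragments the way megablast's score-based ranking would, while
    # leaving any alignment with substantial coverage untouched.
    floor = (min(len(a), len(b)) + 1) // 2
    return 100.0 * matches / max(columns, floor)


def _trim_terminal(row_a: str, row_b: str) -> tuple[int, int]:
    """Bounds of the alignment once terminal-gap columns are removed.

    A terminal gap is a run of gap characters at either end of either row;
    internal gaps are retained (and counted as mismatched columns).
    """
    n = len(row_a)
    lead = 0
    for row in (row_a, row_b):
        i = 0
        while i < n and row[i] == "-":
            i += 1
        lead = max(lead, i)
    trail = 0
    for row in (row_a, row_b):
        i = 0
        while i < n and row[n - 1 - i] == "-":
            i += 1
        trail = max(trail, i)
    return lead, max(lead, n - trail)


def pairwise_identity(query: str, reference: str) -> float:
    """Percent identity between two barcodes from a free-end-gap global alignment.

    Scoring is match +1, mismatch −1, gap −2 with cost-free terminal gaps;
    identity is 100 × matches / aligned columns with terminal-gap columns
    excluded from the denominator and internal gap columns counted as
    non-matches.  Both the forward and reverse-complement orientation of
    the query are tried and the larger identity is returned.
    """
    q = _validate_dna(query)
    r = _validate_dna(reference)
    return max(_identity_one_strand(r, q), _identity_one_strand(r, reverse_complement(q)))


def pairwise_identity_stranded(query: str, reference: str) -> tuple[float, str]:
    """Like :func:`pairwise_identity` but also reports the winning strand."""
    q = _validate_dna(query)
    r = _validate_dna(reference)
    fwd = _identity_one_strand(r, q)
    rev = _identity_one_strand(r, reverse_complement(q))
    if rev > fwd:
        return rev, "reverse-complement"
    return fwd, "forward"


def search_library(
    query: str,
    library: ReferenceLibrary,
    k: int = 10,
    *,
    prefilter: bool = True,
    prefilter_k: int = 12,
) -> list[Hit]:
    """Rank library entries by percent identity to the query.

    Returns up to ``k`` hits sorted by identity descending with stable
    alphabetical tie order by accession.  A k-mer prefilter (entries sharing
    at least one ``prefilter_k``-mer with the query on either strand) prunes
    the candidate set; by construction it can only drop entries that share
    no exact word with the query, which at barcode-level identities never
    includes the top hit.  A query sharing no word with any entry yields an
    empty hit list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(library) == 0:
        raise ValueError(f"library {library.tag!r} is empty")
    q = _validate_dna(query)
    if prefilter:
        index = library.kmer_index(prefilter_k)
        candidates: set[int] = set()
        for strand_seq in (q, reverse_complement(q)):
            for j in range(len(strand_seq) - prefilter_k + 1):
                candidates |= index.get(strand_seq[j : j + prefilter_k], set())
        if not candidates:
            return []
        indices = sorted(candidates)
    else:
        indices = range(len(library.entries))
    hits = []
    for i in indices:
        accession, species, seq = library.entries[i]
        identity, strand = pairwise_identity_stranded(q, seq)
        hits.append(Hit(accession=accession, species=species, identity=identity,
                        library=library.tag, strand=strand))
    hits.sort()
    return hits[:k]


def _round_id(identity: float) -> float:
    # ties are declared at sequencer-scale reproducibility, 0.01%
    return round(identity, 2)


def consensus_assign(
    per_library_hits: Mapping[str, Sequence[Hit]],
    threshold: float = 98.0,
    genus_floor: float = 90.0,
    sample_id: str = "",
) -> IdentificationResult:
    """Combine per-library ranked hits into a single identification.

    Decision order: (1) all libraries' best hits name the same species at or
    above ``threshold`` → species-level call; (2) best species differ but
    share the genus, each at or above threshold → the species with the single
    highest identity across libraries wins ("genus-level agreement");
    (3) an exact tie (identity equal after rounding to 0.01%) at the top of
    any library at or above threshold → all tied species reported as a
    multi-species candidate set; (4) best identity below threshold → a
    genus-level call when it reaches ``genus_floor``, else unidentified.
    Libraries whose best hit falls below the threshold do not veto a call
    supported by the others; disagreement at different genera is reported as
    a two-species candidate set with a "library conflict" note.
    """
    if not per_library_hits:
        raise ValueError("no libraries searched")
    best: dict[str, Hit] = {}
    tied: dict[str, list[Hit]] = {}
    for tag, hits in per_library_hits.items():
        if not hits:
            continue
        top = hits[0]
        best[tag] = top
        tied[tag] = [h for h in hits if _round_id(h.identity) == _round_id(top.identity)]
    if not best:
        return IdentificationResult(
            sample_id=sample_id, candidates=(), best_identity=0.0,
            confidence="unidentified", per_library_best={}, notes="no hits in any library",
        )
    best_identity = max(h.identity for h in best.values())
    notes: list[str] = []

    if best_identity < threshold:
        top_hit = max(best.values(), key=lambda h: h.identity)
        if best_identity >= genus_floor:
            notes.append("reliable only at the genus level")
            return IdentificationResult(
                sample_id=sample_id, candidates=(top_hit.species,),
                best_identity=best_identity, confidence="genus",
                per_library_best=dict(best), notes="; ".join(notes),
            )
        return IdentificationResult(
            sample_id=sample_id, candidates=(), best_identity=best_identity,
            confidence="unidentified", per_library_best=dict(best),
            notes=f"best identity {best_identity:.1f}% below genus floor",
        )

    # only libraries meeting the threshold support a species-level call
    supporting = {t: h for t, h in best.items() if h.identity >= threshold}
    skipped = set(best) - set(supporting)
    if skipped:
        notes.append(f"libraries below threshold ignored: {', '.join(sorted(skipped))}")

    tie_species: set[str] = set()
    for tag, hits in tied.items():
        if tag in supporting and len({h.species for h in hits}) > 1:
            tie_species |= {h.species for h in hits}
    if tie_species:
        support = {
            sp: max(h.identity for hs in tied.values() for h in hs if h.species == sp)
            for sp in tie_species
        }
        ordered = tuple(sorted(tie_species, key=lambda sp: (-support[sp], sp)))
        notes.append("identical top identities to multiple species")
        return IdentificationResult(
            sample_id=sample_id, candidates=ordered, best_identity=best_identity,
            confidence="species", per_library_best=dict(best), notes="; ".join(notes),
        )

    species = {h.species for h in supporting.values()}
    if len(species) == 1:
        return IdentificationResult(
            sample_id=sample_id, candidates=(species.pop(),),
            best_identity=best_identity, confidence="species",
            per_library_best=dict(best), notes="; ".join(notes),
        )
    genera = {sp.split()[0] for sp in species}
    if len(genera) == 1:
        winner = max(supporting.values(), key=lambda h: (h.identity, h.species))
        notes.append("genus-level agreement; highest identity decides")
        return IdentificationResult(
            sample_id=sample_id, candidates=(winner.species,),
            best_identity=best_identity, confidence="species",
            per_library_best=dict(best), notes="; ".join(notes),
        )
    support = {h.species: h.identity for h in supporting.values()}
    ordered = tuple(sorted(species, key=lambda sp: (-support[sp], sp)))
    notes.append("library conflict: top species in different genera")
    return IdentificationResult(
        sample_id=sample_id, candidates=ordered, best_identity=best_identity,
        confidence="species", per_library_best=dict(best), notes="; ".join(notes),
    )


def identify_all(
    queries: Mapping[str, str],
    libraries: Iterable[ReferenceLibrary],
    threshold: float = 98.0,
    genus_floor: float = 90.0,
    *,
    prefilter: bool = True,
    prefilter_k: int = 12,
) -> list[IdentificationResult]:
    """Search every query against every library and assign identities."""
    libraries = list(libraries)
    if not libraries:
        raise ValueError("at least one reference library is required")
    results = []
    for sample_id, seq in queries.items():
        per_lib = {
            lib.tag: search_library(seq, lib, prefilter=prefilter, prefilter_k=prefilter_k)
            for lib in libraries
        }
        results.append(
            consensus_assign(per_lib, threshold=threshold, genus_floor=genus_floor,
                             sample_id=sample_id)
        )
    return results


class BarcodeIdentifier(BaseEstimator):
    """Nearest-reference barcode classifier with consensus assignment.

    scikit-learn style estimator: ``fit`` takes one or more reference
    libraries, ``predict`` takes query sequences and returns representative
    species labels; ``identify`` returns the full
    :class:`IdentificationResult` objects.

    Parameters
    ----------
    threshold : float, default 98.0
        Minimum percent identity for a species-level call.
    genus_floor : float, default 90.0
        Minimum percent identity for a genus-level call below ``threshold``.
    prefilter : bool, default True
        Use a k-mer prefilter before exhaustive pairwise alignment.
    prefilter_k : int, default 12
        Word size of the prefilter.

    Attributes
    ----------
    libraries_ : list of ReferenceLibrary
    n_references_ : int
        Total number of reference records across libraries.
    species_ : ndarray of str
        Sorted union of species present in the fitted libraries.
    """

    def __init__(self, threshold: float = 98.0, genus_floor: float = 90.0,
                 prefilter: bool = True, prefilter_k: int = 12):
        self.threshold = threshold
        self.genus_floor = genus_floor
        self.prefilter = prefilter
        self.prefilter_k = prefilter_k

    def fit(self, X, y=None):
        """Store reference libraries.

        ``X`` is a ReferenceLibrary or an iterable of them; ``y`` is ignored
        (species labels live in the libraries).
        """
        if not 0.0 < self.threshold <= 100.0:
            raise ValueError("threshold must be in (0, 100]")
        if not 0.0 <= self.genus_floor <= self.threshold:
            raise ValueError("genus_floor must be in [0, threshold]")
        if isinstance(X, ReferenceLibrary):
            X = [X]
        libraries = list(X)
        if not libraries or not all(isinstance(l, ReferenceLibrary) for l in libraries):
            raise ValueError("X must be one or more ReferenceLibrary objects")
        self.libraries_ = libraries
        self.n_references_ = sum(len(l) for l in libraries)
        self.species_ = np.array(sorted(set().union(*(l.species for l in libraries))))
        return self

    def _check_fitted(self):
        if not hasattr(self, "libraries_"):
            raise ValueError("BarcodeIdentifier is not fitted; call fit first")

    def identify(self, X) -> list[IdentificationResult]:
        """Full consensus identification for query sequences.

        ``X`` may be a mapping of sample id → sequence, or a sequence of
        DNA strings (ids are then positional).
        """
        self._check_fitted()
        if not isinstance(X, Mapping):
            X = {f"q{i}": seq for i, seq in enumerate(X)}
        return identify_all(
            X, self.libraries_, threshold=self.threshold,
            genus_floor=self.genus_floor, prefilter=self.prefilter,
            prefilter_k=self.prefilter_k,
        )

    def predict(self, X) -> np.ndarray:
        """Representative species per query ('' when unidentified)."""
        return np.array([r.representative or "" for r in self.identify(X)], dtype=object)
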