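"""Synthetic market surveys with known ground truth.

Everything downstream — identification, label calling, the substitutability
audit and the inferential layer — is exercised on data produced here: a
species pool with a heavy-tailed supply spectrum, frame-clean COI-like
reference libraries, commercial-name catalogs, and a purchased-sample table
whose per-name mislabeling probabilities and substitution preferences are
known exactly.

The default study-scale scenario (:func:`study_scenario`) emulates a
three-city, three-vendor-type seafood survey: ~376 samples sold under 48
commercial names drawn from a pool of ~160 candidate species across three
broad origin groups (wild marine bony fishes, wild marine elasmobranchs,
freshwater/anadromous aquaculture species), with roughly a third of samples
mislabeled overall and about half of the observed species appearing exactly
once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .identify import STOP_CODONS, ReferenceLibrary

__all__ = [
    "SpeciesPool",
    "SurveyDesign",
    "GroundTruth",
    "CATEGORIES",
    "mutate_sequence",
    "generate_reference_library",
    "generate_catalogs",
    "simulate_survey",
    "study_scenario",
]

CATEGORIES = ("marine_bony", "elasmobranch", "aquaculture_freshwater")

_BASES = "ACGT"
# all 61+ codons of the vertebrate mitochondrial code that are not stops
_CLEAN_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]


@dataclass(frozen=True)
class SpeciesPool:
    """Candidate species with origin categories and relative supply weights.

    ``species`` holds ``(name, category, weight)`` triples where ``name`` is
    a binomial ("Genus epithet"), ``category`` one of :data:`CATEGORIES`
    and ``weight`` a non-negative relative supply (market availability).
    """

    species: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        total = 0.0
        for name, category, weight in self.species:
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r} for {name}")
            if weight < 0:
                raise ValueError(f"negative supply weight for {name}")
            if len(name.split()) != 2:
                raise ValueError(f"species name {name!r} is not 'Genus epithet'")
            total += weight
        if self.species and total <= 0:
            raise ValueError("supply weights must sum to a positive value")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.species]

    @property
    def weights(self) -> dict[str, float]:
        return {n: w for n, _, w in self.species}

    @property
    def categories(self) -> dict[str, str]:
        return {n: c for n, c, _ in self.species}

    @classmethod
    def zipf(
        cls,
        n_species: int,
        exponent: float = 1.0,
        category_fractions: Mapping[str, float] | None = None,
        n_genera: int | None = None,
        seed: int | None = None,
    ) -> "SpeciesPool":
        """Pool with rank-frequency supply weights ``w_i ∝ i^(-exponent)``.

        Species are spread over ``n_genera`` synthetic genera (default
        ``n_species // 2``, giving a realistic mix of congeners and
        singleton genera) and over the three origin categories in
        ``category_fractions`` (default 70% marine bony, 15% elasmobranch,
        15% aquaculture — roughly the composition of a mixed fish market).
        """
        rng = np.random.default_rng(seed)
        if category_fractions is None:
            category_fractions = {
                "marine_bony": 0.70, "elasmobranch": 0.15, "aquaculture_freshwater": 0.15,
            }
        if n_genera is None:
            n_genera = max(1, n_species // 2)
        genus_names = [f"Genus{string_index}" for string_index in _name_series(n_genera)]
        epithets = _name_series(n_species)
        genus_of = rng.integers(0, n_genera, size=n_species)
        cats = rng.choice(
            list(category_fractions), size=n_species,
            p=np.array(list(category_fractions.values()))
            / sum(category_fractions.values()),
        )
        ranks = np.arange(1, n_species + 1, dtype=float)
        weights = ranks ** -exponent
        order = rng.permutation(n_species)  # decouple rank from genus/category
        species = tuple(
            (f"{genus_names[genus_of[i]]} {epithets[i]}", str(cats[i]), float(weights[order[i]]))
            for i in range(n_species)
        )
        return cls(species)


def _name_series(n: int) -> list[str]:
    """n distinct lowercase pseudo-Latin tokens: a, b, ..., aa, ab, ..."""
    out = []
    letters = "abcdefghijklmnopqrstuvwxyz"
    for i in range(n):
        token = ""
        j = i
        while True:
            token = letters[j % 26] + token
            j = j // 26 - 1
            if j < 0:
                break
        out.append(token)
    return out


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample truth recorded at simulation time.

    ``samples`` maps sample id → (true species, true mislabel flag); the
    flag is True exactly when the true species is not accepted for the
    sample's commercial name in the generating (union) catalog.
    ``name_probabilities`` records the per-name mislabeling probability the
    draw used.
    """

    samples: Mapping[str, tuple[str, bool]]
    name_probabilities: Mapping[str, float]

    def mislabel_count(self) -> int:
        return sum(flag for _, flag in self.samples.values())


@dataclass
class SurveyDesign:
    """Sampling frame and mislabeling structure of a simulated survey."""

    samples_per_name: Mapping[str, int]
    mislabel_probability: Mapping[str, float]
    cities: Sequence[str] = ("Mazatlan", "Mexico City", "Cancun")
    vendor_types: Sequence[str] = ("fish_market", "grocery_store", "restaurant")
    name_sources: Sequence[str] = ("label", "menu", "verbal")
    substitution_weights: Mapping[str, Mapping[str, float]] | None = None
    generic_names: frozenset[str] = frozenset({"pescado"})
    intra_divergence: float = 0.01
    emit_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.mislabel_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mislabel probability for {name!r} outside [0, 1]")
        for name, n in self.samples_per_name.items():
            if n < 0:
                raise ValueError(f"negative sample count for {name!r}")
        if not 0.0 <= self.intra_divergence <= 0.015:
            raise ValueError("intra-species divergence must be in [0, 0.015]")


def mutate_sequence(
    reference: str,
    divergence: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Substitute an exact fraction of positions without creating stop codons.

    Exactly ``round(divergence * len)`` positions are changed (no indels),
    each to a different base than the original; any substitution that would
    put a vertebrate-mitochondrial stop codon into frame 1 is re-drawn at
    another position.  With ``divergence=0`` the input is returned unchanged.
    """
    if not 0.0 <= divergence <= 0.25:
        raise ValueError("divergence must be in [0, 0.25]")
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = list(reference.upper())
    n = len(seq)
    n_sub = round(divergence * n)
    if n_sub == 0:
        return reference.upper()
    positions = rng.permutation(n)
    substituted = 0
    for p in positions:
        if substituted == n_sub:
            break
        p = int(p)
        old = seq[p]
        if old not in _BASES:
            continue
        alternatives = [b for b in _BASES if b != old]
        for j in rng.permutation(3):
            candidate = alternatives[int(j)]
            seq[p] = candidate
            codon_start = (p // 3) * 3
            codon = "".join(seq[codon_start : codon_start + 3])
            if len(codon) == 3 and codon in STOP_CODONS:
                seq[p] = old
                continue
            substituted += 1
            break
    if substituted < n_sub:
        raise ValueError(
            f"could not place {n_sub} substitutions without stop codons "
            f"(placed {substituted})"
        )
    return "".join(seq)


def _random_clean_sequence(length: int, rng: np.random.Generator) -> str:
    codons = rng.choice(len(_CLEAN_CODONS), size=length // 3)
    return "".join(_CLEAN_CODONS[int(i)] for i in codons)


def _hamming_identity_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    eq = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    return eq * 100.0


def generate_reference_library(
    pool: SpeciesPool,
    length: int = 654,
    min_interspecies_divergence: float = 0.05,
    n_libraries: int = 2,
    dropout_per_library: float = 0.0,
    seed: int | None = None,
    library_tags: Sequence[str] | None = None,
) -> list[ReferenceLibrary]:
    """One frame-clean anchor barcode per species, per reference library.

    Each genus receives an independent random backbone; congeners are
    derived from it at ``min_interspecies_divergence`` so that species in
    the same genus are more similar to each other than to other genera
    while all inter-species identities stay at or below
    ``100 * (1 - min_interspecies_divergence)`` (verified exhaustively,
    with bounded re-draws; infeasible settings raise).  Libraries share the
    species anchors (they emulate overlapping public databases) but each
    drops an exact fraction ``dropout_per_library`` of species at random.
    """
    if length % 3 != 0:
        raise ValueError("length must be divisible by 3")
    if not min_interspecies_divergence > 0.02:
        raise ValueError("min_interspecies_divergence must exceed 0.02")
    if not 0.0 <= dropout_per_library < 1.0:
        raise ValueError("dropout_per_library must be in [0, 1)")
    if n_libraries < 1:
        raise ValueError("n_libraries must be >= 1")
    if min_interspecies_divergence > 0.3:
        raise ValueError(
            "min_interspecies_divergence above 0.3 is infeasible for "
            "stop-codon-free sequences of this composition"
        )
    rng = np.random.default_rng(seed)
    names = pool.names
    genera: dict[str, list[str]] = {}
    for name in names:
        genera.setdefault(name.split()[0], []).append(name)

    anchors: dict[str, str] = {}
    max_attempts = 25
    floor = 100.0 * (1.0 - min_interspecies_divergence)
    for genus, members in genera.items():
        backbone = _random_clean_sequence(length, rng)
        for species in members:
            for _ in range(max_attempts):
                candidate = mutate_sequence(backbone, min_interspecies_divergence, rng=rng)
                if all(
                    _hamming_identity(candidate, anchors[other]) <= floor
                    for other in members
                    if other in anchors
                ):
                    anchors[species] = candidate
                    break
            else:
                raise ValueError(
                    f"infeasible divergence {min_interspecies_divergence} for "
                    f"{len(members)} congeners of {genus} at length {length}"
                )
    if len(names) > 1:
        idents = _hamming_identity_matrix([anchors[n] for n in names])
        np.fill_diagonal(idents, 0.0)
        if idents.max() > floor + 1e-9:
            i, j = np.unravel_index(int(idents.argmax()), idents.shape)
            raise ValueError(
                f"anchor identity {idents.max():.2f}% between {names[i]} and "
                f"{names[j]} exceeds the {floor:.2f}% ceiling"
            )

    if library_tags is None:
        library_tags = [f"lib{i + 1}" for i in range(n_libraries)]
    elif len(library_tags) != n_libraries:
        raise ValueError("library_tags length must equal n_libraries")
    libraries = []
    n_drop = round(dropout_per_library * len(names))
    for tag in library_tags:
        dropped = set(
            rng.choice(len(names), size=n_drop, replace=False).tolist()
        ) if n_drop else set()
        entries = tuple(
            (f"{tag.upper()}{i:05d}", name, anchors[name])
            for i, name in enumerate(names)
            if i not in dropped
        )
        libraries.append(ReferenceLibrary(tag=tag, entries=entries))
    return libraries


def _hamming_identity(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def generate_catalogs(
    pool: SpeciesPool,
    commercial_names: Sequence[str],
    n_catalogs: int = 3,
    max_species_per_name: int = 4,
    seed: int | None = None,
    catalog_tags: Sequence[str] | None = None,
):
    """Commercial-name catalogs whose union defines label correctness.

    Every commercial name receives 1..``max_species_per_name`` accepted
    species, drawn supply-weighted without replacement.  Each accepted
    (name, species) pair is then distributed to a non-empty subset of the
    ``n_catalogs`` catalogs, so individual catalogs are incomplete but
    their union recovers the full acceptance mapping — mirroring how
    several partially overlapping national name lists are used jointly.

    Returns ``(catalogs, master)`` where ``catalogs`` is a list of
    :class:`fishaudit.labeling.Catalog` and ``master`` the union mapping
    used as generating truth.
    """
    from .labeling import Catalog, normalize_name

    rng = np.random.default_rng(seed)
    names = pool.names
    weights = np.array([w for _, _, w in pool.species], dtype=float)
    weights = weights / weights.sum()
    master: dict[str, set[str]] = {}
    for cname in commercial_names:
        k = int(rng.integers(1, max_species_per_name + 1))
        k = min(k, len(names))
        accepted = rng.choice(len(names), size=k, replace=False, p=weights)
        master[normalize_name(cname)] = {names[int(i)] for i in accepted}
    if catalog_tags is None:
        catalog_tags = [f"catalog{c + 1}" for c in range(n_catalogs)]
    mappings: list[dict[str, set[str]]] = [dict() for _ in catalog_tags]
    for cname, accepted in master.items():
        for species in sorted(accepted):
            members = rng.random(n_catalogs) < 0.7
            if not members.any():
                members[int(rng.integers(n_catalogs))] = True
            for c in np.flatnonzero(members):
                mappings[int(c)].setdefault(cname, set()).add(species)
    catalogs = [
        Catalog(tag=tag, mapping={k: frozenset(v) for k, v in mapping.items()})
        for tag, mapping in zip(catalog_tags, mappings)
    ]
    return catalogs, master


def simulate_survey(
    pool: SpeciesPool,
    design: SurveyDesign,
    catalogs,
    library: ReferenceLibrary | None = None,
    seed: int | None = None,
):
    """Draw a purchased-sample table with known ground truth.

    For each commercial name in the design, samples are drawn with that
    name's mislabeling probability: a mislabeled sample carries a substitute
    species drawn from the name's substitution-weight row re-normalized
    over species NOT accepted for the name; a correct sample carries an
    accepted species drawn supply-weighted.  When ``design.emit_sequences``
    is set, each sample's query barcode is the species anchor from
    ``library`` mutated at an intra-species divergence drawn uniformly from
    ``[0, design.intra_divergence]``.

    Returns ``(samples, truth)``: a pandas DataFrame with columns
    ``sample_id, city, vendor_type, name_source, commercial_name, price,
    sequence`` and a :class:`GroundTruth`.
    """
    import pandas as pd

    from .labeling import normalize_name

    rng = np.random.default_rng(design.seed if seed is None else seed)
    accepted_union: dict[str, set[str]] = {}
    for catalog in catalogs:
        for cname, species_set in catalog.mapping.items():
            accepted_union.setdefault(cname, set()).update(species_set)

    pool_names = pool.names
    supply = pool.weights
    anchors = (
        {species: seq for _, species, seq in library.entries} if library is not None else {}
    )
    if design.emit_sequences and library is None:
        raise ValueError("emit_sequences=True requires a reference library of anchors")

    rows = []
    truth: dict[str, tuple[str, bool]] = {}
    counter = 0
    for cname in sorted(design.samples_per_name):
        count = design.samples_per_name[cname]
        norm = normalize_name(cname)
        p_mis = design.mislabel_probability.get(cname, 0.0)
        accepted = accepted_union.get(norm, set())
        if norm not in design.generic_names and not accepted:
            raise ValueError(
                f"commercial name {cname!r} is neither in a catalog nor listed generic"
            )
        accepted_in_pool = [s for s in pool_names if s in accepted]
        sub_row = (design.substitution_weights or {}).get(cname, supply)
        substitute_support = [
            s for s in pool_names if s not in accepted and sub_row.get(s, 0.0) > 0
        ]
        if p_mis > 0 and not substitute_support:
            raise ValueError(
                f"name {cname!r} has mislabel probability {p_mis} but no "
                "species with positive substitution weight outside its accepted set"
            )
        for _ in range(count):
            sample_id = f"S{counter:04d}"
            counter += 1
            city = str(rng.choice(design.cities))
            vendor = str(rng.choice(design.vendor_types))
            source = str(rng.choice(design.name_sources))
            mislabeled = bool(rng.random() < p_mis)
            if mislabeled or not accepted_in_pool:
                w = np.array([sub_row.get(s, 0.0) for s in substitute_support])
                species = substitute_support[int(rng.choice(len(substitute_support), p=w / w.sum()))]
            else:
                w = np.array([supply[s] for s in accepted_in_pool])
                if w.sum() <= 0:
                    w = np.ones(len(accepted_in_pool))
                species = accepted_in_pool[int(rng.choice(len(accepted_in_pool), p=w / w.sum()))]
            is_mislabel = species not in accepted  # holds by construction
            sequence = ""
            if design.emit_sequences:
                divergence = float(rng.uniform(0.0, design.intra_divergence))
                sequence = mutate_sequence(anchors[species], divergence, rng=rng)
            price = float(np.round(rng.lognormal(mean=5.0, sigma=0.5), 2))
            rows.append(
                (sample_id, city, vendor, source, cname, price, sequence)
            )
            truth[sample_id] = (species, is_mislabel)
    samples = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "city", "vendor_type", "name_source",
            "commercial_name", "price", "sequence",
        ],
    )
    ground_truth = GroundTruth(
        samples=truth,
        name_probabilities={
            c: design.mislabel_probability.get(c, 0.0) for c in design.samples_per_name
        },
    )
    return samples, ground_truth


def study_scenario(
    seed: int = 0,
    n_samples: int = 376,
    n_names: int = 48,
    n_species: int = 160,
    mean_mislabel_probability: float = 0.31,
    with_library: bool = True,
):
    """The default study-scale synthetic survey.

    Emulates a three-city, three-vendor market survey: ``n_samples``
    purchases under ``n_names`` commercial names with a Zipf-like name
    frequency (many names sampled once, a few dozens of times), a candidate
    pool of ``n_species`` species with Zipf supply weights (exponent 0.65,
    calibrated so that roughly half of the observed species are singletons
    at the default size), availability-driven substitution, and per-name
    mislabeling probabilities drawn Beta(1.1, 2.45) (mean ≈ 0.31, the
    study-wide rate).

    Returns ``(pool, design, catalogs, libraries, master)`` where ``master``
    is the generating union acceptance mapping.
    """
    rng = np.random.default_rng(seed)
    pool = SpeciesPool.zipf(n_species, exponent=0.65, seed=int(rng.integers(2**31)))
    commercial_names = [f"name_{t}" for t in _name_series(n_names)]
    catalogs, master = generate_catalogs(
        pool, commercial_names, seed=int(rng.integers(2**31))
    )
    # Zipf-ish name frequencies scaled to the target sample count
    ranks = np.arange(1, n_names + 1, dtype=float)
    raw = ranks ** -1.0
    counts = np.maximum(1, np.round(raw / raw.sum() * n_samples)).astype(int)
    while counts.sum() > n_samples:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < n_samples:
        counts[int(np.argmin(counts))] += 1
    order = rng.permutation(n_names)
    samples_per_name = {commercial_names[int(i)]: int(c) for i, c in zip(order, counts)}
    a = 1.1
    b = a * (1.0 - mean_mislabel_probability) / mean_mislabel_probability
    probs = {c: float(rng.beta(a, b)) for c in commercial_names}
    design = SurveyDesign(
        samples_per_name=samples_per_name,
        mislabel_probability=probs,
        seed=int(rng.integers(2**31)),
        emit_sequences=with_library,
    )
    libraries = (
        generate_reference_library(pool, seed=int(rng.integers(2**31)))
        if with_library
        else []
    )
    return pool, design, catalogs, libraries, master
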