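"""Tabular readers/writers, run configuration and the report bundle.

Canonical tabular dialect is TSV (UTF-8, "." decimal); CSV is accepted on
input by extension.  Species are serialized as "Genus epithet" with one
ASCII space; multi-candidate sets are ";"-joined.  Every writer's output is
re-readable by the matching reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .audit import NameAudit, SubstitutionEdge, audits_frame
from .labeling import Catalog, normalize_name

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_survey_table",
    "read_catalogs",
    "write_catalogs",
    "read_landings",
    "read_status_table",
    "read_audits",
    "write_audits",
    "write_edges",
    "read_edges",
    "write_report",
]

VENDOR_TYPES = ("fish_market", "grocery_store", "restaurant")
NAME_SOURCES = ("label", "menu", "verbal")


class ValidationError(ValueError):
    """Input failed validation; carries an itemized list of problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("input validation failed:\n" + "\n".join(self.problems))


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


@dataclasses.dataclass
class RunConfig:
    """Paths and thresholds of a pipeline run; loadable from YAML.

    Optional inputs left as None disable the corresponding stage.
    """

    queries: str | None = None
    libraries: tuple[str, ...] = ()
    survey: str | None = None
    catalogs: str | None = None
    landings: str | None = None
    status_table: str | None = None
    out_dir: str = "fishaudit-out"
    threshold: float = 98.0
    genus_floor: float = 90.0
    min_verbal: int = 6
    alpha: float = 0.05
    generic_names: tuple[str, ...] = ("pescado",)
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        problems = []
        if not 0 < self.threshold <= 100:
            problems.append(f"threshold {self.threshold} outside (0, 100]")
        if not 0 <= self.genus_floor <= self.threshold:
            problems.append(f"genus_floor {self.genus_floor} outside [0, threshold]")
        if not 0 < self.alpha < 1:
            problems.append(f"alpha {self.alpha} outside (0, 1)")
        if self.min_verbal < 1:
            problems.append(f"min_verbal {self.min_verbal} must be >= 1")
        if problems:
            raise ValidationError(problems)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError([f"unknown config keys: {sorted(unknown)}"])
        for key in ("libraries", "generic_names"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_survey_table(path) -> pd.DataFrame:
    """Read and validate the purchased-sample table.

    Requires columns ``sample_id, city, vendor_type, name_source,
    commercial_name`` (``price`` and ``sequence`` optional); sample ids must
    be unique and vendor types / name sources must come from the controlled
    vocabularies.  All problems are reported together, with line numbers.
    """
    table = _read_table(path)
    problems = []
    required = ["sample_id", "city", "vendor_type", "name_source", "commercial_name"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError([f"missing required columns: {missing}"])
    dup = table["sample_id"][table["sample_id"].duplicated()]
    for sid in dup.unique():
        problems.append(f"duplicate sample_id {sid!r}")
    for idx, rec in table.iterrows():
        line = idx + 2  # header is line 1
        if rec["vendor_type"] not in VENDOR_TYPES:
            problems.append(
                f"line {line}: vendor_type {rec['vendor_type']!r} not in {VENDOR_TYPES}"
            )
        if rec["name_source"] not in NAME_SOURCES:
            problems.append(
                f"line {line}: name_source {rec['name_source']!r} not in {NAME_SOURCES}"
            )
        if not str(rec["commercial_name"]).strip():
            problems.append(f"line {line}: empty commercial_name")
    if problems:
        raise ValidationError(problems)
    if "price" in table.columns:
        table["price"] = pd.to_numeric(table["price"], errors="coerce")
    return table


def write_survey_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_catalogs(path) -> list[Catalog]:
    """Catalog TSV with columns ``catalog_tag, commercial_name, species``."""
    table = _read_table(path)
    required = ["catalog_tag", "commercial_name", "species"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError([f"catalog file missing columns: {missing}"])
    catalogs = []
    for tag, sub in table.groupby("catalog_tag", sort=True):
        mapping: dict[str, set[str]] = {}
        for _, rec in sub.iterrows():
            mapping.setdefault(normalize_name(rec["commercial_name"]), set()).add(
                rec["species"]
            )
        catalogs.append(
            Catalog(tag=str(tag), mapping={k: frozenset(v) for k, v in mapping.items()})
        )
    if not catalogs:
        raise ValidationError(["catalog file contains no rows"])
    return catalogs


def write_catalogs(catalogs: Sequence[Catalog], path) -> None:
    rows = [
        {"catalog_tag": c.tag, "commercial_name": name, "species": sp}
        for c in catalogs
        for name in sorted(c.mapping)
        for sp in sorted(c.mapping[name])
    ]
    pd.DataFrame(rows, columns=["catalog_tag", "commercial_name", "species"]).to_csv(
        path, sep="\t", index=False
    )


def read_landings(path) -> pd.DataFrame:
    """Landings/imports TSV: ``commercial_name, year, tons``."""
    table = _read_table(path)
    missing = [c for c in ("commercial_name", "tons") if c not in table.columns]
    if missing:
        raise ValidationError([f"landings file missing columns: {missing}"])
    table["tons"] = pd.to_numeric(table["tons"])
    return table


def read_status_table(path) -> pd.DataFrame:
    """Conservation-status TSV: ``species, iucn, cites``."""
    table = _read_table(path)
    missing = [c for c in ("species", "iucn") if c not in table.columns]
    if missing:
        raise ValidationError([f"status table missing columns: {missing}"])
    if "cites" not in table.columns:
        table["cites"] = ""
    return table


_AUDIT_COLUMNS = [
    "commercial_name", "verbal_sample_number", "correctly_labeled",
    "mislabeling_frequency", "mislabeling_percentage", "mislabeling_diversity",
    "substitutability_frequency", "substitutability_diversity",
    "confirmed_samples", "over_sub_representation",
    "over_sub_representation_percentage",
]


def write_audits(audits: Sequence[NameAudit], path) -> None:
    audits_frame(audits)[_AUDIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_audits(path) -> list[NameAudit]:
    table = _read_table(path)
    return [
        NameAudit.from_counts(
            rec["commercial_name"],
            int(rec["verbal_sample_number"]),
            int(rec["correctly_labeled"]),
            int(rec["mislabeling_diversity"]),
            int(rec["substitutability_frequency"]),
            int(rec["substitutability_diversity"]),
        )
        for _, rec in table.iterrows()
    ]


def write_edges(edges: Sequence[SubstitutionEdge], path, json_path=None) -> None:
    """Edge-list TSV (and optional JSON suitable for alluvial/Sankey rendering)."""
    frame = pd.DataFrame(
        [(e.species, e.commercial_name, e.count) for e in edges],
        columns=["species", "commercial_name", "count"],
    )
    frame.to_csv(path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "nodes": sorted(set(frame["species"])) + sorted(set(frame["commercial_name"])),
            "links": [
                {"source": e.species, "target": e.commercial_name, "value": e.count}
                for e in edges
            ],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_edges(path) -> list[SubstitutionEdge]:
    table = _read_table(path)
    return [
        SubstitutionEdge(rec["species"], rec["commercial_name"], int(rec["count"]))
        for _, rec in table.iterrows()
    ]


def read_queries_fasta(path) -> dict[str, str]:
    """Query FASTA keyed by sample id (the record id)."""
    from Bio import SeqIO

    queries = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not queries:
        raise ValidationError([f"no FASTA records in {path}"])
    return queries


def write_queries_fasta(queries: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample_id, seq in queries.items():
            fh.write(f">{sample_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_identifications(results, path) -> None:
    """Per-sample identification TSV (candidates ';'-joined, per-library best hits)."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "candidates": ";".join(r.candidates),
            "best_identity": round(r.best_identity, 2),
            "confidence": r.confidence,
            "notes": r.notes,
        }
        for tag, hit in sorted(r.per_library_best.items()):
            row[f"{tag}_accession"] = hit.accession
            row[f"{tag}_identity"] = round(hit.identity, 2)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    out_dir,
    *,
    audits: Sequence[NameAudit] = (),
    edges: Sequence[SubstitutionEdge] = (),
    category_counts: pd.DataFrame | None = None,
    strata: Mapping[str, tuple] | None = None,
    regressions: Sequence = (),
    config: RunConfig | None = None,
    input_paths: Sequence[str] = (),
) -> dict:
    """Write the full report bundle and its reproducibility manifest.

    Produces ``audits.tsv``, ``edges.tsv``/``edges.json``,
    ``category_matrix.tsv``, one ``strata_<name>.tsv`` per stratification,
    ``regressions.tsv`` and ``manifest.json`` (config, seed and input
    checksums).  The output directory is created (and verified writable)
    before anything is written, so failures do not leave partial bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise OSError(f"output directory {out} is not writable")

    written: dict[str, str] = {}

    write_audits(list(audits), out / "audits.tsv")
    written["audits"] = "audits.tsv"
    write_edges(list(edges), out / "edges.tsv", out / "edges.json")
    written["edges"] = "edges.tsv"
    if category_counts is not None:
        category_counts.to_csv(out / "category_matrix.tsv", sep="\t")
        written["category_matrix"] = "category_matrix.tsv"
    for name, (estimates, pairwise) in (strata or {}).items():
        frame = pd.DataFrame(
            [
                {
                    "stratum": value, "k": e.k, "n": e.n, "rate": e.rate,
                    "ci_low": e.ci_low, "ci_high": e.ci_high,
                }
                for value, e in estimates.items()
            ]
        )
        frame.to_csv(out / f"strata_{name}.tsv", sep="\t", index=False)
        pairwise.to_csv(out / f"strata_{name}_pairwise.tsv", sep="\t", index=False)
        written[f"strata_{name}"] = f"strata_{name}.tsv"
    if regressions:
        pd.DataFrame([dataclasses.asdict(r) for r in regressions]).to_csv(
            out / "regressions.tsv", sep="\t", index=False
        )
        written["regressions"] = "regressions.tsv"

    manifest = {
        "config": config.to_dict() if config else None,
        "seed": config.seed if config else None,
        "inputs": {str(p): _sha256(p) for p in input_paths},
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
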