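"""Readers/writers for the pipeline's external formats, sequence QC and config.

Formats handled here: FASTA (plain and aligned), TSV gene tables, TSV/JSON
result reports and the JSON run configuration.  Gene coordinates are ordinal
gene indices along a replicon (0-based, consecutive), not base pairs; a
converter from start-position sorted input is provided
(:func:`ordinals_from_positions`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .utils import config_hash

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
_VALID_RESIDUES = set(AMINO_ACIDS) | {"X"} | set(GAP_CHARS)

ALLOWED_LABELS = (
    "CcmK1",
    "CcmK2",
    "CcmK12_unsplit",
    "CcmK3",
    "CcmK4",
    "CcmK5",
    "CcmK6",
    "CcmO",
    "CcmP",
    "CcmL",
    "CcmM",
    "CcmN",
    "RbcL",
    "RbcS",
    "Other",
)

#: Labels counted as carboxysome genes by locus assembly.  RubisCO genes are
#: deliberately excluded: adjacency rules operate on shell/core genes only.
CARBOXYSOME_LABELS = frozenset(
    l for l in ALLOWED_LABELS if l.startswith("Ccm")
)

STRANDS = ("+", "-", "unknown")


class FastaParseError(ValueError):
    """Malformed FASTA input (carries the offending line number)."""


class GeneTableError(ValueError):
    """Structurally invalid gene table (duplicates, gaps, bad labels)."""


@dataclass
class ProteinRecord:
    """One protein sequence with its genome of origin and QC flags.

    ``sequence`` may contain gap characters when the record comes from an
    aligned FASTA; ``length`` always counts non-gap residues.
    """

    protein_id: str
    genome_id: str
    sequence: str
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return sum(1 for c in self.sequence if c not in GAP_CHARS)

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.sequence if c not in GAP_CHARS)

    def x_fraction(self) -> float:
        n = self.length
        if n == 0:
            return 0.0
        return self.ungapped.count("X") / n


@dataclass
class GeneTableRow:
    """One gene in a per-genome table; ``ordinal`` is the adjacency coordinate."""

    genome_id: str
    replicon_id: str
    ordinal: int
    gene_id: str
    strand: str = "unknown"
    label: str = "Other"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise GeneTableError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {STRANDS}"
            )
        if self.label not in ALLOWED_LABELS:
            raise GeneTableError(
                f"gene {self.gene_id}: unknown label {self.label!r}; "
                f"allowed labels: {', '.join(ALLOWED_LABELS)}"
            )

    @property
    def is_carboxysome(self) -> bool:
        return self.label in CARBOXYSOME_LABELS


@dataclass
class RunConfig:
    """Run-wide configuration; JSON-serialisable, hashed into output headers."""

    seed: int = 0
    out_dir: str = "."
    classifier: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section in (self.classifier, self.assembly, self.correlation):
            for key, value in section.items():
                if isinstance(value, (int, float)) and not isinstance(value, bool):
                    if key.endswith(("_range",)):
                        continue
                    if value <= 0:
                        raise ValueError(f"config threshold {key}={value} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_json(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str, aligned: bool = False) -> List[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects.

    Header convention: first whitespace token is the protein id, second token
    (when present) the genome id.  Gaps are stripped unless ``aligned`` is
    true.  Malformed headers or illegal residue characters raise
    :class:`FastaParseError` naming the line number.
    """
    records: List[ProteinRecord] = []
    header: Tuple[str, str] | None = None
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not aligned:
            seq = "".join(c for c in seq if c not in GAP_CHARS)
        records.append(ProteinRecord(header[0], header[1], seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                tokens = line[1:].split()
                if not tokens:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header = (tokens[0], tokens[1] if len(tokens) > 1 else "")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                bad = set(line.upper()) - _VALID_RESIDUES
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: illegal residue character(s) "
                        f"{sorted(bad)}"
                    )
                chunks.append(line.upper())
    flush()
    if not records:
        log.warning("no records found in %s", path)
    seen = set()
    for rec in records:
        if rec.protein_id in seen:
            raise FastaParseError(f"{path}: duplicate protein_id {rec.protein_id!r}")
        seen.add(rec.protein_id)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.protein_id}"
            if rec.genome_id:
                header += f" {rec.genome_id}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def qc_filter(
    records: Iterable[ProteinRecord], max_x_fraction: float = 0.20
) -> Tuple[List[ProteinRecord], List[ProteinRecord]]:
    """Split records into (kept, dropped) by 'X' content.

    A record is dropped when its fraction of 'X' residues strictly exceeds
    ``max_x_fraction`` (low-information sequence).  Dropped records receive a
    ``low_information`` flag.
    """
    if not 0 < max_x_fraction <= 1:
        raise ValueError("max_x_fraction must be in (0, 1]")
    kept: List[ProteinRecord] = []
    dropped: List[ProteinRecord] = []
    for rec in records:
        if rec.x_fraction() > max_x_fraction:
            if "low_information" not in rec.flags:
                rec.flags.append("low_information")
            dropped.append(rec)
        else:
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# Gene tables

_GENE_COLUMNS = ["genome_id", "replicon_id", "ordinal", "gene_id", "strand", "label"]


def read_gene_table(path: str, exclude_genomes: Iterable[str] = ()) -> Dict[str, List[GeneTableRow]]:
    """Read a TSV gene table, grouped by genome and sorted by ordinal.

    Rows with a truthy optional ``pseudo`` column are excluded.  Ordinals must
    be unique and consecutive from 0 within each replicon.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _GENE_COLUMNS if c not in df.columns and c not in ("strand", "label")]
    if missing:
        raise GeneTableError(f"{path}: missing column(s) {missing}")
    if "pseudo" in df.columns:
        pseudo_mask = df["pseudo"].fillna("").str.lower().isin(("1", "true", "yes"))
        if pseudo_mask.any():
            log.info("excluding %d pseudogene rows", int(pseudo_mask.sum()))
    else:
        pseudo_mask = pd.Series(False, index=df.index)
    excluded = set(exclude_genomes)
    if excluded:
        keep = ~df["genome_id"].isin(excluded)
        df, pseudo_mask = df[keep], pseudo_mask[keep]

    tables: Dict[str, List[GeneTableRow]] = {}
    pseudo_rows: List[Tuple[str, GeneTableRow]] = []
    for idx, r in df.iterrows():
        row = GeneTableRow(
            genome_id=r["genome_id"],
            replicon_id=r["replicon_id"],
            ordinal=int(r["ordinal"]),
            gene_id=r["gene_id"],
            strand=r.get("strand", "unknown") or "unknown",
            label=r.get("label", "Other") or "Other",
        )
        tables.setdefault(row.genome_id, []).append(row)
        if pseudo_mask.loc[idx]:
            pseudo_rows.append((row.genome_id, row))

    # ordinal integrity is checked with pseudogene rows still in place: they
    # occupy real positions on the replicon
    for genome_id, rows in tables.items():
        rows.sort(key=lambda r: (r.replicon_id, r.ordinal))
        by_replicon: Dict[str, List[int]] = {}
        for row in rows:
            by_replicon.setdefault(row.replicon_id, []).append(row.ordinal)
        for replicon_id, ordinals in by_replicon.items():
            if len(set(ordinals)) != len(ordinals):
                raise GeneTableError(
                    f"{genome_id}/{replicon_id}: duplicate ordinal(s)"
                )
            if ordinals != list(range(len(ordinals))):
                raise GeneTableError(
                    f"{genome_id}/{replicon_id}: ordinals not consecutive from 0 "
                    f"(got {ordinals[:10]}...)"
                )
    # pseudogenes are excluded from analysis by demoting them to Other rather
    # than removing the row, preserving the coordinate system
    for genome_id, row in pseudo_rows:
        row.label = "Other"
    return tables


def write_gene_table(tables: Dict[str, List[GeneTableRow]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for genome_id in sorted(tables):
            for row in sorted(tables[genome_id], key=lambda r: (r.replicon_id, r.ordinal)):
                fh.write(
                    "\t".join(
                        [row.genome_id, row.replicon_id, str(row.ordinal), row.gene_id, row.strand, row.label]
                    )
                    + "\n"
                )


def ordinals_from_positions(rows: List[dict]) -> List[GeneTableRow]:
    """Assign ordinals from GFF-like records with start positions.

    Each input dict needs genome_id, replicon_id, start, gene_id and
    optionally strand/label; genes are sorted by start within each replicon
    and numbered from 0.
    """
    out: List[GeneTableRow] = []
    by_rep: Dict[Tuple[str, str], List[dict]] = {}
    for r in rows:
        by_rep.setdefault((r["genome_id"], r["replicon_id"]), []).append(r)
    for (genome_id, replicon_id), group in by_rep.items():
        group.sort(key=lambda r: int(r["start"]))
        for i, r in enumerate(group):
            out.append(
                GeneTableRow(
                    genome_id=genome_id,
                    replicon_id=replicon_id,
                    ordinal=i,
                    gene_id=r["gene_id"],
                    strand=r.get("strand", "unknown"),
                    label=r.get("label", "Other"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Reports

def _header_lines(config: RunConfig | None) -> List[str]:
    if config is None:
        return []
    return [f"# config_hash={config.hash} seed={config.seed}"]


def write_report(result, path: str, fmt: str = "tsv", config: RunConfig | None = None) -> None:
    """Write a result object (anything with ``to_frame()``/``to_dict()``).

    TSV output carries the config hash and seed in leading ``#`` comment
    lines; JSON output carries them under a ``_meta`` key.  Values round-trip
    through :func:`read_report` to 1e-9.
    """
    if fmt == "tsv":
        frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
        with open(path, "w") as fh:
            for line in _header_lines(config):
                fh.write(line + "\n")
            frame.to_csv(fh, sep="\t", index=False)
    elif fmt == "json":
        payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
        if config is not None:
            payload = {"_meta": {"config_hash": config.hash, "seed": config.seed}, **payload}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str, fmt: str = "tsv"):
    """Read a report written by :func:`write_report`."""
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", comment="#")
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("_meta", None)
        return payload
    raise ValueError(f"unknown report format {fmt!r}")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
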