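"""Group carboxysome genes into loci, find the MCL, call satellites.

All distances are in ordinal gene units.  Two rules drive assembly:

* genes with at most ``satellite_distance`` intervening non-carboxysome genes
  belong to the same locus region (a gene with no carboxysome neighbour
  within that distance is a satellite locus of size 1);
* inside a region, the maximal run with at most ``max_insert`` intervening
  genes between consecutive members forms the locus *core*, which defines
  the signature; region members outside the core are kept but flagged
  loosely associated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .io_formats import GeneTableRow
from .utils import round_half_away

log = logging.getLogger(__name__)

KIND_MCL = "MCL"
KIND_SATELLITE = "satellite"

_SHORT_LABEL = {
    "CcmK1": "K1",
    "CcmK2": "K2",
    "CcmK12_unsplit": "K12",
    "CcmK3": "K3",
    "CcmK4": "K4",
    "CcmK5": "K5",
    "CcmK6": "K6",
    "CcmO": "O",
    "CcmP": "P",
    "CcmL": "L",
    "CcmM": "M",
    "CcmN": "N",
}

_K_MCL_LABELS = {"CcmK1", "CcmK2", "CcmK12_unsplit"}
_CORE_LABELS = {"CcmL", "CcmM", "CcmN"}


class LocusIntegrityError(ValueError):
    """Raised when a genome violates a structural assumption (e.g. two MCLs)."""


@dataclass
class AssemblyConfig:
    max_insert: int = 1
    satellite_distance: int = 10
    satellite_inclusive: bool = True  # "within 10 ORFs" keeps a gap of exactly 10 joined

    def __post_init__(self) -> None:
        if not 0 <= self.max_insert < self.satellite_distance:
            raise ValueError("require 0 <= max_insert < satellite_distance")


@dataclass
class Locus:
    genome_id: str
    replicon_id: str
    members: List[GeneTableRow]  # core members, sorted by ordinal
    loose_members: List[GeneTableRow] = field(default_factory=list)
    kind: str = KIND_SATELLITE
    flags: List[str] = field(default_factory=list)

    @property
    def all_members(self) -> List[GeneTableRow]:
        return sorted(self.members + self.loose_members, key=lambda r: r.ordinal)

    @property
    def span(self) -> Tuple[int, int]:
        ordinals = [r.ordinal for r in self.all_members]
        return (min(ordinals), max(ordinals))

    @property
    def signature(self) -> str:
        return "-".join(_SHORT_LABEL[r.label] for r in self.members)

    @property
    def labels(self) -> List[str]:
        return [r.label for r in self.members]


def _gap(a: GeneTableRow, b: GeneTableRow) -> int:
    """Intervening genes between two rows on the same replicon."""
    return b.ordinal - a.ordinal - 1


def _split_runs(rows: List[GeneTableRow], max_gap: int) -> List[List[GeneTableRow]]:
    runs: List[List[GeneTableRow]] = [[rows[0]]]
    for prev, cur in zip(rows, rows[1:]):
        if _gap(prev, cur) <= max_gap:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    return runs


def assemble_loci(rows: Iterable[GeneTableRow], config: AssemblyConfig | None = None) -> List[Locus]:
    """Assemble loci for one genome's gene table rows.

    Every carboxysome-labelled gene lands in exactly one locus.  Kind is
    provisionally ``satellite``; :func:`identify_mcl` promotes one locus.
    """
    config = config or AssemblyConfig()
    region_gap = config.satellite_distance if config.satellite_inclusive else config.satellite_distance - 1
    by_replicon: Dict[Tuple[str, str], List[GeneTableRow]] = {}
    for row in rows:
        if row.is_carboxysome:
            by_replicon.setdefault((row.genome_id, row.replicon_id), []).append(row)

    loci: List[Locus] = []
    for (genome_id, replicon_id), carb in sorted(by_replicon.items()):
        carb.sort(key=lambda r: r.ordinal)
        for region in _split_runs(carb, region_gap):
            # the longest tight run (ties: leftmost) is the core
            runs = _split_runs(region, config.max_insert)
            core = max(runs, key=len)
            loose = [r for r in region if r not in core]
            flags = ["loosely_associated_members"] if loose else []
            loci.append(
                Locus(
                    genome_id=genome_id,
                    replicon_id=replicon_id,
                    members=core,
                    loose_members=loose,
                    flags=flags,
                )
            )
    return loci


def _is_mcl_candidate(locus: Locus) -> bool:
    labels = set(locus.labels)
    return bool(labels & _K_MCL_LABELS) and _CORE_LABELS <= labels


def _check_mcl_order(locus: Locus) -> None:
    """K genes before L-M-N, ccmO terminal: violations warn, never fail."""
    labels = locus.labels
    try:
        first_core = min(labels.index(l) for l in _CORE_LABELS)
    except ValueError:  # pragma: no cover - candidate guarantees presence
        return
    if any(l in _K_MCL_LABELS for l in labels[first_core:]):
        locus.flags.append("atypical_order")
        log.warning("%s: ccmK gene downstream of ccmL/M/N in MCL", locus.genome_id)
    if "CcmO" in labels and labels[-1] != "CcmO":
        if "atypical_order" not in locus.flags:
            locus.flags.append("atypical_order")
        log.warning("%s: ccmO not terminal in MCL", locus.genome_id)


def identify_mcl(loci: List[Locus]) -> Optional[Locus]:
    """Mark the unique MCL among one genome's loci; others become satellites.

    Returns None (and leaves every locus a satellite) for genomes without an
    MCL-like locus; raises :class:`LocusIntegrityError` when more than one
    qualifies.
    """
    candidates = [l for l in loci if _is_mcl_candidate(l)]
    if len(candidates) > 1:
        sigs = ", ".join(l.signature for l in candidates)
        raise LocusIntegrityError(
            f"{candidates[0].genome_id}: {len(candidates)} MCL candidates ({sigs})"
        )
    for locus in loci:
        locus.kind = KIND_SATELLITE
    if not candidates:
        return None
    mcl = candidates[0]
    mcl.kind = KIND_MCL
    _check_mcl_order(mcl)
    return mcl


CCMO_MCL = "mcl"
CCMO_SATELLITE = "satellite"
CCMO_ABSENT = "absent"


def classify_ccmO_position(loci: List[Locus]) -> str:
    """Where does ccmO sit: in the MCL, in a satellite locus, or nowhere."""
    in_mcl = any(
        r.label == "CcmO"
        for locus in loci
        if locus.kind == KIND_MCL
        for r in locus.all_members
    )
    if in_mcl:
        return CCMO_MCL
    anywhere = any(r.label == "CcmO" for locus in loci for r in locus.all_members)
    return CCMO_SATELLITE if anywhere else CCMO_ABSENT


@dataclass
class LocusSummary:
    signature_counts: Counter
    satellite_counts: Dict[str, int]
    mean_satellites: float
    ccmO_positions: Dict[str, str]
    ccmO_tally: Counter
    no_mcl_genomes: List[str]
    error_genomes: Dict[str, str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.signature_counts.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["signature", "count"],
        )


def assemble_genome(
    rows: Iterable[GeneTableRow], config: AssemblyConfig | None = None
) -> List[Locus]:
    """Convenience: assemble loci and resolve the MCL for one genome."""
    loci = assemble_loci(rows, config)
    identify_mcl(loci)
    return loci


def summarize_locus_types(
    tables: Dict[str, List[GeneTableRow]], config: AssemblyConfig | None = None
) -> LocusSummary:
    """Tally locus signatures, satellite counts and ccmO positions cohort-wide.

    Genomes raising an integrity error (e.g. duplicated MCL) are recorded and
    excluded from every tally.
    """
    config = config or AssemblyConfig()
    signature_counts: Counter = Counter()
    satellite_counts: Dict[str, int] = {}
    ccmO_positions: Dict[str, str] = {}
    no_mcl: List[str] = []
    errors: Dict[str, str] = {}
    for genome_id in sorted(tables):
        loci = assemble_loci(tables[genome_id], config)
        try:
            mcl = identify_mcl(loci)
        except LocusIntegrityError as exc:
            errors[genome_id] = str(exc)
            continue
        if mcl is None:
            no_mcl.append(genome_id)
        for locus in loci:
            signature_counts[locus.signature] += 1
        satellite_counts[genome_id] = sum(1 for l in loci if l.kind == KIND_SATELLITE)
        ccmO_positions[genome_id] = classify_ccmO_position(loci)
    mean_sat = (
        round_half_away(sum(satellite_counts.values()) / len(satellite_counts), 1)
        if satellite_counts
        else float("nan")
    )
    return LocusSummary(
        signature_counts=signature_counts,
        satellite_counts=satellite_counts,
        mean_satellites=mean_sat,
        ccmO_positions=ccmO_positions,
        ccmO_tally=Counter(ccmO_positions.values()),
        no_mcl_genomes=no_mcl,
        error_genomes=errors,
    )


def loci_to_frame(per_genome: Dict[str, List[Locus]]):
    """Flatten loci to a report table (one row per locus)."""
    import pandas as pd

    rows = []
    for genome_id in sorted(per_genome):
        for locus in per_genome[genome_id]:
            lo, hi = locus.span
            rows.append(
                {
                    "genome_id": genome_id,
                    "replicon_id": locus.replicon_id,
                    "span_start": lo,
                    "span_end": hi,
                    "kind": locus.kind,
                    "signature": locus.signature,
                    "flags": ";".join(locus.flags),
                }
            )
    return pd.DataFrame(rows)
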