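"""Synthetic genomes, sequences and expression matrices for pipeline testing.

The generators emulate the statistical structure the analysis assumes for a
cohort of beta-cyanobacterial genomes: one main carboxysome locus (MCL) per
genome with 1-3 ccmK1/2 genes followed by ccmL/M/N and, in most genomes,
ccmO; a ccmK3-ccmK4 satellite pair; a ccmP satellite; optional ccmK5/ccmK6
singletons and satellite ccmO; filler genes in between.  Sequences come from
divergent per-class archetypes with the documented CcmK1/CcmK2 length split,
and expression matrices follow a shared-latent-factor model in which MCL
genes are co-regulated and satellite ccmO is independent.

Everything is driven by explicit seeds: identical spec + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import coexpression as cx
from .io_formats import (
    AMINO_ACIDS,
    GeneTableRow,
    ProteinRecord,
    ensure_dir,
    write_fasta,
    write_gene_table,
)
from .profile_classifier import ClassProfile

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


# Defaults follow the reference cohort's empirical class frequencies
# (227 genomes; ccmK3/4 jointly in 206, ccmK5 in 10, ccmK6 in 25,
# satellite ccmO in 89).
@dataclass
class CohortSpec:
    n_genomes: int = 227
    p_k34: float = 206 / 227
    p_k5: float = 10 / 227
    p_k6: float = 25 / 227
    p_ccmO_satellite: float = 89 / 227
    n_mcl_ccmK_weights: Tuple[float, float, float] = (0.05, 0.75, 0.20)  # for 1, 2, 3 copies
    k34_strict_pair: bool = True
    k5_excludes_k34: bool = True
    filler_range: Tuple[int, int] = (120, 200)
    satellite_distance: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_k34", "p_k5", "p_k6", "p_ccmO_satellite"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if abs(sum(self.n_mcl_ccmK_weights) - 1.0) > 1e-9:
            raise ValueError("n_mcl_ccmK_weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "p_k34": self.p_k34,
            "p_k5": self.p_k5,
            "p_k6": self.p_k6,
            "p_ccmO_satellite": self.p_ccmO_satellite,
            "n_mcl_ccmK_weights": list(self.n_mcl_ccmK_weights),
            "p_ccmO_satellite_target": self.p_ccmO_satellite,
            "seed": self.seed,
        }


@dataclass
class ExpressionSpec:
    n_conditions: int = 200
    mcl_rho: float = 0.8
    satellite_rho: Dict[str, float] = field(default_factory=dict)  # role -> rho, default 0
    baseline: float = 10.0  # keeps linear values positive for the log2 option
    log2_output: bool = False
    log2_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mcl_rho <= 1:
            raise ValueError("mcl_rho must be in [0, 1]")
        for role, rho in self.satellite_rho.items():
            if not 0 <= rho <= 1:
                raise ValueError(f"satellite_rho[{role}] must be in [0, 1]")
        if self.n_conditions < 3:
            raise ValueError("need at least 3 conditions")


# ---------------------------------------------------------------------------
# Genomes

def _place_blocks(
    rng: np.random.Generator,
    blocks: List[List[str]],
    n_filler: int,
    satellite_distance: int,
) -> List[Optional[str]]:
    """Place labelled gene blocks on a linear replicon of filler genes.

    Blocks are separated by more than ``satellite_distance`` intervening
    genes so each forms its own locus region.  Each block start is drawn
    uniformly over the positions still feasible given earlier placements.
    Returns a label per ordinal (None = filler).
    """
    total = n_filler + sum(len(b) for b in blocks)
    slots: List[Optional[str]] = [None] * total
    placed: List[Tuple[int, int]] = []  # (start, end) inclusive
    min_sep = satellite_distance + 2  # ordinal gap giving > satellite_distance intervening
    for block in blocks:
        size = len(block)
        feasible = [
            start
            for start in range(total - size + 1)
            if all(
                (start > e and start - e >= min_sep)
                or (s > start + size - 1 and s - (start + size - 1) >= min_sep)
                for (s, e) in placed
            )
        ]
        if not feasible:
            raise SimulationError(
                "replicon too short to place all carboxysome blocks; "
                "increase filler_range"
            )
        start = int(feasible[int(rng.integers(0, len(feasible)))])
        placed.append((start, start + size - 1))
        for i, label in enumerate(block):
            slots[start + i] = label
    return slots


def _genome_blocks(spec: CohortSpec, rng: np.random.Generator) -> Tuple[List[List[str]], dict]:
    n_k = int(rng.choice((1, 2, 3), p=spec.n_mcl_ccmK_weights))
    o_satellite = bool(rng.random() < spec.p_ccmO_satellite)
    k5 = bool(rng.random() < spec.p_k5)
    # exclusion applied conditionally: a drawn ccmK5 suppresses the K3/K4 pair
    k34 = (not (k5 and spec.k5_excludes_k34)) and bool(rng.random() < spec.p_k34)
    k6 = bool(rng.random() < spec.p_k6)

    mcl = ["CcmK2"]
    if n_k >= 2:
        mcl.append("CcmK1")
    if n_k == 3:
        mcl.append("CcmK2")
    mcl += ["CcmL", "CcmM", "CcmN"]
    if not o_satellite:
        mcl.append("CcmO")

    blocks = [mcl, ["CcmP"]]
    if k34:
        blocks.append(["CcmK3", "CcmK4"])
    if k5:
        blocks.append(["CcmK5"])
    if k6:
        blocks.append(["CcmK6"])
    if o_satellite:
        blocks.append(["CcmO"])
    truth = {
        "n_mcl_ccmK": n_k,
        "ccmO_satellite": o_satellite,
        "k34": k34,
        "k5": k5,
        "k6": k6,
    }
    return blocks, truth


def generate_genomes(spec: CohortSpec) -> Tuple[Dict[str, List[GeneTableRow]], dict]:
    """Generate per-genome gene tables plus a truth record of every draw."""
    rng = np.random.default_rng(spec.seed)
    tables: Dict[str, List[GeneTableRow]] = {}
    truth: dict = {"spec": spec.to_dict(), "genomes": {}}
    for g in range(spec.n_genomes):
        genome_id = f"g{g:04d}"
        blocks, genome_truth = _genome_blocks(spec, rng)
        n_filler = int(rng.integers(spec.filler_range[0], spec.filler_range[1] + 1))
        slots = _place_blocks(rng, blocks, n_filler, spec.satellite_distance)
        rows = [
            GeneTableRow(
                genome_id=genome_id,
                replicon_id="chr",
                ordinal=i,
                gene_id=f"{genome_id}_{i:04d}",
                strand="+",
                label=label or "Other",
            )
            for i, label in enumerate(slots)
        ]
        tables[genome_id] = rows
        truth["genomes"][genome_id] = genome_truth
    return tables, truth


# ---------------------------------------------------------------------------
# Sequences

#: Built-in archetype classes with ungapped consensus lengths.  CcmK1 and
#: CcmK2 share the CcmK1/2 archetype; per-sequence lengths are drawn from the
#: class bracket by C-terminal truncation of the 118-residue archetype.
ARCHETYPE_LENGTHS = {
    "CcmK1/2": 118,
    "CcmK3": 102,
    "CcmK4": 103,
    "CcmK5": 101,
    "CcmK6": 104,
    "CcmO": 230,
    "EutM": 97,
}

K2_LENGTHS = (100, 107)
K1_LENGTHS = (108, 118)

DEFAULT_SEQUENCE_CLASSES = ("CcmK1", "CcmK2", "CcmK3", "CcmK4", "CcmK5", "CcmK6", "CcmO", "EutM")


#: Archetypes are fixed built-ins: their consensus depends only on the class,
#: never on the caller's seed, so sequences and seed alignments generated in
#: different runs share the same class signal.
_ARCHETYPE_SEED = 20170417


def _archetype_consensus(class_name: str, seed: int | None = None) -> str:
    base = "CcmK1/2" if class_name in ("CcmK1", "CcmK2", "CcmK1/2") else class_name
    if base not in ARCHETYPE_LENGTHS:
        raise ValueError(f"no built-in archetype for class {class_name!r}")
    # CcmK1 and CcmK2 share a consensus and differ only in drawn length;
    # crc32 keeps the derived stream stable across interpreter runs
    rng = np.random.default_rng([_ARCHETYPE_SEED, zlib.crc32(base.encode())])
    length = ARCHETYPE_LENGTHS[base]
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, c in enumerate(out):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != c]
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _sample_from_profile(profile: ClassProfile, rng: np.random.Generator) -> str:
    probs = profile.emission_probabilities()
    return "".join(
        AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=p))] for p in probs
    )


def generate_sequences(
    n_per_class: int,
    substitution_rate: float = 0.1,
    classes: Sequence[str] = DEFAULT_SEQUENCE_CLASSES,
    profiles: Optional[Sequence[ClassProfile]] = None,
    seed: int = 0,
) -> Tuple[List[ProteinRecord], Dict[str, str]]:
    """Sample labelled sequences from class archetypes (or given profiles).

    Each sequence is the class consensus (profile emission sample when
    profiles are supplied) point-mutated at ``substitution_rate``.  CcmK2
    sequences are truncated to 100-107 residues, CcmK1 to 108-118.
    Returns (records, protein_id -> true class label).
    """
    if not 0 <= substitution_rate <= 0.3:
        raise ValueError("substitution_rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    records: List[ProteinRecord] = []
    labels: Dict[str, str] = {}
    profile_map = {p.class_name: p for p in profiles} if profiles else {}
    for class_name in classes:
        for i in range(n_per_class):
            if profile_map:
                key = "CcmK1/2" if class_name in ("CcmK1", "CcmK2") else class_name
                consensus = _sample_from_profile(profile_map[key], rng)
            else:
                consensus = _archetype_consensus(class_name, seed)
            if class_name == "CcmK2":
                length = int(rng.integers(K2_LENGTHS[0], K2_LENGTHS[1] + 1))
                consensus = consensus[:length]
            elif class_name == "CcmK1":
                length = int(rng.integers(K1_LENGTHS[0], K1_LENGTHS[1] + 1))
                consensus = consensus[:length]
            seq = _mutate(consensus, substitution_rate, rng)
            pid = f"{class_name.replace('/', '')}_{i:04d}"
            records.append(ProteinRecord(pid, f"sim{i % 10}", seq))
            labels[pid] = class_name
    return records, labels


def generate_seed_alignments(
    classes: Sequence[str] = ("CcmK1/2", "CcmK3", "CcmK4", "CcmK5", "CcmK6", "CcmO", "EutM"),
    n_seed: int = 8,
    substitution_rate: float = 0.02,
    seed: int = 0,
) -> Dict[str, List[ProteinRecord]]:
    """Per-class aligned seed sets for profile building.

    Within a class all sequences share the archetype length; the mixed
    CcmK1/2 seed mixes both length brackets, padded with C-terminal gaps to
    the archetype width (a crude but faithful stand-in for a real seed
    alignment of the superclass).
    """
    rng = np.random.default_rng([seed, 7])
    out: Dict[str, List[ProteinRecord]] = {}
    for class_name in classes:
        consensus = _archetype_consensus(class_name, seed)
        width = len(consensus)
        records = []
        for i in range(n_seed):
            seq = consensus
            if class_name == "CcmK1/2":
                lo, hi = (K2_LENGTHS if i % 2 == 0 else K1_LENGTHS)
                length = int(rng.integers(lo, hi + 1))
                seq = seq[:length]
            seq = _mutate(seq, substitution_rate, rng)
            seq = seq + "-" * (width - len(seq))
            records.append(ProteinRecord(f"{class_name.replace('/', '')}_seed{i}", "seedset", seq))
        out[class_name] = records
    return out


# ---------------------------------------------------------------------------
# Expression

DEFAULT_EXPRESSION_ROLES: Dict[str, str] = {
    "ccmK2": cx.ROLE_MCL_CCMK,
    "ccmK1": cx.ROLE_MCL_CCMK,
    "ccmL": cx.ROLE_MCL_CORE,
    "ccmM": cx.ROLE_MCL_CORE,
    "ccmN": cx.ROLE_MCL_CORE,
    "ccmO": cx.ROLE_SATELLITE_CCMO,
    "ccmK3": cx.ROLE_CCMK3,
    "ccmK4": cx.ROLE_CCMK4,
    "ccmP": cx.ROLE_CCMP,
    "rbcL": cx.ROLE_RBCL,
    "rbcS": cx.ROLE_RBCS,
}


def generate_expression(
    spec: ExpressionSpec,
    gene_roles: Optional[Dict[str, str]] = None,
    dataset_id: str = "sim",
    species_id: str = "sim_species",
) -> cx.ExpressionDataset:
    """Latent-factor expression matrix: ``x_g = b + sqrt(rho_g) f + sqrt(1-rho_g) e_g``.

    MCL-role genes share the factor with ``rho = mcl_rho``; any other role
    uses ``satellite_rho`` (default 0, i.e. independent noise).  Pairwise
    Pearson correlation between genes g and h is sqrt(rho_g * rho_h) in
    expectation.
    """
    gene_roles = dict(gene_roles or DEFAULT_EXPRESSION_ROLES)
    rng = np.random.default_rng(spec.seed)
    factor = rng.standard_normal(spec.n_conditions)
    data = {}
    for gene in gene_roles:  # insertion order: deterministic
        role = gene_roles[gene]
        rho = spec.mcl_rho if role in cx.MCL_ROLES else spec.satellite_rho.get(role, 0.0)
        noise = rng.standard_normal(spec.n_conditions)
        data[gene] = spec.baseline + np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise
    values = pd.DataFrame(
        data, index=[f"c{i:03d}" for i in range(spec.n_conditions)]
    ).T
    scale = cx.SCALE_LINEAR
    if spec.log2_output:
        shifted = values + spec.log2_shift
        if (shifted <= 0).any().any():
            raise SimulationError("log2 output requires positive shifted values; raise baseline")
        values = np.log2(shifted)
        scale = cx.SCALE_LOG2
    return cx.ExpressionDataset(
        dataset_id=dataset_id,
        species_id=species_id,
        scale=scale,
        values=values,
        gene_roles=gene_roles,
    )


# ---------------------------------------------------------------------------
# Cohort bundle (simulate CLI)

def simulate_cohort(
    cohort_spec: CohortSpec,
    expression_spec: Optional[ExpressionSpec] = None,
    out_dir: str = ".",
    n_sequences_per_class: int = 5,
    substitution_rate: float = 0.1,
) -> dict:
    """Write genes.tsv, proteins.fasta, expression.tsv and truth.json."""
    ensure_dir(out_dir)
    expression_spec = expression_spec or ExpressionSpec(seed=cohort_spec.seed)
    tables, truth = generate_genomes(cohort_spec)
    write_gene_table(tables, os.path.join(out_dir, "genes.tsv"))
    records, labels = generate_sequences(
        n_sequences_per_class, substitution_rate, seed=cohort_spec.seed
    )
    write_fasta(records, os.path.join(out_dir, "proteins.fasta"))
    dataset = generate_expression(expression_spec)
    with open(os.path.join(out_dir, "expression.tsv"), "w") as fh:
        fh.write(f"# scale={dataset.scale}\n")
        dataset.values.to_csv(fh, sep="\t", float_format="%.10g")
    truth["sequence_labels"] = labels
    truth["expression"] = {
        "mcl_rho": expression_spec.mcl_rho,
        "n_conditions": expression_spec.n_conditions,
        "gene_roles": dataset.gene_roles,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
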