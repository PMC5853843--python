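"""Desk-scale sequence utilities: identity, redundancy reduction, trimming,
p-distance neighbor joining with monophyly checks, and per-column
information content.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode

from .io_formats import AMINO_ACIDS, GAP_CHARS, ProteinRecord
from .profile_classifier import AA_INDEX, N_AA

log = logging.getLogger(__name__)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over positions where neither is a gap."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    matches = comparable = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        comparable += 1
        if ca == cb:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) positions")
    return matches / comparable


def p_distance(a: str, b: str) -> float:
    return 1.0 - pairwise_identity(a, b)


def reduce_redundancy(
    records: Sequence[ProteinRecord], threshold: float = 0.99
) -> List[ProteinRecord]:
    """Greedy redundancy filter in input order.

    A record is dropped when its identity to an already-kept record exceeds
    ``threshold``.  Greedy, hence order-dependent and non-transitive: in a
    chain A~B~C with A-C below threshold, both A and C survive.
    """
    kept: List[ProteinRecord] = []
    for rec in records:
        if any(pairwise_identity(rec.sequence, k.sequence) > threshold for k in kept):
            continue
        kept.append(rec)
    return kept


def trim_columns(
    records: Sequence[ProteinRecord], max_gap_fraction: float = 0.5
) -> Tuple[List[ProteinRecord], List[int]]:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    Returns the trimmed records plus the retained original column indices.
    """
    if not records:
        raise ValueError("empty alignment")
    width = len(records[0].sequence)
    n = len(records)
    keep = [
        j
        for j in range(width)
        if sum(1 for r in records if r.sequence[j] in GAP_CHARS) / n <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("all columns exceed the gap-fraction threshold")
    trimmed = [
        ProteinRecord(r.protein_id, r.genome_id, "".join(r.sequence[j] for j in keep))
        for r in records
    ]
    return trimmed, keep


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with taxon labels."""

    labels: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index.astype(str)), matrix=df.to_numpy())


def p_distance_matrix(records: Sequence[ProteinRecord]) -> DistanceMatrix:
    n = len(records)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = p_distance(records[i].sequence, records[j].sequence)
    return DistanceMatrix(labels=[r.protein_id for r in records], matrix=m)


def nj_tree(distances: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Backed by scikit-bio's NJ; negative branch lengths are clamped to zero
    (with a warning from the underlying implementation).
    """
    if len(distances.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = skbio.DistanceMatrix(distances.matrix, distances.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = skbio.tree.nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            log.warning("negative branch length %.4g clamped to 0", node.length)
            node.length = 0.0
    return str(tree).strip()


def _bipartitions(tree: TreeNode) -> List[frozenset]:
    """Tip-label sets of every clade below an edge of the (unrooted) tree."""
    out = []
    for node in tree.traverse(include_self=False):
        if not node.is_tip():
            out.append(frozenset(t.name for t in node.tips()))
    return out


def class_monophyly(
    newick: str, label_map: Dict[str, str]
) -> Dict[str, Tuple[bool, int]]:
    """Check which classes form monophyletic groups on an unrooted tree.

    ``label_map`` assigns a class to every leaf.  A class is monophyletic iff
    some edge bipartition isolates exactly its leaves (singletons trivially
    qualify).  Returns class -> (monophyletic, leaf count).
    """
    tree = TreeNode.read(io.StringIO(newick))
    tips = {t.name for t in tree.tips()}
    unlabeled = tips - set(label_map)
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {sorted(unlabeled)}")
    splits = _bipartitions(tree)
    complements = [frozenset(tips - s) for s in splits]
    result: Dict[str, Tuple[bool, int]] = {}
    for cls in sorted(set(label_map[t] for t in tips)):
        members = frozenset(t for t in tips if label_map[t] == cls)
        mono = len(members) == 1 or members in splits or members in complements
        result[cls] = (mono, len(members))
    return result


@dataclass
class ConservationProfile:
    """Per-column information content (bits) and residue letter heights."""

    information: np.ndarray  # (n_columns,)
    heights: np.ndarray  # (n_columns, 20), rows sum to information

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=list(AMINO_ACIDS))
        df.insert(0, "information", self.information)
        return df


def column_information(
    records: Sequence[ProteinRecord],
    background: Optional[np.ndarray] = None,
    pseudocount: float = 1.0,
) -> ConservationProfile:
    """Relative-entropy information content per alignment column.

    ``IC_j = sum_aa f_aa * log2(f_aa / bg_aa)`` with Laplace-smoothed
    frequencies; a residue's letter height is ``f_aa * IC_j``.
    """
    if not records:
        raise ValueError("empty alignment")
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    background = np.asarray(background, dtype=float)
    width = len(records[0].sequence)
    ic = np.zeros(width)
    heights = np.zeros((width, N_AA))
    for j in range(width):
        counts = np.zeros(N_AA)
        for r in records:
            idx = AA_INDEX.get(r.sequence[j])
            if idx is not None:
                counts[idx] += 1
        n = counts.sum()
        if n == 0:
            raise ValueError(f"column {j} has no residues")
        freq = (counts + pseudocount) / (n + N_AA * pseudocount)
        # zero-frequency residues (pseudocount 0) contribute 0 by convention
        safe = np.where(freq > 0, freq, 1.0)
        col_ic = float(np.sum(np.where(freq > 0, freq * np.log2(safe / background), 0.0)))
        col_ic = max(col_ic, 0.0)
        ic[j] = col_ic
        heights[j] = freq * col_ic
    return ConservationProfile(information=ic, heights=heights)
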