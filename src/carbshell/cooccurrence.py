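"""Genome coverage, observed/expected co-occurrence ratios and chi-squared tests.

Expected co-occurrence of two classes under independence is
``n_A * n_B / N`` genomes; the observed/expected ratio flags positive (>1)
or negative (<1) association, and an uncorrected Pearson chi-squared test on
the 2x2 presence table supplies significance stars.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneTableRow
from .locus_assembly import Locus
from .utils import round_half_away

log = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class PresenceMatrix:
    """Binary genome x class presence matrix."""

    genomes: List[str]
    classes: List[str]
    values: np.ndarray  # (n_genomes, n_classes) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.genomes), len(self.classes)):
            raise ValueError("presence matrix shape mismatch")

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def column(self, class_name: str) -> np.ndarray:
        return self.values[:, self.classes.index(class_name)]

    @classmethod
    def from_gene_tables(
        cls, tables: Dict[str, List[GeneTableRow]], classes: Sequence[str]
    ) -> "PresenceMatrix":
        genomes = sorted(tables)
        values = np.zeros((len(genomes), len(classes)), dtype=bool)
        for i, genome_id in enumerate(genomes):
            labels = {r.label for r in tables[genome_id]}
            for j, cl in enumerate(classes):
                values[i, j] = cl in labels
        return cls(genomes=genomes, classes=list(classes), values=values)

    @classmethod
    def from_loci(
        cls, per_genome: Dict[str, List[Locus]], classes: Sequence[str]
    ) -> "PresenceMatrix":
        genomes = sorted(per_genome)
        values = np.zeros((len(genomes), len(classes)), dtype=bool)
        for i, genome_id in enumerate(genomes):
            labels = {r.label for locus in per_genome[genome_id] for r in locus.all_members}
            for j, cl in enumerate(classes):
                values[i, j] = cl in labels
        return cls(genomes=genomes, classes=list(classes), values=values)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceMatrix":
        return cls(
            genomes=list(frame.index.astype(str)),
            classes=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=bool),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.astype(int), index=self.genomes, columns=self.classes)


def coverage(matrix: PresenceMatrix) -> Dict[str, Tuple[int, float]]:
    """Per-class genome coverage as (count, percent to 1 dp)."""
    if matrix.n_genomes == 0:
        raise ValueError("empty presence matrix")
    out: Dict[str, Tuple[int, float]] = {}
    for cl in matrix.classes:
        n_c = int(matrix.column(cl).sum())
        out[cl] = (n_c, round_half_away(100.0 * n_c / matrix.n_genomes, 1))
    return out


def expected_cooccurrence(n_a: int, n_b: int, n_genomes: int) -> float:
    """Expected number of genomes with both classes under independence."""
    if n_genomes <= 0:
        raise ValueError("n_genomes must be positive")
    if not (0 <= n_a <= n_genomes and 0 <= n_b <= n_genomes):
        raise ValueError("coverages must lie in [0, n_genomes]")
    return n_a * n_b / n_genomes


def ratio(observed: int, expected: float) -> Optional[float]:
    """Observed/expected ratio to 2 dp; None (NA) when expected is 0."""
    if expected < 0:
        raise ValueError("expected must be non-negative")
    if expected == 0:
        return None
    return round_half_away(observed / expected, 2)


def stars_from_p(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def chisq_pair(
    matrix: PresenceMatrix, class_a: str, class_b: str
) -> Tuple[Optional[float], Optional[float], str]:
    """Pearson chi-squared (df=1, no continuity correction) on a class pair.

    Returns (chi2, p, stars); (None, None, "NA") when a margin is degenerate
    (a class present in 0% or 100% of genomes).
    """
    a_col = matrix.column(class_a)
    b_col = matrix.column(class_b)
    table = np.array(
        [
            [int((a_col & b_col).sum()), int((a_col & ~b_col).sum())],
            [int((~a_col & b_col).sum()), int((~a_col & ~b_col).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("degenerate margin for pair (%s, %s): chi2 undefined", class_a, class_b)
        return None, None, "NA"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), stars_from_p(float(p))


@dataclass
class CooccurrenceResult:
    n_genomes: int
    coverage: Dict[str, Tuple[int, float]]
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.pairs

    def to_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "coverage": {k: {"n": n, "percent": pct} for k, (n, pct) in self.coverage.items()},
            "pairs": self.pairs.to_dict(orient="records"),
        }


def pairwise_table(matrix: PresenceMatrix) -> CooccurrenceResult:
    """Full coverage + pairwise observed/expected/ratio/chi2 result."""
    cov = coverage(matrix)
    rows = []
    for class_a, class_b in itertools.combinations(matrix.classes, 2):
        n_a, _ = cov[class_a]
        n_b, _ = cov[class_b]
        observed = int((matrix.column(class_a) & matrix.column(class_b)).sum())
        expected = expected_cooccurrence(n_a, n_b, matrix.n_genomes)
        chi2, p, stars = chisq_pair(matrix, class_a, class_b)
        rows.append(
            {
                "class_a": class_a,
                "class_b": class_b,
                "n_a": n_a,
                "n_b": n_b,
                "observed": observed,
                "expected": expected,
                "ratio": ratio(observed, expected),
                "chi2": chi2,
                "p": p,
                "stars": stars,
            }
        )
    return CooccurrenceResult(n_genomes=matrix.n_genomes, coverage=cov, pairs=pd.DataFrame(rows))


def venn_counts(matrix: PresenceMatrix, classes: Sequence[str]) -> Dict[Tuple[bool, ...], int]:
    """Genome counts for every region of the class-combination lattice.

    Keys are presence patterns aligned with ``classes``; values sum to the
    number of genomes.
    """
    if len(classes) > 6:
        raise ValueError("venn_counts supports at most 6 classes")
    cols = [matrix.column(cl) for cl in classes]
    counts: Dict[Tuple[bool, ...], int] = {}
    for pattern in itertools.product((False, True), repeat=len(classes)):
        mask = np.ones(matrix.n_genomes, dtype=bool)
        for col, present in zip(cols, pattern):
            mask &= col if present else ~col
        counts[pattern] = int(mask.sum())
    return counts
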