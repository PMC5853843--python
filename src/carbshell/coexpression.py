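"""Co-regulation of focal shell genes with main-locus genes from expression data.

The statistic per dataset is the mean pairwise Pearson correlation of each
focal gene (ccmO, ccmK1/2, ccmK3/4 or rbcL) with the main-locus (MCL) genes,
averaged over the focal set.  Datasets are then aggregated by the genomic
position of ccmO in the source species (in-MCL vs satellite).

Log2-scaled matrices are linearized before any correlation is computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .utils import round_half_away

log = logging.getLogger(__name__)

SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"

ROLE_MCL_CCMK = "MCL_ccmK"
ROLE_MCL_CORE = "MCL_core"  # ccmL / ccmM / ccmN
ROLE_MCL_CCMO = "MCL_ccmO"
ROLE_SATELLITE_CCMO = "satellite_ccmO"
ROLE_CCMK3 = "ccmK3"
ROLE_CCMK4 = "ccmK4"
ROLE_CCMP = "ccmP"
ROLE_RBCL = "rbcL"
ROLE_RBCS = "rbcS"
ROLE_OTHER = "other"

MCL_ROLES = {ROLE_MCL_CCMK, ROLE_MCL_CORE, ROLE_MCL_CCMO}
RUBISCO_ROLES = {ROLE_RBCL, ROLE_RBCS}


@dataclass
class ExpressionDataset:
    """A genes x conditions matrix with per-gene roles."""

    dataset_id: str
    species_id: str
    scale: str
    values: pd.DataFrame
    gene_roles: Dict[str, str]

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_LINEAR, SCALE_LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.shape[1] < 3:
            raise ValueError("expression dataset needs at least 3 conditions")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def genes_with_role(self, roles: Iterable[str]) -> List[str]:
        roles = set(roles)
        return [g for g in self.values.index if self.gene_roles.get(g, ROLE_OTHER) in roles]

    @property
    def ccmO_position(self) -> str:
        if self.genes_with_role({ROLE_MCL_CCMO}):
            return "mcl"
        if self.genes_with_role({ROLE_SATELLITE_CCMO}):
            return "satellite"
        return "absent"


def linearize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Undo a log2 transform (identity for linear-scale data)."""
    if dataset.scale == SCALE_LINEAR:
        return dataset
    return replace(dataset, values=np.exp2(dataset.values), scale=SCALE_LINEAR)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (with a warning) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 conditions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("zero-variance vector: Pearson undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def mean_corr_with_mcl(
    dataset: ExpressionDataset,
    focal_genes: Sequence[str],
    mcl_genes: Sequence[str],
    exclude: Iterable[str] = (),
) -> float:
    """Mean Pearson correlation of a focal gene set with MCL genes.

    For each focal gene, partners are the MCL genes minus the focal set,
    minus anything in ``exclude``; per-focal means are then averaged.
    Missing genes are skipped with an adjusted divisor.
    """
    data = linearize(dataset).values
    excluded = set(exclude) | set(focal_genes)
    focal_means: List[float] = []
    for f in focal_genes:
        if f not in data.index:
            log.warning("%s: focal gene %s missing, skipped", dataset.dataset_id, f)
            continue
        rs = []
        for m in mcl_genes:
            if m in excluded:
                continue
            if m not in data.index:
                log.warning("%s: MCL gene %s missing, skipped", dataset.dataset_id, m)
                continue
            r = pearson(data.loc[f], data.loc[m])
            if not np.isnan(r):
                rs.append(r)
        if rs:
            focal_means.append(float(np.mean(rs)))
    if not focal_means:
        raise ValueError(f"{dataset.dataset_id}: no usable focal/MCL gene pairs")
    return float(np.mean(focal_means))


@dataclass
class CorrelationSummary:
    """Per-dataset mean correlations of the standard focal sets with the MCL."""

    dataset_id: str
    species_id: str
    ccmO_position: str
    values: Dict[str, float] = field(default_factory=dict)  # focal set -> mean r

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "species_id": self.species_id,
            "ccmO_position": self.ccmO_position,
            **self.values,
        }


def summarize_dataset(dataset: ExpressionDataset, include_rbcL: bool = False) -> CorrelationSummary:
    """Compute the Table-style focal-set correlations for one dataset.

    Focal sets: ccmO (vs MCL ccmKs + ccmL/M/N), ccmK1/2 and ccmK3/4 (vs all
    remaining MCL genes except RubisCO genes), optionally rbcL.
    """
    ds = linearize(dataset)
    mcl_k = ds.genes_with_role({ROLE_MCL_CCMK})
    mcl_core = ds.genes_with_role({ROLE_MCL_CORE})
    mcl_all = ds.genes_with_role(MCL_ROLES)
    rubisco = ds.genes_with_role(RUBISCO_ROLES)
    values: Dict[str, float] = {}

    ccmO = ds.genes_with_role({ROLE_MCL_CCMO, ROLE_SATELLITE_CCMO})
    if ccmO:
        values["ccmO"] = mean_corr_with_mcl(ds, ccmO, mcl_k + mcl_core)
    if mcl_k:
        values["ccmK12"] = mean_corr_with_mcl(ds, mcl_k, mcl_all, exclude=rubisco)
    k34 = ds.genes_with_role({ROLE_CCMK3, ROLE_CCMK4})
    if k34:
        values["ccmK34"] = mean_corr_with_mcl(ds, k34, mcl_all, exclude=rubisco)
    if include_rbcL:
        rbcL = ds.genes_with_role({ROLE_RBCL})
        if rbcL:
            values["rbcL"] = mean_corr_with_mcl(ds, rbcL, mcl_all, exclude=rubisco)
    return CorrelationSummary(
        dataset_id=ds.dataset_id,
        species_id=ds.species_id,
        ccmO_position=ds.ccmO_position,
        values=values,
    )


def aggregate_groups(
    summaries: Sequence[CorrelationSummary],
    grouping: Optional[Dict[str, str]] = None,
) -> Dict[str, Optional[float]]:
    """Aggregate per-dataset values into the headline group means (2 dp).

    ``grouping`` maps dataset_id to "mcl"/"satellite" and defaults to each
    summary's own ccmO position.  Keys: ccmO_mcl_mean, ccmO_satellite_mean,
    ccmK12_overall_mean, ccmK34_overall_mean.
    """

    def _mean(vals: List[float]) -> Optional[float]:
        if not vals:
            return None
        return round_half_away(float(np.mean(vals)), 2)

    mcl_vals, sat_vals, k12_vals, k34_vals = [], [], [], []
    for s in summaries:
        group = (grouping or {}).get(s.dataset_id, s.ccmO_position)
        if "ccmO" in s.values:
            if group == "mcl":
                mcl_vals.append(s.values["ccmO"])
            elif group == "satellite":
                sat_vals.append(s.values["ccmO"])
        if "ccmK12" in s.values:
            k12_vals.append(s.values["ccmK12"])
        if "ccmK34" in s.values:
            k34_vals.append(s.values["ccmK34"])
    return {
        "ccmO_mcl_mean": _mean(mcl_vals),
        "ccmO_satellite_mean": _mean(sat_vals),
        "ccmK12_overall_mean": _mean(k12_vals),
        "ccmK34_overall_mean": _mean(k34_vals),
    }


@dataclass
class CorrelationReport:
    """Round-trippable container for the coexpress CLI output."""

    summaries: List[CorrelationSummary]
    aggregates: Dict[str, Optional[float]]

    def to_dict(self) -> dict:
        return {
            "datasets": {s.dataset_id: s.to_dict() for s in self.summaries},
            "aggregates": self.aggregates,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_dict() for s in self.summaries])


def read_expression_tsv(
    path: str,
    roles_path: str,
    dataset_id: str = "dataset",
    species_id: str = "species",
    scale: str = SCALE_LINEAR,
) -> ExpressionDataset:
    """Read a genes x conditions TSV (first column gene id) plus a roles TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    roles_df = pd.read_csv(roles_path, sep="\t", comment="#")
    roles = dict(zip(roles_df.iloc[:, 0].astype(str), roles_df.iloc[:, 1].astype(str)))
    return ExpressionDataset(
        dataset_id=dataset_id,
        species_id=species_id,
        scale=scale,
        values=values,
        gene_roles=roles,
    )
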