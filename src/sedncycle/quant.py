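"""From alignment tables to per-cell gene and transcript profiles.

The counting chain is: filter alignments (identity and aligned-length
cutoffs) -> count inserts per gene (unique inserts count 1; ambiguously
mapped inserts are split across their targets in proportion to the targets'
unique insert counts) -> divide by gene length -> optionally aggregate to
KEGG Orthologies -> divide by the median abundance of the single-copy
marker genes to obtain genes/cell (metagenome) or transcripts/cell
(metatranscriptome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog

__all__ = [
    "AlignmentRow",
    "CountProfile",
    "AbundanceProfile",
    "PerCellProfile",
    "filter_alignments",
    "count_inserts",
    "length_normalize",
    "aggregate_ko",
    "per_cell_normalize",
    "read_alignment_table",
    "write_alignment_table",
    "write_profile_matrix",
    "read_profile_matrix",
    "IDENTITY_MIN",
    "ALIGNED_BASES_MIN",
    "MARKER_COUNT",
]

# Alignment-retention cutoffs (inclusive).
IDENTITY_MIN = 95.0
ALIGNED_BASES_MIN = 45
# Number of universal single-copy marker genes backing the per-cell unit.
MARKER_COUNT = 10

ALIGNMENT_COLUMNS = ["sample_id", "insert_id", "gene_id", "pct_id", "aligned_bases"]


@dataclass(frozen=True)
class AlignmentRow:
    """One insert-to-gene alignment."""

    insert_id: str
    gene_id: str
    percent_identity: float
    aligned_bases: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )
        if self.aligned_bases < 1:
            raise ValueError(f"aligned_bases must be >= 1, got {self.aligned_bases}")


@dataclass
class CountProfile:
    """Fractional insert counts per gene for one sample and omic layer."""

    sample_id: str
    layer: Literal["metaG", "metaT"]
    counts: pd.Series  # gene_id -> fractional insert count
    n_inserts: int  # distinct inserts counted (after filtering)
    n_discarded: int = 0  # ambiguous inserts dropped under the "discard" policy


@dataclass
class AbundanceProfile:
    """Length-normalized abundances (counts per base), by gene or KO."""

    sample_id: str
    layer: str
    values: pd.Series
    key: Literal["gene", "ko"] = "gene"
    unannotated_mass: float = 0.0  # summed abundance of KO-less genes (KO view only)


@dataclass
class PerCellProfile:
    """Per-cell copy numbers: abundance / median marker abundance."""

    sample_id: str
    layer: str
    values: pd.Series
    marker_median: float
    key: str = "gene"


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame(
        {
            "insert_id": [r.insert_id for r in rows],
            "gene_id": [r.gene_id for r in rows],
            "pct_id": [r.percent_identity for r in rows],
            "aligned_bases": [r.aligned_bases for r in rows],
        }
    )


def filter_alignments(
    rows,
    *,
    min_identity: float = IDENTITY_MIN,
    min_aligned_bases: int = ALIGNED_BASES_MIN,
):
    """Retain alignments with identity and aligned length at or above the cutoffs.

    Accepts a list of :class:`AlignmentRow` (returns a list) or a DataFrame
    with ``pct_id`` and ``aligned_bases`` columns (returns a DataFrame).
    Both cutoffs are inclusive.
    """
    if isinstance(rows, pd.DataFrame):
        keep = (rows["pct_id"] >= min_identity) & (
            rows["aligned_bases"] >= min_aligned_bases
        )
        return rows.loc[keep]
    return [
        r
        for r in rows
        if r.percent_identity >= min_identity and r.aligned_bases >= min_aligned_bases
    ]


def count_inserts(
    rows,
    *,
    sample_id: str = "",
    layer: Literal["metaG", "metaT"] = "metaG",
    zero_unique_policy: Literal["split_equal", "discard"] = "split_equal",
) -> CountProfile:
    """Count inserts per gene with unique-proportional allocation.

    An insert aligning to exactly one gene ("unique") contributes a count of
    1 to that gene.  An insert aligning to several genes ("ambiguous")
    distributes its single count across those genes in proportion to the
    genes' unique insert counts, computed once (no iteration).  If none of
    its targets has a unique count the insert is split equally
    (``zero_unique_policy="split_equal"``, default) or dropped
    (``"discard"``).  Repeated (insert, gene) pairs are deduplicated with a
    warning.  The summed counts equal the number of distinct inserts kept.
    """
    df = _as_frame(rows)
    if df.empty:
        return CountProfile(sample_id, layer, pd.Series(dtype=float), 0)

    pairs = df[["insert_id", "gene_id"]]
    if pairs.duplicated().any():
        n_dup = int(pairs.duplicated().sum())
        warnings.warn(f"deduplicated {n_dup} repeated (insert, gene) pairs")
        pairs = pairs.drop_duplicates()

    n_targets = pairs.groupby("insert_id", sort=False)["gene_id"].transform("size")
    unique_pairs = pairs.loc[n_targets == 1]
    ambiguous = pairs.loc[n_targets > 1].copy()

    unique_counts = unique_pairs.groupby("gene_id", sort=False).size().astype(float)
    counts = unique_counts.copy()

    n_discarded = 0
    if not ambiguous.empty:
        ambiguous["u"] = (
            ambiguous["gene_id"].map(unique_counts).fillna(0.0).astype(float)
        )
        total_u = ambiguous.groupby("insert_id", sort=False)["u"].transform("sum")
        size = ambiguous.groupby("insert_id", sort=False)["u"].transform("size")
        weight = np.where(total_u > 0, ambiguous["u"] / total_u, 1.0 / size)
        if zero_unique_policy == "discard":
            keep = total_u > 0
            n_discarded = int(
                ambiguous.loc[~keep, "insert_id"].nunique()
            )
            ambiguous = ambiguous.loc[keep]
            weight = weight[keep.to_numpy()]
        elif zero_unique_policy != "split_equal":
            raise ValueError(f"unknown zero_unique_policy: {zero_unique_policy!r}")
        frac = (
            pd.Series(weight, index=ambiguous["gene_id"].to_numpy())
            .groupby(level=0, sort=False)
            .sum()
        )
        counts = counts.add(frac, fill_value=0.0)

    n_inserts = int(pairs["insert_id"].nunique()) - n_discarded
    counts.index.name = "gene_id"
    return CountProfile(sample_id, layer, counts, n_inserts, n_discarded)


def length_normalize(profile: CountProfile, catalog: GeneCatalog) -> AbundanceProfile:
    """Divide each gene's insert count by its length (counts per base)."""
    missing = [g for g in profile.counts.index if g not in catalog]
    if missing:
        raise KeyError(f"gene(s) absent from catalog: {missing[:5]}")
    lengths = pd.Series(
        {g: float(catalog[g].length_bp) for g in profile.counts.index}
    )
    values = profile.counts / lengths
    return AbundanceProfile(profile.sample_id, profile.layer, values, key="gene")


def aggregate_ko(profile: AbundanceProfile, catalog: GeneCatalog) -> AbundanceProfile:
    """Sum gene abundances over shared KEGG Orthologies.

    Genes without a KO are excluded from the output; their summed abundance
    is reported in ``unannotated_mass``.
    """
    kos = {g: catalog[g].ko_id for g in profile.values.index if g in catalog}
    annotated = {g: k for g, k in kos.items() if k is not None}
    mask = profile.values.index.isin(annotated)
    unannotated_mass = float(profile.values[~mask].sum())
    if not annotated:
        return AbundanceProfile(
            profile.sample_id,
            profile.layer,
            pd.Series(dtype=float),
            key="ko",
            unannotated_mass=unannotated_mass,
        )
    sub = profile.values[mask]
    ko_index = pd.Index([annotated[g] for g in sub.index], name="ko_id")
    ko_values = sub.groupby(ko_index).sum().sort_index()
    return AbundanceProfile(
        profile.sample_id,
        profile.layer,
        ko_values,
        key="ko",
        unannotated_mass=unannotated_mass,
    )


def per_cell_normalize(
    profile: AbundanceProfile,
    marker_abundances: Sequence[float] | pd.Series,
    *,
    expected_markers: int = MARKER_COUNT,
    allow_partial: bool = False,
) -> PerCellProfile:
    """Convert abundances to per-cell copy numbers.

    Divides every abundance by the median of the single-copy marker gene
    abundances (the "per cell" denominator).  Exactly ``expected_markers``
    marker values are required unless ``allow_partial`` (then a warning is
    issued).  The median uses the standard midpoint rule for even counts.
    """
    markers = np.asarray(marker_abundances, dtype=float)
    if len(markers) != expected_markers:
        msg = (
            f"expected {expected_markers} marker abundances, got {len(markers)}"
        )
        if not allow_partial or len(markers) == 0:
            raise ValueError(msg)
        warnings.warn(msg + "; proceeding with partial marker set")
    m = float(np.median(markers))
    if m <= 0:
        raise ValueError("marker median zero")
    return PerCellProfile(
        profile.sample_id,
        profile.layer,
        profile.values / m,
        marker_median=m,
        key=profile.key,
    )


# ---------------------------------------------------------------------------
# TSV I/O (12 significant digits round-trips losslessly for these magnitudes)

def read_alignment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "insert_id": str})
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table {path}: missing columns {missing}")
    return df


def write_alignment_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_profile_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a features x samples profile matrix as TSV (12 significant digits)."""
    matrix.to_csv(path, sep="\t", float_format="%.12g", index_label="feature_id")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
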