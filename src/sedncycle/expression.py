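"""Expression scores, log2 transforms, pathway summaries, and classification.

The expression score of a gene (or KO) is the ratio of its per-cell
transcript abundance (metatranscriptome) to its per-cell gene abundance
(metagenome): the relative number of transcripts per gene copy.  Pathway
summaries average per-cell abundances, transcript abundances, and
expression scores over the genes of each N-transformation process, and the
genomic-potential classification splits lakes at a mean N-transformation
gene abundance of 0.006 genes/cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ANAMMOX_GENES, GeneCatalog, PathwayMap, PROCESSES, UNANNOTATED
from .quant import PerCellProfile

__all__ = [
    "ExpressionProfile",
    "PathwaySummary",
    "expression_score",
    "log2_transform",
    "pathway_summary",
    "classify_potential",
    "anammox_complete",
    "POTENTIAL_THRESHOLD",
]

#: Genes/cell threshold separating high from low N-transformation potential.
POTENTIAL_THRESHOLD = 0.006


@dataclass
class ExpressionProfile:
    """Transcripts per gene copy, with orphan transcription kept separate.

    ``values`` holds metaT/metaG ratios for keys where the metagenomic
    per-cell abundance is positive.  Keys with transcripts but no detected
    gene copies ("orphan transcription") are reported in ``orphans`` rather
    than folded into a ratio; keys absent from both layers are omitted.
    """

    sample_id: str
    values: pd.Series
    orphans: pd.Series
    key: str = "gene"

    def log2(self) -> pd.Series:
        transformed, _ = log2_transform(self.values)
        return transformed


def expression_score(
    metaG: PerCellProfile, metaT: PerCellProfile
) -> ExpressionProfile:
    """Compute transcripts-per-gene-copy ratios from matched per-cell profiles."""
    g = metaG.values
    t = metaT.values
    keys = g.index.union(t.index)
    g = g.reindex(keys, fill_value=0.0)
    t = t.reindex(keys, fill_value=0.0)
    expressed = g > 0
    orphan = (~expressed) & (t > 0)
    values = (t[expressed] / g[expressed]).rename("expression")
    orphans = t[orphan].rename("orphan_transcripts")
    return ExpressionProfile(metaG.sample_id, values, orphans, key=metaG.key)


def log2_transform(
    profile: pd.Series | pd.DataFrame,
    *,
    zero_policy: str = "half_min_positive",
    pseudocount: float | None = None,
) -> tuple[pd.Series | pd.DataFrame, dict]:
    """log2-transform a non-negative profile, handling zeros by policy.

    Policies:
      - ``half_min_positive`` (default): zeros are replaced by half the
        smallest positive value in the table before taking log2.
      - ``pseudocount``: ``log2(x + pseudocount)`` everywhere.
      - ``drop``: zeros become NaN.

    Returns the transformed table and a metadata dict recording the policy
    and any replacement value used.
    """
    values = np.asarray(profile, dtype=float)
    if np.any(values < 0):
        raise ValueError("log2_transform requires non-negative input")
    meta: dict = {"zero_policy": zero_policy}
    if zero_policy == "half_min_positive":
        positives = values[values > 0]
        if positives.size == 0:
            raise ValueError("no positive values to anchor the zero replacement")
        repl = positives.min() / 2.0
        meta["zero_replacement"] = float(repl)
        out = np.log2(np.where(values > 0, values, repl))
    elif zero_policy == "pseudocount":
        if pseudocount is None or pseudocount <= 0:
            raise ValueError("pseudocount policy requires a positive pseudocount")
        meta["pseudocount"] = float(pseudocount)
        out = np.log2(values + pseudocount)
    elif zero_policy == "drop":
        out = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)), np.nan)
    else:
        raise ValueError(f"unknown zero policy: {zero_policy!r}")
    if isinstance(profile, pd.DataFrame):
        return pd.DataFrame(out, index=profile.index, columns=profile.columns), meta
    if isinstance(profile, pd.Series):
        return pd.Series(out, index=profile.index, name=profile.name), meta
    return out, meta


@dataclass
class PathwaySummary:
    """Per-process means of per-cell abundance, transcription, and expression.

    ``abundance`` and ``transcription`` are means over *all* catalog genes
    of the process (zeros included); ``expression`` is averaged over
    detected genes only, with the number of detected genes reported in
    ``n_detected``.  Dual NO3<->NO2 genes are counted once, under their
    dedicated process.
    """

    abundance: pd.DataFrame  # process x sample, genes/cell
    transcription: pd.DataFrame  # process x sample, transcripts/cell
    expression: pd.DataFrame  # process x sample, transcripts per gene copy
    n_detected: pd.DataFrame  # process x sample, genes with expression defined
    lake_abundance: pd.DataFrame | None = None  # process x lake means
    detected: pd.DataFrame | None = None  # process x sample, any gene detected


def _process_index(catalog: GeneCatalog, pathway_map: PathwayMap) -> pd.Series:
    """Map each catalog gene to its reporting process via its symbol."""
    return pd.Series(
        {r.gene_id: pathway_map.process_of(r.gene_symbol) for r in catalog}
    )


def pathway_summary(
    metaG: pd.DataFrame,
    metaT: pd.DataFrame,
    catalog: GeneCatalog,
    pathway_map: PathwayMap,
    *,
    sample_to_lake: dict[str, str] | None = None,
) -> PathwaySummary:
    """Summarize per-cell profiles (genes x samples) per N process.

    ``metaG`` and ``metaT`` are genes x samples matrices of per-cell
    abundances.  Genes not mapping to an N process are ignored.
    """
    procs = _process_index(catalog, pathway_map)
    n_genes = procs[procs != UNANNOTATED]

    def _proc_mean(mat: pd.DataFrame) -> pd.DataFrame:
        mat = mat.reindex(n_genes.index, fill_value=0.0)
        out = mat.groupby(n_genes).mean()
        return out.reindex(list(PROCESSES), fill_value=0.0)

    abundance = _proc_mean(metaG)
    transcription = _proc_mean(metaT)

    g = metaG.reindex(n_genes.index, fill_value=0.0)
    t = metaT.reindex(n_genes.index, fill_value=0.0)
    ratio = t.where(g > 0) / g.where(g > 0)
    grouped = ratio.groupby(n_genes)
    expression = grouped.mean().reindex(list(PROCESSES))
    n_detected = grouped.count().reindex(list(PROCESSES), fill_value=0)
    expression = expression.fillna(0.0)
    detected = (g.groupby(n_genes).sum() > 0).reindex(list(PROCESSES), fill_value=False)

    lake_abundance = None
    if sample_to_lake is not None:
        lakes = pd.Series(sample_to_lake)
        lake_abundance = abundance.T.groupby(lakes).mean().T
    return PathwaySummary(
        abundance, transcription, expression, n_detected, lake_abundance, detected
    )


def classify_potential(
    lake_means: pd.Series | dict[str, float],
    threshold: float = POTENTIAL_THRESHOLD,
) -> pd.Series:
    """Classify lakes as high/low N-transformation potential.

    ``lake_means`` holds, per lake, the mean per-cell abundance over all
    N-transformation genes.  A lake is "high" iff its mean strictly exceeds
    the threshold (default 0.006 genes/cell).
    """
    s = pd.Series(lake_means, dtype=float)
    return pd.Series(
        np.where(s > threshold, "high", "low"), index=s.index, name="potential"
    )


def anammox_complete(
    transcripts: pd.Series | dict[str, float],
    *,
    gene_set: tuple[str, ...] = ANAMMOX_GENES,
) -> bool:
    """True iff every anammox-pathway gene has detected transcripts.

    ``transcripts`` maps gene symbols to per-cell transcript abundances for
    one sample.  With a non-default gene set a warning is issued so that
    completeness claims remain comparable across runs.
    """
    if tuple(gene_set) != ANAMMOX_GENES:
        warnings.warn(
            f"non-default anammox gene set {gene_set}; completeness is relative to it"
        )
    t = pd.Series(transcripts, dtype=float)
    return all(t.get(g, 0.0) > 0 for g in gene_set)
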