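"""Gene catalog, nitrogen-pathway map, and KEGG annotation filtering.

The catalog holds the representative genes of a metagenomic gene catalog
(one record per gene: length, optional KO annotation, optional N-pathway
assignment, and a flag marking the universal single-copy marker genes used
for per-cell normalization).  Annotation filtering applies the subject
coverage / relative bit-score rule used when assigning KOs to genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneCatalog",
    "AnnotationHit",
    "PathwayMap",
    "PathwayAssignment",
    "read_catalog",
    "write_catalog",
    "filter_annotations",
    "default_pathway_map",
    "NITRIFICATION",
    "NITRATE_NITRITE",
    "NITRATE_REDUCTION",
    "DENITRIFICATION",
    "DNRA",
    "ANAMMOX",
    "PROCESSES",
    "UNANNOTATED",
]

# N-transformation process labels
NITRIFICATION = "nitrification"
NITRATE_NITRITE = "NO3<->NO2"  # dual narGH / nxrAB genes
NITRATE_REDUCTION = "nitrate_reduction"
DENITRIFICATION = "denitrification"
DNRA = "DNRA"
ANAMMOX = "anammox"
PROCESSES = (
    NITRIFICATION,
    NITRATE_NITRITE,
    NITRATE_REDUCTION,
    DENITRIFICATION,
    DNRA,
    ANAMMOX,
)
UNANNOTATED = "unannotated"

# Default subject-coverage and relative bit-score cutoffs for KO assignment.
SUBJECT_COVERAGE_MIN = 0.70
BITSCORE_FRACTION_MIN = 0.50


@dataclass(frozen=True)
class GeneRecord:
    """One representative gene of the catalog."""

    gene_id: str
    length_bp: int
    ko_id: str | None = None
    gene_symbol: str | None = None
    pathway: str | None = None
    is_marker: bool = False

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )
        if self.is_marker and self.pathway is not None:
            raise ValueError(
                f"gene {self.gene_id!r}: a single-copy marker gene cannot carry "
                f"an N-pathway label ({self.pathway!r})"
            )


class GeneCatalog:
    """Collection of :class:`GeneRecord` with unique gene ids."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise ValueError(f"duplicate gene_id in catalog: {rec.gene_id!r}")
            self._records[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    def __iter__(self):
        return iter(self._records.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    def markers(self) -> list[GeneRecord]:
        """The single-copy marker genes (per-cell normalization denominators)."""
        return [r for r in self if r.is_marker]

    def lengths(self) -> pd.Series:
        return pd.Series(
            {r.gene_id: r.length_bp for r in self}, name="length_bp", dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self],
                "length_bp": [r.length_bp for r in self],
                "ko_id": [r.ko_id for r in self],
                "gene_symbol": [r.gene_symbol for r in self],
                "pathway": [r.pathway for r in self],
                "is_marker": [r.is_marker for r in self],
            }
        )


def read_catalog(path: str | Path) -> GeneCatalog:
    """Read a gene catalog from a UTF-8 TSV file.

    Required columns: ``gene_id``, ``length_bp``.  Optional: ``ko_id``,
    ``gene_symbol``, ``pathway``, ``is_marker``.  Missing annotation fields
    become ``None`` (unannotated).  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"catalog {path}: missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _opt(key):
            v = d.get(key)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return None
            return str(v)

        is_marker = d.get("is_marker", False)
        if isinstance(is_marker, str):
            is_marker = is_marker.strip().lower() in {"1", "true", "yes"}
        records.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                length_bp=int(d["length_bp"]),
                ko_id=_opt("ko_id"),
                gene_symbol=_opt("gene_symbol"),
                pathway=_opt("pathway"),
                is_marker=bool(is_marker),
            )
        )
    return GeneCatalog(records)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    df = catalog.to_frame()
    df["is_marker"] = df["is_marker"].astype(int)
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnnotationHit:
    """A candidate gene -> KO alignment hit against the reference database."""

    gene_id: str
    ko_id: str
    subject_coverage: float  # fraction of subject covered, 0..1
    bit_score: float
    max_expected_bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.subject_coverage <= 1.0:
            raise ValueError(
                f"subject_coverage must be in [0, 1], got {self.subject_coverage}"
            )
        if self.max_expected_bit_score <= 0:
            raise ValueError("max_expected_bit_score must be positive")
        if self.bit_score < 0:
            raise ValueError("bit_score must be non-negative")


def filter_annotations(
    hits: Sequence[AnnotationHit],
    *,
    min_subject_coverage: float = SUBJECT_COVERAGE_MIN,
    min_bitscore_fraction: float = BITSCORE_FRACTION_MIN,
) -> dict[str, str]:
    """Filter annotation hits and pick one KO per gene.

    A hit is accepted iff ``subject_coverage >= min_subject_coverage`` and
    ``bit_score >= min_bitscore_fraction * max_expected_bit_score`` (both
    inclusive).  Among accepted hits of a gene the best bit score wins;
    exact ties are broken by the lexicographically smallest KO id so the
    result is deterministic.
    """
    best: dict[str, AnnotationHit] = {}
    for hit in hits:
        if hit.subject_coverage < min_subject_coverage:
            continue
        if hit.bit_score < min_bitscore_fraction * hit.max_expected_bit_score:
            continue
        cur = best.get(hit.gene_id)
        if (
            cur is None
            or hit.bit_score > cur.bit_score
            or (hit.bit_score == cur.bit_score and hit.ko_id < cur.ko_id)
        ):
            best[hit.gene_id] = hit
    return {g: h.ko_id for g, h in best.items()}


@dataclass(frozen=True)
class PathwayAssignment:
    """Pathway lookup result: the reporting process plus candidate processes."""

    process: str
    candidates: tuple[str, ...]
    dual: bool = False


# Gene symbol -> process.  The narG;nxrA and narH;nxrB subunits share KOs
# between nitrate reductase and nitrite oxidoreductase and are reported under
# the dedicated NO3<->NO2 process rather than double-counted.
_DEFAULT_SYMBOLS: dict[str, PathwayAssignment] = {}


def _add(symbols: Iterable[str], process: str) -> None:
    for s in symbols:
        _DEFAULT_SYMBOLS[s] = PathwayAssignment(process, (process,), dual=False)


_add(["amoA", "amoB", "amoC", "hao"], NITRIFICATION)
_add(["napA", "napB", "narI"], NITRATE_REDUCTION)
_add(["nirS", "nirK", "norB", "norC", "nosZ"], DENITRIFICATION)
_add(["nrfA", "nrfH"], DNRA)
_add(["hzsA", "hzsB", "hzsC", "hdh"], ANAMMOX)
for _sym in ("narG;nxrA", "narH;nxrB"):
    _DEFAULT_SYMBOLS[_sym] = PathwayAssignment(
        NITRATE_NITRITE, (NITRATE_REDUCTION, NITRIFICATION), dual=True
    )

#: Default set of genes whose joint transcription marks a complete anammox pathway.
ANAMMOX_GENES = ("hzsA", "hzsB", "hzsC", "hdh")


class PathwayMap:
    """Mapping from gene symbol to N-transformation process.

    Dual-assignment symbols (``narG;nxrA``, ``narH;nxrB``) carry both
    candidate processes and are reported under :data:`NITRATE_NITRITE`.
    """

    def __init__(self, mapping: Mapping[str, PathwayAssignment]):
        self._map = dict(mapping)
        for sym, asg in self._map.items():
            if not asg.dual and len(asg.candidates) != 1:
                raise ValueError(
                    f"symbol {sym!r}: non-dual assignment must have exactly one process"
                )

    def lookup(self, symbol: str | None) -> PathwayAssignment:
        if symbol is None:
            return PathwayAssignment(UNANNOTATED, (UNANNOTATED,))
        return self._map.get(symbol, PathwayAssignment(UNANNOTATED, (UNANNOTATED,)))

    def process_of(self, symbol: str | None) -> str:
        return self.lookup(symbol).process

    def symbols(self, process: str | None = None) -> list[str]:
        if process is None:
            return list(self._map)
        return [s for s, a in self._map.items() if a.process == process]

    def override(self, overrides: Mapping[str, str | Sequence[str]]) -> "PathwayMap":
        """Return a new map with symbol -> process overrides applied."""
        new = dict(self._map)
        for sym, proc in overrides.items():
            if isinstance(proc, str):
                new[sym] = PathwayAssignment(proc, (proc,), dual=False)
            else:
                procs = tuple(proc)
                new[sym] = PathwayAssignment(NITRATE_NITRITE, procs, dual=True)
        return PathwayMap(new)

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayMap":
        """Load a pathway-map override file (JSON: symbol -> process or list)."""
        with open(path) as fh:
            data = json.load(fh)
        return default_pathway_map().override(data)


def default_pathway_map() -> PathwayMap:
    """The built-in gene-symbol -> N-process map (user-overridable)."""
    return PathwayMap(_DEFAULT_SYMBOLS)
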