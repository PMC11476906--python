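"""Synthetic 12-lake sediment study generator.

Emulates the statistical structure of a survey of N-cycling genes and
transcripts across the sediments of 12 lakes falling into three archetypes
(agriculture-influenced, pristine-alpine, large-deep): ground-truth
per-cell gene copy numbers and transcript rates per lake and sediment
layer, simulated metagenomic/metatranscriptomic alignment tables (the
generative inverse of the counting pipeline), porewater and O2
microprofiles, bulk organic-matter profiles, and the lake metadata table.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import (
    ANAMMOX,
    DENITRIFICATION,
    DNRA,
    GeneCatalog,
    GeneRecord,
    NITRATE_NITRITE,
    NITRATE_REDUCTION,
    NITRIFICATION,
    PROCESSES,
    default_pathway_map,
)
from .geochem import OxygenMicroprofile, PorewaterProfile

__all__ = [
    "ArchetypeParams",
    "StudyTruth",
    "StudyData",
    "LAKE_METADATA",
    "HIGH_POTENTIAL_LAKES",
    "DEPTH_LAYERS",
    "default_archetypes",
    "default_catalog",
    "porewater_grid",
    "simulate_lake_truth",
    "simulate_alignment_table",
    "simulate_porewater",
    "simulate_bulk_om",
    "simulate_study",
]

# ---------------------------------------------------------------------------
# Lake roster: morphology and trophic state of the 12 lakes (study metadata).

LAKE_METADATA = pd.DataFrame(
    [
        ("BRI", "pristine_alpine", 29.8, 2.69, 168, 260, "Oligo"),
        ("LUC", "pristine_alpine", 111.0, 3.50, 107, 214, "Oligo"),
        ("SAR", "pristine_alpine", 7.15, 0.76, 34, 52, "Oligo"),
        ("WAL", "pristine_alpine", 24.1, 1.45, 104, 145, "Oligo"),
        ("BAL", "agriculture", 5.22, 4.22, 33, 66, "Eu"),
        ("HAL", "agriculture", 9.95, 3.85, 29, 45, "Meso"),
        ("SEM", "agriculture", 14.1, 17.5, 46, 86, "Meso"),
        ("ZUG", "agriculture", 38.3, 15.1, 84, 197, "Eu"),
        ("CON", "large_deep", 482.0, 4.35, 99, 254, "Oligo"),
        ("GEN", "large_deep", 582.0, 11.4, 153, 310, "Meso"),
        ("MAG", "large_deep", 212.0, 4.10, 177, 372, "Oligo-meso"),
        ("NEU", "large_deep", 213.0, 8.25, 64, 153, "Oligo-meso"),
    ],
    columns=[
        "lake",
        "group",
        "surface_area_km2",
        "residence_time_yr",
        "mean_depth_m",
        "max_depth_m",
        "trophic_state",
    ],
).set_index("lake")

#: Lakes constructed with high N-transformation potential (>0.006 genes/cell):
#: all pristine-alpine lakes plus the large-deep lakes CON and NEU.
HIGH_POTENTIAL_LAKES = frozenset({"BRI", "LUC", "SAR", "WAL", "CON", "NEU"})

#: The two sampled sediment layers per lake (surface 0-5 mm, deeper 5-10 mm).
DEPTH_LAYERS = ("5mm", "10mm")

# Per-process mean genes/cell for high- and low-potential lakes.  The
# nitrification, denitrification, nitrate-reduction, and anammox means are
# the study's per-group values; NO3<->NO2 and DNRA means are package
# defaults chosen to keep the two potential classes on either side of the
# 0.006 genes/cell rule.
GENES_PER_CELL_HIGH = {
    NITRIFICATION: 0.017,
    NITRATE_NITRITE: 0.010,
    NITRATE_REDUCTION: 0.005,
    DENITRIFICATION: 0.004,
    DNRA: 0.005,
    ANAMMOX: 0.004,
}
GENES_PER_CELL_LOW = {
    NITRIFICATION: 0.004,
    NITRATE_NITRITE: 0.002,
    NITRATE_REDUCTION: 0.002,
    DENITRIFICATION: 0.002,
    DNRA: 0.001,
    ANAMMOX: 0.00005,
}

# Mean transcripts/cell per process (study-wide averages for nitrification,
# NO3<->NO2, and denitrification; package defaults for the rest).
TRANSCRIPTS_PER_CELL = {
    NITRIFICATION: 1.2,
    NITRATE_NITRITE: 0.1,
    NITRATE_REDUCTION: 0.02,
    DENITRIFICATION: 0.04,
    DNRA: 0.005,
    ANAMMOX: 0.01,
}


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters of one lake archetype.

    Gene and transcript means are per-process per-cell values; porewater
    shape parameters control the solute profiles (O2 linear decay to its
    penetration depth; NO3-/SO4^2- exponential decay; NH4+ saturating rise
    toward an asymptote); bulk OM means set TOC/TN/isotope levels.
    """

    group: str
    genes_per_cell: dict = field(default_factory=dict)
    transcripts_per_cell: dict = field(default_factory=dict)
    o2_bottom_uM: float = 200.0
    o2_penetration_mm: float = 3.0
    no3_swi_uM: float = 80.0
    no3_decay_cm: float = 0.7
    so4_swi_uM: float = 100.0
    so4_decay_cm: float = 5.0
    nh4_asymptote_uM: float = 100.0
    nh4_scale_cm: float = 2.0
    toc_percent: float = 2.0
    tn_percent: float = 0.3
    d13c_permil: float = -30.0
    d15n_permil: float = 4.0


def default_archetypes() -> dict[str, ArchetypeParams]:
    """The three lake archetypes with their default generative parameters.

    Porewater shapes: agriculture-influenced lakes deplete oxidants within
    the top ~0.5 cm and accumulate NH4+ beyond 300 uM by 5 cm depth
    (shallow O2 penetration, 1.2 mm); pristine-alpine lakes show deep NO3-
    (>1 cm) and SO4^2- (>=5 cm) penetration, deeper O2 penetration
    (4.7 mm), and weak NH4+ build-up; large-deep lakes are intermediate.
    """
    return {
        "agriculture": ArchetypeParams(
            group="agriculture",
            genes_per_cell=dict(GENES_PER_CELL_LOW),
            transcripts_per_cell=dict(TRANSCRIPTS_PER_CELL),
            o2_bottom_uM=90.0,
            o2_penetration_mm=1.2,
            no3_swi_uM=100.0,
            no3_decay_cm=0.2,
            so4_swi_uM=150.0,
            so4_decay_cm=0.3,
            nh4_asymptote_uM=500.0,
            nh4_scale_cm=1.0,
            toc_percent=6.0,
            tn_percent=0.9,
            d13c_permil=-34.0,
            d15n_permil=6.0,
        ),
        "pristine_alpine": ArchetypeParams(
            group="pristine_alpine",
            genes_per_cell=dict(GENES_PER_CELL_HIGH),
            transcripts_per_cell=dict(TRANSCRIPTS_PER_CELL),
            o2_bottom_uM=200.0,
            o2_penetration_mm=4.7,
            no3_swi_uM=80.0,
            no3_decay_cm=0.7,
            so4_swi_uM=100.0,
            so4_decay_cm=5.0,
            nh4_asymptote_uM=100.0,
            nh4_scale_cm=2.0,
            toc_percent=1.0,
            tn_percent=0.13,
            d13c_permil=-27.5,
            d15n_permil=2.0,
        ),
        "large_deep": ArchetypeParams(
            group="large_deep",
            genes_per_cell=dict(GENES_PER_CELL_HIGH),
            transcripts_per_cell=dict(TRANSCRIPTS_PER_CELL),
            o2_bottom_uM=250.0,
            o2_penetration_mm=3.5,
            no3_swi_uM=120.0,
            no3_decay_cm=0.6,
            so4_swi_uM=250.0,
            so4_decay_cm=3.0,
            nh4_asymptote_uM=150.0,
            nh4_scale_cm=2.0,
            toc_percent=3.5,
            tn_percent=0.55,
            d13c_permil=-31.0,
            d15n_permil=4.5,
        ),
    }


# ---------------------------------------------------------------------------
# Gene catalog

# Gene symbol -> KO.  narG;nxrA and narH;nxrB genuinely share KOs between
# nitrate reductase and nitrite oxidoreductase (hence their dual pathway).
_SYMBOL_KO = {
    "amoA": "K10944",
    "amoB": "K10945",
    "amoC": "K10946",
    "hao": "K10535",
    "narG;nxrA": "K00370",
    "narH;nxrB": "K00371",
    "narI": "K00374",
    "napA": "K02567",
    "napB": "K02568",
    "nirS": "K15864",
    "nirK": "K00368",
    "norB": "K04561",
    "norC": "K02305",
    "nosZ": "K00376",
    "nrfA": "K03385",
    "nrfH": "K15876",
    "hzsA": "K20932",
    "hzsB": "K20933",
    "hzsC": "K20934",
    "hdh": "K20935",
}

MARKER_LENGTH_BP = 900


def default_catalog(n_paralogs: int = 2) -> GeneCatalog:
    """Deterministic synthetic gene catalog.

    10 single-copy marker genes (~900 bp) plus ``n_paralogs`` same-KO
    paralogs of each N-cycle gene symbol (1000-2100 bp).  Same-KO paralogs
    are what make multi-mapped ("ambiguous") inserts possible.
    """
    pmap = default_pathway_map()
    records = [
        GeneRecord(f"MG{i:02d}", MARKER_LENGTH_BP, ko_id=f"K99{i:02d}", is_marker=True)
        for i in range(1, 11)
    ]
    for i, (symbol, ko) in enumerate(sorted(_SYMBOL_KO.items())):
        base = 1000 + (i * 137) % 1001  # deterministic spread over 1000-2000 bp
        for p in range(1, n_paralogs + 1):
            records.append(
                GeneRecord(
                    gene_id=f"{symbol}_{p}",
                    length_bp=base + 50 * (p - 1),
                    ko_id=ko,
                    gene_symbol=symbol,
                    pathway=pmap.process_of(symbol),
                )
            )
    return GeneCatalog(records)


def porewater_grid() -> np.ndarray:
    """The 15 porewater sampling depths (cm).

    A bottom-water sample 1 cm above the sediment (-1.0), 0.25 cm intervals
    from 0-2 cm, and 0.5 cm intervals from 2.5-5 cm.
    """
    return np.concatenate(
        [[-1.0], np.arange(0.25, 2.0 + 1e-9, 0.25), np.arange(2.5, 5.0 + 1e-9, 0.5)]
    )


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class StudyTruth:
    """True per-cell copy numbers and transcript abundances for one sample.

    ``table`` is indexed by gene_id with columns ``copies_per_cell`` and
    ``transcripts_per_cell``; marker genes sit at exactly 1 copy/cell.
    """

    lake: str
    layer: str
    table: pd.DataFrame
    seed: int | None = None


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Log-normal draws with the requested arithmetic mean and CV."""
    if mean == 0:
        return np.zeros(size)
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_lake_truth(
    archetype: ArchetypeParams,
    catalog: GeneCatalog,
    *,
    lake: str = "",
    layer: str = DEPTH_LAYERS[0],
    cv: float = 0.3,
    seed=0,
) -> StudyTruth:
    """Draw per-gene ground truth around the archetype's process means.

    Gene copy numbers are log-normal around the process mean with the
    given coefficient of variation; transcripts are copies times the
    process-level expression rate (mean transcripts/cell divided by mean
    genes/cell); markers are fixed at exactly 1 copy/cell with 1
    transcript/cell.
    """
    rng = np.random.default_rng(seed)
    pmap = default_pathway_map()
    gene_ids, copies, transcripts = [], [], []
    for rec in catalog:
        gene_ids.append(rec.gene_id)
        if rec.is_marker:
            copies.append(1.0)
            transcripts.append(1.0)
            continue
        process = pmap.process_of(rec.gene_symbol)
        g_mean = archetype.genes_per_cell.get(process, 0.0)
        t_mean = archetype.transcripts_per_cell.get(process, 0.0)
        c = float(_lognormal(rng, g_mean, cv, 1)[0])
        rate = (t_mean / g_mean) if g_mean > 0 else 0.0
        copies.append(c)
        transcripts.append(c * rate)
    table = pd.DataFrame(
        {"copies_per_cell": copies, "transcripts_per_cell": transcripts},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return StudyTruth(lake, layer, table)


# ---------------------------------------------------------------------------
# Alignment tables


def _paralog_partner(catalog: GeneCatalog) -> dict[str, str]:
    """Map each gene to one same-KO paralog (cyclically), if it has any."""
    by_ko: dict[str, list[str]] = {}
    for rec in catalog:
        if rec.ko_id is not None and not rec.is_marker:
            by_ko.setdefault(rec.ko_id, []).append(rec.gene_id)
    partner = {}
    for genes in by_ko.values():
        if len(genes) < 2:
            continue
        for i, g in enumerate(genes):
            partner[g] = genes[(i + 1) % len(genes)]
    return partner


def simulate_alignment_table(
    truth: StudyTruth,
    catalog: GeneCatalog,
    *,
    layer: str = "metaG",
    n_inserts: int = 100_000,
    f_ambiguous: float = 0.2,
    fail_fraction: float = 0.02,
    seed=0,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Simulate an insert-to-gene alignment table from ground truth.

    Each insert is assigned to a gene with probability proportional to
    copy number (metaG) or transcript abundance (metaT) times gene length.
    A fraction ``f_ambiguous`` of inserts from genes with a same-KO paralog
    is additionally listed against that paralog.  Passing inserts draw
    identities in 95-100% and 45-150 aligned bases; a spiked
    ``fail_fraction`` of inserts falls below one of the retention cutoffs
    (identity 90-94.9% or <45 aligned bases) to exercise the filter.
    """
    if n_inserts < 1:
        raise ValueError("n_inserts must be >= 1")
    if not 0.0 <= f_ambiguous < 1.0:
        raise ValueError("f_ambiguous must be in [0, 1)")
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    rng = np.random.default_rng(seed)
    col = "copies_per_cell" if layer == "metaG" else "transcripts_per_cell"
    genes = np.array(truth.table.index)
    lengths = np.array([catalog[g].length_bp for g in genes], dtype=float)
    weights = truth.table[col].to_numpy(dtype=float) * lengths
    if weights.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    p = weights / weights.sum()

    gene_idx = rng.choice(len(genes), size=n_inserts, p=p)
    n_fail = int(round(fail_fraction * n_inserts))
    fail = np.zeros(n_inserts, dtype=bool)
    fail[:n_fail] = True

    pct = rng.uniform(95.0, 100.0, n_inserts)
    aligned = rng.integers(45, 151, n_inserts)
    # half of the spiked failures fail on identity, half on aligned length
    low_identity = fail & (np.arange(n_inserts) % 2 == 0)
    short_aln = fail & ~low_identity
    pct[low_identity] = rng.uniform(90.0, 94.9, int(low_identity.sum()))
    aligned[short_aln] = rng.integers(20, 45, int(short_aln.sum()))

    partner = _paralog_partner(catalog)
    partner_arr = np.array([partner.get(g, "") for g in genes])
    has_partner = partner_arr[gene_idx] != ""
    ambiguous = has_partner & (rng.random(n_inserts) < f_ambiguous)

    sid = sample_id or f"{truth.lake}-{truth.layer}"
    insert_ids = np.arange(n_inserts)
    base = pd.DataFrame(
        {
            "sample_id": sid,
            "insert_id": insert_ids,
            "gene_id": genes[gene_idx],
            "pct_id": np.round(pct, 2),
            "aligned_bases": aligned,
        }
    )
    extra = base.loc[ambiguous].copy()
    extra["gene_id"] = partner_arr[gene_idx[ambiguous]]
    table = pd.concat([base, extra], ignore_index=True)
    table["insert_id"] = sid + ":" + table["insert_id"].astype(str)
    return table.sort_values(["insert_id", "gene_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Porewater, microprofiles, bulk OM


def simulate_porewater(
    archetype: ArchetypeParams,
    *,
    noise_sd: float = 2.0,
    o2_noise_sd: float = 0.5,
    seed=0,
) -> tuple[dict[str, PorewaterProfile], OxygenMicroprofile]:
    """Simulate porewater profiles and an O2 microprofile for one lake.

    O2 decays linearly from the bottom-water concentration to zero at the
    archetype's penetration depth on a 0.1 mm grid; NO3- and SO4^2- decay
    exponentially below the SWI with the archetype length scales; NH4+
    rises (saturating exponential) toward the archetype asymptote.
    Gaussian noise is added and concentrations clipped at zero; with
    ``noise_sd=0`` the output is seed-independent.
    """
    rng = np.random.default_rng(seed)
    grid = porewater_grid()
    below = np.clip(grid, 0.0, None)

    def _noisy(values: np.ndarray, sd: float) -> np.ndarray:
        if sd > 0:
            values = values + rng.normal(0.0, sd, values.shape)
        return np.clip(values, 0.0, None)

    no3 = archetype.no3_swi_uM * np.exp(-below / archetype.no3_decay_cm)
    so4 = archetype.so4_swi_uM * np.exp(-below / archetype.so4_decay_cm)
    nh4 = archetype.nh4_asymptote_uM * -np.expm1(-below / archetype.nh4_scale_cm)
    profiles = {
        "NO3": PorewaterProfile("NO3", grid, _noisy(no3, noise_sd)),
        "SO4": PorewaterProfile("SO4", grid, _noisy(so4, noise_sd)),
        "NH4": PorewaterProfile("NH4", grid, _noisy(nh4, noise_sd)),
    }

    z_mm = np.arange(0.0, 2 * archetype.o2_penetration_mm + 1e-9, 0.1)
    o2 = archetype.o2_bottom_uM * np.clip(
        1.0 - z_mm / archetype.o2_penetration_mm, 0.0, None
    )
    micro = OxygenMicroprofile(z_mm, _noisy(o2, o2_noise_sd))
    return profiles, micro


def simulate_bulk_om(
    archetype: ArchetypeParams,
    *,
    noise_sd: float = 0.0,
    seed=0,
) -> pd.DataFrame:
    """Bulk OM depth profile (0-5 cm at 0.5 cm resolution).

    TOC and TN decline slightly downcore at a fixed C:N, d13C increases
    systematically with depth, d15N stays flat; optional Gaussian noise is
    relative for TOC/TN and absolute (permil) for the isotopes.
    """
    rng = np.random.default_rng(seed)
    depth = np.arange(0.25, 5.0, 0.5)
    decline = 1.0 - 0.03 * depth  # mild downcore loss
    toc = archetype.toc_percent * decline
    tn = archetype.tn_percent * decline
    d13c = archetype.d13c_permil + 0.15 * depth
    d15n = np.full_like(depth, archetype.d15n_permil)
    if noise_sd > 0:
        toc = np.clip(toc * (1 + rng.normal(0, noise_sd, depth.shape)), 1e-3, None)
        tn = np.clip(tn * (1 + rng.normal(0, noise_sd, depth.shape)), 1e-4, None)
        d13c = d13c + rng.normal(0, noise_sd, depth.shape)
        d15n = d15n + rng.normal(0, noise_sd, depth.shape)
    return pd.DataFrame(
        {
            "depth_cm": depth,
            "TOC_percent": toc,
            "TN_percent": tn,
            "d13C_permil": d13c,
            "d15N_permil": d15n,
        }
    )


# ---------------------------------------------------------------------------
# Whole study


@dataclass
class StudyData:
    """Everything the downstream modules need for one simulated study."""

    catalog: GeneCatalog
    metadata: pd.DataFrame
    truth: dict  # (lake, depth_layer) -> StudyTruth
    alignments: dict  # (lake, depth_layer, omic_layer) -> DataFrame
    porewater: dict  # lake -> {solute -> PorewaterProfile}
    microprofiles: dict  # lake -> OxygenMicroprofile
    bulk_om: dict  # lake -> DataFrame
    potential_level: dict  # lake -> "high" | "low"
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return [f"{lake}-{layer}" for (lake, layer) in self.truth]


def simulate_study(
    *,
    seed: int = 0,
    n_inserts: int = 100_000,
    f_ambiguous: float = 0.2,
    fail_fraction: float = 0.02,
    cv: float = 0.3,
    noise_sd: float = 2.0,
    catalog: GeneCatalog | None = None,
    archetypes: dict[str, ArchetypeParams] | None = None,
) -> StudyData:
    """Simulate the full 12-lake, two-sediment-depth study.

    Each lake gets ground truth and metaG/metaT alignment tables for both
    sediment layers (24 meta-omic sample pairs), porewater and O2
    profiles, and a bulk OM profile.  Pristine-alpine lakes plus CON and
    NEU are constructed with the high-potential gene means, agriculture
    lakes plus GEN and MAG with the low-potential means.  Deterministic
    for a given seed.
    """
    catalog = catalog or default_catalog()
    archetypes = archetypes or default_archetypes()
    ss = np.random.SeedSequence(seed)
    truth: dict = {}
    alignments: dict = {}
    porewater: dict = {}
    microprofiles: dict = {}
    bulk_om: dict = {}
    potential_level: dict = {}

    lakes = list(LAKE_METADATA.index)
    children = ss.spawn(len(lakes))
    for lake, lake_ss in zip(lakes, children):
        group = LAKE_METADATA.loc[lake, "group"]
        arch = archetypes[group]
        level = "high" if lake in HIGH_POTENTIAL_LAKES else "low"
        potential_level[lake] = level
        means = GENES_PER_CELL_HIGH if level == "high" else GENES_PER_CELL_LOW
        lake_arch = replace(arch, genes_per_cell=dict(means))
        sub = lake_ss.spawn(2 + 2 * len(DEPTH_LAYERS) * 2)
        profiles, micro = simulate_porewater(lake_arch, noise_sd=noise_sd, seed=sub[0])
        porewater[lake] = profiles
        microprofiles[lake] = micro
        bulk_om[lake] = simulate_bulk_om(
            lake_arch, noise_sd=min(noise_sd, 0.05), seed=sub[1]
        )
        i = 2
        for depth_layer in DEPTH_LAYERS:
            t = simulate_lake_truth(
                lake_arch, catalog, lake=lake, layer=depth_layer, cv=cv, seed=sub[i]
            )
            i += 1
            truth[(lake, depth_layer)] = t
            for omic in ("metaG", "metaT"):
                alignments[(lake, depth_layer, omic)] = simulate_alignment_table(
                    t,
                    catalog,
                    layer=omic,
                    n_inserts=n_inserts,
                    f_ambiguous=f_ambiguous,
                    fail_fraction=fail_fraction,
                    seed=sub[i],
                )
                i += 1

    return StudyData(
        catalog=catalog,
        metadata=LAKE_METADATA.copy(),
        truth=truth,
        alignments=alignments,
        porewater=porewater,
        microprofiles=microprofiles,
        bulk_om=bulk_om,
        potential_level=potential_level,
        seed=seed,
    )
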