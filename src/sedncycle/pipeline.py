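"""End-to-end pipeline: configuration, orchestration, and result writing.

``run_pipeline`` composes the full chain — synthetic study generation (or
user-supplied alignment tables) -> insert counting and per-cell
normalization -> expression scores and pathway summaries -> porewater
fluxes -> ordination + environmental fitting -> co-expression network —
and writes TSV/JSON outputs plus a manifest recording every threshold and
seed.  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import community, expression, geochem, quant, syndata

__all__ = [
    "ConfigError",
    "StageError",
    "DEFAULT_CONFIG",
    "validate_config",
    "run_pipeline",
    "per_cell_matrices",
    "flux_table",
]

log = logging.getLogger("sedncycle")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "sedncycle_results",
    # synthetic study
    "n_inserts": 100_000,
    "f_ambiguous": 0.2,
    "fail_fraction": 0.02,
    "cv": 0.3,
    "noise_sd": 2.0,
    # alignment / annotation filters
    "min_identity": 95.0,
    "min_aligned_bases": 45,
    "min_subject_coverage": 0.70,
    "min_bitscore_fraction": 0.50,
    "marker_count": 10,
    # geochemistry
    "porosity": 0.9,
    "d0": dict(geochem.D0_5C),
    "gradient_window": 3,
    "detection_limit_uM": 1.0,
    # ordination and permutation statistics
    "nmds_k": 2,
    "nmds_restarts": 20,
    "nmds_seed": 0,
    "permutations": 999,
    "envfit_alpha": 0.01,
    # network and classification
    "network_threshold": 0.8,
    "potential_threshold": 0.006,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(config: dict | None, *, strict: bool = True) -> dict:
    """Schema- and range-check a config; fill and echo defaults.

    Unknown keys raise (strict) or warn (lax).  An empty config yields the
    full default configuration.  Seeds for stochastic stages must not be
    nulled out.
    """
    config = dict(config or {})
    unknown = sorted(set(config) - set(DEFAULT_CONFIG))
    if unknown:
        if strict:
            raise ConfigError(f"unknown config key(s): {unknown}")
        warnings.warn(f"ignoring unknown config key(s): {unknown}")
        for k in unknown:
            config.pop(k)
    merged = {**DEFAULT_CONFIG, **config}

    for key in ("seed", "nmds_seed"):
        if merged[key] is None:
            raise ConfigError(f"config key {key!r} is required (seeds are mandatory)")
    if not 0.0 < merged["porosity"] < 1.0:
        raise ConfigError(f"porosity must be in (0, 1), got {merged['porosity']}")
    for key in (
        "min_identity",
        "min_aligned_bases",
        "min_subject_coverage",
        "min_bitscore_fraction",
        "network_threshold",
        "potential_threshold",
        "detection_limit_uM",
        "n_inserts",
        "marker_count",
        "nmds_restarts",
        "permutations",
    ):
        if not merged[key] > 0:
            raise ConfigError(f"config key {key!r} must be positive")
    if not 0.0 <= merged["f_ambiguous"] < 1.0:
        raise ConfigError("f_ambiguous must be in [0, 1)")
    for solute, d0 in merged["d0"].items():
        if d0 <= 0:
            raise ConfigError(f"D0 for {solute} must be positive")
    return merged


# ---------------------------------------------------------------------------
# Stage helpers (reused by tests and the acceptance script)


def per_cell_matrices(
    study: syndata.StudyData,
    *,
    min_identity: float = quant.IDENTITY_MIN,
    min_aligned_bases: int = quant.ALIGNED_BASES_MIN,
    marker_count: int = quant.MARKER_COUNT,
) -> dict[str, pd.DataFrame]:
    """Per-cell gene matrices (genes x samples) for both omic layers."""
    out: dict[str, dict[str, pd.Series]] = {"metaG": {}, "metaT": {}}
    markers = [r.gene_id for r in study.catalog.markers()]
    for (lake, depth, omic), table in study.alignments.items():
        sample = f"{lake}-{depth}"
        kept = quant.filter_alignments(
            table, min_identity=min_identity, min_aligned_bases=min_aligned_bases
        )
        counts = quant.count_inserts(kept, sample_id=sample, layer=omic)
        abund = quant.length_normalize(counts, study.catalog)
        marker_abund = abund.values.reindex(markers, fill_value=0.0)
        percell = quant.per_cell_normalize(
            abund, marker_abund, expected_markers=marker_count
        )
        out[omic][sample] = percell.values
    return {
        omic: pd.DataFrame(cols).fillna(0.0).sort_index()
        for omic, cols in out.items()
    }


def flux_table(study: syndata.StudyData, config: dict) -> pd.DataFrame:
    """Benthic flux table (lake, group, J_O2, J_NH4, J_NO3) from profiles."""
    rows = []
    for lake in study.metadata.index:
        group = study.metadata.loc[lake, "group"]
        grad_o2 = geochem.o2_gradient(study.microprofiles[lake])
        j_o2 = geochem.fick_flux(
            grad_o2,
            solute="O2",
            porosity=config["porosity"],
            D0=config["d0"]["O2"],
        )
        fluxes = {"J_O2": j_o2.J_mmol_m2_d}
        for solute, col in (("NH4", "J_NH4"), ("NO3", "J_NO3")):
            grad = geochem.fit_gradient(
                study.porewater[lake][solute], window=config["gradient_window"]
            )
            fluxes[col] = geochem.fick_flux(
                grad,
                solute=solute,
                porosity=config["porosity"],
                D0=config["d0"][solute],
            ).J_mmol_m2_d
        pen = geochem.o2_penetration(study.microprofiles[lake])
        om = study.bulk_om[lake]
        rows.append(
            {
                "lake": lake,
                "group": group,
                **fluxes,
                "o2_penetration_mm": pen.depth_mm,
                "cn_molar": float(
                    np.mean(
                        geochem.cn_molar_ratio(om["TOC_percent"], om["TN_percent"])
                    )
                ),
            }
        )
    return pd.DataFrame(rows).set_index("lake")


def _env_table(study: syndata.StudyData, fluxes: pd.DataFrame) -> pd.DataFrame:
    """Per-sample environmental variables (lake-level values repeated)."""
    rows = {}
    for (lake, depth) in study.truth:
        om = study.bulk_om[lake]
        rows[f"{lake}-{depth}"] = {
            "TOC": float(om["TOC_percent"].mean()),
            "TN": float(om["TN_percent"].mean()),
            "CN_molar": fluxes.loc[lake, "cn_molar"],
            "o2_penetration_mm": fluxes.loc[lake, "o2_penetration_mm"],
            "J_O2": fluxes.loc[lake, "J_O2"],
            "J_NO3": fluxes.loc[lake, "J_NO3"],
            "J_NH4": fluxes.loc[lake, "J_NH4"],
            "max_depth_m": float(study.metadata.loc[lake, "max_depth_m"]),
        }
    return pd.DataFrame(rows).T


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, *, strict: bool = True) -> dict:
    """Run the full pipeline and write all outputs.

    Returns a dict with the validated config, output paths, and in-memory
    results.  Any stage failure raises :class:`StageError` naming the
    stage.
    """
    cfg = validate_config(config, strict=strict)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": cfg}
    paths: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("simulate"):
        study = syndata.simulate_study(
            seed=cfg["seed"],
            n_inserts=cfg["n_inserts"],
            f_ambiguous=cfg["f_ambiguous"],
            fail_fraction=cfg["fail_fraction"],
            cv=cfg["cv"],
            noise_sd=cfg["noise_sd"],
        )
        results["study"] = study

    with stage("quantify"):
        matrices = per_cell_matrices(
            study,
            min_identity=cfg["min_identity"],
            min_aligned_bases=cfg["min_aligned_bases"],
            marker_count=cfg["marker_count"],
        )
        results["per_cell"] = matrices
        for omic, mat in matrices.items():
            paths[f"per_cell_{omic}"] = out_dir / f"per_cell_{omic}.tsv"
            quant.write_profile_matrix(mat, paths[f"per_cell_{omic}"])

    with stage("express"):
        pmap = cat.default_pathway_map()
        g_mat, t_mat = matrices["metaG"], matrices["metaT"]
        ratio = t_mat.where(g_mat > 0) / g_mat.where(g_mat > 0)
        results["expression"] = ratio
        paths["expression"] = out_dir / "expression.tsv"
        quant.write_profile_matrix(ratio, paths["expression"])

        sample_to_lake = {s: s.split("-")[0] for s in g_mat.columns}
        summary = expression.pathway_summary(
            g_mat, t_mat, study.catalog, pmap, sample_to_lake=sample_to_lake
        )
        results["summary"] = summary
        paths["pathway_abundance"] = out_dir / "pathway_abundance.tsv"
        quant.write_profile_matrix(summary.abundance, paths["pathway_abundance"])
        paths["pathway_expression"] = out_dir / "pathway_expression.tsv"
        quant.write_profile_matrix(summary.expression, paths["pathway_expression"])

        n_genes = [
            r.gene_id
            for r in study.catalog
            if pmap.process_of(r.gene_symbol) != cat.UNANNOTATED
        ]
        lake_means = (
            g_mat.loc[n_genes]
            .mean(axis=0)
            .groupby(lambda s: s.split("-")[0])
            .mean()
        )
        classes = expression.classify_potential(
            lake_means, threshold=cfg["potential_threshold"]
        )
        results["classification"] = classes

        anammox_flags = {}
        symbol_of = {r.gene_id: r.gene_symbol for r in study.catalog}
        for sample in t_mat.columns:
            by_symbol = t_mat[sample].groupby(symbol_of).sum()
            anammox_flags[sample] = expression.anammox_complete(by_symbol)
        report = {
            "classification": classes.to_dict(),
            "lake_mean_genes_per_cell": lake_means.round(8).to_dict(),
            "threshold": cfg["potential_threshold"],
            "anammox_complete": anammox_flags,
        }
        paths["lake_report"] = out_dir / "lake_report.json"
        paths["lake_report"].write_text(json.dumps(report, indent=2, sort_keys=True))

    with stage("geochem"):
        fluxes = flux_table(study, cfg)
        results["fluxes"] = fluxes
        paths["flux_table"] = out_dir / "flux_table.tsv"
        fluxes.to_csv(paths["flux_table"], sep="\t", float_format="%.12g")

    with stage("ordinate"):
        n_genes_mat = matrices["metaG"].loc[n_genes].T  # samples x genes
        dm = community.bray_curtis(n_genes_mat)
        ordination = community.nmds(
            dm, k=cfg["nmds_k"], restarts=cfg["nmds_restarts"], seed=cfg["nmds_seed"]
        )
        results["ordination"] = ordination
        paths["nmds_coords"] = out_dir / "nmds_coords.tsv"
        ordination.coords.to_csv(
            paths["nmds_coords"], sep="\t", float_format="%.12g", index_label="sample"
        )
        env = _env_table(study, fluxes).loc[ordination.coords.index]
        fit = community.envfit(
            ordination, env, permutations=cfg["permutations"], seed=cfg["nmds_seed"]
        )
        results["envfit"] = fit
        paths["envfit"] = out_dir / "envfit.tsv"
        fit.table.to_csv(paths["envfit"], sep="\t", float_format="%.12g")

    with stage("network"):
        log_expr, meta = expression.log2_transform(ratio.fillna(0.0))
        net = community.coexpression_network(
            log_expr, threshold=cfg["network_threshold"]
        )
        results["network"] = net
        paths["network_edges"] = out_dir / "network_edges.tsv"
        net.edges.to_csv(
            paths["network_edges"], sep="\t", float_format="%.12g", index=False
        )

    with stage("manifest"):
        manifest = {
            "config": {k: v for k, v in cfg.items() if k != "d0"},
            "d0": cfg["d0"],
            "nmds_stress": results["ordination"].stress,
            "files": {name: _sha256(p) for name, p in sorted(paths.items())},
        }
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results["paths"] = {k: str(v) for k, v in paths.items()}
    return results
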