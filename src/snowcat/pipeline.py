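"""End-to-end pipeline: simulate -> deconvolve -> flux -> diversity -> regress.

Each stage reads and writes TSV tables in an output directory so that the
chain can be resumed, inspected or fed with user data at any point.  A
manifest records the package version, the seed, the configuration hash and a
checksum of every output: identical configuration + seed give identical
manifests.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, flux, io, msc, regression, synthetic

__all__ = ["PipelineError", "run_all", "STAGES"]

log = logging.getLogger("snowcat")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            start = time.perf_counter()
            log.info("stage %s: starting", name)
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-label with the stage
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - start)
            return result

        wrapper.__name__ = fn.__name__
        return wrapper

    return decorator


@_stage("simulate")
def stage_simulate(config: io.PipelineConfig, outdir: Path) -> None:
    dataset = synthetic.simulate_dataset(
        seed=config.seed,
        geometry=config.geometry,
        fast_dilution=config.fast_dilution,
    )
    io.write_otu_table(dataset.otu_table, outdir / "otu_table.tsv")
    io.write_taxonomy(dataset.taxonomy, outdir / "taxonomy.tsv")
    io.write_metadata(dataset.otu_table.metadata, outdir / "metadata.tsv")
    io.write_table(dataset.measurements, outdir / "measurements.tsv")
    io.write_table(dataset.cells, outdir / "cells.tsv")
    log.info(
        "simulate: %d samples, %d OTUs (seed %d)",
        len(dataset.otu_table.sample_ids),
        len(dataset.otu_table.otu_ids),
        config.seed,
    )


@_stage("deconvolve")
def stage_deconvolve(config: io.PipelineConfig, outdir: Path) -> None:
    path = outdir / "measurements.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing input file {path}")
    measurements = io.read_table(path)
    ambient = measurements[measurements["msc_tag"] == "nonsink_top"].set_index(
        ["depth_m", "replicate", "rep"]
    )
    rows = []
    for _, row in measurements.iterrows():
        m = msc.FractionMeasurement(
            fraction=row["msc_tag"],
            value=row["value"],
            units=row["units"],
            dilution=row["dilution"],
        )
        m = msc.undilute(m)
        if row["msc_tag"] == "fast_plate":
            key = (row["depth_m"], row["replicate"], row["rep"])
            amb_row = ambient.loc[key]
            amb = msc.undilute(
                msc.FractionMeasurement(
                    fraction="nonsink_top",
                    value=amb_row["value"],
                    units=amb_row["units"],
                    dilution=amb_row["dilution"],
                )
            )
            value = msc.deconvolve_fast_sinking(m, amb, config.geometry)
        else:
            value = m.value
        rows.append(
            {
                "sample_id": row["sample_id"],
                "fraction": row["fraction"],
                "depth_m": row["depth_m"],
                "replicate": row["replicate"],
                "rep": row["rep"],
                "leu_pmol_l_h": value,
                "incubation_h": row["incubation_h"],
            }
        )
    io.write_table(pd.DataFrame(rows), outdir / "rates_per_litre.tsv")


@_stage("flux")
def stage_flux(config: io.PipelineConfig, outdir: Path) -> None:
    rates_path = outdir / "rates_per_litre.tsv"
    cells_path = outdir / "cells.tsv"
    for p in (rates_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input file {p}")
    rates = io.read_table(rates_path)
    cells = io.read_table(cells_path).set_index("sample_id")
    cfg = config.flux
    rows = []
    for sid, group in rates.groupby("sample_id", sort=False):
        first = group.iloc[0]
        uptake = flux.LeucineUptake(
            replicates=tuple(group["leu_pmol_l_h"]),
            incubation_h=float(first["incubation_h"]),
            depth_m=float(first["depth_m"]),
            fraction=first["fraction"],
        )
        php = flux.leucine_to_carbon(uptake, cfg.leucine_factor, cfg.isotope_dilution)
        cell_row = cells.loc[sid]
        conc = flux.cells_per_litre(
            cell_row["cells_per_ml"], cell_row["sd_cells_per_ml"]
        )
        cs = flux.cell_specific(php, conc)
        growth = flux.growth_rate(cs, cfg.cell_carbon_fg)
        if first["fraction"] == "fast":
            loss = flux.carbon_loss(php, mode="respiratory_coefficient", rq=cfg.rq)
        else:
            loss = flux.carbon_loss(php, mode="pge", pge=cfg.pge)
        rows.append(
            {
                "sample_id": sid,
                "fraction": first["fraction"],
                "depth_m": first["depth_m"],
                "replicate": first["replicate"],
                "php_ng_c_l_h": php.mean,
                "php_sd": php.sd,
                "cells_per_l": conc.value,
                "cs_php_ng_c_cell_h": cs.value,
                "growth_rate_h": growth.value,
                "respiration_ng_c_l_h": loss.respiration,
                "demand_ng_c_l_h": loss.demand,
                "loss_mode": loss.mode,
            }
        )
    io.write_table(pd.DataFrame(rows), outdir / "flux_table.tsv")


@_stage("diversity")
def stage_diversity(config: io.PipelineConfig, outdir: Path) -> None:
    otu_path = outdir / "otu_table.tsv"
    if not otu_path.exists():
        raise FileNotFoundError(f"missing input file {otu_path}")
    table = io.read_otu_table(otu_path, outdir / "metadata.tsv")
    taxonomy = io.read_taxonomy(outdir / "taxonomy.tsv")
    cfg = config.diversity
    depth = None if cfg.rarefy_depth == "min" else int(cfg.rarefy_depth)
    rarefied = diversity.rarefy(table, depth=depth, seed=config.seed)

    alpha = diversity.alpha_diversity(rarefied)
    if cfg.shannon_base is not None:
        alpha["shannon"] = diversity.shannon(rarefied, base=cfg.shannon_base)
    io.write_table(alpha.rename_axis("sample_id").reset_index(), outdir / "alpha.tsv")

    dmat = diversity.bray_curtis(rarefied)
    io.write_table(
        dmat.to_frame().rename_axis("sample_id").reset_index(),
        outdir / "bray_curtis.tsv",
    )
    result = diversity.nmds(
        dmat,
        n_restarts=cfg.nmds_restarts,
        max_iter=cfg.nmds_max_iter,
        seed=config.seed,
    )
    coords = pd.DataFrame(
        result.coordinates, index=list(result.ids), columns=["NMDS1", "NMDS2"]
    )
    nmds_path = outdir / "nmds_coords.tsv"
    with open(nmds_path, "w", encoding="utf-8") as handle:
        handle.write(f"# stress={result.stress:.6f} converged={result.converged}\n")
        coords.rename_axis("sample_id").reset_index().to_csv(
            handle, sep="\t", index=False
        )

    families = diversity.family_summary(rarefied, taxonomy, k=cfg.k_families)
    io.write_table(
        families.rename_axis("sample_id").reset_index(), outdir / "family_summary.tsv"
    )

    meta = rarefied.metadata
    shared_rows = []
    core_rows = []
    for depth_m in sorted(meta["depth_m"].unique()):
        fast_ids = meta.index[(meta["fraction"] == "fast") & (meta["depth_m"] == depth_m)]
        non_ids = meta.index[(meta["fraction"] == "nonsink") & (meta["depth_m"] == depth_m)]
        nisk_ids = meta.index[(meta["fraction"] == "niskin") & (meta["depth_m"] == depth_m)]
        if len(fast_ids) and len(non_ids):
            shared_rows.append(
                {
                    "depth_m": depth_m,
                    "shared_pct_fast_vs_nonsink": diversity.shared_otus(
                        rarefied, fast_ids, non_ids
                    ),
                }
            )
            groups = [g for g in (fast_ids, non_ids, nisk_ids) if len(g)]
            core_rows.append(
                {
                    "depth_m": depth_m,
                    "core_otus": len(diversity.core_microbiome(rarefied, groups)),
                }
            )
    io.write_table(pd.DataFrame(shared_rows), outdir / "shared_otus.tsv")
    io.write_table(pd.DataFrame(core_rows), outdir / "core_microbiome.tsv")


@_stage("regress")
def stage_regress(config: io.PipelineConfig, outdir: Path) -> None:
    alpha_path = outdir / "alpha.tsv"
    flux_path = outdir / "flux_table.tsv"
    for p in (alpha_path, flux_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input file {p}")
    alpha = io.read_table(alpha_path).set_index("sample_id")
    flux_table = io.read_table(flux_path).set_index("sample_id")
    merged = alpha.join(flux_table, how="inner")
    excluded = config.regression.exclude_fractions
    excl_label = "excluding_" + ("_".join(excluded) if excluded else "none")
    fits = []
    for label, exclude in (
        ("all_fractions", ()),
        (excl_label, excluded),
    ):
        fit = regression.fit_richness_production(
            merged["observed"],
            merged["cs_php_ng_c_cell_h"],
            fractions=merged["fraction"],
            exclude_fractions=exclude,
        )
        fits.append(
            {
                "model": label,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "p": fit.p,
                "n": fit.n,
                "residual_sd": fit.residual_sd,
            }
        )
    io.write_table(pd.DataFrame(fits), outdir / "regression.tsv")

    grid = np.linspace(merged["observed"].min(), merged["observed"].max(), 50)
    fit_all = regression.RegressionFit(**{
        k: fits[0][k] for k in ("slope", "intercept", "r2", "p", "n", "residual_sd")
    })
    line = pd.DataFrame(
        {"obs": grid, "cs_php_fit": regression.predict(fit_all, grid)}
    )
    io.write_table(line, outdir / "fitted_line.tsv")


STAGES = {
    "simulate": stage_simulate,
    "deconvolve": stage_deconvolve,
    "flux": stage_flux,
    "diversity": stage_diversity,
    "regress": stage_regress,
}


def run_all(config: io.PipelineConfig, outdir, plots: bool = False) -> Path:
    """Execute the full chain and write a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES.values():
        stage(config, outdir)
    if plots:
        _export_plots(outdir)
    manifest = {
        "package": "snowcat",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "outputs": {
            p.name: io.file_sha256(p)
            for p in sorted(outdir.glob("*.tsv"))
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def _export_plots(outdir: Path) -> None:
    """Simple figure exports of the NMDS ordination and the regression."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = pd.read_csv(outdir / "nmds_coords.tsv", sep="\t", comment="#")
    meta = io.read_metadata(outdir / "metadata.tsv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for fraction, group in coords.set_index("sample_id").join(meta).groupby("fraction"):
        ax.scatter(group["NMDS1"], group["NMDS2"], label=fraction, s=20)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "nmds.png", dpi=120)
    plt.close(fig)

    alpha = io.read_table(outdir / "alpha.tsv").set_index("sample_id")
    flux_table = io.read_table(outdir / "flux_table.tsv").set_index("sample_id")
    merged = alpha.join(flux_table)
    line = io.read_table(outdir / "fitted_line.tsv")
    fig, ax = plt.subplots(figsize=(5, 4))
    for fraction, group in merged.groupby("fraction"):
        ax.scatter(group["observed"], group["cs_php_ng_c_cell_h"], label=fraction, s=20)
    ax.plot(line["obs"], line["cs_php_fit"], color="k", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("observed richness (OTUs)")
    ax.set_ylabel("cell-specific PHP (ng C cell$^{-1}$ h$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "regression.png", dpi=120)
    plt.close(fig)
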