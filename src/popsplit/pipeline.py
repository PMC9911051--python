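"""End-to-end orchestration: filter -> diversity/F_st -> f3/LD dating ->
divergence-model fits -> report bundle.

Reports round to the precision used in printed tables (F_st to 3
decimals, percent diversity to 3, years to integers) while full-precision
values are always written alongside; reruns with identical config and
seeds produce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, demography, popgen, variant_io
from .core import GenotypeMatrix, PopulationMap, read_popmap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    out_dir: str
    genetic_map: str | None = None
    site_mask: str | None = None
    max_missing_frac: float = 0.5
    min_qual: float = 30.0
    hwe_alpha: float = 1e-6
    ld_window_bp: int = 50_000
    ld_r2_max: float = 0.5
    ld_step_sites: int = 5
    run_ld_prune: bool = True
    groups: dict[str, list[str]] = field(default_factory=dict)
    f3_block_size: int = 500
    lddate_target: str | None = None
    lddate_refs: list[str] = field(default_factory=list)
    lddate_bin_width_cm: float = 0.05
    lddate_min_cm: float = 0.5
    lddate_max_cm: float = 30.0
    fit_pairs: list[list[str]] = field(default_factory=list)
    fit_families: list[str] = field(default_factory=lambda: ["no_migration"])
    fit_projection: int | None = None
    fit_genealogies: int = 200
    ga_population: int = 16
    ga_generations: int = 15
    local_maxiter: int = 100
    mu: float = 4e-9
    generation_time: float = 1.0
    t_years_max: float | None = None
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fit_pairs = raw.get("fit_pairs") or []
        raw["fit_pairs"] = [list(p) for p in fit_pairs]
        return cls(**raw)

    def validate(self) -> None:
        for name, p in (("vcf", self.vcf), ("popmap", self.popmap)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"pipeline config: {name} file {p!r} not found")
        for name, p in (("genetic_map", self.genetic_map), ("site_mask", self.site_mask)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"pipeline config: {name} file {p!r} not found")


def aggregate_pairwise_table(
    matrix: pd.DataFrame, groups: dict[str, list[str]]
) -> dict[str, float]:
    """Group summaries of a symmetric pairwise table.

    Within-group means use each unordered pair once; min and max run over
    all distinct pairs in the table.  Groups with fewer than two member
    populations get a NaN mean (flagged in logs).
    """
    if not matrix.index.equals(matrix.columns):
        raise ValueError("pairwise table must be square with matching labels")
    vals = matrix.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, equal_nan=True):
        raise ValueError("pairwise table must be symmetric")
    iu = np.triu_indices(len(matrix), k=1)
    all_pairs = vals[iu]
    all_pairs = all_pairs[~np.isnan(all_pairs)]
    out = {
        "min": float(np.min(all_pairs)),
        "max": float(np.max(all_pairs)),
    }
    for name, members in groups.items():
        if len(members) < 2:
            logger.warning("group %r has < 2 populations; mean undefined", name)
            out[f"mean_{name}"] = float("nan")
            continue
        sub = matrix.loc[members, members].to_numpy(dtype=float)
        ii = np.triu_indices(len(members), k=1)
        out[f"mean_{name}"] = float(np.nanmean(sub[ii]))
    return out


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run the full analysis; returns the report bundle as a dict and
    writes TSV/JSON artifacts to ``config.out_dir``.

    Halts with a stage-named error on failure; outputs written before the
    failure are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}

    stage = "read"
    try:
        gm = variant_io.read_vcf(config.vcf)
        popmap = read_popmap(config.popmap)
        popmap.validate_against(gm)
        gmap = (
            variant_io.read_genetic_map(config.genetic_map)
            if config.genetic_map
            else None
        )
        counts = {"input_sites": gm.n_sites}
        if config.site_mask:
            bed = variant_io.read_bed_mask(config.site_mask)
            gm = variant_io.apply_bed_mask(gm, bed)
            counts["after_site_mask"] = gm.n_sites

        stage = "filter"
        gm_f = variant_io.filter_sites(gm, config.max_missing_frac, config.min_qual)
        counts["after_qual_missing"] = gm_f.n_sites
        gm_f = variant_io.hwe_filter(gm_f, popmap, config.hwe_alpha)
        counts["after_hwe"] = gm_f.n_sites
        gm_unpruned = gm_f  # LD-based dating runs on unpruned sites
        if config.run_ld_prune:
            gm_f = variant_io.ld_prune(
                gm_f, config.ld_window_bp, config.ld_r2_max, config.ld_step_sites
            )
        counts["after_ld_prune"] = gm_f.n_sites
        bundle["site_counts"] = counts

        stage = "diversity"
        pops = popmap.populations
        stats = [popgen.diversity_stats(gm_f, popmap, p) for p in pops]
        div_table = popgen.summarize_diversity(stats, config.groups or None)
        _write_tsv(div_table, out / "diversity.tsv")
        bundle["diversity"] = div_table

        stage = "fst"
        mat = pd.DataFrame(np.nan, index=pops, columns=pops)
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                fst = popgen.weir_cockerham_fst(gm_f, popmap, a, b).fst
                mat.loc[a, b] = mat.loc[b, a] = fst
        _write_tsv(mat.round(3), out / "fst_matrix.tsv", index=True)
        bundle["fst_matrix"] = mat
        if config.groups:
            agg = aggregate_pairwise_table(mat, config.groups)
            bundle["fst_groups"] = agg
            (out / "fst_groups.json").write_text(
                json.dumps({k: round(v, 3) for k, v in agg.items()}, sort_keys=True)
            )

        stage = "f3"
        if len(pops) >= 3:
            f3_table = admixture.f3_scan(gm_f, popmap, block_size_snps=config.f3_block_size)
            _write_tsv(f3_table, out / "f3.tsv")
            bundle["f3"] = f3_table

        stage = "lddate"
        if config.lddate_target and gmap is not None:
            refs = config.lddate_refs
            # align the genetic map with the (filtered, unpruned) site set
            key = gm_unpruned.sites[["chrom", "pos"]]
            gmap_sub = key.merge(gmap, on=["chrom", "pos"], how="left")
            if gmap_sub["cM"].isna().any():
                raise ValueError("genetic map does not cover all retained sites")
            curve = admixture.weighted_ld_curve(
                gm_unpruned,
                popmap,
                config.lddate_target,
                refs[0],
                refs[1] if len(refs) > 1 else None,
                genetic_map=gmap_sub,
                bin_width_cm=config.lddate_bin_width_cm,
                min_cm=config.lddate_min_cm,
                max_cm=config.lddate_max_cm,
            )
            fit = admixture.fit_decay(
                curve, d0_cm=config.lddate_min_cm, generation_time=config.generation_time
            )
            bundle["lddate"] = fit
            report = {
                "mode": curve.mode,
                "decay_per_morgan": fit.decay,
                "amp_exp": fit.amp_exp,
                "affine": fit.affine,
                "z": fit.z,
                "date_years": fit.date_years,
                "se_date_years": fit.se_date_years,
                "status": fit.status,
            }
            (out / "lddate.json").write_text(json.dumps(report, sort_keys=True))

        stage = "fit"
        fit_rows = []
        for pair in config.fit_pairs:
            a, b = pair
            obs = popgen.joint_folded_sfs(
                gm_f, popmap, a, b, config.fit_projection, config.fit_projection
            )
            engine = demography.EngineSettings(
                n_genealogies=config.fit_genealogies, seed=config.seed + 7919
            )
            fits = {}
            for family in config.fit_families:
                fit = demography.fit_split_model(
                    obs,
                    family,
                    seed=config.seed,
                    engine=engine,
                    ga=demography.GASettings(
                        population=config.ga_population,
                        generations=config.ga_generations,
                        local_maxiter=config.local_maxiter,
                    ),
                    bounds=demography.FitBounds(T_years_max=config.t_years_max),
                    mu=config.mu,
                    generation_time=config.generation_time,
                )
                conv = demography.convert_units(
                    fit, mu=config.mu, L=obs.L, generation_time=config.generation_time
                )
                fits[family] = fit
                fit_rows.append(
                    {
                        "pop1": a,
                        "pop2": b,
                        "family": family,
                        "nu1": fit.model.nu1,
                        "nu2": fit.model.nu2,
                        "T": fit.model.T,
                        "m12": fit.model.m12,
                        "m21": fit.model.m21,
                        "theta_hat": fit.theta_hat,
                        "loglik": fit.loglik,
                        "N_anc": conv["N_anc"],
                        "N1": conv["N1"],
                        "N2": conv["N2"],
                        "T_years": round(conv["T_years"]),
                        "at_bound": ";".join(fit.at_bound),
                    }
                )
            if "no_migration" in fits:
                for family in ("unidirectional", "bidirectional"):
                    if family in fits:
                        lrt = demography.likelihood_ratio_test(
                            fits["no_migration"], fits[family]
                        )
                        fit_rows.append(
                            {
                                "pop1": a,
                                "pop2": b,
                                "family": f"LRT:no_migration_vs_{family}",
                                "loglik": lrt.statistic,
                                "theta_hat": lrt.p_value,
                            }
                        )
        if fit_rows:
            fit_table = pd.DataFrame(fit_rows)
            _write_tsv(fit_table, out / "fits.tsv")
            bundle["fits"] = fit_table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "site_counts.json").write_text(json.dumps(bundle["site_counts"], sort_keys=True))
    return bundle
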