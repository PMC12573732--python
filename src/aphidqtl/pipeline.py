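"""End-to-end orchestration: simulate -> QC/map -> Marey -> scans -> RHM
-> power -> enrichment, from one configuration with a master seed.

Each stage receives a deterministic child seed derived by hashing the
stage name against the master seed, so toggling one stage never shifts
another stage's randomness. Every intermediate is written in the
documented text formats and a JSON report aggregates the results.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import linkage, marey, power, regions, rhm, scan, simulate

logger = logging.getLogger("aphidqtl")

ALL_STAGES = ("simulate", "qc", "map", "marey", "scan", "rhm", "power", "enrich")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic child seed: crc32 of "master:stage", below 2^31."""
    return zlib.crc32(f"{master}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """All pipeline parameters with study-scale defaults.

    The permutation counts default to the full-scale analysis (1000
    scan and RHM permutations, 10,000 enrichment resamples); reduced
    values are recommended for interactive runs.
    """

    seed: int = 0
    outdir: str = "aphidqtl_run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # cross
    n_f2: int = 192
    n_markers: int = 120
    error_rate: float = 0.001
    missing_rate: float = 0.02
    frac_uninformative: float = 0.05
    frac_f0_het: float = 0.02
    frac_distorted: float = 0.02
    # phenotypes: trait -> target h2
    trait_h2: dict = field(default_factory=lambda: dict(simulate.TRAIT_H2))
    qtl_pve: float = 0.15
    qtl_chrom: str = "A3"
    qtl_pos_cm: float = 68.0
    phenotype_mode: str = "direct"
    # QC / mapping
    distortion_p: float = 0.001
    lod_limit: float = 6.0
    size_limit: int = 5
    join_lod: float = 3.0
    order_runs: int = 10
    error_lod_threshold: float = 5.0
    # scans
    scan_step: float = 1.0
    scan_permutations: int = 1000
    # RHM
    rhm_width: float = 20.0
    rhm_slide: float = 10.0
    rhm_permutations: int = 1000
    rhm_top_windows: int = 2
    # power
    power_n: int = 192
    power_spacing: float = 0.8
    power_alpha: float = 0.01
    # enrichment
    enrich_resamples: int = 10000
    gene_clustering: float = 0.5

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _qtl_effect_for_pve(pve: float, h2: float, polygenic_var: float) -> float:
    """Additive effect giving a QTL the requested share of trait variance.

    With polygenic variance Vp and environmental variance set from the
    target h2, solve a^2/2 = pve * total for the additive effect.
    """
    # total = (a^2/2 + Vp) / h2 ; a^2/2 = pve * total
    # => a^2/2 (1 - pve/h2) = pve/h2 * Vp
    ratio = pve / h2
    if ratio >= 1:
        raise ValueError("QTL share cannot exceed the trait heritability")
    a2_half = ratio * polygenic_var / (1 - ratio)
    return float(np.sqrt(2 * a2_half))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"config": asdict(config), "stages": {}}
    try:
        _run_stages(config, out, report)
    except Exception as exc:  # partial outputs are retained
        failed = report.get("current_stage", "unknown")
        logger.error("stage %s failed: %s", failed, exc)
        report["failed_stage"] = failed
        report["error"] = str(exc)
        _write_report(out, report)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    report.pop("current_stage", None)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _run_stages(config: RunConfig, out: Path, report: dict) -> None:
    stages = set(config.stages)
    genotypes = truth = founders = phenotypes = None
    est_map = None

    if "simulate" not in stages:
        # user-supplied inputs: read the documented formats from outdir
        geno_path = out / "genotypes.csv"
        if geno_path.exists():
            genotypes, mk = simulate.read_genotype_csv(geno_path)
            map_path = out / "true_map.tsv"
            if map_path.exists():
                mk = simulate.read_map_tsv(map_path)
            founders = None
            est_map = mk.copy()
            if "group" not in est_map.columns:
                est_map["group"] = est_map["chrom"]
            logger.info("loaded %d x %d genotypes from %s", *genotypes.shape,
                        geno_path)
        ph_path = out / "phenotypes.csv"
        if ph_path.exists():
            phenotypes = simulate.read_phenotype_csv(ph_path)

    if "simulate" in stages:
        report["current_stage"] = "simulate"
        logger.info("simulate: seed %d", stage_seed(config.seed, "simulate"))
        cross = simulate.CrossConfig(
            n_f2=config.n_f2,
            n_markers=config.n_markers,
            error_rate=config.error_rate,
            missing_rate=config.missing_rate,
            frac_uninformative=config.frac_uninformative,
            frac_f0_het=config.frac_f0_het,
            frac_distorted=config.frac_distorted,
            seed=stage_seed(config.seed, "simulate"),
        )
        founders = simulate.simulate_founders(cross)
        genotypes, truth = simulate.simulate_f2_genotypes(founders, cross)
        pheno_cols = {}
        pheno_seed = stage_seed(config.seed, "phenotypes")
        for i, (trait, h2) in enumerate(sorted(config.trait_h2.items())):
            arch = []
            if trait == "acceptance_alfalfa" and config.qtl_pve > 0:
                a = _qtl_effect_for_pve(config.qtl_pve, h2, 1.0)
                arch = [(config.qtl_chrom, config.qtl_pos_cm, a, 0.0)]
            model = simulate.PhenotypeModel(
                name=trait, architecture=arch, polygenic_var=1.0, h2=h2
            )
            tab = simulate.simulate_phenotypes(
                truth, model, seed=pheno_seed + i, mode=config.phenotype_mode
            )
            if trait.startswith("acceptance"):
                pheno_cols[trait] = tab["acceptance"]
            else:
                pheno_cols[trait] = tab["survival_steps"]
                pheno_cols[trait + "_count"] = tab["survival_count"]
        phenotypes = pd.DataFrame(pheno_cols)
        simulate.write_genotype_csv(out / "genotypes.csv", genotypes,
                                    founders.markers)
        simulate.write_phenotype_csv(out / "phenotypes.csv", phenotypes)
        simulate.write_map_tsv(out / "true_map.tsv", founders.markers)
        (out / "truth.json").write_text(truth.to_json())
        report["stages"]["simulate"] = {
            "n_f2": config.n_f2,
            "n_markers": int(len(founders.markers)),
        }

    retained = genotypes
    if "qc" in stages and genotypes is not None and founders is not None:
        report["current_stage"] = "qc"
        retained, qc = linkage.filter_markers(
            genotypes, founders, distortion_p=config.distortion_p
        )
        qc.to_frame().to_csv(out / "qc_removed.tsv", sep="\t", index=False)
        report["stages"]["qc"] = {
            "retained": int(retained.shape[1]),
            "removed": qc.counts(),
        }
        logger.info("qc: retained %d markers", retained.shape[1])

    if "map" in stages and retained is not None and founders is not None:
        report["current_stage"] = "map"
        mk_info = founders.markers.set_index("marker")
        is_x = (mk_info.loc[retained.columns, "chrom"] == "X").to_numpy()
        r, lod = linkage.pairwise_rf(retained, is_x)
        groups = linkage.group_markers(
            lod, list(retained.columns), config.lod_limit,
            size_limit=config.size_limit, join_lod=config.join_lod,
        )
        ordered: dict[str, list[str]] = {}
        map_seed = stage_seed(config.seed, "map")
        for gi, members in enumerate(groups.groups):
            idx = [list(retained.columns).index(m) for m in members]
            sub_r = r[np.ix_(idx, idx)]
            bp = mk_info.loc[members, "bp"].to_numpy()
            order, _rep = linkage.order_markers(
                sub_r, members, n_runs=config.order_runs, seed=map_seed + gi,
                physical_bp=bp,
            )
            # name the group by its majority true chromosome
            chroms = mk_info.loc[order, "chrom"]
            gname = str(chroms.mode().iloc[0])
            while gname in ordered:
                gname += "b"
            ordered[gname] = order
        is_x_by_marker = {m: bool(mk_info.loc[m, "chrom"] == "X")
                          for m in retained.columns}
        est_map = linkage.build_genetic_map(ordered, retained, is_x_by_marker)
        est_map = est_map.merge(
            mk_info.reset_index()[["marker", "bp", "chrom"]], on="marker"
        )
        _elod_report, elod_flagged = linkage.error_lod_flag(
            retained, est_map[["marker", "group", "cM"]],
            threshold=config.error_lod_threshold, epsilon=config.error_rate,
        )
        if elod_flagged:
            est_map = est_map[~est_map["marker"].isin(elod_flagged)]
        simulate.write_map_tsv(out / "estimated_map.tsv", est_map)
        report["stages"]["map"] = {
            "n_groups": len(groups.groups),
            "group_sizes": groups.sizes(),
            "total_cm": float(est_map.groupby("group")["cM"].max().sum()),
            "error_lod_removed": len(elod_flagged),
        }
        logger.info("map: %d groups, %.1f cM", len(groups.groups),
                    report["stages"]["map"]["total_cm"])

    if "marey" in stages and est_map is not None:
        report["current_stage"] = "marey"
        blocks_out = []
        suppression_out = []
        for group, sub in est_map.groupby("group"):
            mm = sub.rename(columns={"cM": "cM", "bp": "bp"})
            try:
                arr = marey.segment_marey(mm[["marker", "cM", "bp"]])
            except ValueError:
                continue
            frame = arr.to_frame()
            frame.insert(0, "group", group)
            blocks_out.append(frame)
            sup = marey.detect_suppression(mm[["marker", "cM", "bp"]])
            if len(sup):
                sup.insert(0, "group", group)
                suppression_out.append(sup)
        if blocks_out:
            blocks_df = pd.concat(blocks_out, ignore_index=True)
            blocks_df.to_csv(out / "marey_blocks.tsv", sep="\t", index=False)
            report["stages"]["marey"] = {
                "arrangements": {
                    g: [int(b) for b in
                        blocks_df[blocks_df["group"] == g]["block"]
                        * blocks_df[blocks_df["group"] == g]["sign"]]
                    for g in blocks_df["group"].unique()
                }
            }
        if suppression_out:
            pd.concat(suppression_out, ignore_index=True).to_csv(
                out / "suppressed_regions.bed", sep="\t", index=False
            )

    scan_regions = []
    if "scan" in stages and retained is not None:
        report["current_stage"] = "scan"
        use_map = est_map if est_map is not None else founders.markers
        chrom_col = "chrom"
        map_for_scan = use_map[["marker", chrom_col, "cM"]].copy()
        gp = scan.calc_genoprob(
            retained[map_for_scan["marker"]], map_for_scan,
            step=config.scan_step, epsilon=config.error_rate,
        )
        scan_report = {}
        scan_seed = stage_seed(config.seed, "scan")
        for i, trait in enumerate(sorted(config.trait_h2)):
            y = phenotypes[trait]
            model = "nonparametric" if trait.startswith("acceptance") else "two-part"
            if model == "nonparametric":
                res = scan.scan_nonparametric(gp, y, name=trait)
            else:
                res = scan.scan_twopart(gp, y, name=trait)
            thr, _max = scan.scan_permutation_threshold(
                gp, y, model=model, n_perm=config.scan_permutations,
                seed=scan_seed + i,
            )
            peaks = scan.find_peaks(res, thr)
            res.table.to_csv(out / f"scan_{trait}.tsv", sep="\t", index=False,
                             float_format="%.6g")
            scan_report[trait] = {
                "model": model,
                "threshold": thr,
                "peaks": peaks,
            }
            for pk in peaks:
                scan_regions.append((trait, pk["chrom"], *pk["interval"]))
        report["stages"]["scan"] = scan_report
        with open(out / "scan_peaks.json", "w") as fh:
            json.dump(scan_report, fh, indent=1, default=_jsonable)

    rhm_regions = []
    if "rhm" in stages and retained is not None:
        report["current_stage"] = "rhm"
        use_map = est_map if est_map is not None else founders.markers
        rhm_seed = stage_seed(config.seed, "rhm")
        rhm_report = {}
        window_frames = []
        for trait in sorted(config.trait_h2):
            if trait.startswith("survival"):
                y = phenotypes[trait + "_count"].to_numpy()
                family = "binomial"
            else:
                y = phenotypes[trait].to_numpy()
                family = "gaussian"
            res, overall = rhm.regional_scan(
                y, retained, use_map,
                windows=rhm.define_windows(use_map, config.rhm_width,
                                           config.rhm_slide),
                family=family, seed=rhm_seed,
            )
            res.insert(0, "trait", trait)
            # permutation cutoff for the top windows
            mk = use_map[use_map["marker"].isin(retained.columns)]
            X = retained[mk["marker"]].to_numpy()
            chrom = mk["chrom"].to_numpy()
            cm = mk["cM"].to_numpy(dtype=float)
            res["cutoff"] = np.nan
            res["exceeds"] = False
            top = res.dropna(subset=["Vr"]).nlargest(config.rhm_top_windows, "Vr")
            for idx, win in top.iterrows():
                inside = (chrom == win["chrom"]) & (cm >= win["start"]) & (
                    cm < win["end"]
                )
                Kr = rhm.compute_grm(X[:, inside])
                Kb = rhm.compute_grm(X[:, ~inside])
                perm = rhm.regional_permutation_test(
                    y, Kr, Kb, n_perm=config.rhm_permutations,
                    seed=rhm_seed + int(idx), family=family,
                    force=config.rhm_permutations < 100,
                )
                res.loc[idx, "cutoff"] = perm["cutoff"]
                res.loc[idx, "exceeds"] = perm["exceeds"]
                if perm["exceeds"]:
                    rhm_regions.append((trait, win["chrom"], win["start"],
                                        win["end"]))
            window_frames.append(res)
            rhm_report[trait] = {
                "overall_h2": overall.h2_total,
                "windows_exceeding": int(res["exceeds"].sum()),
            }
        pd.concat(window_frames, ignore_index=True).to_csv(
            out / "rhm_windows.tsv", sep="\t", index=False, float_format="%.6g"
        )
        report["stages"]["rhm"] = rhm_report

    if "power" in stages:
        report["current_stage"] = "power"
        tab = power.power_table(
            config.trait_h2, n=config.power_n, spacing_cm=config.power_spacing,
            alpha=config.power_alpha,
        )
        tab.to_csv(out / "power_table.tsv", sep="\t", index=False,
                   float_format="%.6g")
        report["stages"]["power"] = {
            row["trait"]: {"single": round(row["power_single_qtl"], 3),
                           "ten_equal": round(row["power_10_equal_qtl"], 3)}
            for _, row in tab.iterrows()
        }

    if "enrich" in stages and truth is not None:
        report["current_stage"] = "enrich"
        enrich_seed = stage_seed(config.seed, "enrich")
        genes = simulate.simulate_gene_positions(
            truth.config, clustering=config.gene_clustering, seed=enrich_seed
        )
        # regions from scan peaks and exceeding RHM windows, cM -> bp via
        # the true collinear scale when no markers flank
        region_rows = []
        use_map = est_map if est_map is not None else founders.markers
        for trait, chrom, lo, hi in scan_regions + rhm_regions:
            sub = use_map[use_map["chrom"] == chrom]
            if len(sub) < 2:
                continue
            bp_lo = float(np.interp(lo, sub["cM"], sub["bp"]))
            bp_hi = float(np.interp(hi, sub["cM"], sub["bp"]))
            lo_bp, hi_bp = sorted((bp_lo, bp_hi))
            if hi_bp > lo_bp:
                region_rows.append((f"{trait}_{chrom}_{lo:.0f}-{hi:.0f}",
                                    chrom, int(lo_bp), int(hi_bp) + 1))
        enrich_report = {"n_regions": len(region_rows)}
        if region_rows:
            reg = pd.DataFrame(region_rows,
                               columns=["name", "chrom", "start", "end"])
            reg.to_csv(out / "acceptance_regions.tsv", sep="\t", index=False)
            per, union, annotated = regions.genes_in_regions(genes, reg)
            annotated.to_csv(out / "genes_annotated.tsv", sep="\t", index=False)
            rng = np.random.default_rng(enrich_seed)
            subset = list(
                genes["gene"].sample(
                    n=min(24, len(genes)), random_state=int(rng.integers(2**31))
                )
            )
            perm = regions.region_enrichment_permutation(
                genes, subset, reg, n_perm=config.enrich_resamples,
                seed=enrich_seed,
            )
            n_or = int((genes["category"] == "OR").sum())
            in_reg = set(union)
            or_in = sum(1 for g in in_reg
                        if genes.set_index("gene").loc[g, "category"] == "OR")
            table = [[or_in, len(in_reg) - or_in],
                     [n_or - or_in, len(genes) - len(in_reg) - (n_or - or_in)]]
            fisher = regions.fisher_enrichment(table)
            enrich_report.update(
                {"genes_in_regions": len(union), "permutation": perm,
                 "fisher_OR": fisher}
            )
        report["stages"]["enrich"] = enrich_report

    report.pop("current_stage", None)
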