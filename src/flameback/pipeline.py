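"""End-to-end orchestration: simulate -> colour metrics -> pigment statistics
-> group tests -> phenotype score -> GWAS -> FST -> CNV -> report.

``run_all`` consumes a single :class:`RunConfig`, writes per-stage output
tables under the configured output directory, and returns a summary report
(also written as JSON). All randomness is routed through one seed-spawning
policy so every stage is independently reproducible; each stage logs its
parameters, seed and input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cnv, colour_score, pigments, spectra, stats, synthetic_data

log = logging.getLogger("flameback")

ELEMENT_COLUMNS = {"keto_c4": "mean_keto_c4", "oxy_c3": "mean_oxy_c3",
                   "epsilon": "mean_epsilon"}


@dataclass
class RunConfig:
    outdir: str = "flameback_run"
    seed: int = 0
    sim: synthetic_data.SimConfig | None = None   # None -> read existing inputs
    spectra_path: str | None = None
    spectra_dialect: str = "long"
    profiles_path: str | None = None
    lab_path: str | None = None
    vcf_path: str | None = None
    groups_path: str | None = None
    pigment_table_path: str = "default"
    n_resamples: int = 100_000
    alpha: float = 0.05
    filter_params: dict = dc_field(default_factory=dict)
    imputation: str = "group_mean"
    pca_mode: str = "covariance"
    fst_estimator: str = "hudson"
    fst_window_bp: int = assoc.FST_WINDOW_BP
    fst_window_mode: str = "sequenced"
    cnv_params: dict = dc_field(default_factory=dict)
    per_site_lambda: bool = True

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def _stage_seed(config: RunConfig, stage: str) -> int:
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _log_stage(stage: str, seed, **params) -> None:
    log.info("stage=%s seed=%s params=%s", stage, seed,
             json.dumps(params, default=str, sort_keys=True))


def run_all(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(config.to_json())
    report: dict = {"seed": config.seed}

    # --- inputs -----------------------------------------------------------
    if config.sim is not None:
        _log_stage("simulate", config.sim.seed)
        paths = synthetic_data.simulate(config.sim, outdir / "inputs")
    else:
        paths = {"spectra": config.spectra_path,
                 "pigment_profiles": config.profiles_path,
                 "lab": config.lab_path, "vcf": config.vcf_path,
                 "groups": config.groups_path}
        missing = [k for k, v in paths.items() if v is None]
        if missing:
            raise ValueError(f"no simulation requested and inputs missing: {missing}")
    for name, p in paths.items():
        if p and Path(p).exists():
            log.info("input=%s sha256=%s", name, _file_hash(p))

    groups_df = pd.read_csv(paths["groups"])
    groups = dict(zip(groups_df["sample_id"].astype(str), groups_df["group"].astype(str)))

    # --- colour metrics ---------------------------------------------------
    seed = _stage_seed(config, "colour")
    _log_stage("colour_metrics", seed, n_resamples=config.n_resamples)
    spec_list = spectra.read_spectra(paths["spectra"], dialect=config.spectra_dialect)
    metrics = spectra.metrics_per_sample(spec_list)
    metrics.to_csv(outdir / "colour_metrics.csv", index=False)
    groups_here = {s: groups[s] for s in metrics["sample_id"]}
    summary = spectra.summarize_colour_by_group(metrics, groups_here)
    summary.to_csv(outdir / "colour_group_summary.csv", index=False)
    hue = metrics.dropna(subset=["hue_r50_nm"])
    hue_test = stats.fisher_pitman_test(
        stats.GroupedValues(hue["hue_r50_nm"].to_numpy(),
                            hue["sample_id"].map(groups).to_numpy()),
        n_resamples=config.n_resamples, seed=seed)
    report["colour"] = {
        "group_summary": summary.to_dict(orient="records"),
        "hue_permutation_p": hue_test.p_value,
        "hue_permutation_method": hue_test.method,
    }

    # --- pigment functional groups ---------------------------------------
    seed = _stage_seed(config, "pigments")
    _log_stage("pigments", seed, table=config.pigment_table_path)
    table = pigments.load_pigment_table(config.pigment_table_path)
    profiles = pigments.read_profiles(paths["pigment_profiles"])
    fg = pigments.profiles_to_table(profiles, table)
    fg["group"] = fg["sample_id"].map(groups)
    fg.to_csv(outdir / "functional_groups.csv", index=False)

    pig_report = {}
    ss = np.random.SeedSequence(seed)
    elem_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    hue_by_sample = hue.set_index("sample_id")["hue_r50_nm"]
    for i, (element, col) in enumerate(ELEMENT_COLUMNS.items()):
        gv = stats.GroupedValues(fg[col].to_numpy(), fg["group"].to_numpy())
        omni = stats.fisher_pitman_test(gv, n_resamples=config.n_resamples,
                                        seed=elem_seeds[2 * i])
        posthoc = stats.pairwise_posthoc(gv, n_resamples=config.n_resamples,
                                         seed=elem_seeds[2 * i + 1])
        posthoc.to_csv(outdir / f"posthoc_{element}.csv", index=False)
        shared = fg[fg["sample_id"].isin(hue_by_sample.index)]
        rho = stats.spearman_corr(hue_by_sample.loc[shared["sample_id"]].to_numpy(),
                                  shared[col].to_numpy())
        pig_report[element] = {
            "group_means": fg.groupby("group")[col].mean().to_dict(),
            "permutation_p": omni.p_value,
            "posthoc_adjusted_p": {f"{r.group1}-{r.group2}": r.p_adjusted
                                   for r in posthoc.itertuples()},
            "hue_spearman_rho": rho.statistic,
            "hue_spearman_p": rho.p_value,
        }
    report["pigments"] = pig_report

    # --- phenotype score --------------------------------------------------
    _log_stage("colour_score", None, mode=config.pca_mode)
    colours = colour_score.read_lab(paths["lab"])
    scores = colour_score.score_table(colours, mode=config.pca_mode)
    scores.to_csv(outdir / "phenotype_scores.csv", index=False)
    score_by_sample = scores.set_index("sample_id")["score"]
    report["phenotype_score"] = {
        "pc_index": int(scores["pc_index"].iloc[0]),
        "variance_explained": float(scores["variance_explained"].iloc[0]),
        "group_means": score_by_sample.groupby(
            score_by_sample.index.map(groups)).mean().to_dict(),
    }

    # --- GWAS -------------------------------------------------------------
    _log_stage("gwas", None, filter=config.filter_params, impute=config.imputation)
    matrix = assoc.read_vcf(paths["vcf"])
    filtered, filter_counts = assoc.filter_variants(matrix, **config.filter_params)
    imputed = assoc.impute_missing(filtered, method=config.imputation, groups=groups)
    K = assoc.centred_kinship(imputed)
    y = score_by_sample.reindex(imputed.samples)
    if y.isna().any():
        raise ValueError("samples in VCF without a phenotype score")
    gwas = assoc.lmm_wald(y.to_numpy(), imputed, K,
                          per_site_lambda=config.per_site_lambda)
    gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    manhattan = assoc.manhattan_table(gwas, alpha=config.alpha)
    manhattan.to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
    sig = manhattan[manhattan["significant"]]
    report["gwas"] = {
        "filter_counts": filter_counts,
        "n_sites_tested": int(len(gwas)),
        "n_significant": int(len(sig)),
        "significant_sites": sig[["chrom", "pos"]].astype(str).to_dict(orient="records"),
        "top_site": (gwas.loc[gwas["wald_p"].idxmin(), ["chrom", "pos", "wald_p"]]
                     .astype(str).to_dict() if len(gwas) else None),
    }

    # --- windowed FST (red vs yellow, allopatric groups) ------------------
    _log_stage("fst", None, estimator=config.fst_estimator,
               window_bp=config.fst_window_bp)
    pops = {s: g for s, g in groups.items()
            if g in ("red", "yellow") and s in imputed.samples}
    rows = [i for i, s in enumerate(imputed.samples) if s in pops]
    sub = assoc.GenotypeMatrix(
        samples=[imputed.samples[i] for i in rows],
        chrom=imputed.chrom, pos=imputed.pos, ref=imputed.ref, alt=imputed.alt,
        gt=imputed.gt[rows], dp=imputed.dp[rows], gq=imputed.gq[rows],
        ad_ref=imputed.ad_ref[rows], ad_alt=imputed.ad_alt[rows],
        dosages=None if imputed.dosages is None else imputed.dosages[rows],
    )
    fst = assoc.windowed_fst(sub, pops, window_sequenced_bp=config.fst_window_bp,
                             estimator=config.fst_estimator,
                             window_mode=config.fst_window_mode)
    fst.to_csv(outdir / "fst_windows.tsv", sep="\t", index=False)
    report["fst"] = {
        "n_windows": int(len(fst)),
        "mean_fst": float(fst["fst"].mean()) if len(fst) else None,
        "max_fst": float(fst["fst"].max()) if len(fst) else None,
    }

    # --- CNV screen -------------------------------------------------------
    _log_stage("cnv", None, **{**cnv.CNV_DEFAULTS, **config.cnv_params,
                               "dup_band": "0.15-0.35|0.65-0.85"})
    profile = cnv.depth_profile(filtered)
    flags = cnv.flag_cnv(profile, **config.cnv_params)
    flagged = flags[flags["verdict"] != "normal"]
    flagged.to_csv(outdir / "cnv_flags.tsv", sep="\t", index=False)
    site_report = cnv.cnv_group_report(flags, groups)
    restricted = site_report[site_report["group_restricted"]
                             & (site_report["n_flagged"] >= 3)]
    site_report.to_csv(outdir / "cnv_site_report.tsv", sep="\t", index=False)
    report["cnv"] = {
        "note": cnv.BIAS_NOTE,
        "n_flagged_genotypes": int(len(flagged)),
        "group_restricted_sites": restricted[["chrom", "pos", "restricted_to"]]
            .astype(str).to_dict(orient="records"),
    }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
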