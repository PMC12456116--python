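"""Read-depth and allele-balance screen for candidate duplications.

A duplicated locus collapses onto a single reference position, so its reads
pile up: per-individual site depth exceeds that individual's genome-wide
mean. If a diploid carries a duplication and the copies differ in allele,
a heterozygous call shows a skewed allele balance near 3:1 (alt fraction
around 0.25 or 0.75) instead of 1:1; very high depth ratios suggest many
copies. The screen normalises each site depth by the individual's mean,
flags elevated-depth genotypes whose allele balance sits in the
duplication-consistent band, and reports sites whose flags are confined to
one phenotypic group.

Thresholds are screening defaults, all configurable; no correction for GC or
fragment-length amplification bias is attempted (the report carries a note
to that effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import GenotypeMatrix

CNV_DEFAULTS = dict(elevated_ratio=2.0, high_copy_ratio=10.0,
                    dup_band=((0.15, 0.35), (0.65, 0.85)), min_alleles=8)
BIAS_NOTE = ("read-depth ratios are not corrected for GC-content or "
             "fragment-length amplification bias")

VERDICTS = ("normal", "elevated_depth", "duplication_consistent", "high_copy")


@dataclass(frozen=True)
class DepthProfile:
    """Per-(site, individual) depths plus per-individual genome-wide means."""

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    total_depth: np.ndarray     # (n_samples, n_sites)
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    is_het: np.ndarray          # (n_samples, n_sites) bool
    mean_depth: np.ndarray      # (n_samples,)


def depth_profile(matrix: GenotypeMatrix) -> DepthProfile:
    """Build a depth profile from a genotype matrix with DP/AD fields.

    The per-individual mean is taken over that individual's genotyped
    (non-missing GT, finite DP) sites.
    """
    genotyped = np.all(matrix.gt >= 0, axis=2) & np.isfinite(matrix.dp)
    n_geno = genotyped.sum(axis=1)
    if np.any(n_geno == 0):
        bad = [s for s, k in zip(matrix.samples, n_geno) if k == 0]
        raise ValueError(f"individuals with zero genotyped sites: {bad}")
    means = np.where(genotyped, matrix.dp, np.nan)
    mean_depth = np.nanmean(means, axis=1)
    is_het = genotyped & (matrix.gt[:, :, 0] != matrix.gt[:, :, 1])
    return DepthProfile(list(matrix.samples), matrix.chrom, matrix.pos,
                        matrix.dp, matrix.ad_ref, matrix.ad_alt,
                        is_het, mean_depth)


def depth_normalize(profile: DepthProfile) -> np.ndarray:
    """depth_ratio = site depth / individual genome-wide mean depth."""
    if np.any(profile.mean_depth <= 0):
        raise ValueError("individual with non-positive mean depth")
    with np.errstate(invalid="ignore"):
        return profile.total_depth / profile.mean_depth[:, None]


def flag_cnv(profile: DepthProfile, **params) -> pd.DataFrame:
    """Per-(site, individual) copy-number verdicts.

    ``high_copy``: depth ratio >= high_copy_ratio. ``duplication_consistent``:
    ratio >= elevated_ratio at a heterozygous call with alt fraction in the
    3:1 band and at least min_alleles informative (ref+alt) reads.
    ``elevated_depth``: only the ratio criterion holds. ``normal`` otherwise.
    """
    p = {**CNV_DEFAULTS, **params}
    ratio = depth_normalize(profile)
    informative = profile.ref_depth + profile.alt_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(informative > 0, profile.alt_depth / informative, np.nan)
    in_band = np.zeros_like(ratio, dtype=bool)
    for lo, hi in p["dup_band"]:
        in_band |= (alt_frac >= lo) & (alt_frac <= hi)
    elevated = np.isfinite(ratio) & (ratio >= p["elevated_ratio"])
    enough_reads = np.where(np.isfinite(informative), informative, -1.0) >= p["min_alleles"]
    dup = elevated & profile.is_het & in_band & enough_reads
    high = np.isfinite(ratio) & (ratio >= p["high_copy_ratio"])

    verdict = np.full(ratio.shape, "normal", dtype=object)
    verdict[elevated] = "elevated_depth"
    verdict[dup] = "duplication_consistent"
    verdict[high] = "high_copy"

    n, m = ratio.shape
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    return pd.DataFrame({
        "chrom": profile.chrom[jj.ravel()],
        "pos": profile.pos[jj.ravel()],
        "sample_id": np.array(profile.samples, dtype=object)[ii.ravel()],
        "depth_ratio": ratio.ravel(),
        "alt_fraction": alt_frac.ravel(),
        "verdict": verdict.ravel(),
    })


def cnv_group_report(flags: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Per-site, per-group verdict fractions; marks group-restricted sites.

    A site is group-restricted when every elevated/duplication/high-copy
    verdict at the site falls in a single phenotypic group.
    """
    unknown = set(flags["sample_id"]) - set(groups)
    if unknown:
        raise ValueError(f"samples without group labels: {sorted(unknown)[:5]}")
    df = flags.copy()
    df["group"] = df["sample_id"].map(groups)
    df["flagged"] = df["verdict"] != "normal"
    rows = []
    for (chrom, pos), site in df.groupby(["chrom", "pos"], sort=False):
        row = {"chrom": chrom, "pos": pos}
        flagged_groups = set(site.loc[site["flagged"], "group"])
        for g, grp in site.groupby("group"):
            for v in VERDICTS:
                row[f"{g}_frac_{v}"] = float(np.mean(grp["verdict"] == v))
        row["n_flagged"] = int(site["flagged"].sum())
        row["group_restricted"] = len(flagged_groups) == 1
        row["restricted_to"] = next(iter(flagged_groups)) if len(flagged_groups) == 1 else ""
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["note"] = BIAS_NOTE
    return out
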