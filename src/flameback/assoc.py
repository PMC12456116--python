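"""Genotype handling, mixed-model association and windowed FST.

The association pipeline mirrors a reduced-representation (GBS) workflow
downstream of genotype calling:

1. site/genotype filtering (biallelic SNPs; per-genotype depth and quality
   masking; minor-allele-count and missingness thresholds);
2. mean-dosage imputation of remaining missing genotypes;
3. a centred relatedness (kinship) matrix K = X_c X_c^T / p from the imputed
   dosage matrix;
4. per-SNP association with the scalar colour phenotype under the linear
   mixed model y = W a + x b + u + e, var(u) = sg^2 K, var(e) = se^2 I,
   tested with a Wald chi-square on b (GEMMA-style: the variance ratio
   lambda = sg^2/se^2 is profiled by maximum likelihood on a log grid with
   Brent refinement, after a single eigendecomposition of K);
5. Hudson-style windowed FST between two allopatric phenotypic groups over
   non-overlapping windows of sequenced (covered) base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from scipy import optimize, stats as sps

from .stats import bh_fdr

FILTER_DEFAULTS = dict(biallelic_only=True, mac_min=3, dp_min=3, gq_min=25,
                       max_missing_frac=0.6)
LAMBDA_LOG10_RANGE = (-5.0, 5.0)
LAMBDA_GRID_POINTS = 50
FST_WINDOW_BP = 10_000


# ---------------------------------------------------------------------------
# genotype container and VCF I/O
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Genotypes plus the per-genotype FORMAT fields the pipeline uses.

    ``gt`` holds allele indices (n_samples, n_sites, 2) with -1 for missing;
    ``dp``/``gq``/``ad_ref``/``ad_alt`` are (n_samples, n_sites) with NaN
    where the field was absent. ``dosages`` is filled by imputation.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dosages: np.ndarray | None = None
    contig_lengths: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def is_biallelic_snp(self) -> np.ndarray:
        return np.array([("," not in a) and len(r) == 1 and len(a) == 1 and a != "*"
                         for r, a in zip(self.ref, self.alt)])

    def dosage_matrix(self) -> np.ndarray:
        """Alt-allele counts in {0,1,2}; NaN for missing or non-{0,1} alleles."""
        d = np.sum(self.gt == 1, axis=2).astype(float)
        bad = np.any((self.gt < 0) | (self.gt > 1), axis=2)
        d[bad] = np.nan
        return d

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx], pos=self.pos[idx],
            ref=self.ref[idx], alt=self.alt[idx],
            gt=self.gt[:, idx, :].copy(),
            dp=self.dp[:, idx].copy(), gq=self.gq[:, idx].copy(),
            ad_ref=self.ad_ref[:, idx].copy(), ad_alt=self.ad_alt[:, idx].copy(),
            dosages=None if self.dosages is None else self.dosages[:, idx].copy(),
            contig_lengths=dict(self.contig_lengths),
        )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT/DP/GQ/AD from a VCF 4.x file (plain or bgzipped)."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError("VCF has no samples in the header")
    n = len(samples)
    chrom, pos, ref, alt = [], [], [], []
    gt_rows, dp_rows, gq_rows, ad_ref_rows, ad_alt_rows = [], [], [], [], []
    for rec in vf:
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref or "N")
        alt.append(",".join(rec.alts) if rec.alts else ".")
        gts = np.full((n, 2), -1, dtype=np.int8)
        dps = np.full(n, np.nan)
        gqs = np.full(n, np.nan)
        adr = np.full(n, np.nan)
        ada = np.full(n, np.nan)
        for i, s in enumerate(samples):
            sd = rec.samples[s]
            g = sd.get("GT")
            if g is not None:
                alleles = [(-1 if a is None else a) for a in g][:2]
                alleles += [-1] * (2 - len(alleles))
                gts[i] = alleles
            if sd.get("DP") is not None:
                dps[i] = sd["DP"]
            if sd.get("GQ") is not None:
                gqs[i] = sd["GQ"]
            ad = sd.get("AD")
            if ad is not None and ad[0] is not None:
                adr[i] = ad[0]
                ada[i] = ad[1] if len(ad) > 1 and ad[1] is not None else 0
        gt_rows.append(gts)
        dp_rows.append(dps)
        gq_rows.append(gqs)
        ad_ref_rows.append(adr)
        ad_alt_rows.append(ada)
    lengths = {c: vf.header.contigs[c].length for c in vf.header.contigs}
    vf.close()
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object), pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        gt=np.stack(gt_rows, axis=1) if gt_rows else np.empty((n, 0, 2), dtype=np.int8),
        dp=np.column_stack(dp_rows) if dp_rows else np.empty((n, 0)),
        gq=np.column_stack(gq_rows) if gq_rows else np.empty((n, 0)),
        ad_ref=np.column_stack(ad_ref_rows) if ad_ref_rows else np.empty((n, 0)),
        ad_alt=np.column_stack(ad_alt_rows) if ad_alt_rows else np.empty((n, 0)),
        contig_lengths={k: v for k, v in lengths.items() if v},
    )


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write GT/DP/GQ/AD (uncompressed VCF); lossless for the fields read."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (ref,alt)">')
    contigs = dict(matrix.contig_lengths)
    for c in pd.unique(matrix.chrom):
        length = contigs.get(c) or int(matrix.pos[matrix.chrom == c].max()) + 1000
        header.add_line(f"##contig=<ID={c},length={length}>")
    for s in matrix.samples:
        header.add_sample(s)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for j in range(matrix.n_sites):
        rec = vf.new_record(contig=str(matrix.chrom[j]), start=int(matrix.pos[j]) - 1,
                            alleles=(str(matrix.ref[j]),
                                     *str(matrix.alt[j]).split(",")))
        for i, s in enumerate(matrix.samples):
            g = matrix.gt[i, j]
            rec.samples[s]["GT"] = tuple(None if a < 0 else int(a) for a in g)
            rec.samples[s].phased = False
            if np.isfinite(matrix.dp[i, j]):
                rec.samples[s]["DP"] = int(matrix.dp[i, j])
            if np.isfinite(matrix.gq[i, j]):
                rec.samples[s]["GQ"] = int(matrix.gq[i, j])
            if np.isfinite(matrix.ad_ref[i, j]):
                extra_alts = len(rec.alleles) - 2  # pad AD for extra alt alleles
                rec.samples[s]["AD"] = (int(matrix.ad_ref[i, j]),
                                        int(matrix.ad_alt[i, j]),
                                        *([0] * extra_alts))
        vf.write(rec)
    vf.close()


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------

def filter_variants(matrix: GenotypeMatrix, **params):
    """Apply the fixed-order site/genotype filters.

    Order: (1) drop non-biallelic / non-SNP records; (2) mask genotypes with
    DP < dp_min or GQ < gq_min; (3) drop sites with minor allele count <
    mac_min among the remaining genotypes; (4) drop sites with missing
    fraction > max_missing_frac. Returns (filtered matrix, per-rule counts).
    """
    p = {**FILTER_DEFAULTS, **params}
    counts = {}
    m = matrix
    n_in = m.n_sites

    if p["biallelic_only"]:
        keep = m.is_biallelic_snp
        counts["non_biallelic_snp"] = int(np.sum(~keep))
        m = m.take_sites(np.flatnonzero(keep))
    else:
        counts["non_biallelic_snp"] = 0
        m = m.take_sites(np.arange(m.n_sites))  # work on a copy

    # per-genotype masking; NaN DP/GQ (field absent) passes
    with np.errstate(invalid="ignore"):
        mask = (m.dp < p["dp_min"]) | (m.gq < p["gq_min"])
    m.gt[mask] = -1
    counts["genotypes_masked"] = int(np.sum(mask))

    dos = m.dosage_matrix()
    called = ~np.isnan(dos)
    alt_count = np.nansum(dos, axis=0)
    total_alleles = 2 * called.sum(axis=0)
    mac = np.minimum(alt_count, total_alleles - alt_count)
    keep = mac >= p["mac_min"]
    counts["mac_below_min"] = int(np.sum(~keep))
    m = m.take_sites(np.flatnonzero(keep))

    dos = m.dosage_matrix()
    missing_frac = np.mean(np.isnan(dos), axis=0)
    keep = missing_frac <= p["max_missing_frac"]
    counts["excess_missing"] = int(np.sum(~keep))
    m = m.take_sites(np.flatnonzero(keep))

    counts["sites_in"] = n_in
    counts["sites_out"] = m.n_sites
    if m.n_sites == 0:
        import warnings
        warnings.warn("no sites survived filtering")
    return m, counts


def impute_missing(matrix: GenotypeMatrix, method: str = "group_mean",
                   groups: dict | None = None) -> GenotypeMatrix:
    """Replace missing dosages with the (group or global) per-site mean.

    Imputed values are fractional dosages, matching the expectation-based
    genotype files mixed-model software consumes.
    """
    dos = matrix.dosage_matrix()
    if method not in ("group_mean", "global_mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    if method == "group_mean" and groups is None:
        method = "global_mean"
    site_all_missing = np.all(np.isnan(dos), axis=0)
    if np.any(site_all_missing):
        bad = np.flatnonzero(site_all_missing)[:5]
        raise ValueError(f"sites entirely missing after filtering "
                         f"(e.g. column indices {bad.tolist()}); drop them first")
    global_mean = np.nanmean(dos, axis=0)
    filled = dos.copy()
    if method == "global_mean":
        idx = np.where(np.isnan(filled))
        filled[idx] = global_mean[idx[1]]
    else:
        labels = np.array([groups[s] for s in matrix.samples])
        for g in np.unique(labels):
            rows = labels == g
            sub = filled[rows]
            gmean = np.nanmean(np.where(np.isnan(sub), np.nan, sub), axis=0)
            gmean = np.where(np.isnan(gmean), global_mean, gmean)  # group all-missing
            idx = np.where(np.isnan(sub))
            sub[idx] = gmean[idx[1]]
            filled[rows] = sub
    out = matrix.take_sites(np.arange(matrix.n_sites))
    out.dosages = filled
    return out


# ---------------------------------------------------------------------------
# kinship and mixed-model association
# ---------------------------------------------------------------------------

def centred_kinship(matrix_or_dosages) -> np.ndarray:
    """Centred relatedness matrix K = X_c X_c^T / p (site-mean-centred)."""
    X = (matrix_or_dosages.dosages if isinstance(matrix_or_dosages, GenotypeMatrix)
         else np.asarray(matrix_or_dosages, dtype=float))
    if X is None:
        raise ValueError("impute before computing kinship")
    if np.any(np.isnan(X)):
        raise ValueError("dosage matrix contains missing values; impute first")
    if X.shape[1] < 1:
        raise ValueError("no sites")
    Xc = X - X.mean(axis=0, keepdims=True)
    K = Xc @ Xc.T / X.shape[1]
    if np.allclose(K, 0):
        import warnings
        warnings.warn("all sites monomorphic: kinship is zero")
    return K


def _ml_loglik_terms(lam, s, wt, xt, yt):
    """Profiled ML log-likelihood pieces for all sites at one lambda.

    Returns (loglik per site, beta, var_beta_unit) where var(beta) =
    sigma_e^2 * var_beta_unit.
    """
    d = lam * s + 1.0
    w = 1.0 / d
    a11 = np.sum(w * wt * wt)
    b1 = np.sum(w * wt * yt)
    yy = np.sum(w * yt * yt)
    a12 = (w * wt) @ xt
    a22 = w @ (xt * xt)
    b2 = (w * yt) @ xt
    det = a11 * a22 - a12 * a12
    det = np.where(det <= 0, np.nan, det)
    beta = (a11 * b2 - a12 * b1) / det
    alpha = (a22 * b1 - a12 * b2) / det
    rss = yy - (alpha * b1 + beta * b2)
    rss = np.clip(rss, 1e-300, None)
    n = yt.size
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0) - 0.5 * np.sum(np.log(d))
    return loglik, beta, a11 / det, rss


def lmm_wald(y, matrix_or_dosages, K: np.ndarray,
             per_site_lambda: bool = True, fdr: bool = True) -> pd.DataFrame:
    """Univariate LMM Wald association of each SNP with the phenotype.

    For each site, the variance ratio lambda is profiled by ML on a
    log10 grid over [-5, 5] with Brent refinement (or fitted once under the
    null when ``per_site_lambda`` is False); the Wald statistic
    (beta/se)^2 is referred to chi-square(1). Returns a table with beta, se,
    wald_p, fdr_adjusted_p and minus_log10_p (of the adjusted p).
    """
    X = (matrix_or_dosages.dosages if isinstance(matrix_or_dosages, GenotypeMatrix)
         else np.asarray(matrix_or_dosages, dtype=float))
    if X is None or np.any(np.isnan(X)):
        raise ValueError("complete (imputed) dosage matrix required")
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("phenotype length does not match sample count")
    if not np.allclose(K, K.T):
        raise ValueError("K must be symmetric")
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-8 * max(s.max(), 1.0):
        raise ValueError("K is not positive semi-definite")
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    wt = U.T @ np.ones(n)
    Xt = U.T @ X

    grid = np.logspace(*LAMBDA_LOG10_RANGE, LAMBDA_GRID_POINTS)
    step = (LAMBDA_LOG10_RANGE[1] - LAMBDA_LOG10_RANGE[0]) / (LAMBDA_GRID_POINTS - 1)

    if not per_site_lambda:
        # null model: intercept only
        def negll(loglam):
            d = 10.0**loglam * s + 1.0
            w = 1.0 / d
            a11 = np.sum(w * wt * wt)
            b1 = np.sum(w * wt * yt)
            rss = max(np.sum(w * yt * yt) - b1 * b1 / a11, 1e-300)
            return 0.5 * n * (np.log(2 * np.pi * rss / n) + 1) + 0.5 * np.sum(np.log(d))
        res = optimize.minimize_scalar(negll, bounds=LAMBDA_LOG10_RANGE, method="bounded")
        lam_all = np.full(p, 10.0**res.x)
        ll, beta, vb_unit, rss = _ml_loglik_terms(lam_all[0], s, wt, Xt, yt)
    else:
        lls = np.empty((grid.size, p))
        for i, lam in enumerate(grid):
            lls[i], _, _, _ = _ml_loglik_terms(lam, s, wt, Xt, yt)
        best = np.nanargmax(lls, axis=0)
        lam_all = np.empty(p)
        beta = np.empty(p)
        vb_unit = np.empty(p)
        rss = np.empty(p)
        log_grid = np.log10(grid)
        for j in range(p):
            lo = log_grid[max(best[j] - 1, 0)]
            hi = log_grid[min(best[j] + 1, grid.size - 1)]
            if hi - lo < 1e-9:
                lam_j = grid[best[j]]
            else:
                xtj = Xt[:, j]

                def negll_site(loglam, xtj=xtj):
                    ll_j, _, _, _ = _ml_loglik_terms(10.0**loglam, s, wt,
                                                     xtj[:, None], yt)
                    return -ll_j[0]
                r = optimize.minimize_scalar(negll_site, bounds=(lo, hi),
                                             method="bounded",
                                             options={"xatol": step * 1e-3})
                lam_j = 10.0**r.x
            lam_all[j] = lam_j
            ll_j, b_j, v_j, r_j = _ml_loglik_terms(lam_j, s, wt, Xt[:, j:j+1], yt)
            beta[j], vb_unit[j], rss[j] = b_j[0], v_j[0], r_j[0]

    dof = n - 2  # intercept + SNP
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * vb_unit)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, (beta / se) ** 2, 0.0)
    pvals = sps.chi2.sf(wald, df=1)
    pvals = np.clip(np.where(np.isnan(pvals), 1.0, pvals), np.finfo(float).tiny, 1.0)
    beta = np.where(np.isnan(beta), 0.0, beta)

    out = pd.DataFrame({
        "chrom": (matrix_or_dosages.chrom if isinstance(matrix_or_dosages, GenotypeMatrix)
                  else np.arange(p).astype(str)),
        "pos": (matrix_or_dosages.pos if isinstance(matrix_or_dosages, GenotypeMatrix)
                else np.arange(1, p + 1)),
        "beta": beta, "se": se, "lambda_ml": lam_all, "wald_p": pvals,
    })
    if fdr:
        out["fdr_adjusted_p"] = bh_fdr(out["wald_p"].to_numpy())
        out["minus_log10_p"] = -np.log10(out["fdr_adjusted_p"])
    return out


# ---------------------------------------------------------------------------
# windowed FST
# ---------------------------------------------------------------------------

def _hudson_components(ac1, an1, ac2, an2):
    """Per-site Hudson numerator/denominator from allele counts.

    Sample-size corrected: num = (p1-p2)^2 - p1 q1/(n1-1) - p2 q2/(n2-1),
    den = p1 q2 + p2 q1. Sites with fewer than 2 alleles in a population get
    NaN components and are excluded from window sums.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ac1 / an1
        p2 = ac2 / an2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (an1 - 1)
               - p2 * (1 - p2) / (an2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (an1 < 2) | (an2 < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def _wc_components(ac1, an1, ac2, an2):
    """Weir & Cockerham (1984) two-population theta components per site."""
    with np.errstate(divide="ignore", invalid="ignore"):
        n1, n2 = an1 / 2.0, an2 / 2.0          # diploid sample sizes
        p1, p2 = ac1 / an1, ac2 / an2
        nbar = (n1 + n2) / 2.0
        r = 2.0
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * 2 * p1 * (1 - p1) * an1 / (an1 - 1)
                + n2 * 2 * p2 * (1 - p2) * an2 / (an2 - 1)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (an1 < 2) | (an2 < 2)
    num = np.where(bad, np.nan, a)
    den = np.where(bad, np.nan, a + b + c)
    return num, den


def windowed_fst(matrix: GenotypeMatrix, pop_assignments: dict,
                 window_sequenced_bp: int = FST_WINDOW_BP,
                 estimator: str = "hudson",
                 window_mode: str = "sequenced") -> pd.DataFrame:
    """Ratio-of-averages FST in non-overlapping windows between two groups.

    ``sequenced`` window mode advances over the ordered covered positions
    (here: the variant sites), closing a window when the cumulative covered-
    position count reaches ``window_sequenced_bp``; ``genomic`` mode uses
    fixed genomic-coordinate bins of that width. Windows whose summed
    denominator is zero (or with no usable sites) are omitted.
    """
    pops = sorted(set(pop_assignments.values()))
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    if estimator not in ("hudson", "weir_cockerham"):
        raise ValueError(f"unknown FST estimator {estimator!r}")
    dos = matrix.dosage_matrix() if matrix.dosages is None else matrix.dosages
    labels = np.array([pop_assignments.get(s) for s in matrix.samples], dtype=object)
    if any(l is None for l in labels):
        missing = [s for s, l in zip(matrix.samples, labels) if l is None]
        raise ValueError(f"samples without population assignment: {missing[:5]}")

    def pop_counts(rows):
        sub = dos[rows]
        called = ~np.isnan(sub)
        # fractional (imputed) dosages contribute fractionally to allele counts
        return np.nansum(sub, axis=0), 2 * called.sum(axis=0)

    ac1, an1 = pop_counts(labels == pops[0])
    ac2, an2 = pop_counts(labels == pops[1])
    comp = _hudson_components if estimator == "hudson" else _wc_components
    num, den = comp(ac1.astype(float), an1.astype(float),
                    ac2.astype(float), an2.astype(float))

    rows = []
    for c in pd.unique(matrix.chrom):
        idx = np.flatnonzero(matrix.chrom == c)
        idx = idx[np.argsort(matrix.pos[idx], kind="stable")]
        positions = matrix.pos[idx]
        if window_mode == "sequenced":
            bounds = np.arange(0, idx.size, window_sequenced_bp)
            chunks = [idx[b:b + window_sequenced_bp] for b in bounds]
        elif window_mode == "genomic":
            bin_idx = (positions - 1) // window_sequenced_bp
            chunks = [idx[bin_idx == b] for b in np.unique(bin_idx)]
        else:
            raise ValueError(f"unknown window mode {window_mode!r}")
        for chunk in chunks:
            usable = chunk[np.isfinite(num[chunk]) & np.isfinite(den[chunk])]
            if usable.size == 0:
                continue
            d = float(np.sum(den[usable]))
            if d <= 0:
                continue
            rows.append({
                "chrom": c,
                "window_start": int(matrix.pos[usable].min()),
                "window_end": int(matrix.pos[usable].max()),
                "n_sites": int(usable.size),
                "fst": float(np.sum(num[usable]) / d),
            })
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                       "n_sites", "fst"])


def genome_coverage_percent(covered_bp: int, genome_bp: float) -> float:
    """Percent of the reference genome covered by sequenced bases.

    Reduced-representation (GBS) data covers a small fraction of the genome;
    this bookkeeping quantity contextualises the windowed statistics built
    over sequenced base pairs.
    """
    if covered_bp < 0 or genome_bp <= 0:
        raise ValueError("base-pair counts must be positive")
    return 100.0 * covered_bp / genome_bp


def manhattan_table(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready table; sites with FDR-adjusted p <= alpha are flagged."""
    threshold = -np.log10(alpha)
    out = assoc[["chrom", "pos"]].copy()
    out["minus_log10_q"] = -np.log10(assoc["fdr_adjusted_p"])
    out["significant"] = out["minus_log10_q"] >= threshold
    return out
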