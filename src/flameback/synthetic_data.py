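"""Synthetic study generator.

Produces every input the pipeline consumes — pigment profiles, reflectance
spectra, LAB colours, genotypes with per-genotype depth/quality fields, a
phenotype and a truth table — for three phenotypic groups (red, orange,
yellow) with the statistical structure the analysis assumes:

* group-specific pigment mixtures (red: astaxanthin-dominant keto
  carotenoids; yellow: lutein / 3'-dehydro-lutein with epsilon-ringed
  metabolites; orange: intermediate blends), log-normal around group means;
* sigmoidal reflectance curves whose half-rise hue tracks each bird's
  keto-carotenoid prevalence, calibrated so group mean hues hit the
  configured targets (602 / 575 / 546 nm red / orange / yellow by default);
* LAB colours whose a (redness) channel follows the keto statistic and b
  (yellowness) the yellow-pigment share;
* Balding-Nichols genotypes with weak background differentiation between
  the red and yellow groups, a few strongly divergent causal SNPs that build
  the quantitative phenotype, duplication loci with inflated depth and a
  3:1 allele balance confined to one group, and configurable missingness.

Everything is driven by one integer seed; equal seeds give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import GenotypeMatrix, write_vcf
from .colour_score import LabColour
from .pigments import PigmentProfile, PigmentTable, functional_group_mean, load_pigment_table
from .spectra import Spectrum

GROUPS = ("red", "orange", "yellow")

# group pigment mixtures (concentration means, ug per g pigmented feather)
DEFAULT_PIGMENT_MEANS = {
    "red": {
        "astaxanthin": 120.0, "adonirubin": 10.0, "alpha-doradexanthin": 8.0,
        "papilioerythrinone": 6.0, "canthaxanthin": 5.0, "lutein": 2.0,
    },
    "yellow": {
        "lutein": 80.0, "3'-dehydro-lutein": 50.0, "zeaxanthin": 8.0,
        "beta-cryptoxanthin": 6.0, "canary-xanthophyll A": 10.0,
        "canary-xanthophyll B": 8.0, "papilioerythrinone": 1.0,
        "alpha-doradexanthin": 1.0, "canthaxanthin": 0.5,
    },
    "orange": {
        "lutein": 40.0, "3'-dehydro-lutein": 25.0, "zeaxanthin": 4.0,
        "beta-cryptoxanthin": 3.0, "canary-xanthophyll A": 6.0,
        "canary-xanthophyll B": 5.0, "alpha-doradexanthin": 25.0,
        "papilioerythrinone": 20.0, "astaxanthin": 8.0,
        "canthaxanthin": 3.0, "adonirubin": 3.0,
    },
}


@dataclass
class SimConfig:
    seed: int = 0
    n_per_group: dict = dc_field(default_factory=lambda: {
        "red": 45, "orange": 25, "yellow": 36})
    hue_targets_nm: dict = dc_field(default_factory=lambda: {
        "red": 602.0, "orange": 575.0, "yellow": 546.0})
    pigment_means: dict = dc_field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PIGMENT_MEANS.items()})
    concentration_sigma: float = 0.3     # log-normal sigma on concentrations
    spectrum_base: float = 5.0           # % reflectance floor
    spectrum_amplitude: float = 45.0     # % rise of the sigmoid
    spectrum_slope_nm: float = 10.0      # sigmoid scale
    spectrum_noise_sd: float = 0.5       # % per-wavelength replicate noise
    lab_noise_sd: float = 1.0
    n_snps: int = 2000
    n_chroms: int = 5
    background_fst: float = 0.05
    causal_loci: list = dc_field(default_factory=lambda: [(2, 50, 0.5)])
    causal_divergent: bool = True   # give causal loci strong red/yellow freq gap
    cnv_loci: list = dc_field(default_factory=lambda: [(3, 40, "red", 3.0)])
    polygenic_h2: float = 0.3
    mean_depth: float = 20.0
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if any(self.n_per_group.get(g, 0) < 2 for g in GROUPS):
            raise ValueError("each group needs at least 2 individuals")

    def sample_ids(self) -> list[str]:
        return [f"{g}_{i:03d}" for g in GROUPS for i in range(self.n_per_group[g])]

    def group_labels(self) -> dict:
        return {sid: sid.rsplit("_", 1)[0] for sid in self.sample_ids()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per stage derived from the one seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


def gen_pigment_profiles(config: SimConfig,
                         table: PigmentTable | None = None) -> tuple[list[PigmentProfile], dict]:
    """Group-structured pigment profiles; concentrations log-normal around
    the group means, same unit for every pigment."""
    table = table or load_pigment_table()
    for g in GROUPS:
        for name in config.pigment_means[g]:
            if name not in table:
                raise KeyError(f"pigment {name!r} in config absent from the table")
    rng = _rng(config, "pigments")
    profiles = []
    for sid in config.sample_ids():
        g = sid.rsplit("_", 1)[0]
        conc = {}
        for name, mean in config.pigment_means[g].items():
            noise = rng.lognormal(0.0, config.concentration_sigma) \
                if config.concentration_sigma > 0 else 1.0
            conc[name] = mean * noise
        profiles.append(PigmentProfile(sid, conc, "mantle"))
    return profiles, config.group_labels()


def _keto_stats(profiles, table) -> np.ndarray:
    return np.array([functional_group_mean(p, table, "keto_c4") for p in profiles])


def _hue_map(config: SimConfig, profiles, table):
    """Piecewise-linear monotone map keto-statistic -> sigmoid midpoint,
    anchored at the group keto means and the configured hue targets."""
    groups = np.array([p.sample_id.rsplit("_", 1)[0] for p in profiles])
    keto = _keto_stats(profiles, table)
    anchors = sorted(((float(keto[groups == g].mean()), config.hue_targets_nm[g])
                      for g in GROUPS))
    ak = np.array([a[0] for a in anchors])
    ah = np.array([a[1] for a in anchors])

    def mapper(k):
        k = np.asarray(k, dtype=float)
        m = np.interp(k, ak, ah)
        # linear extrapolation beyond the outer anchors
        lo_slope = (ah[1] - ah[0]) / (ak[1] - ak[0])
        hi_slope = (ah[-1] - ah[-2]) / (ak[-1] - ak[-2])
        m = np.where(k < ak[0], ah[0] + (k - ak[0]) * lo_slope, m)
        m = np.where(k > ak[-1], ah[-1] + (k - ak[-1]) * hi_slope, m)
        return m
    return mapper


def gen_spectra(config: SimConfig, profiles: list[PigmentProfile],
                table: PigmentTable | None = None) -> list[Spectrum]:
    """Three replicate sigmoidal reflectance curves per bird, 375-700 nm at
    1-nm steps, with the half-rise midpoint set by the bird's keto
    prevalence."""
    table = table or load_pigment_table()
    rng = _rng(config, "spectra")
    mapper = _hue_map(config, profiles, table)
    midpoints = mapper(_keto_stats(profiles, table))
    wl = np.arange(375.0, 701.0)
    out = []
    for prof, m in zip(profiles, midpoints):
        clean = (config.spectrum_base
                 + config.spectrum_amplitude
                 / (1.0 + np.exp(-(wl - m) / config.spectrum_slope_nm)))
        for rep in range(1, 4):
            noise = (rng.normal(0.0, config.spectrum_noise_sd, wl.size)
                     if config.spectrum_noise_sd > 0 else 0.0)
            out.append(Spectrum(wl, np.clip(clean + noise, 0.0, None),
                                prof.sample_id, str(rep)))
    return out


def gen_lab_colours(config: SimConfig, profiles: list[PigmentProfile],
                    table: PigmentTable | None = None) -> list[LabColour]:
    """LAB triplets: a tracks the keto statistic (redness), b the yellow
    pigment share, L mildly varying."""
    table = table or load_pigment_table()
    rng = _rng(config, "lab")
    keto = _keto_stats(profiles, table)
    out = []
    for prof, k in zip(profiles, keto):
        total = sum(prof.concentrations.values())
        yellow_share = sum(c for name, c in prof.concentrations.items()
                           if table[name].origin_class in
                           ("dietary_yellow", "metabolised_yellow")) / total
        noise = (rng.normal(0.0, config.lab_noise_sd, 3)
                 if config.lab_noise_sd > 0 else np.zeros(3))
        L = float(np.clip(60.0 + noise[0], 0.0, 100.0))
        a = float(5.0 + 12.0 * k + noise[1])
        b = float(10.0 + 40.0 * yellow_share + noise[2])
        out.append(LabColour(prof.sample_id, L, a, b))
    return out


def gen_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, pd.Series, pd.DataFrame]:
    """Balding-Nichols genotypes, phenotype and truth table.

    Red and yellow group allele frequencies are independently drawn around a
    uniform ancestral frequency with drift parameter F = background_fst;
    orange (admixed) frequencies are the average of the two. Causal loci get
    strong red/yellow divergence and additive standardised effects; the
    phenotype adds a polygenic term built from all SNPs (variance
    polygenic_h2) and residual noise (variance 1 - polygenic_h2). CNV loci
    are heterozygous in the target group with depth multiplied and alt
    fraction in the 3:1 band.
    """
    rng = _rng(config, "genotypes")
    samples = config.sample_ids()
    labels = np.array([s.rsplit("_", 1)[0] for s in samples])
    n = len(samples)
    p = config.n_snps
    per_chrom = np.full(config.n_chroms, p // config.n_chroms)
    per_chrom[: p % config.n_chroms] += 1

    chrom = np.concatenate([np.full(c, f"chr{i+1}", dtype=object)
                            for i, c in enumerate(per_chrom)])
    pos = np.concatenate([np.cumsum(rng.integers(200, 4000, size=c))
                          for c in per_chrom]).astype(np.int64)

    anc = rng.uniform(0.05, 0.95, size=p)
    F = config.background_fst
    if F > 0:
        a_par = anc * (1 - F) / F
        b_par = (1 - anc) * (1 - F) / F
        freq = {"red": rng.beta(a_par, b_par), "yellow": rng.beta(a_par, b_par)}
    else:
        freq = {"red": anc.copy(), "yellow": anc.copy()}
    freq["orange"] = 0.5 * (freq["red"] + freq["yellow"])

    chrom_offsets = {f"chr{i+1}": int(np.sum(per_chrom[:i]))
                     for i in range(config.n_chroms)}

    causal_idx, causal_effects = [], []
    for c, idx, eff in config.causal_loci:
        j = chrom_offsets[f"chr{c}"] + idx
        if idx >= per_chrom[c - 1]:
            raise ValueError(f"causal index {idx} out of range for chr{c}")
        if config.causal_divergent:
            freq["red"][j] = rng.uniform(0.80, 0.95)
            freq["yellow"][j] = rng.uniform(0.05, 0.20)
            freq["orange"][j] = 0.5 * (freq["red"][j] + freq["yellow"][j])
        causal_idx.append(j)
        causal_effects.append(eff)

    cnv_sites = []
    for c, idx, group, mult in config.cnv_loci:
        j = chrom_offsets[f"chr{c}"] + idx
        if idx >= per_chrom[c - 1]:
            raise ValueError(f"CNV index {idx} out of range for chr{c}")
        cnv_sites.append((j, group, float(mult)))

    # genotypes
    dosage = np.empty((n, p), dtype=float)
    for g in GROUPS:
        rows = labels == g
        dosage[rows] = rng.binomial(2, freq[g][None, :], size=(rows.sum(), p))

    # CNV loci: heterozygous in the target group
    for j, group, mult in cnv_sites:
        rows = labels == group
        dosage[rows, j] = 1.0

    gt = np.zeros((n, p, 2), dtype=np.int8)
    gt[:, :, 0] = (dosage >= 1)
    gt[:, :, 1] = (dosage == 2)
    # hets as 0/1
    het = dosage == 1
    gt[het, 0] = 0
    gt[het, 1] = 1

    # phenotype
    Xc = dosage - dosage.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Xc / sd
    y = np.zeros(n)
    for j, eff in zip(causal_idx, causal_effects):
        y += eff * Z[:, j]
    if config.polygenic_h2 > 0:
        w = rng.normal(0.0, 1.0, size=p)
        u = Z @ w
        u_sd = u.std()
        if u_sd > 0:
            y += np.sqrt(config.polygenic_h2) * u / u_sd
    y += rng.normal(0.0, np.sqrt(max(1.0 - config.polygenic_h2, 0.0)), size=n)

    # depths, qualities, allele depths
    dp = rng.poisson(config.mean_depth, size=(n, p)).astype(float)
    gq = rng.integers(30, 61, size=(n, p)).astype(float)
    is_het = gt[:, :, 0] != gt[:, :, 1]
    alt = np.where(gt[:, :, 0] + gt[:, :, 1] == 2, dp, 0.0)
    alt_het = rng.binomial(dp.astype(int), 0.5)
    alt = np.where(is_het, alt_het, alt)

    for j, group, mult in cnv_sites:
        rows = np.flatnonzero(labels == group)
        dp[rows, j] = rng.poisson(config.mean_depth * mult, size=rows.size)
        alt[rows, j] = rng.binomial(dp[rows, j].astype(int), 0.25)
    ad_ref = dp - alt

    if config.missing_rate > 0:
        miss = rng.random((n, p)) < config.missing_rate
        gt[miss] = -1

    matrix = GenotypeMatrix(
        samples=samples, chrom=chrom, pos=pos,
        ref=np.full(p, "A", dtype=object), alt=np.full(p, "G", dtype=object),
        gt=gt, dp=dp, gq=gq, ad_ref=ad_ref, ad_alt=alt,
    )
    phenotype = pd.Series(y, index=samples, name="score")

    truth_rows = []
    for j, eff in zip(causal_idx, causal_effects):
        truth_rows.append({"chrom": chrom[j], "pos": int(pos[j]), "kind": "causal",
                           "effect": eff, "group": "",
                           "freq_red": freq["red"][j], "freq_yellow": freq["yellow"][j]})
    for j, group, mult in cnv_sites:
        truth_rows.append({"chrom": chrom[j], "pos": int(pos[j]), "kind": "cnv",
                           "effect": mult, "group": group,
                           "freq_red": freq["red"][j], "freq_yellow": freq["yellow"][j]})
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "kind", "effect",
                                              "group", "freq_red", "freq_yellow"])
    return matrix, phenotype, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def spectra_to_csv(spectra: list[Spectrum], path) -> None:
    frames = [pd.DataFrame({"sample": s.sample_id, "replicate": s.replicate_id,
                            "wavelength": s.wavelengths_nm,
                            "reflectance": s.reflectance_pct})
              for s in spectra]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def profiles_to_csv(profiles: list[PigmentProfile], path) -> None:
    rows = [{"sample_id": p.sample_id, "feather_region": p.feather_region,
             "pigment": name, "concentration": conc}
            for p in profiles for name, conc in p.concentrations.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def lab_to_csv(colours: list[LabColour], path) -> None:
    pd.DataFrame({"sample_id": [c.sample_id for c in colours],
                  "L": [c.L for c in colours],
                  "a": [c.a for c in colours],
                  "b": [c.b for c in colours]}).to_csv(path, index=False)


def simulate(config: SimConfig, outdir) -> dict:
    """Generate the full synthetic study and write every pipeline input.

    Returns the paths of the emitted files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_pigment_table()
    profiles, groups = gen_pigment_profiles(config, table)
    spectra = gen_spectra(config, profiles, table)
    colours = gen_lab_colours(config, profiles, table)
    matrix, phenotype, truth = gen_genotypes(config)

    paths = {
        "spectra": outdir / "spectra.csv",
        "pigment_profiles": outdir / "pigment_profiles.csv",
        "lab": outdir / "lab_colours.csv",
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth.tsv",
        "groups": outdir / "groups.csv",
        "phenotype_truth": outdir / "phenotype_truth.csv",
        "config": outdir / "config.json",
    }
    spectra_to_csv(spectra, paths["spectra"])
    profiles_to_csv(profiles, paths["pigment_profiles"])
    lab_to_csv(colours, paths["lab"])
    write_vcf(matrix, paths["vcf"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}
                 ).to_csv(paths["groups"], index=False)
    phenotype.rename_axis("sample_id").reset_index().to_csv(
        paths["phenotype_truth"], index=False)
    paths["config"].write_text(config.to_json())
    return {k: str(v) for k, v in paths.items()}
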