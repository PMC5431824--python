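"""Synthetic dioecious populations with an XY-type sex-determining region.

The generator emulates the statistical structure the downstream analyses
assume: a compact SDR of fully sex-linked SNPs (females homozygous reference,
"XX"; males heterozygous, "XY"), genome-wide background SNPs whose ALT
frequencies follow latitudinal clines on the logit scale, an approximately
1:1 sex ratio, a small fraction of SDR recombinants (individuals carrying a
partially swapped SDR haplotype), clonal ramets within plantation sites, and
quantitative traits with latitude effects and an optional sex effect.

Every draw comes from per-stage child streams of a single root seed, so an
identical ``(config, seed)`` pair reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError
from .types import GenotypeMatrix

# stage order for SeedSequence.spawn; fixed so adding stages never reshuffles
_STAGES = ("sex", "geography", "background", "sdr", "missing")

#: FLNRO-style collection window (degrees west), used for the longitude column
_LON_RANGE = (-137.9, -121.2)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of a synthetic dioecious population.

    Defaults describe the population regime the pipeline is designed for: a
    ~1:1 sex ratio, a 12-marker fully sex-linked SDR, <1% SDR recombinants,
    ~1% per-marker mistyping, and background SNPs with moderate latitudinal
    clines over a 44.0-59.6 degN collection window.
    """

    n_individuals: int = 500
    sex_ratio: float = 0.5           # P(male)
    n_background_snps: int = 1000
    n_sdr_snps: int = 12
    maf_range: tuple = (0.05, 0.5)   # range of baseline ALT frequencies
    cline_sd: float = 0.05           # SD of per-SNP logit slope per degree
    lat_range: tuple = (44.0, 59.6)  # degrees north
    sdr_error_rate: float = 0.01     # P(marker mistyped to opposite-sex class)
    missing_rate: float = 0.02
    recombinant_fraction: float = 0.005
    n_ramets_per_genotype: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sex_ratio", "sdr_error_rate", "missing_rate",
                     "recombinant_fraction"):
            v = getattr(self, name)
            _check(np.isfinite(v) and 0.0 <= v <= 1.0,
                   f"{name} must be a probability in [0, 1], got {v!r}")
        _check(self.n_individuals >= 1, "n_individuals must be >= 1")
        _check(self.n_sdr_snps >= 1, "n_sdr_snps must be >= 1")
        _check(self.n_background_snps >= 0, "n_background_snps must be >= 0")
        _check(self.n_ramets_per_genotype >= 1,
               "n_ramets_per_genotype must be >= 1")
        lo, hi = self.maf_range
        _check(0.0 < lo <= hi <= 0.5,
               f"maf_range must lie within (0, 0.5], got {self.maf_range!r}")
        _check(np.isfinite(self.cline_sd) and self.cline_sd >= 0.0,
               f"cline_sd must be a finite non-negative SD, got {self.cline_sd!r}")
        la, lb = self.lat_range
        _check(-90.0 <= la <= lb <= 90.0,
               f"lat_range must be an ordered latitude interval, got {self.lat_range!r}")


@dataclass
class TraitSimConfig:
    """Generative model for one quantitative trait.

    ``plantation`` design:
        y = mu + beta_lat*lat + delta_sex*[male] + beta_interaction*lat*[male]
            + G_genotype + eps,
    with the genotype effect G shared across all ramets and sites of a clone.

    ``factorial_warming`` design (paired 2x2 chilling-scenario x forcing-
    temperature experiment):
        y = mu + beta_scenario*[later] + beta_temperature*[warm]
            + beta_scenario_temperature*[later & warm] + delta_sex*[male]
            + G_genotype + eps.

    ``confound_sex_lat`` is a sampling-bias switch: when non-zero, the
    probability that a sample is phenotyped depends on sex x latitude
    (logistic in centred latitude), inducing the sex-latitude correlation
    that produces spurious dimorphism when geography is not modelled.
    """

    trait_name: str = "trait"
    mu: float = 0.0
    beta_lat: float = 0.0
    delta_sex: float = 0.0
    beta_interaction: float = 0.0
    sigma_G: float = 1.0
    sigma_E: float = 1.0
    confound_sex_lat: float = 0.0
    design: str = "plantation"
    beta_scenario: float = 0.0
    beta_temperature: float = 0.0
    beta_scenario_temperature: float = 0.0

    def __post_init__(self) -> None:
        _check(np.isfinite(self.sigma_G) and self.sigma_G >= 0.0,
               f"sigma_G must be >= 0, got {self.sigma_G!r}")
        _check(np.isfinite(self.sigma_E) and self.sigma_E > 0.0,
               f"sigma_E must be > 0, got {self.sigma_E!r}")
        if self.design not in ("plantation", "factorial_warming"):
            raise ConfigError(
                f"design must be 'plantation' or 'factorial_warming', "
                f"got {self.design!r}")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated population."""

    true_sex: pd.Series                 # sample_id -> 'F'/'M'
    recombinant: pd.Series              # sample_id -> bool
    sex_linked: pd.Series               # snp id -> bool
    baseline_freq: pd.Series            # snp id -> p0 (nan for SDR SNPs)
    cline_slope: pd.Series              # snp id -> logit slope per degree
    lat_mid: float = 0.0
    trait_variance_components: dict = field(default_factory=dict)

    def allele_frequency(self, snp_id: str, lat: float) -> float:
        """Realized ALT frequency of a background SNP at a given latitude."""
        p0 = self.baseline_freq[snp_id]
        b = self.cline_slope[snp_id]
        return float(expit(logit(p0) + b * (lat - self.lat_mid)))

    def to_dict(self) -> dict:
        return {
            "true_sex": self.true_sex.to_dict(),
            "recombinant": {k: bool(v) for k, v in self.recombinant.items()},
            "sex_linked": {k: bool(v) for k, v in self.sex_linked.items()},
            "baseline_freq": {
                k: (None if isinstance(v, float) and math.isnan(v) else float(v))
                for k, v in self.baseline_freq.items()
            },
            "cline_slope": {k: float(v) for k, v in self.cline_slope.items()},
            "lat_mid": float(self.lat_mid),
            "trait_variance_components": self.trait_variance_components,
        }


def _stage_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def simulate_population(config: SimConfig):
    """Draw a dioecious population: genotypes, sample sheet and truth record.

    Returns
    -------
    (GenotypeMatrix, DataFrame, TruthRecord)
        The sample sheet has columns ``sample_id, genotype_id, sex, latitude,
        longitude, source`` with sex in {'F', 'M'} (true sex; callers mask it
        to 'U' to emulate unsexed material).
    """
    rngs = _stage_rngs(config.seed)
    n = config.n_individuals
    ids = [f"G{i + 1:05d}" for i in range(n)]

    is_male = rngs["sex"].random(n) < config.sex_ratio
    recomb = rngs["sex"].random(n) < config.recombinant_fraction

    lat_lo, lat_hi = config.lat_range
    lat = rngs["geography"].uniform(lat_lo, lat_hi, size=n)
    lon = rngs["geography"].uniform(*_LON_RANGE, size=n)
    lat_mid = 0.5 * (lat_lo + lat_hi)

    m_bg = config.n_background_snps
    m_sdr = config.n_sdr_snps
    dos = np.empty((n, m_bg + m_sdr), dtype=float)

    # background SNPs: latitude-dependent ALT frequency on the logit scale
    p0 = rngs["background"].uniform(*config.maf_range, size=m_bg)
    slope = rngs["background"].normal(0.0, config.cline_sd, size=m_bg)
    if m_bg:
        p_lat = expit(logit(p0)[None, :] + slope[None, :] * (lat - lat_mid)[:, None])
        dos[:, :m_bg] = rngs["background"].binomial(2, p_lat).astype(float)

    # SDR: females hom-ref (0), males het (1); block-swap for recombinants;
    # independent per-marker mistyping to the opposite-sex class
    sdr = np.where(is_male[:, None], 1.0, 0.0) * np.ones((n, m_sdr))
    half = m_sdr // 2
    if half:
        swap_block = np.zeros(m_sdr, dtype=bool)
        swap_block[m_sdr - half:] = True   # contiguous half of the SDR
        sdr[np.ix_(recomb, swap_block)] = 1.0 - sdr[np.ix_(recomb, swap_block)]
    flips = rngs["sdr"].random((n, m_sdr)) < config.sdr_error_rate
    sdr[flips] = 1.0 - sdr[flips]
    dos[:, m_bg:] = sdr

    if config.missing_rate > 0:
        miss = rngs["missing"].random(dos.shape) < config.missing_rate
        dos[miss] = np.nan

    chroms = [f"Chr{(j % 19) + 1:02d}" for j in range(m_bg)]
    positions = [100_000 + 500 * (j // 19) for j in range(m_bg)]
    snp_ids = [f"bg{j + 1:05d}" for j in range(m_bg)]
    # SDR markers sit in a compact window on chromosome 19
    chroms += ["Chr19"] * m_sdr
    positions += [15_890_000 + 100 * j for j in range(m_sdr)]
    snp_ids += [f"sdr{j + 1:03d}" for j in range(m_sdr)]

    bases = ("A", "C", "G", "T")
    snps = pd.DataFrame({
        "chrom": chroms,
        "pos": positions,
        "id": snp_ids,
        "ref": [bases[j % 4] for j in range(m_bg + m_sdr)],
        "alt": [bases[(j + 1) % 4] for j in range(m_bg + m_sdr)],
    })
    G = GenotypeMatrix(dosages=dos, snps=snps, samples=ids)

    samples = pd.DataFrame({
        "sample_id": ids,
        "genotype_id": ids,
        "sex": np.where(is_male, "M", "F"),
        "latitude": lat,
        "longitude": lon,
        "source": "sim",
    })

    truth = TruthRecord(
        true_sex=pd.Series(np.where(is_male, "M", "F"), index=ids),
        recombinant=pd.Series(recomb, index=ids),
        sex_linked=pd.Series(
            [False] * m_bg + [True] * m_sdr, index=snp_ids),
        baseline_freq=pd.Series(
            np.concatenate([p0, np.full(m_sdr, np.nan)]), index=snp_ids),
        cline_slope=pd.Series(
            np.concatenate([slope, np.zeros(m_sdr)]), index=snp_ids),
        lat_mid=lat_mid,
    )
    return G, samples, truth


def simulate_traits(config: TraitSimConfig, samples: pd.DataFrame,
                    n_sites: int = 1, seed: int = 0,
                    n_ramets: int = 1, truth: TruthRecord | None = None
                    ) -> pd.DataFrame:
    """Simulate a trait table for the genotypes in a sample sheet.

    Genotype effects are drawn once per clone and shared across every ramet
    and site; residual noise is independent per planted tree. When
    ``confound_sex_lat`` is non-zero, each genotype enters the phenotyped set
    with probability ``expit(+/- confound * (lat - lat_mid))`` (sign by sex),
    emulating geographically biased sampling of males versus females.

    Returns a long-format DataFrame (one row per ramet x site observation)
    with columns ``genotype_id, ramet, site, year, sex, latitude, longitude,
    trait, value`` (plus ``scenario`` and ``temperature`` for the
    factorial_warming design). Realized variance components are appended to
    ``truth.trait_variance_components`` when a truth record is supplied.
    """
    if config.design not in ("plantation", "factorial_warming"):
        raise ConfigError(f"unknown design {config.design!r}")
    required = {"genotype_id", "sex", "latitude"}
    missing = required - set(samples.columns)
    if missing:
        raise ConfigError(f"sample sheet lacks columns {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    geno = samples.drop_duplicates("genotype_id").reset_index(drop=True)
    lat = geno["latitude"].to_numpy(float)
    lat_mid = 0.5 * (lat.min() + lat.max()) if len(lat) else 0.0
    male = (geno["sex"].astype(str).str.upper().str[0] == "M").to_numpy()

    if config.confound_sex_lat != 0.0:
        eta = config.confound_sex_lat * (lat - lat_mid)
        p_inc = np.where(male, expit(eta), expit(-eta))
        keep = rng.random(len(geno)) < p_inc
        geno = geno[keep].reset_index(drop=True)
        lat, male = lat[keep], male[keep]

    g_eff = rng.normal(0.0, config.sigma_G, size=len(geno))

    rows = []
    if config.design == "plantation":
        fixed = (config.mu
                 + config.beta_lat * lat
                 + config.delta_sex * male
                 + config.beta_interaction * lat * male)
        for site in range(1, n_sites + 1):
            for ramet in range(1, n_ramets + 1):
                eps = rng.normal(0.0, config.sigma_E, size=len(geno))
                rows.append(pd.DataFrame({
                    "genotype_id": geno["genotype_id"].to_numpy(),
                    "ramet": ramet,
                    "site": f"site{site}",
                    "year": 2010,
                    "sex": np.where(male, "M", "F"),
                    "latitude": lat,
                    "longitude": geno.get(
                        "longitude", pd.Series(np.nan, index=geno.index)
                    ).to_numpy(),
                    "trait": config.trait_name,
                    "value": fixed + g_eff + eps,
                }))
    else:  # factorial_warming: each genotype observed at both temperatures
        scen = np.where(rng.random(len(geno)) < 0.5, "early", "later")
        for temp in (10, 20):
            warm = float(temp == 20)
            later = (scen == "later").astype(float)
            fixed = (config.mu
                     + config.beta_scenario * later
                     + config.beta_temperature * warm
                     + config.beta_scenario_temperature * later * warm
                     + config.delta_sex * male)
            eps = rng.normal(0.0, config.sigma_E, size=len(geno))
            rows.append(pd.DataFrame({
                "genotype_id": geno["genotype_id"].to_numpy(),
                "ramet": 1,
                "site": "chamber",
                "year": 2015,
                "sex": np.where(male, "M", "F"),
                "latitude": lat,
                "longitude": geno.get(
                    "longitude", pd.Series(np.nan, index=geno.index)
                ).to_numpy(),
                "scenario": scen,
                "temperature": temp,
                "trait": config.trait_name,
                "value": fixed + g_eff + eps,
            }))

    table = pd.concat(rows, ignore_index=True)
    if truth is not None:
        truth.trait_variance_components[config.trait_name] = {
            "sigma_G": config.sigma_G, "sigma_E": config.sigma_E,
            "delta_sex": config.delta_sex, "beta_lat": config.beta_lat,
            "beta_interaction": config.beta_interaction,
            "design": config.design,
        }
    return table


def config_to_dict(config) -> dict:
    """Serializable view of a simulation config (for provenance stanzas)."""
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
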