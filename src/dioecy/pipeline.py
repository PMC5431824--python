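"""End-to-end pipeline: simulate (optional) -> scan -> profile/select ->
call sex -> dimorphism tests, with per-stage provenance stanzas.

Every stage writes its table plus a JSON provenance record naming the inputs,
parameters and seed that produced it, so re-running an identical
configuration reproduces identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .simpop import SimConfig, TraitSimConfig, simulate_population, \
    simulate_traits, config_to_dict
from .scan import FilterSettings, run_scan
from .sexcall import (profile_markers, select_predictive, call_sex,
                      profiles_to_frame, calls_to_frame, summarize_calls,
                      EmptyPanelWarning)
from .dimorph import run_battery
from .tables import read_sample_table, read_trait_table, write_sample_table, \
    write_trait_table
from .vcf import read_vcf, write_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    out_dir: str = "dioecy_out"
    vcf_path: str | None = None
    sample_path: str | None = None
    trait_path: str | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    maf_min: float = 0.05
    call_rate_min: float = 0.9
    alpha: float = 0.05
    test: str = "trend"
    pca_correction: int = 0
    min_acc: float = 0.90
    tau: float = 0.9
    min_markers: int = 5
    max_mismatch: float = 0.05
    geography_mode: str = "latlon"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha!r}")
        for name in ("maf_min", "call_rate_min", "min_acc", "tau",
                     "max_mismatch"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.test not in ("trend", "logistic"):
            raise ConfigError(f"unknown test {self.test!r}")
        if self.geography_mode not in ("latlon", "pcs"):
            raise ConfigError(f"unknown geography_mode {self.geography_mode!r}")
        if self.min_markers < 1:
            raise ConfigError("min_markers must be >= 1")
        if not self.simulate:
            for p in (self.vcf_path, self.sample_path):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"input path missing or absent: {p!r}")
            if self.trait_path is not None and not Path(self.trait_path).exists():
                raise ConfigError(f"trait table not found: {self.trait_path!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("sim", {}).items()})
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg


def _provenance(out: Path, stage: str, inputs: dict, params: dict) -> None:
    stanza = {"stage": stage, "inputs": inputs, "params": params,
              "package": "dioecy", "version": __version__}
    (out / f"{stage}.provenance.json").write_text(
        json.dumps(stanza, indent=2, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        G, samples, truth = simulate_population(config.sim)
        write_vcf(G, out / "genotypes.vcf")
        write_sample_table(samples, out / "samples.csv")
        (out / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2) + "\n")
        _provenance(out, "simulate", {}, {"sim": config_to_dict(config.sim)})
        trait_table = None
        if config.trait_path:
            trait_table = read_trait_table(config.trait_path)
    else:
        G = read_vcf(config.vcf_path)
        samples = read_sample_table(config.sample_path)
        trait_table = (read_trait_table(config.trait_path)
                       if config.trait_path else None)

    # association scan on samples with known sex
    scan_res = run_scan(
        G, samples, test=config.test, pca_correction=config.pca_correction,
        alpha=config.alpha,
        filters=FilterSettings(config.maf_min, config.call_rate_min))
    scan_res.to_csv(out / "assoc.tsv", sep="\t", index=False)
    _provenance(out, "scan",
                {"vcf": str(config.vcf_path), "samples": str(config.sample_path)},
                {"test": config.test, "alpha": config.alpha,
                 "pca_correction": config.pca_correction,
                 "maf_min": config.maf_min,
                 "call_rate_min": config.call_rate_min,
                 "seed": config.seed})

    # marker profiling on significant SNPs, panel selection
    hits = scan_res.loc[scan_res["significant_bonferroni"], "id"].tolist()
    if not hits:
        log.warning("no Bonferroni-significant SNPs; stopping after scan")
        return out
    sexes = samples.set_index("sample_id")["sex"]
    known_ids = [s for s in G.samples
                 if str(sexes.get(s, "U")).upper()[:1] in ("F", "M")]
    profiles = profile_markers(G.take_samples(known_ids),
                               sexes.loc[known_ids], hits)
    profiles_to_frame(profiles).to_csv(out / "marker_profiles.tsv",
                                       sep="\t", index=False)
    panel = select_predictive(profiles, min_acc=config.min_acc)
    _provenance(out, "profile", {"assoc": "assoc.tsv"},
                {"min_acc": config.min_acc, "n_candidates": len(hits)})
    if isinstance(panel, EmptyPanelWarning):
        log.warning("empty marker panel (min_acc=%s); stopping", config.min_acc)
        return out

    # sex calling on samples lacking a sex label
    unknown_ids = [s for s in G.samples if s not in known_ids]
    target = G.take_samples(unknown_ids) if unknown_ids else G
    calls = call_sex(target, panel, tau=config.tau,
                     min_markers=config.min_markers)
    calls_to_frame(calls).to_csv(out / "sex_calls.tsv", sep="\t", index=False)
    summary = summarize_calls(calls)
    (out / "call_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    _provenance(out, "call", {"panel": "marker_profiles.tsv"},
                {"tau": config.tau, "min_markers": config.min_markers})

    # dimorphism battery, when traits are available
    if trait_table is not None:
        meta = samples.drop_duplicates("genotype_id").set_index("genotype_id")
        for col in ("sex", "latitude", "longitude"):
            if col not in trait_table.columns and col in meta.columns:
                trait_table[col] = trait_table["genotype_id"].map(meta[col])
        battery = run_battery(trait_table,
                              geography_mode=config.geography_mode)
        battery.to_csv(out / "dimorphism.tsv", sep="\t", index=False)
        (out / "battery_summary.json").write_text(json.dumps({
            "n_traits": int(len(battery)),
            "n_significant_nominal": int(battery["significant_nominal"].sum()),
            "min_q_value": (float(battery["q_value"].min())
                            if battery["q_value"].notna().any() else None),
        }, indent=2) + "\n")
        _provenance(out, "dimorphism",
                    {"traits": str(config.trait_path)},
                    {"geography_mode": config.geography_mode})
    return out
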