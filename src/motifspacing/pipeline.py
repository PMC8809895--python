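"""End-to-end orchestration: simulate -> call sites -> classify spacing ->
annotate variants -> effect sizes -> CRISPR quantification.

A single RunConfig (YAML-serialisable) drives every stage with explicit
seeds; each run directory receives the stage outputs, the config echo and
a manifest with checksums so deterministic stages can be verified to
reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .motifs import PWM, fpr_threshold, trim_pwm, call_sites_in_peak, parse_jaspar
from .spacing import classify_pair, spike_null
from .simulate import (
    SpacingModel,
    plant_cobinding,
    regions_from_truth,
    simulate_crispr_reads,
    simulate_genome,
    simulate_strain_tags,
    simulate_variants,
)
from .variants import class_enrichment_table, locate_and_classify
from .effects import normalize_tags, strain_effect_table
from .crispr import TestRegion, quantify_region, read_sam
from .motifs import BindingSite

#: Synthetic demonstration motifs (JASPAR count-matrix text). These are
#: in-silico stand-ins shaped like a typical ETS-family and bZIP-family
#: core motif; they are not measured matrices.
DEMO_JASPAR = """\
>TFA
A [  5  80   2   1  95   1   1  90  20 ]
C [ 10   5   3   1   1   1   1   3  30 ]
G [ 75  10  90  97   2  97   1   4  25 ]
T [ 10   5   5   1   2   1  97   3  25 ]
>TFB
A [  2  90   1   1  10  30   1  90   5 ]
C [  3   4   1  95  60  20   2   5   5 ]
G [  5   3   2   2  20  40   2   2  85 ]
T [ 90   3  96   2  10  10  95   3   5 ]
"""

_DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["simulate", "sites", "spacing", "variants", "effects", "crispr"],
    "genome": {"length": 300_000, "gc": 0.41},
    "jaspar": None,  # path; None -> built-in synthetic demo motifs
    "n_regions": 300,
    "spacing_model": {
        "kind": "constrained",
        "s0": 7,
        "concentration": 0.3,
        "jitter_sd": 0.0,
        "decay": 0.03,
    },
    "site_calling": {
        "fpr": 0.001,
        "ic_threshold": 0.3,
        "max_dist": 50,
        "pseudocount": 0.8,
    },
    "spacing": {"window": 100, "alpha_spike": 0.05 / 200 / 4, "alpha_relaxed": 1e-3,
                "ks_reps": 100},
    "variants": {
        "base_rates": {"singleton": 0.04, "rare": 0.03, "high_frequency": 0.01},
        "singleton_between_multiplier": 2.0,
    },
    "effects": {
        "n_per_category": 200,
        "depth": 100.0,
        "dispersion": 10.0,
        "effect_map": {},
    },
    "crispr": {
        "depth": 50_000,
        "binding_loss_overlap": 0.1,
        "binding_loss_spacing": 1.0,
        "cut_tolerance": 10,
        "min_frac": 0.0005,
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        merged = _merge(_DEFAULT_CONFIG, overrides or {})
        return cls(data=merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.data[key]


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict) and key not in (
            "effect_map",
            "base_rates",
        ):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``out_dir/manifest.json``),
    listing per-stage outputs with SHA-256 checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.data
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict = {"stages": {}, "config": cfg}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    stages = list(cfg["stages"])
    state: dict = {}

    if "simulate" in stages:
        state.update(_stage_simulate(cfg, out, rng))
        manifest["stages"]["simulate"] = _checksum_all(state["simulate_files"])
    if "sites" in stages:
        state.update(_stage_sites(cfg, out, state))
        manifest["stages"]["sites"] = _checksum_all(state["site_files"])
    if "spacing" in stages:
        state.update(_stage_spacing(cfg, out, state, rng))
        manifest["stages"]["spacing"] = _checksum_all(state["spacing_files"])
    if "variants" in stages:
        state.update(_stage_variants(cfg, out, state, rng))
        manifest["stages"]["variants"] = _checksum_all(state["variant_files"])
    if "effects" in stages:
        state.update(_stage_effects(cfg, out, rng))
        manifest["stages"]["effects"] = _checksum_all(state["effect_files"])
    if "crispr" in stages:
        state.update(_stage_crispr(cfg, out, state, rng))
        manifest["stages"]["crispr"] = _checksum_all(state["crispr_files"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _checksum_all(paths) -> dict:
    return {str(Path(p).name): _sha256(Path(p)) for p in paths}


def _load_pwms(cfg) -> list[PWM]:
    ps = cfg["site_calling"]["pseudocount"]
    if cfg["jaspar"]:
        with open(cfg["jaspar"]) as fh:
            pwms = parse_jaspar(fh, pseudocount=ps)
    else:
        pwms = parse_jaspar(DEMO_JASPAR, pseudocount=ps)
    if len(pwms) < 2:
        raise ConfigError("need at least two motifs")
    return [trim_pwm(p, cfg["site_calling"]["ic_threshold"]) for p in pwms[:2]]


def _stage_simulate(cfg, out, rng):
    pwmA, pwmB = _load_pwms(cfg)
    genome = simulate_genome(cfg["genome"]["length"], cfg["genome"]["gc"], rng)
    model = SpacingModel(**cfg["spacing_model"])
    lomA, lomB = pwmA.log_odds(), pwmB.log_odds()
    thrA = fpr_threshold(lomA, cfg["site_calling"]["fpr"])
    thrB = fpr_threshold(lomB, cfg["site_calling"]["fpr"])
    genome, peaksA, peaksB, truth = plant_cobinding(
        genome, pwmA, pwmB, cfg["n_regions"], model, rng,
        min_score_A=thrA, min_score_B=thrB,
    )
    files = [
        msio.write_fasta({"chr1": genome}, out / "genome.fa"),
        msio.write_peaks_bed(peaksA, out / "peaks_A.bed"),
        msio.write_peaks_bed(peaksB, out / "peaks_B.bed"),
    ]
    truth.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    files.append(out / "truth_regions.tsv")
    return {
        "genome": {"chr1": genome},
        "peaksA": peaksA,
        "peaksB": peaksB,
        "truth": truth,
        "pwms": (pwmA, pwmB),
        "thresholds": (thrA, thrB),
        "simulate_files": files,
    }


def _stage_sites(cfg, out, state):
    pwmA, pwmB = state["pwms"]
    thrA, thrB = state["thresholds"]
    lomA, lomB = pwmA.log_odds(), pwmB.log_odds()
    max_dist = cfg["site_calling"]["max_dist"]
    genome = state["genome"]
    sitesA, sitesB = [], []
    for peak in state["peaksA"]:
        sitesA.extend(call_sites_in_peak(lomA, genome, peak, thrA, max_dist))
    for peak in state["peaksB"]:
        sitesB.extend(call_sites_in_peak(lomB, genome, peak, thrB, max_dist))
    files = [
        msio.write_sites_bed(sitesA, out / "sites_A.bed"),
        msio.write_sites_tsv(sitesA, out / "sites_A.tsv"),
        msio.write_sites_bed(sitesB, out / "sites_B.bed"),
        msio.write_sites_tsv(sitesB, out / "sites_B.tsv"),
    ]
    return {"sitesA": sitesA, "sitesB": sitesB, "site_files": files}


def _stage_spacing(cfg, out, state, rng):
    pwmA, pwmB = state["pwms"]
    thrA, thrB = state["thresholds"]
    lomA, lomB = pwmA.log_odds(), pwmB.log_odds()
    genome = state["genome"]
    scfg = cfg["spacing"]
    max_dist = cfg["site_calling"]["max_dist"]
    null = spike_null(seed=rng)
    dists, results = classify_pair(
        state["peaksA"],
        state["peaksB"],
        lambda p: call_sites_in_peak(lomA, genome, p, thrA, max_dist),
        lambda p: call_sites_in_peak(lomB, genome, p, thrB, max_dist),
        tfA=pwmA.name,
        tfB=pwmB.name,
        window=scfg["window"],
        null=null,
        seed=rng,
        alpha_spike=scfg["alpha_spike"],
        alpha_relaxed=scfg["alpha_relaxed"],
    )
    files = []
    for orient, dist in dists.items():
        p = out / f"spacing_{orient.replace('+', 'p').replace('-', 'm')}.tsv"
        msio.write_spacing_tsv(dist, p)
        files.append(p)
    rows = [
        {
            "tfA": r.tfA,
            "tfB": r.tfB,
            "orientation": o,
            "label": r.label,
            "spike_positions": ";".join(str(i) for i, _ in r.spike_positions),
            "min_spike_p": min((p for _, p in r.spike_positions), default=float("nan")),
            "ks_mean_p": r.ks_mean_p,
        }
        for o, r in results.items()
    ]
    table = pd.DataFrame(rows)
    table.to_csv(out / "relationships.tsv", sep="\t", index=False)
    files.append(out / "relationships.tsv")
    return {"relationships": table, "spacing_dists": dists, "spacing_files": files}


def _stage_variants(cfg, out, state, rng):
    genome = state["genome"]["chr1"]
    regions = regions_from_truth(state["truth"])
    vcfg = cfg["variants"]
    zone_mult = {"between": {"singleton": vcfg["singleton_between_multiplier"]}}
    variants, vtruth = simulate_variants(
        regions, genome, base_rates=vcfg["base_rates"], zone_multipliers=zone_mult, seed=rng
    )
    vcf = msio.write_vcf(variants, out / "variants.vcf", {"chr1": len(genome)})
    located = locate_and_classify(regions, variants)
    located.to_csv(out / "variant_locations.tsv", sep="\t", index=False)
    enrich = class_enrichment_table(located)
    enrich.to_csv(out / "variant_enrichment.tsv", sep="\t", index=False)
    files = [vcf, out / "variant_locations.tsv", out / "variant_enrichment.tsv"]
    return {"variant_enrichment": enrich, "variant_files": files}


def _stage_effects(cfg, out, rng):
    ecfg = cfg["effects"]
    from .variants import ImpactCategory

    cats = [c.value for c in ImpactCategory for _ in range(ecfg["n_per_category"])]
    tags = simulate_strain_tags(
        cats,
        depth=ecfg["depth"],
        dispersion=ecfg["dispersion"],
        effect_map=ecfg["effect_map"],
        seed=rng,
    )
    tags.to_csv(out / "strain_tags.tsv", sep="\t", index=False)
    library = float(tags[["ref_tags", "strain_1"]].to_numpy().sum())
    table = strain_effect_table(
        normalize_tags(tags["ref_tags"], library),
        normalize_tags(tags["strain_1"], library),
        tags["category"],
    )
    table.to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
    return {"effect_table": table, "effect_files": [out / "strain_tags.tsv", out / "effect_sizes.tsv"]}


def _stage_crispr(cfg, out, state, rng):
    ccfg = cfg["crispr"]
    genome = state["genome"]["chr1"]
    region = TestRegion(
        chrom="chr1",
        start=0,
        end=300,
        siteA=BindingSite("chr1", 100, 112, "+", 0.0, "TFA"),
        siteB=BindingSite("chr1", 150, 162, "+", 0.0, "TFB"),
        cut_site=131,
    )
    sim = simulate_crispr_reads(
        region,
        genome[:300],
        depth=ccfg["depth"],
        binding_loss_overlap=ccfg["binding_loss_overlap"],
        binding_loss_spacing=ccfg["binding_loss_spacing"],
        seed=rng,
        out_dir=out / "crispr",
    )
    chip_reads, _ = read_sam(sim["chip_sam"], region, "chip")
    input_reads, _ = read_sam(sim["input_sam"], region, "input")
    table, stats = quantify_region(
        chip_reads, input_reads, region,
        cut_tolerance=ccfg["cut_tolerance"], min_frac=ccfg["min_frac"],
    )
    table.to_csv(out / "crispr_groups.tsv", sep="\t", index=False)
    with open(out / "crispr_summary.json", "w") as fh:
        json.dump(stats, fh, indent=2)
    return {
        "crispr_table": table,
        "crispr_stats": stats,
        "crispr_files": [out / "crispr_groups.tsv", out / "crispr_summary.json"],
    }
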