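"""Pipeline configuration: a flat YAML file with one section per stage.

Every key has a documented default (see ``DEFAULTS``); unknown keys are
rejected so typos fail loudly.  Paths inside the config are resolved
relative to the config file's directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .construct import PromoterLayout
from .crosstalk import AlignmentParams, OrthogonalityThresholds
from .io import read_fasta, read_pwm
from .offtarget import DEFAULT_MISMATCH_WEIGHTS, OffTargetScoringModel
from .pool import (
    DEFAULT_DISALLOWED_MOTIFS,
    AnnealSchedule,
    GenerationConstraints,
)

DEFAULTS: dict = {
    "rng_seed": 0,
    "genomes": [],
    "pool_fasta": None,
    "generation": {
        "spacer_length": 23,
        "max_repeat_len": 8,
        "max_inverted_repeat_len": 8,
        "disallowed_motifs": list(DEFAULT_DISALLOWED_MOTIFS),
        "pwm_files": [],
        "pwm_threshold": 8.0,
        "screen_genomes": [],
        "kmer_k": 11,
        "max_shared_kmers": 0,
        "tm_target": 60.0,
        "tm_tolerance": 2.0,
        "pool_size": 10,
        "anneal": {
            "initial_temperature": 5.0,
            "cooling": 0.95,
            "steps": 4000,
            "retries": 25,
        },
    },
    "scoring": {
        "pam": "TTTN",
        "max_mismatches": 7,
        "score_cutoff": 0.8,
        "weights": list(DEFAULT_MISMATCH_WEIGHTS),
    },
    "hybrid": {
        "energy_range": None,  # [min, max] kcal/mol; stage skipped when unset
    },
    "crosstalk": {
        "max_sw_score": 30.0,
        "max_shared_substring": 10,
        "min_mfe": -15.0,
        "alignment": {"match": 2.0, "mismatch": -1.0, "gap": -2.0},
    },
    "construct": {
        "uas_seq": None,  # None -> shipped placeholder UAS block
        "pam": "TTTC",
        "orientation": "outward",
        "gap_uas_to_5prime_site": 36,
        "dist_uas_to_3prime_site": 105,
        "dist_tss_to_3prime_site": 10,
        "tail_len": 10,
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    generation: GenerationConstraints
    scoring: OffTargetScoringModel
    hybrid_energy_range: tuple | None
    thresholds: OrthogonalityThresholds
    alignment: AlignmentParams
    layout: PromoterLayout
    genomes: tuple  # resolved genome FASTA paths
    pool_fasta: str | None
    rng_seed: int


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        if key in overrides:
            value = overrides[key]
            if isinstance(default, dict) and isinstance(value, dict):
                out[key] = _merge(default, value, f"{path}{key}.")
            else:
                out[key] = value
        else:
            out[key] = default
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def _resolve(base_dir: str, p: str) -> str:
    return p if os.path.isabs(p) else os.path.normpath(os.path.join(base_dir, p))


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse and validate a config file; unspecified keys take the
    documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    merged = _merge(DEFAULTS, raw)
    base_dir = os.path.dirname(os.path.abspath(path))

    genome_paths = []
    for p in merged["genomes"]:
        resolved = _resolve(base_dir, p)
        if not os.path.exists(resolved):
            raise ConfigError(f"genome path does not exist: {p}")
        genome_paths.append(resolved)

    gen = merged["generation"]
    screen_records = []
    for p in gen["screen_genomes"]:
        resolved = _resolve(base_dir, p)
        if not os.path.exists(resolved):
            raise ConfigError(f"screen genome path does not exist: {p}")
        screen_records.extend(read_fasta(resolved))
    pwms = []
    for p in gen["pwm_files"]:
        resolved = _resolve(base_dir, p)
        if not os.path.exists(resolved):
            raise ConfigError(f"PWM path does not exist: {p}")
        pwms.append(tuple(map(tuple, read_pwm(resolved))))

    try:
        generation = GenerationConstraints(
            spacer_length=gen["spacer_length"],
            max_repeat_len=gen["max_repeat_len"],
            max_inverted_repeat_len=gen["max_inverted_repeat_len"],
            disallowed_motifs=tuple(gen["disallowed_motifs"]),
            pwms=tuple(pwms),
            pwm_threshold=gen["pwm_threshold"],
            screen_genomes=tuple(screen_records),
            kmer_k=gen["kmer_k"],
            max_shared_kmers=gen["max_shared_kmers"],
            tm_target=gen["tm_target"],
            tm_tolerance=gen["tm_tolerance"],
            pool_size=gen["pool_size"],
            anneal=AnnealSchedule(**gen["anneal"]),
        )
        scoring = OffTargetScoringModel(
            weights=tuple(merged["scoring"]["weights"]),
            pam=merged["scoring"]["pam"],
            max_mismatches=merged["scoring"]["max_mismatches"],
            cutoff=merged["scoring"]["score_cutoff"],
        )
        ct = merged["crosstalk"]
        thresholds = OrthogonalityThresholds(
            max_sw_score=ct["max_sw_score"],
            max_shared_substring=ct["max_shared_substring"],
            min_mfe=ct["min_mfe"],
        )
        alignment = AlignmentParams(**ct["alignment"])
        cons = merged["construct"]
        layout_kwargs = dict(
            pam=cons["pam"],
            orientation=cons["orientation"],
            gap_uas_to_5prime_site=cons["gap_uas_to_5prime_site"],
            dist_uas_to_3prime_site=cons["dist_uas_to_3prime_site"],
            dist_tss_to_3prime_site=cons["dist_tss_to_3prime_site"],
            tail_len=cons["tail_len"],
            site_len=gen["spacer_length"],
        )
        if cons["uas_seq"] is not None:
            layout_kwargs["uas_seq"] = cons["uas_seq"].upper()
        layout = PromoterLayout(**layout_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    hybrid_range = merged["hybrid"]["energy_range"]
    if hybrid_range is not None:
        lo, hi = hybrid_range
        if lo > hi:
            raise ConfigError(f"hybrid energy_range min > max: [{lo}, {hi}]")
        hybrid_range = (float(lo), float(hi))

    pool_fasta = merged["pool_fasta"]
    if pool_fasta is not None:
        pool_fasta = _resolve(base_dir, pool_fasta)
        if not os.path.exists(pool_fasta):
            raise ConfigError(f"pool_fasta path does not exist: {merged['pool_fasta']}")

    if not isinstance(merged["rng_seed"], int):
        raise ConfigError("rng_seed must be an integer")

    return PipelineConfig(
        generation=generation,
        scoring=scoring,
        hybrid_energy_range=hybrid_range,
        thresholds=thresholds,
        alignment=alignment,
        layout=layout,
        genomes=tuple(genome_paths),
        pool_fasta=pool_fasta,
        rng_seed=merged["rng_seed"],
    )
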