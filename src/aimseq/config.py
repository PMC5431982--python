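"""Flat YAML configuration with validated defaults.

All analysis thresholds live here: depth cutoffs (10/10 reads), the
Bayes-factor significance threshold (10), the copy-neutral log-ratio window
(-0.15, 0.15), the hypermutation rate (10 mutations/Mb over a 38 Mb exome)
and the 50-nt-rule boundary convention.
"""

from __future__ import annotations

import difflib
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """One or more configuration problems; ``errors`` lists all of them."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


DEFAULTS: dict = {
    # inputs (None means: simulate)
    "mutations": None,
    "transcripts": None,
    "transcript_format": "gtf",
    "segments": None,
    "covariates": None,
    # qc filters
    "min_dna_depth": 10,
    "min_rna_depth": 10,
    "hypermutation_rate": 10.0,
    "exome_size_mb": 38.0,
    "cn_low": -0.15,
    "cn_high": 0.15,
    # AI test
    "alpha": 1.0,
    "beta": 1.0,
    "bf_threshold": 10.0,
    "grid_dna": [0, 10, 20, 30, 40, 50],
    "grid_rna": [0, 10, 20, 30, 40, 50],
    # NMD annotation
    "nmd_boundary_inclusive": True,
    "allow_retranslation": False,
    # enrichment
    "focal_class": "sig_pos_afd",
    "min_events": 1,
    "neglogp_cutoff": 2.5,
    # simulation
    "seed": 0,
    "n_samples": 50,
    "n_genes": 200,
    "preset": "BRCA",
    "retention": 0.25,
    "boost": 4.0,
    "dna_depth": 80.0,
    "rna_depth": 80.0,
    "depth_dispersion": 8.0,
    "neutral_cn_fraction": 0.8,
    "hypermutator_fraction": 0.02,
    "mean_mutations_per_sample": 60.0,
}

_TYPES: dict[str, tuple] = {
    "mutations": (str, type(None)), "transcripts": (str, type(None)),
    "transcript_format": (str,), "segments": (str, type(None)),
    "covariates": (str, type(None)),
    "min_dna_depth": (int,), "min_rna_depth": (int,),
    "hypermutation_rate": (int, float), "exome_size_mb": (int, float),
    "cn_low": (int, float), "cn_high": (int, float),
    "alpha": (int, float), "beta": (int, float), "bf_threshold": (int, float),
    "grid_dna": (list,), "grid_rna": (list,),
    "nmd_boundary_inclusive": (bool,), "allow_retranslation": (bool,),
    "focal_class": (str,), "min_events": (int,), "neglogp_cutoff": (int, float),
    "seed": (int,), "n_samples": (int,), "n_genes": (int,), "preset": (str,),
    "retention": (int, float), "boost": (int, float),
    "dna_depth": (int, float), "rna_depth": (int, float),
    "depth_dispersion": (int, float), "neutral_cn_fraction": (int, float),
    "hypermutator_fraction": (int, float), "mean_mutations_per_sample": (int, float),
}


def validate_config(path_or_mapping) -> dict:
    """Load + validate a config, injecting defaults.

    Unknown keys and type mismatches are collected and reported together in a
    single :class:`ConfigError`; unknown keys come with close-match suggestions.
    """
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text())
        if raw is None:
            raw = {}
    else:
        raw = dict(path_or_mapping or {})
    if not isinstance(raw, dict):
        raise ConfigError([f"config must be a mapping, got {type(raw).__name__}"])
    errors: list[str] = []
    cfg = dict(DEFAULTS)
    for key, value in raw.items():
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS, n=3)
            suffix = f" (did you mean: {', '.join(hint)}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
            continue
        ok = _TYPES[key]
        if isinstance(value, bool) and bool not in ok:
            errors.append(f"key {key!r}: expected {ok[0].__name__}, got bool")
            continue
        if value is not None and not isinstance(value, ok):
            expected = "/".join(t.__name__ for t in ok if t is not type(None))
            errors.append(
                f"key {key!r}: expected {expected}, got {type(value).__name__} ({value!r})"
            )
            continue
        cfg[key] = value
    if cfg["cn_low"] >= cfg["cn_high"]:
        errors.append("cn_low must be < cn_high")
    if errors:
        raise ConfigError(errors)
    return cfg
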