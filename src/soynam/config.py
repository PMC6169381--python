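"""Run configuration: one YAML document drives the whole pipeline.

Defaults follow the reference field study wherever it states a value (MAF
threshold 10%, 5 cM linkage window, -log10(p) >= 3, F5 single-seed-descent
lines, 40-entry sets); population sizes default to a desk-scale demo.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import TRAITS


def _default_stages() -> dict:
    return {"simulate": True, "prep": True, "blup": True, "gwas": True,
            "bins": True}


def _default_group_counts() -> dict:
    return {"EL": 2, "BX": 2, "PI": 1}


def _default_group_effects() -> dict:
    return {"EL": {"mean": 5.0, "sd": 40.0},
            "BX": {"mean": -20.0, "sd": 40.0},
            "PI": {"mean": -50.0, "sd": 40.0}}


def _default_varcomp() -> dict:
    # plot-level noise on the same order as the genotypic variance the
    # default architecture generates, giving entry-mean H around 0.8-0.9
    return {"env": 800.0, "block": 150.0, "residual": 2000.0}


@dataclass
class RunConfig:
    seed: int = 1
    stages: dict = field(default_factory=_default_stages)

    # germplasm / genome
    group_counts: dict = field(default_factory=_default_group_counts)
    n_families: int = 5
    rils_per_family: int = 40
    final_generation: int = 5
    n_chromosomes: int = 2
    cm_length: float = 100.0
    markers_per_chromosome: int = 150
    # chip markers were ascertained to segregate in most families, so the
    # non-hub allele is common among founders by design
    allele_freq: float = 0.75
    bp_model: dict = field(default_factory=lambda: {"kind": "linear",
                                                    "bp_per_cM": 1e6})

    # trait architecture
    traits: list = field(default_factory=lambda: list(TRAITS[:2]))
    n_qtl: int = 5
    group_effects: dict = field(default_factory=_default_group_effects)
    polygenic_var: float = 100.0

    # trial
    n_environments: int = 3
    sets_evaluated: object = "all"   # "all" or per-environment counts
    planting_date_model: dict = field(default_factory=lambda: {
        "base_julian": 135, "spread_days": 28})
    variance_components: dict = field(default_factory=_default_varcomp)
    planting_slope: float = 0.0
    missing_rate: float = 0.02
    checks: list = field(default_factory=lambda: ["CHK1", "CHK2", "CHK3"])

    vcf_export: bool = False

    # genoprep
    maf_threshold: float = 0.10

    # gwas / bins
    window_cm: float = 5.0
    sig_threshold: float = 3.0
    gap_cm: float = 5.0

    # paths (inputs when the simulate stage is disabled)
    map_path: str | None = None
    genotypes_path: str | None = None
    plots_path: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()
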