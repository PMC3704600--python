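"""Run configuration with documented defaults and lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from soymir.simulate import DEFAULT_ADAPTER3, SimConfig


@dataclass
class RunConfig:
    """All stage parameters of an end-to-end run."""

    seed: int = 42
    outdir: str = "soymir_out"
    # paths; empty means "use the bundled simulation outputs"
    genome: str = ""
    libraries_dir: str = ""
    known_precursors: str = ""
    known_precursor_gff: str = ""
    annotated_matures: str = ""
    ncrna_bed: str = ""
    genes_gff: str = ""
    transcripts: str = ""
    # read processing
    adapter3: str = DEFAULT_ADAPTER3
    min_len: int = 18
    max_len: int = 30
    min_qual: float = 20.0
    # known-variant unification
    majority_frac: float = 0.5
    closeness_ratio: float = 2.0
    window: int = 2
    min_secondary: int = 100
    # novel discovery
    flank: int = 100
    merge_dist: int = 200
    mfe_cutoff: float = -20.0
    min_total: int = 100
    min_candidate_count: int = 20
    # differential expression
    alpha: float = 0.05
    lfc: float = 1.0
    min_reads: int = 100
    tail: str = "two-sided"
    # target prediction
    max_score: float = 2.0
    # simulation block (used when no input paths are given)
    simulation: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        params.setdefault("adapter3", self.adapter3)
        return SimConfig(**params)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
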