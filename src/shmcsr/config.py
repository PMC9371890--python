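"""YAML run configuration: parsing, defaults, and all-at-once validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigurationError

ALL_STAGES = ("simulate", "consensus", "annotate", "spectrum", "junctions")


@dataclass
class RunConfig:
    seed: int = 17
    output_dir: str = "shmcsr_out"
    stages: tuple[str, ...] = ALL_STAGES
    genotypes: tuple[str, ...] = ("WT-like", "DA-like", "KO-like")

    # germline
    germline_length: int = 294
    gc_fraction: float = 0.5

    # repertoire
    n_clones: int = 300
    clone_size_geometric_p: float = 0.5
    inherited_fraction: float = 0.25

    # reads
    umi_length: int = 8
    reads_per_molecule: int = 3
    error_rate: float = 0.001
    overlap: int = 60

    # consensus
    min_overlap: int = 10
    merge_max_mismatch_frac: float = 0.1
    min_family_size: int = 1

    # annotation
    annotate_max_mismatch_frac: float = 0.2

    # spectrum
    n_iterations: int = 1000
    alpha: float = 0.05

    # junctions / CSR
    n_junctions: int = 40
    anchor_min: int = 10
    switch_ref_length: int = 400
    csr_n_cells: int = 10000

    def validate(self) -> None:
        v = []
        if not isinstance(self.seed, int):
            v.append("seed must be an integer")
        for st in self.stages:
            if st not in ALL_STAGES:
                v.append(f"unknown stage {st!r}")
        if self.germline_length < 30:
            v.append("germline_length must be >= 30")
        if not 0.0 <= self.gc_fraction <= 1.0:
            v.append("gc_fraction must be in [0,1]")
        if self.n_clones < 1:
            v.append("n_clones must be >= 1")
        if not 0.0 < self.clone_size_geometric_p <= 1.0:
            v.append("clone_size_geometric_p must be in (0,1]")
        if not 0.0 <= self.inherited_fraction <= 1.0:
            v.append("inherited_fraction must be in [0,1]")
        if self.umi_length < 4:
            v.append("umi_length must be >= 4")
        if self.reads_per_molecule < 1:
            v.append("reads_per_molecule must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            v.append("error_rate must be in [0,1)")
        if self.min_overlap < 10:
            v.append("min_overlap must be >= 10")
        if self.min_family_size < 1:
            v.append("min_family_size must be >= 1")
        if self.n_iterations < 1:
            v.append("n_iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            v.append("alpha must be in (0,1)")
        if self.n_junctions < 2:
            v.append("n_junctions must be >= 2")
        if self.anchor_min < 1:
            v.append("anchor_min must be >= 1")
        if self.switch_ref_length < 40:
            v.append("switch_ref_length must be >= 40")
        if v:
            raise ConfigurationError(v)


def validate_config(raw_text: str | None) -> RunConfig:
    """Parse YAML config text, apply defaults, and validate.

    Every violation is reported at once. An empty config yields all
    defaults.
    """
    data = {}
    if raw_text and raw_text.strip():
        try:
            data = yaml.safe_load(raw_text)
        except yaml.YAMLError as exc:
            raise ConfigurationError([f"config is not valid YAML: {exc}"]) from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(["config root must be a mapping"])

    known = {f.name for f in fields(RunConfig)}
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ConfigurationError([f"unknown config key {k!r}" for k in unknown])
    for key in ("stages", "genotypes"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def load_config(path: str | None) -> RunConfig:
    if path is None:
        cfg = RunConfig()
        cfg.validate()
        return cfg
    with open(path) as fh:
        return validate_config(fh.read())
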