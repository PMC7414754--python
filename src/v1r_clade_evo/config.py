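"""Pipeline configuration: defaults for every stage, YAML round-trip, manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Resolved parameters for a pipeline run.

    Every parameter has a default; a config file only lists overrides.  The
    run manifest records the fully resolved values.  Stochastic stages
    (simulation) refuse to run without an explicit seed.
    """

    out_dir: str = "run"
    seed: int | None = None
    species_tree: str | None = None  # newick path; None = built-in Mus fixture
    reference_species: str = "domesticus"
    focal_species: str = "domesticus"

    # simulate: SimParams overrides (n_root_genes, dup_rate, loss_rate, ...)
    simulate: dict[str, Any] = field(default_factory=dict)
    clade_assignment: str = "round_robin"  # or "single:<clade>"

    # mine: receptor gene model; the pipeline default opens the lower bound
    # so one-exon truncated variants stay visible to the variant classifier
    gene_model: dict[str, Any] = field(default_factory=lambda: {"min_len": 150, "max_len": 400})
    identity_threshold: float = 30.0
    identity_use_min: bool = False
    external_hits: str | None = None  # blast tabular path

    # orthogroups:
    gene_tree: str = "truth"  # truth | nj | <newick path>
    outgroup: str | None = None
    collapse_support: float = 50.0
    manual_names: dict[str, str] = field(default_factory=dict)

    # dupvar:
    end_window: int = 10
    gap_window: int = 5
    truncation_frac: float = 0.75

    # select:
    fdr_q: float = 0.05
    fdr_scope: str = "pooled"  # pooled | per_orthogroup
    min_orthogroup_size: int = 4
    external_tests: str | None = None  # per-branch p-value TSV path

    # summarize:
    min_support: int = 3
    pseudogene_table: str | None = None

    # sites:
    short_len_frac: float = 0.8
    topology_table: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def file_checksum(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: PipelineConfig, out_dir: str, inputs: dict[str, str], stages: list[str]) -> str:
    from v1r_clade_evo import __version__

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "input_checksums": {k: file_checksum(v) for k, v in inputs.items() if v and os.path.exists(v)},
        "stages": stages,
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
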