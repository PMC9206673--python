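"""Pipeline configuration: a single validated block of parameters.

Unknown keys are rejected; every threshold deviating from its default is
reported so runs are self-documenting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_exons: int = 14
    alt3ss_exons: list[int] = [7]
    n_isoforms: int = 12
    n_samples: int = 4
    reads_per_sample: int = 500
    dirichlet_alpha: float = 5.0
    substitution_rate: float = 0.01
    insertion_rate: float = 0.0025
    deletion_rate: float = 0.0025
    truncation_prob: float = 0.0
    short_read_length: int = 100
    short_reads_per_sample: int = 1000
    seed: int = 0


class AlignBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 13
    min_intron: int = 20
    max_intron: int = 1_000_000
    band: int = 16
    reject_identity: float = 0.66
    refine_window: int = 10


class AnnotateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    match: int = 1
    mismatch: int = -2
    gap_open: int = -2
    gap_extend: int = -1
    min_cov: float = 0.8
    min_ident: float = 0.85
    qc_min_identity: float = 0.85
    min_cluster_reads: int = 1


class PipelineConfig(BaseModel):
    """Full run configuration; serialized alongside every output tree."""

    model_config = ConfigDict(extra="forbid")
    mode: Literal["pacbio", "ont"] = "pacbio"
    demux_max_mismatch: int = 2
    demux_window: int = 100
    boundary_tol: int = 3
    exon_min_support: int = 2
    junction_overhang_5p: int = 9
    junction_overhang_3p: int = 6
    junction_min_overlap: int = 15
    simulate: SimulateBlock = SimulateBlock()
    align: AlignBlock = AlignBlock()
    annotate: AnnotateBlock = AnnotateBlock()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def non_default_fields(self) -> dict:
        """Thresholds deviating from defaults, for provenance logs."""
        default = PipelineConfig()
        out = {}
        for name in type(self).model_fields:
            v, d = getattr(self, name), getattr(default, name)
            if isinstance(v, BaseModel):
                sub = {k: getattr(v, k) for k in type(v).model_fields
                       if getattr(v, k) != getattr(d, k)}
                if sub:
                    out[name] = sub
            elif v != d:
                out[name] = v
        return out

    def write_provenance(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump({"tool": "exonarch", "version": __version__,
                       "config": self.model_dump(),
                       "non_default": self.non_default_fields()},
                      fh, indent=1)
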