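"""Pipeline configuration: every threshold in one structured object.

Defaults are the conventional values for this kind of gene-catalogue
pipeline: identity floors 40/50/60/70/80/90/95 for the seven ranks, an
E-value prefilter of 1e-4 for top-score selection, dbCAN base thresholds
coverage 0.3 / 80 aa / 1e-5 / 1e-3 and strict thresholds 1e-18 / 0.35, a
maximum of 10 EC entries per reference protein, and a 1000 nt contig
eligibility cutoff.  All are overridable from a YAML file and again from
command-line flags (flags win).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .hmm_filter import DbcanThresholds
from .lca import DEFAULT_MIN_IDENTITY, RankThresholds
from .quantify import DEFAULT_CONTIG_LENGTH_CUTOFF


@dataclass
class PipelineConfig:
    min_identity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_IDENTITY)
    )
    gene_majority: float = 0.5
    contig_consensus: float = 0.5
    identity_gate: str = "per_hit"
    uniform_gene_weights: bool = False
    max_evalue: float = 1e-4
    dbcan_min_coverage: float = 0.3
    dbcan_long_alignment_aa: int = 80
    dbcan_long_max_evalue: float = 1e-5
    dbcan_short_max_evalue: float = 1e-3
    dbcan_strict_max_evalue: float = 1e-18
    dbcan_strict_min_coverage: float = 0.35
    max_protein_ecs: int = 10
    min_contig_len: int = DEFAULT_CONTIG_LENGTH_CUTOFF
    exclude_contigs_path: str | None = None

    def rank_thresholds(self) -> RankThresholds:
        return RankThresholds(
            min_identity=dict(self.min_identity),
            gene_majority=self.gene_majority,
            contig_consensus=self.contig_consensus,
            identity_gate=self.identity_gate,
            uniform_gene_weights=self.uniform_gene_weights,
        )

    def dbcan_thresholds(self) -> DbcanThresholds:
        return DbcanThresholds(
            min_coverage=self.dbcan_min_coverage,
            long_alignment_aa=self.dbcan_long_alignment_aa,
            long_max_evalue=self.dbcan_long_max_evalue,
            short_max_evalue=self.dbcan_short_max_evalue,
            strict_max_evalue=self.dbcan_strict_max_evalue,
            strict_min_coverage=self.dbcan_strict_min_coverage,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data).difference(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        """A copy with the given non-None fields replaced (flags win)."""
        data = self.to_dict()
        for k, v in kwargs.items():
            if v is not None:
                data[k] = v
        return PipelineConfig(**data)
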