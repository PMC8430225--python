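"""Run-wide configuration: every tunable threshold of the pipeline in one place.

The defaults are the thresholds the analysis is defined with: signed Pearson
correlation > 0.6 at p < 0.01 for ceRNA pair calling, hypergeometric p < 0.05,
motif hits at p < 1e-4, genes dropped when more than 70% of samples are zero,
hubs as the top 10% of nodes by degree, 1,000 permutation networks, and
promoters as +/-2,000 bp around the TSS.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

PERMUTATION_SCHEMES = ("gnm", "degree_preserving")


@dataclass
class RunConfig:
    """All pipeline thresholds, the RNG seed and the permutation null scheme.

    Attributes
    ----------
    pcc_cutoff : signed Pearson correlation threshold for ceRNA pair calling.
    pcc_p_cutoff : two-sided p-value threshold for the correlation test.
    hyper_p_cutoff : upper-tail hypergeometric p threshold for shared-miRNA
        enrichment (the level is configurable; 0.05 is the conventional default).
    motif_p_cutoff : per-window PWM match p-value threshold.
    zero_fraction : genes with a strictly greater fraction of zero values are
        removed before any correlation analysis.
    hub_fraction : fraction of highest-degree nodes reported as hubs
        (``ceil(fraction * n_nodes)`` nodes).
    m6a_pcc_cutoff : correlation threshold for the lncRNA-m6A network.
    key_gene_min_degree : key genes of the m6A network have degree >= this
        (equivalently, strictly greater than ``key_gene_min_degree - 1``).
    n_permutations : number of null networks per permutation test.
    promoter_flank : promoter half-width around the TSS, bp.
    enhancer_max_dist : maximum TSS-to-enhancer distance for assignment, bp.
    rng_seed : seed for every stochastic stage.
    permutation_scheme : "gnm" (uniform graphs with the same node and edge
        counts) or "degree_preserving" (double-edge-swap rewiring).
    """

    pcc_cutoff: float = 0.6
    pcc_p_cutoff: float = 0.01
    hyper_p_cutoff: float = 0.05
    motif_p_cutoff: float = 1e-4
    zero_fraction: float = 0.7
    hub_fraction: float = 0.10
    m6a_pcc_cutoff: float = 0.6
    key_gene_min_degree: int = 3
    n_permutations: int = 1000
    promoter_flank: int = 2000
    enhancer_max_dist: int = 100_000
    rng_seed: int = 0
    permutation_scheme: str = "gnm"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("pcc_p_cutoff", "hyper_p_cutoff", "motif_p_cutoff",
                     "zero_fraction", "hub_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.pcc_cutoff <= 1.0:
            raise ValidationError(f"pcc_cutoff={self.pcc_cutoff} outside [-1, 1]")
        if not -1.0 <= self.m6a_pcc_cutoff <= 1.0:
            raise ValidationError(f"m6a_pcc_cutoff={self.m6a_pcc_cutoff} outside [-1, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.promoter_flank <= 0:
            raise ValidationError("promoter_flank must be positive")
        if self.enhancer_max_dist <= self.promoter_flank:
            raise ValidationError("enhancer_max_dist must exceed promoter_flank")
        if self.key_gene_min_degree < 1:
            raise ValidationError("key_gene_min_degree must be >= 1")
        if self.permutation_scheme not in PERMUTATION_SCHEMES:
            raise ValidationError(
                f"permutation_scheme must be one of {PERMUTATION_SCHEMES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a RunConfig from YAML or JSON (decided by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
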