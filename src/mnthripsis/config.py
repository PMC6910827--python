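"""Pipeline configuration: one structured file holding every threshold.

Defaults are the analysis' published operating points: quantal < 1.5 /
> 2.5 for loss/gain with a -1 aneuploid correction, > 90% span coverage
for merging, > 100 kb size floor, < 70% reciprocal overlap for
uniqueness, parental homozygosity at BAF < 0.05 / > 0.95, BAF shift
bounds 0.15/0.85, a > 10 kb junction-span filter, and 1e6 permutations
for the enrichment test.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Union

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # CNA calling
    loss_threshold: float = 1.5
    gain_threshold: float = 2.5
    aneuploid_correction: float = 1.0
    merge_coverage: float = 0.90
    min_cna_size: int = 100_000
    uniqueness_ro: float = 0.70
    # haplotype assignment
    hom_lo: float = 0.05
    hom_hi: float = 0.95
    shift_lo: float = 0.15
    shift_hi: float = 0.85
    trisomic_window: float = 0.12
    ab_window: float = 0.08
    gain_window: float = 0.08
    min_snps: int = 3
    majority_margin: float = 2 / 3
    min_pairs: int = 3
    binomial_alpha: float = 0.05
    # junction analysis
    min_junction_span: int = 10_000
    templated_min_len: int = 20
    min_anchor: int = 10
    exact_multinomial_threshold: int = 20
    # enrichment
    n_permutations: int = 1_000_000
    weighting: str = "length_times_copy"

    def validate(self) -> "PipelineConfig":
        if not (0 < self.loss_threshold < self.gain_threshold):
            raise ValueError("need 0 < loss_threshold < gain_threshold")
        if not (0 <= self.hom_lo < self.hom_hi <= 1):
            raise ValueError("need 0 <= hom_lo < hom_hi <= 1")
        if not (0 <= self.shift_lo < self.shift_hi <= 1):
            raise ValueError("need 0 <= shift_lo < shift_hi <= 1")
        if not (0 < self.merge_coverage <= 1):
            raise ValueError("merge_coverage must lie in (0, 1]")
        if not (0 < self.uniqueness_ro <= 1):
            raise ValueError("uniqueness_ro must lie in (0, 1]")
        return self


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML config; None yields the defaults.  Unknown keys error."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data).validate()


def save_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))
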