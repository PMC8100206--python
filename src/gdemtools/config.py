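"""Configuration objects shared across pipeline stages.

Every threshold that appears in result tables (stratification cutoffs,
FDR level, annotation window sizes, resampling counts) lives here so stage
logic never hard-codes it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

#: Chromosome names treated as sex chromosomes and removed before testing.
DEFAULT_ALLOSOMES: Tuple[str, ...] = ("chrX", "chrY", "X", "Y", "chrSX")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage child seed from the global seed.

    Hash-based fan-out so that stages can be re-run in isolation with
    identical results. Always < 2**31.
    """
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimConfig:
    """Parameters of the synthetic miniature study.

    Defaults emulate the study conditions: a 17-sample cohort split into a
    high swollen-joint-count group (SJC66 >= 9) and a low group (1-8), a
    deliberate sex confound, planted promoter DMRs (runs of consecutive
    CpGs shifted by ``dmr_effect`` percentage points), planted differential
    transcripts at ``expr_lfc`` log2 fold change, and planted monotone
    methylation-expression coupling of magnitude ``eqtm_rho``.
    """

    n_high: int = 9
    n_low: int = 8
    n_zero: int = 0
    n_genes: int = 60
    transcripts_per_gene: Tuple[int, int] = (1, 5)
    n_cpgs: Optional[int] = None    # default: genome length / cpg_spacing_bp
    cpg_spacing_bp: int = 120       # mean background inter-CpG distance
    dmr_effect: float = 30.0        # percentage points, high - low
    expr_lfc: float = 2.0           # |log2 fold change| of planted transcripts
    eqtm_rho: float = 0.9           # |target methylation-expression correlation|
    coverage_mean: float = 30.0     # mean WGBS depth per CpG
    dispersion: float = 0.1         # NB dispersion of counts
    seed: int = 0
    # planted-truth layout
    n_gdem: int = 20                # genes planted with DMR + expression effect + coupling
    n_discordant: int = 4           # subset of the GDEMs with opposite-sign transcripts
    n_gde_only: int = 10            # expression effect, no DMR
    n_dmr_only: int = 10            # DMR, no expression effect
    n_allosome_genes: int = 2       # genes placed on the synthetic allosome chrSX
    dmr_len: Tuple[int, int] = (10, 50)   # run length in consecutive CpGs
    sex_confound_rate: float = 0.75  # fraction of the high group assigned one sex

    def __post_init__(self) -> None:
        for name in ("n_high", "n_low", "n_zero", "n_genes",
                     "n_gdem", "n_discordant", "n_gde_only", "n_dmr_only",
                     "n_allosome_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cpgs is not None and self.n_cpgs < 0:
            raise ValueError("n_cpgs must be >= 0")
        if self.cpg_spacing_bp <= 0:
            raise ValueError("cpg_spacing_bp must be positive")
        if not 0.0 <= self.eqtm_rho <= 1.0:
            raise ValueError("eqtm_rho must be in [0, 1]")
        if not 0.0 <= self.dmr_effect <= 100.0:
            raise ValueError("dmr_effect must be in [0, 100] percentage points")
        if self.n_discordant > self.n_gdem:
            raise ValueError("n_discordant cannot exceed n_gdem")
        if self.n_gdem + self.n_gde_only + self.n_dmr_only > self.n_genes:
            raise ValueError("planted gene roles exceed n_genes")


@dataclass
class AnnotationConfig:
    """Promoter-window rule used to link DMRs to genes.

    A DMR is linked to a gene when it overlaps (>= 1 bp) the strand-aware
    window extending ``upstream_bp`` upstream and ``downstream_bp``
    downstream of the anchor. The default anchor is the whole gene body;
    ``anchor="tss"`` uses the transcription start site only. ``midpoint``
    requires the DMR midpoint (rather than any overlap) inside the window.
    """

    upstream_bp: int = 5000
    downstream_bp: int = 1000
    anchor: str = "body"            # "body" | "tss"
    require_midpoint: bool = False

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be >= 0")
        if self.anchor not in ("body", "tss"):
            raise ValueError("anchor must be 'body' or 'tss'")


@dataclass
class EqtmConfig:
    n_bootstrap: int = 1000
    n_permutation: int = 1000
    ci_level: float = 0.95
    log2_pseudocount: float = 1.0
    min_cpg_coverage: int = 1       # reads required for a CpG to contribute
    tail: str = "two-sided"         # "two-sided" (|r|) or "greater" (literal rule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.n_permutation < 1:
            raise ValueError("n_bootstrap and n_permutation must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.tail not in ("two-sided", "greater"):
            raise ValueError("tail must be 'two-sided' or 'greater'")


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    samples_tsv: str = "samples.tsv"
    counts_tsv: str = "counts.tsv"
    genes_gtf: str = "genes.gtf"
    dmrs_bed: str = "dmrs.bed"
    coverage_dir: str = "."         # directory of <sample>.cov files
    out_dir: str = "results"
    seed: int = 0
    alpha: float = 0.05             # FDR threshold for GDE / transcript calls
    weight_floor: float = 1.0       # base-expression floor for Lancaster weights
    sjc66_high_min: int = 9
    sjc66_low_max: int = 8
    allosomes: Tuple[str, ...] = DEFAULT_ALLOSOMES
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    eqtm: EqtmConfig = field(default_factory=EqtmConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ann = AnnotationConfig(**raw.pop("annotation", {}))
        eqtm = EqtmConfig(**raw.pop("eqtm", {}))
        if "allosomes" in raw:
            raw["allosomes"] = tuple(raw["allosomes"])
        return cls(annotation=ann, eqtm=eqtm, **raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (file locations excluded)."""
        params = asdict(self)
        for key in ("samples_tsv", "counts_tsv", "genes_gtf", "dmrs_bed",
                    "coverage_dir", "out_dir"):
            params.pop(key, None)
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
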