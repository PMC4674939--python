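"""Simulation and threshold configuration.

Threshold defaults are the operating point for allohexaploid wheat
methyl-seq; simulation defaults describe the synthetic study conditions the
pipeline is validated against (see docs/methods.md for the rationale behind
each value).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: Default pattern mix. 11.9% of analyzable cytosines are methylated in one or
#: more sub-genomes; among those, 45% tri-genome, 20% differential (uni+bi,
#: split 2:1 uni:bi and evenly between genomes/pairs) and 35% intermediate.
_METH_FRACTION = 0.119
DEFAULT_PATTERN_MIX = {
    "tri": _METH_FRACTION * 0.45,
    "uni_A": _METH_FRACTION * 0.20 * (2 / 3) / 3,
    "uni_B": _METH_FRACTION * 0.20 * (2 / 3) / 3,
    "uni_D": _METH_FRACTION * 0.20 * (2 / 3) / 3,
    "bi_AB": _METH_FRACTION * 0.20 * (1 / 3) / 3,
    "bi_AD": _METH_FRACTION * 0.20 * (1 / 3) / 3,
    "bi_BD": _METH_FRACTION * 0.20 * (1 / 3) / 3,
    "intermediate": _METH_FRACTION * 0.35,
    "unmethylated": 1.0 - _METH_FRACTION,
}

DEFAULT_CONTEXT_LEVEL_MEANS = {"CpG": 0.90, "CHG": 0.80, "CHH": 0.70}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic allohexaploid methyl-seq experiment."""

    n_contigs: int = 20
    contig_length: int = 2000  # bp
    snp_rate: float = 0.05  # substitutions per bp between sub-genomes
    tri_allelic_fraction: float = 0.05  # SNPs where all three genomes differ
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    context_level_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_LEVEL_MEANS))
    level_sd: float = 0.04  # per-site jitter around the context mean
    intermediate_level_range: tuple[float, float] = (0.35, 0.65)
    #: sequenced span per fragment. The emulated libraries are 2 x 100 bp
    #: paired-end; both mates of a fragment come from one molecule (same
    #: sub-genome, same conversion state), so a fragment is simulated as one
    #: contiguous 200-bp read — the minimum span consistent with the protocol.
    read_length: int = 200
    depth: float = 50.0  # mean fold-coverage per sub-genome
    conversion_rate: float = 0.9892  # P(unmethylated C reads as T)
    error_rate: float = 0.001  # per-base sequencing error
    directional: bool = False
    low_mapq_fraction: float = 0.02  # reads emitted with MAPQ 10
    control_length: int = 6000  # unmethylated control contig, bp
    promoter_suppression: float = 0.89  # expression factor for uni-methylated promoters
    de_fraction: float = 0.1  # regions simulated as differentially expressed (PPLR)
    seed: int = 0

    def validate(self) -> None:
        mix_sum = sum(self.pattern_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"pattern_mix sums to {mix_sum!r}, expected 1")
        allowed = {"tri", "uni_A", "uni_B", "uni_D", "bi_AB", "bi_AD", "bi_BD",
                   "intermediate", "unmethylated"}
        unknown = set(self.pattern_mix) - allowed
        if unknown:
            raise ValueError(f"unknown pattern_mix keys: {sorted(unknown)}")
        if any(v < 0 for v in self.pattern_mix.values()):
            raise ValueError("pattern_mix proportions must be non-negative")
        for name in ("conversion_rate", "error_rate", "tri_allelic_fraction",
                     "low_mapq_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not 0.0 <= self.snp_rate < 0.2:
            raise ValueError("snp_rate must lie in [0, 0.2)")
        if 0.0 < self.snp_rate and self.contig_length * self.snp_rate < 1.0:
            raise ValueError(
                "contig_length too short to host at least one SNP at this snp_rate")
        if self.read_length > self.contig_length:
            raise ValueError("read_length exceeds contig_length")
        if not 0.0 <= self.promoter_suppression:
            raise ValueError("promoter_suppression must be non-negative")
        lo, hi = self.intermediate_level_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("intermediate_level_range must be an interval in [0, 1]")


@dataclass
class Thresholds:
    """Methylation-calling and testing thresholds (percentages in [0, 100])."""

    cpg_meth: float = 75.0  # CpG level >= this -> Methylated
    cpg_unmeth: float = 25.0  # CpG level <= this -> Unmethylated
    non_cpg_meth: float = 10.0  # CHG/CHH level > this -> Methylated
    within_sample_diff: float = 50.0  # min diff, sub-genome comparisons
    between_sample_diff: float = 25.0  # min diff, sample A-A/B-B/D-D comparisons
    dmr_diff: float = 25.0  # min diff per region
    diploid_compare_diff: float = 50.0  # diploid vs sub-genome D
    q_cutoff: float = 0.01
    single_depth: int = 5  # min reads for a single-genome label
    pair_depth: int = 10  # min reads for a genome-pair label
    mapq_min: int = 20  # reads with MAPQ <= this are not assigned
    promoter_bp: int = 2000
    expr_conserved_window: float = 5.0  # % window for conserved co-expression
    pplr_de_low: float = 0.4
    pplr_de_high: float = 0.6
    pplr_highde_low: float = 0.10
    pplr_highde_high: float = 0.90

    def validate(self) -> None:
        for name in ("cpg_meth", "cpg_unmeth", "non_cpg_meth", "within_sample_diff",
                     "between_sample_diff", "dmr_diff", "diploid_compare_diff",
                     "expr_conserved_window"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not 0.0 < self.q_cutoff < 1.0:
            raise ValueError("q_cutoff must lie in (0, 1)")
        if self.cpg_unmeth > self.cpg_meth:
            raise ValueError("cpg_unmeth must not exceed cpg_meth")
        for name in ("pplr_de_low", "pplr_de_high", "pplr_highde_low",
                     "pplr_highde_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: Optional[int] = None  # overrides simulation.seed when set

    def validate(self) -> None:
        self.simulation.validate()
        self.thresholds.validate()

    @property
    def effective_seed(self) -> int:
        return self.seed if self.seed is not None else self.simulation.seed


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "intermediate_level_range" in kwargs:
        kwargs["intermediate_level_range"] = tuple(kwargs["intermediate_level_range"])
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline config from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        simulation=_from_mapping(SimulationConfig, data.get("simulation", {}) or {}),
        thresholds=_from_mapping(Thresholds, data.get("thresholds", {}) or {}),
        seed=data.get("seed"),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    data = {
        "simulation": dataclasses.asdict(cfg.simulation),
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "seed": cfg.seed,
    }
    data["simulation"]["intermediate_level_range"] = list(
        cfg.simulation.intermediate_level_range)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
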