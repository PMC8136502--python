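"""Simulation and pipeline run configuration.

``SimConfig`` fixes every knob of the synthetic-data generator; one config
plus one seed determines every file the pipeline consumes, so downstream
recovery tests are exact bookkeeping exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    seed: int = 0

    # genome / repeat library
    genome_length: int = 1_000_000
    n_subfamilies: int = 4
    consensus_length: int = 190  # the B2 RNA length scale
    per_copy_divergence: float = 0.02  # substitutions per site
    n_shared_insertions: int = 300
    n_specific_insertions_per_strain: int = 50
    insertion_length_range: tuple[int, int] = (120, 300)
    tsd_length: int = 9  # target-site duplication, typical for L1 machinery
    plant_short_control: bool = False  # one 110-bp truncated copy (below floor)
    plant_low_occupancy_control: bool = False  # 150-bp fragment in a 200-bp gap

    # melRNA-seq
    zipf_exponent: float = 1.0
    n_reads: int = 200_000
    frac_5p8S: float = 0.30  # 5.8S rRNA surrogate (5' mono-P, always ligatable)
    frac_5S: float = 0.02  # 5S rRNA surrogate (5' tri-P, Pol III class)
    frac_degraded: float = 0.30  # molecules missing the 3' adaptor
    adaptor3: str = "TGGAATTCTCGGGTGCCAAGG"
    untreated_polIII_inclusion: float = 0.05  # tri-P carryover without TAP

    # methylation
    meth_coupling_strength: float = 3.0  # expression multiplier exp(-c * level)
    meth_attenuation_cpg_poor: float = 0.2  # coupling scale for <=2-CpG loci
    meth_depth: float = 30.0  # mean per-CpG bisulfite coverage

    # peaks / allelic
    peak_count: int = 40
    peak_length_range: tuple[int, int] = (2_000, 4_000)
    frac_boundary_anchored: float = 0.5  # fraction of peak EDGES at a copy edge
    extension_length: int = 1_000  # free-allele domain extension past breakpoint
    allelic_fold: float = 6.0  # free-allele / carrier-allele coverage ratio
    snp_density: float = 0.005  # per-base heterozygous SNP rate
    allelic_depth: float = 30.0  # mean reads per SNP
    profile_depth_high: float = 50.0  # per-bin coverage inside a domain
    profile_depth_low: float = 2.0

    def validate(self) -> None:
        fracs = {
            "frac_5p8S": self.frac_5p8S,
            "frac_5S": self.frac_5S,
            "frac_degraded": self.frac_degraded,
            "frac_boundary_anchored": self.frac_boundary_anchored,
            "untreated_polIII_inclusion": self.untreated_polIII_inclusion,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.frac_5p8S + self.frac_5S > 1.0:
            raise ValueError("rRNA surrogate fractions exceed 1")
        lo, hi = self.insertion_length_range
        if not (1 <= lo <= hi <= self.genome_length):
            raise ValueError("insertion_length_range outside [1, genome_length]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.n_subfamilies < 2:
            raise ValueError("need at least 2 subfamilies")
        if self.genome_length < 10 * hi:
            raise ValueError("genome_length must be >= 10x max insertion length")
        if self.meth_coupling_strength < 0:
            raise ValueError("meth_coupling_strength must be >= 0")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["insertion_length_range"] = list(self.insertion_length_range)
        data["peak_length_range"] = list(self.peak_length_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("insertion_length_range", "peak_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunConfig:
    """End-to-end pipeline run: a simulation config plus analysis knobs."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: Path = Path("sineboundary_run")
    min_gap_len: int = 120
    max_gap_len: int = 300
    min_occupancy: float = 0.80
    min_flank: int = 50
    min_flank_identity: float = 0.90
    profile_window: int = 2_000
    profile_bin: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in data.pop("sim", {}).items()})
        sim.validate()
        data["outdir"] = Path(data.get("outdir", "sineboundary_run"))
        return cls(sim=sim, **data)
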