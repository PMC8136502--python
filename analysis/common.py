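"""Shared configuration for the numbered analysis scripts.

One seeded study configuration (1 Mb strain genomes, 100 strain-specific
insertions, 200k-read libraries) drives every script; intermediate bulky
files live under scratch/, small result tables under results/.
"""

from pathlib import Path

from sineboundary.config import SimConfig
from sineboundary import synthetic

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

STUDY_SEED = 1


def study_cfg(**kw) -> SimConfig:
    base = dict(
        seed=STUDY_SEED,
        genome_length=1_000_000,
        n_shared_insertions=300,
        n_specific_insertions_per_strain=50,
        insertion_length_range=(150, 250),
        per_copy_divergence=0.02,
        n_reads=200_000,
        peak_count=40,
        plant_short_control=True,
        plant_low_occupancy_control=True,
    )
    base.update(kw)
    cfg = SimConfig(**base)
    cfg.validate()
    return cfg


def build_study():
    """Deterministically regenerate the study inputs (seconds)."""
    cfg = study_cfg()
    lib = synthetic.make_consensus_library(cfg)
    genome_a, genome_b, truth = synthetic.simulate_genome_pair(cfg, lib)
    return cfg, lib, genome_a, genome_b, truth


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
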