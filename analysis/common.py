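"""Shared configuration for the numbered analysis scripts.

The study: a 300 kb synthetic genome standing in for the 37 Mb fungal
genome, two biological replicates at 14x per-strand coverage with a 0.5%
unmethylated spike-in, sequenced as 49 bp read pairs from ~200 bp
(replicate 1) and ~250 bp (replicate 2) fragments. Intermediate data
(FASTQ/TSV) go under scratch/, small result tables under results/.
"""

from pathlib import Path

from hollowmeth import RunConfig, SimConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY = RunConfig(sim=SimConfig(seed=1, genome_length=300_000))
REPLICATES = (1, 2)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
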