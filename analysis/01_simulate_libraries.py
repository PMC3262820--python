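"""Simulate the study: genome + truth methylome + two bisulfite libraries.

Writes the reference (with the unmethylated control contig), the repeat
annotation, the truth methylome (empty: this genome is unmethylated) and
paired FASTQ for both replicates under scratch/study/; a short summary
goes to results/01_simulation_summary.json.
"""

import json

from common import REPLICATES, RESULTS, SCRATCH, STUDY, ensure_dirs
from hollowmeth import simulate_bisulfite_reads, simulate_genome, simulate_methylome
from hollowmeth.simdata import replicate_config

ensure_dirs()
ref, repeats = simulate_genome(STUDY.sim)
meth = simulate_methylome(ref, STUDY.sim)
ref.to_fasta(SCRATCH / "genome.fasta")
repeats.to_bed(SCRATCH / "repeats.bed")
meth.to_tsv(SCRATCH / "truth_methylome.tsv")

summary = {
    "contigs": {n: len(s) for n, s in ref.contigs.items()},
    "control_contigs": sorted(ref.control_names),
    "n_repeat_copies": len(repeats.intervals),
    "n_methylated_truth_sites": len(meth),
    "replicates": {},
}
for rid in REPLICATES:
    cfg = replicate_config(STUDY.sim, rid)
    reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
    reads.to_fastq(SCRATCH / f"rep{rid}_R1.fastq.gz", SCRATCH / f"rep{rid}_R2.fastq.gz")
    truth.to_csv(SCRATCH / f"rep{rid}_truth_origins.tsv", sep="\t", index=False)
    summary["replicates"][rid] = {
        "fragment_mean": cfg.fragment_mean,
        "n_read_pairs": len(reads),
        "n_control_pairs": int((truth.contig.isin(ref.control_names)).sum()),
    }

with open(RESULTS / "01_simulation_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print(json.dumps(summary, indent=2))
print("Two libraries simulated from one unmethylated genome; "
      "the control contig will calibrate the false-positive rate.")
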