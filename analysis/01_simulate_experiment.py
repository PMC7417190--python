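#!/usr/bin/env python
"""Simulate the demo experiment: genome, ground truth, ChIP and ATAC samples.

Writes the genome FASTA, truth BED files, the TSS table and fragment BEDs
under results/sim/, and prints the planted structure.
"""

from pathlib import Path

from chromtrace.synthetic_data import (
    SimConfig,
    simulate_atac,
    simulate_chip,
    simulate_genome,
)

OUT = Path("results/sim")


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed)
    genome, truth = simulate_genome(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    genome.to_fasta(OUT / "genome.fa")
    genome.to_chrom_sizes(OUT / "genome.chrom.sizes")
    truth.write(OUT / "truth")
    cfg.to_json(OUT / "sim_config.json")

    print(f"genome: {len(genome.chrom_names)} chromosomes, "
          f"{genome.total_length:,} bp total")
    print(f"planted sites: {len(truth.bound_sites_A)} A-only, "
          f"{len(truth.bound_sites_B)} B-only, "
          f"{len(truth.bound_sites_shared)} shared, "
          f"{len(truth.unbound_sites)} unbound copies of {truth.motif!r}")

    for factor in ("A", "B", "input"):
        frags = simulate_chip(genome, truth, cfg, factor)
        frags.to_bed(OUT / f"chip_{factor}.bed")
        print(f"ChIP {factor}: {frags.total_count:,} fragments")
    for cond in ("wt", "knockdown_A", "overexpress_A"):
        frags = simulate_atac(genome, truth, cfg, cond)
        frags.to_bed(OUT / f"atac_{cond}.bed")
        print(f"ATAC {cond}: {frags.total_count:,} fragments "
              f"(depth exact by construction)")


if __name__ == "__main__":
    main()
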