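#!/usr/bin/env python
"""Generate the four synthetic dataset families used by the analyses.

Writes each dataset, with its planted truth, under scratch/data/ so the
downstream scripts can either reload the files or regenerate the same
objects in memory from the seed.
"""

import argparse
from pathlib import Path

from asmdiff.simulate import (
    gen_genome_pair,
    gen_proteome_pair,
    gen_region_fixtures,
    gen_transcripts,
)

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "data")
    args = ap.parse_args()

    genome = gen_genome_pair(seed=args.seed, with_sequence=True)
    genome.to_dir(args.out / "genome_pair")
    print(f"genome pair: {len(genome.blocks)} alignment blocks, "
          f"{len(genome.planted_inversions)} planted inversions, "
          f"{len(genome.decoy_blocks)} decoy inverted blocks")

    proteome = gen_proteome_pair(seed=args.seed)
    proteome.to_dir(args.out / "proteome_pair")
    print(f"proteome pair: {len(proteome.genes_a)} A-genes, "
          f"{len(proteome.genes_b)} B-genes, "
          f"{len(proteome.decoy_b_ids)} planted decoys")

    transcripts = gen_transcripts(seed=args.seed)
    transcripts.to_dir(args.out / "transcripts")
    print(f"transcripts: {len(transcripts.genes)} genes, "
          f"{len(transcripts.chains)} read chains, "
          f"{len(transcripts.truth_events)} planted events")

    regions = gen_region_fixtures(seed=args.seed)
    regions.to_dir(args.out / "region_fixtures")
    print(f"region fixtures: {len({f.gap_id for f in regions.flanks})} gaps, "
          f"{len(regions.markers)} markers, "
          f"{len(regions.methylation_sites)} methylation sites")
    print(f"all datasets written to {args.out}")


if __name__ == "__main__":
    main()
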