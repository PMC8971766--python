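#!/usr/bin/env python
"""Design the MUT/WT long-peptide panel for the candidate variants.

Each missense candidate yields 20mer pairs with the mutant residue at
peptide positions 6 and 15; the frameshift candidate yields overlapping
20mer tiles over its non-templated run. Peptides are pooled per gene and
written as FASTA plus a manifest TSV.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from mutanome2vax import peptide_design as pep
from mutanome2vax import pipeline, variant_select as vs

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    candidates = vs.read_variant_table(BASE / "candidates.tsv")
    proteome = {rec.id: str(rec.seq) for rec in SeqIO.parse(
        str(BASE / "synthetic" / "proteome.fasta"), "fasta")}
    contexts = pipeline.build_contexts(candidates, proteome)

    peptides = []
    for ctx in contexts:
        if ctx.is_frameshift:
            peptides.extend(pep.design_frameshift_tiles(ctx))
        else:
            for offset in (6, 15):
                peptides.extend(pep.design_missense_pair(ctx, offset))
    peptides = pep.assign_pools(peptides, "auto")

    pep.peptides_to_fasta(peptides, BASE / "peptides.fasta")
    pd.DataFrame([{"id": p.id, "gene": p.gene, "sequence": p.sequence,
                   "is_mut": p.is_mut, "mut_index": p.mut_index,
                   "pool_id": p.pool_id} for p in peptides]
                 ).to_csv(BASE / "peptides.tsv", sep="\t", index=False)
    n_tiles = sum(p.id.split("_")[-1].startswith("t") for p in peptides)
    print(f"{len(peptides)} peptides ({n_tiles} frameshift tiles) in "
          f"{len({p.pool_id for p in peptides})} per-gene pools "
          f"-> results/peptides.fasta")


if __name__ == "__main__":
    main()
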