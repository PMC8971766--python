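#!/usr/bin/env python
"""Assemble the polyepitope vaccine insert.

One mutation-centered fragment per candidate gene (29mer with 14-residue
flanks; the frameshift fragment spans its whole novel tail), partitioned
into three fusion cassettes balanced by residue length and joined with
5-aa linkers cycling GSGSG, SGSGS, GSTSG, SGTGS.
"""

from pathlib import Path

from Bio import SeqIO

from mutanome2vax import cassette_design as cas
from mutanome2vax import pipeline, variant_select as vs

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    candidates = vs.read_variant_table(BASE / "candidates.tsv")
    proteome = {rec.id: str(rec.seq) for rec in SeqIO.parse(
        str(BASE / "synthetic" / "proteome.fasta"), "fasta")}
    contexts = pipeline.build_contexts(candidates, proteome)
    first_per_gene = {}
    for ctx in contexts:
        first_per_gene.setdefault(ctx.gene, ctx)

    fragments = [cas.make_fragment(ctx) for ctx in first_per_gene.values()]
    construct = cas.assemble_construct(fragments, n_cassettes=3,
                                       strategy="balanced")
    cas.write_construct(construct, BASE / "construct.fasta")
    lengths = sorted(len(f.sequence) for f in fragments)
    print(f"{len(fragments)} fragments (lengths {lengths[0]}..{lengths[-1]} aa)"
          f" in 3 cassettes of {[len(c) for c in construct.cassettes]} aa "
          f"-> results/construct.fasta")


if __name__ == "__main__":
    main()
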