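#!/usr/bin/env python
"""Filter MHC binding predictions to candidate neoepitopes.

Enumerates mutation-spanning 8–11mers and 15mers from the candidate
contexts, draws synthetic MUT/WT IC50 tables over them (a seeded stand-in
for NetMHCpan-style output), keeps high-affinity binders (class I IC50
≤ 500 nM, class II ≤ 1000 nM, boundary inclusive) and labels each surviving
mutant k-mer MUT-specific or shared with the matched wild-type window.
"""

from pathlib import Path

from Bio import SeqIO

from mutanome2vax import epitope_filter as epi
from mutanome2vax import pipeline, synthetic_data, variant_select as vs

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main():
    candidates = vs.read_variant_table(BASE / "candidates.tsv")
    proteome = {rec.id: str(rec.seq) for rec in SeqIO.parse(
        str(BASE / "synthetic" / "proteome.fasta"), "fasta")}
    contexts = pipeline.build_contexts(candidates, proteome)
    cfg = synthetic_data.SimulationConfig(seed=SEED)
    mut, wt = synthetic_data.generate_binding_predictions(cfg, contexts)
    mut.to_csv(BASE / "predictions_mut.tsv", sep="\t", index=False)
    wt.to_csv(BASE / "predictions_wt.tsv", sep="\t", index=False)
    classified = epi.mut_specific_binders(mut, wt)
    classified.to_csv(BASE / "candidate_neoepitopes.tsv", sep="\t",
                      index=False)
    n_spec = int((classified["label"] == "MUT_specific").sum())
    n_shared = int((classified["label"] == "shared").sum())
    n_no_wt = int((classified["note"] == "no_wt_context").sum())
    print(f"{len(mut)} predictions -> {len(classified)} high-affinity "
          f"({n_spec} MUT-specific, {n_shared} shared with WT; "
          f"{n_no_wt} frameshift-novel without WT context)")
    by_class = classified.groupby("mhc_class").size()
    print(f"by MHC class: {dict(by_class)}")
    print("candidate table -> results/candidate_neoepitopes.tsv")


if __name__ == "__main__":
    main()
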