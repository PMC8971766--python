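#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Emulates the case-study conditions: a two-site variant landscape
(2219 / 2384 somatic variants, ~100 non-synonymous each, 23 expressed over
18 gene products with one frameshift), ELISpot plates with 5 planted
responder antigens of 18, and CDR3β repertoires with planted viral,
condition-exclusive, tumor-shared, expanded and ex-vivo-detectable clones.

Writes all input tables plus the truth manifest under results/synthetic/.
"""

from pathlib import Path

from mutanome2vax import pipeline, synthetic_data

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 1


def main():
    cfg = synthetic_data.SimulationConfig(seed=SEED)
    pipeline.run_pipeline(cfg, OUT, stages=("simulate",))
    truth = synthetic_data.read_manifest(OUT / "truth_manifest.json")
    print(f"synthetic inputs written to {OUT}")
    print(f"  expressed variants planted: {truth['variants']['n_expressed']} "
          f"in {truth['variants']['n_expressed_genes']} genes")
    print(f"  responder antigens: {', '.join(truth['responders'])}")
    print(f"  unique clonotypes: {truth['repertoire']['n_unique_total']}")


if __name__ == "__main__":
    main()
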