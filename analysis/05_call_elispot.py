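#!/usr/bin/env python
"""Call spontaneous T-cell responses from the ELISpot plate.

Applies the mean+2SD cutoff over the irrelevant (HIV) peptide control
together with an unpaired Student t-test at alpha 0.05, classifies each
reactive antigen's MUT/WT pattern, and reports the response rate as an
exact fraction with the whole-percent alongside.
"""

from pathlib import Path

from mutanome2vax import elispot_analysis as eli
from mutanome2vax import pipeline

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    plate = eli.read_elispot_csv(BASE / "synthetic" / "elispot.csv")
    calls = eli.call_plate(plate, alpha=0.05)
    calls.to_csv(BASE / "elispot_calls.tsv", sep="\t", index=False)
    mut = calls[calls["condition"] == "MUT"]
    n_pos, n_tot = int(mut["positive"].sum()), len(mut)
    print(f"reactive MUT gene variants: {pipeline.format_fraction(n_pos, n_tot)}")
    reactive = mut[mut["positive"]]
    for _, row in reactive.iterrows():
        print(f"  {row['antigen']}: mean {row['mean_sfc']:.1f} SFC "
              f"(cutoff {row['cutoff']:.1f}), p={row['p_value']:.2g}, "
              f"{row['specificity']}")
    print("full calls -> results/elispot_calls.tsv")


if __name__ == "__main__":
    main()
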