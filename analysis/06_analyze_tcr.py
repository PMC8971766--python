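#!/usr/bin/env python
"""Track neoantigen-specific TCR clonotypes across blood and tumor.

Excludes virus-reactive CDR3β junctions, measures CD8/CD4 subset overlap,
extracts condition-exclusive (operationally neoantigen-specific)
clonotypes per peptide culture, quantifies sharing with the two tumor
sites under the site-exclusive denominator convention, and flags tumor
expansion and direct ex vivo detection.
"""

from pathlib import Path

from mutanome2vax import pipeline, tcr_repertoire as tcr

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    reps = tcr.read_repertoires(BASE / "synthetic" / "repertoire_manifest.tsv")
    summary, n_total = tcr.unique_clonotypes(reps)
    summary.to_csv(BASE / "repertoire_summary.tsv", sep="\t", index=False)
    print(f"{n_total} unique CDR3β junctions across "
          f"{len(reps.samples)} compartments")

    cleaned, viral = tcr.flag_and_exclude_viral(reps)
    print(f"viral: {viral['n_viral']} unique junctions, "
          f"{viral['n_viral_in_antigen_cultures']} recurring in antigen "
          f"cultures (excluded)")

    cd8 = set().union(*(cleaned.keys_of(c) for c in
                        cleaned.culture_compartments if c.endswith(":CD8")))
    cd4 = set().union(*(cleaned.keys_of(c) for c in
                        cleaned.culture_compartments if c.endswith(":CD4")))
    n_ov, pct = tcr.subset_overlap(cd8, cd4)
    print(f"CD8/CD4 overlap: {n_ov} ({pct}%)")

    specific = tcr.all_condition_exclusive(cleaned)
    n_cd8 = sum(len(v) for c, v in specific.items() if c.endswith(":CD8"))
    n_cd4 = sum(len(v) for c, v in specific.items() if c.endswith(":CD4"))
    print(f"condition-exclusive: CD8 {pipeline.format_fraction(n_cd8, len(cd8))}, "
          f"CD4 {pipeline.format_fraction(n_cd4, len(cd4))}")

    site_sets = tcr.tumor_site_sets(cleaned)
    sharing = tcr.tumor_sharing(specific, site_sets)
    sharing.to_csv(BASE / "tumor_sharing.tsv", sep="\t", index=False)
    for _, row in sharing.iterrows():
        print(f"sharing with {row['site']}: {row['n_shared']}/{row['n_tumor']}"
              f" ({row['sharing_pct']}%) [denominator: {row['denominator']}]")

    ann = tcr.annotate_clonotypes(cleaned, specific)
    ann.to_csv(BASE / "clonotype_annotations.tsv", sep="\t", index=False)
    print(f"expanded in tumor: {int(ann['expanded'].sum())}; "
          f"detected ex vivo: {int(ann['detected_ex_vivo'].sum())} "
          f"-> results/clonotype_annotations.tsv")


if __name__ == "__main__":
    main()
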