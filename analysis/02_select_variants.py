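#!/usr/bin/env python
"""Triage the somatic variant tables to expressed non-synonymous candidates.

Reads the two per-site variant TSVs and the expression table written by
01_simulate.py, reports the non-synonymous counts, the tumor mutational
burden at a 38 Mb capture size, the two-site overlap per variant class, and
the expressed candidate set (variants and distinct gene products).
"""

from pathlib import Path

from mutanome2vax import variant_select as vs

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    site1 = vs.read_variant_table(BASE / "synthetic" / "variants_site1.tsv")
    site2 = vs.read_variant_table(BASE / "synthetic" / "variants_site2.tsv")
    expr = vs.read_expression_table(BASE / "synthetic" / "expression.tsv")

    n1 = int(site1["effect"].isin(vs.NONSYNONYMOUS_EFFECTS).sum())
    n2 = int(site2["effect"].isin(vs.NONSYNONYMOUS_EFFECTS).sum())
    print(f"site 1: {len(site1)} variants, {n1} non-synonymous, "
          f"TMB {vs.compute_tmb(n1):.2f}/Mb")
    print(f"site 2: {len(site2)} variants, {n2} non-synonymous, "
          f"TMB {vs.compute_tmb(n2):.2f}/Mb")

    overlap = vs.site_overlap(site1, site2)
    overlap.to_csv(BASE / "site_overlap.tsv", sep="\t", index=False)
    print("two-site overlap by class:")
    print(overlap.to_string(index=False))

    candidates = vs.filter_candidates(site1, expr, tpm_threshold=0.0)
    candidates.variants.to_csv(BASE / "candidates.tsv", sep="\t", index=False)
    print(f"expressed candidates: {len(candidates)} variants in "
          f"{candidates.n_gene_products} gene products -> results/candidates.tsv")


if __name__ == "__main__":
    main()
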