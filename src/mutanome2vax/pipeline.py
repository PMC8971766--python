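"""End-to-end orchestration: simulate → variant triage → peptide and
cassette design → ELISpot calling → TCR clonotype analysis → neoepitope
filtering, with per-stage artifacts and a consolidated report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import (cassette_design, elispot_analysis, epitope_filter,
               peptide_design, synthetic_data, tcr_repertoire, variant_select)
from .peptide_design import MutantContext

logger = logging.getLogger(__name__)

STAGES = ("simulate", "variants", "peptides", "cassette", "elispot", "tcr",
          "epitopes")


def build_contexts(candidates: pd.DataFrame,
                   proteome: dict[str, str]) -> list[MutantContext]:
    """Protein-level mutant contexts for every candidate variant."""
    contexts = []
    for _, row in candidates.iterrows():
        change = variant_select.parse_hgvs_p(row["hgvs_p"])
        if change.is_frameshift:
            ctx = MutantContext(gene=row["gene"], protein=proteome[row["gene"]],
                                position=change.position,
                                novel_tail=row.get("novel_tail") or None)
        else:
            ctx = MutantContext(gene=row["gene"], protein=proteome[row["gene"]],
                                position=change.position,
                                ref_aa=change.ref_aa, alt_aa=change.alt_aa)
        contexts.append(ctx)
    return contexts


def format_fraction(n: int, total: int) -> str:
    """``"5/18 (28%)"`` — exact fraction alongside the whole percent."""
    pct = int(100.0 * n / total + 0.5) if total else 0
    return f"{n}/{total} ({pct}%)"


def run_pipeline(config: synthetic_data.SimulationConfig, out_dir,
                 tpm_threshold: float = 0.0, exome_mb: float = 38.0,
                 alpha: float = 0.05, expansion_min: int = 2,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the enabled stages in order on synthetic inputs and write all
    artifacts plus ``report.json`` / ``report.txt`` under ``out_dir``.
    Deterministic for a fixed (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # -- simulate -----------------------------------------------------------
    if "simulate" not in stages:
        raise ValueError("the synthetic pipeline needs the simulate stage")
    proteome = synthetic_data.generate_proteome(config)
    site1, site2, expression, var_truth = \
        synthetic_data.plant_variants(config, proteome)
    synthetic_data.write_proteome_fasta(proteome, out / "proteome.fasta")
    site1.to_csv(out / "variants_site1.tsv", sep="\t", index=False)
    site2.to_csv(out / "variants_site2.tsv", sep="\t", index=False)
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)

    antigens = var_truth["expressed_genes"]
    responders = synthetic_data.responder_antigens(config, antigens)
    plate = synthetic_data.generate_elispot(config, antigens, responders)
    plate.to_csv(out / "elispot.csv", index=False)

    reps, rep_truth = synthetic_data.generate_repertoires(config, responders)
    rep_dir = out / "repertoires"
    rep_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for comp, df in sorted(reps.samples.items()):
        fname = comp.replace(":", "_") + ".tsv"
        df.to_csv(rep_dir / fname, sep="\t", index=False)
        manifest_rows.append({"compartment": comp,
                              "path": f"repertoires/{fname}"})
    pd.DataFrame(manifest_rows).to_csv(out / "repertoire_manifest.tsv",
                                       sep="\t", index=False)
    truth = {"variants": var_truth, "responders": responders,
             "repertoire": rep_truth}
    synthetic_data.write_manifest(truth, out / "truth_manifest.json")

    # -- variants -----------------------------------------------------------
    if "variants" in stages:
        candidates = variant_select.filter_candidates(site1, expression,
                                                      tpm_threshold)
        overlap = variant_select.site_overlap(site1, site2)
        n_nonsyn1 = int(site1["effect"].isin(
            variant_select.NONSYNONYMOUS_EFFECTS).sum())
        n_nonsyn2 = int(site2["effect"].isin(
            variant_select.NONSYNONYMOUS_EFFECTS).sum())
        candidates.variants.to_csv(out / "candidates.tsv", sep="\t",
                                   index=False)
        overlap.to_csv(out / "site_overlap.tsv", sep="\t", index=False)
        report["variants"] = {
            "n_site1": len(site1), "n_site2": len(site2),
            "n_nonsynonymous_site1": n_nonsyn1,
            "n_nonsynonymous_site2": n_nonsyn2,
            "n_candidates": len(candidates),
            "n_gene_products": candidates.n_gene_products,
            "tmb_site1": variant_select.compute_tmb(n_nonsyn1, exome_mb),
            "tmb_site2": variant_select.compute_tmb(n_nonsyn2, exome_mb),
            "overlap_all_pct": float(
                overlap.loc[overlap["variant_class"] == "all",
                            "overlap_pct"].iloc[0]),
        }
        logger.info("variants: %d -> %d candidates in %d genes",
                    len(site1), len(candidates), candidates.n_gene_products)
    else:
        return _finish(report, out)

    contexts = build_contexts(candidates.variants, proteome)

    # -- peptides -----------------------------------------------------------
    if "peptides" in stages:
        peptides = []
        for ctx in contexts:
            if ctx.is_frameshift:
                peptides.extend(peptide_design.design_frameshift_tiles(ctx))
            else:
                for offset in (6, 15):
                    mut, wt = peptide_design.design_missense_pair(ctx, offset)
                    peptides.extend([mut, wt])
        peptides = peptide_design.assign_pools(peptides, "auto")
        peptide_design.peptides_to_fasta(peptides, out / "peptides.fasta")
        pd.DataFrame([{"id": p.id, "gene": p.gene, "sequence": p.sequence,
                       "is_mut": p.is_mut, "mut_index": p.mut_index,
                       "pool_id": p.pool_id} for p in peptides]
                     ).to_csv(out / "peptides.tsv", sep="\t", index=False)
        report["peptides"] = {
            "n_peptides": len(peptides),
            "n_pools": len({p.pool_id for p in peptides}),
        }

    # -- cassette -----------------------------------------------------------
    if "cassette" in stages:
        first_per_gene: dict[str, MutantContext] = {}
        for ctx in contexts:
            first_per_gene.setdefault(ctx.gene, ctx)
        fragments = [cassette_design.make_fragment(c)
                     for c in first_per_gene.values()]
        construct = cassette_design.assemble_construct(fragments)
        cassette_design.write_construct(construct, out / "construct.fasta")
        report["cassette"] = {
            "n_fragments": len(fragments),
            "cassette_lengths": [len(c) for c in construct.cassettes],
            "total_length": construct.total_length,
        }

    # -- elispot ------------------------------------------------------------
    if "elispot" in stages:
        calls = elispot_analysis.call_plate(plate, alpha=alpha)
        calls.to_csv(out / "elispot_calls.tsv", sep="\t", index=False)
        mut_calls = calls[calls["condition"] == "MUT"]
        n_pos = int(mut_calls["positive"].sum())
        n_tot = len(mut_calls)
        pct = int(100.0 * n_pos / n_tot + 0.5) if n_tot else 0
        report["elispot"] = {
            "n_positive": n_pos, "n_antigens": n_tot,
            "response_rate_pct": pct,
            "response_rate": format_fraction(n_pos, n_tot),
            "reactive_antigens": sorted(
                mut_calls.loc[mut_calls["positive"], "antigen"]),
        }

    # -- tcr ----------------------------------------------------------------
    if "tcr" in stages:
        summary, n_total = tcr_repertoire.unique_clonotypes(reps)
        cleaned, viral_report = tcr_repertoire.flag_and_exclude_viral(reps)
        specific = tcr_repertoire.all_condition_exclusive(cleaned)
        cd8 = set().union(*(cleaned.keys_of(c)
                            for c in cleaned.culture_compartments
                            if c.endswith(":CD8"))) \
            if cleaned.culture_compartments else set()
        cd4 = set().union(*(cleaned.keys_of(c)
                            for c in cleaned.culture_compartments
                            if c.endswith(":CD4"))) \
            if cleaned.culture_compartments else set()
        n_overlap, overlap_pct = tcr_repertoire.subset_overlap(cd8, cd4)
        site_sets = tcr_repertoire.tumor_site_sets(cleaned)
        sharing = tcr_repertoire.tumor_sharing(specific, site_sets)
        viral_keys = set()
        for comp in tcr_repertoire.VIRAL_COMPARTMENTS:
            if comp in reps.samples:
                viral_keys |= reps.keys_of(comp)
        annotations = tcr_repertoire.annotate_clonotypes(
            cleaned, specific, viral_keys, expansion_min)
        summary.to_csv(out / "repertoire_summary.tsv", sep="\t", index=False)
        sharing.to_csv(out / "tumor_sharing.tsv", sep="\t", index=False)
        annotations.to_csv(out / "clonotype_annotations.tsv", sep="\t",
                           index=False)
        n_cd8_specific = sum(len(v) for c, v in specific.items()
                             if c.endswith(":CD8"))
        n_cd4_specific = sum(len(v) for c, v in specific.items()
                             if c.endswith(":CD4"))
        report["tcr"] = {
            "n_unique_total": n_total,
            "n_viral": viral_report["n_viral"],
            "n_viral_in_antigen_cultures":
                viral_report["n_viral_in_antigen_cultures"],
            "n_cd8": len(cd8), "n_cd4": len(cd4),
            "cd8_cd4_overlap_n": n_overlap,
            "cd8_cd4_overlap_pct": overlap_pct,
            "n_cd8_specific": n_cd8_specific,
            "n_cd4_specific": n_cd4_specific,
            "cd8_specific": format_fraction(n_cd8_specific, len(cd8)),
            "cd4_specific": format_fraction(n_cd4_specific, len(cd4)),
            "tumor_sharing": sharing.to_dict(orient="records"),
            "n_expanded": int(annotations["expanded"].sum())
            if len(annotations) else 0,
            "n_detected_ex_vivo": int(annotations["detected_ex_vivo"].sum())
            if len(annotations) else 0,
        }

    # -- epitopes -----------------------------------------------------------
    if "epitopes" in stages:
        mut_pred, wt_pred = synthetic_data.generate_binding_predictions(
            config, contexts)
        mut_pred.to_csv(out / "predictions_mut.tsv", sep="\t", index=False)
        wt_pred.to_csv(out / "predictions_wt.tsv", sep="\t", index=False)
        classified = epitope_filter.mut_specific_binders(mut_pred, wt_pred)
        classified.to_csv(out / "candidate_neoepitopes.tsv", sep="\t",
                          index=False)
        report["epitopes"] = {
            "n_predictions": len(mut_pred),
            "n_high_affinity": len(classified),
            "n_mut_specific": int((classified["label"] == "MUT_specific").sum()),
            "n_shared": int((classified["label"] == "shared").sum()),
        }

    return _finish(report, out)


def _finish(report: dict, out: Path) -> dict:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable summary; every percentage appears next to its exact
    fraction."""
    lines = [f"mutanome2vax run (seed {report.get('seed')})", ""]
    v = report.get("variants")
    if v:
        lines += [
            "Variant selection",
            f"  site 1: {v['n_site1']} variants, "
            f"{v['n_nonsynonymous_site1']} non-synonymous "
            f"(TMB {v['tmb_site1']:.2f}/Mb)",
            f"  site 2: {v['n_site2']} variants, "
            f"{v['n_nonsynonymous_site2']} non-synonymous "
            f"(TMB {v['tmb_site2']:.2f}/Mb)",
            f"  two-site overlap (all classes): {v['overlap_all_pct']}%",
            f"  expressed candidates: {v['n_candidates']} variants in "
            f"{v['n_gene_products']} gene products", ""]
    else:
        lines += ["Variant selection: absent", ""]
    p = report.get("peptides")
    if p:
        lines += ["Long peptides",
                  f"  {p['n_peptides']} peptides in {p['n_pools']} pools", ""]
    c = report.get("cassette")
    if c:
        lines += ["Vaccine construct",
                  f"  {c['n_fragments']} fragments in "
                  f"{len(c['cassette_lengths'])} cassettes "
                  f"(lengths {c['cassette_lengths']}, "
                  f"total {c['total_length']} aa)", ""]
    e = report.get("elispot")
    if e:
        lines += ["ELISpot",
                  f"  reactive MUT gene variants: {e['response_rate']}",
                  f"  reactive antigens: {', '.join(e['reactive_antigens']) or 'none'}",
                  ""]
    else:
        lines += ["ELISpot: absent", ""]
    t = report.get("tcr")
    if t:
        lines += [
            "TCR repertoire",
            f"  unique clonotypes: {t['n_unique_total']}",
            f"  viral: {t['n_viral']} unique, "
            f"{t['n_viral_in_antigen_cultures']} recurring in antigen "
            f"cultures (excluded)",
            f"  CD8/CD4 overlap: {t['cd8_cd4_overlap_n']} "
            f"({t['cd8_cd4_overlap_pct']}%)",
            f"  condition-exclusive: CD8 {t['cd8_specific']}, "
            f"CD4 {t['cd4_specific']}"]
        for row in t["tumor_sharing"]:
            lines.append(
                f"  sharing with {row['site']}: "
                f"{row['n_shared']}/{row['n_tumor']} ({row['sharing_pct']}%)"
                f" [denominator: {row['denominator']}]")
        lines += [f"  expanded in tumor: {t['n_expanded']}; "
                  f"detected ex vivo: {t['n_detected_ex_vivo']}", ""]
    ep = report.get("epitopes")
    if ep:
        lines += ["Candidate neoepitopes",
                  f"  {ep['n_high_affinity']} high-affinity of "
                  f"{ep['n_predictions']} predictions "
                  f"({ep['n_mut_specific']} MUT-specific, "
                  f"{ep['n_shared']} shared with WT)", ""]
    return "\n".join(lines) + "\n"
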