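"""Minimal-epitope candidate selection from MHC binding predictions.

Mutation-spanning k-mers (8–11mers for class I, 15mers for class II) are
enumerated from each variant context to build prediction input; externally
produced IC50 tables are then filtered at the affinity thresholds of
500 nM (class I) and 1000 nM (class II), and surviving mutant k-mers are
classified as MUT-specific or shared with the matched wild-type window.
"""

from __future__ import annotations

import pandas as pd

from .peptide_design import MutantContext

CLASS_I_MAX_NM = 500.0
CLASS_II_MAX_NM = 1000.0
CLASS_I_LENGTHS = range(8, 12)
CLASS_II_LENGTH = 15

PREDICTION_COLUMNS = ["peptide", "allele", "mhc_class", "ic50_nm"]


def mutated_positions(ctx: MutantContext) -> set[int]:
    """1-based positions in the mutant protein that differ from wild type:
    the substituted residue for a missense, every novel-tail residue for a
    frameshift."""
    if ctx.is_frameshift:
        return set(range(ctx.position, ctx.position + len(ctx.novel_tail)))
    return {ctx.position}


def spanning_kmer_windows(ctx: MutantContext, k: int,
                          sequence: str | None = None) -> list[tuple[int, str]]:
    """(start, k-mer) pairs for all windows of ``sequence`` (default: the
    mutant protein) that contain at least one mutated residue, ordered by
    1-based start. Duplicated sequences at different starts are kept — the
    start is part of the identity for MUT/WT matching."""
    if k < 1:
        raise ValueError("k must be positive")
    seq = ctx.mutant_protein if sequence is None else sequence
    if k > len(seq):
        return []
    hot = mutated_positions(ctx)
    return [(start, seq[start - 1: start - 1 + k])
            for start in range(1, len(seq) - k + 2)
            if any(start <= p <= start + k - 1 for p in hot)]


def enumerate_spanning_kmers(ctx: MutantContext, k: int) -> list[str]:
    """All k-mers of the mutant sequence containing at least one mutated
    residue, ordered by start position and deduplicated. Returns an empty
    list when the mutant sequence is shorter than k."""
    seen, out = set(), []
    for _, kmer in spanning_kmer_windows(ctx, k):
        if kmer not in seen:
            seen.add(kmer)
            out.append(kmer)
    return out


def spanning_kmer_table(ctx: MutantContext,
                        lengths: list[int] | None = None) -> pd.DataFrame:
    """Mutation-spanning k-mers over the standard class I/II lengths, as a
    table (gene, k, peptide) ready for a prediction tool."""
    lengths = lengths or [*CLASS_I_LENGTHS, CLASS_II_LENGTH]
    rows = [{"gene": ctx.gene, "k": k, "peptide": p}
            for k in lengths for p in enumerate_spanning_kmers(ctx, k)]
    return pd.DataFrame(rows, columns=["gene", "k", "peptide"])


def filter_high_affinity(binders: pd.DataFrame,
                         class_i_max: float = CLASS_I_MAX_NM,
                         class_ii_max: float = CLASS_II_MAX_NM) -> pd.DataFrame:
    """Retain high-affinity rows: IC50 ≤ 500 nM for class I, ≤ 1000 nM for
    class II (boundary values retained)."""
    if binders.empty:
        return binders.copy()
    classes = set(binders["mhc_class"].unique())
    unknown = classes - {"I", "II"}
    if unknown:
        raise ValueError(f"unknown MHC class labels: {sorted(unknown)}")
    keep = ((binders["mhc_class"] == "I") & (binders["ic50_nm"] <= class_i_max)) | \
           ((binders["mhc_class"] == "II") & (binders["ic50_nm"] <= class_ii_max))
    return binders[keep].reset_index(drop=True)


def mut_specific_binders(mut_binders: pd.DataFrame,
                         wt_binders: pd.DataFrame,
                         class_i_max: float = CLASS_I_MAX_NM,
                         class_ii_max: float = CLASS_II_MAX_NM) -> pd.DataFrame:
    """Classify each high-affinity mutant k-mer as ``MUT_specific`` or
    ``shared`` with the positionally matched wild-type prediction.

    ``wt_binders`` must carry the same join keys (``window_start``, allele,
    mhc_class, and peptide length) for matched windows; a mutant k-mer with
    no wild-type counterpart (frameshift novel sequence) is MUT_specific
    with a ``no_wt_context`` note.
    """
    mut_hi = filter_high_affinity(mut_binders, class_i_max, class_ii_max)
    if mut_hi.empty:
        return mut_hi.assign(label=pd.Series(dtype=str),
                             note=pd.Series(dtype=str))
    wt_hi = filter_high_affinity(wt_binders, class_i_max, class_ii_max) \
        if not wt_binders.empty else wt_binders
    join = ["window_start", "allele", "mhc_class"]
    wt_keys = set() if wt_binders.empty else {
        tuple(r) for r in wt_binders[join].itertuples(index=False)}
    wt_hi_keys = set() if (wt_binders.empty or wt_hi.empty) else {
        tuple(r) for r in wt_hi[join].itertuples(index=False)}
    labels, notes = [], []
    for r in mut_hi[join].itertuples(index=False):
        key = tuple(r)
        if key not in wt_keys:
            labels.append("MUT_specific")
            notes.append("no_wt_context")
        elif key in wt_hi_keys:
            labels.append("shared")
            notes.append("")
        else:
            labels.append("MUT_specific")
            notes.append("")
    return mut_hi.assign(label=labels, note=notes)


def read_predictions(path) -> pd.DataFrame:
    """Read a binding-prediction TSV (peptide, allele, mhc_class, ic50_nm),
    a minimal dialect of IEDB tool output."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    df["ic50_nm"] = df["ic50_nm"].astype(float)
    if (df["ic50_nm"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    return df
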