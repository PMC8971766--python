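# Methods

This note records the models, conventions and open design choices behind
the package, and what the synthetic conditions do and do not show about
real data.

## Scope and assumptions

The pipeline covers the downstream half of a personalized neoantigen
workflow: it consumes *annotated* somatic variant tables (protein-level
HGVS), a gene-level TPM table, protein sequences, ELISpot plate counts,
AIRR-style clonotype tables and externally produced MHC IC50 predictions.
Variant calling, TCR read mapping and the binding predictors themselves are
out of scope; their outputs are inputs here.

All protein-level reasoning is done on single canonical isoforms. Isoform
duplicates of one variant (same gene, same protein change on different
transcripts) collapse to a single candidate, so candidate counting reports
both variants and distinct gene products.

## Variant selection

Non-synonymous means `effect ∈ {missense, frameshift}`. "Expressed" is
`TPM > t` with `t = 0` by default — the threshold is deliberately minimal
because presence in the tumor transcriptome, not a quantitative cutoff, is
the selection criterion; `t` is configurable. Genes missing from the
expression table count as TPM 0 with a warning rather than an error, since
expression tables routinely drop zero rows.

Two-site overlap uses variant identity `(gene, hgvs_p, variant_class)` and
an intersection-over-union denominator, reported per class to one decimal.
TMB is non-synonymous mutations per megabase of captured exome; the capture
size defaults to 38 Mb (typical for clinical research exome kits) and is
configurable, as assays differ.

## Long peptides

Missense candidates yield 20mer MUT/WT pairs with the variant residue at
peptide position 6 or 15. Because real placements drift with the variant's
position in the transcript, the designer emits *both* offsets per variant
by default; the window start `position − offset + 1` is clamped to the
protein so the peptide keeps length 20 whenever the protein allows, and
proteins shorter than 20 aa are used whole (no padding characters, ever).
A MUT/WT pair differs at exactly one position — this is asserted as a
package invariant.

Frameshift peptides tile the concatenation of the last 15 native residues
before the divergence point and the entire novel tail, as 20mers at a
10-residue step, with a final right-aligned tile so the last residue is
always covered. The flank/step defaults place the first novel residue near
peptide position 6 and make adjacent tiles overlap by half, mirroring the
MUT-at-6/15 convention of the missense pairs.

Pools group all peptides of one gene (`auto`) or follow an explicit
per-gene size plan; pools never mix genes.

## Vaccine cassettes

Each candidate gene contributes one fragment centered on its variant:
`[position − 14, position + 14]` clamped to the protein (29 aa in the
interior, shorter near termini), or flank-plus-whole-novel-tail for a
frameshift. Fragments are partitioned into three fusion cassettes and
neighbours are joined by 5-aa linkers cycling GSGSG → SGSGS → GSTSG →
SGTGS (restarting per cassette). The partition is contiguous in the input
order and, by default, balances total residue length by brute force over
the contiguous splits (136 splits for 18 fragments in 3 cassettes); an
`equal`-count strategy exists. Linkers appear only between fragments, so
cassette length always equals Σ fragment lengths + 5 × (n − 1); this
identity is tested. Cassette FASTA headers carry fragment lengths, variant
offsets and linkers so a construct round-trips through write/read exactly.

## ELISpot calling

The positivity cutoff is `mean + 2 × SD` of the irrelevant-control wells,
with the sample SD (ddof 1); a single control replicate degrades to SD 0
with a warning. Positivity additionally requires a two-sided unpaired
Student (equal-variance) t-test at α = 0.05 against the control wells —
plain unpaired t-tests in mainstream plate-analysis software are Student's,
and the conjunction is the conservative merge of the two published rules;
a cutoff-only mode is available. Two zero-variance groups with equal means
get p := 1 by convention. Replicate wells are treated as exchangeable
observations. Response rates are reported as exact fractions with a
whole-percent rounded half away from zero; the CD8/CD4 overlap statistic
is the one quantity reported to one decimal.

MUT/WT classification: MUT+ and WT− → MUT_only; both positive → split by
which mean is larger (WT_dominant vs MUT_and_WT); MUT− → negative.

## TCR clonotype analysis

Clonotype identity is the CDR3β amino-acid junction alone by default —
bulk tumor TCR-seq cannot resolve chain pairing, and V-call participation
is configurable. The analysis order matters and is fixed: (1) any junction
seen in a viral-pool culture is flagged viral-reactive and removed from all
peptide-expanded cultures (tumor and ex vivo samples are kept whole so
occupancy questions remain answerable); (2) a junction is
*condition-exclusive* when it occurs in exactly one culture condition —
presence in tumor or unstimulated blood does **not** disqualify, since that
cross-compartment sharing is the quantity of interest; (3) tumor sharing
divides the specific junctions found in a tumor site by that site's
*site-exclusive* unique count (junctions seen at both sites are excluded
from the denominator; a `site_total` convention is available and flagged in
the output); (4) expansion means clone count ≥ 2 in a tumor sample —
published "expanded" flags come without a numeric rule and the observed
example counts are consistent with 2 as the threshold; ex vivo detection
means occurrence in unstimulated sorted blood. Junctions seen only ex vivo
(attributable to no stimulation condition) are excluded from specificity
claims.

## Neoepitope filtering

Candidate minimal epitopes are the 8–11mers (class I) and 15mers (class
II) of the mutant sequence that cover at least one mutated position —
the substituted residue, or any novel-tail residue for frameshifts.
High-affinity means predicted IC50 ≤ 500 nM (class I) or ≤ 1000 nM (class
II), boundary inclusive. A surviving mutant k-mer is MUT-specific when the
positionally matched wild-type window is not itself high-affinity, and
shared otherwise; frameshift-novel windows have no wild-type counterpart
and are MUT-specific with an explicit `no_wt_context` note. Only IC50
thresholds are consulted; percentile ranks are not modeled.

## Synthetic data: what it emulates, and what it does not

The generator's defaults *are* the study conditions: 2219 / 2384 variants
per site with 102 / 105 non-synonymous, exactly 23 expressed over 18 genes
(one frameshift with a 62-residue novel tail, giving the 76-aa vaccine
fragment), ELISpot control wells as rounded draws from Normal(12, 2²)
truncated at zero with a +10 SD mean shift on 5 planted responders of 18,
and CDR3β repertoires (length 8–20, C…F junction shape) of fixed
per-compartment sizes with planted viral, condition-exclusive,
tumor-shared, expanded and ex-vivo-detectable clones. Truncated rounded
Normal noise is the simplest model under which the mean+2SD rule has
predictable behavior, and the 10×SD planted effect makes recovery
deterministic in practice while keeping the generator stochastic in form.

Three structural choices make planted truth exactly recoverable and are
worth knowing when adapting the generator: (a) planted tumor-shared clones
are a subset of the planted condition-exclusive clones of the same
condition, because any clone sitting in a single culture is necessarily
condition-exclusive; (b) background filler clones are each placed in at
least two cultures, so no unplanted clone can masquerade as
condition-exclusive; (c) the viral-pool compartments contain exactly the
planted viral clones, because viral flagging is defined by occupancy.
Tumor copy numbers for planted shared clones cycle 7, 2, 1, so roughly two
thirds of them are "expanded" under the ≥ 2 rule.

The generator works at the clonotype level only: no read-level simulation,
no sequencing error, no clone-size power laws, no UMI structure, and IC50
tables are log-uniform draws with one planted strong binder per context
rather than output of a binding model. Passing recovery tests therefore
demonstrates that the *bookkeeping* — filtering, exclusivity, sharing,
thresholding — is exact, not that the pipeline is robust to the noise
modes of real sequencing or real predictors.

All generators are pure functions of the configuration; the seed feeds
independent `numpy` `default_rng` streams per generator, and replays are
byte-identical (V/J labels are derived from a CRC of the junction string,
not from Python's randomized string hash).

## Problem sizes and numerical conventions

The default synthetic study (2219-variant cohort, 26 repertoire
compartments, ~1800 unique junctions, 18-antigen plates) runs end-to-end
in a few seconds; the test suite's Monte-Carlo checks use 600 null
antigens for the false-positive bound and 400 planted responders across
200 seeds for the recovery bound. Percentages round half away from zero to
whole percent, except intersection-over-union overlaps (one decimal). TMB
rounds to two decimals. Ties in the balanced cassette partition break
toward the lexicographically smallest cut positions.

## Known limitations

- HGVS parsing covers the `p.Xxx123Yyy`, `p.Xxx123fs` (with optional
  `Yyyfs*N`) and `p.Xxx123=` forms used here, not the full HGVS grammar
  (no extensions, delins, or ranges).
- Condition-exclusivity is an operational proxy for antigen specificity;
  clones reactive to several antigens, or bystander-expanded, are
  indistinguishable from noise under it.
- The cutoff+t-test conjunction with 3 replicates has low power for small
  true shifts; the synthetic 10×SD effects do not probe that regime.
- Multi-isoform proteins, somatic phasing and proteasomal processing are
  not modeled.
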