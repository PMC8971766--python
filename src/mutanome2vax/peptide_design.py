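"""Long-peptide design for immunogenicity testing.

Each missense candidate yields a matched MUT/WT 20mer pair with the variant
residue placed at peptide position 6 or 15 (clamped near protein termini).
A frameshift candidate yields overlapping 20mer tiles covering the whole
non-templated amino-acid run. Peptides for one gene are grouped into a
stimulation pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PEPTIDE_LENGTH = 20


@dataclass(frozen=True)
class MutantContext:
    """Protein-level context of one candidate variant.

    For a missense variant ``protein[position]`` (1-based) is ``ref_aa`` and
    the mutant protein substitutes ``alt_aa`` there. For a frameshift,
    ``novel_tail`` is the non-templated run that replaces the native sequence
    from ``position`` onward.
    """

    gene: str
    protein: str
    position: int
    ref_aa: str | None = None
    alt_aa: str | None = None
    novel_tail: str | None = None

    @property
    def is_frameshift(self) -> bool:
        return self.novel_tail is not None

    def __post_init__(self):
        if not (1 <= self.position <= len(self.protein)):
            raise ValueError(
                f"{self.gene}: variant position {self.position} outside "
                f"protein of length {len(self.protein)}")
        if self.is_frameshift:
            if not self.novel_tail:
                raise ValueError(f"{self.gene}: empty frameshift tail")
        else:
            if self.ref_aa is None or self.alt_aa is None:
                raise ValueError(f"{self.gene}: missense context needs ref and alt")
            if self.ref_aa == self.alt_aa:
                raise ValueError(f"{self.gene}: ref equals alt ({self.ref_aa})")
            if self.protein[self.position - 1] != self.ref_aa:
                raise ValueError(
                    f"{self.gene}: protein has {self.protein[self.position - 1]} "
                    f"at {self.position}, expected {self.ref_aa}")

    @property
    def mutant_protein(self) -> str:
        """Full mutant sequence (substitution applied, or native prefix plus
        the novel tail for a frameshift)."""
        i = self.position - 1
        if self.is_frameshift:
            return self.protein[:i] + self.novel_tail
        return self.protein[:i] + self.alt_aa + self.protein[i + 1:]


@dataclass(frozen=True)
class LongPeptide:
    id: str
    sequence: str
    gene: str
    is_mut: bool
    mut_index: int | None = None  # 1-based within the peptide; None for WT/tiles
    pool_id: str | None = None

    def __post_init__(self):
        if len(self.sequence) > PEPTIDE_LENGTH:
            raise ValueError(f"{self.id}: peptide longer than {PEPTIDE_LENGTH} aa")
        if not set(self.sequence) <= set(AA_ALPHABET):
            raise ValueError(f"{self.id}: non-standard residues in sequence")


def design_missense_pair(ctx: MutantContext, offset: int = 6
                         ) -> tuple[LongPeptide, LongPeptide]:
    """Design a matched (MUT, WT) 20mer pair with the variant residue at
    peptide position ``offset`` (6 or 15 conventionally).

    The window start is ``position - offset + 1``, clamped so the peptide
    stays inside the protein; proteins shorter than 20 aa are used whole.
    The two peptides are identical except at the variant index.
    """
    if ctx.is_frameshift:
        raise ValueError("missense pair design called on a frameshift context")
    n = len(ctx.protein)
    if n < PEPTIDE_LENGTH:
        start = 1
        length = n
    else:
        start = min(max(ctx.position - offset + 1, 1), n - PEPTIDE_LENGTH + 1)
        length = PEPTIDE_LENGTH
    mut_index = ctx.position - start + 1
    wt_seq = ctx.protein[start - 1: start - 1 + length]
    mut_seq = (wt_seq[: mut_index - 1] + ctx.alt_aa + wt_seq[mut_index:])
    base = f"{ctx.gene}_p{ctx.position}{ctx.ref_aa}{ctx.alt_aa}_o{offset}"
    mut = LongPeptide(id=f"{base}_MUT", sequence=mut_seq, gene=ctx.gene,
                      is_mut=True, mut_index=mut_index)
    wt = LongPeptide(id=f"{base}_WT", sequence=wt_seq, gene=ctx.gene,
                     is_mut=False, mut_index=mut_index)
    return mut, wt


def tile_starts(length: int, step: int, width: int = PEPTIDE_LENGTH) -> list[int]:
    """1-based start positions tiling ``length`` residues with ``width``-mers
    at the given step; the final tile is right-aligned so the last residue is
    always covered."""
    if length <= width:
        return [1]
    starts = list(range(1, length - width + 2, step))
    if starts[-1] + width - 1 < length:
        starts.append(length - width + 1)
    return starts


def design_frameshift_tiles(ctx: MutantContext, upstream_flank: int = 15,
                            step: int = 10) -> list[LongPeptide]:
    """Tile the frameshift region — the last ``upstream_flank`` native
    residues before the divergence point plus the whole novel tail — into
    overlapping 20mers. Every novel residue is covered at least once; a
    region shorter than 20 aa yields a single full-length peptide."""
    if not ctx.is_frameshift:
        raise ValueError("frameshift tiling called on a missense context")
    flank_start = max(ctx.position - upstream_flank, 1)
    region = ctx.protein[flank_start - 1: ctx.position - 1] + ctx.novel_tail
    peptides = []
    for i, start in enumerate(tile_starts(len(region), step), start=1):
        seq = region[start - 1: start - 1 + PEPTIDE_LENGTH]
        peptides.append(LongPeptide(
            id=f"{ctx.gene}_fs{ctx.position}_t{i}", sequence=seq,
            gene=ctx.gene, is_mut=True))
    return peptides


def assign_pools(peptides: list[LongPeptide],
                 pool_plan: dict[str, list[int]] | str = "auto"
                 ) -> list[LongPeptide]:
    """Group peptides into per-gene stimulation pools.

    ``pool_plan`` maps gene -> list of pool sizes, or ``"auto"`` to pool all
    of a gene's peptides together. Pools never mix genes; a plan whose sizes
    do not sum to the gene's peptide count is an error naming the gene.
    """
    by_gene: dict[str, list[LongPeptide]] = {}
    for p in peptides:
        by_gene.setdefault(p.gene, []).append(p)
    out: list[LongPeptide] = []
    for gene, peps in by_gene.items():
        if pool_plan == "auto":
            sizes = [len(peps)]
        else:
            sizes = pool_plan.get(gene, [len(peps)])
            if sum(sizes) != len(peps):
                raise ValueError(
                    f"pool plan for gene {gene} covers {sum(sizes)} peptides "
                    f"but {len(peps)} were designed")
        i = 0
        for k, size in enumerate(sizes, start=1):
            pool_id = f"{gene}_pool{k}"
            for p in peps[i:i + size]:
                out.append(LongPeptide(id=p.id, sequence=p.sequence,
                                       gene=p.gene, is_mut=p.is_mut,
                                       mut_index=p.mut_index, pool_id=pool_id))
            i += size
    return out


def peptides_to_fasta(peptides: list[LongPeptide], path) -> None:
    """Write peptides as FASTA with ``id|MUT/WT|pool`` headers."""
    with open(path, "w") as fh:
        for p in peptides:
            tag = "MUT" if p.is_mut else "WT"
            fh.write(f">{p.id}|{tag}|{p.pool_id or 'unpooled'}\n{p.sequence}\n")
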