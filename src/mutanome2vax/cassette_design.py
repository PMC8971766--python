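"""Polyepitope cassette assembly for an MVA-vectored vaccine insert.

Each candidate variant contributes a mutation-centered fragment (29mer by
default: 14-residue flanks around the variant; frameshifts carry the whole
novel tail). Fragments are partitioned into three fusion cassettes and
joined by 5-aa glycine/serine linkers cycling through GSGSG, SGSGS, GSTSG,
SGTGS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptide_design import AA_ALPHABET, MutantContext

LINKERS = ("GSGSG", "SGSGS", "GSTSG", "SGTGS")
LINKER_LEN = 5


@dataclass(frozen=True)
class VaccineFragment:
    gene: str
    sequence: str
    mut_offset: int  # 1-based index of the variant residue / novel-run start

    def __post_init__(self):
        if not (1 <= self.mut_offset <= len(self.sequence)):
            raise ValueError(f"{self.gene}: mut_offset outside fragment")
        if not set(self.sequence) <= set(AA_ALPHABET):
            raise ValueError(f"{self.gene}: non-standard residues")


@dataclass(frozen=True)
class Cassette:
    fragments: tuple[VaccineFragment, ...]
    linkers: tuple[str, ...]  # one linker between each consecutive pair

    def __post_init__(self):
        if len(self.linkers) != max(len(self.fragments) - 1, 0):
            raise ValueError("need exactly n_fragments - 1 linkers")
        if any(lk not in LINKERS for lk in self.linkers):
            raise ValueError("linker outside the allowed set")

    @property
    def sequence(self) -> str:
        parts = []
        for frag, linker in itertools.zip_longest(self.fragments, self.linkers):
            parts.append(frag.sequence)
            if linker is not None:
                parts.append(linker)
        return "".join(parts)

    def __len__(self) -> int:
        return (sum(len(f.sequence) for f in self.fragments)
                + LINKER_LEN * len(self.linkers))


@dataclass(frozen=True)
class VaccineConstruct:
    cassettes: tuple[Cassette, ...]

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.cassettes)


def make_fragment(ctx: MutantContext, flank: int = 14) -> VaccineFragment:
    """Cut the vaccine fragment for one variant.

    Missense: the window ``[position - flank, position + flank]`` clamped to
    the protein (29 aa when both flanks fit). Frameshift: the upstream flank
    plus the entire novel tail.
    """
    start = max(ctx.position - flank, 1)
    if ctx.is_frameshift:
        seq = ctx.protein[start - 1: ctx.position - 1] + ctx.novel_tail
    else:
        end = min(ctx.position + flank, len(ctx.protein))
        mutant = ctx.mutant_protein
        seq = mutant[start - 1: end]
    return VaccineFragment(gene=ctx.gene, sequence=seq,
                           mut_offset=ctx.position - start + 1)


def _balanced_partition(lengths: list[int], n_parts: int) -> list[int]:
    """Split points (indices after which to cut) minimising the maximum
    part length including linker overhead; brute force over contiguous
    splits, ties broken by the lexicographically smallest cut tuple."""
    n = len(lengths)

    def part_len(i: int, j: int) -> int:  # fragments i..j-1 plus linkers
        return sum(lengths[i:j]) + LINKER_LEN * (j - i - 1)

    best_cuts, best_cost = None, None
    for cuts in itertools.combinations(range(1, n), n_parts - 1):
        bounds = [0, *cuts, n]
        cost = max(part_len(a, b) for a, b in zip(bounds, bounds[1:]))
        if best_cost is None or cost < best_cost:
            best_cuts, best_cost = cuts, cost
    return list(best_cuts or [])


def assemble_construct(fragments: list[VaccineFragment], n_cassettes: int = 3,
                       strategy: str = "balanced") -> VaccineConstruct:
    """Partition fragments (in the given order) into contiguous cassettes and
    join neighbours with linkers cycling GSGSG -> SGSGS -> GSTSG -> SGTGS.

    ``strategy`` is ``"balanced"`` (minimise the longest cassette) or
    ``"equal"`` (equal fragment counts, remainder to the leading cassettes).
    """
    n = len(fragments)
    if n < n_cassettes:
        raise ValueError(f"{n} fragments cannot fill {n_cassettes} cassettes")
    if strategy == "balanced":
        cuts = _balanced_partition([len(f.sequence) for f in fragments],
                                   n_cassettes)
    elif strategy == "equal":
        base, extra = divmod(n, n_cassettes)
        sizes = [base + (1 if i < extra else 0) for i in range(n_cassettes)]
        cuts = list(itertools.accumulate(sizes))[:-1]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    bounds = [0, *cuts, n]
    cassettes = []
    for a, b in zip(bounds, bounds[1:]):
        group = tuple(fragments[a:b])
        linkers = tuple(LINKERS[i % len(LINKERS)] for i in range(len(group) - 1))
        cassettes.append(Cassette(fragments=group, linkers=linkers))
    return VaccineConstruct(cassettes=tuple(cassettes))


def write_construct(construct: VaccineConstruct, path) -> None:
    """Write one FASTA record per cassette; the description encodes fragment
    genes, lengths, variant offsets and linkers so the construct round-trips
    through :func:`read_construct` exactly."""
    if not construct.cassettes:
        raise ValueError("construct has no cassettes")
    records = []
    for i, cas in enumerate(construct.cassettes, start=1):
        frag_spec = ",".join(f"{f.gene}:{len(f.sequence)}:{f.mut_offset}"
                             for f in cas.fragments)
        link_spec = ",".join(cas.linkers) or "-"
        rec = SeqRecord(Seq(cas.sequence), id=f"cassette_{i}",
                        description=f"fragments={frag_spec} linkers={link_spec}")
        records.append(rec)
    SeqIO.write(records, path, "fasta")


def read_construct(path) -> VaccineConstruct:
    """Re-parse a construct FASTA written by :func:`write_construct`."""
    cassettes = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = dict(part.split("=", 1)
                      for part in rec.description.split(" ")[1:])
        linkers = tuple(lk for lk in fields["linkers"].split(",") if lk != "-")
        seq = str(rec.seq)
        frags, pos = [], 0
        specs = fields["fragments"].split(",")
        for j, spec in enumerate(specs):
            gene, length, offset = spec.split(":")
            frags.append(VaccineFragment(gene=gene,
                                         sequence=seq[pos:pos + int(length)],
                                         mut_offset=int(offset)))
            pos += int(length)
            if j < len(specs) - 1:
                pos += LINKER_LEN
        cassettes.append(Cassette(fragments=tuple(frags), linkers=linkers))
    return VaccineConstruct(cassettes=tuple(cassettes))
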