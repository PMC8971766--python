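"""Somatic-variant triage: HGVS parsing, expressed non-synonymous filtering,
two-site overlap, and tumor mutational burden.

The selection logic mirrors a personalized-vaccine workflow for a low-TMB
tumor: starting from per-site annotated somatic variant tables, keep the
non-synonymous subset, intersect with tumor RNA expression, and report the
surviving candidates together with the number of distinct gene products they
involve.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

NONSYNONYMOUS_EFFECTS = frozenset({"missense", "frameshift"})
VARIANT_CLASSES = frozenset({"SNP", "MNP", "INS", "DEL"})

#: Columns of a variant table, in canonical order.
VARIANT_COLUMNS = ["gene", "transcript", "variant_class", "effect",
                   "hgvs_c", "hgvs_p", "site"]


class HgvsParseError(ValueError):
    """Raised when a protein-level HGVS string cannot be interpreted."""


@dataclass(frozen=True)
class ProteinChange:
    """Parsed protein-level consequence of a somatic variant.

    ``ref_aa`` and ``alt_aa`` are one-letter codes; ``alt_aa`` is ``None``
    for frameshifts, where translation diverges from ``position`` onward.
    """

    ref_aa: str
    position: int
    alt_aa: str | None

    @property
    def is_frameshift(self) -> bool:
        return self.alt_aa is None


@dataclass(frozen=True)
class CandidateSet:
    """Expressed non-synonymous variants surviving the filter chain."""

    variants: pd.DataFrame
    n_gene_products: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "n_gene_products",
                           self.variants["gene"].nunique())

    def __len__(self) -> int:
        return len(self.variants)


_AA3 = "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val"
_MISSENSE_RE = re.compile(rf"^p\.({_AA3})(\d+)({_AA3})$")
_FRAMESHIFT_RE = re.compile(rf"^p\.({_AA3})(\d+)(?:{_AA3})?fs(?:\*\d+)?$")


def parse_hgvs_p(hgvs_p: str) -> ProteinChange:
    """Parse a protein HGVS string like ``p.Leu86Ser`` or ``p.Val608fs``.

    Returns a :class:`ProteinChange` with one-letter residue codes. A
    frameshift yields ``alt_aa=None``. Raises :class:`HgvsParseError` on
    malformed input or when reference and alternate residues coincide.
    """
    if not isinstance(hgvs_p, str) or not hgvs_p.startswith("p."):
        raise HgvsParseError(f"not a protein HGVS string: {hgvs_p!r}")
    m = _FRAMESHIFT_RE.match(hgvs_p)
    if m:
        ref3, pos = m.group(1), int(m.group(2))
        return ProteinChange(seq1(ref3), pos, None)
    m = _MISSENSE_RE.match(hgvs_p)
    if m:
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if ref3 == alt3:
            raise HgvsParseError(
                f"reference and alternate residue are identical in {hgvs_p!r}")
        if pos < 1:
            raise HgvsParseError(f"non-positive residue position in {hgvs_p!r}")
        return ProteinChange(seq1(ref3), pos, seq1(alt3))
    # Name the first token that breaks the expected grammar.
    token = hgvs_p[2:] or "<empty>"
    raise HgvsParseError(f"cannot parse protein change token {token!r} in {hgvs_p!r}")


_AA1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def format_hgvs_p(change: ProteinChange) -> str:
    """Inverse of :func:`parse_hgvs_p` (frameshifts render as ``p.Xxx123fs``)."""
    ref3 = _AA1TO3[change.ref_aa]
    if change.is_frameshift:
        return f"p.{ref3}{change.position}fs"
    return f"p.{ref3}{change.position}{_AA1TO3[change.alt_aa]}"


def _variant_key(df: pd.DataFrame) -> pd.Series:
    return df["gene"] + "|" + df["hgvs_p"] + "|" + df["variant_class"]


def site_overlap(site_a: pd.DataFrame, site_b: pd.DataFrame) -> pd.DataFrame:
    """Per-variant-class overlap between two tumor sites.

    Identity is (gene, hgvs_p, variant_class); overlap percent is
    intersection over union, one decimal. Returns a table with one row per
    class present in either site plus an ``all`` summary row.
    """
    if site_a.empty or site_b.empty:
        logger.warning("site_overlap called with an empty variant table")
        return pd.DataFrame(columns=["variant_class", "n_a", "n_b",
                                     "n_shared", "n_union", "overlap_pct"])
    rows = []
    classes = sorted(set(site_a["variant_class"]) | set(site_b["variant_class"]))
    for cls in classes + ["all"]:
        a = site_a if cls == "all" else site_a[site_a["variant_class"] == cls]
        b = site_b if cls == "all" else site_b[site_b["variant_class"] == cls]
        keys_a, keys_b = set(_variant_key(a)), set(_variant_key(b))
        union = keys_a | keys_b
        shared = keys_a & keys_b
        pct = round(100.0 * len(shared) / len(union), 1) if union else 0.0
        rows.append({"variant_class": cls, "n_a": len(keys_a),
                     "n_b": len(keys_b), "n_shared": len(shared),
                     "n_union": len(union), "overlap_pct": pct})
    return pd.DataFrame(rows)


def filter_candidates(variants: pd.DataFrame, expression: pd.DataFrame,
                      tpm_threshold: float = 0.0) -> CandidateSet:
    """Keep non-synonymous variants whose gene is expressed (TPM > threshold).

    Genes absent from the expression table are treated as unexpressed (TPM 0)
    with a warning. Isoform duplicates — identical (gene, hgvs_p) on
    different transcripts — collapse to a single candidate.
    """
    tpm = expression.set_index("gene")["tpm"]
    nonsyn = variants[variants["effect"].isin(NONSYNONYMOUS_EFFECTS)].copy()
    missing = sorted(set(nonsyn["gene"]) - set(tpm.index))
    if missing:
        logger.warning("%d candidate genes missing from expression table; "
                       "treated as TPM 0: %s", len(missing), missing[:5])
    gene_tpm = nonsyn["gene"].map(tpm).fillna(0.0)
    survivors = nonsyn[gene_tpm > tpm_threshold]
    survivors = survivors.drop_duplicates(subset=["gene", "hgvs_p"])
    return CandidateSet(variants=survivors.reset_index(drop=True))


def compute_tmb(n_nonsynonymous: int, exome_mb: float = 38.0) -> float:
    """Tumor mutational burden: non-synonymous mutations per megabase,
    rounded to two decimals. ``exome_mb`` is the capture size of the exome
    assay (default 38 Mb)."""
    if exome_mb <= 0 or not math.isfinite(exome_mb):
        raise ValueError(f"exome size must be positive, got {exome_mb}")
    if n_nonsynonymous < 0:
        raise ValueError("mutation count must be non-negative")
    return round(n_nonsynonymous / exome_mb, 2)


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant TSV (gene, transcript, variant_class, effect, hgvs_c,
    hgvs_p, site)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df


def read_expression_table(path) -> pd.DataFrame:
    """Read an expression TSV (gene, tpm)."""
    df = pd.read_csv(path, sep="\t")
    df["tpm"] = df["tpm"].astype(float)
    if (df["tpm"] < 0).any():
        raise ValueError("negative TPM values in expression table")
    return df
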