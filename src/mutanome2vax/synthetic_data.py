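"""Seeded generators for every input the pipeline consumes, with planted
ground truth.

The defaults emulate the study conditions of a TMB-low lung tumor case:
a two-site variant landscape (2219 / 2384 variants with ~100 non-synonymous
each), a 23-variant expressed subset spread over 18 gene products including
one frameshift with a non-templated tail, ELISpot plates with 5 responder
antigens of 18, and CDR3β repertoires with planted viral,
condition-exclusive, tumor-shared, expanded and ex-vivo-detectable clones.

Every generator is a pure function of its configuration (which carries the
seed): reruns produce identical bytes. Planted truth is emitted as a sidecar
manifest; downstream recovery tests read truth only from the manifest.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .peptide_design import AA_ALPHABET
from .tcr_repertoire import RepertoireSet, culture_name
from .variant_select import VARIANT_COLUMNS, _AA1TO3


class ConfigurationError(ValueError):
    """A simulation configuration that cannot be realised."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Counts default to the case-study magnitudes; maps left ``None`` are
    derived from the planted responder antigens at generation time.
    """

    seed: int = 0
    # proteome
    n_genes: int = 360
    protein_length_range: tuple[int, int] = (120, 700)
    # variant landscape
    n_variants_site1: int = 2219
    n_variants_site2: int = 2384
    n_nonsynonymous: int = 102
    n_nonsynonymous_site2: int = 105
    n_expressed: int = 23
    n_expressed_genes: int = 18
    frameshift_tail_length: int = 62
    site_shared_fraction: float = 0.2
    expressed_tpm_range: tuple[float, float] = (2.0, 120.0)
    # ELISpot
    elispot_control_mean: float = 12.0
    elispot_control_sd: float = 2.0
    elispot_replicates: int = 3
    responder_shift_sds: float = 10.0
    planted_responders: int | list[str] = 5
    planted_wt_responders: tuple[str, ...] = ()
    # repertoires
    culture_size: int = 60
    specific_per_cd8_culture: int = 38
    specific_per_cd4_culture: int = 55
    shared_primary_per_mut_culture: int = 2
    shared_metastasis_per_mut_culture: int = 4
    ex_vivo_detected_per_mut_culture: int = 1
    tumor_both_site: int = 12
    planted_viral: int = 12
    planted_viral_recurrent: int = 8
    repertoire_sizes: dict[str, int] | None = None
    planted_specific: dict[str, int] | None = None
    planted_tumor_shared: dict[tuple[str, str], int] | None = None
    planted_ex_vivo: dict[str, int] | None = None
    cdr3_length_range: tuple[int, int] = (8, 20)

    def __post_init__(self):
        if not (self.n_expressed <= self.n_nonsynonymous
                <= self.n_variants_site1):
            raise ConfigurationError(
                "need n_expressed <= n_nonsynonymous <= n_variants_site1")
        if self.n_expressed_genes > self.n_expressed:
            raise ConfigurationError("n_expressed_genes exceeds n_expressed")
        if self.n_expressed and self.n_expressed_genes < 1:
            raise ConfigurationError("expressed variants need >= 1 gene")
        for name in ("n_genes", "n_variants_site1", "n_variants_site2",
                     "n_nonsynonymous", "n_expressed", "planted_viral",
                     "planted_viral_recurrent", "culture_size"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        lo, hi = self.protein_length_range
        if lo < 40 or hi < lo:
            raise ConfigurationError(
                "protein lengths must be >= 40 aa and ordered")
        if self.elispot_control_sd <= 0:
            raise ConfigurationError("elispot_control_sd must be positive")
        if self.elispot_replicates < 2:
            raise ConfigurationError("need >= 2 control replicates")
        if self.planted_viral_recurrent > self.planted_viral:
            raise ConfigurationError(
                "recurrent viral clones cannot exceed planted_viral")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stream."""
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# proteome

def generate_proteome(config: SimulationConfig) -> dict[str, str]:
    """Random protein sequences over the 20-aa alphabet with unique gene
    symbols, ordered and deterministic for a fixed seed."""
    if config.n_genes < 1:
        raise ConfigurationError("need at least one gene")
    rng = config.rng(1)
    alphabet = np.array(list(AA_ALPHABET))
    lo, hi = config.protein_length_range
    proteome = {}
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        proteome[f"GENE{i + 1:04d}"] = seq
    return proteome


def write_proteome_fasta(proteome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, seq in proteome.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# variants and expression

_SYN_CLASSES = ["SNP", "SNP", "SNP", "MNP", "INS", "DEL"]


def _missense_hgvs(rng, protein: str, position: int) -> tuple[str, str, str]:
    ref = protein[position - 1]
    alt = str(rng.choice([a for a in AA_ALPHABET if a != ref]))
    return ref, alt, f"p.{_AA1TO3[ref]}{position}{_AA1TO3[alt]}"


def plant_variants(config: SimulationConfig, proteome: dict[str, str]
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate the two-site somatic variant tables, the expression table
    and the planted-truth record.

    Site 1 carries exactly ``n_nonsynonymous`` non-synonymous variants, of
    which exactly ``n_expressed`` (over ``n_expressed_genes`` genes,
    including one frameshift with a generated non-templated tail) fall in
    genes expressed above TPM 0. A configurable fraction of site-1 variants
    recurs at site 2.
    """
    rng = config.rng(2)
    genes = list(proteome)
    margin = 21  # missense >= 20 aa from the termini so full 20mers exist
    hosts = [g for g in genes if len(proteome[g]) >= 2 * margin + 1]
    if len(hosts) < config.n_expressed_genes + 1:
        raise ConfigurationError("proteome too small to host planted variants")

    host_order = list(rng.permutation(hosts))
    expressed_genes = host_order[:config.n_expressed_genes]
    unexpressed_pool = host_order[config.n_expressed_genes:]

    rows: list[dict] = []
    truth_expressed: list[dict] = []
    used_positions: dict[str, set[int]] = {}

    def draw_position(gene: str) -> int:
        seq = proteome[gene]
        taken = used_positions.setdefault(gene, set())
        while True:
            pos = int(rng.integers(margin, len(seq) - margin + 1))
            if pos not in taken:
                taken.add(pos)
                return pos

    def add_variant(gene: str, effect: str, site: str) -> dict:
        pos = draw_position(gene)
        if effect == "frameshift":
            ref = proteome[gene][pos - 1]
            tail = "".join(rng.choice(list(AA_ALPHABET),
                                      size=config.frameshift_tail_length))
            row = {"gene": gene, "transcript": f"{gene}.t1",
                   "variant_class": "DEL", "effect": "frameshift",
                   "hgvs_c": f"c.{3 * pos}delC",
                   "hgvs_p": f"p.{_AA1TO3[ref]}{pos}fs",
                   "site": site, "novel_tail": tail}
        elif effect == "missense":
            ref, alt, hgvs_p = _missense_hgvs(rng, proteome[gene], pos)
            base = int(rng.integers(1, 4))
            row = {"gene": gene, "transcript": f"{gene}.t1",
                   "variant_class": "SNP", "effect": "missense",
                   "hgvs_c": f"c.{3 * (pos - 1) + base}T>C",
                   "hgvs_p": hgvs_p, "site": site, "novel_tail": ""}
        else:  # synonymous / other
            ref = proteome[gene][pos - 1]
            row = {"gene": gene, "transcript": f"{gene}.t1",
                   "variant_class": str(rng.choice(_SYN_CLASSES)),
                   "effect": str(rng.choice(["synonymous", "other"])),
                   "hgvs_c": f"c.{3 * pos}C>T",
                   "hgvs_p": f"p.{_AA1TO3[ref]}{pos}=",
                   "site": site, "novel_tail": ""}
        rows.append(row)
        return row

    # Expressed non-synonymous variants: one per expressed gene, then second
    # variants on the leading genes until n_expressed is reached; the first
    # expressed variant is the frameshift.
    gene_cycle = (expressed_genes
                  * (config.n_expressed // max(len(expressed_genes), 1) + 2))
    for i in range(config.n_expressed):
        effect = "frameshift" if i == 0 else "missense"
        row = add_variant(gene_cycle[i], effect, "site1")
        truth_expressed.append(row)

    # Non-expressed non-synonymous variants live in unexpressed genes.
    n_hidden = config.n_nonsynonymous - config.n_expressed
    if n_hidden and not unexpressed_pool:
        raise ConfigurationError("no unexpressed genes left for hidden variants")
    for i in range(n_hidden):
        add_variant(unexpressed_pool[i % len(unexpressed_pool)],
                    "missense", "site1")

    # Synonymous / non-coding remainder across all genes.
    for i in range(config.n_variants_site1 - config.n_nonsynonymous):
        add_variant(hosts[int(rng.integers(0, len(hosts)))],
                    "synonymous", "site1")

    site1 = pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["novel_tail"])

    # Site 2: a shared fraction of site-1 variants plus fresh ones.
    n_shared = int(round(config.site_shared_fraction * len(site1)))
    shared_idx = rng.choice(len(site1), size=n_shared, replace=False)
    site2_rows = [dict(site1.iloc[i], site="site2") for i in sorted(shared_idx)]
    n_shared_nonsyn = sum(r["effect"] in ("missense", "frameshift")
                          for r in site2_rows)
    rows2: list[dict] = []
    rows, rows2 = rows2, rows  # add_variant appends into `rows`
    for i in range(max(config.n_nonsynonymous_site2 - n_shared_nonsyn, 0)):
        add_variant(unexpressed_pool[(i + 7) % len(unexpressed_pool)],
                    "missense", "site2")
    while len(rows) + len(site2_rows) < config.n_variants_site2:
        add_variant(hosts[int(rng.integers(0, len(hosts)))],
                    "synonymous", "site2")
    site2 = pd.DataFrame(site2_rows + rows,
                         columns=VARIANT_COLUMNS + ["novel_tail"])

    # Expression: expressed genes get TPM in the configured range; genes
    # hosting hidden non-synonymous variants stay at 0; the rest of the
    # proteome gets a mix for realism.
    lo, hi = config.expressed_tpm_range
    hidden_genes = set(unexpressed_pool)
    tpm = {}
    for g in genes:
        if g in expressed_genes:
            tpm[g] = float(np.round(rng.uniform(lo, hi), 2))
        elif g in hidden_genes:
            tpm[g] = 0.0
        else:
            tpm[g] = float(np.round(rng.uniform(0, hi), 2)) \
                if rng.random() < 0.5 else 0.0
    expression = pd.DataFrame({"gene": genes, "tpm": [tpm[g] for g in genes]})

    truth = {
        "n_variants_site1": int(len(site1)),
        "n_variants_site2": int(len(site2)),
        "n_nonsynonymous_site1": config.n_nonsynonymous,
        "n_expressed": config.n_expressed,
        "n_expressed_genes": config.n_expressed_genes,
        "expressed_genes": expressed_genes,
        "expressed_variants": [
            {"gene": r["gene"], "hgvs_p": r["hgvs_p"], "effect": r["effect"],
             "novel_tail": r["novel_tail"]} for r in truth_expressed],
    }
    return site1, site2, expression, truth


# ---------------------------------------------------------------------------
# ELISpot

def responder_antigens(config: SimulationConfig,
                       expressed_genes: list[str]) -> list[str]:
    """Resolve the planted-responder spec to concrete gene symbols."""
    if isinstance(config.planted_responders, int):
        if config.planted_responders > len(expressed_genes):
            raise ConfigurationError("more responders than antigens")
        return expressed_genes[:config.planted_responders]
    unknown = set(config.planted_responders) - set(expressed_genes)
    if unknown:
        raise ConfigurationError(f"planted responders not among antigens: "
                                 f"{sorted(unknown)}")
    return list(config.planted_responders)


def generate_elispot(config: SimulationConfig, antigens: list[str],
                     responders: list[str] | None = None) -> pd.DataFrame:
    """Simulate an ELISpot plate: per antigen, MUT and WT wells plus shared
    positive and irrelevant (HIV) control wells.

    Well counts are rounded draws from a Normal truncated at zero; planted
    responders receive a mean shift of ``responder_shift_sds`` × control SD
    on the MUT condition (and on WT for planted WT responders).
    """
    rng = config.rng(3)
    if responders is None:
        responders = responder_antigens(config, antigens)
    mu, sd = config.elispot_control_mean, config.elispot_control_sd
    shift = config.responder_shift_sds * sd

    def wells(mean: float) -> list[int]:
        draws = rng.normal(mean, sd, size=config.elispot_replicates)
        return [int(round(max(x, 0.0))) for x in draws]

    rows = []
    for antigen in antigens:
        for condition in ("MUT", "WT"):
            shifted = ((condition == "MUT" and antigen in responders)
                       or (condition == "WT"
                           and antigen in config.planted_wt_responders))
            for rep, sfc in enumerate(wells(mu + shift if shifted else mu),
                                      start=1):
                rows.append({"antigen": antigen, "condition": condition,
                             "replicate": rep, "sfc": sfc})
    for rep, sfc in enumerate(wells(mu + 2.5 * shift), start=1):
        rows.append({"antigen": "viral_pool", "condition": "positive_control",
                     "replicate": rep, "sfc": sfc})
    for rep, sfc in enumerate(wells(mu), start=1):
        rows.append({"antigen": "HIV", "condition": "irrelevant_control",
                     "replicate": rep, "sfc": sfc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repertoires

class _Cdr3Factory:
    """Unique CDR3β junction strings: C + 6–18 random residues + F."""

    def __init__(self, rng: np.random.Generator,
                 length_range: tuple[int, int] = (8, 20)):
        self.rng = rng
        self.lo, self.hi = length_range
        self.seen: set[str] = set()

    def draw(self) -> str:
        while True:
            length = int(self.rng.integers(self.lo, self.hi + 1))
            core = "".join(self.rng.choice(list(AA_ALPHABET),
                                           size=length - 2))
            cdr3 = "C" + core + "F"
            if cdr3 not in self.seen:
                self.seen.add(cdr3)
                return cdr3

    def draw_many(self, n: int) -> list[str]:
        return [self.draw() for _ in range(n)]


def default_repertoire_plan(config: SimulationConfig, antigens: list[str]
                            ) -> tuple[dict[str, int], dict[str, int],
                                       dict[tuple[str, str], int],
                                       dict[str, int]]:
    """Derive (sizes, specific, tumor_shared, ex_vivo) maps for the default
    culture layout: one culture per (antigen, MUT/WT, CD8/CD4)."""
    sizes: dict[str, int] = {}
    specific: dict[str, int] = {}
    shared: dict[tuple[str, str], int] = {}
    ex_vivo: dict[str, int] = {}
    for antigen in antigens:
        for allele in ("MUT", "WT"):
            for subset in ("CD8", "CD4"):
                cond = culture_name(antigen, allele, subset)
                sizes[cond] = config.culture_size
                specific[cond] = (config.specific_per_cd8_culture
                                  if subset == "CD8"
                                  else config.specific_per_cd4_culture)
                if allele == "MUT":
                    shared[(cond, "primary_tumor")] = \
                        config.shared_primary_per_mut_culture
                    shared[(cond, "metastasis")] = \
                        config.shared_metastasis_per_mut_culture
                    ex_vivo[cond] = config.ex_vivo_detected_per_mut_culture
    sizes.update({"primary_tumor": 180, "metastasis": 400,
                  "ex_vivo_CD8": 120, "ex_vivo_CD4": 100,
                  "viral_culture_CD8": (config.planted_viral + 1) // 2,
                  "viral_culture_CD4": config.planted_viral // 2})
    if config.repertoire_sizes:
        sizes.update(config.repertoire_sizes)
    if config.planted_specific is not None:
        specific = dict(config.planted_specific)
    if config.planted_tumor_shared is not None:
        shared = dict(config.planted_tumor_shared)
    if config.planted_ex_vivo is not None:
        ex_vivo = dict(config.planted_ex_vivo)
    return sizes, specific, shared, ex_vivo


def generate_repertoires(config: SimulationConfig, antigens: list[str]
                         ) -> tuple[RepertoireSet, dict]:
    """Simulate compartment-labeled clonotype tables with planted truth.

    Planted per culture: condition-exclusive clones (present in exactly one
    culture), of which leading slices also recur in tumor tissue (with
    copy numbers cycling 7, 2, 1 — clones reaching >= 2 copies are the
    planted "expanded" set) and/or in unstimulated blood. Viral clones are
    seeded into the viral-pool cultures, a subset recurring in antigen
    cultures. Background clones each occupy >= 2 cultures so no unplanted
    clonotype can masquerade as condition-exclusive. Every compartment's
    unique clonotype count equals its configured size exactly.
    """
    rng = config.rng(4)
    factory = _Cdr3Factory(rng, config.cdr3_length_range)
    sizes, specific_n, shared_n, ex_vivo_n = \
        default_repertoire_plan(config, antigens)
    cultures = sorted(k for k in sizes if k.startswith("culture:"))

    membership: dict[str, dict[str, int]] = {c: {} for c in sizes}

    def place(comp: str, key: str, count: int) -> None:
        membership[comp][key] = count

    truth_specific: dict[str, list[str]] = {}
    truth_shared: dict[str, dict[str, list[str]]] = {}
    truth_ex_vivo: dict[str, list[str]] = {}
    truth_expanded: list[str] = []

    tumor_copy_cycle = (7, 2, 1)
    for cond in cultures:
        n_spec = specific_n.get(cond, 0)
        keys = factory.draw_many(n_spec)
        truth_specific[cond] = keys
        for key in keys:
            place(cond, key, int(rng.integers(2, 60)))
        # leading slices recur in tumor sites (disjoint per site)
        cursor = 0
        site_map: dict[str, list[str]] = {}
        for site in ("primary_tumor", "metastasis"):
            k = shared_n.get((cond, site), 0)
            if cursor + k > n_spec:
                raise ConfigurationError(
                    f"{cond}: tumor-shared clones exceed planted specific")
            slice_keys = keys[cursor: cursor + k]
            cursor += k
            site_map[site] = slice_keys
            for j, key in enumerate(slice_keys):
                copies = tumor_copy_cycle[j % len(tumor_copy_cycle)]
                place(site, key, copies)
                if copies >= 2:
                    truth_expanded.append(key)
        truth_shared[cond] = site_map
        # leading keys also detected directly ex vivo
        n_ev = ex_vivo_n.get(cond, 0)
        if n_ev > n_spec:
            raise ConfigurationError(f"{cond}: ex-vivo clones exceed specific")
        subset = cond.rsplit(":", 1)[1]
        for key in keys[:n_ev]:
            place(f"ex_vivo_{subset}", key, int(rng.integers(1, 4)))
        truth_ex_vivo[cond] = keys[:n_ev]

    # viral clones: seeded into the viral-pool cultures, a subset recurring
    # in antigen cultures (round robin)
    viral_keys = factory.draw_many(config.planted_viral)
    for i, key in enumerate(viral_keys):
        comp = "viral_culture_CD8" if i % 2 == 0 else "viral_culture_CD4"
        place(comp, key, int(rng.integers(1, 30)))
    recurrent = viral_keys[:config.planted_viral_recurrent]
    for i, key in enumerate(recurrent):
        if not cultures:
            break
        place(cultures[i % len(cultures)], key, int(rng.integers(1, 10)))

    # background culture filler: each clone occupies >= 2 cultures
    remaining = {c: sizes[c] - len(membership[c]) for c in cultures}
    if any(v < 0 for v in remaining.values()):
        bad = [c for c, v in remaining.items() if v < 0]
        raise ConfigurationError(f"planted clones exceed repertoire size in {bad}")
    if sum(remaining.values()) % 2 == 1:
        top3 = sorted(remaining, key=lambda c: -remaining[c])[:3]
        if len([c for c in top3 if remaining[c] > 0]) < 3:
            raise ConfigurationError("cannot pair background clones; "
                                     "adjust culture sizes")
        key = factory.draw()
        for c in top3:
            place(c, key, int(rng.integers(1, 20)))
            remaining[c] -= 1
    while sum(remaining.values()) > 0:
        order = sorted(remaining, key=lambda c: -remaining[c])
        a, b = order[0], order[1]
        if remaining[b] == 0:
            raise ConfigurationError("cannot pair background clones; "
                                     "adjust culture sizes")
        key = factory.draw()
        place(a, key, int(rng.integers(1, 20)))
        place(b, key, int(rng.integers(1, 20)))
        remaining[a] -= 1
        remaining[b] -= 1

    # tumor filler: both-site clones then site-exclusive clones
    for key in factory.draw_many(config.tumor_both_site):
        place("primary_tumor", key, int(rng.integers(1, 6)))
        place("metastasis", key, int(rng.integers(1, 6)))
    for site in ("primary_tumor", "metastasis"):
        deficit = sizes[site] - len(membership[site])
        if deficit < 0:
            raise ConfigurationError(f"planted clones exceed {site} size")
        for key in factory.draw_many(deficit):
            place(site, key, int(rng.integers(1, 6)))

    # ex vivo filler: ambiguous clones seen nowhere else
    for comp in ("ex_vivo_CD8", "ex_vivo_CD4"):
        deficit = sizes[comp] - len(membership[comp])
        if deficit < 0:
            raise ConfigurationError(f"planted clones exceed {comp} size")
        for key in factory.draw_many(deficit):
            place(comp, key, int(rng.integers(1, 3)))

    samples = {}
    for comp in sorted(membership):
        items = membership[comp]
        samples[comp] = pd.DataFrame({
            "junction_aa": list(items),
            "v_call": [f"TRBV{(zlib.crc32(k.encode()) % 30) + 1}" for k in items],
            "j_call": [f"TRBJ{(zlib.crc32(k.encode()) % 13) + 1}" for k in items],
            "duplicate_count": list(items.values()),
        })
    reps = RepertoireSet(samples=samples)

    all_keys = set()
    for comp in membership:
        all_keys |= set(membership[comp])
    truth = {
        "cultures": cultures,
        "specific": truth_specific,
        "tumor_shared": truth_shared,
        "ex_vivo_detected": truth_ex_vivo,
        "expanded": sorted(truth_expanded),
        "viral": viral_keys,
        "viral_recurrent": recurrent,
        "n_unique_total": len(all_keys),
        "compartment_sizes": {c: len(membership[c]) for c in sorted(membership)},
    }
    return reps, truth


# ---------------------------------------------------------------------------
# binding predictions (stand-in for an external prediction tool; synthetic)

def generate_binding_predictions(config: SimulationConfig, contexts,
                                 alleles: tuple[str, ...] = (
                                     "HLA-A*02:01", "HLA-B*27:05"),
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic MUT and WT IC50 tables over mutation-spanning windows.

    This is a seeded stand-in for NetMHCpan/NetMHCIIpan output, not a
    binding model: IC50s are log-uniform draws with a planted strong binder
    per context so the downstream filter has something to find.
    """
    from .epitope_filter import spanning_kmer_windows, CLASS_I_LENGTHS, \
        CLASS_II_LENGTH

    rng = config.rng(5)
    mut_rows, wt_rows = [], []
    for ctx in contexts:
        wt_seq = ctx.protein
        for mhc_class, ks in (("I", list(CLASS_I_LENGTHS)),
                              ("II", [CLASS_II_LENGTH])):
            for k in ks:
                windows = spanning_kmer_windows(ctx, k)
                strong = int(rng.integers(0, len(windows))) if windows else -1
                for allele in alleles if mhc_class == "I" else ("HLA-DRB1*04:01",):
                    for w_i, (start, kmer) in enumerate(windows):
                        ic50 = float(np.round(10 ** rng.uniform(1.0, 4.7), 1))
                        if w_i == strong:
                            ic50 = float(np.round(rng.uniform(5, 400), 1))
                        mut_rows.append({"gene": ctx.gene, "peptide": kmer,
                                         "allele": allele,
                                         "mhc_class": mhc_class,
                                         "ic50_nm": ic50,
                                         "window_start": start})
                        wt_kmer = wt_seq[start - 1: start - 1 + k]
                        if len(wt_kmer) == k and not ctx.is_frameshift:
                            wt_rows.append({"gene": ctx.gene, "peptide": wt_kmer,
                                            "allele": allele,
                                            "mhc_class": mhc_class,
                                            "ic50_nm": float(np.round(
                                                10 ** rng.uniform(2.5, 4.7), 1)),
                                            "window_start": start})
    cols = ["gene", "peptide", "allele", "mhc_class", "ic50_nm", "window_start"]
    return (pd.DataFrame(mut_rows, columns=cols),
            pd.DataFrame(wt_rows, columns=cols))


# ---------------------------------------------------------------------------
# manifest

def write_manifest(truth: dict, path) -> None:
    """Planted-truth sidecar, JSON with sorted keys (stable bytes)."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if d.get("planted_tumor_shared"):
        d["planted_tumor_shared"] = {f"{k[0]}|{k[1]}": v
                                     for k, v in d["planted_tumor_shared"].items()}
    return d
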