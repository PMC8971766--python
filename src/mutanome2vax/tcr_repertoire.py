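"""TCR CDR3β clonotype bookkeeping across tumor, blood and peptide cultures.

Clonotype identity defaults to the CDR3β amino-acid junction alone (bulk
tumor TCR-seq cannot resolve chain pairing). The analysis follows the
case-study logic: flag and exclude virus-reactive clonotypes, measure
CD8/CD4 subset overlap, define condition-exclusive (operationally
"neoantigen-specific") clonotypes, quantify sharing with the two tumor
sites, and annotate tumor expansion and direct ex vivo detection.

Compartment naming convention
-----------------------------
``primary_tumor``, ``metastasis``, ``ex_vivo_CD8``, ``ex_vivo_CD4``,
``viral_culture_CD8``, ``viral_culture_CD4`` and peptide-expanded cultures
``culture:{antigen}:{MUT|WT}:{CD8|CD4}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

AIRR_COLUMNS = ["junction_aa", "v_call", "j_call", "duplicate_count"]

CULTURE_PREFIX = "culture:"
VIRAL_COMPARTMENTS = ("viral_culture_CD8", "viral_culture_CD4")
EX_VIVO_COMPARTMENTS = ("ex_vivo_CD8", "ex_vivo_CD4")
TUMOR_COMPARTMENTS = ("primary_tumor", "metastasis")


def is_culture(compartment: str) -> bool:
    return compartment.startswith(CULTURE_PREFIX)


def culture_name(antigen: str, allele: str, subset: str) -> str:
    """Compartment label for a peptide-expanded culture, e.g.
    ``culture:MAFF:MUT:CD8``."""
    if allele not in ("MUT", "WT") or subset not in ("CD8", "CD4"):
        raise ValueError(f"bad culture spec ({antigen}, {allele}, {subset})")
    return f"{CULTURE_PREFIX}{antigen}:{allele}:{subset}"


def parse_culture(compartment: str) -> tuple[str, str, str]:
    _, antigen, allele, subset = compartment.split(":")
    return antigen, allele, subset


@dataclass
class RepertoireSet:
    """All repertoire samples of one study, keyed by compartment label.

    Each sample is an AIRR-style frame (junction_aa, v_call, j_call,
    duplicate_count) with unique junctions per compartment.
    """

    samples: dict[str, pd.DataFrame] = field(default_factory=dict)
    identity: str = "junction_aa"  # or "junction_aa+v_call"

    def keys_of(self, compartment: str) -> set[str]:
        df = self.samples[compartment]
        if self.identity == "junction_aa":
            return set(df["junction_aa"])
        return set(df["junction_aa"] + "|" + df["v_call"].fillna(""))

    def counts_of(self, compartment: str) -> dict[str, int]:
        df = self.samples[compartment]
        if self.identity != "junction_aa":
            keyed = df.assign(
                key=df["junction_aa"] + "|" + df["v_call"].fillna(""))
            return dict(zip(keyed["key"], keyed["duplicate_count"]))
        return dict(zip(df["junction_aa"], df["duplicate_count"]))

    @property
    def culture_compartments(self) -> list[str]:
        return sorted(k for k in self.samples if is_culture(k))

    def remove_keys(self, keys: set[str]) -> "RepertoireSet":
        """New RepertoireSet with the given clonotype keys dropped from the
        peptide-expanded cultures (tumor and ex vivo samples are kept whole
        so occupancy questions stay answerable)."""
        out = {}
        for comp, df in self.samples.items():
            if is_culture(comp):
                mask = ~df["junction_aa"].isin(keys)
                out[comp] = df[mask].reset_index(drop=True)
            else:
                out[comp] = df
        return RepertoireSet(samples=out, identity=self.identity)


def unique_clonotypes(reps: RepertoireSet) -> tuple[pd.DataFrame, int]:
    """Per-compartment unique clonotype counts and the global union size."""
    if not reps.samples:
        raise ValueError("no repertoire samples")
    rows, union = [], set()
    for comp in sorted(reps.samples):
        keys = reps.keys_of(comp)
        union |= keys
        rows.append({"compartment": comp, "n_unique": len(keys)})
    return pd.DataFrame(rows), len(union)


def flag_and_exclude_viral(reps: RepertoireSet
                           ) -> tuple[RepertoireSet, dict]:
    """Remove virus-reactive clonotypes (any key seen in a viral-pool
    culture) from all peptide-expanded cultures.

    Returns the cleaned repertoire set and a report: the number of unique
    viral keys, how many recur in antigen cultures, and a cross-tabulation
    of viral-key recurrence per non-viral compartment.
    """
    viral_keys: set[str] = set()
    for comp in VIRAL_COMPARTMENTS:
        if comp in reps.samples:
            viral_keys |= reps.keys_of(comp)
    recurrence = {}
    in_cultures: set[str] = set()
    for comp in sorted(reps.samples):
        if comp in VIRAL_COMPARTMENTS:
            continue
        hits = viral_keys & reps.keys_of(comp)
        recurrence[comp] = len(hits)
        if is_culture(comp):
            in_cultures |= hits
    report = {"n_viral": len(viral_keys),
              "n_viral_in_antigen_cultures": len(in_cultures),
              "recurrence": recurrence}
    return reps.remove_keys(viral_keys), report


def subset_overlap(set_a: set[str], set_b: set[str]) -> tuple[int, float]:
    """Intersection size and intersection-over-union percent (one decimal)."""
    union = set_a | set_b
    if not union:
        logger.warning("overlap of two empty sets; reporting 0")
        return 0, 0.0
    inter = set_a & set_b
    return len(inter), round(100.0 * len(inter) / len(union), 1)


def condition_exclusive(reps: RepertoireSet, condition: str) -> set[str]:
    """Clonotypes recovered exclusively from one peptide-expanded culture.

    A key qualifies when it occurs in the named culture and in no other
    culture condition (any other antigen, the matched WT/MUT partner, either
    subset). Presence in tumor tissue or directly ex vivo does not
    disqualify — that is exactly the sharing being studied. Viral exclusion
    must be applied first.
    """
    if condition not in reps.samples or not is_culture(condition):
        raise ValueError(f"unknown culture condition {condition!r}")
    mine = reps.keys_of(condition)
    for comp in reps.culture_compartments:
        if comp != condition:
            mine -= reps.keys_of(comp)
    return mine


def all_condition_exclusive(reps: RepertoireSet) -> dict[str, set[str]]:
    """condition -> exclusive clonotype set, for every culture compartment."""
    return {c: condition_exclusive(reps, c) for c in reps.culture_compartments}


def tumor_site_sets(reps: RepertoireSet) -> dict[str, set[str]]:
    """Partition tumor clonotypes into primary-exclusive, metastasis-
    exclusive and both-site sets."""
    primary = reps.keys_of("primary_tumor") if "primary_tumor" in reps.samples else set()
    met = reps.keys_of("metastasis") if "metastasis" in reps.samples else set()
    return {"primary_exclusive": primary - met,
            "metastasis_exclusive": met - primary,
            "both_sites": primary & met}


def tumor_sharing(specific_sets: dict[str, set[str]],
                  site_sets: dict[str, set[str]],
                  denominator: str = "site_exclusive") -> pd.DataFrame:
    """Sharing of condition-exclusive clonotypes with each tumor site.

    Per site, the overall percentage is the fraction of the site's tumor
    clonotype set that recurs in any condition-exclusive culture set,
    rounded to a whole percent. With the default ``site_exclusive``
    convention the denominator excludes clonotypes seen at both sites;
    ``site_total`` includes them.
    """
    if denominator not in ("site_exclusive", "site_total"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    all_specific: set[str] = set().union(*specific_sets.values()) if specific_sets else set()
    rows = []
    for site, excl_key in (("primary_tumor", "primary_exclusive"),
                           ("metastasis", "metastasis_exclusive")):
        denom_set = set(site_sets[excl_key])
        if denominator == "site_total":
            denom_set |= site_sets["both_sites"]
        if not denom_set:
            logger.warning("empty tumor set for %s; sharing undefined", site)
            rows.append({"site": site, "n_shared": 0, "n_tumor": 0,
                         "sharing_pct": 0, "denominator": denominator})
            continue
        shared = all_specific & denom_set
        pct = int(100.0 * len(shared) / len(denom_set) + 0.5)
        by_subset = {"CD8": 0, "CD4": 0}
        for cond, keys in specific_sets.items():
            subset = parse_culture(cond)[2]
            by_subset[subset] += len(keys & denom_set)
        rows.append({"site": site, "n_shared": len(shared),
                     "n_cd8": by_subset["CD8"], "n_cd4": by_subset["CD4"],
                     "n_tumor": len(denom_set), "sharing_pct": pct,
                     "denominator": denominator})
    return pd.DataFrame(rows)


def annotate_clonotypes(reps: RepertoireSet,
                        specific_sets: dict[str, set[str]],
                        viral_keys: set[str] | None = None,
                        expansion_min_count: int = 2) -> pd.DataFrame:
    """Per-clonotype annotation table over all condition-exclusive keys.

    ``expanded`` means the clone reaches ``expansion_min_count`` copies in a
    tumor sample; ``detected_ex_vivo`` means the junction is also seen in
    unstimulated blood. ``shared_sites`` lists the tumor sites carrying it.
    """
    tumor_counts = {site: (reps.counts_of(site) if site in reps.samples else {})
                    for site in TUMOR_COMPARTMENTS}
    ex_vivo_keys: set[str] = set()
    for comp in EX_VIVO_COMPARTMENTS:
        if comp in reps.samples:
            ex_vivo_keys |= reps.keys_of(comp)
    viral_keys = viral_keys or set()
    rows = []
    for cond in sorted(specific_sets):
        for key in sorted(specific_sets[cond]):
            sites = [s for s in TUMOR_COMPARTMENTS if key in tumor_counts[s]]
            expanded = any(tumor_counts[s][key] >= expansion_min_count
                           for s in sites)
            rows.append({"key": key, "specific_to": cond,
                         "viral_reactive": key in viral_keys,
                         "shared_sites": ",".join(sites),
                         "expanded": expanded,
                         "detected_ex_vivo": key in ex_vivo_keys})
    return pd.DataFrame(rows)


def read_repertoires(manifest_path) -> RepertoireSet:
    """Load a repertoire set from a two-column manifest TSV
    (compartment, path) pointing at AIRR-style clonotype TSVs; relative
    paths resolve against the manifest's directory."""
    from pathlib import Path
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    samples = {}
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        df = pd.read_csv(path, sep="\t")
        missing = set(AIRR_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{row['path']}: missing AIRR columns {sorted(missing)}")
        samples[row["compartment"]] = df
    return RepertoireSet(samples=samples)
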