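import pandas as pd
import pytest

from mutanome2vax import tcr_repertoire as tcr
from mutanome2vax.tcr_repertoire import RepertoireSet, culture_name


def sample(keys, counts=None):
    counts = counts or [1] * len(keys)
    return pd.DataFrame({"junction_aa": list(keys),
                         "v_call": ["TRBV1"] * len(keys),
                         "j_call": ["TRBJ1"] * len(keys),
                         "duplicate_count": counts})


def reps_from(mapping, counts=None):
    counts = counts or {}
    return RepertoireSet(samples={
        comp: sample(keys, counts.get(comp)) for comp, keys in mapping.items()})


CONDITION_A = culture_name("A", "MUT", "CD8")
CONDITION_AW = culture_name("A", "WT", "CD8")
CONDITION_B = culture_name("B", "MUT", "CD8")
CONDITION_B4 = culture_name("B", "MUT", "CD4")


class TestUniqueClonotypes:
    def test_union_across_samples(self):
        reps = reps_from({CONDITION_A: ["Ca", "Cb"], CONDITION_B: ["Cb", "Cc"]})
        table, total = tcr.unique_clonotypes(reps)
        assert total == 3
        assert dict(zip(table["compartment"], table["n_unique"])) == {
            CONDITION_A: 2, CONDITION_B: 2}

    def test_empty_sample_counts_zero(self):
        reps = reps_from({CONDITION_A: []})
        table, total = tcr.unique_clonotypes(reps)
        assert total == 0 and table["n_unique"].iloc[0] == 0


class TestViralExclusion:
    def test_viral_keys_removed_from_cultures(self):
        reps = reps_from({"viral_culture_CD8": ["Cx"],
                          CONDITION_A: ["Cx", "Cy"]})
        cleaned, report = tcr.flag_and_exclude_viral(reps)
        assert cleaned.keys_of(CONDITION_A) == {"Cy"}
        assert report["n_viral"] == 1
        assert report["n_viral_in_antigen_cultures"] == 1

    def test_empty_viral_set_is_identity(self):
        reps = reps_from({"viral_culture_CD8": [], CONDITION_A: ["Ca", "Cb"]})
        cleaned, report = tcr.flag_and_exclude_viral(reps)
        assert cleaned.keys_of(CONDITION_A) == {"Ca", "Cb"}
        assert report["n_viral"] == 0

    def test_recurrence_crosstab(self):
        reps = reps_from({"viral_culture_CD8": ["Cx", "Cz"],
                          CONDITION_A: ["Cx"], CONDITION_B: ["Cx", "Cz"],
                          "primary_tumor": ["Cz"]})
        _, report = tcr.flag_and_exclude_viral(reps)
        assert report["recurrence"] == {CONDITION_A: 1, CONDITION_B: 2,
                                        "primary_tumor": 1}
        assert report["n_viral_in_antigen_cultures"] == 2


class TestSubsetOverlap:
    def test_intersection_over_union(self):
        a, b = {"x", "y", "z"}, {"z", "w"}
        assert tcr.subset_overlap(a, b) == (1, 25.0)

    def test_identical_and_disjoint(self):
        s = {"a", "b"}
        assert tcr.subset_overlap(s, set(s)) == (2, 100.0)
        assert tcr.subset_overlap(s, {"c"}) == (0, 0.0)

    def test_both_empty_reports_zero(self):
        assert tcr.subset_overlap(set(), set()) == (0, 0.0)


class TestConditionExclusive:
    def test_key_in_single_culture_is_specific(self):
        reps = reps_from({CONDITION_A: ["Conly", "Cshared"],
                          CONDITION_B: ["Cshared", "Cother"],
                          "primary_tumor": ["Conly"],
                          "ex_vivo_CD8": ["Conly"]})
        # tumor and ex vivo occurrence must NOT disqualify
        assert tcr.condition_exclusive(reps, CONDITION_A) == {"Conly"}

    def test_mut_wt_partner_sharing_disqualifies(self):
        reps = reps_from({CONDITION_A: ["Ck"], CONDITION_AW: ["Ck"]})
        assert tcr.condition_exclusive(reps, CONDITION_A) == set()
        assert tcr.condition_exclusive(reps, CONDITION_AW) == set()

    def test_unknown_condition_raises(self):
        reps = reps_from({CONDITION_A: ["Ca"]})
        with pytest.raises(ValueError):
            tcr.condition_exclusive(reps, "culture:NOPE:MUT:CD8")

    def test_specific_sets_pairwise_disjoint(self):
        reps = reps_from({CONDITION_A: ["Ca", "Cs"], CONDITION_B: ["Cb", "Cs"],
                          CONDITION_B4: ["Cd"]})
        sets = tcr.all_condition_exclusive(reps)
        conds = list(sets)
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                assert not (sets[conds[i]] & sets[conds[j]])

    def test_specific_plus_ambiguous_reconstructs_union(self):
        reps = reps_from({CONDITION_A: ["Ca", "Cs"], CONDITION_B: ["Cb", "Cs"]})
        sets = tcr.all_condition_exclusive(reps)
        union = set().union(*(reps.keys_of(c)
                              for c in reps.culture_compartments))
        specific = set().union(*sets.values())
        ambiguous = union - specific
        assert specific | ambiguous == union
        assert ambiguous == {"Cs"}


class TestTumorSharing:
    def build_sets(self, n_cd8, n_cd4, n_tumor, site):
        cd8 = {f"C8_{i}" for i in range(n_cd8)}
        cd4 = {f"C4_{i}" for i in range(n_cd4)}
        filler = {f"T_{i}" for i in range(n_tumor - n_cd8 - n_cd4)}
        specific = {culture_name("A", "MUT", "CD8"): cd8,
                    culture_name("A", "MUT", "CD4"): cd4}
        site_sets = {"primary_exclusive": set(), "metastasis_exclusive": set(),
                     "both_sites": set()}
        site_sets[site] = cd8 | cd4 | filler
        return specific, site_sets

    def test_primary_sharing_convention(self):
        specific, site_sets = self.build_sets(21, 15, 291, "primary_exclusive")
        out = tcr.tumor_sharing(specific, site_sets).set_index("site")
        row = out.loc["primary_tumor"]
        assert (row["n_cd8"], row["n_cd4"]) == (21, 15)
        assert row["sharing_pct"] == 12  # 36/291 = 12.4 -> 12

    def test_metastasis_sharing_convention(self):
        specific, site_sets = self.build_sets(95, 40, 958, "metastasis_exclusive")
        out = tcr.tumor_sharing(specific, site_sets).set_index("site")
        assert out.loc["metastasis", "sharing_pct"] == 14  # 135/958

    def test_zero_sharing(self):
        specific = {CONDITION_A: {"Cx"}}
        site_sets = {"primary_exclusive": {"Cy"}, "metastasis_exclusive": set(),
                     "both_sites": set()}
        out = tcr.tumor_sharing(specific, site_sets).set_index("site")
        assert out.loc["primary_tumor", "sharing_pct"] == 0

    def test_monotone_under_added_shared_clones(self):
        specific, site_sets = self.build_sets(5, 5, 100, "primary_exclusive")
        base = tcr.tumor_sharing(specific, site_sets).set_index("site")
        specific[culture_name("A", "MUT", "CD8")] |= {"T_0", "T_1"}
        more = tcr.tumor_sharing(specific, site_sets).set_index("site")
        assert more.loc["primary_tumor", "n_shared"] >= \
            base.loc["primary_tumor", "n_shared"]

    def test_site_total_denominator_option(self):
        specific, site_sets = self.build_sets(10, 0, 50, "primary_exclusive")
        site_sets["both_sites"] = {f"B_{i}" for i in range(50)}
        excl = tcr.tumor_sharing(specific, site_sets).set_index("site")
        total = tcr.tumor_sharing(specific, site_sets,
                                  denominator="site_total").set_index("site")
        assert excl.loc["primary_tumor", "sharing_pct"] == 20   # 10/50
        assert total.loc["primary_tumor", "sharing_pct"] == 10  # 10/100


class TestAnnotation:
    def test_expansion_and_ex_vivo_flags(self):
        reps = reps_from(
            {CONDITION_A: ["Cexp", "Clow", "Cev"],
             "primary_tumor": ["Cexp", "Clow"],
             "ex_vivo_CD8": ["Cev"]},
            counts={"primary_tumor": [7, 1]})
        specific = {CONDITION_A: {"Cexp", "Clow", "Cev"}}
        ann = tcr.annotate_clonotypes(reps, specific).set_index("key")
        assert bool(ann.loc["Cexp", "expanded"])          # tumor count 7
        assert not bool(ann.loc["Clow", "expanded"])      # tumor count 1
        assert bool(ann.loc["Cev", "detected_ex_vivo"])
        assert ann.loc["Cexp", "shared_sites"] == "primary_tumor"


class TestManifestIO:
    def test_roundtrip_via_manifest(self, tmp_path):
        reps = reps_from({CONDITION_A: ["Ca", "Cb"],
                          "primary_tumor": ["Ca"]})
        rows = []
        for comp, df in reps.samples.items():
            fname = comp.replace(":", "_") + ".tsv"
            df.to_csv(tmp_path / fname, sep="\t", index=False)
            rows.append({"compartment": comp, "path": fname})
        pd.DataFrame(rows).to_csv(tmp_path / "manifest.tsv", sep="\t",
                                  index=False)
        back = tcr.read_repertoires(tmp_path / "manifest.tsv")
        assert back.keys_of(CONDITION_A) == {"Ca", "Cb"}
        assert back.keys_of("primary_tumor") == {"Ca"}
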