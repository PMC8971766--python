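import io

import pandas as pd
import pytest

from mutanome2vax import synthetic_data as syn
from mutanome2vax import variant_select as vs
from mutanome2vax.synthetic_data import ConfigurationError, SimulationConfig


def small_config(**kw):
    defaults = dict(seed=3, n_genes=60, protein_length_range=(80, 200),
                    n_variants_site1=200, n_variants_site2=220,
                    n_nonsynonymous=30, n_nonsynonymous_site2=32,
                    n_expressed=8, n_expressed_genes=6)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_expressed=50, n_nonsynonymous=30),
        dict(n_expressed_genes=9, n_expressed=8),
        dict(elispot_control_sd=0.0),
        dict(protein_length_range=(10, 200)),
        dict(planted_viral=2, planted_viral_recurrent=5),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small_config(**kw)


class TestProteome:
    def test_seed_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=1, n_genes=2)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            proteome = syn.generate_proteome(cfg)
            for gene, seq in proteome.items():
                buf.write(f">{gene}\n{seq}\n")
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_cardinality_and_alphabet(self):
        proteome = syn.generate_proteome(SimulationConfig(seed=1, n_genes=18))
        assert len(proteome) == 18
        assert all(set(s) <= set("ACDEFGHIKLMNPQRSTVWY")
                   for s in proteome.values())

    def test_seeds_differ(self):
        p1 = syn.generate_proteome(SimulationConfig(seed=1, n_genes=3))
        p2 = syn.generate_proteome(SimulationConfig(seed=2, n_genes=3))
        assert list(p1.values()) != list(p2.values())


class TestPlantVariants:
    def test_planted_counts_recovered_by_filter_chain(self):
        cfg = small_config()
        proteome = syn.generate_proteome(cfg)
        site1, site2, expression, truth = syn.plant_variants(cfg, proteome)
        assert len(site1) == 200 and len(site2) == 220
        nonsyn = site1["effect"].isin(vs.NONSYNONYMOUS_EFFECTS)
        assert int(nonsyn.sum()) == 30
        cand = vs.filter_candidates(site1, expression, 0.0)
        assert (len(cand), cand.n_gene_products) == (8, 6)

    def test_zero_expressed_empty_candidates(self):
        cfg = small_config(n_expressed=0, n_expressed_genes=0)
        proteome = syn.generate_proteome(cfg)
        site1, _, expression, _ = syn.plant_variants(cfg, proteome)
        assert len(vs.filter_candidates(site1, expression)) == 0

    def test_frameshift_tail_roundtrips_from_record(self):
        cfg = small_config(frameshift_tail_length=57)
        proteome = syn.generate_proteome(cfg)
        site1, _, _, truth = syn.plant_variants(cfg, proteome)
        fs = site1[site1["effect"] == "frameshift"]
        assert len(fs) >= 1
        planted = [t for t in truth["expressed_variants"]
                   if t["effect"] == "frameshift"][0]
        row = fs[fs["hgvs_p"] == planted["hgvs_p"]].iloc[0]
        assert row["novel_tail"] == planted["novel_tail"]
        assert len(row["novel_tail"]) == 57

    def test_hgvs_strings_well_formed(self):
        cfg = small_config()
        proteome = syn.generate_proteome(cfg)
        site1, _, _, _ = syn.plant_variants(cfg, proteome)
        nonsyn = site1[site1["effect"].isin(vs.NONSYNONYMOUS_EFFECTS)]
        for hgvs_p in nonsyn["hgvs_p"]:
            vs.parse_hgvs_p(hgvs_p)  # raises on malformed strings

    def test_proteome_too_small_raises(self):
        cfg = small_config(n_genes=4, n_expressed=8, n_expressed_genes=6,
                           n_nonsynonymous=30)
        proteome = syn.generate_proteome(cfg)
        with pytest.raises(ConfigurationError):
            syn.plant_variants(cfg, proteome)


class TestElispotGenerator:
    def test_control_wells_and_columns(self):
        cfg = small_config()
        plate = syn.generate_elispot(cfg, [f"G{i}" for i in range(4)],
                                     responders=["G0"])
        assert set(plate.columns) == {"antigen", "condition", "replicate", "sfc"}
        controls = plate[plate["condition"] == "irrelevant_control"]
        assert len(controls) == cfg.elispot_replicates
        assert (plate["sfc"] >= 0).all()

    def test_responder_shift_present(self):
        cfg = small_config()
        plate = syn.generate_elispot(cfg, ["G0", "G1"], responders=["G0"])
        mut = plate[plate["condition"] == "MUT"].groupby("antigen")["sfc"].mean()
        assert mut["G0"] > mut["G1"] + 5 * cfg.elispot_control_sd

    def test_determinism(self):
        cfg = small_config()
        p1 = syn.generate_elispot(cfg, ["G0", "G1"], responders=["G0"])
        p2 = syn.generate_elispot(cfg, ["G0", "G1"], responders=["G0"])
        pd.testing.assert_frame_equal(p1, p2)


class TestRepertoireGenerator:
    def test_sizes_match_configuration_exactly(self, default_repertoires):
        reps, truth = default_repertoires
        for comp, df in reps.samples.items():
            assert len(df) == truth["compartment_sizes"][comp]
            assert df["junction_aa"].is_unique

    def test_cdr3_shape(self, default_repertoires):
        reps, _ = default_repertoires
        for df in reps.samples.values():
            for cdr3 in df["junction_aa"]:
                assert cdr3.startswith("C") and cdr3.endswith("F")
                assert 8 <= len(cdr3) <= 20

    def test_determinism_identical_tables(self):
        cfg = SimulationConfig(seed=5)
        antigens = ["G1", "G2", "G3", "G4", "G5"]
        r1, t1 = syn.generate_repertoires(cfg, antigens)
        r2, t2 = syn.generate_repertoires(cfg, antigens)
        assert t1 == t2
        for comp in r1.samples:
            pd.testing.assert_frame_equal(r1.samples[comp], r2.samples[comp])

    def test_zero_viral_is_noop(self):
        cfg = SimulationConfig(seed=5, planted_viral=0,
                               planted_viral_recurrent=0)
        reps, truth = syn.generate_repertoires(cfg, ["G1", "G2", "G3",
                                                     "G4", "G5"])
        assert truth["viral"] == []
        from mutanome2vax import tcr_repertoire as tcr
        before = {c: reps.keys_of(c) for c in reps.culture_compartments}
        cleaned, report = tcr.flag_and_exclude_viral(reps)
        assert report["n_viral"] == 0
        assert all(cleaned.keys_of(c) == before[c] for c in before)

    def test_overfull_planting_rejected(self):
        cfg = SimulationConfig(seed=5, culture_size=10,
                               specific_per_cd8_culture=30)
        with pytest.raises(ConfigurationError):
            syn.generate_repertoires(cfg, ["G1", "G2"])
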