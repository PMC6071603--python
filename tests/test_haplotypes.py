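"""HLA allele normalisation, ambiguity resolution and one-vs-rest recoding."""

import numpy as np
import pandas as pd
import pytest

from balseldiff import (
    PopulationPanel,
    disambiguate_calls,
    haplotype_fst_by_maf_bin,
    haplotype_fst_table,
    load_hla_calls,
    normalize_two_field,
    per_snp_fst,
    recode_one_vs_rest,
    resolve_ambiguous_call,
    wc_components_from_genotypes,
)


def panel_of(samples_pops):
    df = pd.DataFrame(
        [{"sample_id": s, "population": p, "group": p[0]} for s, p in samples_pops]
    )
    return PopulationPanel(table=df)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("A*01:01:01:02", "A*01:01"),
            ("B*15:02", "B*15:02"),
            ("DRB1*04:05:01", "DRB1*04:05"),
        ],
    )
    def test_two_field_truncation(self, raw, expected):
        assert normalize_two_field(raw) == expected

    @pytest.mark.parametrize("bad", ["A*01", "A01:01", "", "*01:01"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_two_field(bad)

    def test_idempotent(self):
        for name in ("A*01:01:03", "C*07:02", "DQB1*06:02:01:01"):
            once = normalize_two_field(name)
            assert normalize_two_field(once) == once


class TestAmbiguityResolution:
    def test_most_common_wins(self):
        assert resolve_ambiguous_call({"X*01:01", "Y*01:01"},
                                      {"X*01:01": 0.12, "Y*01:01": 0.03}) == "X*01:01"

    def test_singleton(self):
        assert resolve_ambiguous_call({"B*07:02"}, {}) == "B*07:02"

    def test_tie_breaks_lexicographically(self):
        assert resolve_ambiguous_call({"B*15:02", "B*15:01"},
                                      {"B*15:01": 0.1, "B*15:02": 0.1}) == "B*15:01"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_ambiguous_call(set(), {})

    def test_iterative_resolution_uses_pooled_frequencies(self):
        # 6 unambiguous A*02:01 vs 2 A*01:01; the ambiguous call must go to A*02:01
        rows = [
            {"sample_id": f"S{i}", "gene": "A", "copy": c,
             "candidates": ("A*02:01:05",)}
            for i in range(3) for c in (1, 2)
        ]
        rows += [
            {"sample_id": "S3", "gene": "A", "copy": 1, "candidates": ("A*01:01",)},
            {"sample_id": "S3", "gene": "A", "copy": 2, "candidates": ("A*01:01",)},
            {"sample_id": "S4", "gene": "A", "copy": 1,
             "candidates": ("A*01:01", "A*02:01")},
            {"sample_id": "S4", "gene": "A", "copy": 2, "candidates": ("A*02:01",)},
        ]
        out = disambiguate_calls(pd.DataFrame(rows))
        amb = out[(out.sample_id == "S4") & (out["copy"] == 1)]
        assert amb["allele"].iloc[0] == "A*02:01"


class TestRecoding:
    def _calls(self):
        rows = []
        data = {
            "S1": ("A*01:01", "A*01:01"),
            "S2": ("A*01:01", "A*02:01"),
            "S3": ("A*02:01", "A*03:01"),
            "S4": ("A*03:01", "A*03:01"),
        }
        for s, (a1, a2) in data.items():
            rows.append({"sample_id": s, "gene": "A", "copy": 1,
                         "candidates": (a1,)})
            rows.append({"sample_id": s, "gene": "A", "copy": 2,
                         "candidates": (a2,)})
        return disambiguate_calls(pd.DataFrame(rows))

    def test_one_locus_per_distinct_allele(self):
        panel = panel_of([("S1", "P1"), ("S2", "P1"), ("S3", "P2"), ("S4", "P2")])
        loci = recode_one_vs_rest(self._calls(), panel)
        assert sorted(l.allele for l in loci) == ["A*01:01", "A*02:01", "A*03:01"]

    def test_per_sample_allele_conservation(self):
        panel = panel_of([("S1", "P1"), ("S2", "P1"), ("S3", "P2"), ("S4", "P2")])
        loci = recode_one_vs_rest(self._calls(), panel)
        totals = np.sum([l.genotypes for l in loci], axis=0)
        assert np.all(totals == 2)

    def test_homozygote_coding(self):
        panel = panel_of([("S1", "P1"), ("S2", "P1"), ("S3", "P2"), ("S4", "P2")])
        loci = {l.allele: l for l in recode_one_vs_rest(self._calls(), panel)}
        s1 = loci["A*01:01"].sample_ids.index("S1")
        assert loci["A*01:01"].genotypes[s1] == 2
        assert loci["A*02:01"].genotypes[s1] == 0

    def test_untyped_samples_dropped(self):
        panel = panel_of([("S1", "P1"), ("S2", "P1"), ("S3", "P2"),
                          ("S4", "P2"), ("S5", "P2")])
        loci = recode_one_vs_rest(self._calls(), panel)
        assert all("S5" not in l.sample_ids for l in loci)

    def test_fixed_private_allele_has_fst_one(self):
        # allele X fixed in pop 1, absent in pop 2
        rows = []
        for i, (pop, allele) in enumerate(
            [("P1", "A*01:01")] * 3 + [("P2", "A*02:01")] * 2
            + [("P2", "A*03:01")]
        ):
            for c in (1, 2):
                rows.append({"sample_id": f"S{i}", "gene": "A", "copy": c,
                             "candidates": (allele,)})
        calls = disambiguate_calls(pd.DataFrame(rows))
        panel = panel_of([(f"S{i}", "P1" if i < 3 else "P2") for i in range(6)])
        table = haplotype_fst_table(recode_one_vs_rest(calls, panel), panel)
        assert table.set_index("allele").loc["A*01:01", "fst"] == pytest.approx(1.0)

    def test_pseudo_locus_equals_snp_with_same_genotypes(self):
        """A pseudo-biallelic locus and a SNP with identical genotype counts
        give identical WC components."""
        rng = np.random.default_rng(3)
        gt = rng.binomial(2, 0.4, size=40)
        codes = np.repeat([0, 1], 20)
        vc_snp = wc_components_from_genotypes(gt[None, :], codes, 2)
        alleles = {0: ("X*02:01", "X*02:01"), 1: ("X*01:01", "X*02:01"),
                   2: ("X*01:01", "X*01:01")}
        rows = []
        for i, g in enumerate(gt):
            a1, a2 = alleles[int(g)]
            rows.append({"sample_id": f"S{i:02d}", "gene": "X", "copy": 1,
                         "candidates": (a1,)})
            rows.append({"sample_id": f"S{i:02d}", "gene": "X", "copy": 2,
                         "candidates": (a2,)})
        panel = panel_of([(f"S{i:02d}", "P1" if i < 20 else "P2")
                          for i in range(40)])
        calls = disambiguate_calls(pd.DataFrame(rows))
        loci = {l.allele: l for l in recode_one_vs_rest(calls, panel)}
        table = haplotype_fst_table([loci["X*01:01"]], panel)
        assert table["fst"].iloc[0] == pytest.approx(
            float(per_snp_fst(vc_snp)[0]), abs=1e-12
        )


class TestPipelineOnSyntheticCalls:
    def test_loads_and_recodes_generator_output(self, small_dataset, tmp_path):
        from balseldiff import emit_fixture, load_panel

        paths = emit_fixture(small_dataset, tmp_path)
        panel = load_panel(paths["panel"])
        calls = disambiguate_calls(load_hla_calls(paths["hla_calls"]))
        loci = recode_one_vs_rest(calls, panel)
        assert loci
        # conservation within each gene
        for gene in {l.gene for l in loci}:
            gl = [l for l in loci if l.gene == gene]
            totals = np.sum([l.genotypes for l in gl], axis=0)
            assert np.all(totals == 2)
        table = haplotype_fst_table(loci, panel)
        assert np.isfinite(table["global_maf"]).all()

    def test_haplotype_differentiation_below_control(self, default_dataset,
                                                     default_fst_table):
        """Per MAF bin, haplotype-level loci are less differentiated than the
        control SNPs (the focal class carries the weaker concentration)."""
        ds = default_dataset
        panel = PopulationPanel(table=ds.panel.loc[ds.panel.admixed == "no",
                                                   ["sample_id", "population",
                                                    "group"]])
        rows = []
        for d in ds.hla_calls.to_dict("records"):
            for gene in ("A", "B", "C"):
                for c in (1, 2):
                    rows.append({"sample_id": d["sample_id"], "gene": gene,
                                 "copy": c,
                                 "candidates": tuple(d[f"{gene}.{c}"].split("/"))})
        calls = disambiguate_calls(pd.DataFrame(rows))
        hap = haplotype_fst_table(recode_one_vs_rest(calls, panel), panel)
        snps = default_fst_table
        comp = haplotype_fst_by_maf_bin(
            hap,
            snps[snps.region_class == "HLA"],
            snps[snps.region_class == "control"],
        )
        tested = comp.dropna(subset=["p_vs_control"])
        ok = tested["hap_median"] < tested["control_median"]
        assert ok.mean() >= 0.75
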