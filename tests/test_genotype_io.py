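"""Panel loading, region classification and VCF site filters."""

import numpy as np
import pandas as pd
import pytest

from balseldiff import (
    RegionMap,
    apply_site_filters,
    classify_snp_region,
    emit_fixture,
    load_annotations,
    load_panel,
    load_region_map,
)
from balseldiff.genotype_io import PopulationPanel

from conftest import SMALL_CONFIG
from dataclasses import replace

from balseldiff import generate_dataset


def write_panel(path, rows):
    pd.DataFrame(rows, columns=["sample_id", "population", "group",
                                "admixed"]).to_csv(path, sep="\t", index=False)
    return path


class TestPanel:
    def test_admixed_populations_dropped(self, tmp_path):
        rows = []
        for i in range(26):
            adm = "yes" if i < 6 else "no"
            for j in range(3):
                rows.append((f"S{i}_{j}", f"POP{i}", f"G{i % 4}", adm))
        panel = load_panel(write_panel(tmp_path / "p.tsv", rows))
        assert len(panel.populations) == 20
        assert panel.n_excluded_populations == 6
        assert panel.counts().sum() == 60

    def test_no_admixed_is_identity(self, tmp_path):
        rows = [(f"S{i}", f"POP{i % 3}", "G", "no") for i in range(9)]
        panel = load_panel(write_panel(tmp_path / "p.tsv", rows))
        assert len(panel.sample_ids) == 9

    def test_duplicate_sample_rejected(self, tmp_path):
        rows = [("S1", "A", "G", "no"), ("S1", "B", "G", "no"),
                ("S2", "B", "G", "no")]
        with pytest.raises(ValueError, match="duplicate"):
            load_panel(write_panel(tmp_path / "p.tsv", rows))

    def test_single_population_rejected(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "population": ["P", "P"],
                           "group": ["G", "G"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            PopulationPanel(table=df)


class TestRegionMap:
    def setup_method(self):
        self.rm = RegionMap(
            hla_intervals=[("chr6", 100, 200, "HLA_A")],
            peri_intervals=[("chr6", 300, 400, "PERI1")],
            excluded_sites={("chr6", 150)},
        )

    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("chr6", 100, "HLA"),      # closed interval: boundary included
            ("chr6", 200, "HLA"),
            ("chr6", 350, "periHLA"),
            ("chr6", 250, "control"),
            ("chr1", 150, "control"),  # other chromosome -> control default
        ],
    )
    def test_classification(self, chrom, pos, expected):
        assert classify_snp_region(chrom, pos, self.rm) == expected

    def test_overlapping_hla_peri_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            RegionMap(hla_intervals=[("chr6", 100, 200, "A")],
                      peri_intervals=[("chr6", 150, 300, "B")])

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            RegionMap(hla_intervals=[("chr6", 200, 100, "A")])


def write_toy_vcf(path, samples, records):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1>\n##contig=<ID=chr6>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


class TestSiteFilters:
    def _setup(self, tmp_path):
        samples = [f"S{i}" for i in range(8)]
        panel = load_panel(write_panel(
            tmp_path / "panel.tsv",
            [(s, "P1" if i < 4 else "P2", "G", "no")
             for i, s in enumerate(samples)],
        ))
        het = ["0/1"] * 4 + ["0/0"] * 4
        hom = ["0/0"] * 8
        records = [
            ("chr1", 100, "A", "G", het),        # pass
            ("chr1", 200, "A", "G,T", het),      # multiallelic
            ("chr1", 300, "A", "G", hom),        # monomorphic everywhere
            ("chr1", 400, "C", "T", het),        # on exclusion list
            ("chr1", 500, "AT", "A", het),       # indel -> not a SNV
            ("chr1", 600, "G", "C", het),        # pass
            ("chr6", 150, "T", "C", het),        # pass (HLA)
            ("chr6", 350, "T", "A", het),        # pass (periHLA)
            ("chr6", 700, "G", "A", het),        # intronic -> dropped
            ("chr6", 800, "G", "T", het),        # pass
        ]
        vcf = write_toy_vcf(tmp_path / "toy.vcf", samples, records)
        ann = pd.DataFrame(
            [
                {"chrom": c, "pos": p,
                 "functional_class": "intronic" if p == 700 else "exonic",
                 "gene": "GENE"}
                for c, p, *_ in records
            ]
        )
        ann_path = tmp_path / "ann.tsv"
        ann.to_csv(ann_path, sep="\t", index=False)
        rm = RegionMap(hla_intervals=[("chr6", 100, 200, "HLA_A")],
                       peri_intervals=[("chr6", 300, 400, "PERI1")],
                       excluded_sites={("chr1", 400)})
        return vcf, panel, load_annotations(ann_path), rm

    def test_drop_counts_and_retained_sites(self, tmp_path):
        vcf, panel, ann, rm = self._setup(tmp_path)
        gm = apply_site_filters(vcf, panel, ann, rm, "exonic")
        assert len(gm.sites) == 5
        assert gm.provenance == {"multiallelic": 2, "excluded": 1,
                                 "functional_class": 1, "monomorphic": 1}
        # provenance sums to input - retained
        assert sum(gm.provenance.values()) == 10 - len(gm.sites)

    def test_region_classes_partition_sites(self, tmp_path):
        vcf, panel, ann, rm = self._setup(tmp_path)
        gm = apply_site_filters(vcf, panel, ann, rm, "exonic")
        counts = gm.sites["region_class"].value_counts()
        assert counts.get("HLA", 0) == 1
        assert counts.get("periHLA", 0) == 1
        assert counts.sum() == len(gm.sites)

    def test_zero_surviving_sites_is_an_error(self, tmp_path):
        vcf, panel, ann, rm = self._setup(tmp_path)
        with pytest.raises(ValueError, match="zero sites"):
            apply_site_filters(vcf, panel, ann, rm, "splicing")

    def test_panel_sample_missing_from_vcf(self, tmp_path):
        vcf, panel, ann, rm = self._setup(tmp_path)
        bad = PopulationPanel(table=pd.concat(
            [panel.table,
             pd.DataFrame([{"sample_id": "GHOST", "population": "P9",
                            "group": "G"}])],
            ignore_index=True))
        with pytest.raises(ValueError, match="absent from VCF"):
            apply_site_filters(vcf, bad, ann, rm, "exonic")


class TestFixtureRoundTrip:
    def test_clean_fixture_loads_without_drops(self, tmp_path):
        """A fixture built to pass every filter round-trips exactly."""
        cfg = replace(SMALL_CONFIG, intronic_frac=0.0, exclusion_frac=0.0,
                      rng_seed=21)
        ds = generate_dataset(cfg)
        paths = emit_fixture(ds, tmp_path / "fx")
        panel = load_panel(paths["panel"])
        rm = load_region_map(paths["regions"], paths["exclude"])
        ann = load_annotations(paths["annotations"])
        gm = apply_site_filters(paths["vcf"], panel, ann, rm, "exonic")
        assert all(v == 0 for v in gm.provenance.values())
        np.testing.assert_array_equal(gm.genotypes, ds.genotypes)
        assert list(gm.sites["region_class"]) == list(ds.sites["region_class"])

    def test_planted_filter_targets_are_dropped(self, small_dataset, tmp_path):
        ds = small_dataset
        paths = emit_fixture(ds, tmp_path / "fx")
        panel = load_panel(paths["panel"])
        rm = load_region_map(paths["regions"], paths["exclude"])
        ann = load_annotations(paths["annotations"])
        gm = apply_site_filters(paths["vcf"], panel, ann, rm, "exonic")
        n_excluded = int(ds.sites["excluded"].sum())
        n_intronic = int((ds.sites["functional_class"] == "intronic").sum())
        assert gm.provenance["excluded"] == n_excluded
        assert gm.provenance["functional_class"] == n_intronic
        assert len(gm.sites) == len(ds.sites) - n_excluded - n_intronic
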