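"""Variant model, MAF/VCF readers, tallies, TMB and gene-ranking screens."""

import numpy as np
import pandas as pd
import pytest

from neoprio.cohort_model import (
    Focus,
    FormatError,
    Patient,
    SomaticVariant,
    VariantClass,
    VariantType,
    collapse_substitution,
    compute_tmb,
    consistent_genes_across_patients,
    rank_genes,
    read_cohort_tsv,
    read_maf,
    snv_six_class_spectrum,
    summarize_cohort,
    tally_variant_classes,
    write_cohort_tsv,
)
from neoprio.synthetic_data import write_maf

from .conftest import make_snv

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\tTumor_Sample_Barcode\n"
)


class TestTypes:
    def test_hla_allele_pattern_enforced(self):
        Patient("P4", ("HLA-A*02:01", "HLA-B*15:01"))
        with pytest.raises(ValueError):
            Patient("P4", ("A*02:01",))

    def test_snv_alleles_must_be_single_differing_bases(self):
        with pytest.raises(ValueError):
            make_snv(ref="C", alt="C")
        with pytest.raises(ValueError):
            make_snv(ref="CT", alt="A")

    def test_frameshift_length_constraint(self):
        with pytest.raises(ValueError):
            SomaticVariant(
                "P1.1", "G", "G", 5, "CAT", "-",
                VariantClass.FRAMESHIFT_DEL, VariantType.DEL,
            )
        # a 3-base deletion is a valid in-frame deletion
        SomaticVariant(
            "P1.1", "G", "G", 5, "CAT", "-", VariantClass.IN_FRAME_DEL, VariantType.DEL
        )


class TestReadMaf:
    def test_missense_row_parsed(self, tmp_path):
        p = tmp_path / "one.maf"
        p.write_text(
            MAF_HEADER + "NANOGNB\tNANOGNB\t7\tC\tT\tMissense_Mutation\tSNV\tP4.1\n"
        )
        variants, foci = read_maf(p)
        (v,) = variants
        assert v.gene == "NANOGNB"
        assert v.variant_class is VariantClass.MISSENSE
        assert v.sample_id == "P4.1"
        assert foci == [Focus("P4.1", "P4")]

    def test_empty_variant_section(self, tmp_path):
        p = tmp_path / "empty.maf"
        p.write_text(MAF_HEADER)
        variants, foci = read_maf(p)
        assert variants == [] and foci == []

    def test_silent_rows_parsed_but_not_tallied(self, tmp_path):
        p = tmp_path / "two.maf"
        p.write_text(
            MAF_HEADER
            + "A\tA\t5\tC\tT\tSilent\tSNV\tS1\n"
            + "B\tB\t9\tG\tA\tMissense_Mutation\tSNV\tS1\n"
        )
        variants, _ = read_maf(p)
        assert len(variants) == 2
        counts, _ = tally_variant_classes(variants, exclude_silent=True)
        assert sum(counts.values()) == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.maf"
        p.write_text("Hugo_Symbol\tChromosome\nX\t1\n")
        with pytest.raises(FormatError, match="Start_Position"):
            read_maf(p)

    def test_unknown_classification_lists_vocabulary(self, tmp_path):
        p = tmp_path / "bad2.maf"
        p.write_text(MAF_HEADER + "A\tA\t5\tC\tT\tWeird_Class\tSNV\tS1\n")
        with pytest.raises(FormatError, match="Missense_Mutation"):
            read_maf(p)

    def test_write_read_round_trip(self, tmp_path):
        variants = [
            make_snv(sample="P1.1", gene="G1", pos=4),
            SomaticVariant(
                "P1.1", "G2", "G2", 8, "AT", "-",
                VariantClass.FRAMESHIFT_DEL, VariantType.DEL,
            ),
        ]
        p = tmp_path / "rt.maf"
        write_maf(p, variants)
        back, _ = read_maf(p)
        assert back == variants


class TestAnnotatedVcf:
    def test_snv_and_indel_normalized(self, tmp_path):
        p = tmp_path / "one.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP4.1\n"
            "G1\t7\t.\tC\tT\t.\tPASS\tGENE=G1;CLASS=Missense_Mutation\tGT\t0/1\n"
            "G2\t10\t.\tGA\tG\t.\tPASS\tGENE=G2;CLASS=Frame_Shift_Del\tGT\t0/1\n"
        )
        variants, _ = read_maf(p, dialect="ANNOTATED_VCF")
        snv, dele = variants
        assert (snv.pos, snv.ref_allele, snv.alt_allele) == (7, "C", "T")
        # anchor base stripped, position shifted to first deleted base
        assert (dele.pos, dele.ref_allele, dele.alt_allele) == (11, "A", "-")
        assert dele.variant_type is VariantType.DEL


class TestTallies:
    def test_paper_scale_missense_proportion(self):
        variants = [make_snv(gene=f"G{i}", pos=i + 1) for i in range(754)] + [
            make_snv(gene=f"H{i}", pos=i + 1, vclass=VariantClass.NONSENSE)
            for i in range(246)
        ]
        _, props = tally_variant_classes(variants)
        assert props[VariantClass.MISSENSE] == pytest.approx(0.754)

    def test_single_variant_and_empty(self):
        _, props = tally_variant_classes([make_snv()])
        assert props[VariantClass.MISSENSE] == 1.0
        counts, props = tally_variant_classes([])
        assert sum(counts.values()) == 0 and props is None

    def test_proportions_sum_to_one_and_counts_conserve(self):
        rng = np.random.default_rng(7)
        classes = [  # classes realizable as single-base substitutions
            VariantClass.MISSENSE,
            VariantClass.NONSENSE,
            VariantClass.NONSTOP,
            VariantClass.SPLICE_SITE,
            VariantClass.SILENT,
        ]
        variants = [
            make_snv(gene=f"G{i}", pos=i + 1, vclass=classes[j])
            for i, j in enumerate(rng.integers(0, len(classes), 200))
        ]
        counts, props = tally_variant_classes(variants, exclude_silent=True)
        non_silent = sum(1 for v in variants if not v.is_silent)
        assert sum(counts.values()) == non_silent
        assert sum(props.values()) == pytest.approx(1.0)


class TestSpectrum:
    def test_complement_collapse(self):
        variants = [make_snv(pos=i + 1, ref="G", alt="A") for i in range(3)] + [
            make_snv(pos=i + 10, ref="C", alt="T") for i in range(2)
        ]
        spec = snv_six_class_spectrum(variants)
        assert spec["C>T"] == 1.0

    def test_even_split(self):
        variants = [make_snv(pos=1, ref="C", alt="T"), make_snv(pos=2, ref="T", alt="C")]
        spec = snv_six_class_spectrum(variants)
        assert spec["C>T"] == 0.5 and spec["T>C"] == 0.5

    @pytest.mark.parametrize("ref,alt", [("G", "A"), ("A", "G"), ("C", "T"), ("G", "C")])
    def test_collapse_idempotent(self, ref, alt):
        once = collapse_substitution(ref, alt)
        assert collapse_substitution(*once.split(">")) == once

    def test_transition_dominant_spectrum_ranks_first(self):
        rng = np.random.default_rng(11)
        subs = (
            [("C", "T")] * 40 + [("T", "C")] * 30 + [("C", "A")] * 10
            + [("T", "G")] * 5 + [("C", "G")] * 5 + [("T", "A")] * 5
        )
        rng.shuffle(subs)
        variants = [make_snv(pos=i + 1, ref=r, alt=a) for i, (r, a) in enumerate(subs)]
        spec = snv_six_class_spectrum(variants)
        top_two = sorted(spec, key=spec.get, reverse=True)[:2]
        assert set(top_two) == {"C>T", "T>C"}


class TestTmb:
    def test_arithmetic(self):
        variants = [make_snv(sample="S1", gene=f"G{i}", pos=i + 1) for i in range(76)]
        tmb = compute_tmb(variants, interrogated_mb=38.0)
        assert tmb.loc["S1", "total_tmb"] == pytest.approx(2.0)

    def test_zero_variants(self):
        tmb = compute_tmb([], interrogated_mb=38.0, samples=["S1"])
        assert tmb.loc["S1", "total_tmb"] == 0.0

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            compute_tmb([], interrogated_mb=0)

    def test_snv_plus_indel_additivity(self):
        rng = np.random.default_rng(3)
        variants = []
        for i in range(100):
            if rng.random() < 0.7:
                variants.append(make_snv(sample=f"S{i % 5}", gene=f"G{i}", pos=i + 1))
            else:
                variants.append(
                    SomaticVariant(
                        f"S{i % 5}", f"G{i}", f"G{i}", i + 1, "A", "-",
                        VariantClass.FRAMESHIFT_DEL, VariantType.DEL,
                    )
                )
        tmb = compute_tmb(variants)
        assert (tmb["snv_tmb"] + tmb["indel_tmb"]).equals(tmb["total_tmb"])


class TestRankGenes:
    def test_samples_mutated_ordering(self):
        variants = [
            make_snv(sample=s, gene="geneA", pos=i + 1)
            for i, s in enumerate(["S1", "S2", "S3"])
        ] + [make_snv(sample="S1", gene="geneB", pos=50)]
        ranked = rank_genes(variants, 10)
        assert list(ranked.index) == ["geneA", "geneB"]

    def test_total_count_tie_break(self):
        variants = (
            [make_snv(sample="S1", gene="geneA", pos=1), make_snv(sample="S2", gene="geneA", pos=2)]
            + [
                make_snv(sample="S1", gene="geneB", pos=10),
                make_snv(sample="S1", gene="geneB", pos=11),
                make_snv(sample="S2", gene="geneB", pos=12),
            ]
        )
        ranked = rank_genes(variants, 2)
        assert list(ranked.index) == ["geneB", "geneA"]

    def test_agrees_with_brute_force_sort(self):
        rng = np.random.default_rng(5)
        variants = [
            make_snv(sample=f"S{rng.integers(6)}", gene=f"G{rng.integers(20):02d}", pos=i + 1)
            for i in range(150)
        ]
        ranked = rank_genes(variants, 100)
        # independent brute force: count per gene, sort by the documented key
        by_gene = {}
        for v in variants:
            by_gene.setdefault(v.gene, []).append(v.sample_id)
        expected = sorted(
            by_gene,
            key=lambda g: (-len(set(by_gene[g])), -len(by_gene[g]), g),
        )
        assert list(ranked.index) == expected

    def test_implanted_top_genes_recovered(self):
        variants = []
        pos = 1
        for gene, n_samples in [("MUC16", 6), ("EGFR", 5), ("RBM10", 4)]:
            for s in range(n_samples):
                variants.append(make_snv(sample=f"S{s}", gene=gene, pos=pos))
                pos += 1
        for i in range(20):
            variants.append(make_snv(sample="S0", gene=f"BG{i:02d}", pos=pos))
            pos += 1
        top = rank_genes(variants, 3)
        assert list(top.index) == ["MUC16", "EGFR", "RBM10"]


class TestConsistentGenes:
    @staticmethod
    def _foci(n_patients=4):
        return [Focus(f"P{i}.1", f"P{i}") for i in range(1, n_patients + 1)]

    def test_same_class_in_all_patients_included(self):
        foci = self._foci()
        variants = [
            make_snv(sample=f"P{i}.1", gene="BCLAF1", pos=i) for i in range(1, 5)
        ]
        assert consistent_genes_across_patients(variants, foci) == ["BCLAF1"]

    def test_class_mismatch_excluded(self):
        foci = self._foci()
        variants = [
            make_snv(sample=f"P{i}.1", gene="USP6", pos=i) for i in range(1, 4)
        ] + [
            SomaticVariant(
                "P4.1", "USP6", "USP6", 9, "A", "-",
                VariantClass.FRAMESHIFT_DEL, VariantType.DEL,
            )
        ]
        assert consistent_genes_across_patients(variants, foci) == []

    def test_matches_exhaustive_oracle_on_random_fixture(self):
        rng = np.random.default_rng(13)
        foci = self._foci()
        classes = [VariantClass.MISSENSE, VariantClass.NONSENSE]
        variants = []
        for i in range(120):
            variants.append(
                make_snv(
                    sample=f"P{rng.integers(1, 5)}.1",
                    gene=f"G{rng.integers(10)}",
                    pos=i + 1,
                    vclass=classes[rng.integers(2)],
                )
            )
        result = consistent_genes_across_patients(variants, foci)
        # brute force over every gene
        expected = []
        for g in sorted({v.gene for v in variants}):
            vs = [v for v in variants if v.gene == g]
            patients = {v.sample_id.split(".")[0] for v in vs}
            classes_seen = {v.variant_class for v in vs}
            if patients == {"P1", "P2", "P3", "P4"} and len(classes_seen) == 1:
                expected.append(g)
        assert result == expected

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            consistent_genes_across_patients([], [Focus("P1.1", "P1")])


class TestSummaryAndCohortIo:
    def test_summary_shapes_and_conservation(self):
        variants = [
            make_snv(sample="S1", gene="G1", pos=1),
            make_snv(sample="S1", gene="G2", pos=2, vclass=VariantClass.SILENT),
            make_snv(sample="S2", gene="G1", pos=3),
        ]
        summary = summarize_cohort(variants)
        assert int(summary.class_counts.sum().sum()) == 2  # silent excluded
        assert summary.snv_spectrum.loc["S1"].sum() == pytest.approx(1.0)

    def test_cohort_tsv_round_trip(self, tmp_path):
        patients = [Patient("P4", ("HLA-A*02:01",))]
        foci = [Focus("P4.1", "P4"), Focus("P4.2", "P4")]
        p = tmp_path / "cohort.tsv"
        write_cohort_tsv(p, patients, foci)
        back_p, back_f = read_cohort_tsv(p)
        assert back_p == patients and back_f == foci
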