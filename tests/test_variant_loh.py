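"""LOH statistic: formula fidelity, boundary conventions, VCF plumbing."""

import gzip
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hurthleseq.variant_loh import (
    NI_CHROMOSOMES,
    VariantCall,
    VariantSet,
    chromosome_loh,
    genome_loh,
    loh_feature_table,
    loh_feature_vector,
    loh_profile,
    loh_statistic,
    normalize_chromosome,
    read_variants_vcf,
    write_loh_tsv,
)
from hurthleseq.synthdata import CohortSpec, generate_variants


def loh_brute_force(vafs):
    """Literal transcription of the defining formulas (independent oracle)."""
    vafs = [v for v in vafs if v != 1.0]
    n_all_het = sum(1 for v in vafs if 0 < v < 1)
    n_loss_het = sum(1 for v in vafs if 0 < v < 0.2 or 0.8 < v < 1)
    if n_all_het == 0:
        return math.nan
    return n_loss_het / n_all_het


@pytest.mark.parametrize(
    "vafs, expected",
    [
        ([0.5, 0.5, 0.5, 0.5], 0.0),
        ([0.1, 0.9, 0.95, 0.15], 1.0),
        ([0.1, 0.5, 0.5, 0.9, 1.0], 0.5),  # the VAF=1 call is pre-filtered
        ([0.2, 0.8, 0.5], 0.0),            # boundaries are not loss (strict)
        ([0.0, 0.5], 0.0),                 # VAF=0 is not a het candidate
        ([1.0, 1.0], math.nan),
        ([], math.nan),
        ([0.0], math.nan),
    ],
)
def test_loh_statistic_worked_examples(vafs, expected):
    got = loh_statistic(vafs)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_loh_statistic_rejects_out_of_range():
    with pytest.raises(ValueError):
        loh_statistic([0.5, 1.2])


# mix of continuous values and the exact boundary points 0, 0.2, 0.8, 1
vaf_values = st.one_of(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    st.sampled_from([0.0, 0.2, 0.8, 1.0, 0.5]),
)


@settings(max_examples=300, derandomize=True)
@given(st.lists(vaf_values, max_size=60))
def test_loh_statistic_matches_brute_force(vafs):
    got, want = loh_statistic(vafs), loh_brute_force(vafs)
    assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(vaf_values, min_size=1, max_size=40).filter(
        lambda v: not math.isnan(loh_brute_force(v))
    ),
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
)
def test_loh_statistic_monotone_in_appended_variant(vafs, extra):
    """Appending a loss-zone VAF never lowers LOH; a retained-zone VAF never raises it."""
    before = loh_statistic(vafs)
    after = loh_statistic(vafs + [extra])
    if 0 < extra < 0.2 or 0.8 < extra < 1:
        assert after >= before - 1e-12
    elif 0.2 <= extra <= 0.8:
        assert after <= before + 1e-12
    else:  # exactly 0 or 1: excluded entirely, value unchanged
        assert after == pytest.approx(before)


class TestChromosomeAndGenome:
    @pytest.fixture()
    def two_chrom_set(self):
        calls = [VariantCall("1", 10, 0.5), VariantCall("1", 20, 0.5),
                 VariantCall("2", 10, 0.1), VariantCall("2", 20, 0.9)]
        return VariantSet("s1", calls)

    def test_chromosome_level(self, two_chrom_set):
        assert chromosome_loh(two_chrom_set, "1") == 0.0
        assert chromosome_loh(two_chrom_set, "2") == 1.0
        assert math.isnan(chromosome_loh(two_chrom_set, "3"))

    def test_genome_excludes_mt_x_y(self):
        vs = VariantSet("s", [VariantCall("1", 1, 0.1), VariantCall("1", 2, 0.9),
                              VariantCall("X", 3, 0.99), VariantCall("X", 4, 0.99),
                              VariantCall("MT", 5, 0.95)])
        assert genome_loh(vs) == 1.0

    def test_genome_undefined_for_sex_only_set(self):
        vs = VariantSet("s", [VariantCall("Y", 1, 0.5)])
        assert math.isnan(genome_loh(vs))

    def test_genome_pools_autosomes(self):
        vs = VariantSet("s", [VariantCall("1", 1, 0.5), VariantCall("2", 1, 0.5),
                              VariantCall("3", 1, 0.1), VariantCall("4", 1, 0.9)])
        assert genome_loh(vs) == 0.5

    def test_genome_invariant_under_mt_x_y_injection(self, two_chrom_set):
        rng = np.random.default_rng(0)
        base = genome_loh(two_chrom_set)
        noisy = VariantSet(
            "s",
            two_chrom_set.variants
            + [VariantCall(rng.choice(["MT", "X", "Y"]), i + 1, rng.random())
               for i in range(30)],
        )
        assert genome_loh(noisy) == pytest.approx(base)

    def test_feature_vector_shape_and_order(self, two_chrom_set):
        vec = loh_feature_vector(two_chrom_set)
        assert vec.shape == (16,)
        custom = loh_feature_vector(two_chrom_set, ["1", "2"])
        assert custom[0] == 0.0 and custom[1] == 1.0
        assert custom[2] == pytest.approx(genome_loh(two_chrom_set))

    def test_feature_vector_empty_set_and_imputation(self):
        empty = VariantSet("e", [])
        vec = loh_feature_vector(empty)
        assert np.isnan(vec).all() and len(vec) == 16
        imputed = loh_feature_vector(empty, impute=0.0)
        assert (imputed == 0.0).all()

    def test_feature_table_columns(self, two_chrom_set):
        table = loh_feature_table([two_chrom_set])
        assert list(table.columns) == [f"loh_chr{c}" for c in NI_CHROMOSOMES] + ["loh_genome"]
        assert table.index.tolist() == ["s1"]


@pytest.mark.parametrize(
    "raw, expected",
    [("chr1", "1"), ("1", "1"), ("chrM", "MT"), ("MT", "MT"), ("m", "MT"),
     ("chrX", "X"), ("22", "22")],
)
def test_chromosome_normalization(raw, expected):
    assert normalize_chromosome(raw) == expected


def test_chromosome_normalization_rejects_noncanonical():
    with pytest.raises(ValueError):
        normalize_chromosome("chr1_random")


def test_planted_fraction_recovery():
    """chromosome_loh estimates the planted extreme-VAF fraction within sampling error."""
    spec = CohortSpec(loh_fraction=0.6, variants_per_chromosome=400, seed=11)
    rng = np.random.default_rng(5)
    vs = generate_variants("H+N+", spec, has_loh=True, rng=rng)
    for chrom in spec.loh_chromosomes:
        est = chromosome_loh(vs, chrom)
        # planted fraction plus baseline leakage from the Beta(6,6) tails
        assert abs(est - 0.62) < 0.12
    quiet = generate_variants("H-N-", spec, rng=rng)
    assert genome_loh(quiet) < 0.1


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=chrM>
##FILTER=<ID=q10,Description="low qual">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:10,10
1\t200\t.\tA\tG\t.\tPASS\t.\tGT:AD\t1/1:0,20
1\t300\t.\tA\tG,T\t.\tPASS\t.\tGT:AD\t1/2:0,10,10
1\t400\t.\tA\tG\t.\tq10\t.\tGT:AD\t0/1:5,5
1\t500\t.\tA\tG\t.\tPASS\t.\tGT:AD:AF\t0/1:10,10:0.25
chrM\t600\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:1,19
"""


class TestVcfReading:
    @pytest.fixture()
    def vcf_path(self, tmp_path):
        path = tmp_path / "sample.vcf"
        path.write_text(VCF_TEXT)
        return path

    def test_ad_derived_vafs_and_skips(self, vcf_path):
        vs = read_variants_vcf(vcf_path, "S1")
        by_pos = {v.position: v for v in vs.variants}
        assert by_pos[100].vaf == pytest.approx(0.5)
        assert by_pos[200].vaf == pytest.approx(1.0)  # pre-filtered later, not here
        assert 300 not in by_pos                      # multi-allelic skipped
        assert 400 not in by_pos                      # non-PASS skipped

    def test_dedicated_fraction_field_takes_precedence(self, vcf_path):
        vs = read_variants_vcf(vcf_path, "S1")
        by_pos = {v.position: v for v in vs.variants}
        assert by_pos[500].vaf == pytest.approx(0.25)

    def test_include_nonpass_flag(self, vcf_path):
        vs = read_variants_vcf(vcf_path, "S1", include_nonpass=True)
        assert 400 in {v.position for v in vs.variants}

    def test_mitochondrial_record_retained_but_excluded_from_genome(self, vcf_path):
        vs = read_variants_vcf(vcf_path, "S1")
        mt = [v for v in vs.variants if v.chromosome == "MT"]
        assert len(mt) == 1 and mt[0].vaf == pytest.approx(0.95)
        assert genome_loh(vs) == pytest.approx(
            loh_statistic([v.vaf for v in vs.variants if v.chromosome == "1"])
        )

    def test_gzip_input(self, tmp_path):
        path = tmp_path / "sample.vcf.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(VCF_TEXT)
        vs = read_variants_vcf(path, "S1")
        assert len(vs) == 4

    def test_single_sample_vcf_without_explicit_id(self, vcf_path):
        vs = read_variants_vcf(vcf_path)
        assert vs.sample_id == "S1" and len(vs) == 4


def test_loh_profile_tsv_round_trip(tmp_path):
    import pandas as pd

    vs = VariantSet("s1", [VariantCall("1", 1, 0.1), VariantCall("2", 1, 0.5)])
    prof = loh_profile(vs)
    out = tmp_path / "loh.tsv"
    write_loh_tsv([prof], out)
    table = pd.read_csv(out, sep="\t")
    assert list(table.columns) == ["sample_id"] + [f"chr{i}" for i in range(1, 23)] + ["genome"]
    assert table.loc[0, "chr1"] == 1.0
    assert math.isnan(table.loc[0, "chr3"])
    assert table.loc[0, "genome"] == 0.5
    assert prof.n_all_het["1"] == 1
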