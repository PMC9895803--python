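"""Linkage statistic, depth filter, variant classification and VCF ingestion."""

import dataclasses
from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedpurge.poolscan import (
    FilterConfig,
    PoolAlleleDepths,
    PooledVariant,
    ZeroDepthError,
    classify_variant,
    depth_filter,
    format_linkage,
    linkage_percent,
    read_pooled_vcf,
    records_to_frame,
    select_candidates,
    summarize_classes,
)
from seedpurge.simdata import simulate_dataset, write_simulated_vcf

counts = st.integers(min_value=0, max_value=500)


class TestLinkagePercent:
    @pytest.mark.parametrize(
        "depths, expected",
        [
            ((130, 0, 0, 100), "100.00"),  # fully concordant pools
            ((10, 10, 10, 10), "50.00"),
            ((12, 4, 3, 8), "74.07"),  # 20/27, the second-ranked published site
        ],
    )
    def test_printed_examples(self, depths, expected):
        assert format_linkage(linkage_percent(PoolAlleleDepths(*depths))) == expected

    def test_exhaustive_against_rational_oracle(self):
        """Brute-force rational arithmetic agrees for all count 4-tuples <= 6."""
        for gw, gm, aw, am in product(range(7), repeat=4):
            total = gw + gm + aw + am
            if total == 0:
                continue
            oracle = float(100 * Fraction(gw + am, total))
            assert linkage_percent(PoolAlleleDepths(gw, gm, aw, am)) == pytest.approx(
                oracle, abs=1e-9
            )

    def test_zero_total_is_signalled_not_zero(self):
        with pytest.raises(ZeroDepthError):
            linkage_percent(PoolAlleleDepths(0, 0, 0, 0))

    @given(gw=counts, gm=counts, aw=counts, am=counts, k=st.integers(1, 20))
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, gw, gm, aw, am, k):
        if gw + gm + aw + am == 0:
            return
        a = linkage_percent(PoolAlleleDepths(gw, gm, aw, am))
        b = linkage_percent(PoolAlleleDepths(k * gw, k * gm, k * aw, k * am))
        assert a == pytest.approx(b, abs=1e-9)

    @given(gw=counts, gm=counts, aw=counts, am=counts)
    @settings(max_examples=200, derandomize=True)
    def test_label_swap_complement(self, gw, gm, aw, am):
        if gw + gm + aw + am == 0:
            return
        a = linkage_percent(PoolAlleleDepths(gw, gm, aw, am))
        b = linkage_percent(PoolAlleleDepths(gm, gw, am, aw))
        assert a + b == pytest.approx(100.0, abs=1e-9)


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("GC", "GCC", "insertion"),
            ("A", "C", "SNP"),
            ("AGAT", "AGATGAT", "insertion"),
            ("AG", "A", "deletion"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_variant(ref, alt) == expected

    def test_mnp_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("AT", "GC")


class TestDepthFilter:
    @pytest.mark.parametrize(
        "green, albino, expected",
        [
            ((3, 0), (5, 5), False),  # lower bound strict
            ((50, 50), (25, 25), False),  # upper bound strict
            ((2, 2), (50, 49), True),  # interior
        ],
    )
    def test_per_pool_strict_bounds(self, green, albino, expected):
        d = PoolAlleleDepths(green[0], green[1], albino[0], albino[1])
        assert depth_filter(d, FilterConfig()) is expected

    def test_summed_mode(self):
        d = PoolAlleleDepths(2, 0, 1, 1)  # pools of 2 each, sum 4
        assert not depth_filter(d, FilterConfig())
        assert depth_filter(d, FilterConfig(per_pool=False))


def _depths_for_fraction(numer: int, denom: int) -> PoolAlleleDepths:
    """Counts whose linked/total ratio is numer/denom with pool totals in (3, 100)."""
    linked, unlinked = numer, denom - numer
    gw, am = (linked + 1) // 2, linked // 2
    gm, aw = (unlinked + 1) // 2, unlinked // 2
    d = PoolAlleleDepths(gw, gm, aw, am)
    assert 3 < d.green_total < 100 and 3 < d.albino_total < 100
    return d


PUBLISHED_PERCENTS = ["100.00", "74.07", "72.41", "70.73", "68.18", "67.86", "64.52", "64.29"]


def _smallest_fraction(display: str) -> tuple[int, int]:
    """Smallest-denominator read fraction printing as the given 2-dp percent."""
    from seedpurge._round import round_half_up

    target = float(display)
    for denom in range(8, 300):
        for numer in range(denom + 1):
            if f"{round_half_up(100 * numer / denom, 2):.2f}" == display:
                return numer, denom
    raise AssertionError(f"no fraction reproduces {display}")


class TestSelectCandidates:
    def test_published_rows_flagged_at_threshold_60(self):
        """Reconstructed count tables for the eight top-ranked sites all pass
        a 60% linkage threshold."""
        variants = []
        for i, pct in enumerate(PUBLISHED_PERCENTS):
            n, d = _smallest_fraction(pct)
            variants.append(
                PooledVariant("chr1", 100 + i, "A", "C", _depths_for_fraction(n, d))
            )
        records = select_candidates(variants, FilterConfig(linkage_threshold=60.0))
        assert all(r.candidate for r in records)
        displayed = [format_linkage(r.linkage_percent) for r in records]
        assert displayed == PUBLISHED_PERCENTS  # sorted descending

    def test_empty_input(self):
        assert select_candidates([]) == []

    def test_candidate_implies_passed_depth_and_threshold(self, clean_config):
        cfg = FilterConfig()
        ds = simulate_dataset(dataclasses.replace(clean_config, rng_seed=5))
        for r in select_candidates(ds.variants, cfg):
            if r.candidate:
                assert r.passed_depth and r.linkage_percent >= cfg.linkage_threshold

    def test_causal_site_scores_exactly_100_without_error_or_carriers(self, clean_config):
        for seed in range(10):
            ds = simulate_dataset(dataclasses.replace(clean_config, rng_seed=seed))
            causal = next(v for v in ds.variants if v.chrom == clean_config.causal_chrom
                          and v.pos == clean_config.causal_pos)
            assert linkage_percent(causal.depths) == 100.0


class TestSummaries:
    def test_published_class_composition(self):
        variants = (
            [PooledVariant("c", i + 1, "A", "C", PoolAlleleDepths(1, 1, 1, 1)) for i in range(105)]
            + [PooledVariant("c", 200 + i, "A", "AT", PoolAlleleDepths(1, 1, 1, 1)) for i in range(40)]
            + [PooledVariant("c", 400 + i, "AT", "A", PoolAlleleDepths(1, 1, 1, 1)) for i in range(72)]
        )
        counts = summarize_classes(variants)
        assert counts == {"SNP": 105, "insertion": 40, "deletion": 72}
        assert sum(counts.values()) == 217

    def test_empty_and_singleton(self):
        assert summarize_classes([]) == {"SNP": 0, "insertion": 0, "deletion": 0}
        one = [PooledVariant("c", 1, "A", "AT", PoolAlleleDepths(1, 0, 0, 1))]
        assert summarize_classes(one) == {"SNP": 0, "insertion": 1, "deletion": 0}


class TestVcfIngestion:
    def test_round_trip_preserves_counts(self, tmp_path, default_dataset):
        path = tmp_path / "pools.vcf"
        write_simulated_vcf(default_dataset.variants, path, truth=default_dataset.truth)
        variants, skipped = read_pooled_vcf(str(path))
        assert skipped == 0
        assert len(variants) == len(default_dataset.variants) == 217
        by_key = {(v.chrom, v.pos): v for v in default_dataset.variants}
        for v in variants:
            orig = by_key[(v.chrom, v.pos)]
            assert (v.ref, v.alt, v.depths) == (orig.ref, orig.alt, orig.depths)
        assert (tmp_path / "pools.vcf.truth.tsv").exists()

    def test_missing_sample_raises(self, tmp_path, default_dataset):
        path = tmp_path / "pools.vcf"
        write_simulated_vcf(default_dataset.variants[:3], path)
        with pytest.raises(KeyError):
            read_pooled_vcf(str(path), green_sample_name="nope")

    def test_multiallelic_skipped_with_count(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tgreen\talbino\n"
            "chr1\t10\t.\tA\tC\t.\t.\t.\tAD\t5,1\t1,7\n"
            "chr1\t20\t.\tA\tC,G\t.\t.\t.\tAD\t5,1,1\t1,7,0\n"
        )
        variants, skipped = read_pooled_vcf(str(vcf))
        assert len(variants) == 1 and skipped == 1

    def test_missing_ad_names_the_record(self, tmp_path):
        vcf = tmp_path / "noad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tgreen\talbino\n"
            "chr1\t10\t.\tA\tC\t.\t.\t.\tGT\t0/0\t1/1\n"
        )
        with pytest.raises(ValueError, match="chr1:10"):
            read_pooled_vcf(str(vcf))


def test_records_frame_columns(default_dataset):
    table = records_to_frame(select_candidates(default_dataset.variants))
    assert list(table.columns) == [
        "chrom", "pos", "ref", "alt", "var_class", "green_wt", "green_mut",
        "albino_wt", "albino_mut", "linkage_percent", "passed_depth", "candidate",
    ]
    assert len(table) == 217
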