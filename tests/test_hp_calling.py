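"""Candidate calling, the five-criterion heteroplasmy filter, annotation."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitopool.hp_calling import (
    FilterConfig,
    annotate_sites,
    call_candidates,
    containment_report,
    filter_hp_sites,
    read_vcf,
    write_hp_vcf,
)


def make_counts(rows):
    """Allele-count frame from (position, ref, A, C, G, T) tuples; uniform
    high qualities."""
    recs = []
    for pos, ref, a, c, g, t in rows:
        depth = a + c + g + t
        recs.append(
            {
                "position": pos, "ref": ref, "A": a, "C": c, "G": g, "T": t,
                "depth": depth,
                "bq_A": 37.0 if a else 0.0, "bq_C": 37.0 if c else 0.0,
                "bq_G": 37.0 if g else 0.0, "bq_T": 37.0 if t else 0.0,
                "map_qual": 60.0,
            }
        )
    return pd.DataFrame(recs)


def exact_binom_tail(k, n, p):
    """Independent oracle: P(X >= k) by exact rational summation of the
    lower tail."""
    pf = Fraction(p).limit_denominator(10**9)
    lower = sum(
        Fraction(comb(n, i)) * pf**i * (1 - pf) ** (n - i) for i in range(k)
    )
    return float(1 - lower)


class TestCallCandidates:
    def test_site_without_minor_allele_omitted(self):
        counts = make_counts([(10, "A", 1000, 0, 0, 0)])
        assert call_candidates(counts).empty

    def test_fixed_difference_dropped(self):
        """A site where all reads carry one non-reference allele is a
        consensus difference with no minor allele, not heteroplasmy."""
        counts = make_counts([(10, "A", 0, 1000, 0, 0)])
        assert call_candidates(counts).empty

    def test_minor_allele_call_and_exact_binomial_p(self):
        counts = make_counts([(42, "A", 4950, 50, 0, 0)])
        out = call_candidates(counts, FilterConfig(error_rate=0.001))
        assert len(out) == 1
        row = out.iloc[0]
        assert row.alt == "C" and row.alt_count == 50
        assert row.maf == pytest.approx(0.01)
        assert row.p_value < 1e-10
        assert row.p_value == pytest.approx(exact_binom_tail(50, 5000, 0.001), rel=1e-9)

    def test_consensus_difference_reorients_to_minor_fraction(self):
        # 99% C on an A reference: minor allele is the residual reference
        counts = make_counts([(7, "A", 10, 990, 0, 0)])
        out = call_candidates(counts)
        row = out.iloc[0]
        assert row.alt == "C"  # the non-reference allele involved
        assert row.alt_count == 10 and row.maf == pytest.approx(0.01)

    def test_multiallelic_takes_most_frequent_minor(self):
        counts = make_counts([(7, "A", 4960, 30, 10, 0)])
        row = call_candidates(counts).iloc[0]
        assert row.alt == "C" and row.alt_count == 30

    def test_maf_always_oriented_below_half(self):
        rng = np.random.default_rng(0)
        rows = []
        for pos in range(1, 60):
            counts4 = rng.multinomial(2000, rng.dirichlet([0.6] * 4))
            rows.append((pos, "ACGT"[rng.integers(4)], *counts4))
        out = call_candidates(make_counts(rows))
        assert ((out.maf > 0) & (out.maf <= 0.5)).all()

    def test_zero_depth_sites_skipped(self):
        counts = make_counts([(1, "A", 0, 0, 0, 0), (2, "C", 10, 990, 0, 0)])
        out = call_candidates(counts)
        assert list(out.position) == [2]

    def test_invalid_reference_base_rejected(self):
        counts = make_counts([(1, "N", 5, 5, 0, 0)])
        with pytest.raises(ValueError, match="reference base"):
            call_candidates(counts)

    def test_p_value_non_increasing_in_alt_count(self):
        rows = [(k, "A", 5000 - k, k, 0, 0) for k in range(1, 60)]
        out = call_candidates(make_counts(rows)).sort_values("alt_count")
        assert (np.diff(out.p_value) <= 1e-15).all()


class TestFilter:
    def _passing_candidates(self, depths, **overrides):
        base = dict(maf=0.01, p_value=1e-6, base_qual=37.0, map_qual=60.0)
        base.update(overrides)
        return pd.DataFrame(
            [
                {"position": i + 1, "ref": "A", "alt": "C",
                 "alt_count": max(1, int(d * base["maf"])), "depth": d, **base}
                for i, d in enumerate(depths)
            ]
        )

    def test_median_depth_rule_is_strict(self):
        cands = self._passing_candidates([10, 20, 30, 40, 50])
        out = filter_hp_sites(cands)
        assert sorted(out.depth) == [40, 50]
        assert out.attrs["median_depth"] == 30

    def test_even_count_median_is_mean_of_central_pair(self):
        cands = self._passing_candidates([10, 20, 40, 50])
        out = filter_hp_sites(cands)
        assert sorted(out.depth) == [40, 50]  # median 30, strict >

    def test_maf_boundary_strict(self):
        cands = self._passing_candidates([100, 200, 300], maf=0.001)
        assert filter_hp_sites(cands).empty

    def test_p_value_boundary(self):
        cands = self._passing_candidates([100, 200, 300], p_value=0.049)
        assert len(filter_hp_sites(cands)) == 1  # depth 300 > median 200

    def test_quality_thresholds_strict(self):
        low_bq = self._passing_candidates([100, 200, 300], base_qual=20.0)
        assert filter_hp_sites(low_bq).empty
        low_mq = self._passing_candidates([100, 200, 300], map_qual=30.0)
        assert filter_hp_sites(low_mq).empty

    def test_empty_input_passes_through(self):
        out = filter_hp_sites(pd.DataFrame(columns=["depth", "maf"]))
        assert out.empty

    def test_idempotent_with_frozen_median(self):
        cands = self._passing_candidates([10, 20, 30, 40, 50])
        first = filter_hp_sites(cands)
        again = filter_hp_sites(first, median_depth=first.attrs["median_depth"])
        pd.testing.assert_frame_equal(first, again)

    @settings(max_examples=50, derandomize=True)
    @given(st.data())
    def test_raising_any_threshold_never_gains_sites(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        n = data.draw(st.integers(1, 25))
        cands = pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "ref": "A", "alt": "C",
                "alt_count": rng.integers(1, 50, n),
                "depth": rng.integers(10, 5000, n),
                "maf": rng.uniform(0, 0.02, n),
                "p_value": rng.uniform(0, 0.1, n),
                "base_qual": rng.uniform(10, 40, n),
                "map_qual": rng.uniform(20, 70, n),
            }
        )
        base = FilterConfig()
        tighter = data.draw(
            st.sampled_from(
                [
                    base.with_(min_base_quality=30.0),
                    base.with_(min_mapping_quality=45.0),
                    base.with_(min_maf=0.005),
                    base.with_(max_p=0.01),
                ]
            )
        )
        assert len(filter_hp_sites(cands, tighter)) <= len(filter_hp_sites(cands, base))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        cands = pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "ref": "A", "alt": "G",
                "alt_count": rng.integers(1, 100, n),
                "depth": rng.integers(10, 3000, n),
                "maf": rng.uniform(0, 0.03, n),
                "p_value": rng.uniform(0, 0.1, n),
                "base_qual": rng.uniform(15, 40, n),
                "map_qual": rng.uniform(25, 70, n),
            }
        )
        cfg = FilterConfig()
        med = float(np.median(cands.depth))
        expected = [
            int(r.position)
            for r in cands.itertuples()
            if r.base_qual > cfg.min_base_quality
            and r.map_qual > cfg.min_mapping_quality
            and r.maf > cfg.min_maf
            and r.p_value < cfg.max_p
            and r.depth > med
        ]
        assert list(filter_hp_sites(cands, cfg).position) == expected


class TestAnnotateSites:
    def test_full_annotation_columns_and_load_flags(self, paper_scale_genome, catalogue):
        reference, annotation = paper_scale_genome
        picks = pd.concat(
            [
                catalogue[catalogue.klass == "noncoding"].head(1),
                catalogue[catalogue.klass == "missense_benign"].head(1),
                catalogue[catalogue.klass == "missense_deleterious"].head(1),
                catalogue[catalogue.klass == "lof"].head(1),
                catalogue[catalogue.klass == "synonymous"].head(1),
            ]
        )
        sites = pd.DataFrame(
            {
                "position": picks.position.to_numpy(),
                "ref": picks.ref.to_numpy(),
                "alt": picks.alt.to_numpy(),
                "alt_count": 50, "depth": 5000, "maf": 0.01, "p_value": 1e-9,
                "base_qual": 37.0, "map_qual": 60.0,
            }
        )
        out = annotate_sites(sites, annotation, reference)
        by_class = dict(zip(picks.klass, out.itertuples()))
        assert not by_class["noncoding"].is_load
        assert np.isnan(by_class["noncoding"].grantham)
        assert not by_class["missense_benign"].is_load
        assert by_class["missense_deleterious"].is_load
        assert by_class["missense_deleterious"].grantham > 150
        assert by_class["lof"].is_load
        assert not by_class["synonymous"].is_load
        assert set(out.ts_tv) <= {"Ts", "Tv"}

    def test_reference_mismatch_reported_with_site_context(self, small_genome):
        reference, annotation = small_genome
        pos = 1
        wrong = "A" if reference[0] != "A" else "C"
        sites = pd.DataFrame(
            [{"position": pos, "ref": wrong, "alt": "G", "alt_count": 5,
              "depth": 100, "maf": 0.05, "p_value": 0.01,
              "base_qual": 37.0, "map_qual": 60.0}]
        )
        with pytest.raises(ValueError, match=f"site {pos}"):
            annotate_sites(sites, annotation, reference)


class TestIO:
    def test_vcf_round_trip(self, tmp_path, paper_scale_genome, catalogue):
        reference, annotation = paper_scale_genome
        picks = catalogue[catalogue.klass == "missense_deleterious"].head(3)
        sites = pd.DataFrame(
            {
                "position": picks.position.to_numpy(),
                "ref": picks.ref.to_numpy(),
                "alt": picks.alt.to_numpy(),
                "alt_count": 40, "depth": 4000, "maf": 0.01, "p_value": 1e-8,
                "base_qual": 37.0, "map_qual": 60.0,
            }
        )
        annotated = annotate_sites(sites, annotation, reference)
        vcf_path = tmp_path / "hp.vcf"
        write_hp_vcf(annotated, vcf_path, contig_length=len(reference))
        back = read_vcf(vcf_path)
        assert back.empty  # no AD fields: sites-only VCF is annotation output
        text = vcf_path.read_text()
        assert "MAF=" in text and "EFF=missense" in text and "LOAD" in text

    def test_read_vcf_with_allele_depths(self, tmp_path):
        vcf = tmp_path / "counts.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="mapq">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="depths">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            "##contig=<ID=MT,length=16615>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "MT\t100\t.\tA\tC\t.\t.\tMQ=55\tAD:DP\t990,10:1000\n"
        )
        counts = read_vcf(vcf)
        assert len(counts) == 1
        row = counts.iloc[0]
        assert row.position == 100 and row.A == 990 and row.C == 10
        assert row.depth == 1000 and row.map_qual == 55.0
        out = call_candidates(counts)
        assert out.iloc[0].maf == pytest.approx(0.01)

    def test_containment_report(self):
        a = pd.DataFrame({"position": [1, 2, 3], "alt": ["C", "G", "T"]})
        b = pd.DataFrame({"position": [2, 3, 9], "alt": ["G", "T", "A"]})
        rep = containment_report(a, b)
        assert rep["n_shared"] == 2
        assert rep["fraction_a_in_b"] == pytest.approx(2 / 3)
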