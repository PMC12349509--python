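"""Burden estimators, MAF spectra and chromosome distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gburden.burden_stats import (BurdenError, chrom_distribution,
                                  compute_burdens, maf_spectrum)
from gburden.variant_io import HET, HOM_ALT

from conftest import make_variantset


def full_dset(vs):
    return vs.site_frame()


def brute_force_burdens(vs, dset):
    """Independent oracle: literally count deleterious alleles per genotype."""
    keys = set(zip(dset["chrom"], dset["pos"], dset["ref"], dset["alt"]))
    rows = {}
    for j, sample in enumerate(vs.samples):
        n_het = n_hom = n_loci = 0
        for i in range(vs.n_sites):
            key = (vs.chrom[i], vs.pos[i], vs.ref[i], vs.alt[i])
            if key not in keys:
                continue
            n_loci += 1
            g = vs.genotypes[i, j]
            if g == HET:
                n_het += 1
            elif g == HOM_ALT:
                n_hom += 1
        alleles = 2 * n_hom + n_het
        rows[sample] = (n_het, n_hom, n_het / (2 * n_loci),
                        2 * n_hom / (2 * n_loci), alleles / (2 * n_loci))
    return rows


class TestComputeBurdens:
    def test_single_sample_worked_example(self):
        # genotypes at 4 deleterious loci: hom_ref, het, hom_alt, het
        vs = make_variantset([[0], [1], [2], [1]])
        out = compute_burdens(vs, full_dset(vs))
        row = out.iloc[0]
        assert (row.n_het, row.n_hom, row.L) == (2, 1, 4)
        assert row.B_het == pytest.approx(2 / 8)
        assert row.B_hom == pytest.approx(2 / 8)
        assert row.B_tot == pytest.approx(0.5)

    def test_all_hom_ref_gives_zero_burdens(self):
        vs = make_variantset(np.zeros((5, 3)))
        out = compute_burdens(vs, full_dset(vs))
        assert (out[["B_het", "B_hom", "B_tot"]] == 0).all().all()

    def test_all_hom_alt_saturates(self):
        vs = make_variantset(np.full((5, 3), 2))
        out = compute_burdens(vs, full_dset(vs))
        assert (out["B_tot"] == 1).all() and (out["B_hom"] == 1).all()
        assert (out["B_het"] == 0).all()

    def test_empty_dsnp_set_raises(self):
        vs = make_variantset([[0], [1]])
        with pytest.raises(BurdenError, match="no deleterious loci"):
            compute_burdens(vs, full_dset(vs).iloc[:0])

    def test_missing_keys_raise_consistency_error(self):
        vs = make_variantset([[0], [1]])
        dset = full_dset(vs)
        dset.loc[1, "pos"] = 999_999
        with pytest.raises(BurdenError, match="absent"):
            compute_burdens(vs, dset)

    def test_agrees_with_allele_count_oracle_at_scale(self):
        rng = np.random.default_rng(42)
        vs = make_variantset(rng.integers(0, 3, size=(1000, 600)))
        dset = full_dset(vs).iloc[rng.choice(1000, 700, replace=False)]
        out = compute_burdens(vs, dset)
        oracle = brute_force_burdens(vs, dset)
        for sample, (n_het, n_hom, b_het, b_hom, b_tot) in oracle.items():
            row = out.loc[sample]
            assert (row.n_het, row.n_hom) == (n_het, n_hom)
            assert row.B_het == pytest.approx(b_het, abs=0)
            assert row.B_hom == pytest.approx(b_hom, abs=0)
            assert row.B_tot == pytest.approx(b_tot, abs=1e-15)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_additivity_and_double_counting_identity(self, seed):
        rng = np.random.default_rng(seed)
        vs = make_variantset(rng.integers(0, 3, size=(30, 8)))
        out = compute_burdens(vs, full_dset(vs))
        # the three-way decomposition holds exactly for every sample
        assert (out["B_tot"] - (out["B_het"] + out["B_hom"]) == 0).all()
        # per-sample allele totals equal per-site allele totals
        per_sample = (2 * out["n_hom"] + out["n_het"]).sum()
        per_site = int((vs.genotypes == HET).sum()
                       + 2 * (vs.genotypes == HOM_ALT).sum())
        assert per_sample == per_site

    def test_sample_permutation_permutes_rows_only(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(20, 6))
        vs = make_variantset(geno)
        perm = rng.permutation(6)
        vs2 = make_variantset(geno[:, perm])
        vs2.samples = [vs.samples[p] for p in perm]
        a = compute_burdens(vs, full_dset(vs))
        b = compute_burdens(vs2, full_dset(vs2))
        pd.testing.assert_frame_equal(a.loc[b.index], b)

    def test_explicit_deleterious_allele_column_flips_reference_sites(self):
        vs = make_variantset([[0, 2], [1, 1]])
        dset = full_dset(vs)
        dset["deleterious_allele"] = [dset["ref"].iloc[0], dset["alt"].iloc[1]]
        out = compute_burdens(vs, dset, deleterious_allele="column")
        # site 0 flipped: hom_ref counts as two deleterious alleles
        assert out.loc["S1", "n_hom"] == 1 and out.loc["S2", "n_hom"] == 0


class TestMafSpectrum:
    def test_direct_frequency_count(self):
        vs = make_variantset([[1, 2]])  # het + hom_alt in 2 samples
        spec = maf_spectrum(vs)
        assert spec.sites["p_alt"].iloc[0] == pytest.approx(0.75)
        assert spec.sites["maf"].iloc[0] == pytest.approx(0.25)

    def test_invariant_heterozygous_flag(self):
        vs = make_variantset([[1, 1, 1, 1]])
        spec = maf_spectrum(vs)
        assert spec.sites["maf"].iloc[0] == pytest.approx(0.5)
        assert bool(spec.sites["invariant_het"].iloc[0])

    def test_fixed_flag(self):
        vs = make_variantset([[2, 2, 2]])
        spec = maf_spectrum(vs)
        assert bool(spec.sites["fixed"].iloc[0])
        assert spec.sites["maf"].iloc[0] == pytest.approx(0.0)
        assert spec.n_fixed == 1

    def test_band_flags_and_histogram(self):
        geno = np.zeros((3, 100), dtype=int)
        geno[0, 0] = 1          # p = 0.005 -> singleton band
        geno[1, :8] = 1         # p = 0.04  -> rare band
        geno[2, :30] = 1        # p = 0.15  -> neither
        spec = maf_spectrum(make_variantset(geno))
        assert spec.sites["singleton_band"].tolist() == [True, False, False]
        assert spec.sites["rare_band"].tolist() == [True, True, False]
        assert spec.histogram["count"].sum() == 3


class TestChromDistribution:
    def test_printed_totals_give_printed_means(self):
        n_snp, n_dsnp = 58_548, 588
        chroms = [f"Gm{(i % 20) + 1:02d}" for i in range(n_snp)]
        vs = make_variantset(np.ones((n_snp, 1)), chrom=chroms,
                             pos=np.arange(1, n_snp + 1))
        dset = vs.site_frame().iloc[:n_dsnp]
        dist = chrom_distribution(vs, dset)
        summ = dist.summary.set_index("track")
        assert summ.loc["snp_count", "mean"] == pytest.approx(2927.4)
        assert summ.loc["dsnp_count", "mean"] == pytest.approx(29.4)

    def test_single_chromosome_carries_everything(self):
        vs = make_variantset(np.ones((10, 1)), chrom=["Gm07"] * 10)
        dist = chrom_distribution(vs, None, n_chrom=20)
        table = dist.table.set_index("chromosome")
        assert table.loc[7, "snp_count"] == 10
        assert table["snp_count"].sum() == 10

    def test_unexpected_labels_counted_under_other(self):
        vs = make_variantset(np.ones((4, 1)),
                             chrom=["Gm01", "Gm01", "scaffold_991", "Gm02"])
        with pytest.warns(UserWarning, match="other"):
            dist = chrom_distribution(vs, None, n_chrom=2)
        table = dist.table.set_index("chromosome")
        assert table.loc["other", "snp_count"] == 1
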