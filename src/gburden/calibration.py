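"""Reference summary tallies from a seed-based soybean genebank assay.

The pipeline's defaults and its self-checks are calibrated against the
printed summary tables of a seed-based RNA-Seq assay of 190 conserved
soybean accessions: 58,548 complete biallelic SNPs classified into 16
most-severe consequence classes, 5912 SIFT-deleterious SNPs after excluding
941 low-confidence calls, and 588 SNPs deleterious under the combined
SIFT + RS rule, split 45/477/66 across the weak/mild/high RS severity bins.
This module carries those printed counts and builds synthetic fixtures that
realise them exactly, so the tally, classification, MAF and
chromosome-distribution mechanics can be verified against the published
arithmetic without the (unpublished-scale) raw data.

All fixtures are synthetic reconstructions: they reproduce the printed
marginal counts, not the underlying variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate_classify import ANNOTATION_COLUMNS
from .variant_io import HET, HOM_REF, VariantSet

#: printed per-class counts of the 58,548 assayed SNPs (sums to the total)
CONSEQUENCE_COUNTS: dict[str, int] = {
    "missense_variant": 19_847,
    "synonymous_variant": 20_478,
    "splice_acceptor_variant": 45,
    "splice_donor_variant": 50,
    "stop_gained": 450,
    "stop_lost": 57,
    "start_lost": 45,
    "splice_region_variant": 194,
    "stop_retained_variant": 28,
    "5_prime_UTR_variant": 5354,
    "3_prime_UTR_variant": 7068,
    "non_coding_transcript_exon_variant": 208,
    "intron_variant": 1131,
    "upstream_gene_variant": 1584,
    "downstream_gene_variant": 863,
    "intergenic_variant": 1146,
}

TOTAL_SNPS = 58_548
SIFT_DELETERIOUS = 6853          # SIFT <= 0.05 before the confidence filter
LOW_CONFIDENCE = 941             # excluded deleterious_low_confidence calls
SIFT_DELETERIOUS_NORMAL = SIFT_DELETERIOUS - LOW_CONFIDENCE   # 5912
TOLERATED = 34_076               # SIFT-scored, tolerated
N_DSNP = 588                     # SIFT + RS combined rule
SEVERITY_COUNTS = {"weak": 45, "mild": 477, "high": 66}
N_CHROMOSOMES = 20

#: printed minor-allele-frequency band counts of the 588 dSNPs
DSNP_MAF_LE_05 = 507             # MAF <= 0.05
DSNP_MAF_LE_01 = 123             # MAF <= 0.01
INVARIANT_HET_SNPS = 1344        # of the 58,548 SNPs, heterozygous everywhere

#: printed per-sample burden means (total = het + hom)
BURDEN_MEANS = {"B_tot": 0.051, "B_het": 0.015, "B_hom": 0.036}


def build_reference_annotation(seed: int = 0) -> pd.DataFrame:
    """Annotation table realising the printed counts exactly.

    One row per SNP (58,548 rows): consequence classes at their printed
    counts; 6853 SIFT-deleterious rows of which 941 low-confidence; 588 of
    the remaining 5912 carry RS > 0 at the printed severity split; 34,076
    further rows carry tolerated SIFT scores. Scores are drawn uniformly
    within each stratum — only the stratum memberships are meaningful.
    """
    rng = np.random.default_rng(seed)
    consequence = np.repeat(list(CONSEQUENCE_COUNTS),
                            list(CONSEQUENCE_COUNTS.values()))
    n = consequence.size
    assert n == TOTAL_SNPS

    sift = np.full(n, np.nan)
    conf = np.full(n, "normal", dtype=object)
    rs = np.full(n, np.nan)

    # SIFT-deleterious rows sit among the missense class (first block)
    sift[:SIFT_DELETERIOUS] = rng.uniform(0.0, 0.05, SIFT_DELETERIOUS)
    conf[:LOW_CONFIDENCE] = "low_confidence"
    rs[:LOW_CONFIDENCE] = rng.uniform(0.5, 4.0, LOW_CONFIDENCE)

    # the 588 combined-rule dSNPs at the printed severity split
    start = LOW_CONFIDENCE
    for sev, (lo, hi) in (("weak", (0.05, 0.999)), ("mild", (1.0, 3.0)),
                          ("high", (3.001, 6.0))):
        k = SEVERITY_COUNTS[sev]
        rs[start:start + k] = rng.uniform(lo, hi, k)
        start += k
    # remaining SIFT-deleterious rows: unconstrained (RS <= 0) or unscored
    rest = np.arange(start, SIFT_DELETERIOUS)
    half = rest.size // 2
    rs[rest[:half]] = rng.uniform(-3.0, 0.0, half)

    # tolerated SIFT scores fill the remaining scored rows
    tol_idx = np.arange(SIFT_DELETERIOUS, SIFT_DELETERIOUS + TOLERATED)
    sift[tol_idx] = rng.uniform(0.051, 1.0, TOLERATED)

    pos = np.arange(1, n + 1) * 100
    chrom = np.array([f"Gm{(i % N_CHROMOSOMES) + 1:02d}" for i in range(n)],
                     dtype=object)
    ann = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "ref": np.full(n, "A", dtype=object),
        "alt": np.full(n, "G", dtype=object),
        "gene_id": [f"Glyma.g{i // 8:06d}" for i in range(n)],
        "consequence": consequence,
        "sift_score": sift, "sift_confidence": conf, "rs_score": rs,
    })
    return ann[ANNOTATION_COLUMNS]


def build_dsnp_maf_variantset(n_samples: int = 100) -> VariantSet:
    """588-site genotype matrix realising the printed dSNP MAF bands.

    123 singleton sites (one heterozygote), 384 further rare sites (MAF
    0.04) and 81 commoner sites (MAF 0.15), giving the printed 20.9% and
    86.2% band fractions.
    """
    n_single = DSNP_MAF_LE_01
    n_rare = DSNP_MAF_LE_05 - DSNP_MAF_LE_01
    n_common = N_DSNP - DSNP_MAF_LE_05
    geno = np.zeros((N_DSNP, n_samples), dtype=np.int8)
    geno[:n_single, 0] = HET
    geno[n_single:n_single + n_rare, :8] = HET            # p = 0.04
    geno[n_single + n_rare:, :30] = HET                   # p = 0.15
    return _variantset(geno)


def build_invariant_het_variantset(n_samples: int = 4) -> VariantSet:
    """58,548-site matrix with the printed number of invariant-het SNPs."""
    geno = np.zeros((TOTAL_SNPS, n_samples), dtype=np.int8)
    geno[:INVARIANT_HET_SNPS, :] = HET
    geno[INVARIANT_HET_SNPS:, 0] = HET   # ordinary segregating sites
    return _variantset(geno)


def build_chromosome_variantset() -> tuple[VariantSet, pd.DataFrame]:
    """Site lists with 58,548 SNPs and 588 dSNPs over 20 chromosomes."""
    vs = _variantset(np.full((TOTAL_SNPS, 1), HOM_REF + 1, dtype=np.int8))
    dset = vs.site_frame().iloc[:N_DSNP].copy()
    return vs, dset


def _variantset(geno: np.ndarray) -> VariantSet:
    n = geno.shape[0]
    return VariantSet(
        chrom=np.array([f"Gm{(i % N_CHROMOSOMES) + 1:02d}" for i in range(n)],
                       dtype=object),
        pos=np.arange(1, n + 1) * 10,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        genotypes=geno,
        samples=[f"S{j + 1}" for j in range(geno.shape[1])])
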