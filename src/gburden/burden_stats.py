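"""Per-sample mutation-burden estimators, MAF spectra and genomic spread.

For a sample carrying genotypes at L deleterious loci (the dSNP set), with
n_het loci heterozygous and n_hom loci homozygous for the deleterious allele:

    B_het = n_het / (2 L)         heterozygous burden per deleterious locus
    B_hom = 2 n_hom / (2 L)       homozygous burden per deleterious locus
    B_tot = (2 n_hom + n_het) / (2 L) = B_het + B_hom

i.e. the count of deleterious alleles carried, normalised by the total number
of allele slots at deleterious loci. The deleterious allele is, by default,
the alternate allele of the SIFT-scored substitution (no outgroup
polarisation); an explicit per-site deleterious-allele column may override.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate_classify import KEY_COLS
from .variant_io import HET, HOM_ALT, HOM_REF, VariantSet

logger = logging.getLogger("gburden")


class BurdenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# burden estimators
# ---------------------------------------------------------------------------

def _dsnp_site_indices(vs: VariantSet, dset: pd.DataFrame) -> np.ndarray:
    """Row indices in ``vs`` of the deleterious-set keys; error on absentees."""
    site_index = pd.MultiIndex.from_arrays(
        [vs.chrom, vs.pos, vs.ref, vs.alt], names=KEY_COLS)
    want = pd.MultiIndex.from_frame(dset[KEY_COLS])
    locs = site_index.get_indexer(want)
    if (locs < 0).any():
        missing = want[locs < 0].tolist()
        head = ", ".join(map(str, missing[:5]))
        raise BurdenError(
            f"{len(missing)} deleterious key(s) absent from the variant set: "
            f"{head}{' ...' if len(missing) > 5 else ''}")
    return locs


def compute_burdens(vs: VariantSet, dset: pd.DataFrame,
                    deleterious_allele: str = "alt") -> pd.DataFrame:
    """Compute the three per-sample burden estimators over the dSNP loci.

    ``dset`` is a deleterious set (rows keyed by chrom/pos/ref/alt, all keys
    present in ``vs``). Under the default ``deleterious_allele="alt"``
    convention the deleterious allele is the alternate allele; with
    ``"column"`` the dset must carry a ``deleterious_allele`` column of bases
    and sites whose deleterious allele is the reference are counted with
    genotype states inverted.

    Returns a DataFrame indexed by sample with columns
    ``n_het, n_hom, L, B_het, B_hom, B_tot``.
    """
    L = len(dset)
    if L == 0:
        raise BurdenError("no deleterious loci (empty dSNP set)")
    locs = _dsnp_site_indices(vs, dset)
    geno = vs.genotypes[locs]  # (L, n_samples)

    if deleterious_allele == "column":
        if "deleterious_allele" not in dset.columns:
            raise BurdenError("convention 'column' needs a deleterious_allele column")
        flip = (dset["deleterious_allele"].to_numpy()
                == dset["ref"].to_numpy())
        geno = geno.copy()
        geno[flip] = 2 - geno[flip]
    elif deleterious_allele != "alt":
        raise BurdenError(f"unknown deleterious-allele convention: {deleterious_allele!r}")

    n_het = (geno == HET).sum(axis=0)
    n_hom = (geno == HOM_ALT).sum(axis=0)
    denom = 2.0 * L
    b_het = n_het / denom
    b_hom = 2.0 * n_hom / denom
    out = pd.DataFrame({
        "n_het": n_het.astype(int),
        "n_hom": n_hom.astype(int),
        "L": L,
        "B_het": b_het,
        "B_hom": b_hom,
        # summed, not (2*n_hom + n_het)/(2L), so the three-way decomposition
        # B_tot = B_het + B_hom holds exactly in floating point
        "B_tot": b_het + b_hom,
    }, index=pd.Index(vs.samples, name="sample_id"))
    logger.info("compute_burdens: L=%d loci, %d samples; mean B_tot=%.4f",
                L, vs.n_samples, out["B_tot"].mean())
    return out


# ---------------------------------------------------------------------------
# minor allele frequency spectrum
# ---------------------------------------------------------------------------

@dataclass
class MafSpectrum:
    """Per-site allele frequencies, band flags and an MAF histogram."""

    sites: pd.DataFrame            # per-site p_alt, maf and flags
    histogram: pd.DataFrame        # bin_left, bin_right, count

    @property
    def n_fixed(self) -> int:
        return int(self.sites["fixed"].sum())

    def band_fraction(self, flag: str) -> float:
        """Fraction of sites carrying a given flag column."""
        return float(self.sites[flag].mean()) if len(self.sites) else 0.0


def maf_spectrum(vs: VariantSet, subset: pd.DataFrame | None = None,
                 bins: int | np.ndarray = 10,
                 singleton_band: float = 0.01,
                 rare_band: float = 0.05) -> MafSpectrum:
    """Alternate-allele and minor-allele frequencies per site, with flags.

    p_alt = (2 x hom_alt + het) / (2 x n_samples); MAF = min(p, 1 - p).
    Flags: ``fixed`` (deleterious/alternate allele at frequency 1 in every
    sample), ``invariant_het`` (every sample heterozygous, MAF 0.5),
    ``singleton_band`` (MAF <= 0.01) and ``rare_band`` (MAF <= 0.05).
    ``subset`` (keyed rows, e.g. a deleterious set) restricts the spectrum.
    """
    if subset is not None:
        geno = vs.genotypes[_dsnp_site_indices(vs, subset)]
        site_frame = subset[KEY_COLS].reset_index(drop=True)
    else:
        geno = vs.genotypes
        site_frame = vs.site_frame()

    n = geno.shape[1]
    p = (2.0 * (geno == HOM_ALT).sum(axis=1) + (geno == HET).sum(axis=1)) / (2.0 * n)
    maf = np.minimum(p, 1.0 - p)
    sites = site_frame.copy()
    sites["p_alt"] = p
    sites["maf"] = maf
    sites["fixed"] = (geno == HOM_ALT).all(axis=1)
    sites["invariant_het"] = (geno == HET).all(axis=1)
    sites["singleton_band"] = maf <= singleton_band
    sites["rare_band"] = maf <= rare_band

    edges = np.histogram_bin_edges(maf, bins=bins, range=(0.0, 0.5)) \
        if np.isscalar(bins) else np.asarray(bins, dtype=float)
    counts, edges = np.histogram(maf, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
    return MafSpectrum(sites=sites, histogram=hist)


# ---------------------------------------------------------------------------
# per-chromosome distribution
# ---------------------------------------------------------------------------

@dataclass
class ChromDistribution:
    """SNP and dSNP counts per chromosome with min/max/mean summaries.

    Means divide by the expected chromosome number ``n_chrom`` even when some
    chromosomes carry no variant of a track.
    """

    table: pd.DataFrame   # chromosome, snp_count, dsnp_count
    n_chrom: int
    summary: pd.DataFrame  # track, min, max, mean


_CHROM_NUM = re.compile(r"(\d+)$")


def _chrom_number(label: str) -> int | None:
    m = _CHROM_NUM.search(str(label))
    return int(m.group(1)) if m else None


def chrom_distribution(vs: VariantSet, dset: pd.DataFrame | None = None,
                       n_chrom: int = 20) -> ChromDistribution:
    """Count SNPs (and optionally dSNPs) per chromosome.

    Chromosome labels are matched by their trailing number (``Gm07``,
    ``Chr07`` and ``7`` all map to chromosome 7); labels outside 1..n_chrom
    are tallied under ``other`` with a warning. Summary means are computed
    over the full expected chromosome count.
    """
    def bucket(labels) -> pd.Series:
        nums = [_chrom_number(c) for c in labels]
        keys = [n if (n is not None and 1 <= n <= n_chrom) else "other"
                for n in nums]
        return pd.Series(keys).value_counts()

    snp_counts = bucket(vs.chrom)
    dsnp_counts = bucket(dset["chrom"]) if dset is not None else pd.Series(dtype=int)
    if "other" in snp_counts.index or "other" in dsnp_counts.index:
        warnings.warn(f"chromosome labels outside 1..{n_chrom} counted under 'other'",
                      stacklevel=2)

    rows = [*range(1, n_chrom + 1)] + (["other"] if ("other" in snp_counts.index
                                                     or "other" in dsnp_counts.index) else [])
    table = pd.DataFrame({
        "chromosome": rows,
        "snp_count": [int(snp_counts.get(r, 0)) for r in rows],
        "dsnp_count": [int(dsnp_counts.get(r, 0)) for r in rows],
    })

    main = table[table["chromosome"] != "other"]
    summ = []
    for track in ("snp_count", "dsnp_count"):
        vals = main[track]
        summ.append({"track": track, "min": int(vals.min()), "max": int(vals.max()),
                     "total": int(vals.sum()), "mean": vals.sum() / n_chrom})
    return ChromDistribution(table=table, n_chrom=n_chrom,
                             summary=pd.DataFrame(summ))
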