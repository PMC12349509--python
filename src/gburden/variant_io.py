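"""Reading, filtering and writing of genotype and metadata inputs.

The analysis operates on a complete biallelic SNP genotype matrix. Raw VCF
records (as produced by an RNA-Seq SNP-calling workflow) are read into a
:class:`RawVariantTable`, then reduced by :func:`filter_variants` with the
standard site/genotype quality rules — biallelic SNPs only, site quality
>= 20, per-genotype depth >= 10, and no missing calls — yielding a
:class:`VariantSet` plus an auditable :class:`FilterLedger`.

Genotype states are encoded as integers throughout::

    0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
    -1 = missing (raw tables only; a VariantSet is complete by construction)
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger("gburden")

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed (malformed header, missing GT)."""


class MetadataError(ValueError):
    """Raised when an accession metadata row violates its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawVariantTable:
    """Unfiltered site-by-sample genotype records from a VCF.

    Arrays are aligned site-wise; ``alts`` holds the full ALT list per site so
    multi-allelic sites can be recognised and dropped downstream.
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int, 1-based
    ref: np.ndarray            # (n_sites,) str
    alts: list[tuple[str, ...]]
    qual: np.ndarray           # (n_sites,) float; NaN when QUAL is "."
    genotypes: np.ndarray      # (n_sites, n_samples) int8 in {0,1,2,-1}
    dp: np.ndarray | None      # (n_sites, n_samples) int32, <0 missing; None if no DP FORMAT
    samples: list[str]
    is_snp: np.ndarray         # (n_sites,) bool — single-base REF and all ALTs

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class FilterLedger:
    """Per-rule site attrition counts.

    Each dropped site is attributed to the first rule it fails, in the fixed
    order indel -> multiallelic -> qual -> DP/missing, so the counts are
    deterministic and sum to the input site count.
    """

    n_input: int = 0
    dropped_indel: int = 0
    dropped_multiallelic: int = 0
    dropped_qual: int = 0
    dropped_missing: int = 0
    surviving: int = 0

    def check(self) -> None:
        total = (self.surviving + self.dropped_indel + self.dropped_multiallelic
                 + self.dropped_qual + self.dropped_missing)
        if total != self.n_input:
            raise AssertionError(f"ledger does not sum: {total} != {self.n_input}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": [f.name for f in fields(self)],
             "count": [getattr(self, f.name) for f in fields(self)]}
        )


@dataclass
class VariantSet:
    """Filtered, complete, biallelic genotype matrix with site keys.

    Invariants: every ALT is a single base, no genotype is missing, and
    (chrom, pos, ref, alt) keys are unique.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray            # (n_sites,) str — single alternate base
    genotypes: np.ndarray      # (n_sites, n_samples) int8 in {0,1,2}
    samples: list[str]
    ledger: FilterLedger | None = None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def keys(self) -> pd.MultiIndex:
        """Unique (chrom, pos, ref, alt) site keys, in site order."""
        return pd.MultiIndex.from_arrays(
            [self.chrom, self.pos, self.ref, self.alt],
            names=["chrom", "pos", "ref", "alt"])

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                             "ref": self.ref, "alt": self.alt})

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_sites, self.n_samples):
            raise ValueError("genotype matrix shape does not match sites x samples")
        if self.n_sites and self.genotypes.size:
            bad = ~np.isin(self.genotypes, (HOM_REF, HET, HOM_ALT))
            if bad.any():
                raise ValueError("VariantSet contains missing/invalid genotypes")
        if self.n_sites != len(set(zip(self.chrom, self.pos, self.ref, self.alt))):
            raise ValueError("duplicate (chrom, pos, ref, alt) site keys")


@dataclass
class AccessionMetadata:
    """Conservation covariates for one genebank accession.

    ``y_acq``  — years since acquisition; ``y_last`` — years since the last
    regeneration; ``r`` — completed regeneration cycles. An accession never
    regenerated has ``y_last == y_acq``.
    """

    sample_id: str
    country: str
    y_acq: int
    y_last: int
    r: int
    rin: float

    def validate(self) -> None:
        if self.y_acq < 0 or self.y_last < 0 or self.r < 0:
            raise MetadataError(f"{self.sample_id}: negative covariate")
        if self.y_last > self.y_acq:
            raise MetadataError(
                f"{self.sample_id}: years since last regeneration ({self.y_last}) "
                f"exceeds years since acquisition ({self.y_acq})")
        if self.r == 0 and self.y_last != self.y_acq:
            raise MetadataError(
                f"{self.sample_id}: zero regenerations but y_last != y_acq")
        if not (1.0 <= self.rin <= 10.0):
            raise MetadataError(f"{self.sample_id}: RIN {self.rin} outside [1, 10]")


def metadata_frame(meta: list[AccessionMetadata]) -> pd.DataFrame:
    """Tabulate a metadata list, indexed by sample_id."""
    return pd.DataFrame(
        [{"sample_id": m.sample_id, "country": m.country, "y_acq": m.y_acq,
          "y_last": m.y_last, "r": m.r, "rin": m.rin} for m in meta]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def _precheck_vcf(path: str) -> None:
    # cyvcf2/htslib error messages are terse; surface the offending header
    # line ourselves for the common failure modes.
    with open(path, "rt") as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(
                f"{path}: line 1 is not a '##fileformat=VCF...' header: {first.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if cols[:8] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                "FILTER", "INFO"]:
                    raise VcfParseError(
                        f"{path}: malformed #CHROM header at line {lineno}")
                return
            raise VcfParseError(
                f"{path}: expected '#CHROM' header before data at line {lineno}")
    raise VcfParseError(f"{path}: no '#CHROM' column header line found")


def read_vcf(path: str | os.PathLike) -> RawVariantTable:
    """Read a VCF v4.x into a :class:`RawVariantTable`.

    One record per data line; indel and multi-allelic records are retained
    (flagged via ``is_snp`` / ``alts``) so that filtering can attribute them.
    Half-calls (e.g. ``./1``) are recorded as missing. A record without a GT
    field raises :class:`VcfParseError`.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    _precheck_vcf(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - htslib-level failure
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc

    samples = list(vcf.samples)
    chrom, pos, ref, alts, qual, snp = [], [], [], [], [], []
    gts, dps = [], []
    saw_dp = False
    for i, var in enumerate(vcf):
        if "GT" not in var.FORMAT:
            raise VcfParseError(
                f"{path}: record {var.CHROM}:{var.POS} has no GT FORMAT field")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt_list = tuple(var.ALT)
        alts.append(alt_list)
        qual.append(np.nan if var.QUAL is None else float(var.QUAL))
        snp.append(len(var.REF) == 1 and len(alt_list) >= 1
                   and all(len(a) == 1 and a in "ACGTacgt" for a in alt_list))
        # derive genotype state from raw allele indices: any -1 allele or any
        # allele index > 1 at a biallelic reading is handled downstream;
        # state = allele-count of non-reference alleles when both calls known.
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a = g[:-1]  # last element is the phasing flag
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                continue  # half-call / missing / haploid -> missing
            row[j] = int(a[0] != 0) + int(a[1] != 0)
        gts.append(row)
        try:
            dp = var.format("DP")
        except KeyError:  # DP absent from the FORMAT header entirely
            dp = None
        if dp is not None:
            saw_dp = True
            dps.append(dp.reshape(-1).astype(np.int32))
        else:
            dps.append(np.full(len(samples), -1, dtype=np.int32))

    n = len(pos)
    table = RawVariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alts=alts,
        qual=np.array(qual, dtype=float),
        genotypes=(np.vstack(gts) if n else np.empty((0, len(samples)), np.int8)),
        dp=(np.vstack(dps) if (n and saw_dp) else None),
        samples=samples,
        is_snp=np.array(snp, dtype=bool),
    )
    logger.info("read_vcf: %d records, %d samples from %s", n, len(samples), path)
    return table


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_variants(raw: RawVariantTable | VariantSet,
                    min_dp: int = 10,
                    min_qual: float = 20.0,
                    require_complete: bool = True) -> VariantSet:
    """Apply site/genotype quality filters and return a complete VariantSet.

    Rules, in ledger order: (1) non-SNP (indel) sites dropped; (2) sites with
    more than one ALT dropped; (3) sites with QUAL < ``min_qual`` dropped
    (absent QUAL fails); (4) genotype calls with DP < ``min_dp`` are set
    missing, and — when ``require_complete`` — any site retaining a missing
    call is dropped. ``min_dp=0`` disables the depth requirement, so DP-less
    input loses nothing to rule 4 except genuinely missing calls.

    Filtering is idempotent: an already-filtered :class:`VariantSet` passes
    through unchanged (aside from a fresh ledger).
    """
    if isinstance(raw, VariantSet):
        # a VariantSet is complete and depth-free; the DP rule is vacuous
        min_dp = 0
        raw = RawVariantTable(
            chrom=raw.chrom, pos=raw.pos, ref=raw.ref,
            alts=[(a,) for a in raw.alt],
            qual=np.full(raw.n_sites, np.inf),
            genotypes=raw.genotypes, dp=None, samples=raw.samples,
            is_snp=np.ones(raw.n_sites, dtype=bool))

    ledger = FilterLedger(n_input=raw.n_sites)
    n_alts = np.array([len(a) for a in raw.alts], dtype=int)

    fail_indel = ~raw.is_snp
    fail_multi = ~fail_indel & (n_alts != 1)
    if min_qual > 0:
        # absent QUAL (".") cannot vouch for the site and fails the rule
        with np.errstate(invalid="ignore"):
            qual_ok = (raw.qual >= min_qual) & ~np.isnan(raw.qual)
    else:
        qual_ok = np.ones(raw.n_sites, dtype=bool)
    fail_qual = ~fail_indel & ~fail_multi & ~qual_ok

    geno = raw.genotypes.copy()
    if min_dp > 0:
        if raw.dp is None:
            # conservative: depth unknown -> genotype cannot be trusted
            geno[:] = MISSING
        else:
            geno[raw.dp < min_dp] = MISSING
    missing_any = (geno == MISSING).any(axis=1) if geno.size else \
        np.zeros(raw.n_sites, dtype=bool)
    candidate = ~(fail_indel | fail_multi | fail_qual)
    fail_missing = candidate & missing_any if require_complete else \
        np.zeros(raw.n_sites, dtype=bool)
    keep = candidate & ~fail_missing

    ledger.dropped_indel = int(fail_indel.sum())
    ledger.dropped_multiallelic = int(fail_multi.sum())
    ledger.dropped_qual = int(fail_qual.sum())
    ledger.dropped_missing = int(fail_missing.sum())
    ledger.surviving = int(keep.sum())
    ledger.check()
    logger.info("filter_variants: %s", ledger)

    if ledger.surviving == 0:
        warnings.warn("no sites survive filtering; returning empty VariantSet",
                      stacklevel=2)

    vs = VariantSet(
        chrom=raw.chrom[keep],
        pos=raw.pos[keep],
        ref=raw.ref[keep],
        alt=np.array([raw.alts[i][0] for i in np.flatnonzero(keep)], dtype=object),
        genotypes=geno[keep],
        samples=list(raw.samples),
        ledger=ledger,
    )
    if require_complete:
        vs.validate()
    return vs


# ---------------------------------------------------------------------------
# VCF / TSV output
# ---------------------------------------------------------------------------

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(vs: VariantSet, path: str | os.PathLike) -> None:
    """Write a VariantSet as a minimal uncompressed VCF v4.2."""
    path = os.fspath(path)
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(vs.chrom):  # preserve first-seen order
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vs.samples) + "\n")
        for i in range(vs.n_sites):
            calls = "\t".join(_GT_STR[g] for g in vs.genotypes[i])
            fh.write(f"{vs.chrom[i]}\t{vs.pos[i]}\t.\t{vs.ref[i]}\t{vs.alt[i]}"
                     f"\t.\t.\t.\tGT\t{calls}\n")


def write_ledger(ledger: FilterLedger, path: str | os.PathLike) -> None:
    ledger.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# accession metadata
# ---------------------------------------------------------------------------

_ELAPSED_COLS = {"years_since_acquisition": "y_acq",
                 "years_since_regeneration": "y_last"}
_CALENDAR_COLS = {"year_acquired", "year_last_regeneration"}


def read_metadata(path: str | os.PathLike,
                  reference_year: int | None = None) -> list[AccessionMetadata]:
    """Read a per-accession metadata TSV and validate every row.

    Two dialects are accepted. Elapsed: columns ``years_since_acquisition`` /
    ``years_since_regeneration``. Calendar: columns ``year_acquired`` /
    ``year_last_regeneration`` converted to elapsed years against
    ``reference_year`` (the assay year; e.g. seed received in 2022). Both need
    ``sample_id``, ``country``, ``regeneration_cycles`` and ``rin``.
    Invariant violations are reported with their row numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    cols = set(df.columns)
    required = {"sample_id", "country", "regeneration_cycles", "rin"}
    if not required <= cols:
        raise MetadataError(f"metadata missing columns: {sorted(required - cols)}")

    if _CALENDAR_COLS <= cols:
        if reference_year is None:
            raise MetadataError(
                "calendar-year metadata requires reference_year (the assay year)")
        y_acq = reference_year - df["year_acquired"]
        y_last = reference_year - df["year_last_regeneration"]
    elif set(_ELAPSED_COLS) <= cols:
        y_acq = df["years_since_acquisition"]
        y_last = df["years_since_regeneration"]
    else:
        raise MetadataError(
            "metadata must carry either calendar-year or elapsed-year columns")

    out: list[AccessionMetadata] = []
    errors: list[str] = []
    for idx in df.index:
        try:
            m = AccessionMetadata(
                sample_id=str(df.at[idx, "sample_id"]),
                country=str(df.at[idx, "country"]),
                y_acq=int(y_acq[idx]),
                y_last=int(y_last[idx]),
                r=int(df.at[idx, "regeneration_cycles"]),
                rin=float(df.at[idx, "rin"]),
            )
            m.validate()
            out.append(m)
        except (MetadataError, ValueError, TypeError) as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise MetadataError("invalid metadata rows:\n" + "\n".join(errors))
    return out


def write_metadata(meta: list[AccessionMetadata], path: str | os.PathLike) -> None:
    df = metadata_frame(meta).reset_index()
    df = df.rename(columns={"y_acq": "years_since_acquisition",
                            "y_last": "years_since_regeneration",
                            "r": "regeneration_cycles"})
    df.to_csv(path, sep="\t", index=False)
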