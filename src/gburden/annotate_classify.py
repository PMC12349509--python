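"""Deleterious classification from SIFT and GERP++ RS scores.

A SNP is called deleterious (a "dSNP") when its amino-acid substitution is
predicted damaging by SIFT (score <= 0.05, normal confidence) *and* it falls
at an evolutionarily constrained site (GERP++ rejected-substitution score
strictly positive). dSNPs are binned by RS into weakly (< 1), mildly ([1, 3])
and highly (> 3) detrimental. Consequence-class tallies over the closed
VEP-style vocabulary (16 classes, one most-severe class per SNP) provide the
annotation summary, including the loss-of-function aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gburden")

KEY_COLS = ["chrom", "pos", "ref", "alt"]

#: the closed most-severe-consequence vocabulary (VEP-style)
CONSEQUENCE_CLASSES: tuple[str, ...] = (
    "missense_variant",
    "synonymous_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_region_variant",
    "stop_retained_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

#: classes aggregated as loss-of-function: the three stop_, three splice_ and start_lost
LOF_CLASSES: frozenset[str] = frozenset({
    "stop_gained", "stop_lost", "stop_retained_variant",
    "splice_acceptor_variant", "splice_donor_variant",
    "splice_region_variant", "start_lost",
})

SEVERITY_LEVELS = ("weak", "mild", "high")

ANNOTATION_COLUMNS = KEY_COLS + ["gene_id", "consequence",
                                 "sift_score", "sift_confidence", "rs_score"]


class VocabularyError(ValueError):
    """Raised when a consequence label is outside the closed vocabulary."""


def read_annotation(path) -> pd.DataFrame:
    """Read a per-variant annotation TSV (one row per variant key).

    Expected columns: chrom, pos, ref, alt, gene_id, consequence, sift_score,
    sift_confidence ("normal"/"low_confidence"), rs_score. Absent scores may
    be empty cells (NaN).
    """
    ann = pd.read_csv(path, sep="\t",
                      dtype={"chrom": str, "ref": str, "alt": str,
                             "gene_id": str, "sift_confidence": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann.duplicated(KEY_COLS).any():
        dup = ann.loc[ann.duplicated(KEY_COLS), KEY_COLS].head()
        raise ValueError(f"duplicate variant keys in annotation, e.g.\n{dup}")
    unknown = set(ann["consequence"]) - set(CONSEQUENCE_CLASSES)
    if unknown:
        raise VocabularyError(
            f"unknown consequence class label(s): {sorted(unknown)}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def bin_severity(rs: float | np.ndarray) -> np.ndarray | str:
    """Bin a deleterious variant's RS score into weak / mild / high.

    weak: RS < 1; mild: 1 <= RS <= 3; high: RS > 3. Only defined for
    positive RS (a deleterious call requires RS > 0).
    """
    arr = np.asarray(rs, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("bin_severity requires RS > 0 (deleterious variants only)")
    out = np.where(arr < 1.0, "weak", np.where(arr <= 3.0, "mild", "high"))
    return out.item() if np.isscalar(rs) or arr.ndim == 0 else out


def classify_deleterious(ann: pd.DataFrame,
                         sift_max: float = 0.05,
                         rs_min: float | None = 0.0,
                         exclude_low_confidence: bool = True) -> pd.DataFrame:
    """Identify deleterious SNPs by the combined SIFT + RS rule.

    A variant is deleterious iff ``sift_score <= sift_max``, its SIFT call is
    not low-confidence (when ``exclude_low_confidence``), and
    ``rs_score > rs_min``. Variants lacking either required score are never
    deleterious. ``rs_min=None`` drops the constraint filter entirely
    (SIFT-only classification, e.g. for the annotation-summary tally).

    Returns the deleterious subset with variant keys, ``gene_id`` and
    ``severity`` (RS bins; only when the RS filter is active).
    """
    sift = pd.to_numeric(ann["sift_score"], errors="coerce")
    keep = sift.notna() & (sift <= sift_max)
    if exclude_low_confidence:
        keep &= ann["sift_confidence"].fillna("normal") != "low_confidence"
    if rs_min is not None:
        rs = pd.to_numeric(ann["rs_score"], errors="coerce")
        keep &= rs.notna() & (rs > rs_min)
    dset = ann.loc[keep, KEY_COLS + ["gene_id", "rs_score"]].copy()
    if rs_min is not None and len(dset):
        dset["severity"] = bin_severity(dset["rs_score"].to_numpy(dtype=float))
    else:
        dset["severity"] = pd.Series(dtype=object)
    logger.info("classify_deleterious: %d of %d variants deleterious "
                "(sift_max=%s, rs_min=%s)", len(dset), len(ann), sift_max, rs_min)
    return dset.reset_index(drop=True)


def intersect_dsnp_sets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersect two deleterious sets by variant key.

    Severity is taken from ``a``; rows where the two sets disagree on the bin
    are flagged in the ``severity_conflict`` column.
    """
    merged = a.merge(b[KEY_COLS + ["severity"]], on=KEY_COLS, how="inner",
                     suffixes=("", "_b"))
    merged["severity_conflict"] = (
        merged["severity"].notna() & merged["severity_b"].notna()
        & (merged["severity"] != merged["severity_b"]))
    n_conflict = int(merged["severity_conflict"].sum())
    if n_conflict:
        logger.warning("intersect_dsnp_sets: %d severity-bin conflicts", n_conflict)
    return merged.drop(columns=["severity_b"])


# ---------------------------------------------------------------------------
# consequence tally
# ---------------------------------------------------------------------------

@dataclass
class ConsequenceTally:
    """Counts and proportions per consequence class, plus the LoF aggregate."""

    counts: dict[str, int]
    total: int
    proportions: dict[str, float] = field(init=False)
    lof_count: int = field(init=False)
    lof_proportion: float = field(init=False)

    def __post_init__(self):
        self.proportions = {c: (n / self.total if self.total else 0.0)
                            for c, n in self.counts.items()}
        self.lof_count = sum(self.counts.get(c, 0) for c in LOF_CLASSES)
        self.lof_proportion = self.lof_count / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "consequence": list(self.counts),
            "count": list(self.counts.values()),
            "proportion": [self.proportions[c] for c in self.counts],
        })


def tally_consequences(ann: pd.DataFrame) -> ConsequenceTally:
    """Tally most-severe consequence classes over the closed vocabulary."""
    validate_annotation(ann)
    vc = ann["consequence"].value_counts()
    counts = {c: int(vc.get(c, 0)) for c in CONSEQUENCE_CLASSES}
    return ConsequenceTally(counts=counts, total=int(len(ann)))
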