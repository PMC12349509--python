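"""Forward-in-time simulator of selfing germplasm under genebank conservation.

The generative model follows the life of one conserved accession. Seeds sit
in cold storage, where each reference allele copy at a mutable site mutates
to the deleterious state with a small probability per year (``mu_storage``).
At each regeneration a plant is grown and selfed: every heterozygous site
segregates Mendelianly (het -> 1/4 hom_ref, 1/2 het, 1/4 hom_alt),
transmitted reference alleles acquire new mutations at the per-generation
gametic rate ``mu_regen`` (a regeneration is a full plant generation, hence
far more DNA replication than frozen storage), and the resulting seed
survives viability selection with fitness
w = prod_sites (1 - s_i)^[hom] * (1 - h*s_i)^[het]. The accession continues
by single-seed descent: one surviving seed becomes the next stored
generation.

Selection in this setting has a sharp structural consequence: a site
homozygous in the parent is homozygous in every selfed offspring, so
within-family selection can never remove it — purging acts only at
segregating (heterozygous) sites, by biasing their resolution away from the
deleterious homozygote. The deleterious-capable sites therefore come in two
classes:

* **legacy** sites (a small fraction) carry the standing variation the
  accession brought into the bank. By survivorship these alleles have
  attenuated fitness effects (``s_legacy``, near zero) — that is why they
  segregate at appreciable frequency at all — and they supply the static
  homozygous load. Under an infinite-sites rule they receive no further
  mutation.
* **active** sites start empty and are populated by storage and
  regeneration mutations. Their fitness cost (``s``, near one) makes the
  deleterious homozygote almost inviable, so fresh mutations accumulate as
  heterozygotes and are purged when selfing exposes them.

Consequences, mirrored in conserved selfing collections: heterozygous load
equilibrates at m / (1 - P(het|survive)) where m is the per-cycle mutation
input, so it *rises* with the number of completed regenerations and
saturates; homozygous load stays at the legacy level, flat across cycles.
Default parameters are calibrated to those equilibria so simulated
per-sample burdens match a seed-assayed soybean collection (B_het ~ 0.015,
B_hom ~ 0.036, B_tot ~ 0.051 at L = 588 deleterious loci); mutation rates
are deliberately inflated far above per-base biological rates to give
desk-scale signal at a few hundred loci and make no claim of per-site
realism. Functional severity (the RS score bin) is assigned independently
of the fitness class: a variant deleterious to gene function need not be
proportionally deleterious to whole-plant fitness.

The generator emits everything the analysis pipeline consumes: a genotype
VariantSet (segregating sites only, as a SNP caller would report), a SIFT/RS
annotation table with decoy classes, accession metadata with realistic
conservation covariates, a TPM matrix plus RIN values with a specified
correlation structure to burden, and a truth record for parameter-recovery
tests.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotate_classify import ANNOTATION_COLUMNS, classify_deleterious
from .association import AssociationResult, regress
from .burden_stats import compute_burdens
from .variant_io import (AccessionMetadata, HET, HOM_ALT, HOM_REF, VariantSet,
                         metadata_frame, write_metadata, write_vcf)

logger = logging.getLogger("gburden")


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnnotationModel:
    """Score-mixture parameters for the simulated annotation table.

    Deleterious sites get SIFT ~ U(0, 0.05) at normal confidence and RS > 0
    drawn from the weak/mild/high severity mixture. Decoys exercise each
    branch of the classifier: tolerated (SIFT > 0.05), SIFT-deleterious but
    unconstrained (RS <= 0), low-confidence SIFT calls, and non-missense
    classes with no SIFT score at all.
    """

    n_tolerated: int = 300
    n_sift_only: int = 60          # SIFT <= 0.05 but RS <= 0
    n_low_confidence: int = 25
    n_other: int = 300             # non-missense consequence classes
    severity_props: tuple[float, float, float] = (0.077, 0.811, 0.112)
    sift_deleterious_max: float = 0.05


@dataclass
class ExpressionModel:
    """Coefficients linking burden and RIN to the expression outputs.

    RIN declines with years since the last regeneration (RNA degrades in
    storage); expressed gene count falls with total burden and rises with
    RIN; mean TPM does the opposite. Coefficients act on z-scores of the
    true total burden and the realised RIN.
    """

    n_genes: int = 175
    n_core_genes: int = 119        # expressed in every sample
    count_base: float = 155.0
    count_burden_coef: float = -2.5
    count_rin_coef: float = 2.0
    count_noise_sd: float = 3.0
    tpm_base: float = 13.2
    tpm_burden_coef: float = 0.6
    tpm_rin_coef: float = -0.8
    tpm_noise_sd: float = 1.5
    rin_base: float = 8.6
    rin_ylast_coef: float = 0.06   # RIN units lost per storage year
    rin_noise_sd: float = 0.35


@dataclass
class SimConfig:
    """Generative parameters of the conservation simulator.

    Defaults sit at the selfing-purging equilibria that reproduce the
    seed-assay burden means (see module docstring): with s = 0.99, h = 0.02
    the per-cycle het retention is P(het|survive) ~ 0.66, so the het
    equilibrium is m / 0.34 ~ 17.6 loci at m = 2 * mu_regen * n_active ~ 6;
    the homozygous load is the legacy standing level,
    legacy_frac * l_sites * legacy_freq_mean ~ 21 loci.
    """

    n_samples: int = 190
    l_sites: int = 588                 # deleterious-capable sites
    mu_storage: float = 5e-5           # per allele copy, per storage year
    mu_regen: float = 5.8e-3           # per allele copy, per regeneration
    s: float = 0.99                    # selection vs fresh deleterious homozygote
    h: float = 0.02                    # dominance (het fitness = 1 - h*s_i)
    s_legacy: float = 0.02             # attenuated selection at legacy sites
    legacy_frac: float = 0.12          # fraction of deleterious sites that are legacy
    legacy_freq_mean: float = 0.30     # mean legacy deleterious-allele frequency
    legacy_freq_conc: float = 2.0      # Beta concentration of legacy frequencies
    neutral_freq_mean: float = 0.035   # background frequency at neutral sites
    neutral_freq_conc: float = 3.0
    background_het: float = 0.01       # residual heterozygosity at acquisition
    n_regen: int = 20                  # plants grown per regeneration
    reference_year: int = 2022
    acq_year_range: tuple[int, int] = (1972, 2004)
    y_last_range: tuple[int, int] = (4, 25)
    max_regen_cycles: int = 10
    mode: str = "single_seed"          # or "pooled"
    rejection_cap: int = 200_000       # candidate seeds per survivor slot
    seed: int = 0
    annotation_model: AnnotationModel = field(default_factory=AnnotationModel)
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)

    def validate(self) -> None:
        if not (0.0 <= self.mu_storage <= 1.0 and 0.0 <= self.mu_regen <= 1.0):
            raise ValueError("mutation probabilities must lie in [0, 1]")
        for s in (self.s, self.s_legacy):
            if not (0.0 <= self.h * s <= s <= 1.0):
                raise ValueError("need 0 <= h*s <= s <= 1")
        if not (0.0 <= self.legacy_frac <= 1.0):
            raise ValueError("legacy_frac must lie in [0, 1]")
        if self.n_regen < 1:
            raise ValueError("n_regen must be >= 1")
        if self.mode not in ("single_seed", "pooled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lo, hi = self.acq_year_range
        if hi >= self.reference_year or lo > hi:
            raise ValueError("acquisition years must precede the reference year")
        if self.y_last_range[0] < 1 or self.y_last_range[0] > self.y_last_range[1]:
            raise ValueError("invalid y_last_range")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("annotation_model"), dict):
            d["annotation_model"] = AnnotationModel(**d["annotation_model"])
        if isinstance(d.get("expression_model"), dict):
            d["expression_model"] = ExpressionModel(**d["expression_model"])
        for k in ("acq_year_range", "y_last_range", "severity_props"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SiteModel:
    """Per-site generative parameters shared by all accessions of a run."""

    frame: pd.DataFrame        # chrom, pos, ref, alt, role, fitness_class
    p_bg: np.ndarray           # initial deleterious-allele frequency
    s_site: np.ndarray         # per-site selection coefficient (0 = neutral)
    mut_mask: np.ndarray       # sites open to new mutation (infinite-sites rule)

    @property
    def n_sites(self) -> int:
        return len(self.p_bg)

    @property
    def sel_mask(self) -> np.ndarray:
        return (self.frame["role"] == "deleterious").to_numpy()


@dataclass
class SimOutput:
    """Everything one simulated collection provides to the pipeline."""

    variant_set: VariantSet
    annotation: pd.DataFrame
    metadata: list[AccessionMetadata]
    tpm: pd.DataFrame
    truth: pd.DataFrame            # per-accession true n_het/n_hom and covariates
    trajectories: dict[str, pd.DataFrame]
    config: SimConfig

    def metadata_frame(self) -> pd.DataFrame:
        return metadata_frame(self.metadata)


# ---------------------------------------------------------------------------
# core dynamics
# ---------------------------------------------------------------------------

def storage_mutation_step(geno: np.ndarray, mu: float, mut_mask: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """One year of storage mutation at the mutable sites.

    Each reference allele copy independently mutates with probability
    ``mu``: hom_ref -> het w.p. 2*mu*(1-mu) (or -> hom_alt w.p. mu^2),
    het -> hom_alt w.p. mu. Mutation is irreversible and, by the
    infinite-sites rule, never strikes legacy sites.
    """
    if mu == 0.0:
        return geno
    out = geno.copy()
    sub = geno[..., mut_mask]
    u = rng.random(sub.shape)
    new = sub.copy()
    ref = sub == HOM_REF
    new[ref & (u < mu * mu)] = HOM_ALT
    new[ref & (u >= mu * mu) & (u < mu * mu + 2 * mu * (1 - mu))] = HET
    new[(sub == HET) & (u < mu)] = HOM_ALT
    out[..., mut_mask] = new
    return out


def selfing_offspring(parent: np.ndarray, mu_regen: float, n: int,
                      rng: np.random.Generator,
                      mut_mask: np.ndarray | None = None) -> np.ndarray:
    """Draw ``n`` selfed offspring genotype vectors from one parent.

    Reference implementation used as the oracle for the fast regeneration
    path: per site, each of the two transmitted alleles is deleterious with
    probability mu (parent hom_ref), (1+mu)/2 (het) or 1 (hom_alt); sites
    outside ``mut_mask`` transmit without mutation.
    """
    p = np.empty(parent.shape, dtype=float)
    mu_site = np.full(parent.shape, mu_regen)
    if mut_mask is not None:
        mu_site[~mut_mask] = 0.0
    p[parent == HOM_REF] = mu_site[parent == HOM_REF]
    p[parent == HET] = 0.5 * (1.0 + mu_site[parent == HET])
    p[parent == HOM_ALT] = 1.0
    alleles = rng.random((n, 2, parent.size)) < p
    return alleles.sum(axis=1).astype(np.int8)


def regenerate_single_seed(parent: np.ndarray, sm: SiteModel, h: float,
                           mu_regen: float, rng: np.random.Generator,
                           rejection_cap: int = 200_000,
                           batch: int = 256) -> np.ndarray:
    """Draw one viable selfed seed from ``parent`` by rejection sampling.

    A candidate survives with probability
    w = prod (1-s_i)^[hom] * (1-h*s_i)^[het]. Because surviving seeds are
    i.i.d., one accepted seed is distributionally identical to "grow
    n_regen survivors and pick one uniformly". The cap bounds total
    candidate draws; breach (or a parent locked homozygous for a lethal
    allele, where every offspring has w = 0) raises, advising weaker
    selection.

    Candidates differ from the parent only at heterozygous sites and at
    fresh-mutation sites, so only those are drawn: het sites resolve with
    probabilities ((1-a)^2, 2a(1-a), a^2), a = (1+mu)/2 at mutable sites;
    new mutations at homozygous-reference mutable sites arrive as
    per-candidate binomial counts (exactly equivalent to per-site Bernoulli
    draws) and land on uniformly chosen sites once a candidate is accepted.

    Fitness factors from the parent's fixed (homozygous) load are identical
    for every selfed offspring; they scale absolute viability but cancel in
    the conditional distribution of the surviving seed, so the acceptance
    weight uses fitness relative to the best possible offspring. (A genebank
    keeps sowing until a seed establishes.)
    """
    s_site, mut_mask = sm.s_site, sm.mut_mask
    locked_hom = np.flatnonzero(parent == HOM_ALT)
    if np.any(s_site[locked_hom] >= 1.0):
        raise SimulationError(
            "parent is homozygous for a lethal allele: every candidate seed "
            "has survival probability 0; reduce s")

    het_idx = np.flatnonzero(parent == HET)
    nh = het_idx.size
    a = np.where(mut_mask[het_idx], 0.5 * (1.0 + mu_regen), 0.5)
    p0 = (1.0 - a) ** 2
    p1 = 2.0 * a * (1.0 - a)
    log_het = np.log1p(-h * s_site[het_idx])
    with np.errstate(divide="ignore"):
        log_hom = np.where(s_site[het_idx] >= 1.0, -np.inf,
                           np.log1p(-np.minimum(s_site[het_idx], 1.0)))

    # fresh mutations at hom_ref mutable sites, grouped by fitness class
    # (selection coefficients are constant within a class, so counts suffice
    # for the fitness weight; site identities are drawn after acceptance)
    ref_mut = np.flatnonzero((parent == HOM_REF) & mut_mask)
    classes = []
    for s_val in np.unique(s_site[ref_mut]) if ref_mut.size else []:
        idx = ref_mut[s_site[ref_mut] == s_val]
        classes.append((float(s_val), idx))
    p_het_new = 2.0 * mu_regen * (1.0 - mu_regen)
    p_hom_new = mu_regen * mu_regen

    tries = 0
    while tries < rejection_cap:
        b = min(batch, rejection_cap - tries)
        tries += b
        u = rng.random((b, nh))
        res = np.where(u < p0, HOM_REF,
                       np.where(u < p0 + p1, HET, HOM_ALT)).astype(np.int8)
        logw = (res == HET) @ log_het
        hom_draw = res == HOM_ALT
        if np.isneginf(log_hom).any():
            logw = np.where((hom_draw & np.isneginf(log_hom)).any(axis=1),
                            -np.inf, logw + hom_draw @ np.where(
                                np.isneginf(log_hom), 0.0, log_hom))
        else:
            logw = logw + hom_draw @ log_hom
        new_counts = []
        for s_val, idx in classes:
            k_het = rng.binomial(idx.size, p_het_new, size=b)
            k_hom = rng.binomial(idx.size, p_hom_new, size=b)
            new_counts.append((k_het, k_hom))
            if s_val > 0:
                logw = logw + k_het * np.log1p(-h * s_val)
                if s_val >= 1.0:
                    logw = np.where(k_hom > 0, -np.inf, logw)
                else:
                    logw = logw + k_hom * np.log1p(-s_val)
        with np.errstate(divide="ignore"):
            ok = np.log(rng.random(b)) < logw
        hits = np.flatnonzero(ok)
        if hits.size == 0:
            continue
        pick = hits[0]
        child = parent.copy()
        child[het_idx] = res[pick]
        for (s_val, idx), (k_het, k_hom) in zip(classes, new_counts):
            k1, k2 = int(k_het[pick]), int(k_hom[pick])
            if k1 + k2:
                chosen = rng.choice(idx, size=k1 + k2, replace=False)
                child[chosen[:k1]] = HET
                child[chosen[k1:]] = HOM_ALT
        return child
    raise SimulationError(
        f"no viable seed within {rejection_cap} candidates; "
        "reduce s or the number of deleterious loci")


def regenerate_pooled(plants: np.ndarray, sm: SiteModel, h: float,
                      mu_regen: float, rng: np.random.Generator,
                      n_regen: int, rejection_cap: int = 200_000) -> np.ndarray:
    """One regeneration in pooled mode: ``n_regen`` surviving seeds.

    Each seed selfs from a uniformly drawn parent plant of the previous
    generation (a selfing stand) and passes viability selection; within-
    accession allele frequencies can therefore respond to selection across
    plants, the Schoen-style contrast to single-seed descent.
    """
    out = np.empty((n_regen, plants.shape[1]), dtype=np.int8)
    for k in range(n_regen):
        parent = plants[rng.integers(plants.shape[0])]
        out[k] = regenerate_single_seed(parent, sm, h, mu_regen, rng,
                                        rejection_cap)
    return out


# ---------------------------------------------------------------------------
# schedules and accessions
# ---------------------------------------------------------------------------

@dataclass
class Schedule:
    """One accession's conservation timeline, in years before the assay."""

    y_acq: int
    y_last: int
    r: int
    regen_times: tuple[int, ...]   # strictly decreasing, last == y_last

    def validate(self) -> None:
        if self.r != len(self.regen_times):
            raise ValueError("regen count does not match schedule")
        if self.r == 0:
            if self.y_last != self.y_acq:
                raise ValueError("unregenerated accession must have y_last == y_acq")
        else:
            if self.regen_times[-1] != self.y_last:
                raise ValueError("last regeneration time must equal y_last")
            if max(self.regen_times) >= self.y_acq or min(self.regen_times) < 1:
                raise ValueError("regeneration times must fall inside conservation span")
            if list(self.regen_times) != sorted(self.regen_times, reverse=True):
                raise ValueError("regeneration times must be strictly decreasing")


def draw_schedule(cfg: SimConfig, rng: np.random.Generator) -> Schedule:
    """Draw one accession's schedule with the study's covariate structure.

    Acquisition years are uniform over the collection's span; the number of
    completed cycles rises with time in the bank (older accessions have been
    regenerated more), and the last regeneration falls 4-25 years before the
    assay. This induces the positive cycles-by-acquisition-age correlation a
    real genebank shows.
    """
    lo, hi = cfg.acq_year_range
    y_acq = int(cfg.reference_year - rng.integers(lo, hi + 1))
    span = cfg.reference_year - lo - 4  # oldest possible conservation span
    p_regen = min(0.95, max(0.05, (y_acq - 14) / span))
    r = int(min(rng.binomial(cfg.max_regen_cycles, p_regen), cfg.max_regen_cycles))
    yl_lo, yl_hi = cfg.y_last_range
    if r == 0 and y_acq > yl_hi:
        r = 1  # accessions old enough must have been regenerated at least once
    if r == 0:
        return Schedule(y_acq=y_acq, y_last=y_acq, r=0, regen_times=())
    y_last = int(rng.integers(yl_lo, min(yl_hi, y_acq - r) + 1))
    earlier = rng.choice(np.arange(y_last + 1, y_acq), size=r - 1, replace=False)
    times = tuple(sorted([*earlier.tolist(), y_last], reverse=True))
    sched = Schedule(y_acq=y_acq, y_last=y_last, r=r, regen_times=times)
    sched.validate()
    return sched


def initial_genotype(sm: SiteModel, het_prob: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Genotype of the accession's founding seed at acquisition.

    Donated germplasm is near-fully selfed: per site, homozygous deleterious
    with the site's background frequency, residually heterozygous with a
    small constant probability, else homozygous reference.
    """
    u = rng.random(sm.n_sites)
    geno = np.zeros(sm.n_sites, dtype=np.int8)
    geno[u < sm.p_bg] = HOM_ALT
    geno[(u >= sm.p_bg) & (u < sm.p_bg + het_prob)] = HET
    return geno


def simulate_accession(cfg: SimConfig, schedule: Schedule, sm: SiteModel,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one accession from acquisition to the assay year.

    Returns the assayed seed's genotype over all sites and a trajectory
    table of deleterious-site het/hom counts (one row per year, after any
    regeneration that year).
    """
    sel = sm.sel_mask
    geno = initial_genotype(sm, cfg.background_het, rng)
    if cfg.mode == "pooled":
        plants = np.repeat(geno[None, :], cfg.n_regen, axis=0)
    regen_at = set(schedule.regen_times)

    years, hets, homs = [], [], []

    def record(t):
        g = geno if cfg.mode == "single_seed" else plants[0]
        years.append(t)
        hets.append(int((g[sel] == HET).sum()))
        homs.append(int((g[sel] == HOM_ALT).sum()))

    record(schedule.y_acq)
    for t in range(schedule.y_acq, 0, -1):  # t = years before assay
        if cfg.mode == "single_seed":
            geno = storage_mutation_step(geno, cfg.mu_storage, sm.mut_mask, rng)
            if t in regen_at:
                geno = regenerate_single_seed(geno, sm, cfg.h, cfg.mu_regen,
                                              rng, cfg.rejection_cap)
        else:
            plants = storage_mutation_step(plants, cfg.mu_storage, sm.mut_mask, rng)
            if t in regen_at:
                plants = regenerate_pooled(plants, sm, cfg.h, cfg.mu_regen,
                                           rng, cfg.n_regen, cfg.rejection_cap)
        record(t - 1)

    if cfg.mode == "pooled":
        geno = plants[rng.integers(plants.shape[0])]  # the assayed seed
    traj = pd.DataFrame({"years_before_assay": years, "n_het": hets,
                         "n_hom": homs})
    return geno, traj


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

_OTHER_CLASSES = ("synonymous_variant", "5_prime_UTR_variant",
                  "3_prime_UTR_variant", "intron_variant",
                  "upstream_gene_variant", "downstream_gene_variant",
                  "non_coding_transcript_exon_variant", "intergenic_variant")


def build_site_model(cfg: SimConfig, rng: np.random.Generator) -> SiteModel:
    """Draw site coordinates, roles, fitness classes and background frequencies."""
    am = cfg.annotation_model
    n_total = (cfg.l_sites + am.n_tolerated + am.n_sift_only
               + am.n_low_confidence + am.n_other)
    chrom_idx = rng.integers(0, 20, size=n_total)
    pos = np.zeros(n_total, dtype=np.int64)
    for c in range(20):
        idx = np.flatnonzero(chrom_idx == c)
        pos[idx] = np.cumsum(rng.integers(500, 200_000, size=idx.size)) + 1000
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_total)]
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])

    roles = np.array(
        ["deleterious"] * cfg.l_sites + ["tolerated"] * am.n_tolerated
        + ["sift_only"] * am.n_sift_only
        + ["low_confidence"] * am.n_low_confidence + ["other"] * am.n_other)
    n_legacy = int(round(cfg.legacy_frac * cfg.l_sites))
    fitness_class = np.where(roles == "deleterious", "active", "neutral")
    fitness_class[:n_legacy] = "legacy"     # first n_legacy are deleterious
    order = rng.permutation(n_total)
    roles, fitness_class = roles[order], fitness_class[order]

    p_bg = np.zeros(n_total)
    legacy = fitness_class == "legacy"
    neutral = fitness_class == "neutral"
    mean, conc = cfg.legacy_freq_mean, cfg.legacy_freq_conc
    p_bg[legacy] = rng.beta(mean / (1 - mean) * conc, conc, legacy.sum())
    mean, conc = cfg.neutral_freq_mean, cfg.neutral_freq_conc
    p_bg[neutral] = rng.beta(mean / (1 - mean) * conc, conc, neutral.sum())

    s_site = np.zeros(n_total)
    s_site[fitness_class == "active"] = cfg.s
    s_site[legacy] = cfg.s_legacy

    frame = pd.DataFrame({
        "chrom": [f"Gm{c + 1:02d}" for c in chrom_idx[order]],
        "pos": pos[order], "ref": ref[order], "alt": alt[order],
        "role": roles, "fitness_class": fitness_class})
    return SiteModel(frame=frame, p_bg=p_bg, s_site=s_site,
                     mut_mask=~legacy)


def _make_annotation(cfg: SimConfig, sm: SiteModel,
                     rng: np.random.Generator) -> pd.DataFrame:
    am = cfg.annotation_model
    sites = sm.frame
    n = len(sites)
    gene_no = rng.integers(1, max(2, cfg.l_sites), size=n)
    ann = sites[["chrom", "pos", "ref", "alt"]].copy()
    ann["gene_id"] = [f"Glyma.{c[2:]}g{g:06d}"
                      for c, g in zip(sites["chrom"], gene_no)]
    consequence = np.empty(n, dtype=object)
    sift = np.full(n, np.nan)
    conf = np.empty(n, dtype=object)
    conf[:] = "normal"
    rs = np.full(n, np.nan)

    role = sites["role"].to_numpy()
    mis = role != "other"
    consequence[mis] = "missense_variant"
    consequence[~mis] = rng.choice(_OTHER_CLASSES, size=(~mis).sum())

    d = role == "deleterious"
    sift[d] = rng.uniform(0.0, am.sift_deleterious_max, d.sum())
    sev = rng.choice(3, size=d.sum(), p=np.asarray(am.severity_props)
                     / sum(am.severity_props))
    rs_d = np.empty(d.sum())
    rs_d[sev == 0] = rng.uniform(0.05, 0.999, (sev == 0).sum())   # weak
    rs_d[sev == 1] = rng.uniform(1.0, 3.0, (sev == 1).sum())      # mild
    rs_d[sev == 2] = rng.uniform(3.001, 6.0, (sev == 2).sum())    # high
    rs[d] = rs_d

    t = role == "tolerated"
    sift[t] = rng.uniform(am.sift_deleterious_max + 1e-6, 1.0, t.sum())
    rs[t] = rng.normal(0.0, 2.0, t.sum())

    so = role == "sift_only"
    sift[so] = rng.uniform(0.0, am.sift_deleterious_max, so.sum())
    rs[so] = rng.uniform(-3.0, 0.0, so.sum())   # RS <= 0: not constrained

    lc = role == "low_confidence"
    sift[lc] = rng.uniform(0.0, am.sift_deleterious_max, lc.sum())
    conf[lc] = "low_confidence"
    rs[lc] = rng.uniform(0.5, 4.0, lc.sum())

    ann["consequence"] = consequence
    ann["sift_score"] = sift
    ann["sift_confidence"] = conf
    ann["rs_score"] = rs
    return ann[ANNOTATION_COLUMNS]


def _make_expression(cfg: SimConfig, b_tot: np.ndarray, rin: np.ndarray,
                     dsnp_genes: np.ndarray, sample_ids: list[str],
                     rng: np.random.Generator) -> pd.DataFrame:
    em = cfg.expression_model
    pool = np.unique(dsnp_genes)
    if pool.size >= em.n_genes:
        genes = rng.choice(pool, em.n_genes, replace=False)
    else:  # tiny configs: pad with extra gene labels
        extra = np.array([f"Glyma.00g{k:06d}" for k in range(em.n_genes - pool.size)])
        genes = np.concatenate([pool, extra])
    rng.shuffle(genes)
    n_genes, n_samp = len(genes), len(sample_ids)
    n_core = min(em.n_core_genes, n_genes)

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    zb, zr = z(np.asarray(b_tot, float)), z(np.asarray(rin, float))
    counts = np.rint(em.count_base + em.count_burden_coef * zb
                     + em.count_rin_coef * zr
                     + rng.normal(0, em.count_noise_sd, n_samp))
    counts = np.clip(counts, n_core, n_genes).astype(int)
    target_mean = np.clip(em.tpm_base + em.tpm_burden_coef * zb
                          + em.tpm_rin_coef * zr
                          + rng.normal(0, em.tpm_noise_sd, n_samp), 4.0, None)

    base = rng.lognormal(np.log(8.0), 0.8, n_genes)
    popularity = np.argsort(np.argsort(-base))  # dense rank, most abundant first
    tpm = np.zeros((n_genes, n_samp))
    for j in range(n_samp):
        expressed = np.zeros(n_genes, dtype=bool)
        expressed[:n_core] = True
        n_extra = counts[j] - n_core
        if n_extra > 0:
            tail = np.arange(n_core, n_genes)
            score = popularity[tail] + rng.normal(0, 6.0, tail.size)
            expressed[tail[np.argsort(score)[:n_extra]]] = True
        vals = base[expressed] * rng.lognormal(0.0, 0.3, int(expressed.sum()))
        vals *= target_mean[j] / vals.mean()
        tpm[expressed, j] = vals
    return pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)


_COUNTRIES = ("Canada", "USA", "Poland", "Russia", "China", "Sweden",
              "South Korea", "Hungary", "Switzerland", "Lithuania",
              "Yugoslavia", "Germany", "France", "Japan", "Ukraine",
              "Romania", "Czechia", "Netherlands", "Denmark", "Belarus",
              "Kazakhstan")
_COUNTRY_W = np.array([69, 18, 12, 14, 10, 8, 8, 7, 6, 6,
                       5, 5, 4, 4, 4, 3, 3, 2, 1, 1, 1], dtype=float)


def generate_dataset(cfg: SimConfig | None = None,
                     seed: int | None = None) -> SimOutput:
    """Simulate a full conserved collection and assemble all pipeline inputs.

    Deterministic: identical config (incl. seed) gives byte-identical
    outputs. Only segregating sites (some alternate allele observed in at
    least one sample) enter the emitted VariantSet and annotation, as a SNP
    caller would report.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = SimConfig.from_dict({**cfg.to_dict(), "seed": seed})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    sm = build_site_model(cfg, rng)
    sample_ids = [f"ACC{i + 1:04d}" for i in range(cfg.n_samples)]
    schedules = [draw_schedule(cfg, rng) for _ in range(cfg.n_samples)]
    geno = np.empty((sm.n_sites, cfg.n_samples), dtype=np.int8)
    trajectories: dict[str, pd.DataFrame] = {}
    for j, (sid, sched) in enumerate(zip(sample_ids, schedules)):
        g, traj = simulate_accession(cfg, sched, sm, rng)
        geno[:, j] = g
        trajectories[sid] = traj

    annotation = _make_annotation(cfg, sm, rng)

    # metadata with RIN declining over years since last regeneration
    em = cfg.expression_model
    y_last = np.array([s.y_last for s in schedules], dtype=float)
    rin = np.clip(em.rin_base - em.rin_ylast_coef * y_last
                  + rng.normal(0, em.rin_noise_sd, cfg.n_samples), 1.0, 10.0)
    rin = np.round(rin, 1)
    countries = rng.choice(_COUNTRIES, size=cfg.n_samples,
                           p=_COUNTRY_W / _COUNTRY_W.sum())
    metadata = [AccessionMetadata(sample_id=sid, country=str(c),
                                  y_acq=s.y_acq, y_last=s.y_last, r=s.r,
                                  rin=float(v))
                for sid, c, s, v in zip(sample_ids, countries, schedules, rin)]
    for m in metadata:
        m.validate()

    # keep segregating sites only
    segregating = (geno != HOM_REF).any(axis=1)
    vs = VariantSet(
        chrom=sm.frame["chrom"].to_numpy()[segregating].astype(object),
        pos=sm.frame["pos"].to_numpy()[segregating],
        ref=sm.frame["ref"].to_numpy()[segregating].astype(object),
        alt=sm.frame["alt"].to_numpy()[segregating].astype(object),
        genotypes=geno[segregating], samples=sample_ids)
    vs.validate()
    annotation = annotation.loc[segregating].reset_index(drop=True)

    # truth record over the emitted deleterious sites (the realised dSNP set)
    emitted_sel = sm.sel_mask[segregating]
    sel_geno = vs.genotypes[emitted_sel]
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "n_het": (sel_geno == HET).sum(axis=0),
        "n_hom": (sel_geno == HOM_ALT).sum(axis=0),
        "L": int(emitted_sel.sum()),
        "y_acq": [s.y_acq for s in schedules],
        "y_last": [s.y_last for s in schedules],
        "r": [s.r for s in schedules],
    }).set_index("sample_id")

    L = max(int(emitted_sel.sum()), 1)
    b_tot = (2 * truth["n_hom"] + truth["n_het"]).to_numpy() / (2 * L)
    dsnp_genes = annotation.loc[emitted_sel, "gene_id"].to_numpy()
    tpm = _make_expression(cfg, b_tot, rin, dsnp_genes, sample_ids, rng)

    logger.info("generate_dataset: %d sites emitted (%d deleterious), "
                "%d accessions", vs.n_sites, int(emitted_sel.sum()),
                cfg.n_samples)
    return SimOutput(variant_set=vs, annotation=annotation, metadata=metadata,
                     tpm=tpm, truth=truth, trajectories=trajectories,
                     config=cfg)


# ---------------------------------------------------------------------------
# output files and hashing
# ---------------------------------------------------------------------------

def write_sim_output(sim: SimOutput, outdir: str | os.PathLike) -> dict[str, str]:
    """Write VCF, annotation/metadata/TPM/truth TSVs and the config YAML."""
    import yaml

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "vcf": "genotypes.vcf", "annotation": "annotation.tsv",
        "metadata": "metadata.tsv", "tpm": "tpm.tsv", "truth": "truth.tsv",
        "config": "sim_config.yaml"}.items()}
    write_vcf(sim.variant_set, paths["vcf"])
    sim.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    write_metadata(sim.metadata, paths["metadata"])
    sim.tpm.to_csv(paths["tpm"], sep="\t")
    sim.truth.to_csv(paths["truth"], sep="\t")
    with open(paths["config"], "wt") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=True)
    return paths


def output_digest(sim: SimOutput) -> str:
    """SHA-256 over all emitted tables (determinism checks)."""
    h = hashlib.sha256()
    h.update(sim.variant_set.genotypes.tobytes())
    for arr in (sim.variant_set.chrom, sim.variant_set.pos,
                sim.variant_set.ref, sim.variant_set.alt):
        h.update(np.asarray(arr, dtype="U").tobytes())
    h.update(sim.annotation.to_csv(index=False).encode())
    h.update(metadata_frame(sim.metadata).to_csv().encode())
    h.update(sim.tpm.to_csv().encode())
    h.update(sim.truth.to_csv().encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryCheck:
    name: str
    result: AssociationResult
    passed: bool


@dataclass
class RecoveryReport:
    checks: list[RecoveryCheck]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"check": c.name, "slope": c.result.slope,
                              "p_value": c.result.p_value, "passed": c.passed}
                             for c in self.checks])


def recover_parameters(sim: SimOutput, alpha: float = 0.05) -> RecoveryReport:
    """Run the pipeline on simulated data and test the accumulation signature.

    Checks: heterozygous and total burden rise significantly with completed
    regeneration cycles; homozygous burden shows no significant cycle trend
    (fresh mutations almost never survive to homozygosity); RIN declines
    with years since the last regeneration.
    """
    dset = classify_deleterious(sim.annotation)
    burden = compute_burdens(sim.variant_set, dset)
    meta = sim.metadata_frame()
    df = burden.join(meta, how="inner")

    checks = []
    res = regress(df["B_het"], df["r"], "B_het", "r")
    checks.append(RecoveryCheck("B_het_increases_with_cycles", res,
                                res.slope > 0 and res.p_value < alpha))
    res = regress(df["B_tot"], df["r"], "B_tot", "r")
    checks.append(RecoveryCheck("B_tot_increases_with_cycles", res,
                                res.slope > 0 and res.p_value < alpha))
    res = regress(df["B_hom"], df["r"], "B_hom", "r")
    checks.append(RecoveryCheck("B_hom_flat_with_cycles", res,
                                res.p_value >= alpha))
    res = regress(df["rin"], df["y_last"], "rin", "y_last")
    checks.append(RecoveryCheck("RIN_declines_with_storage_years", res,
                                res.slope < 0))
    return RecoveryReport(checks=checks)
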