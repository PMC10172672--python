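"""Synthetic multi-omics cohort with planted ground truth.

Emulates the study design: paired liver-metastasis / adjacent-liver samples
plus unpaired colon controls, across four layers (somatic variants, mRNA and
miRNA counts, methylation betas, copy-number segments). Metastasis expression
is a mixture f*liver + (1-f)*tumor, where the latent tumor profile is the
colon baseline with planted log-fold-changes — so contamination correction is
required before differential testing, exactly the confound the cohort exists
to exercise. One planted "quadruple" gene is consistent across all four
layers: up-regulated, recurrently gained, promoter-hypomethylated, and
targeted by an up-regulated miRNA (counter-regulation).

All randomness flows through one numpy Generator seeded from the config, so a
fixed config yields a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    FeatureMatrix,
    GeneAnnotation,
    SampleMeta,
    SegmentRecord,
    VariantRecord,
    write_gene_annotation,
    write_gene_sets,
    write_matrix,
    write_sample_meta,
    write_segments,
    write_variants,
)
from .mutsig_tmb import CONTEXTS_96, revcomp

GENE_SPAN = 5_000       # bases covered by each synthetic gene
GENE_SPACING = 10_000   # distance between consecutive gene starts


class CohortConfigError(ValueError):
    """Inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the study's scale where stated (8 paired metastasis/liver
    patients, 9 unpaired colon controls, ~70% synchronous chronicity) and a
    desk-scale feature space elsewhere (2,000 genes with a 50-gene liver-marker
    block, 4,000 probes, 300 miRNAs).
    """

    n_patients: int = 8
    n_controls: int = 9
    n_genes: int = 2000
    n_liver_markers: int = 50
    n_mirnas: int = 300
    n_probes: int = 4000

    # per-patient latent fractions
    f_range: tuple[float, float] = (0.2, 0.6)
    f_values: tuple[float, ...] | None = None
    purity_range: tuple[float, float] = (0.5, 0.9)
    purity_values: tuple[float, ...] | None = None

    # planted effects
    n_de_genes: int = 200
    de_logfc: float = 2.0
    n_dm_probes: int = 300
    dm_delta_beta: float = 0.3
    n_bias_probes: int = 300
    bias_delta: float = 0.4
    n_de_mirnas: int = 20
    mirna_logfc: float = 2.0
    n_cnv_genes: int = 100          # per direction
    cnv_gain_cn: int = 4
    cnv_loss_cn: int = 1
    cnv_recurrence: float = 0.75    # fraction of patients carrying planted CNVs

    # cross-layer overlaps among the planted DE genes (split over up/down)
    n_deg_cnv_overlap: int = 30
    n_deg_meth_overlap: int = 20
    n_deg_mirna_overlap: int = 10

    # noise / scale
    dispersion: float = 0.1         # NB: Var = mu + phi mu^2
    depth: float = 1.0              # multiplies all expression means
    count_mean_log: float = math.log(100.0)
    count_mean_sd: float = 1.0
    liver_marker_mean: float = 200.0
    marker_background_mean: float = 0.1
    beta_noise_sd: float = 0.03
    mirna_mean_log: float = math.log(200.0)
    mirna_mean_sd: float = 1.0

    # somatic variants
    n_somatic_variants: int = 500
    variant_depth: int = 200
    frac_subclonal: float = 0.3
    frac_synonymous: float = 0.25
    signature_mixture: tuple[float, ...] = (0.6, 0.3, 0.1)

    target_map_density: float = 0.01
    plant_quadruple: bool = True
    seed: int = 0

    def effect_counts(self) -> tuple[int, int, int, int]:
        return (self.n_de_genes, self.n_dm_probes, self.n_de_mirnas, self.n_cnv_genes)

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise CohortConfigError("need at least 2 patients and 2 controls")
        for name in ("f_range", "purity_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi < 1.0):
                raise CohortConfigError(f"{name} must lie inside (0, 1)")
        if self.f_values is not None and any(not 0.0 <= f <= 1.0 for f in self.f_values):
            raise CohortConfigError("f_values must lie in [0, 1]")
        ng_main = self.n_genes - self.n_liver_markers
        if ng_main <= 0:
            raise CohortConfigError("n_liver_markers must be smaller than n_genes")
        if self.n_de_genes > ng_main:
            raise CohortConfigError("n_de_genes exceeds available genes")
        if self.n_dm_probes > self.n_probes:
            raise CohortConfigError("n_dm_probes exceeds n_probes")
        if self.n_de_mirnas > self.n_mirnas:
            raise CohortConfigError("n_de_mirnas exceeds n_mirnas")
        counts = self.effect_counts()
        if self.plant_quadruple and any(c == 0 for c in counts) and not all(c == 0 for c in counts):
            raise CohortConfigError(
                "quadruple gene impossible: some planted-effect counts are zero "
                f"(n_de_genes, n_dm_probes, n_de_mirnas, n_cnv_genes) = {counts}"
            )
        if self.n_de_genes:
            n_up = (self.n_de_genes + 1) // 2
            n_down = self.n_de_genes // 2
            need_up = 1 + self.n_deg_cnv_overlap // 2 + self.n_deg_meth_overlap // 2 \
                + self.n_deg_mirna_overlap // 2
            need_down = (self.n_deg_cnv_overlap + 1) // 2 \
                + (self.n_deg_meth_overlap + 1) // 2 + (self.n_deg_mirna_overlap + 1) // 2
            if need_up > n_up or need_down > n_down:
                raise CohortConfigError("cross-layer overlaps exceed DE gene blocks")
        if not math.isclose(sum(self.signature_mixture), 1.0, abs_tol=1e-6):
            raise CohortConfigError("signature_mixture must sum to 1")
        if not (0.0 < self.cnv_recurrence <= 1.0):
            raise CohortConfigError("cnv_recurrence must lie in (0, 1]")


@dataclass
class CohortTruth:
    """Planted ground truth of one generated cohort."""

    f: dict[str, float]                      # patient -> contamination fraction
    purity: dict[str, float]                 # patient -> tumor purity
    de_genes: dict[str, float]               # gene -> signed logFC (tumor vs colon)
    dm_probes: dict[str, str]                # probe -> hyper/hypo (met vs liver)
    dm_genes: dict[str, str]                 # gene -> direction of its planted probe
    bias_probes: set[str] = field(default_factory=set)
    cnv_gain_genes: set[str] = field(default_factory=set)
    cnv_loss_genes: set[str] = field(default_factory=set)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    signature_exposures: dict[str, float] = field(default_factory=dict)
    quadruple_gene: str | None = None
    planted_targets: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bias_probes"] = sorted(self.bias_probes)
        d["cnv_gain_genes"] = sorted(self.cnv_gain_genes)
        d["cnv_loss_genes"] = sorted(self.cnv_loss_genes)
        return d


@dataclass
class OmicsCohort:
    """Sample metadata plus the four generated data layers."""

    samples: list[SampleMeta]
    mrna_counts: FeatureMatrix
    mirna_counts: FeatureMatrix
    betas: FeatureMatrix
    variants: list[VariantRecord]
    segments: list[SegmentRecord]
    gene_annotation: dict[str, GeneAnnotation]
    mirna_targets: list[tuple[str, str]]
    liver_markers: list[str]
    signatures: pd.DataFrame

    def sample_ids(self, tissue: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.tissue == tissue]

    def paired_liver(self, met_sample: str) -> str:
        patient = next(s.patient_id for s in self.samples if s.sample_id == met_sample)
        return next(
            s.sample_id for s in self.samples
            if s.patient_id == patient and s.tissue == "adjacent_liver"
        )


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def nb_sample(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draw parameterized by mean and dispersion phi,
    Var = mu + phi mu^2 (gamma-Poisson mixture; phi=0 degrades to Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * np.maximum(mean, 0.0))
    return rng.poisson(lam)


def mix_counts(
    tumor_mean: np.ndarray,
    liver_mean: np.ndarray,
    f: float,
    depth: float = 1.0,
    dispersion: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw metastasis counts around the depth-scaled mixture
    f*liver_mean + (1-f)*tumor_mean with NB noise."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"contamination fraction f={f} outside [0, 1]")
    tumor_mean = np.asarray(tumor_mean, dtype=float)
    liver_mean = np.asarray(liver_mean, dtype=float)
    if (tumor_mean < 0).any() or (liver_mean < 0).any():
        raise ValueError("expression means must be non-negative")
    rng = _as_rng(seed)
    mu = depth * (f * liver_mean + (1.0 - f) * tumor_mean)
    return nb_sample(mu, dispersion, rng)


def expected_vaf(purity: float, copy_number: int = 2, multiplicity: int = 1) -> float:
    """Allele-dosage expectation: mult*p / (CN*p + 2(1-p))."""
    return multiplicity * purity / (copy_number * purity + 2.0 * (1.0 - purity))


def sample_vafs(
    purity: float,
    copy_state: tuple[int, int] = (2, 1),
    depth: int = 100,
    n: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binomial VAF draws at the allele-dosage expectation.

    ``copy_state`` is (total copy number, mutation multiplicity); the
    copy-neutral heterozygous expectation is purity/2.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity {purity} outside (0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    cn, mult = copy_state
    rng = _as_rng(seed)
    e = expected_vaf(purity, cn, mult)
    return rng.binomial(depth, e, size=n) / depth


def synthetic_signatures(
    n_signatures: int = 3, seed: int = 12345, concentration: float = 5.0
) -> pd.DataFrame:
    """Well-separated column-stochastic 96 x k signature matrix.

    Each signature places 90% of its mass on its own block of contexts (drawn
    from a Dirichlet) plus a flat 10% background, so distinct signatures have
    nearly disjoint support — convenient for exposure-recovery tests.
    """
    if not 1 <= n_signatures <= 6:
        raise ValueError("n_signatures must be in [1, 6]")
    rng = np.random.default_rng(seed)
    block = 96 // n_signatures
    S = np.full((96, n_signatures), 0.1 / 96.0)
    for j in range(n_signatures):
        lo = j * block
        hi = 96 if j == n_signatures - 1 else lo + block
        weights = rng.dirichlet(np.full(hi - lo, concentration))
        S[lo:hi, j] += 0.9 * weights
    S /= S.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        S, index=CONTEXTS_96, columns=[f"SIGS{j + 1}" for j in range(n_signatures)]
    )


def _context_from_bin(label: str) -> tuple[str, str, str]:
    """96-bin label -> (ref, alt, reference-strand context)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> tuple[OmicsCohort, CohortTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)

    ng_main = config.n_genes - config.n_liver_markers
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    main_genes = genes[:ng_main]
    marker_genes = genes[ng_main:]
    mirnas = [f"mir{i:04d}" for i in range(config.n_mirnas)]
    probes = [f"cg{i:06d}" for i in range(config.n_probes)]

    plant = config.plant_quadruple and all(c > 0 for c in config.effect_counts())

    # ---- planted-effect layout on the main genes -------------------------
    n_up = (config.n_de_genes + 1) // 2
    n_down = config.n_de_genes // 2
    up_genes = main_genes[:n_up]
    down_genes = main_genes[n_up:n_up + n_down]

    a_up = config.n_deg_cnv_overlap // 2 if config.n_de_genes else 0
    b_up = config.n_deg_meth_overlap // 2 if config.n_de_genes else 0
    c_up = config.n_deg_mirna_overlap // 2 if config.n_de_genes else 0
    a_down = config.n_deg_cnv_overlap - a_up if config.n_de_genes else 0
    b_down = config.n_deg_meth_overlap - b_up if config.n_de_genes else 0
    c_down = config.n_deg_mirna_overlap - c_up if config.n_de_genes else 0

    quad_gene = up_genes[0] if plant else None
    # disjoint sub-blocks of the up/down DE genes (index 0 reserved for quad)
    pos = 1
    cnv_up = up_genes[pos:pos + a_up]; pos += a_up
    meth_up = up_genes[pos:pos + b_up]; pos += b_up
    mirna_up_targets = up_genes[pos:pos + c_up]
    pos = 0
    cnv_down = down_genes[pos:pos + a_down]; pos += a_down
    meth_down = down_genes[pos:pos + b_down]; pos += b_down
    mirna_down_targets = down_genes[pos:pos + c_down]

    # remaining CNV / DM effects live on non-DE genes
    free = list(main_genes[config.n_de_genes:])
    n_gain_extra = max(0, config.n_cnv_genes - len(cnv_up) - (1 if plant else 0))
    n_loss_extra = max(0, config.n_cnv_genes - len(cnv_down))
    n_dm_planted = (1 if plant else 0) + len(meth_up) + len(meth_down)
    n_dm_extra = max(0, config.n_dm_probes - n_dm_planted)
    if n_gain_extra + n_loss_extra + n_dm_extra > len(free):
        raise CohortConfigError("not enough non-DE genes for planted CNV/DM effects")
    gain_extra = free[:n_gain_extra]
    loss_extra = free[n_gain_extra:n_gain_extra + n_loss_extra]
    dm_extra = free[n_gain_extra + n_loss_extra:n_gain_extra + n_loss_extra + n_dm_extra]

    gain_genes = set(cnv_up) | set(gain_extra) | ({quad_gene} if plant else set())
    loss_genes = set(cnv_down) | set(loss_extra)

    de_genes: dict[str, float] = {}
    for g in up_genes:
        de_genes[g] = config.de_logfc
    for g in down_genes:
        de_genes[g] = -config.de_logfc

    # ---- gene annotation and probe map -----------------------------------
    gene_index = {g: i for i, g in enumerate(genes)}
    annotation: dict[str, GeneAnnotation] = {}
    for g, i in gene_index.items():
        start = i * GENE_SPACING + 1
        annotation[g] = GeneAnnotation(g, "1", start, start + GENE_SPAN - 1)
    # probe i < ng_main -> promoter probe of gene i; next block -> body probes
    probe_gene: dict[str, tuple[str, str]] = {}
    for i, probe in enumerate(probes):
        if i < ng_main:
            probe_gene[probe] = (main_genes[i], "promoter")
        elif i < 2 * ng_main:
            probe_gene[probe] = (main_genes[i - ng_main], "body")
        # remaining probes are open-sea, unassigned to genes
    for probe, (g, region) in probe_gene.items():
        annotation[g].probe_ids[probe] = region

    dm_probes: dict[str, str] = {}
    dm_gene_dir: dict[str, str] = {}

    def plant_dm(gene: str, direction: str) -> None:
        probe = probes[gene_index[gene]]  # the gene's promoter probe
        dm_probes[probe] = direction
        dm_gene_dir[gene] = direction

    if plant:
        plant_dm(quad_gene, "hypo")
    for g in meth_up:
        plant_dm(g, "hypo")       # hypomethylated promoter, up-regulated gene
    for g in meth_down:
        plant_dm(g, "hyper")
    for g in dm_extra:
        plant_dm(g, "hypo" if rng.random() < 0.5 else "hyper")

    # tissue-bias probes: body probes of genes with no planted methylation
    bias_probes: set[str] = set()
    if config.n_bias_probes:
        candidates = [
            p for i, p in enumerate(probes[ng_main:2 * ng_main], start=ng_main)
            if probe_gene[p][0] not in dm_gene_dir
        ]
        if len(candidates) < config.n_bias_probes:
            raise CohortConfigError("not enough body probes for tissue-bias planting")
        bias_probes = set(candidates[:config.n_bias_probes])

    # ---- miRNA layer ------------------------------------------------------
    n_up_mir = (config.n_de_mirnas + 1) // 2
    up_mirs = mirnas[:n_up_mir]
    down_mirs = mirnas[n_up_mir:config.n_de_mirnas]
    de_mirnas = {m: config.mirna_logfc for m in up_mirs}
    de_mirnas.update({m: -config.mirna_logfc for m in down_mirs})

    planted_targets: list[tuple[str, str]] = []
    if plant:
        planted_targets.append((up_mirs[0], quad_gene))  # counter-regulation pair
    for i, g in enumerate(mirna_up_targets):             # repression: down-miR, up-gene
        if down_mirs:
            planted_targets.append((down_mirs[i % len(down_mirs)], g))
    for i, g in enumerate(mirna_down_targets):           # repression: up-miR, down-gene
        if up_mirs:
            planted_targets.append((up_mirs[i % len(up_mirs)], g))

    link_mask = rng.random((config.n_mirnas, ng_main)) < config.target_map_density
    targets = set(planted_targets)
    for mi, gi in zip(*np.nonzero(link_mask)):
        targets.add((mirnas[mi], main_genes[gi]))
    mirna_targets = sorted(targets)

    # ---- per-patient latent fractions ------------------------------------
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    if config.f_values is not None:
        f_vals = [config.f_values[i % len(config.f_values)] for i in range(config.n_patients)]
    else:
        f_vals = list(rng.uniform(*config.f_range, size=config.n_patients))
    if config.purity_values is not None:
        p_vals = [config.purity_values[i % len(config.purity_values)]
                  for i in range(config.n_patients)]
    else:
        p_vals = list(rng.uniform(*config.purity_range, size=config.n_patients))
    f_truth = dict(zip(patients, map(float, f_vals)))
    purity_truth = dict(zip(patients, map(float, p_vals)))

    n_sync = int(round(0.7 * config.n_patients))
    samples: list[SampleMeta] = []
    for i, p in enumerate(patients):
        chron = "synchronous" if i < n_sync else "metachronous"
        samples.append(SampleMeta(f"{p}_met", p, "metastasis", chron))
        samples.append(SampleMeta(f"{p}_liv", p, "adjacent_liver", chron))
    controls = [f"C{j + 1:02d}" for j in range(config.n_controls)]
    samples.extend(SampleMeta(c, c, "control_colon", "none") for c in controls)

    # ---- expression means -------------------------------------------------
    colon_mean = np.empty(config.n_genes)
    colon_mean[:ng_main] = rng.lognormal(config.count_mean_log, config.count_mean_sd, ng_main)
    colon_mean[ng_main:] = config.marker_background_mean
    liver_mean = colon_mean.copy()
    liver_mean[ng_main:] = config.liver_marker_mean
    tumor_mean = colon_mean.copy()
    for g, lfc in de_genes.items():
        tumor_mean[gene_index[g]] = colon_mean[gene_index[g]] * 2.0 ** lfc

    # ---- mRNA counts ------------------------------------------------------
    mrna_cols: dict[str, np.ndarray] = {}
    for p in patients:
        mrna_cols[f"{p}_met"] = mix_counts(
            tumor_mean, liver_mean, f_truth[p], config.depth, config.dispersion, rng
        )
        mrna_cols[f"{p}_liv"] = nb_sample(config.depth * liver_mean, config.dispersion, rng)
    for c in controls:
        mrna_cols[c] = nb_sample(config.depth * colon_mean, config.dispersion, rng)
    mrna = FeatureMatrix(pd.DataFrame(mrna_cols, index=genes), kind="counts")

    # ---- miRNA counts -----------------------------------------------------
    mir_liver_mean = rng.lognormal(config.mirna_mean_log, config.mirna_mean_sd, config.n_mirnas)
    mir_met_mean = mir_liver_mean.copy()
    mir_index = {m: i for i, m in enumerate(mirnas)}
    for m, lfc in de_mirnas.items():
        mir_met_mean[mir_index[m]] = mir_liver_mean[mir_index[m]] * 2.0 ** lfc
    mirna_cols: dict[str, np.ndarray] = {}
    for p in patients:
        mirna_cols[f"{p}_met"] = nb_sample(config.depth * mir_met_mean, config.dispersion, rng)
        mirna_cols[f"{p}_liv"] = nb_sample(config.depth * mir_liver_mean, config.dispersion, rng)
    mirna = FeatureMatrix(pd.DataFrame(mirna_cols, index=mirnas), kind="counts")

    # ---- methylation betas ------------------------------------------------
    base = rng.uniform(0.1, 0.9, config.n_probes)
    liver_beta = base.copy()
    colon_beta = base.copy()
    tumor_beta = base.copy()
    probe_idx = {p: i for i, p in enumerate(probes)}
    for probe, direction in dm_probes.items():
        i = probe_idx[probe]
        b = rng.uniform(0.35, 0.65)
        liver_beta[i] = colon_beta[i] = b
        tumor_beta[i] = b - config.dm_delta_beta if direction == "hypo" else b + config.dm_delta_beta
    for probe in bias_probes:
        i = probe_idx[probe]
        hi = rng.uniform(0.6, 0.9)
        liver_beta[i] = hi
        colon_beta[i] = hi - config.bias_delta
        tumor_beta[i] = colon_beta[i]  # tumor cells carry the colon methylome

    def draw_betas(mean: np.ndarray) -> np.ndarray:
        return np.clip(mean + rng.normal(0.0, config.beta_noise_sd, mean.shape), 0.01, 0.99)

    beta_cols: dict[str, np.ndarray] = {}
    for p in patients:
        beta_cols[f"{p}_met"] = draw_betas(tumor_beta)
        beta_cols[f"{p}_liv"] = draw_betas(liver_beta)
    for c in controls:
        beta_cols[c] = draw_betas(colon_beta)
    betas = FeatureMatrix(pd.DataFrame(beta_cols, index=probes), kind="beta")

    # ---- copy-number segments --------------------------------------------
    n_carriers = max(1, int(round(config.cnv_recurrence * config.n_patients)))
    gain_carriers = list(rng.choice(patients, size=n_carriers, replace=False))
    loss_carriers = list(rng.choice(patients, size=n_carriers, replace=False))
    segments: list[SegmentRecord] = []
    for p in patients:
        sid = f"{p}_met"
        for g in sorted(gain_genes):
            if p in gain_carriers:
                a = annotation[g]
                segments.append(SegmentRecord(a.chrom, a.start, a.end, config.cnv_gain_cn, sid))
        for g in sorted(loss_genes):
            if p in loss_carriers:
                a = annotation[g]
                segments.append(SegmentRecord(a.chrom, a.start, a.end, config.cnv_loss_cn, sid))

    # ---- somatic variants -------------------------------------------------
    signatures = synthetic_signatures(len(config.signature_mixture))
    w = np.asarray(config.signature_mixture, dtype=float)
    context_probs = signatures.to_numpy() @ w
    context_probs = context_probs / context_probs.sum()
    sig_truth = dict(zip(signatures.columns, map(float, w)))

    variants: list[VariantRecord] = []
    for p in patients:
        sid = f"{p}_met"
        purity = purity_truth[p]
        gidx = rng.integers(0, ng_main, size=config.n_somatic_variants)
        bins = rng.choice(96, size=config.n_somatic_variants, p=context_probs)
        flip = rng.random(config.n_somatic_variants) < 0.5
        subclonal = rng.random(config.n_somatic_variants) < config.frac_subclonal
        cons_draw = rng.random(config.n_somatic_variants)
        for k in range(config.n_somatic_variants):
            g = main_genes[gidx[k]]
            cn = 2
            if g in gain_genes and p in gain_carriers:
                cn = config.cnv_gain_cn
            elif g in loss_genes and p in loss_carriers:
                cn = config.cnv_loss_cn
            e = expected_vaf(purity, cn, 1)
            if subclonal[k]:
                e *= 0.5
            depth = config.variant_depth
            vaf = rng.binomial(depth, e) / depth
            ref, alt, context = _context_from_bin(CONTEXTS_96[bins[k]])
            if flip[k]:
                from .mutsig_tmb import COMPLEMENT
                ref, alt, context = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)
            a = annotation[g]
            pos_v = int(rng.integers(a.start + 1, a.end - 1))
            if cons_draw[k] < config.frac_synonymous:
                consequence = "synonymous"
            elif cons_draw[k] < config.frac_synonymous + 0.70:
                consequence = "nonsynonymous"
            else:
                consequence = "other"
            variants.append(VariantRecord(
                chrom=a.chrom, pos=pos_v, ref=ref, alt=alt,
                vaf=float(vaf), depth=depth, context=context,
                consequence=consequence, vclass="SNV", sample_id=sid,
                clonality="subclonal" if subclonal[k] else "clonal",
            ))

    cohort = OmicsCohort(
        samples=samples,
        mrna_counts=mrna,
        mirna_counts=mirna,
        betas=betas,
        variants=variants,
        segments=segments,
        gene_annotation=annotation,
        mirna_targets=mirna_targets,
        liver_markers=list(marker_genes),
        signatures=signatures,
    )
    truth = CohortTruth(
        f=f_truth,
        purity=purity_truth,
        de_genes=de_genes,
        dm_probes=dm_probes,
        dm_genes=dm_gene_dir,
        bias_probes=bias_probes,
        cnv_gain_genes=gain_genes,
        cnv_loss_genes=loss_genes,
        de_mirnas=de_mirnas,
        signature_exposures=sig_truth,
        quadruple_gene=quad_gene,
        planted_targets=planted_targets,
    )
    return cohort, truth


def write_cohort(cohort: OmicsCohort, truth: CohortTruth, out_dir: str | Path) -> None:
    """Write every layer in the pipeline's standard dialects plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sample_meta(cohort.samples, out / "samples.tsv")
    write_matrix(cohort.mrna_counts, out / "mrna_counts.tsv")
    write_matrix(cohort.mirna_counts, out / "mirna_counts.tsv")
    write_matrix(cohort.betas, out / "betas.tsv")
    write_variants(cohort.variants, out / "variants.tsv", dialect="tsv")
    write_segments(cohort.segments, out / "segments.seg", dialect="seg")
    write_gene_annotation(cohort.gene_annotation, out / "genes.tsv", out / "probes.tsv")
    cohort.signatures.to_csv(out / "signatures.tsv", sep="\t", index_label="context")
    with open(out / "mirna_targets.tsv", "w") as fh:
        fh.write("mirna\tgene\n")
        for m, g in cohort.mirna_targets:
            fh.write(f"{m}\t{g}\n")
    write_gene_sets({"liver_markers": cohort.liver_markers}, out / "liver_markers.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
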