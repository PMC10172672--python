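"""End-to-end orchestration: contamination-corrected differential analysis of
all four layers followed by direction-aware integration.

Stages: TMM normalisation of mRNA counts -> per-patient liver-contamination
estimate from liver-marker genes -> subtraction of the liver component from
each metastasis profile -> exact-NB differential expression of cleaned
metastases against colon controls -> tissue-bias-filtered moderated-t
methylation testing (metastasis vs adjacent liver) -> miRNA differential
expression -> purity, signature refitting and TMB from somatic variants ->
gene-level recurrent CNVs -> per-DEG attribution and multiway overlap.

The integration step defaults to ``mirna_policy='any'``: the cohort's planted
quadruple gene pairs an up-regulated gene with an up-regulated targeting miRNA
(counter-regulation), the reading under which such a gene counts as
miRNA-linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_summary import GeneCnvCall, gene_level_calls, recurrent_genes, segment_length_stats
from .differential import (
    count_de_test,
    dm_test,
    filter_tissue_bias_probes,
    mirna_de,
    scale_normalize_counts,
)
from .integration import (
    OverlapReport,
    attribute_deg_sources,
    multiway_overlap,
    valid_target_filter,
)
from .mutsig_tmb import SignatureFit, TmbResult, build_96_catalog, compute_tmb, fit_signature_exposures
from .purity_decontam import (
    PurityEstimate,
    copy_neutral_variants,
    decontaminate_matrix,
    estimate_contamination,
    estimate_purity_vaf,
)
from .synthetic_cohort import OmicsCohort


@dataclass
class PipelineResult:
    contamination: dict[str, float]            # metastasis sample -> f-hat
    purity: dict[str, PurityEstimate] = field(default_factory=dict)
    de: pd.DataFrame | None = None
    dm: pd.DataFrame | None = None
    dm_probe_table: pd.DataFrame | None = None
    mirna: pd.DataFrame | None = None
    cnv_calls: list[GeneCnvCall] = field(default_factory=list)
    recurrent_gain: set[str] = field(default_factory=set)
    recurrent_loss: set[str] = field(default_factory=set)
    length_stats: dict = field(default_factory=dict)
    signature_fit: SignatureFit | None = None
    tmb: dict[str, TmbResult] = field(default_factory=dict)
    mirna_pairs: pd.DataFrame | None = None
    attributions: pd.DataFrame | None = None
    overlap: OverlapReport | None = None


def run_pipeline(
    cohort: OmicsCohort,
    de_fdr: float = 0.01,
    de_lfc: float = 1.0,
    dm_fdr: float = 0.01,
    mirna_fdr: float = 0.05,
    tissue_bias_tau: float = 0.2,
    mirna_policy: str = "any",
    meth_regions: tuple[str, ...] | None = ("promoter",),
    region_mb: float = 30.0,
    recurrence_fraction: float = 0.5,
    de_group_dispersion: str = "max",
) -> PipelineResult:
    met_ids = cohort.sample_ids("metastasis")
    liv_ids = cohort.sample_ids("adjacent_liver")
    colon_ids = cohort.sample_ids("control_colon")
    pairing = {m: cohort.paired_liver(m) for m in met_ids}

    # --- normalisation and contamination correction ----------------------
    _, norm = scale_normalize_counts(cohort.mrna_counts.values)
    colon_baseline = norm[colon_ids].mean(axis=1)
    fractions: dict[str, float] = {}
    for m in met_ids:
        est = estimate_contamination(
            norm[m], norm[pairing[m]], colon=colon_baseline,
            liver_markers=cohort.liver_markers, sample_id=m,
        )
        fractions[m] = est.fraction
    cleaned = decontaminate_matrix(norm[met_ids], norm[liv_ids], fractions, pairing)

    # --- differential expression: cleaned metastases vs colon controls ---
    # the contamination markers are excluded: after subtraction their values
    # are dominated by the f-hat estimation error (and the non-negativity
    # clip biases them upward), so they would resurface as false positives
    de_input = pd.concat([cleaned, norm[colon_ids]], axis=1)
    de_input = de_input.drop(index=[g for g in cohort.liver_markers if g in de_input.index])
    de = count_de_test(
        de_input, met_ids, colon_ids,
        fdr_threshold=de_fdr, lfc_threshold=de_lfc, normalize=False,
        group_dispersion=de_group_dispersion,  # cleaned profiles are noisier than controls
    )

    # --- methylation: tissue-bias filter, then metastasis vs liver -------
    betas = cohort.betas.values
    keep = filter_tissue_bias_probes(betas[liv_ids], betas[colon_ids], tau=tissue_bias_tau)
    dm = dm_test(betas.loc[keep[keep].index], met_ids, liv_ids, fdr_threshold=dm_fdr)
    probe_gene = {
        probe: (g.gene_id, region)
        for g in cohort.gene_annotation.values()
        for probe, region in g.probe_ids.items()
    }
    dm_probe_table = dm.copy()
    dm_probe_table["gene_id"] = [probe_gene.get(p, ("", ""))[0] for p in dm.index]
    dm_probe_table["region"] = [probe_gene.get(p, ("", ""))[1] for p in dm.index]
    dm_probe_table = dm_probe_table[dm_probe_table["gene_id"] != ""]

    # --- miRNA ------------------------------------------------------------
    mirna = mirna_de(cohort.mirna_counts.values, met_ids, liv_ids, fdr_threshold=mirna_fdr)

    # --- variants: purity, signatures, TMB --------------------------------
    purity: dict[str, PurityEstimate] = {}
    tmb: dict[str, TmbResult] = {}
    by_sample: dict[str, list] = {}
    for v in cohort.variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    for sid, recs in sorted(by_sample.items()):
        neutral = copy_neutral_variants(recs, cohort.segments)
        try:
            purity[sid] = estimate_purity_vaf(neutral)
        except ValueError:
            pass
        tmb[sid] = compute_tmb(recs, region_mb=region_mb, sample_id=sid)
    catalog = build_96_catalog(cohort.variants, sample_id="cohort")
    signature_fit = fit_signature_exposures(catalog, cohort.signatures)

    # --- CNV --------------------------------------------------------------
    cnv_calls = gene_level_calls(cohort.segments, cohort.gene_annotation)
    gains, losses = recurrent_genes(cnv_calls, min_fraction=recurrence_fraction)
    length_stats = segment_length_stats(cohort.segments)

    # --- integration ------------------------------------------------------
    mirna_pairs = valid_target_filter(mirna, cohort.mirna_targets, de)
    attributions = attribute_deg_sources(
        de, gains, losses, dm_probes=dm_probe_table, mirna_pairs=mirna_pairs,
        mirna_policy=mirna_policy, meth_regions=meth_regions,
    )
    overlap = multiway_overlap(attributions)

    return PipelineResult(
        contamination=fractions,
        purity=purity,
        de=de,
        dm=dm,
        dm_probe_table=dm_probe_table,
        mirna=mirna,
        cnv_calls=cnv_calls,
        recurrent_gain=gains,
        recurrent_loss=losses,
        length_stats=length_stats,
        signature_fit=signature_fit,
        tmb=tmb,
        mirna_pairs=mirna_pairs,
        attributions=attributions,
        overlap=overlap,
    )
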