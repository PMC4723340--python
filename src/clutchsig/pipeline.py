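"""End-to-end orchestration: QC -> normalization -> calls -> statistics.

Mirrors the analysis order of the study: extreme-gene removal and
suspect-probe removal on raw data, quantile normalization between arrays,
expressed-gene calling from the raw-data variance bimodality, then
fold-change variability, distinct-level signature detection and per-gene
clutch ANOVA on the normalized values of each expressed gene's
representative probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import (
    ProbeMatrix,
    QCReport,
    detect_suspect_probes,
    quantile_normalize,
    remove_extreme_genes,
)
from .expression import ExpressionCalls, call_expression
from .variability import mfc_table, mfc_summary
from .signature import ClutchProfile, SignatureCluster, group_clusters, profile_table
from .diffexp import anova_table

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    qc: QCReport
    normalized: ProbeMatrix
    calls: ExpressionCalls
    mfc: pd.DataFrame
    mfc_fractions: pd.DataFrame
    profiles: list[ClutchProfile] = field(default_factory=list)
    clusters: list[SignatureCluster] = field(default_factory=list)
    anova: pd.DataFrame | None = None

    @property
    def signature_genes(self) -> dict[str, str]:
        return {p.gene_id: p.code for p in self.profiles if p.code is not None}


def run_pipeline(
    raw: ProbeMatrix,
    annotation: pd.DataFrame,
    fc_threshold: float = 3000.0,
    corr_cut: float = -0.8,
    sd_cut: float | None = None,
    posterior_threshold: float = 0.95,
    min_arrays: int = 4,
    fdr: float = 0.05,
    fc_summary_thresholds=(2.0, 4.0),
    qvalue_method: str = "storey",
) -> PipelineResult:
    """Run the full analysis on a raw probe matrix with its annotation."""
    filtered, qc = remove_extreme_genes(raw, annotation, fc_threshold)
    suspect = detect_suspect_probes(filtered, corr_cut=corr_cut, sd_cut=sd_cut)
    qc.suspect_probes = suspect.suspect_probes
    qc.suspect_probe_stats = suspect.suspect_probe_stats
    qc.thresholds.update(suspect.thresholds)
    if suspect.suspect_probes:
        keep = [p for p in filtered.values.index if p not in set(suspect.suspect_probes)]
        filtered = filtered.subset_probes(keep)

    normalized = quantile_normalize(filtered)
    calls = call_expression(
        filtered,
        annotation,
        posterior_threshold=posterior_threshold,
        min_arrays=min_arrays,
    )

    genes = sorted(calls.expressed_genes)
    rep = {g: calls.representative_probe[g] for g in genes}
    table = mfc_table(normalized, rep, genes)
    fractions = mfc_summary(table, fc_summary_thresholds)
    profiles = profile_table(normalized, rep, genes)
    clusters = group_clusters(profiles)
    anova = anova_table(normalized, rep, genes, fdr=fdr, method=qvalue_method)

    return PipelineResult(
        qc=qc,
        normalized=normalized,
        calls=calls,
        mfc=table,
        mfc_fractions=fractions,
        profiles=profiles,
        clusters=clusters,
        anova=anova,
    )
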