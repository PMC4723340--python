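"""Quality filtering and between-array normalization of probe intensity matrices.

The raw input is a probes x samples matrix of log2 single-channel intensities
from individual unfertilized eggs, with each sample assigned to the mother
(clutch) it came from.  Before any expression calling, three steps run in
order: removal of genes with a single unrealistically extreme value, removal
of probes whose signal anti-correlates with the per-array scaling factors
(transcripts carrying native long poly(A) tails, which the polyadenylation-
based labeling cannot normalize), and quantile normalization between arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ProbeMatrix",
    "QCReport",
    "remove_extreme_genes",
    "detect_suspect_probes",
    "quantile_normalize",
    "read_matrix_tsv",
    "read_annotation_tsv",
    "read_sample_sheet_tsv",
]


@dataclass
class ProbeMatrix:
    """Probes x samples log2 intensities with clutch metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    sample_meta
        Mapping ``sample_id -> mother_id`` covering every column.
    """

    values: pd.DataFrame
    sample_meta: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("intensity matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.sample_meta]
        if missing:
            raise ValueError(f"samples without a mother assignment: {missing}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def clutches(self) -> dict[str, list[str]]:
        """Samples grouped by mother, in column order."""
        out: dict[str, list[str]] = {}
        for s in self.values.columns:
            out.setdefault(self.sample_meta[s], []).append(s)
        return out

    def subset_probes(self, probe_ids) -> "ProbeMatrix":
        return ProbeMatrix(self.values.loc[list(probe_ids)], self.sample_meta)


@dataclass
class QCReport:
    """Record of what quality filtering removed and why."""

    removed_extreme_genes: list[str] = field(default_factory=list)
    # gene -> (offending sample, log2 gap to the max of the other samples)
    extreme_gene_stats: dict[str, tuple[str, float]] = field(default_factory=dict)
    suspect_probes: list[str] = field(default_factory=list)
    # probe -> (anti-correlation with scaling factors, centered sd)
    suspect_probe_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": g, "kind": "extreme_gene", "sample": s, "statistic": gap}
            for g, (s, gap) in self.extreme_gene_stats.items()
        ] + [
            {"item": p, "kind": "suspect_probe", "anti_correlation": r, "centered_sd": sd}
            for p, (r, sd) in self.suspect_probe_stats.items()
        ]
        return pd.DataFrame(rows)


def remove_extreme_genes(
    m: ProbeMatrix,
    annotation: pd.DataFrame | None = None,
    fc_threshold: float = 3000.0,
) -> tuple[ProbeMatrix, QCReport]:
    """Drop genes with one unrealistically high sample.

    A gene is removed when exactly one sample sits ``log2(fc_threshold)`` or
    more above the maximum of all its other samples — a fold change no real
    transcript shows, indicating a measurement artifact.  With an annotation
    (probe_id/gene_id columns) the rule is evaluated on each gene's
    highest-signal behaviour and all probes of a flagged gene are dropped;
    without one, each probe is treated as its own gene.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    gap_log2 = float(np.log2(fc_threshold))
    vals = m.values.to_numpy()

    if annotation is not None:
        ann = annotation.set_index("probe_id")["gene_id"]
        genes = ann.reindex(m.values.index)
    else:
        genes = pd.Series(m.values.index, index=m.values.index)

    report = QCReport(thresholds={"fc_threshold": fc_threshold})
    # top two values per probe row; the gene-level gap is assessed on the
    # probe that carries the extreme value
    order = np.argsort(vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, -1]]
    second = vals[np.arange(len(vals)), order[:, -2]]
    extreme_rows = (top - second) >= gap_log2

    flagged_genes: dict[str, tuple[str, float]] = {}
    for i in np.flatnonzero(extreme_rows):
        g = genes.iloc[i]
        if pd.isna(g):
            g = m.values.index[i]
        s = m.values.columns[order[i, -1]]
        gap = float(top[i] - second[i])
        if g not in flagged_genes or gap > flagged_genes[g][1]:
            flagged_genes[g] = (s, gap)

    report.removed_extreme_genes = sorted(flagged_genes)
    report.extreme_gene_stats = flagged_genes
    keep = ~genes.isin(flagged_genes).to_numpy()
    return ProbeMatrix(m.values.loc[keep], m.sample_meta), report


def array_scaling_factors(m: ProbeMatrix) -> pd.Series:
    """Per-array scaling factor: array mean log2 intensity minus grand mean."""
    col_means = m.values.mean(axis=0)
    return col_means - col_means.mean()


def detect_suspect_probes(
    m: ProbeMatrix,
    corr_cut: float = -0.8,
    sd_cut: float | None = None,
    sd_cut_quantile: float = 0.9,
) -> QCReport:
    """Flag probes whose signal anti-correlates with the array scaling factors.

    Intensities are centered on each array's average; the scaling factor of an
    array is its average minus the grand average.  A probe whose centered
    intensities move opposite to the scaling factors (correlation <= corr_cut)
    with a large centered sd (>= sd_cut) is not being normalized like the rest
    of the array — the behaviour of transcripts with native long poly(A)
    tails — and is flagged for removal.  ``sd_cut`` defaults to the
    ``sd_cut_quantile`` quantile of the centered sds.
    """
    if m.values.shape[1] < 3:
        raise ValueError("suspect-probe statistics need at least 3 samples")
    vals = m.values.to_numpy(dtype=float)
    col_means = vals.mean(axis=0)
    scaling = col_means - col_means.mean()
    centered = vals - col_means  # broadcast over rows

    sd = centered.std(axis=1, ddof=1)
    cs = centered - centered.mean(axis=1, keepdims=True)
    ss = scaling - scaling.mean()
    denom = np.sqrt((cs**2).sum(axis=1) * (ss**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cs @ ss / denom, 0.0)

    if sd_cut is None:
        sd_cut = float(np.quantile(sd, sd_cut_quantile))
    flagged = (corr <= corr_cut) & (sd >= sd_cut) & (sd > 0)

    report = QCReport(thresholds={"corr_cut": corr_cut, "sd_cut": sd_cut})
    idx = m.values.index
    report.suspect_probes = [idx[i] for i in np.flatnonzero(flagged)]
    report.suspect_probe_stats = {
        idx[i]: (float(corr[i]), float(sd[i])) for i in np.flatnonzero(flagged)
    }
    # keep the full statistic vectors for rank-based diagnostics
    report.thresholds["n_flagged"] = float(flagged.sum())
    report.anti_correlation = pd.Series(corr, index=idx)  # type: ignore[attr-defined]
    report.centered_sd = pd.Series(sd, index=idx)  # type: ignore[attr-defined]
    return report


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Quantile normalization between arrays.

    Each column's sorted values are replaced by the across-column mean of the
    sorted values, so all arrays end with an identical empirical distribution
    while within-array ranks are preserved.  Ties within a column receive the
    mean of their tied quantile values.
    """
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return ProbeMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.sample_meta,
    )


# ---------------------------------------------------------------------------
# TSV I/O


def read_matrix_tsv(matrix_path, sample_sheet_path) -> ProbeMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    meta = dict(zip(sheet["sample_id"], sheet["mother_id"]))
    return ProbeMatrix(values, meta)


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "transcript_id", "gene_id"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return ann


def read_sample_sheet_tsv(path) -> dict[str, str]:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(sheet["sample_id"], sheet["mother_id"]))
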