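"""Expressed vs non-expressed calling from intensity-variance bimodality.

On single-egg arrays, probes that detect real transcripts vary between eggs
(biologically and technically) while probes reading background do not.  The
distribution of per-probe log variances is therefore bimodal.  The procedure:

1. per probe, the natural log of the across-experiment variance of the log2
   intensities;
2. the valley of the bimodal log-variance distribution splits probes into a
   low-variance (background) and a high-variance (expressed) population;
3. Bayes' theorem turns the two populations into a per-array, per-probe
   posterior probability that a probe's intensity was drawn from the
   high-variance class; a probe is expressed on an array when that posterior
   exceeds a stringent threshold (default 0.95);
4. a transcript (one probe per transcript) is expressed in the experiment
   when its probe is expressed on at least ``min_arrays`` arrays (default 4);
5. a gene is expressed when any of its transcripts is, and is thereafter
   represented by its probe with the highest mean intensity over all samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .preprocess import ProbeMatrix

__all__ = [
    "VarianceSplit",
    "ExpressionCalls",
    "BimodalityError",
    "probe_log_variance",
    "find_valley_threshold",
    "classify_probe_variance",
    "posterior_expressed",
    "call_transcripts",
    "collapse_genes",
    "call_expression",
]


class BimodalityError(ValueError):
    """Raised when a log-variance distribution shows no two modes."""


@dataclass
class VarianceSplit:
    """Partition of probes at the valley of the log-variance distribution.

    Probes exactly at the valley go to the high-variance class (boundary
    convention: ``log_variance >= valley`` is high).
    """

    log_variance: pd.Series
    valley: float
    low_probes: list[str] = field(default_factory=list)
    high_probes: list[str] = field(default_factory=list)

    @property
    def prior_high(self) -> float:
        n = len(self.low_probes) + len(self.high_probes)
        return len(self.high_probes) / n if n else 0.0


@dataclass
class ExpressionCalls:
    """Per-probe/per-sample posteriors and the derived expressed sets."""

    posterior: pd.DataFrame
    probe_sample_expressed: pd.DataFrame
    expressed_transcripts: set[str]
    expressed_genes: set[str]
    nonexpressed_genes: set[str]
    representative_probe: dict[str, str]
    posterior_threshold: float = 0.95
    min_arrays: int = 4


def probe_log_variance(m: ProbeMatrix) -> pd.Series:
    """Natural log of the unbiased across-sample variance of each probe.

    Zero-variance probes (log undefined) are mapped to one below the minimum
    finite log-variance so they always land in the low-variance class.
    """
    if m.values.shape[1] < 2:
        raise ValueError("variance needs at least 2 samples")
    var = m.values.var(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore"):
        logv = np.log(var)
    finite = np.isfinite(logv)
    if not finite.any():
        raise ValueError("all probes have zero variance")
    logv[~finite] = logv[finite].min() - 1.0
    return pd.Series(logv, index=m.values.index, name="log_variance")


def _binned_kde(x: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE evaluated on a uniform grid via binned convolution."""
    step = grid[1] - grid[0]
    counts, _ = np.histogram(x, bins=len(grid), range=(grid[0] - step / 2, grid[-1] + step / 2))
    dens = gaussian_filter1d(counts.astype(float), sigma=bandwidth / step, mode="constant")
    return dens / (len(x) * step)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, robustified with the IQR."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("degenerate sample for bandwidth selection")
    return 0.9 * scale * len(x) ** (-1 / 5)


def find_valley_threshold(
    log_variances,
    bandwidth: float | None = None,
    grid_size: int = 512,
    n_bins: int = 200,
) -> float:
    """Locate the density minimum between the two main log-variance modes.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a grid; the valley is
    the grid minimum strictly between the two highest local maxima.  If the
    KDE shows a single mode, a 200-bin histogram is tried as a fallback;
    unimodal input raises :class:`BimodalityError` rather than returning a
    silent threshold.
    """
    x = np.asarray(log_variances, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("too few values for valley detection")
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
    pad = 3 * h
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = _binned_kde(x, grid, h)

    valley = _valley_between_modes(grid, dens)
    if valley is not None:
        return valley
    # histogram fallback: coarser but bandwidth-free; count noise is
    # Poisson, so a mode must also clear a few counting standard deviations
    counts, edges = np.histogram(x, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    valley = _valley_between_modes(
        centers, counts.astype(float), min_prominence=4 * np.sqrt(counts.max())
    )
    if valley is None:
        raise BimodalityError("log-variance distribution is not bimodal")
    return valley


def _valley_between_modes(
    grid: np.ndarray, dens: np.ndarray, min_prominence: float = 0.0
) -> float | None:
    # a mode must rise at least 5% of the maximum density above its
    # surroundings; this rejects sampling ripples on a unimodal density
    peaks, _ = find_peaks(dens, prominence=max(0.05 * dens.max(), min_prominence))
    if len(peaks) < 2:
        return None
    top2 = sorted(sorted(peaks, key=lambda p: dens[p], reverse=True)[:2])
    lo, hi = top2
    if hi - lo < 2:
        return None
    seg = slice(lo + 1, hi)
    return float(grid[seg][np.argmin(dens[seg])])


def classify_probe_variance(log_variances: pd.Series, valley: float) -> VarianceSplit:
    """Split probes at the valley; the valley itself belongs to the high class."""
    if not np.isfinite(valley):
        raise ValueError("valley must be finite")
    lv = log_variances
    high = lv[lv >= valley].index
    low = lv[lv < valley].index
    return VarianceSplit(
        log_variance=lv,
        valley=float(valley),
        low_probes=list(low),
        high_probes=list(high),
    )


def _class_density_grids(
    x_low: np.ndarray,
    x_high: np.ndarray,
    density: str,
    grid_size: int = 2048,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = min(x_low.min(), x_high.min())
    hi = max(x_low.max(), x_high.max())
    pad = 0.05 * (hi - lo) + 1e-9
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    if density == "kde":
        f_low = _binned_kde(x_low, grid, silverman_bandwidth(x_low))
        f_high = _binned_kde(x_high, grid, silverman_bandwidth(x_high))
    elif density == "gaussian":
        from scipy.stats import norm

        f_low = norm.pdf(grid, x_low.mean(), x_low.std(ddof=1))
        f_high = norm.pdf(grid, x_high.mean(), x_high.std(ddof=1))
    else:
        raise ValueError("density must be 'kde' or 'gaussian'")
    return grid, f_low, f_high


def posterior_expressed(
    m: ProbeMatrix,
    split: VarianceSplit,
    density: str = "kde",
    per_array: bool = True,
) -> pd.DataFrame:
    """Posterior P(high-variance class | intensity), per probe and array.

    Class-conditional intensity densities are estimated from each array's own
    low-class and high-class probe intensities (``per_array=False`` pools all
    arrays); priors are the experiment-wide class proportions.  Where both
    densities vanish (an intensity outside either class's support) the
    posterior is assigned by which class's observed support is nearer.  With
    a degenerate prior (one class empty) the posterior is constant 1 (no low
    class) or 0 (no high class).
    """
    if not split.low_probes:
        return pd.DataFrame(1.0, index=m.values.index, columns=m.values.columns)
    if not split.high_probes:
        return pd.DataFrame(0.0, index=m.values.index, columns=m.values.columns)
    pi_high = split.prior_high
    pi_low = 1.0 - pi_high
    vals = m.values
    low_idx = vals.index.isin(split.low_probes)
    high_idx = vals.index.isin(split.high_probes)

    out = np.empty(vals.shape)
    if not per_array:
        x_low = vals.to_numpy()[low_idx].ravel()
        x_high = vals.to_numpy()[high_idx].ravel()
        pooled = _class_density_grids(x_low, x_high, density)
    for j in range(vals.shape[1]):
        if per_array:
            x_low = vals.iloc[:, j].to_numpy()[low_idx]
            x_high = vals.iloc[:, j].to_numpy()[high_idx]
            grid, f_low, f_high = _class_density_grids(x_low, x_high, density)
        else:
            grid, f_low, f_high = pooled
        x = vals.iloc[:, j].to_numpy()
        fl = np.interp(x, grid, f_low, left=0.0, right=0.0)
        fh = np.interp(x, grid, f_high, left=0.0, right=0.0)
        num = pi_high * fh
        den = num + pi_low * fl
        with np.errstate(invalid="ignore"):
            post = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        # nearest-support rule where both densities vanish
        bad = ~np.isfinite(post)
        if bad.any():
            d_low = np.minimum(np.abs(x[bad] - x_low.min()), np.abs(x[bad] - x_low.max()))
            d_high = np.minimum(np.abs(x[bad] - x_high.min()), np.abs(x[bad] - x_high.max()))
            post[bad] = (d_high < d_low).astype(float)
        out[:, j] = post
    return pd.DataFrame(out, index=vals.index, columns=vals.columns)


def call_transcripts(
    probe_sample_expressed: pd.DataFrame,
    probe_to_transcript: dict[str, str],
    min_arrays: int = 4,
) -> tuple[set[str], list[str]]:
    """Transcripts expressed somewhere in the experiment.

    A transcript is expressed iff its probe is expressed on at least
    ``min_arrays`` arrays.  Returns the expressed set and the list of probes
    without a transcript mapping (reported, excluded).
    """
    if min_arrays < 1:
        raise ValueError("min_arrays must be >= 1")
    counts = probe_sample_expressed.sum(axis=1)
    unmapped = [p for p in probe_sample_expressed.index if p not in probe_to_transcript]
    expressed = {
        probe_to_transcript[p]
        for p, c in counts.items()
        if c >= min_arrays and p in probe_to_transcript
    }
    return expressed, unmapped


def collapse_genes(
    expressed_transcripts: set[str],
    annotation: pd.DataFrame,
    m: ProbeMatrix,
) -> tuple[set[str], set[str], dict[str, str]]:
    """Collapse transcript calls to genes and pick a representative probe.

    A gene is expressed when at least one of its transcripts is.  Among a
    gene's probes present in the matrix, the representative is the probe with
    the highest mean intensity over all samples (ties: lexicographically
    smallest probe id).  Genes with no probe in the matrix are excluded.
    """
    mean_int = m.values.mean(axis=1)
    ann = annotation[annotation["probe_id"].isin(m.values.index)].copy()
    ann["mean_intensity"] = ann["probe_id"].map(mean_int)

    expressed_genes: set[str] = set(
        ann.loc[ann["transcript_id"].isin(expressed_transcripts), "gene_id"]
    )
    all_genes = set(ann["gene_id"])
    nonexpressed_genes = all_genes - expressed_genes

    representative: dict[str, str] = {}
    for gene, grp in ann.groupby("gene_id"):
        best = grp.sort_values(
            ["mean_intensity", "probe_id"], ascending=[False, True]
        ).iloc[0]
        representative[gene] = best["probe_id"]
    return expressed_genes, nonexpressed_genes, representative


def call_expression(
    m: ProbeMatrix,
    annotation: pd.DataFrame,
    posterior_threshold: float = 0.95,
    min_arrays: int = 4,
    density: str = "kde",
    per_array: bool = True,
    valley: float | None = None,
) -> ExpressionCalls:
    """Run the full expressed-gene calling procedure on a (raw) matrix."""
    logv = probe_log_variance(m)
    if valley is None:
        valley = find_valley_threshold(logv)
    split = classify_probe_variance(logv, valley)
    post = posterior_expressed(m, split, density=density, per_array=per_array)
    expressed_mat = post > posterior_threshold
    probe_to_transcript = dict(zip(annotation["probe_id"], annotation["transcript_id"]))
    transcripts, _ = call_transcripts(expressed_mat, probe_to_transcript, min_arrays)
    genes, nongenes, rep = collapse_genes(transcripts, annotation, m)
    return ExpressionCalls(
        posterior=post,
        probe_sample_expressed=expressed_mat,
        expressed_transcripts=transcripts,
        expressed_genes=genes,
        nonexpressed_genes=nongenes,
        representative_probe=rep,
        posterior_threshold=posterior_threshold,
        min_arrays=min_arrays,
    )
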