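"""Fold-change variability of gene expression, experiment-wide and per clutch.

The maximum fold change (mFC) of a gene is the ratio of its highest to its
lowest expression over a sample set; on log2 data it is simply max minus min.
The within-clutch mFC restricts the comparison to eggs of a single mother and
takes the largest such range over all clutches — the key statistic showing
that egg-to-egg variability inside a clutch is far smaller than between
mothers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import ProbeMatrix

__all__ = ["max_fold_change", "within_clutch_mfc", "mfc_table", "mfc_summary"]


def max_fold_change(values) -> float:
    """Experiment-wide log2 mFC: max log2 intensity minus min."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("mFC needs at least 2 samples")
    return float(x.max() - x.min())


def within_clutch_mfc(values, clutch_assignment) -> float:
    """Largest within-clutch log2 range over all clutches.

    ``clutch_assignment`` maps each sample position to a clutch label; every
    clutch must contain at least 2 samples for its range to be defined.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(clutch_assignment)
    if x.shape != labels.shape:
        raise ValueError("values and clutch assignment differ in length")
    best = 0.0
    for c in np.unique(labels):
        grp = x[labels == c]
        if grp.size < 2:
            raise ValueError(f"clutch {c!r} has fewer than 2 samples")
        best = max(best, float(grp.max() - grp.min()))
    return best


def mfc_table(
    m: ProbeMatrix,
    representative_probe: dict[str, str],
    genes=None,
) -> pd.DataFrame:
    """Per-gene mFC statistics on the representative probe's values.

    Returns a frame indexed by gene with ``mfc_experiment``,
    ``mfc_within_clutch`` (both log2) and per-clutch min/max/mean columns.
    """
    if genes is None:
        genes = sorted(representative_probe)
    probes = [representative_probe[g] for g in genes]
    sub = m.values.loc[probes].to_numpy()
    labels = np.array([m.sample_meta[s] for s in m.values.columns])

    rows: dict[str, np.ndarray] = {
        "mfc_experiment": sub.max(axis=1) - sub.min(axis=1),
    }
    clutch_ranges = []
    for c in sorted(set(labels)):
        grp = sub[:, labels == c]
        if grp.shape[1] < 2:
            raise ValueError(f"clutch {c!r} has fewer than 2 samples")
        rows[f"min_{c}"] = grp.min(axis=1)
        rows[f"max_{c}"] = grp.max(axis=1)
        rows[f"mean_{c}"] = grp.mean(axis=1)
        clutch_ranges.append(grp.max(axis=1) - grp.min(axis=1))
    rows["mfc_within_clutch"] = np.max(clutch_ranges, axis=0)
    out = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"))
    return out[["mfc_experiment", "mfc_within_clutch"]
               + [c for c in out.columns if c not in ("mfc_experiment", "mfc_within_clutch")]]


def mfc_summary(table: pd.DataFrame, thresholds=(2.0, 4.0)) -> pd.DataFrame:
    """Fractions of genes with mFC at or below each fold-change threshold.

    Thresholds are plain fold changes (>1) applied as ``log2 mFC <= log2(t)``.
    """
    rows = []
    for t in thresholds:
        if t <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        bound = np.log2(t)
        rows.append(
            {
                "threshold_fc": t,
                "frac_experiment": float((table["mfc_experiment"] <= bound).mean()),
                "frac_within_clutch": float((table["mfc_within_clutch"] <= bound).mean()),
            }
        )
    return pd.DataFrame(rows)
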