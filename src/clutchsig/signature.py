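"""Absolute distinct mother-specific expression levels and signature clusters.

For every expressed gene the per-clutch intensity range is computed.  If the
five clutch ranges separate into groups with no overlap between groups, the
gene shows "absolute distinct" mother-specific expression levels.  Each such
gene is encoded by a profile code with one digit per mother giving the rank
of that mother's level (1 = highest); genes sharing a code form a signature
cluster, and two-level codes come in inverse pairs (1s and 2s swapped).

Overlap is taken on closed intervals — a shared endpoint counts as overlap —
so "no overlap" requires a strict gap between levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClutchProfile",
    "SignatureCluster",
    "clutch_ranges",
    "detect_distinct_levels",
    "profile_table",
    "group_clusters",
    "inverse_code",
    "find_inverse_pairs",
]


@dataclass
class ClutchProfile:
    """Per-clutch intensity intervals and the distinct-level profile of a gene."""

    gene_id: str
    # clutch id -> (min, max) of log2 intensity, fixed clutch order
    intervals: dict[str, tuple[float, float]]
    # level groups, highest first; each a list of clutch ids
    level_groups: list[list[str]]
    n_levels: int
    code: str | None  # None when n_levels == 1 (no signature)


@dataclass
class SignatureCluster:
    """Genes sharing a distinct-level profile code."""

    code: str
    genes: list[str]
    inverse_code: str | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def clutch_ranges(values, clutch_assignment) -> dict[str, tuple[float, float]]:
    """[min, max] of log2 intensity per clutch (each clutch needs >= 2 eggs)."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(clutch_assignment)
    out: dict[str, tuple[float, float]] = {}
    for c in np.unique(labels):
        grp = x[labels == c]
        if grp.size < 2:
            raise ValueError(f"clutch {c!r} has fewer than 2 samples")
        out[str(c)] = (float(grp.min()), float(grp.max()))
    return out


def _merge_overlapping(intervals: dict[str, tuple[float, float]]) -> list[list[str]]:
    """Transitive closed-interval overlap groups, ordered by hull midpoint desc.

    Intervals [a,b] and [c,d] overlap iff a <= d and c <= b; groups are the
    connected components of the overlap graph, found by a sweep over the
    intervals sorted by lower bound.
    """
    items = sorted(intervals.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    groups: list[list[str]] = []
    hulls: list[tuple[float, float]] = []
    for clutch, (lo, hi) in items:
        if groups and lo <= hulls[-1][1]:
            groups[-1].append(clutch)
            hulls[-1] = (hulls[-1][0], max(hulls[-1][1], hi))
        else:
            groups.append([clutch])
            hulls.append((lo, hi))
    # rank by hull midpoint descending; ties by group minimum descending
    order = sorted(
        range(len(groups)),
        key=lambda i: ((hulls[i][0] + hulls[i][1]) / 2, hulls[i][0]),
        reverse=True,
    )
    return [sorted(groups[i]) for i in order]


def detect_distinct_levels(
    intervals: dict[str, tuple[float, float]],
    gene_id: str = "",
    mother_order: list[str] | None = None,
) -> ClutchProfile:
    """Partition clutch intervals into absolutely distinct expression levels.

    Clutches are merged by transitive interval overlap; if more than one group
    remains, every pair of group hulls is separated by a strict gap (this is
    guaranteed by the transitive merge) and the gene carries an absolute
    distinct mother-specific signature.  Groups are ranked by hull midpoint,
    highest first, and the profile code assigns each mother the rank digit of
    its group.  ``n_levels == 1`` means no signature and no code.
    """
    if mother_order is None:
        mother_order = sorted(intervals)
    groups = _merge_overlapping(intervals)
    n_levels = len(groups)
    if n_levels == 1:
        return ClutchProfile(gene_id, dict(intervals), groups, 1, None)
    rank = {c: i + 1 for i, grp in enumerate(groups) for c in grp}
    code = "".join(str(rank[c]) for c in mother_order)
    return ClutchProfile(gene_id, dict(intervals), groups, n_levels, code)


def profile_table(
    m,
    representative_probe: dict[str, str],
    genes=None,
) -> list[ClutchProfile]:
    """Distinct-level profiles for every gene on its representative probe."""
    if genes is None:
        genes = sorted(representative_probe)
    labels = [m.sample_meta[s] for s in m.values.columns]
    mother_order = sorted(set(labels))
    out = []
    for g in genes:
        vals = m.values.loc[representative_probe[g]].to_numpy()
        out.append(
            detect_distinct_levels(clutch_ranges(vals, labels), g, mother_order)
        )
    return out


def group_clusters(
    profiles: list[ClutchProfile],
    min_size: int = 1,
) -> list[SignatureCluster]:
    """Group signature genes (n_levels > 1) by profile code.

    One cluster per distinct code, ordered by size descending (ties by code);
    ``min_size`` filters the report (the headline report threshold in this
    design is 25 genes).
    """
    by_code: dict[str, list[str]] = {}
    for p in profiles:
        if p.code is not None:
            by_code.setdefault(p.code, []).append(p.gene_id)
    clusters = [
        SignatureCluster(code, sorted(genes))
        for code, genes in by_code.items()
        if len(genes) >= min_size
    ]
    clusters.sort(key=lambda c: (-c.size, c.code))
    codes = {c.code for c in clusters}
    for c in clusters:
        if set(c.code) <= {"1", "2"}:
            inv = inverse_code(c.code)
            c.inverse_code = inv if inv in codes else None
    return clusters


def inverse_code(code: str) -> str:
    """Swap the two levels of a two-level profile code (an involution)."""
    if not set(code) <= {"1", "2"}:
        raise ValueError(f"not a two-level code: {code!r}")
    return code.translate(str.maketrans("12", "21"))


def find_inverse_pairs(clusters: list[SignatureCluster]) -> list[tuple[str, str]]:
    """Pairs of two-level codes where both a code and its inverse are present.

    Codes with more than two levels are skipped.  Each pair is reported once,
    with the lexicographically smaller code first.
    """
    codes = {c.code for c in clusters if set(c.code) <= {"1", "2"}}
    pairs = set()
    for code in codes:
        inv = inverse_code(code)
        if inv in codes and inv != code:
            pairs.add((min(code, inv), max(code, inv)))
    return sorted(pairs)


def profiles_to_frame(profiles: list[ClutchProfile]) -> pd.DataFrame:
    """Per-gene profile table (gene_id, code, n_levels, per-clutch min/max)."""
    rows = []
    for p in profiles:
        row = {"gene_id": p.gene_id, "code": p.code or "", "n_levels": p.n_levels}
        for c, (lo, hi) in p.intervals.items():
            row[f"min_{c}"] = lo
            row[f"max_{c}"] = hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
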