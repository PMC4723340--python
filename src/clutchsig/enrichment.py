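"""3'UTR motif enrichment, gene-set overrepresentation, and chromosome clustering.

Maternal transcripts stored in the egg are stabilized and translationally
activated through elements in their 3'UTRs: polyadenylation hexamers (AAUAAA,
AUUAAA), U-rich cytoplasmic polyadenylation elements (CPE: UUUUAU, UUUUAMU),
the Pumilio binding element (UGUA(N)AUA) and long embryonic CPEs (runs of
11-20 Us).  Enrichment of a motif in a foreground set of UTRs against control
UTRs is tested with a one-sided Wilcoxon rank-sum test on per-sequence
average-odds scores, Bonferroni-corrected across the motif set.

The module also provides the generic hypergeometric overrepresentation test
(miRNA target sets, pathway-style gene sets), the overlap ratio against
externally defined gene clusters, and the clusters x chromosomes fraction
matrix with Euclidean/Ward hierarchical clustering used to show that inverse
signature clusters share chromosome distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import gammaln, logsumexp

__all__ = [
    "Motif",
    "EnrichmentResult",
    "builtin_motifs",
    "scan_motif",
    "rank_sum_pvalue",
    "motif_enrichment",
    "hypergeom_overrep",
    "gene_set_overlap",
    "chromosome_fraction_matrix",
    "ward_cluster_rows",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC", "B": "CGU", "D": "AGU",
    "H": "ACU", "V": "ACG", "N": "ACGU",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class Motif:
    """An RNA sequence element given as an IUPAC pattern.

    The pattern expands to a position-weight representation with probability
    ``1/|allowed bases|`` per column against a uniform 0.25 background.
    """

    id: str
    pattern: str
    odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("T", "U")
        if not pat:
            raise ValueError("empty motif pattern")
        bad = set(pat) - set(_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols in {self.pattern!r}: {bad}")
        self.pattern = pat
        odds = np.zeros((len(pat), 4))
        for i, sym in enumerate(pat):
            allowed = _IUPAC[sym]
            for b in allowed:
                odds[i, _BASE_INDEX[b]] = (1.0 / len(allowed)) / 0.25
        self.odds = odds

    def __len__(self) -> int:
        return len(self.pattern)

    def consensus(self, rng: np.random.Generator | None = None) -> str:
        """A concrete realization of the pattern (random choice at ambiguity)."""
        if rng is None:
            rng = np.random.default_rng(0)
        return "".join(
            _IUPAC[s][rng.integers(len(_IUPAC[s]))] if len(_IUPAC[s]) > 1 else s
            for s in self.pattern
        )


def builtin_motifs() -> list[Motif]:
    """The 3'UTR element set: PAS hexamers, CPEs, PBE and eCPE U-runs 11-20.

    Each poly-U length is its own motif in the Bonferroni family.
    """
    motifs = [
        Motif("PAS_AAUAAA", "AAUAAA"),
        Motif("PAS_AUUAAA", "AUUAAA"),
        Motif("CPE_UUUUAU", "UUUUAU"),
        Motif("CPE_UUUUAMU", "UUUUAMU"),
        Motif("PBE_UGUANAUA", "UGUANAUA"),
    ]
    motifs += [Motif(f"eCPE_U{k}", "U" * k) for k in range(11, 21)]
    return motifs


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("T", "U")
    idx = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype="S1") == b.encode()] = i
    return idx


def scan_motif(sequence: str, motif: Motif) -> tuple[float, int]:
    """Average-odds score of a motif over one sequence, plus exact-hit count.

    The score is the mean over all windows (same strand only) of the product
    of per-position odds ``p(base|motif)/0.25``; a window containing a base
    the pattern disallows contributes 0.  Ambiguous sequence letters (N)
    contribute odds 1 at their position.  The exact-hit count is the number
    of windows matching the IUPAC pattern.  Sequences shorter than the motif
    score 0 with 0 hits.
    """
    k = len(motif)
    idx = _encode(sequence)
    L = len(idx)
    if L < k:
        return 0.0, 0
    n_win = L - k + 1
    # per-position odds, with N (and other non-ACGU) as neutral odds 1
    odds_cols = np.empty((k, L))
    for i in range(k):
        col = np.ones(L)
        valid = idx >= 0
        col[valid] = motif.odds[i, idx[valid]]
        odds_cols[i] = col
    windows = np.ones(n_win)
    matches = np.ones(n_win, dtype=bool)
    for i in range(k):
        seg = odds_cols[i, i : i + n_win]
        windows *= seg
        matches &= seg > 0
        # an N in the sequence is neutral for scoring but not an exact match
        matches &= idx[i : i + n_win] >= 0
    return float(windows.mean()), int(matches.sum())


def rank_sum_pvalue(fg_scores, ct_scores, max_enumeration: int = 100_000) -> float:
    """One-sided (foreground greater) Wilcoxon rank-sum p-value.

    Consensus-motif scores on short UTRs are essentially hit counts, so the
    pooled scores often take only a handful of distinct values; there the
    normal approximation is anti-conservative and the p-value is instead
    computed exactly, by enumerating the permutation distribution of the
    foreground mid-rank sum over the tie classes (a multivariate
    hypergeometric).  Rich, near-continuous scores use the standard
    tie-corrected asymptotic test.  All scores tied gives p = 1.
    """
    fg = np.asarray(fg_scores, dtype=float)
    ct = np.asarray(ct_scores, dtype=float)
    pooled = np.concatenate([fg, ct])
    values, counts = np.unique(pooled, return_counts=True)
    if len(values) == 1:
        return 1.0

    base = int(np.argmax(counts))
    others = [i for i in range(len(values)) if i != base]
    n_comb = int(np.prod([counts[i] + 1 for i in others], dtype=float))
    if n_comb > max_enumeration:
        return float(stats.mannwhitneyu(fg, ct, alternative="greater")[1])

    # mid-ranks per tie class
    ends = np.cumsum(counts)
    starts = ends - counts + 1
    midranks = (starts + ends) / 2.0
    n_fg, n_total = len(fg), len(pooled)

    j_obs = np.array([np.sum(fg == v) for v in values])
    t_obs = float(j_obs @ midranks)

    import itertools as _it

    log_denom = gammaln(n_total + 1) - gammaln(n_fg + 1) - gammaln(n_total - n_fg + 1)
    log_terms = []
    for combo in _it.product(*(range(counts[i] + 1) for i in others)):
        j_base = n_fg - sum(combo)
        if not 0 <= j_base <= counts[base]:
            continue
        j = np.empty(len(values))
        j[others] = combo
        j[base] = j_base
        if j @ midranks < t_obs - 1e-9:
            continue
        log_p = (
            np.sum(gammaln(counts + 1) - gammaln(j + 1) - gammaln(counts - j + 1))
            - log_denom
        )
        log_terms.append(log_p)
    if not log_terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class EnrichmentResult:
    id: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_foreground: int
    n_background: int


def motif_enrichment(
    foreground: dict[str, str],
    control: dict[str, str],
    motifs: list[Motif] | None = None,
) -> list[EnrichmentResult]:
    """Discriminative motif enrichment of foreground vs control UTRs.

    Per motif, every sequence is scored with the average-odds score and a
    one-sided Wilcoxon rank-sum test asks whether foreground scores exceed
    control scores; p-values are Bonferroni-adjusted for the size of the
    motif set.  All-tied scores give p = 1.
    """
    if not foreground or not control:
        raise ValueError("both sequence groups must be non-empty")
    if motifs is None:
        motifs = builtin_motifs()
    out = []
    for motif in motifs:
        fg = np.array([scan_motif(s, motif)[0] for s in foreground.values()])
        ct = np.array([scan_motif(s, motif)[0] for s in control.values()])
        pooled = np.concatenate([fg, ct])
        ranks = stats.rankdata(pooled)
        stat = float(ranks[: len(fg)].sum())
        p = rank_sum_pvalue(fg, ct)
        out.append(
            EnrichmentResult(
                id=motif.id,
                statistic=float(stat),
                p_raw=float(p),
                p_adjusted=min(1.0, float(p) * len(motifs)),
                n_foreground=len(fg),
                n_background=len(ct),
            )
        )
    return out


def hypergeom_overrep(
    set_of_interest: set[str],
    annotation_set: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric overrepresentation of an annotation set.

    With universe size N, annotation size K, interest size n and overlap k,
    the p-value is ``P(X >= k)`` for X hypergeometric(N, K, n); an observed
    overlap of 0 gives p = 1.
    """
    if not universe:
        raise ValueError("empty universe")
    interest = set_of_interest & universe
    annot = annotation_set & universe
    k = len(interest & annot)
    N, K, n = len(universe), len(annot), len(interest)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        id="hypergeometric",
        statistic=float(k),
        p_raw=p,
        p_adjusted=p,
        n_foreground=n,
        n_background=N,
    )


def gene_set_overlap(our_set: set[str], reference_set: set[str]) -> float:
    """Fraction of an external reference gene set recovered by ours."""
    if not reference_set:
        raise ValueError("empty reference set")
    return len(set(our_set) & set(reference_set)) / len(reference_set)


def chromosome_fraction_matrix(
    clusters: dict[str, list[str]],
    gene_chromosome: dict[str, str],
    unplaced_label: str = "unplaced",
) -> pd.DataFrame:
    """Clusters x chromosomes matrix of gene-location fractions (rows sum to 1).

    Genes without a chromosome assignment count in an ``unplaced`` column;
    empty clusters are dropped (with their row absent rather than NaN).
    """
    chroms = sorted(set(gene_chromosome.values()))
    rows = {}
    for name, genes in clusters.items():
        if not genes:
            continue
        counts = pd.Series(0.0, index=chroms + [unplaced_label])
        for g in genes:
            counts[gene_chromosome.get(g, unplaced_label)] += 1
        rows[name] = counts / counts.sum()
    out = pd.DataFrame(rows).T
    if out.get(unplaced_label, pd.Series(dtype=float)).sum() == 0:
        out = out.drop(columns=[unplaced_label], errors="ignore")
    return out


def ward_cluster_rows(
    matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Hierarchical clustering of matrix rows (Euclidean distance, Ward linkage).

    Returns the scipy linkage matrix, the leaf order (row labels), and the
    list of row pairs that merge as first-level pairs (both members original
    leaves) — the analogue of inverse-profile clusters pairing up in the
    chromosome-distribution clusterogram.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN")
    # sort rows by label so the tree does not depend on input row order
    ordered = matrix.sort_index()
    Z = hierarchy.linkage(ordered.to_numpy(), method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    labels = list(ordered.index)
    leaf_order = [labels[i] for i in leaves]
    n = len(labels)
    leaf_pairs = [
        (labels[int(a)], labels[int(b)]) if labels[int(a)] <= labels[int(b)]
        else (labels[int(b)], labels[int(a)])
        for a, b, _, _ in Z
        if a < n and b < n
    ]
    return Z, leaf_order, sorted(leaf_pairs)
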