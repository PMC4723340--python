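"""Per-gene one-way ANOVA with clutch as factor, with FDR control.

Each gene's normalized log2 intensities are fitted to a fixed-effects one-way
model with clutch (= mother) as the single factor; the F statistic tests
whether any mother differs from any other.  Multiple testing is controlled
with Storey q-values (pi0 estimated on a lambda grid with a cubic-smoother
extrapolation), with Benjamini-Hochberg available as a fallback mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DEGResult", "anova_f_per_gene", "anova_table", "estimate_qvalues"]

_TINY_P = np.nextafter(0, 1)


@dataclass
class DEGResult:
    gene_id: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    zero_within_variance: bool = False


def anova_f_per_gene(values, clutch_assignment) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects F test for a single gene.

    Returns ``(F, (df_between, df_within), p)``.  With zero within-group
    variance but non-zero between-group variance the p-value is reported as
    the smallest positive float rather than 0.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(clutch_assignment)
    groups = [x[labels == c] for c in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 clutches with >= 2 samples each")
    k = len(groups)
    n = len(x)
    grand = x.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, (dfb, dfw), 1.0
        return np.inf, (dfb, dfw), _TINY_P
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), (dfb, dfw), p


def anova_table(
    m,
    representative_probe: dict[str, str],
    genes=None,
    fdr: float = 0.05,
    method: str = "storey",
) -> pd.DataFrame:
    """Vectorized per-gene clutch ANOVA over the representative probes.

    Returns a frame indexed by gene with F, dfs, p, q and a ``significant``
    flag at the requested FDR.
    """
    if genes is None:
        genes = sorted(representative_probe)
    probes = [representative_probe[g] for g in genes]
    x = m.values.loc[probes].to_numpy(dtype=float)
    labels = np.array([m.sample_meta[s] for s in m.values.columns])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clutches")
    n = x.shape[1]
    k = len(uniq)
    grand = x.mean(axis=1, keepdims=True)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for c in uniq:
        grp = x[:, labels == c]
        if grp.shape[1] < 2:
            raise ValueError(f"clutch {c!r} has fewer than 2 samples")
        gm = grp.mean(axis=1, keepdims=True)
        ssb += grp.shape[1] * (gm - grand).ravel() ** 2
        ssw += ((grp - gm) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n - k
    zero_within = (ssw == 0) & (ssb > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    f[(ssw == 0) & (ssb == 0)] = 0.0
    p = stats.f.sf(f, dfb, dfw)
    p[zero_within] = _TINY_P
    p[(ssw == 0) & (ssb == 0)] = 1.0

    q, significant, pi0 = estimate_qvalues(p, fdr=fdr, method=method)
    out = pd.DataFrame(
        {
            "f_statistic": f,
            "df_between": dfb,
            "df_within": dfw,
            "p_value": p,
            "q_value": q,
            "significant": significant,
            "zero_within_variance": zero_within,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    out.attrs["pi0"] = pi0
    return out


def estimate_qvalues(
    p_values,
    fdr: float = 0.05,
    method: str = "storey",
    lambdas=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Storey q-values with smoothed pi0, or Benjamini-Hochberg.

    pi0 is estimated as ``#{p > lambda} / (m (1 - lambda))`` over a lambda
    grid (default 0.05..0.95 step 0.05), extrapolated to lambda -> 1 with a
    cubic polynomial smoother and clipped to (0, 1].  The q-value of the
    gene ranked ``i`` by p is ``min_{j >= i} pi0 * m * p_(j) / j``.  With
    ``method='bh'`` (or a degenerate p distribution) pi0 is fixed at 1,
    which reduces exactly to Benjamini-Hochberg adjusted p-values.

    Returns ``(q, significant, pi0)`` with ``significant = q < fdr``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        if np.all(pi0_l == 0):
            pi0 = 1.0 / m  # all p tiny; effectively no nulls
        else:
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    else:
        raise ValueError("method must be 'storey' or 'bh'")

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q, q < fdr, pi0
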