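"""Group-comparison statistics: Mann-Whitney, Kruskal-Wallis + Dunn, BH FDR.

Two-group comparisons use the two-sided Mann-Whitney U test (exact null
distribution when both groups have n <= 8 and no ties are present, normal
approximation with tie correction otherwise).  More than two groups use the
Kruskal-Wallis omnibus test followed by Dunn's pairwise z-tests on mean ranks;
Dunn p-values are reported both raw and BH-adjusted.  Significance bands
follow the study's convention, including the trend band: § < 0.1, * < 0.05,
** < 0.01, *** < 0.001, **** < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "mann_whitney",
    "kruskal_dunn",
    "bh_fdr",
    "ddct_fold_change",
    "significance_band",
    "compare_groups",
]


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    adjusted_p: float | None = None
    band: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", significance_band(self.p_value))


def significance_band(p: float) -> str:
    """The study's significance annotation, including the § < 0.1 trend band."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "§"
    return "ns"


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney(x, y, *, names: tuple[str, str] = ("x", "y")) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both samples have n <= 8 and no ties;
    otherwise the plain normal approximation with tie correction (no
    continuity correction, which keeps the null rejection rate close to
    nominal at moderate n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = x.size <= 8 and y.size <= 8 and not _has_ties(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=False)
    return ComparisonResult(
        groups=names, statistic=float(res.statistic),
        p_value=float(res.pvalue), method="mann_whitney",
        n=(x.size, y.size),
    )


def kruskal_dunn(groups: dict[str, np.ndarray] | list) -> tuple[
        ComparisonResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus H plus Dunn's pairwise post-hoc z-tests.

    ``groups`` is a mapping name -> values (or a list of value sets, which
    get positional names).  Returns the omnibus result and a tidy pairwise
    table with z, raw p, BH-adjusted p, and significance bands for both.
    Dunn's z uses mean ranks over the pooled sample with tie correction:

        z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T)(1/n_i + 1/n_j)]

    with T = Σ(t³ − t) / (12(N − 1)) over tie groups.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i}": v for i, v in enumerate(groups)}
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    if len(data) < 3:
        raise ValueError("kruskal_dunn needs at least 3 groups")
    if any(v.size == 0 for v in data):
        raise ValueError("all groups must be non-empty")

    H, p = sps.kruskal(*data)
    omnibus = ComparisonResult(
        groups=tuple(names), statistic=float(H), p_value=float(p),
        method="kruskal_dunn", n=tuple(v.size for v in data),
    )

    pooled = np.concatenate(data)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for v in data:
        mean_ranks.append(ranks[start:start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            praw = 2.0 * sps.norm.sf(abs(z))
            rows.append((names[i], names[j], z, praw))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    pairwise["p_adjusted"] = bh_fdr(pairwise["p_raw"].to_numpy())
    pairwise["band_raw"] = pairwise["p_raw"].map(significance_band)
    pairwise["band_adjusted"] = pairwise["p_adjusted"].map(significance_band)
    return omnibus, pairwise


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ddct_fold_change(ct_target_sample: float, ct_ref_sample: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """qPCR relative expression by the 2^-ΔΔCt method.

    ΔCt normalizes the target gene to the reference (the study uses TBP);
    ΔΔCt subtracts the control-condition ΔCt; one cycle equals a two-fold
    change.
    """
    ddct = ((ct_target_sample - ct_ref_sample)
            - (ct_target_control - ct_ref_control))
    return float(2.0 ** (-ddct))


def compare_groups(table: pd.DataFrame, value_col: str, group_col: str):
    """Dispatch on group count: Mann-Whitney for 2, Kruskal+Dunn for >= 3.

    Returns a tidy results DataFrame.
    """
    groups = {str(k): v[value_col].to_numpy()
              for k, v in table.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        (na, xa), (nb, xb) = groups.items()
        r = mann_whitney(xa, xb, names=(na, nb))
        return pd.DataFrame([{
            "group_a": na, "group_b": nb, "statistic": r.statistic,
            "p_value": r.p_value, "band": r.band, "method": r.method,
            "n_a": r.n[0], "n_b": r.n[1],
        }])
    omnibus, pairwise = kruskal_dunn(groups)
    pairwise = pairwise.copy()
    pairwise["omnibus_H"] = omnibus.statistic
    pairwise["omnibus_p"] = omnibus.p_value
    pairwise["method"] = omnibus.method
    return pairwise
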