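"""Association statistics for categorical and scalar cohort variables.

Implements the four tests used for the group comparisons: Pearson
chi-square with the phi effect size, the exact r x c Fisher test
(Freeman-Halton), Spearman rank correlation, and one-way ANOVA with
Bonferroni-corrected pairwise post-hoc tests.

phi is computed as sqrt(chi2 / N) for every table ("phi, paper
convention"); for df = 1 this is the classical phi coefficient and for
min(r-1, c-1) = 1 it coincides with Cramer's V.  No continuity correction
is applied anywhere.

The exact Fisher p sums, under the multivariate hypergeometric
distribution with fixed margins, the probabilities of all tables no more
probable than the observed one.  It is computed by exhaustive enumeration
of the fixed-margin tables, vectorized and pruned by the column caps; a
seeded Monte-Carlo fallback (proportion of sampled fixed-margin tables no
more probable, with add-one correction) covers tables too large to
enumerate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "FisherResult",
    "chi_square",
    "fisher_exact_rxc",
    "spearman",
    "anova_bonferroni",
    "build_group_symptom_table",
]

EXACT_MAX_DIM = 5
EXACT_MAX_N = 100
EXACT_MAX_TABLES = 5 * 10**7


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.allclose(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    phi: float
    n: int


@dataclass
class FisherResult:
    p: float
    method: str  # "exact" (enumeration) or "monte_carlo"
    n_tables: int | None = None
    reps: int | None = None
    seed: int | None = None
    mc_se: float | None = None


def chi_square(t: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square without continuity correction; phi = sqrt(chi2/N)."""
    counts = t.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(counts, correction=False)
    phi = float(np.sqrt(res.statistic / t.n))
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue),
        phi=phi, n=t.n,
    )


# ---------------------------------------------------------------------------
# exact r x c Fisher
# ---------------------------------------------------------------------------


def _compositions(total: int, caps: list[int]) -> np.ndarray:
    """All non-negative integer vectors summing to ``total`` under caps."""
    out: list[list[int]] = []

    def rec(i: int, rem: int, cur: list[int]) -> None:
        if i == len(caps) - 1:
            if rem <= caps[i]:
                out.append(cur + [rem])
            return
        lo = max(0, rem - sum(caps[i + 1:]))
        for v in range(lo, min(rem, caps[i]) + 1):
            rec(i + 1, rem - v, cur + [v])

    rec(0, total, [])
    if not out:
        return np.empty((0, len(caps)), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def _estimate_n_tables(row_margins: np.ndarray, ncols: int) -> float:
    # loose upper bound: unconstrained compositions of all but the largest row
    rows = np.sort(row_margins)[:-1]
    from math import comb

    est = 1.0
    for r in rows:
        est *= comb(int(r) + ncols - 1, ncols - 1)
    return est


def _fisher_enumerate(counts: np.ndarray) -> tuple[float, int]:
    R = counts.sum(axis=1)
    C = counts.sum(axis=0)
    n = counts.sum()
    logconst = gammaln(R + 1).sum() + gammaln(C + 1).sum() - gammaln(n + 1)
    logp_obs = logconst - gammaln(counts + 1).sum()
    order = np.argsort(R)  # fill the small rows first, largest row implied
    partial = np.zeros((1, len(C)), dtype=np.int64)
    logw = np.zeros(1)
    for rsum in R[order][:-1]:
        parts, weights = [], []
        for p, lw in zip(partial, logw):
            comps = _compositions(int(rsum), (C - p).tolist())
            if len(comps) == 0:
                continue
            parts.append(p + comps)
            weights.append(lw - gammaln(comps + 1).sum(axis=1))
        if not parts:
            return 0.0, 0
        partial = np.concatenate(parts)
        logw = np.concatenate(weights)
    last = C - partial
    logp_all = logconst + logw - gammaln(last + 1).sum(axis=1)
    keep = logp_all <= logp_obs + 1e-7
    return float(np.exp(logp_all[keep]).sum()), int(len(logp_all))


def _fisher_monte_carlo(
    counts: np.ndarray, reps: int, seed: int
) -> tuple[float, float]:
    R = counts.sum(axis=1)
    C = counts.sum(axis=0)
    n = int(counts.sum())
    nr, nc = counts.shape
    logp_obs = -gammaln(counts + 1).sum()  # margin terms are shared, drop them
    row_codes = np.repeat(np.arange(nr), R)
    col_codes = np.repeat(np.arange(nc), C)
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 20_000
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        perms = rng.permuted(np.broadcast_to(col_codes, (b, n)), axis=1)
        cell = row_codes[None, :] * nc + perms
        offsets = (np.arange(b) * nr * nc)[:, None]
        flat = np.bincount((cell + offsets).ravel(), minlength=b * nr * nc)
        tables = flat.reshape(b, nr * nc)
        logp = -gammaln(tables + 1).sum(axis=1)
        hits += int(np.count_nonzero(logp <= logp_obs + 1e-7))
        done += b
    p = (hits + 1) / (reps + 1)
    se = float(np.sqrt(p * (1 - p) / reps))
    return float(p), se


def fisher_exact_rxc(
    t: ContingencyTable,
    method: str = "exact",
    reps: int = 10**6,
    seed: int | None = None,
) -> FisherResult:
    """Exact (Freeman-Halton) or Monte-Carlo Fisher test for an r x c table."""
    counts = t.counts
    nr, nc = counts.shape
    if nr == 1 or nc == 1:
        return FisherResult(p=1.0, method="exact", n_tables=1)
    if method == "exact":
        if nr > EXACT_MAX_DIM or nc > EXACT_MAX_DIM or t.n > EXACT_MAX_N:
            raise ValueError(
                f"table {nr}x{nc} with N={t.n} exceeds the exact enumeration limit "
                f"({EXACT_MAX_DIM}x{EXACT_MAX_DIM}, N<={EXACT_MAX_N}); "
                "use method='monte_carlo'"
            )
        if _estimate_n_tables(counts.sum(axis=1), nc) > EXACT_MAX_TABLES:
            raise ValueError(
                "too many candidate tables for exact enumeration; use method='monte_carlo'"
            )
        p, n_tables = _fisher_enumerate(counts)
        return FisherResult(p=min(p, 1.0), method="exact", n_tables=n_tables)
    if method == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo method requires a seed")
        p, se = _fisher_monte_carlo(counts, reps, seed)
        return FisherResult(p=p, method="monte_carlo", reps=reps, seed=seed, mc_se=se)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Spearman and ANOVA
# ---------------------------------------------------------------------------


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided p.

    For n <= ``exact_max_n`` the p-value is computed by exact permutation
    of one variable; above that the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho, p_t = sps.spearmanr(x, y)
    rho = float(rho)
    if n <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
        rho_perm = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(p_t)


def anova_bonferroni(groups, values) -> tuple[float, float, dict[tuple[str, str], float]]:
    """One-way ANOVA F test plus Bonferroni-corrected pairwise comparisons.

    Pairwise tests use the pooled within-group variance (the ANOVA mean
    squared error) with N - k degrees of freedom; raw p-values are
    multiplied by the number of comparisons and capped at 1.
    """
    groups = np.asarray(groups)
    values = np.asarray(values, dtype=float)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: values[groups == g] for g in labels}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    f_stat, p = sps.f_oneway(*samples.values())
    n_total = len(values)
    k = len(labels)
    sse = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    mse = sse / (n_total - k)
    m = k * (k - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(labels, 2):
        va, vb = samples[a], samples[b]
        se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        tval = (va.mean() - vb.mean()) / se
        praw = 2 * sps.t.sf(abs(tval), n_total - k)
        pairwise[(a, b)] = float(min(1.0, praw * m))
    return float(f_stat), float(p), pairwise


def build_group_symptom_table(
    records: pd.DataFrame, symptom: str, group_col: str = "group",
    categories: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate diagnosis group against a symptom coding.

    With a boolean symptom column this yields the presence/absence (2 x g)
    table; a categorical column (e.g. none / bilateral / ipsilateral)
    yields the multi-level table with (levels-1) x (g-1) degrees of
    freedom.
    """
    if records.empty:
        raise ValueError("no records")
    col = records[symptom]
    if col.dtype == bool:
        col = col.map({True: "present", False: "absent"})
    tab = pd.crosstab(col, records[group_col])
    if categories:
        tab = tab.reindex(categories, fill_value=0)
    return ContingencyTable(
        tab.to_numpy(), [str(i) for i in tab.index], [str(c) for c in tab.columns]
    )
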