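"""Differential suppression after miRNA transfection, and co-repression overlap.

Probe-level log2 expression matrices (treated vs non-targeting control, a
few replicates each) are quantile-normalized across arrays, probes
suppressed by each miRNA are called with a SAM-style moderated d-statistic
and label-permutation FDR, and co-repression across miRNAs is quantified
with Venn membership patterns and chi-squared 2x2 overlap enrichment over
the detected-probe population.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "SamResult",
    "SuppressedSet",
    "OverlapResult",
    "quantile_normalize",
    "impute_row_mean",
    "sam_test",
    "select_suppressed",
    "select_pathway_input",
    "venn_counts",
    "pairwise_overlap_chisq",
    "pairwise_overlap_exact",
    "overlap_analysis",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes x samples log2 intensity table with condition:replicate columns.

    Column labels follow ``condition:replicate`` (e.g. ``miR-544a:1``,
    ``NT:2``).  Missing values are rejected at construction; imputation is a
    deliberate upstream step (`impute_row_mean`), never silent.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError(
                "expression matrix contains missing values; impute explicitly "
                "(impute_row_mean) before constructing"
            )
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        for col in self.values.columns:
            if ":" not in str(col):
                raise ValueError(
                    f"column '{col}' is not in condition:replicate form"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for col in self.values.columns:
            cond = str(col).rsplit(":", 1)[0]
            if cond not in seen:
                seen.append(cond)
        return seen

    def condition_columns(self, condition: str) -> list[str]:
        cols = [
            c for c in self.values.columns if str(c).rsplit(":", 1)[0] == condition
        ]
        if not cols:
            raise ValueError(f"condition '{condition}' not present")
        return cols


def impute_row_mean(raw: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by their probe's row mean (explicit, logged step)."""
    out = raw.apply(lambda row: row.fillna(row.mean()), axis=1)
    if out.isna().any().any():
        raise ValueError("rows with all values missing cannot be imputed")
    return out


def quantile_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across arrays.

    Every column is mapped onto the common reference distribution formed by
    the across-column means of the sorted values, so all columns end with an
    identical value multiset while within-column ranks are preserved.  Tied
    entries in a column receive the mean of the reference values at the tied
    rank positions.
    """
    if raw.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    if raw.isna().any().any():
        raise ValueError(
            "missing values present; impute explicitly (impute_row_mean) first"
        )
    arr = raw.to_numpy(dtype=float)
    n, _ = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.take_along_axis(arr, order, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        o = order[:, j]
        sorted_col = arr[o, j]
        # tie groups: runs of equal values in the sorted column share the
        # mean of their positions' reference values
        boundaries = np.flatnonzero(np.diff(sorted_col)) + 1
        starts = np.concatenate(([0], boundaries))
        sums = np.add.reduceat(ref, starts)
        lens = np.diff(np.concatenate((starts, [n])))
        group_means = sums / lens
        assigned = np.repeat(group_means, lens)
        out[o, j] = assigned
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


@dataclass(frozen=True)
class SamResult:
    """Per-probe SAM statistics for one treated-vs-control comparison.

    ``table`` columns: d (moderated difference statistic), fold_change
    (linear-scale treated/control), q_value (permutation FDR at the probe's
    |d| threshold), called_down.  ``s0`` is the fudge constant actually
    used; ``n_perm`` the number of relabelings in the null.
    """

    treated: str
    control: str
    table: pd.DataFrame
    s0: float
    n_perm: int
    exhaustive: bool


def _balanced_relabelings(n1: int, n2: int) -> list[np.ndarray]:
    """All choices of n1 'treated' columns out of n1 + n2 (identity included)."""
    total = n1 + n2
    out = []
    for treated_idx in itertools.combinations(range(total), n1):
        mask = np.zeros(total, dtype=bool)
        mask[list(treated_idx)] = True
        out.append(mask)
    return out


def _d_stat(
    x: np.ndarray, treated_mask: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """SAM relative difference d = (mean_t - mean_c) / (s + s0) per probe.

    s is the pooled standard error
    sqrt((1/n1 + 1/n2) * (SS_t + SS_c) / (n1 + n2 - 2)).
    """
    t = x[:, treated_mask]
    c = x[:, ~treated_mask]
    n1, n2 = t.shape[1], c.shape[1]
    diff = t.mean(axis=1) - c.mean(axis=1)
    ss = ((t - t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (c - c.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (s + s0)
    return d, s


def sam_test(
    matrix: ExpressionMatrix,
    treated: str,
    control: str,
    s0: float | str = "median",
    n_label_perm: int = 200,
    seed: int = 0,
) -> SamResult:
    """SAM-style differential test with label-permutation FDR.

    For each probe, d = (mean_treated - mean_control) / (s + s0) with s the
    pooled standard error and s0 a positive fudge constant stabilizing
    low-variance probes.  The null is built from balanced relabelings of
    the sample columns — exhaustively (identity included) when there are at
    most ``n_label_perm`` of them, as with duplicate arrays (2 vs 2 has only
    6), otherwise ``n_label_perm`` random relabelings.  The q-value at each
    probe's |d| threshold is the median false-call count across relabelings
    divided by the observed call count, capped at 1 and made monotone
    non-increasing in |d|.

    Parameters
    ----------
    s0
        ``"median"`` (default) uses the median of the per-probe pooled
        standard errors; pass a positive float to fix it (required for
        noiseless data where every s is 0).
    """
    t_cols = matrix.condition_columns(treated)
    c_cols = matrix.condition_columns(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition (got {len(t_cols)} treated, "
            f"{len(c_cols)} control)"
        )
    x = matrix.values[t_cols + c_cols].to_numpy(dtype=float)
    n1, n2 = len(t_cols), len(c_cols)
    identity = np.zeros(n1 + n2, dtype=bool)
    identity[:n1] = True

    _, s = _d_stat(x, identity, s0=0.0)
    if s0 == "median":
        s0_val = float(np.median(s))
        if s0_val <= 0.0:
            raise ValueError(
                "median pooled standard error is 0 (constant probes); "
                "pass an explicit positive s0"
            )
    else:
        s0_val = float(s0)
        if s0_val < 0.0:
            raise ValueError("s0 must be >= 0")
        if s0_val == 0.0 and np.any(s == 0.0):
            raise ValueError(
                "probe with zero scatter and s0 = 0 makes d undefined; use s0 > 0"
            )

    d_obs, _ = _d_stat(x, identity, s0_val)
    diff = x[:, :n1].mean(axis=1) - x[:, n1:].mean(axis=1)
    fold_change = 2.0 ** diff

    from math import comb

    n_balanced = comb(n1 + n2, n1)
    if n_balanced <= n_label_perm:
        masks = _balanced_relabelings(n1, n2)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        masks = []
        for _ in range(n_label_perm):
            idx = rng.choice(n1 + n2, size=n1, replace=False)
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[idx] = True
            masks.append(mask)
        exhaustive = False

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    # observed calls at threshold |d_(i)|: number of probes with |d| >= it
    sorted_abs = np.sort(abs_obs)
    n_probes = len(abs_obs)
    observed_calls = n_probes - np.searchsorted(sorted_abs, thresholds, side="left")

    false_counts = np.empty((len(masks), n_probes))
    for b, mask in enumerate(masks):
        d_b, _ = _d_stat(x, mask, s0_val)
        sorted_b = np.sort(np.abs(d_b))
        false_counts[b] = n_probes - np.searchsorted(sorted_b, thresholds, side="left")
    median_false = np.median(false_counts, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw_q = np.where(observed_calls > 0, median_false / observed_calls, 1.0)
    raw_q = np.minimum(raw_q, 1.0)
    # monotone: q at a tighter threshold never exceeds any looser one's estimate
    q_ranked = np.minimum.accumulate(raw_q[::-1])[::-1]
    q = np.empty(n_probes)
    q[order] = q_ranked

    table = pd.DataFrame(
        {
            "d": d_obs,
            "fold_change": fold_change,
            "q_value": q,
            "called_down": (d_obs < 0) & (q <= 0.05),
        },
        index=matrix.probe_ids,
    )
    return SamResult(
        treated=treated,
        control=control,
        table=table,
        s0=s0_val,
        n_perm=len(masks),
        exhaustive=exhaustive,
    )


@dataclass(frozen=True)
class SuppressedSet:
    """Probes suppressed by one miRNA at the FDR and fold-change gates."""

    mir_id: str
    probes: frozenset[str]
    fc_min: float
    fdr_max: float

    def __len__(self) -> int:
        return len(self.probes)


def select_suppressed(
    res: SamResult, fc_min: float = 1.4, fdr_max: float = 0.05
) -> SuppressedSet:
    """Probes suppressed ``fc_min``-fold or greater at FDR <= ``fdr_max``.

    "Suppressed fc-fold" means linear fold change treated/control at or
    below 1/fc_min; the boundary value is included.
    """
    if fc_min <= 0:
        raise ValueError("fc_min must be positive")
    t = res.table
    # boundary inclusive up to floating error ("1.4-fold or greater")
    cut = (1.0 / fc_min) * (1.0 + 1e-12)
    hit = (t["fold_change"] <= cut) & (t["q_value"] <= fdr_max)
    return SuppressedSet(
        mir_id=res.treated,
        probes=frozenset(t.index[hit]),
        fc_min=fc_min,
        fdr_max=fdr_max,
    )


def select_pathway_input(
    res: SamResult, fc_min: float = 2.0, fdr_max: float = 0.05
) -> frozenset[str]:
    """The stricter (>= 2-fold) suppressed set handed to pathway testing."""
    return select_suppressed(res, fc_min=fc_min, fdr_max=fdr_max).probes


@dataclass(frozen=True)
class OverlapResult:
    """Venn membership-pattern counts and pairwise overlap enrichment.

    ``pattern_counts`` maps each non-empty membership pattern (frozenset of
    set labels) to the number of elements exactly in those sets; counts sum
    to the union size.  ``pairwise`` maps label pairs to (2x2 table, chi2,
    p) computed over the stated detected-probe population.
    """

    labels: tuple[str, ...]
    pattern_counts: dict[frozenset, int]
    n_common_all: int
    frac_union_ge2: float
    pairwise: dict[tuple[str, str], tuple[np.ndarray, float, float]]
    population_size: int | None


def venn_counts(sets: dict[str, set | frozenset]) -> OverlapResult:
    """Exact Venn pattern counts for 2-4 labelled sets.

    Every element of the union is classified into one of the 2^k - 1
    non-empty membership patterns; also reports the all-sets intersection
    count and the fraction of the union belonging to >= 2 sets.
    """
    k = len(sets)
    if not 2 <= k <= 4:
        raise ValueError(f"venn_counts handles 2-4 sets, got {k}")
    labels = tuple(sorted(sets))
    frozen = {lab: frozenset(sets[lab]) for lab in labels}
    union: set = set()
    for s in frozen.values():
        union |= s
    counts: dict[frozenset, int] = {}
    n_ge2 = 0
    for el in union:
        pattern = frozenset(lab for lab in labels if el in frozen[lab])
        counts[pattern] = counts.get(pattern, 0) + 1
        if len(pattern) >= 2:
            n_ge2 += 1
    all_pattern = frozenset(labels)
    return OverlapResult(
        labels=labels,
        pattern_counts=counts,
        n_common_all=counts.get(all_pattern, 0),
        frac_union_ge2=(n_ge2 / len(union)) if union else 0.0,
        pairwise={},
        population_size=None,
    )


def _overlap_table(A: frozenset, B: frozenset, N: int) -> np.ndarray:
    both = len(A & B)
    only_a = len(A) - both
    only_b = len(B) - both
    neither = N - len(A | B)
    return np.array([[both, only_a], [only_b, neither]], dtype=float)


def pairwise_overlap_chisq(
    A: set | frozenset, B: set | frozenset, N: int
) -> tuple[float, float]:
    """Pearson chi-squared (df 1, no continuity correction) for 2-set overlap.

    The 2x2 table cross-classifies the ``N`` detected probes by membership
    in A and in B.  ``N`` is the analysis population (total detected probes)
    and must be supplied explicitly.
    """
    A, B = frozenset(A), frozenset(B)
    if len(A | B) > N:
        raise ValueError("population size N smaller than |A union B|")
    table = _overlap_table(A, B, N)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / N
    if np.any(expected == 0.0):
        raise ValueError(
            "a zero expected cell (degenerate margin); use "
            "pairwise_overlap_exact instead"
        )
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def pairwise_overlap_exact(
    A: set | frozenset, B: set | frozenset, N: int
) -> float:
    """Exact upper-tail hypergeometric overlap p-value (small-margin fallback)."""
    A, B = frozenset(A), frozenset(B)
    if len(A | B) > N:
        raise ValueError("population size N smaller than |A union B|")
    k = len(A & B)
    return float(stats.hypergeom.sf(k - 1, N, len(A), len(B)))


def overlap_analysis(
    sets: dict[str, set | frozenset], population_size: int
) -> OverlapResult:
    """Venn patterns plus all pairwise chi-squared overlap tests."""
    base = venn_counts(sets)
    pairwise: dict[tuple[str, str], tuple[np.ndarray, float, float]] = {}
    for a, b in itertools.combinations(base.labels, 2):
        table = _overlap_table(frozenset(sets[a]), frozenset(sets[b]), population_size)
        chi2, p = pairwise_overlap_chisq(sets[a], sets[b], population_size)
        pairwise[(a, b)] = (table, chi2, p)
    return OverlapResult(
        labels=base.labels,
        pattern_counts=base.pattern_counts,
        n_common_all=base.n_common_all,
        frac_union_ge2=base.frac_union_ge2,
        pairwise=pairwise,
        population_size=population_size,
    )
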