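"""Pathway over-representation of miRNA target sets and cross-miR combination.

Predicted miRNA->gene interaction scores (microT-style confidences in
[0, 1]) are thresholded into per-miR target sets; each (miR, pathway) pair
is tested for over-representation with an upper-tail hypergeometric test
over the gene universe; per-pathway evidence is combined across miRNAs with
Fisher's combined probability method (-2 * sum(ln p) ~ chi-squared with
2k degrees of freedom).  The -log10(p) miR x pathway matrix feeds a
hierarchically clustered heatmap, pathways carry functional-group labels
(AIM: adhesion/invasion/motility, ICS: intracellular signaling, CSS:
cancer-specific signaling), and locus miRNAs are ranked by their burden of
significantly targeted AIM pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "FUNCTIONAL_GROUPS",
    "TargetScoreTable",
    "Pathway",
    "PathwayCollection",
    "EnrichmentCell",
    "CombinedPathwayResult",
    "RankedMir",
    "HeatmapMatrix",
    "threshold_targets",
    "pathway_hypergeom",
    "combine_fisher",
    "enrich_all",
    "bh_adjust",
    "build_heatmap_matrix",
    "cluster_rows",
    "assign_groups",
    "rank_by_aim",
    "export_pathway_network",
]

FUNCTIONAL_GROUPS = ("AIM", "ICS", "CSS")
UNASSIGNED = "unassigned"

#: floor applied to p-values before log-transform so Fisher's method stays
#: defined for values that underflowed the smallest positive double
P_FLOOR = 1e-300


@dataclass(frozen=True)
class TargetScoreTable:
    """Long-form (mir_id, gene_id) -> score table plus its gene universe.

    ``scores`` has columns mir_id, gene_id, score.  The universe defaults to
    the union of scored genes but may be wider (an explicit background list).
    """

    scores: pd.DataFrame
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        required = {"mir_id", "gene_id", "score"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"score table must have columns {sorted(required)}")
        s = self.scores["score"].to_numpy(dtype=float)
        if s.size and (np.nanmin(s) < 0.0 or np.nanmax(s) > 1.0):
            raise ValueError("scores must lie in [0, 1]")
        scored = frozenset(self.scores["gene_id"])
        if not scored <= self.gene_universe:
            raise ValueError("gene_universe must contain every scored gene")

    @classmethod
    def from_frame(
        cls, scores: pd.DataFrame, universe: set[str] | None = None
    ) -> "TargetScoreTable":
        uni = frozenset(universe) if universe is not None else frozenset(scores["gene_id"])
        return cls(scores=scores.reset_index(drop=True), gene_universe=uni)

    @property
    def mir_ids(self) -> list[str]:
        return sorted(self.scores["mir_id"].unique())


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset[str]
    group: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} has an empty gene set")


@dataclass(frozen=True)
class PathwayCollection:
    """Gene-set collection (KEGG-like), each set optionally group-labelled."""

    pathways: dict[str, Pathway]

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            if pid != pw.pathway_id:
                raise ValueError(f"key {pid} != pathway_id {pw.pathway_id}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, pid: str) -> Pathway:
        return self.pathways[pid]

    def ids(self) -> list[str]:
        return sorted(self.pathways)

    def by_group(self, group: str) -> list[Pathway]:
        return [p for p in self if p.group == group]


@dataclass(frozen=True)
class EnrichmentCell:
    """One (miR, pathway) hypergeometric over-representation result."""

    mir_id: str
    pathway_id: str
    overlap: int
    pathway_size: int
    target_count: int
    universe_size: int
    p_hyper: float


@dataclass(frozen=True)
class CombinedPathwayResult:
    """Fisher-combined cross-miR evidence for one pathway."""

    pathway_id: str
    pvalues: tuple[float, ...]
    X2: float
    df: int
    p_combined: float

    @property
    def neglog10(self) -> float:
        return -float(np.log10(max(self.p_combined, P_FLOOR)))


@dataclass(frozen=True)
class RankedMir:
    mir_id: str
    n_significant_aim: int
    aim_score: float
    rank: int


def threshold_targets(
    table: TargetScoreTable, tau: float = 0.6
) -> dict[str, frozenset[str]]:
    """Per-miR target gene sets: gene in set(m) iff score(m, g) >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    hits = table.scores[table.scores["score"] >= tau]
    out: dict[str, frozenset[str]] = {m: frozenset() for m in table.mir_ids}
    for mir, grp in hits.groupby("mir_id"):
        out[str(mir)] = frozenset(grp["gene_id"])
    return out


def pathway_hypergeom(
    targets: set[str] | frozenset[str],
    pathway: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    mir_id: str = "",
    pathway_id: str = "",
) -> EnrichmentCell:
    """Upper-tail hypergeometric over-representation of a target set in a pathway.

    With ``N = |universe|``, ``K = |pathway|``, ``n = |targets|`` and
    ``k = |targets & pathway|``, returns P(X >= k) for
    X ~ Hypergeom(N, K, n): the chance a random size-n draw from the
    universe overlaps the pathway at least as much as observed.
    """
    if not universe:
        raise ValueError("gene universe is empty")
    targets = frozenset(targets)
    pathway = frozenset(pathway)
    if not targets <= universe:
        raise ValueError("target set contains genes outside the universe")
    if not pathway <= universe:
        raise ValueError("pathway contains genes outside the universe")
    N = len(universe)
    K = len(pathway)
    n = len(targets)
    k = len(targets & pathway)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentCell(
        mir_id=mir_id,
        pathway_id=pathway_id,
        overlap=k,
        pathway_size=K,
        target_count=n,
        universe_size=N,
        p_hyper=min(1.0, max(p, P_FLOOR)),
    )


def combine_fisher(
    pvalues: list[float] | tuple[float, ...], pathway_id: str = ""
) -> CombinedPathwayResult:
    """Fisher's combined probability method.

    X2 = -2 * sum(ln p_i) is referred to a chi-squared distribution with
    2 * len(pvalues) degrees of freedom.  A single input is returned
    unchanged (the df-2 identity).  Values below 1e-300 are floored before
    the log; non-positive values are rejected.
    """
    if len(pvalues) == 0:
        raise ValueError("need at least one p-value")
    arr = np.asarray(pvalues, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError("p-values must be > 0 (floor underflows upstream)")
    if np.any(arr > 1.0):
        raise ValueError("p-values must be <= 1")
    arr = np.maximum(arr, P_FLOOR)
    X2 = float(-2.0 * np.log(arr).sum())
    df = 2 * len(arr)
    p_comb = float(stats.chi2.sf(X2, df))
    return CombinedPathwayResult(
        pathway_id=pathway_id,
        pvalues=tuple(float(x) for x in arr),
        X2=X2,
        df=df,
        p_combined=min(1.0, max(p_comb, P_FLOOR)),
    )


def enrich_all(
    targets_by_mir: dict[str, frozenset[str]],
    pathways: PathwayCollection,
    universe: set[str] | frozenset[str],
) -> tuple[list[EnrichmentCell], list[CombinedPathwayResult]]:
    """All per-(miR, pathway) cells plus the per-pathway cross-miR combination.

    Combination is across miRNAs within each pathway: a pathway's member
    p-values are its hypergeometric p-values over the tested miRNAs.
    """
    cells: list[EnrichmentCell] = []
    for mir in sorted(targets_by_mir):
        tset = targets_by_mir[mir]
        for pw in sorted(pathways, key=lambda p: p.pathway_id):
            cells.append(
                pathway_hypergeom(
                    tset, pw.genes, universe, mir_id=mir, pathway_id=pw.pathway_id
                )
            )
    combined = []
    for pid in pathways.ids():
        ps = [c.p_hyper for c in cells if c.pathway_id == pid]
        combined.append(combine_fisher(ps, pathway_id=pid))
    return cells, combined


def bh_adjust(cells: list[EnrichmentCell]) -> dict[tuple[str, str], float]:
    """Optional Benjamini-Hochberg adjustment of per-cell p-values.

    Off the default path (the conventional analysis applies no per-cell
    multiplicity correction); provided for sensitivity analyses.
    """
    if not cells:
        return {}
    p = np.array([c.p_hyper for c in cells])
    q = stats.false_discovery_control(p, method="bh")
    return {(c.mir_id, c.pathway_id): float(qi) for c, qi in zip(cells, q)}


@dataclass(frozen=True)
class HeatmapMatrix:
    """miR x pathway matrix of -log10 p with a per-cell significance mask.

    Columns are restricted to pathways whose Fisher-combined p-value passed
    the significance threshold.
    """

    values: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def build_heatmap_matrix(
    cells: list[EnrichmentCell],
    combined: list[CombinedPathwayResult],
    alpha: float = 0.05,
) -> HeatmapMatrix:
    """Assemble the -log10(p_hyper) matrix over combined-significant pathways."""
    keep = [c.pathway_id for c in combined if c.p_combined <= alpha]
    mirs = sorted({c.mir_id for c in cells})
    mat = pd.DataFrame(0.0, index=mirs, columns=keep)
    sig = pd.DataFrame(False, index=mirs, columns=keep)
    for c in cells:
        if c.pathway_id in mat.columns:
            mat.loc[c.mir_id, c.pathway_id] = -np.log10(max(c.p_hyper, P_FLOOR))
            sig.loc[c.mir_id, c.pathway_id] = c.p_hyper <= alpha
    return HeatmapMatrix(values=mat, significant=sig, alpha=alpha)


def cluster_rows(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """One-way agglomerative clustering of matrix rows.

    Euclidean distance, average linkage; deterministic for a given row
    order (scipy breaks distance ties by lowest pair index).  Returns the
    dendrogram leaf order (row labels) and the scipy linkage matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(matrix.to_numpy(dtype=float), method="average", metric="euclidean")
    order = [matrix.index[i] for i in leaves_list(Z)]
    return order, Z


def assign_groups(
    pathways: PathwayCollection, mapping: dict[str, str]
) -> PathwayCollection:
    """Attach functional-group labels; unmapped pathways become 'unassigned'.

    Unknown pathway ids in the mapping raise a warning, not an error —
    curated group files routinely outlive a pathway collection revision.
    """
    unknown = sorted(set(mapping) - set(pathways.pathways))
    if unknown:
        warnings.warn(
            f"group mapping names unknown pathways (ignored): {unknown[:5]}",
            stacklevel=2,
        )
    valid = set(FUNCTIONAL_GROUPS) | {UNASSIGNED}
    bad = sorted({g for g in mapping.values() if g not in valid})
    if bad:
        raise ValueError(f"unknown functional groups {bad}; expected {sorted(valid)}")
    new = {}
    for pid, pw in pathways.pathways.items():
        group = mapping.get(pid, UNASSIGNED)
        new[pid] = Pathway(pw.pathway_id, pw.name, pw.genes, group)
    return PathwayCollection(new)


def rank_by_aim(
    cells: list[EnrichmentCell],
    pathways: PathwayCollection,
    alpha: float = 0.05,
) -> list[RankedMir]:
    """Rank miRNAs by their burden of significantly targeted AIM pathways.

    Primary key: number of AIM pathways with p <= alpha; secondary: summed
    -log10(p) over those pathways; ties broken lexicographically by
    identifier.  Rank 1 is the heaviest AIM burden.
    """
    aim_ids = {p.pathway_id for p in pathways.by_group("AIM")}
    per_mir: dict[str, tuple[int, float]] = {}
    for mir in sorted({c.mir_id for c in cells}):
        sig = [
            c
            for c in cells
            if c.mir_id == mir and c.pathway_id in aim_ids and c.p_hyper <= alpha
        ]
        score = float(sum(-np.log10(max(c.p_hyper, P_FLOOR)) for c in sig))
        per_mir[mir] = (len(sig), score)
    ordered = sorted(
        per_mir, key=lambda m: (-per_mir[m][0], -per_mir[m][1], m)
    )
    return [
        RankedMir(mir_id=m, n_significant_aim=per_mir[m][0], aim_score=per_mir[m][1], rank=i + 1)
        for i, m in enumerate(ordered)
    ]


def export_pathway_network(
    cells: list[EnrichmentCell],
    combined: list[CombinedPathwayResult] | None = None,
    alpha: float = 0.05,
    min_mirs: int = 2,
) -> pd.DataFrame:
    """Edge table (pathway_id, mir_id, p_hyper) of pathways co-targeted by
    at least ``min_mirs`` miRNAs at per-cell significance ``alpha``.

    When ``combined`` is given, pathways must additionally pass the
    Fisher-combined threshold.  The table is the plain-text stand-in for a
    pathway–miR network graph.
    """
    allowed: set[str] | None = None
    if combined is not None:
        allowed = {c.pathway_id for c in combined if c.p_combined <= alpha}
    sig = [
        c
        for c in cells
        if c.p_hyper <= alpha and (allowed is None or c.pathway_id in allowed)
    ]
    degree: dict[str, int] = {}
    for c in sig:
        degree[c.pathway_id] = degree.get(c.pathway_id, 0) + 1
    rows = [
        {"pathway_id": c.pathway_id, "mir_id": c.mir_id, "p_hyper": c.p_hyper}
        for c in sig
        if degree[c.pathway_id] >= min_mirs
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "mir_id", "p_hyper"]).sort_values(
        ["pathway_id", "mir_id"], ignore_index=True
    )
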