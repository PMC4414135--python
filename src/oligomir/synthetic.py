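"""Synthetic study-condition generator with planted, recoverable structure.

Every input the pipeline consumes is emulated here: a miRNA array panel
with one genomic-locus cluster, differential miRNA sets enriched for that
locus, miRNA->gene target-score tables with pathway-concentrated targeting
for designated "planted" miRNAs, replicate transfection expression matrices
with planted shared down-regulation, and exponential survival cohorts with
a group hazard ratio and censoring.  All planted structure is returned (and
written to a ground-truth JSON sidecar) so every downstream stage can be
scored for recovery.

Default dimensions mirror a typical clinical profiling design: a
~377-miRNA array card, a
20-member 14q32-style locus, a 39-member differential set whose locus odds
multiplier (17) reproduces the reference 14-of-39 configuration in
expectation, duplicate arrays per transfection condition, 24 patients per
survival group.  Dimensions without a fixed real-world analogue (gene,
pathway and probe counts) are scaled-down stand-ins chosen once; see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import (
    FUNCTIONAL_GROUPS,
    Pathway,
    PathwayCollection,
    TargetScoreTable,
)
from .locus import ArrayPanel, DifferentialMirSet, MirRecord
from .suppression import ExpressionMatrix
from .survival import SurvivalRecord, median_split

__all__ = [
    "SynthConfig",
    "ConfigError",
    "gen_panel",
    "gen_differential",
    "fixed_locus_differential",
    "gen_pathways",
    "gen_target_scores",
    "gen_planted_suppression",
    "gen_transfection_expression",
    "gen_survival",
    "simulate_all",
]

LOCUS_LABEL = "14q32"


class ConfigError(ValueError):
    """A synthetic-data configuration violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic-data generator.

    Attributes
    ----------
    n_array_mirs, n_locus_mirs
        Array size and locus-cluster size (377 / 20; array cards of this
        class do not publish a locus composition, so these stay
        configurable).
    n_diff, locus_enrichment_odds
        Differential-set size and the odds multiplier for a locus miRNA to
        enter it.  Odds 17 reproduce the reference 14-of-39 configuration in
        expectation under the sequential renormalized-weight sampler.
    n_planted_mirs
        Locus miRNAs given concentrated pathway targeting, planted
        suppression sets and survival relevance (the four-miR panel analog).
    n_genes, n_pathways, pathway_size_range, targeting_concentration,
    background_target_rate
        Gene universe, pathway collection geometry, the fraction of a
        planted miR's above-threshold targets drawn from its designated
        pathways, and the background above-threshold rate per miRNA.
    n_probes, n_replicates, n_suppressed_per_mir, suppression_log2fc,
    noise_sd, shared_fraction
        Transfection-expression geometry.  ``shared_fraction`` is the
        fraction of the union of planted suppressed probes shared by >= 2
        miRNAs (0.31, the reference study condition).
    n_patients_per_group, hazard_ratio, censor_rate, followup_horizon
        Survival cohort: 24 per group, low-vs-high hazard ratio, uniform
        early-censoring rate, administrative horizon in months.
    """

    seed: int = 0
    n_array_mirs: int = 377
    n_locus_mirs: int = 20
    n_diff: int = 39
    locus_enrichment_odds: float = 17.0
    n_planted_mirs: int = 4
    n_genes: int = 2000
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (20, 60)
    targeting_concentration: float = 0.7
    background_target_rate: float = 0.05
    n_probes: int = 2000
    n_replicates: int = 2
    n_suppressed_per_mir: int = 150
    suppression_log2fc: float = 1.0
    noise_sd: float = 0.15
    shared_fraction: float = 0.31
    n_patients_per_group: int = 24
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    followup_horizon: float = 60.0

    def validate(self) -> None:
        errs = []
        if self.n_array_mirs < 1:
            errs.append("n_array_mirs must be >= 1")
        if not 0 <= self.n_locus_mirs <= self.n_array_mirs:
            errs.append("need 0 <= n_locus_mirs <= n_array_mirs")
        if not 0 <= self.n_diff <= self.n_array_mirs:
            errs.append("need 0 <= n_diff <= n_array_mirs")
        if self.locus_enrichment_odds < 1:
            errs.append("locus_enrichment_odds must be >= 1")
        if not 0 <= self.n_planted_mirs <= self.n_locus_mirs:
            errs.append("need 0 <= n_planted_mirs <= n_locus_mirs")
        for name in (
            "targeting_concentration",
            "background_target_rate",
            "shared_fraction",
            "censor_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must lie in [0, 1]")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            errs.append("pathway_size_range must satisfy 2 <= min <= max")
        if hi > self.n_genes:
            errs.append("pathway sizes cannot exceed n_genes")
        if self.n_replicates < 2:
            errs.append("n_replicates must be >= 2")
        if self.n_suppressed_per_mir > self.n_probes:
            errs.append("n_suppressed_per_mir cannot exceed n_probes")
        if self.noise_sd < 0:
            errs.append("noise_sd must be >= 0")
        if self.hazard_ratio <= 0:
            errs.append("hazard_ratio must be > 0")
        if self.followup_horizon <= 0:
            errs.append("followup_horizon must be > 0")
        if self.n_patients_per_group < 1:
            errs.append("n_patients_per_group must be >= 1")
        if errs:
            raise ConfigError("; ".join(errs))


def _rng(cfg: SynthConfig, stream: int, rng: np.random.Generator | None):
    """Per-stage independent stream so stages stay reproducible in isolation."""
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def gen_panel(cfg: SynthConfig, rng: np.random.Generator | None = None) -> ArrayPanel:
    """Array panel with a contiguous locus cluster on chromosome 14.

    Which identifiers carry the locus label is randomized per seed; the
    composition counts are forced by the config.
    """
    cfg.validate()
    r = _rng(cfg, 1, rng)
    n = cfg.n_array_mirs
    ids = [f"sim-miR-{i + 1:04d}" for i in range(n)]
    locus_idx = set(r.choice(n, size=cfg.n_locus_mirs, replace=False).tolist())
    records = []
    locus_rank = 0
    for i, mid in enumerate(ids):
        if i in locus_idx:
            start = 101_000_000 + locus_rank * 5_000  # contiguous cluster window
            records.append(MirRecord(mid, "chr14", start, start + 80, LOCUS_LABEL))
            locus_rank += 1
        else:
            chrom = f"chr{int(r.integers(1, 23))}"
            start = int(r.integers(1_000_000, 90_000_000))
            records.append(MirRecord(mid, chrom, start, start + 80, ""))
    return ArrayPanel(records=tuple(records), name="synthetic-array")


def gen_differential(
    panel: ArrayPanel,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    dataset_label: str = "synthetic",
) -> DifferentialMirSet:
    """Weighted sample of ``n_diff`` miRNAs without replacement.

    Locus members carry weight ``locus_enrichment_odds``; all others
    weight 1.  Sampling is sequential with renormalized weights (one of
    several unequal-probability schemes; documented because they differ).
    """
    cfg.validate()
    if cfg.n_diff > len(panel):
        raise ConfigError(f"n_diff {cfg.n_diff} exceeds panel size {len(panel)}")
    r = _rng(cfg, 2, rng)
    ids = [rec.mir_id for rec in panel.records]
    locus = panel.locus_members(LOCUS_LABEL)
    w = np.array(
        [cfg.locus_enrichment_odds if m in locus else 1.0 for m in ids], dtype=float
    )
    chosen: list[str] = []
    for _ in range(cfg.n_diff):
        p = w / w.sum()
        i = int(r.choice(len(ids), p=p))
        chosen.append(ids[i])
        w[i] = 0.0
    chosen_set = frozenset(chosen)
    return DifferentialMirSet(
        dataset_label=dataset_label,
        mir_ids=chosen_set,
        locus_count=len(chosen_set & locus),
    )


def fixed_locus_differential(
    panel: ArrayPanel,
    n_total: int,
    n_locus: int,
    rng: np.random.Generator | None = None,
    dataset_label: str = "fixture",
) -> DifferentialMirSet:
    """Differential set with an exact planted locus count (reference fixtures)."""
    r = rng if rng is not None else np.random.default_rng(0)
    locus = sorted(panel.locus_members(LOCUS_LABEL))
    other = sorted(panel.mir_ids - panel.locus_members(LOCUS_LABEL))
    if n_locus > len(locus) or n_total - n_locus > len(other):
        raise ConfigError("requested composition exceeds panel strata")
    picked = list(r.choice(locus, size=n_locus, replace=False)) + list(
        r.choice(other, size=n_total - n_locus, replace=False)
    )
    return DifferentialMirSet(
        dataset_label=dataset_label, mir_ids=frozenset(picked), locus_count=n_locus
    )


def gen_pathways(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> PathwayCollection:
    """Random gene-set collection with cycling AIM/ICS/CSS group labels."""
    cfg.validate()
    r = _rng(cfg, 3, rng)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(cfg.n_genes)])
    lo, hi = cfg.pathway_size_range
    pathways = {}
    for j in range(cfg.n_pathways):
        size = int(r.integers(lo, hi + 1))
        members = frozenset(r.choice(genes, size=size, replace=False).tolist())
        pid = f"PW{j + 1:03d}"
        group = FUNCTIONAL_GROUPS[j % len(FUNCTIONAL_GROUPS)]
        pathways[pid] = Pathway(pid, f"synthetic pathway {j + 1}", members, group)
    return PathwayCollection(pathways)


def gen_target_scores(
    mirs: list[str],
    pathways: PathwayCollection,
    cfg: SynthConfig,
    planted: dict[str, list[str]] | None = None,
    rng: np.random.Generator | None = None,
) -> TargetScoreTable:
    """microT-style target-score table with pathway-concentrated planting.

    Every (miR, gene) pair receives a score: a fixed count of genes per miR
    (``background_target_rate * n_genes``) scores uniformly in [0.6, 1)
    (above threshold), the rest uniformly in [0, 0.6).  Fixing the
    above-threshold count makes the downstream hypergeometric null exact.
    For a planted miR, a ``targeting_concentration`` fraction of the
    above-threshold genes is drawn from its designated pathways' genes.
    """
    cfg.validate()
    planted = planted or {}
    for mir, pids in planted.items():
        unknown = [p for p in pids if p not in pathways.pathways]
        if unknown:
            raise ConfigError(f"planted miR {mir} designates unknown pathways {unknown}")
    r = _rng(cfg, 4, rng)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(cfg.n_genes)])
    gene_set = frozenset(genes.tolist())
    for pw in pathways:
        if not pw.genes <= gene_set:
            raise ConfigError("pathway genes outside the configured gene universe")

    n_above = int(round(cfg.background_target_rate * cfg.n_genes))
    n_above = min(max(n_above, 0), cfg.n_genes)
    frames = []
    for mir in mirs:
        if mir in planted and planted[mir]:
            designated = sorted(
                set().union(*(pathways[p].genes for p in planted[mir]))
            )
            n_conc = min(
                int(round(cfg.targeting_concentration * n_above)), len(designated)
            )
            from_pw = r.choice(designated, size=n_conc, replace=False)
            rest_pool = np.array(sorted(gene_set - set(from_pw.tolist())))
            from_bg = r.choice(rest_pool, size=n_above - n_conc, replace=False)
            above = np.concatenate([from_pw, from_bg])
        else:
            above = r.choice(genes, size=n_above, replace=False)
        above_set = set(above.tolist())
        scores = np.where(
            np.isin(genes, above),
            0.6 + 0.4 * r.random(cfg.n_genes),
            0.6 * r.random(cfg.n_genes),
        )
        # clip the open upper bound so scores stay within [0, 1)
        scores = np.minimum(scores, np.nextafter(1.0, 0.0))
        assert len(above_set) == n_above
        frames.append(
            pd.DataFrame({"mir_id": mir, "gene_id": genes, "score": scores})
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["mir_id", "gene_id", "score"])
    )
    return TargetScoreTable.from_frame(table, universe=set(gene_set))


def gen_planted_suppression(
    cfg: SynthConfig,
    probe_ids: list[str],
    mirs: list[str],
    rng: np.random.Generator | None = None,
) -> dict[str, frozenset[str]]:
    """Planted suppressed probe sets with a controlled shared fraction.

    One pool shared by all ``k`` miRNAs plus disjoint unique remainders,
    sized so the fraction of the union lying in >= 2 sets equals
    ``shared_fraction``: ``|shared| = round(m * f * k / (f * k + 1 - f))``
    for per-miR size ``m``.
    """
    cfg.validate()
    r = _rng(cfg, 5, rng)
    k = len(mirs)
    m = cfg.n_suppressed_per_mir
    if k == 0 or m == 0:
        return {mir: frozenset() for mir in mirs}
    f = cfg.shared_fraction
    if k == 1:
        shared_size = 0
    else:
        shared_size = int(round(m * f * k / (f * k + 1.0 - f))) if f > 0 else 0
    unique_size = m - shared_size
    need = shared_size + k * unique_size
    if need > len(probe_ids):
        raise ConfigError(
            f"planted design needs {need} probes but only {len(probe_ids)} exist"
        )
    pool = r.choice(np.array(probe_ids), size=need, replace=False)
    shared = frozenset(pool[:shared_size].tolist())
    out = {}
    for i, mir in enumerate(mirs):
        lo = shared_size + i * unique_size
        out[mir] = shared | frozenset(pool[lo : lo + unique_size].tolist())
    return out


def gen_transfection_expression(
    cfg: SynthConfig,
    planted: dict[str, frozenset[str] | set[str]],
    probe_ids: list[str] | None = None,
    control: str = "NT",
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Replicate log2 expression matrix with planted down-shifts.

    One column block per condition (each planted miRNA plus the
    non-targeting control), ``n_replicates`` columns each.  Planted probes
    are shifted down by ``suppression_log2fc`` in their miRNA's columns;
    homoscedastic Gaussian noise (``noise_sd``) is added everywhere.
    """
    cfg.validate()
    r = _rng(cfg, 6, rng)
    if probe_ids is None:
        probe_ids = [f"PROBE{i + 1:05d}" for i in range(cfg.n_probes)]
    probe_index = {p: i for i, p in enumerate(probe_ids)}
    for mir, probes in planted.items():
        unknown = set(probes) - set(probe_ids)
        if unknown:
            raise ConfigError(
                f"planted probes for {mir} not in the probe universe: "
                f"{sorted(unknown)[:3]}"
            )
    conditions = list(planted) + [control]
    baseline = r.normal(8.0, 1.5, size=len(probe_ids))
    cols = {}
    for cond in conditions:
        shift = np.zeros(len(probe_ids))
        if cond in planted:
            idx = [probe_index[p] for p in planted[cond]]
            shift[idx] = -cfg.suppression_log2fc
        for rep in range(1, cfg.n_replicates + 1):
            noise = r.normal(0.0, cfg.noise_sd, size=len(probe_ids))
            cols[f"{cond}:{rep}"] = baseline + shift + noise
    df = pd.DataFrame(cols, index=probe_ids)
    return ExpressionMatrix(values=df)


def gen_survival(
    cfg: SynthConfig,
    mir_names: tuple[str, ...] = ("miR-A", "miR-B", "miR-C", "miR-D"),
    rng: np.random.Generator | None = None,
) -> list[SurvivalRecord]:
    """Two survival cohorts separated by mean miRNA expression.

    Per-patient mean scores are drawn strictly above (high group) or below
    (low group) a common gap, so the mean-expression median split recovers
    the generating groups by construction; per-miR values scatter around
    the score with the score preserved exactly.  Event times are
    exponential with the high group's rate set so S(horizon) = 0.6 and the
    low group's rate ``hazard_ratio`` times larger.  A ``censor_rate``
    fraction of patients is censored early (uniformly before their event);
    everyone else is observed to the event or administratively censored at
    the horizon, reproducing the "+"-tick pattern of clinical curves.
    """
    cfg.validate()
    r = _rng(cfg, 7, rng)
    n = cfg.n_patients_per_group
    k = len(mir_names)
    lam_high = float(np.log(1.0 / 0.6) / cfg.followup_horizon)
    lam_low = cfg.hazard_ratio * lam_high

    records: list[SurvivalRecord] = []
    pid = 0
    for group, lam, sign in (("high", lam_high, 1.0), ("low", lam_low, -1.0)):
        scores = sign * r.uniform(0.2, 2.0, size=n)
        for i in range(n):
            pid += 1
            dev = r.normal(0.0, 0.5, size=k)
            dev -= dev.mean()  # mean over miRs equals the score exactly
            expr = {m: float(scores[i] + d) for m, d in zip(mir_names, dev)}
            t_event = float(r.exponential(1.0 / lam))
            if r.random() < cfg.censor_rate:
                # early censoring: observed before the event would occur
                time = float(r.uniform(0.0, min(t_event, cfg.followup_horizon)))
                event = 0
            elif t_event <= cfg.followup_horizon:
                time, event = t_event, 1
            else:
                time, event = cfg.followup_horizon, 0  # administrative "+"
            records.append(
                SurvivalRecord(
                    patient_id=f"P{pid:03d}", time=time, event=event, expr=expr
                )
            )
    return records


def simulate_all(cfg: SynthConfig) -> dict:
    """Generate the full linked bundle plus its ground-truth sidecar.

    Returns a dict with keys: panel, differential, pathways, target_scores,
    expression, planted_suppression, survival, truth.  ``truth`` records
    every planted structure (locus members, realized differential locus
    count, planted miR -> pathway designations, suppressed probe sets,
    survival groups) for downstream recovery scoring.
    """
    cfg.validate()
    panel = gen_panel(cfg)
    diff = gen_differential(panel, cfg)
    pathways = gen_pathways(cfg)

    locus_in_diff = sorted(diff.mir_ids & panel.locus_members(LOCUS_LABEL))
    planted_mirs = locus_in_diff[: cfg.n_planted_mirs]
    aim_ids = [p.pathway_id for p in pathways.by_group("AIM")]
    # each planted miR concentrates on a couple of AIM pathways; the first
    # AIM pathway is designated for all of them so it is co-targeted
    planted_targets: dict[str, list[str]] = {}
    for i, mir in enumerate(planted_mirs):
        extra = aim_ids[1 + (i % max(1, len(aim_ids) - 1))] if len(aim_ids) > 1 else aim_ids[0]
        planted_targets[mir] = sorted({aim_ids[0], extra}) if aim_ids else []

    score_mirs = locus_in_diff  # all locus members of the differential set
    scores = gen_target_scores(score_mirs, pathways, cfg, planted=planted_targets)

    probe_ids = [f"PROBE{i + 1:05d}" for i in range(cfg.n_probes)]
    planted_sup = gen_planted_suppression(cfg, probe_ids, planted_mirs)
    expr = gen_transfection_expression(cfg, planted_sup, probe_ids=probe_ids)

    surv = gen_survival(cfg, mir_names=tuple(planted_mirs) or ("miR-A",))
    groups = median_split(surv, list(planted_mirs) or ["miR-A"])

    truth = {
        "locus_label": LOCUS_LABEL,
        "locus_members": sorted(panel.locus_members(LOCUS_LABEL)),
        "differential_mirs": sorted(diff.mir_ids),
        "differential_locus_count": diff.locus_count,
        "planted_mirs": list(planted_mirs),
        "planted_pathways": planted_targets,
        "co_targeted_pathway": aim_ids[0] if aim_ids else None,
        "planted_suppression": {m: sorted(s) for m, s in planted_sup.items()},
        "survival_groups": groups,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
    }
    return {
        "panel": panel,
        "differential": diff,
        "pathways": pathways,
        "target_scores": scores,
        "expression": expr,
        "planted_suppression": planted_sup,
        "survival": surv,
        "truth": truth,
    }
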