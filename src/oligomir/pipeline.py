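"""End-to-end orchestration: simulate -> locus test -> enrichment -> SAM ->
overlap -> survival, configured from one flat YAML file, fully seeded, with
a provenance-carrying report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as oio
from .enrichment import (
    build_heatmap_matrix,
    cluster_rows,
    enrich_all,
    export_pathway_network,
    rank_by_aim,
    threshold_targets,
)
from .locus import locus_fraction, permutation_locus_test
from .suppression import (
    overlap_analysis,
    quantile_normalize,
    sam_test,
    select_suppressed,
    ExpressionMatrix,
)
from .survival import km_curve, logrank, median_split, survival_at
from .synthetic import LOCUS_LABEL, ConfigError, SynthConfig, simulate_all

__all__ = ["RunConfig", "RunReport", "validate_config", "load_config", "run_all"]

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "tau",
    "alpha",
    "fdr",
    "fc",
    "fc_pathway",
    "min_mirs",
    "n_perm",
    "locus_label",
    "sam_s0",
    "synth",
}


@dataclass
class RunConfig:
    """Flat run configuration: thresholds, seeds, locus label, synth block.

    Thresholds default to the conventional constants of this analysis
    chain: microT tau 0.6, combined
    alpha 0.05, SAM FDR 5% with fold change >= 1.4, a stricter >= 2.0 gate
    for pathway input, pathway co-targeting degree >= 2, 10^6 permutation
    replicates (the packaged fast profile lowers n_perm; the value actually
    used is recorded in provenance).
    """

    seed: int = 0
    out_dir: str = "oligomir-run"
    tau: float = 0.6
    alpha: float = 0.05
    fdr: float = 0.05
    fc: float = 1.4
    fc_pathway: float = 2.0
    min_mirs: int = 2
    n_perm: int = 10**6
    locus_label: str = LOCUS_LABEL
    sam_s0: float | str = "median"
    synth: SynthConfig = field(default_factory=SynthConfig)

    def violations(self) -> list[str]:
        errs = []
        if not 0.0 <= self.tau <= 1.0:
            errs.append(f"tau = {self.tau} outside [0, 1]")
        for name in ("alpha", "fdr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                errs.append(f"{name} = {v} outside (0, 1]")
        for name in ("fc", "fc_pathway"):
            v = getattr(self, name)
            if v < 1.0:
                errs.append(f"{name} = {v} must be >= 1")
        if self.min_mirs < 1:
            errs.append(f"min_mirs = {self.min_mirs} must be >= 1")
        if self.n_perm < 1:
            errs.append(f"n_perm = {self.n_perm} must be >= 1")
        if not self.locus_label:
            errs.append("locus_label must be non-empty")
        try:
            self.synth.validate()
        except ConfigError as exc:
            errs.extend(f"synth: {v}" for v in str(exc).split("; "))
        return errs

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["synth"] = asdict(self.synth)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Build a RunConfig from a parsed mapping, returning ALL violations."""
    errs: list[str] = []
    if not isinstance(raw, dict):
        return None, ["configuration must be a mapping"]
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        errs.append(f"unknown configuration keys: {unknown}")
    synth_raw = raw.get("synth", {}) or {}
    synth_fields = set(SynthConfig.__dataclass_fields__)
    bad_synth = sorted(set(synth_raw) - synth_fields)
    if bad_synth:
        errs.append(f"unknown synth keys: {bad_synth}")
    if errs:
        return None, errs
    try:
        if "pathway_size_range" in synth_raw:
            synth_raw = dict(synth_raw)
            synth_raw["pathway_size_range"] = tuple(synth_raw["pathway_size_range"])
        synth = SynthConfig(**synth_raw)
    except (TypeError, ValueError) as exc:
        return None, [f"synth: {exc}"]
    kwargs = {k: v for k, v in raw.items() if k != "synth"}
    try:
        cfg = RunConfig(synth=synth, **kwargs)
    except TypeError as exc:
        return None, [str(exc)]
    errs = cfg.violations()
    return (cfg, errs) if not errs else (None, errs)


def load_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        return None, [f"unparseable YAML: {exc}"]
    return validate_config(raw or {})


@dataclass
class RunReport:
    """Per-stage summaries plus a provenance block."""

    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def to_text(self) -> str:
        lines = ["oligomir run report", "===================", ""]
        for stage, summary in self.stages.items():
            lines.append(f"[{stage}]")
            for k, v in summary.items():
                lines.append(f"  {k}: {v}")
            lines.append("")
        if self.warnings:
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
            lines.append("")
        lines.append("provenance:")
        for k, v in self.provenance.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage in dependency order on the synthetic bundle.

    Identical configuration and seed reproduce byte-identical outputs.  A
    stage failure stops its dependents but leaves completed outputs and is
    recorded with its stage name.
    """
    errs = cfg.violations()
    if errs:
        raise ConfigError("; ".join(errs))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    chash = cfg.config_hash()
    report.provenance = {
        "config_hash": chash,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "thresholds": {
            "tau": cfg.tau,
            "alpha": cfg.alpha,
            "fdr": cfg.fdr,
            "fc": cfg.fc,
            "fc_pathway": cfg.fc_pathway,
            "min_mirs": cfg.min_mirs,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": _pkg_version(),
    }

    def record(path: Path, stage: str) -> str:
        rel = str(path.relative_to(out))
        report.outputs[rel] = {"stage": stage, "config_hash": chash}
        return rel

    # ---- simulate ------------------------------------------------------
    synth = SynthConfig(**{**asdict(cfg.synth), "seed": cfg.seed})
    bundle = simulate_all(synth)
    panel, diff = bundle["panel"], bundle["differential"]
    pathways = bundle["pathways"]
    truth = bundle["truth"]
    oio.write_panel_tsv(panel, out / "panel.tsv")
    oio.write_mir_list(diff, out / "differential.txt")
    oio.write_gmt(pathways, out / "pathways.gmt")
    oio.write_target_scores(bundle["target_scores"], out / "target_scores.tsv")
    oio.write_expression(bundle["expression"], out / "expression.tsv")
    oio.write_survival(bundle["survival"], out / "survival.tsv")
    oio.write_json(truth, out / "ground_truth.json")
    for f in (
        "panel.tsv", "differential.txt", "pathways.gmt", "target_scores.tsv",
        "expression.tsv", "survival.tsv", "ground_truth.json",
    ):
        record(out / f, "simulate")
    report.stages["simulate"] = {
        "panel_size": len(panel),
        "locus_members": len(panel.locus_members(cfg.locus_label)),
        "differential_size": len(diff),
        "planted_mirs": ", ".join(truth["planted_mirs"]),
    }

    # ---- locus test ----------------------------------------------------
    perm = permutation_locus_test(
        diff, panel, cfg.locus_label, n_perm=cfg.n_perm, seed=cfg.seed
    )
    count, total, percent = locus_fraction(diff, panel, cfg.locus_label)
    oio.write_json(
        {
            "locus_label": cfg.locus_label,
            "observed_count": perm.observed_count,
            "set_size": perm.set_size,
            "percent": percent,
            "n_perm": perm.n_perm,
            "exceed_count": perm.exceed_count,
            "p_empirical": perm.p_empirical,
            "p_exact": perm.p_exact,
            "p_printed": perm.format_p(),
        },
        out / "locus_test.json",
    )
    record(out / "locus_test.json", "locus-test")
    report.stages["locus-test"] = {
        "locus_fraction": f"{count}/{total} ({percent}%)",
        "p_empirical": perm.p_empirical,
        "p_printed": perm.format_p(),
    }

    # ---- enrichment ----------------------------------------------------
    targets = threshold_targets(bundle["target_scores"], tau=cfg.tau)
    cells, combined = enrich_all(
        targets, pathways, bundle["target_scores"].gene_universe
    )
    heat = build_heatmap_matrix(cells, combined, alpha=cfg.alpha)
    if heat.values.shape[0] >= 2 and heat.values.shape[1] >= 1:
        order, _ = cluster_rows(heat.values)
        heat_out = heat.values.loc[order]
    else:
        heat_out = heat.values
    heat_out.to_csv(out / "heatmap.tsv", sep="\t", index_label="mir_id")
    ranking = rank_by_aim(cells, pathways, alpha=cfg.alpha)
    edges = export_pathway_network(
        cells, combined, alpha=cfg.alpha, min_mirs=cfg.min_mirs
    )
    edges.to_csv(out / "pathway_network.tsv", sep="\t", index=False)
    oio.write_json(
        [asdict_ranked(r) for r in ranking], out / "aim_ranking.json"
    )
    for f in ("heatmap.tsv", "pathway_network.tsv", "aim_ranking.json"):
        record(out / f, "enrich")
    n_sig = sum(1 for c in combined if c.p_combined <= cfg.alpha)
    report.stages["enrich"] = {
        "tau": cfg.tau,
        "alpha": cfg.alpha,
        "pathways_combined_significant": n_sig,
        "top_aim_mir": ranking[0].mir_id if ranking else "",
        "network_pathways": int(edges["pathway_id"].nunique()) if len(edges) else 0,
    }

    # ---- differential suppression -------------------------------------
    norm = quantile_normalize(bundle["expression"].values)
    nm = ExpressionMatrix(values=norm)
    suppressed = {}
    for mir in truth["planted_mirs"]:
        res = sam_test(nm, treated=mir, control="NT", s0=cfg.sam_s0, seed=cfg.seed)
        suppressed[mir] = select_suppressed(res, fc_min=cfg.fc, fdr_max=cfg.fdr)
    rows = [
        {"mir_id": m, "probe_id": p}
        for m, s in suppressed.items()
        for p in sorted(s.probes)
    ]
    import pandas as pd

    pd.DataFrame(rows, columns=["mir_id", "probe_id"]).to_csv(
        out / "suppressed_sets.tsv", sep="\t", index=False
    )
    record(out / "suppressed_sets.tsv", "de")
    report.stages["de"] = {
        "fdr": cfg.fdr,
        "fc": cfg.fc,
        **{f"n_suppressed[{m}]": len(s) for m, s in suppressed.items()},
    }

    # ---- overlap -------------------------------------------------------
    if len(suppressed) >= 2:
        ov = overlap_analysis(
            {m: s.probes for m, s in suppressed.items()},
            population_size=cfg.synth.n_probes,
        )
        oio.write_json(
            {
                "population_size": ov.population_size,
                "n_common_all": ov.n_common_all,
                "frac_union_ge2": ov.frac_union_ge2,
                "patterns": {
                    "+".join(sorted(k)): v for k, v in ov.pattern_counts.items()
                },
                "pairwise": {
                    f"{a}|{b}": {"chi2": chi2, "p": p}
                    for (a, b), (_, chi2, p) in ov.pairwise.items()
                },
            },
            out / "overlap.json",
        )
        record(out / "overlap.json", "overlap")
        report.stages["overlap"] = {
            "population_size": ov.population_size,
            "common_all": ov.n_common_all,
            "frac_union_ge2": round(ov.frac_union_ge2, 4),
            "max_pairwise_p": max(p for *_, p in ov.pairwise.values()),
        }
    else:
        report.stages["overlap"] = {"skipped": "fewer than 2 suppressed sets"}

    # ---- survival ------------------------------------------------------
    records = bundle["survival"]
    mirs = truth["planted_mirs"] or sorted(records[0].expr)
    groups = median_split(records, mirs)
    high = [r for r in records if groups[r.patient_id] == "high"]
    low = [r for r in records if groups[r.patient_id] == "low"]
    lr = logrank(high, low)
    curves = {}
    for label, grp in (("high", high), ("low", low)):
        c = km_curve(grp)
        curves[label] = c
        pd.DataFrame(
            {"time": c.event_times, "survival": c.survival, "at_risk": c.at_risk}
        ).to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
        record(out / f"km_{label}.tsv", "survival")
    oio.write_json(
        {
            "logrank_statistic": lr.statistic,
            "df": lr.df,
            "p": lr.p,
            "five_year_survival": {
                lab: survival_at(c, 60.0) for lab, c in curves.items()
            },
            "n": {"high": len(high), "low": len(low)},
        },
        out / "survival_test.json",
    )
    record(out / "survival_test.json", "survival")
    report.stages["survival"] = {
        "n_high": len(high),
        "n_low": len(low),
        "logrank_p": lr.p,
        "S5y_high": round(survival_at(curves["high"], 60.0), 4),
        "S5y_low": round(survival_at(curves["low"], 60.0), 4),
    }

    # ---- report --------------------------------------------------------
    oio.write_json(report.to_dict(), out / "report.json")
    (out / "report.txt").write_text(report.to_text())
    return report


def asdict_ranked(r) -> dict:
    return {
        "mir_id": r.mir_id,
        "n_significant_aim": r.n_significant_aim,
        "aim_score": r.aim_score,
        "rank": r.rank,
    }


def _pkg_version() -> str:
    try:
        from importlib.metadata import version

        return version("oligomir")
    except Exception:
        return "unknown"
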