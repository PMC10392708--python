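"""End-to-end orchestration: synth -> normalize/merge -> DE -> scores ->
group stats -> survival -> overrepresentation, with a JSON run report.

Every choice the analysis leaves open (reference selection, thresholds,
tie rules) is logged so a run is auditable; all randomness flows from
the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellscores import default_pairs, score_table
from .diffexpr import differential_expression
from .enrichment import GeneSetCollection, ora_test, read_gmt
from .io import write_clinical, write_marker_map, write_matrix
from .normalize import genorm_stability, housekeeping_normalize, merge_panels
from .stats import dunn_posthoc, kruskal_wallis, wilcoxon_rank_sum
from .survival import ConvergenceError, evaluate_marker
from .synth import ENDPOINTS, SynthConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: a synthetic cohort plus analysis thresholds."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    panel_order: tuple[str, str] = ("A", "B")   # first, subsequent codeset
    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    v_threshold: float = 0.15
    qc_min: float = 20.0
    de_ref_level: str = "CA"
    endpoints: tuple[str, ...] = ENDPOINTS
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        for val, name in [(self.p_thresh, "p_thresh"), (self.lfc_thresh, "lfc_thresh"),
                          (self.v_threshold, "v_threshold"), (self.qc_min, "qc_min")]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        if "effect_map" in synth_raw:
            synth_raw["effect_map"] = tuple(tuple(e) for e in synth_raw["effect_map"])
        if "cell_types" in synth_raw:
            synth_raw["cell_types"] = tuple(synth_raw["cell_types"])
        for key in ("panel_order", "endpoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=SynthConfig(**synth_raw), **raw)


def _df_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.round(9).to_csv().encode()).hexdigest()[:16]


def select_references(panel, min_refs: int = 3, v_threshold: float = 0.15) -> list[str]:
    """geNorm-selected housekeeping genes of one panel's raw counts."""
    hk = panel.housekeeping_genes
    if len(hk) < 3:
        log.info("panel %s: only %d housekeeping genes; using all", panel.panel_id, len(hk))
        return hk
    log2_hk = np.log2(panel.values.loc[hk] + 0.5)
    res = genorm_stability(log2_hk, v_threshold=v_threshold)
    log.info("panel %s: geNorm selected %d/%d reference genes",
             panel.panel_id, len(res.selected), len(hk))
    return res.selected


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write its outputs under ``out_dir``.

    Returns the JSON-serializable run summary (also written to
    ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"tilscore_version": __version__, "seed": config.synth.seed,
                     "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # 1. synthetic cohort ------------------------------------------------
    cohort = stage("synth")(lambda: generate_cohort(config.synth))
    write_matrix(cohort.panel_a, out / "panel_A_counts.csv")
    write_matrix(cohort.panel_b, out / "panel_B_counts.csv")
    write_marker_map(cohort.marker_map.entries, out / "marker_map.tsv")
    write_clinical(cohort.clinical, out / "clinical.csv")
    cohort.truth.abundance.to_csv(out / "truth_abundance.csv")
    summary["stages"]["synth"] = {
        "n_samples": cohort.config.n_samples,
        "genes_panel_a": len(cohort.panel_a.gene_names),
        "genes_panel_b": len(cohort.panel_b.gene_names),
    }

    # 2. normalize + merge ----------------------------------------------
    panels = {"A": cohort.panel_a, "B": cohort.panel_b}
    first_id, second_id = config.panel_order

    def normalize_stage():
        results = {}
        for pid in (first_id, second_id):
            refs = select_references(panels[pid], v_threshold=config.v_threshold)
            results[pid] = housekeeping_normalize(panels[pid], refs, qc_min=config.qc_min)
        return results

    norm = stage("normalize")(normalize_stage)
    excluded = sorted(set(norm[first_id].excluded_samples)
                      | set(norm[second_id].excluded_samples))
    kept = [s for s in panels[first_id].sample_names if s not in excluded]
    merged = stage("merge")(lambda: merge_panels(
        norm[first_id].matrix.subset_samples(kept),
        norm[second_id].matrix.subset_samples(kept)))
    write_matrix(merged, out / "merged_normalized.csv")
    clinical = cohort.clinical[cohort.clinical["sample"].isin(kept)].reset_index(drop=True)
    summary["stages"]["normalize_merge"] = {
        "excluded_samples": excluded, "n_samples_after_qc": len(kept),
        "n_genes_merged": len(merged.gene_names),
        "refs": {pid: norm[pid].refs for pid in norm},
    }

    merged_log2 = merged.to_log2()

    # 3. differential expression by race --------------------------------
    groups = clinical.set_index("sample")["race"]
    de = stage("de")(lambda: differential_expression(
        merged_log2, groups, ref_level=config.de_ref_level,
        p_thresh=config.p_thresh, lfc_thresh=config.lfc_thresh))
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)
    de_hits = de[de["p_raw"] < config.p_thresh]
    summary["stages"]["de"] = {
        "n_genes_tested": len(de), "n_p_raw_lt_thresh": int(len(de_hits)),
        "n_by_significant": int((de["p_by"] < config.p_thresh).sum()),
        "results_hash": _df_hash(de),
    }

    # 4. cell scores -----------------------------------------------------
    scores = stage("scores")(lambda: score_table(merged_log2, cohort.marker_map))
    scores.raw.to_csv(out / "scores_raw.csv")
    scores.til.to_frame().T.to_csv(out / "scores_til.csv")
    rel = scores.relative.copy()
    rel.index = [f"{n}:{d}" for n, d in rel.index]
    rel.to_csv(out / "scores_relative.csv")
    summary["stages"]["scores"] = {"n_cell_types": len(scores.raw.index),
                                   "pairs": list(rel.index)}

    # 5. group statistics on relative scores -----------------------------
    def stats_stage():
        rows = []
        cl = clinical.set_index("sample").loc[rel.columns]
        two_level = {"race": ("AA", "CA"), "grade_group": ("low", "high"),
                     "event_bcr": (0, 1), "event_metastasis": (0, 1)}
        multi = ("gleason", "psa_group", "age_group")
        for pair_name, values in rel.iterrows():
            for var, (lv0, lv1) in two_level.items():
                x = values[cl[var] == lv0].to_numpy()
                y = values[cl[var] == lv1].to_numpy()
                if x.size and y.size:
                    res = wilcoxon_rank_sum(x, y)
                    rows.append((pair_name, var, f"{lv0}_vs_{lv1}",
                                 res.method, res.statistic, res.p))
            for var in multi:
                grouped = [values[cl[var] == lv].to_numpy()
                           for lv in sorted(cl[var].unique())]
                grouped = [g for g in grouped if g.size]
                if len(grouped) >= 3:
                    kw = kruskal_wallis(grouped)
                    rows.append((pair_name, var, "omnibus", kw.method,
                                 kw.statistic, kw.p))
                    dunn = dunn_posthoc(grouped,
                                        labels=sorted(cl[var].unique()))
                    for (a, b), z, p_adj in dunn.pairwise:
                        rows.append((pair_name, var, f"{a}_vs_{b}", "dunn", z, p_adj))
        return pd.DataFrame(rows, columns=["score", "variable", "comparison",
                                           "method", "statistic", "p"])

    group_stats = stage("stats")(stats_stage)
    group_stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    summary["stages"]["stats"] = {"n_tests": len(group_stats)}

    # 6. survival ---------------------------------------------------------
    def survival_stage():
        rows = []
        cl = clinical.set_index("sample").loc[rel.columns]
        for endpoint in config.endpoints:
            times = cl[f"time_{endpoint}"].to_numpy()
            events = cl[f"event_{endpoint}"].to_numpy()
            if events.sum() < 2 or events.sum() >= events.size:
                log.warning("endpoint %s: degenerate event distribution; skipped",
                            endpoint)
                continue
            for pair_name, values in rel.iterrows():
                try:
                    res = evaluate_marker(values, times, events, name=pair_name,
                                          endpoint=endpoint)
                except (ValueError, ConvergenceError) as exc:
                    log.warning("survival %s/%s skipped: %s", pair_name, endpoint, exc)
                    continue
                for method, (chi2, p) in res.logrank.items():
                    cp = res.cutpoints[method]
                    counts = cp.groups.value_counts()
                    rows.append((pair_name, endpoint, method, cp.cutoff,
                                 int(counts.get("low", 0)), int(counts.get("high", 0)),
                                 chi2, p, res.cox_hr, res.cox_p))
                for (method, level), curve in res.km_curves.items():
                    curve.to_csv(out / f"km_{endpoint}_{pair_name.replace(':', '_vs_')}"
                                       f"_{method}_{level}.tsv", sep="\t", index=False)
        return pd.DataFrame(rows, columns=[
            "score", "endpoint", "method", "cutoff", "n_low", "n_high",
            "logrank_chi2", "logrank_p", "hr", "hr_p"])

    surv = stage("survival")(survival_stage)
    surv.to_csv(out / "survival_results.tsv", sep="\t", index=False)
    summary["stages"]["survival"] = {"n_rows": len(surv)}

    # 7. overrepresentation ----------------------------------------------
    def ora_stage():
        if config.gmt_path:
            collection = read_gmt(config.gmt_path)
        else:
            # fall back to marker-map-derived sets so the stage always runs
            collection = GeneSetCollection(sets={
                f"{c}_markers": genes for c, genes in cohort.marker_map.entries.items()})
        query = de_hits["gene"].tolist()
        if not query:
            log.warning("ORA skipped: empty DE query list")
            return pd.DataFrame(columns=["set", "K", "n", "k", "gene_ratio",
                                         "p", "p_adj", "overlap"])
        return ora_test(query, collection, universe=merged.endogenous_genes)

    ora = stage("ora")(ora_stage)
    ora.to_csv(out / "ora_results.tsv", sep="\t", index=False)
    summary["stages"]["ora"] = {"n_sets": len(ora)}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
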