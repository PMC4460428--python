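"""Stage-wise group statistics and the end-to-end pipeline.

Whole-network and lobar metrics are compared across diagnostic groups with
one-way ANOVA followed by the Tukey–Kramer honest-significant-difference
procedure (studentized-range based, valid and conservative for unequal
group sizes).  Pearson correlations link network metrics to clinical
scores, both within each group and pooled over all subjects; correlation
p-values are reported uncorrected by default, with optional
Benjamini–Hochberg adjustment.

``run_group_pipeline`` orchestrates the full analysis on a cohort:
connectivity, optional degree screen, fixed-density networks, per-subject
metrics, group comparisons (whole-brain and per lobar cell), correlation
tables, and group-level rich-club curves, all deterministic given the
configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import default_lobe_map
from .connectivity import build_mi_matrix
from .graphmetrics import (
    NODAL_METRICS,
    WHOLE_BRAIN_METRICS,
    compute_metrics,
    lobar_average,
)
from .netbuild import (
    detect_degree_outliers,
    exclusion_table,
    group_mean_network,
    threshold_absolute,
    threshold_to_density,
)
from .richclub import normalized_rich_club
from .synthetic import GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "PipelineConfig",
    "anova_oneway",
    "tukey_hsd",
    "correlate_metric_clinical",
    "benjamini_hochberg",
    "run_group_pipeline",
]


@dataclass
class GroupComparisonResult:
    metric_name: str
    anova_F: float
    anova_p: float
    # (group_a, group_b) -> (mean_diff, adjusted_p, significant_at_05)
    pairwise: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": self.metric_name, "group_a": a, "group_b": b,
             "mean_diff": d, "adjusted_p": p, "significant_at_05": s}
            for (a, b), (d, p, s) in self.pairwise.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    metric_name: str
    score_name: str
    p: float
    R2: float
    r: float
    group_scope: str = "all"
    n: int = 0


def anova_oneway(values_by_group: dict) -> tuple[float, float]:
    """One-way ANOVA (F, p) across the groups of a metric."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if all(np.ptp(g) == 0 for g in groups):
        if len({g[0] for g in groups}) == 1:
            logger.debug("all values identical: F defined as 0")
            return 0.0, 1.0
        raise ValueError("zero within-group variance everywhere: F undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def tukey_hsd(values_by_group: dict) -> dict:
    """Tukey–Kramer all-pairs comparison.

    Returns {(group_a, group_b): (mean_diff, adjusted_p, significant_at_05)}
    over all unordered pairs, with mean_diff = mean(a) - mean(b).
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    res = stats.tukey_hsd(*groups)
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(groups[i].mean() - groups[j].mean())
            p = float(res.pvalue[i, j])
            out[(names[i], names[j])] = (diff, p, bool(p < 0.05))
    return out


def correlate_metric_clinical(metric_values, score_values,
                              metric_name: str = "", score_name: str = "",
                              group_scope: str = "all") -> CorrelationResult:
    """Pearson correlation of a network metric with a clinical score.

    Missing values in either variable are pairwise-deleted (and logged).
    Constant input after deletion leaves the correlation undefined (NaN,
    flagged via the log).
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(score_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("metric and score vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        logger.debug("correlation %s~%s: %d pairs dropped (missing)",
                     metric_name, score_name, dropped)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("correlation %s~%s undefined: constant input",
                     metric_name, score_name)
        return CorrelationResult(metric_name, score_name, float("nan"),
                                 float("nan"), float("nan"), group_scope, x.size)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(metric_name, score_name, float(p), float(r) ** 2,
                             float(r), group_scope, x.size)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional alternative to the uncorrected default)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Everything the end-to-end analysis needs beyond the cohort itself."""

    density: float = 0.07
    n_bins: int | None = None          # None -> ceil(sqrt(T/5)) in [4, 16]
    screen_tau: float | None = None    # absolute-MI screen threshold; None = off
    k_values: tuple = tuple(range(1, 16))
    n_random: int = 1000               # rich-club null ensemble size
    swap_factor: int = 10
    modularity_restarts: int = 20
    seed: int = 0
    adjust_correlations: bool = False  # Benjamini-Hochberg on correlation p

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_group_pipeline(subjects, config: PipelineConfig | None = None,
                       lobe_map: pd.DataFrame | None = None,
                       out_dir=None) -> dict:
    """Full stage-wise analysis of a cohort.

    ``subjects`` is a list of (TimeSeriesMatrix, SubjectRecord) as produced
    by :func:`adnetworks.synthetic.generate_cohort` or
    :func:`adnetworks.synthetic.load_cohort`.

    Returns a bundle of DataFrames: ``metrics`` (per-subject whole-brain),
    ``lobar`` (per-subject lobe x hemisphere nodal means), ``comparisons``
    (ANOVA + Tukey, whole-brain and lobar), ``correlations``, ``richclub``
    (per-group curves), ``exclusions``, and a JSON-able ``summary``.  With
    ``out_dir`` set, every table is also written as TSV.
    """
    config = config or PipelineConfig()
    if lobe_map is None:
        lobe_map = default_lobe_map()
    if not subjects:
        raise PipelineError("input", "empty cohort")

    # -- connectivity ----------------------------------------------------
    try:
        conn = [(build_mi_matrix(ts, config.n_bins), rec) for ts, rec in subjects]
    except Exception as exc:  # re-raise with stage tag
        raise PipelineError("connectivity", str(exc)) from exc

    # -- degree screen (optional) ---------------------------------------
    n_before = len(conn)
    excl_df = pd.DataFrame()
    if config.screen_tau is not None:
        try:
            degs = [threshold_absolute(c, config.screen_tau).degrees().sum()
                    for c, _ in conn]
            reports = detect_degree_outliers(
                degs, [rec.subject_id for _, rec in conn])
            excl_df = exclusion_table(reports)
            keep = [not r.excluded for r in reports]
            conn = [cr for cr, k in zip(conn, keep) if k]
        except Exception as exc:
            raise PipelineError("screen", str(exc)) from exc
    if not conn:
        raise PipelineError("screen", "screen excluded every subject")

    # -- networks and metrics --------------------------------------------
    try:
        metrics_rows, lobar_rows = [], []
        for C, rec in conn:
            net = threshold_to_density(C, config.density,
                                       provenance=rec.subject_id)
            m = compute_metrics(net, n_restarts=config.modularity_restarts,
                                seed=config.seed)
            row = {"subject_id": rec.subject_id, "group": rec.group}
            row.update(m.whole_brain().to_dict())
            row.update(rec.clinical_scores)
            metrics_rows.append(row)
            for nodal_metric in NODAL_METRICS:
                cell_means = lobar_average(m.nodal[nodal_metric].to_dict(),
                                           lobe_map)
                for (lobe, hemi), val in cell_means.items():
                    lobar_rows.append({
                        "subject_id": rec.subject_id, "group": rec.group,
                        "metric": nodal_metric, "lobe": lobe,
                        "hemisphere": hemi, "value": val,
                    })
        metrics_df = pd.DataFrame(metrics_rows)
        lobar_df = pd.DataFrame(lobar_rows)
    except Exception as exc:
        raise PipelineError("metrics", str(exc)) from exc

    score_names = [k for k in subjects[0][1].clinical_scores]
    groups_present = [g for g in GROUPS if (metrics_df["group"] == g).any()]

    # -- group comparisons ----------------------------------------------
    comparisons = []
    if len(groups_present) < 2:
        logger.warning("single-group cohort: group comparisons skipped")
    else:
        try:
            for metric in WHOLE_BRAIN_METRICS:
                sub = metrics_df.dropna(subset=[metric])
                by_group = {g: sub.loc[sub["group"] == g, metric].to_numpy()
                            for g in groups_present}
                by_group = {g: v for g, v in by_group.items() if v.size >= 2}
                if len(by_group) < 2:
                    continue
                f, p = anova_oneway(by_group)
                res = GroupComparisonResult(metric, f, p, tukey_hsd(by_group))
                df = res.to_frame()
                df.insert(0, "scope", "whole_brain")
                df["anova_F"], df["anova_p"] = f, p
                comparisons.append(df)
            for (metric, lobe, hemi), cell in lobar_df.groupby(
                    ["metric", "lobe", "hemisphere"]):
                by_group = {g: cell.loc[cell["group"] == g, "value"].to_numpy()
                            for g in groups_present}
                by_group = {g: v for g, v in by_group.items() if v.size >= 2}
                if len(by_group) < 2:
                    continue
                f, p = anova_oneway(by_group)
                res = GroupComparisonResult(metric, f, p, tukey_hsd(by_group))
                df = res.to_frame()
                df.insert(0, "scope", f"{lobe}_{hemi}")
                df["anova_F"], df["anova_p"] = f, p
                comparisons.append(df)
        except Exception as exc:
            raise PipelineError("comparisons", str(exc)) from exc
    comparisons_df = (pd.concat(comparisons, ignore_index=True)
                      if comparisons else pd.DataFrame())

    # -- correlations -----------------------------------------------------
    try:
        corr_rows = []
        scopes = [("all", metrics_df)] + [
            (g, metrics_df[metrics_df["group"] == g]) for g in groups_present
        ]
        for scope, frame in scopes:
            for metric in WHOLE_BRAIN_METRICS:
                for score in score_names:
                    pair = frame[[metric, score]].to_numpy(dtype=float)
                    finite = np.isfinite(pair).all(axis=1)
                    if finite.sum() < 3:
                        continue
                    r = correlate_metric_clinical(
                        pair[:, 0], pair[:, 1], metric, score, scope)
                    corr_rows.append(r.__dict__)
        corr_df = pd.DataFrame(corr_rows)
        if config.adjust_correlations and not corr_df.empty:
            corr_df["p_adjusted"] = benjamini_hochberg(corr_df["p"].to_numpy())
    except Exception as exc:
        raise PipelineError("correlations", str(exc)) from exc

    # -- group-level rich club -------------------------------------------
    try:
        rc_rows = []
        for g in groups_present:
            Cs = [c for c, rec in conn if rec.group == g]
            gnet = group_mean_network(Cs, config.density, provenance=g)
            curve = normalized_rich_club(
                gnet, k_values=config.k_values, n_random=config.n_random,
                seed=config.seed, swap_factor=config.swap_factor)
            df = curve.to_frame()
            df.insert(0, "group", g)
            rc_rows.append(df)
        richclub_df = pd.concat(rc_rows, ignore_index=True)
    except Exception as exc:
        raise PipelineError("richclub", str(exc)) from exc

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "density": config.density,
        "n_subjects_input": n_before,
        "n_subjects_analyzed": len(conn),
        "n_excluded_by_screen": n_before - len(conn),
        "groups": {g: int((metrics_df["group"] == g).sum())
                   for g in groups_present},
    }
    bundle = {
        "metrics": metrics_df,
        "lobar": lobar_df,
        "comparisons": comparisons_df,
        "correlations": corr_df,
        "richclub": richclub_df,
        "exclusions": excl_df,
        "summary": summary,
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for name, obj in bundle.items():
            if name == "summary":
                path = out / "summary.json"
                path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
            else:
                path = out / f"{name}.tsv"
                obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
    except Exception:
        for path in written:  # leave no partial output behind
            path.unlink(missing_ok=True)
        raise
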