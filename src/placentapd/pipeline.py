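"""End-to-end study orchestration: simulate -> measure -> metrics -> inference.

``run_single`` executes one full in-silico study and produces the endpoint
summary table (one row per marker: slopes with SEM, slope-comparison p, FRI
with SEM, response-pattern label).  ``run_study`` repeats this over replicate
cohorts with independent seeds and reports Monte-Carlo means and errors of
every summary cell — the package's analogue of running the whole animal
experiment many times.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .calibration import StudyConfig
from .cohort import Cohort, generate_cohort
from .errors import ConfigurationError
from .measure import measure_cohort
from .metrics import compute_pd_metrics
from .stats import ancova_slopes, linear_regression, oneway_anova_tukey, pairwise_contrasts_by_time, pearson, rm_anova

RESPONSE_LABELS = (
    "trajectory inversion",
    "attenuated progression",
    "partial mitigation",
    "enhanced increase",
    "no slope alteration",
    "accelerated decline",
)


def classify_response(slope_disease_adj: float, slope_treated_adj: float, p: float,
                      alpha: float = 0.05, strong_alpha: float = 0.01) -> str:
    """Label the treated-arm trajectory change relative to the disease arm.

    Inputs are directionally *adjusted* group-mean slopes (positive = moving
    toward the healthy phenotype) and the slope-comparison p-value.
    """
    if not np.isfinite(p) or p >= alpha:
        return "no slope alteration"
    a_d, a_t = slope_disease_adj, slope_treated_adj
    if a_t > a_d:
        if a_d < 0.0 < a_t:
            return "trajectory inversion"
        if a_t <= 0.0:
            # deterioration slowed but not reversed
            return "attenuated progression" if p < strong_alpha else "partial mitigation"
        return "enhanced increase"
    if a_t < a_d:
        return "accelerated decline"
    return "no slope alteration"


@dataclass
class RunManifest:
    """Provenance for one pipeline run."""

    config_hash: str
    seed: int | None
    replicates: int
    version: str
    stage_rows: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


@dataclass
class SingleRun:
    cohort: Cohort
    measured: pd.DataFrame
    metrics: pd.DataFrame
    stats: pd.DataFrame          # STATS_SCHEMA rows
    summary: pd.DataFrame        # SUMMARY_SCHEMA rows
    detection: pd.DataFrame      # per marker x GD treated-vs-disease contrast
    manifest: RunManifest


@dataclass
class StudyResult:
    summary: pd.DataFrame                  # aggregated (or single-run) summary
    replicate_summaries: list[pd.DataFrame]
    detection_frequency: pd.DataFrame | None
    manifest: RunManifest
    first_run: SingleRun | None = None


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def temporal_detection(measured: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Treated-vs-disease Bonferroni contrast per marker per gestational day."""
    rows = []
    for cal in config.markers:
        sub = measured[measured["marker"] == cal.name]
        if sub.empty:
            continue
        data = sub.rename(columns={"dam_id": "subject", "gd": "time"})
        contrasts = pairwise_contrasts_by_time(data[["subject", "group", "time", "value"]])
        tvd = contrasts[((contrasts["group1"] == "disease") & (contrasts["group2"] == "treated"))
                        | ((contrasts["group1"] == "treated") & (contrasts["group2"] == "disease"))]
        for _, row in tvd.iterrows():
            rows.append({"marker": cal.name, "gd": int(row["time"]),
                         "p_bonferroni": row["p_bonferroni"],
                         "significant": bool(row["p_bonferroni"] < config.analysis.alpha)})
    return pd.DataFrame(rows)


def _marker_stats(measured: pd.DataFrame, metrics: pd.DataFrame,
                  endpoints: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Full inference table: RM-ANOVA, slope ANCOVA, FRI ANOVA+Tukey, correlations."""
    rows = []
    for cal in config.markers:
        sub = measured[measured["marker"] == cal.name].dropna(subset=["value"])
        long = sub.rename(columns={"dam_id": "subject", "gd": "time"})
        table = rm_anova(long[["subject", "group", "time", "value"]],
                         gg_correction=config.analysis.gg_correction)
        for effect in ("group", "time", "group:time"):
            row = table[effect]
            rows.append({"marker": cal.name, "effect": f"rm_anova:{effect}",
                         "statistic": row.f, "df": f"{row.df:g}", "p": row.p,
                         "adjustment": "greenhouse-geisser"
                         if config.analysis.gg_correction and effect != "group" else "none"})
        pair = sub[sub["group"].isin(["disease", "treated"])]
        comp = ancova_slopes(pair.rename(columns={"dam_id": "subject"})
                             [["subject", "group", "gd", "value"]])
        rows.append({"marker": cal.name, "effect": "ancova:slope_interaction",
                     "statistic": comp.f_interaction,
                     "df": f"{comp.df[0]:g},{comp.df[1]:g}", "p": comp.p,
                     "adjustment": "none"})
        if comp.p_subject is not None:
            rows.append({"marker": cal.name, "effect": "subject_slopes:t",
                         "statistic": comp.t_subject, "df": "", "p": comp.p_subject,
                         "adjustment": "none"})

    # FRI comparison across imaging modalities (treated arm)
    imaging = [m.name for m in config.markers if m.grid == "imaging"]
    fri_lists = {
        m: metrics[(metrics["marker"] == m) & (metrics["group"] == "treated")]
        ["fri_percent"].dropna().to_numpy()
        for m in imaging
    }
    fri_lists = {m: v for m, v in fri_lists.items() if len(v) >= 2}
    if len(fri_lists) >= 2:
        table, tukey = oneway_anova_tukey(fri_lists)
        rows.append({"marker": "fri_across_modalities", "effect": "oneway_anova",
                     "statistic": table["between"].f, "df": f"{table['between'].df:g}",
                     "p": table["between"].p, "adjustment": "none"})
        for _, row in tukey.iterrows():
            rows.append({"marker": "fri_across_modalities",
                         "effect": f"tukey:{row['group1']}_vs_{row['group2']}",
                         "statistic": row["q"], "df": "", "p": row["p_tukey"],
                         "adjustment": "tukey-hsd"})

    # fetal-weight association with each FRI (treated arm), and in-vivo/ex-vivo checks
    treated_ep = endpoints[endpoints["group"] == "treated"].set_index("dam_id")
    for m in imaging:
        fri_t = metrics[(metrics["marker"] == m) & (metrics["group"] == "treated")]
        merged = fri_t.set_index("dam_id").join(treated_ep["fetal_weight"], how="inner").dropna(
            subset=["fri_percent", "fetal_weight"])
        if len(merged) >= 3 and merged["fri_percent"].nunique() > 1:
            reg = linear_regression(merged["fri_percent"], merged["fetal_weight"])
            rows.append({"marker": m, "effect": "fetal_weight~fri:r", "statistic": reg.r,
                         "df": "", "p": reg.p, "adjustment": "none"})
    final_gd = config.design.final_gd
    for m, ep_col, effect in (("so2", "hif1a", "so2~hif1a:r"), ("vi", "cd31", "vi~cd31:r")):
        if m not in imaging:
            continue
        meas = measured[(measured["marker"] == m) & (measured["gd"] == final_gd)]
        merged = meas.set_index("dam_id").join(endpoints.set_index("dam_id")[ep_col],
                                               how="inner").dropna(subset=["value", ep_col])
        if len(merged) >= 3 and merged["value"].nunique() > 1 and merged[ep_col].nunique() > 1:
            corr = pearson(merged["value"], merged[ep_col])
            rows.append({"marker": m, "effect": effect, "statistic": corr.r, "df": "",
                         "p": corr.p, "adjustment": "none"})
    return pd.DataFrame(rows, columns=pio.STATS_SCHEMA)


def summarize(measured: pd.DataFrame, metrics: pd.DataFrame,
              config: StudyConfig) -> pd.DataFrame:
    """Endpoint summary table, one row per marker.

    Slope SEMs are the per-subject slope dispersion within each arm (SD/sqrt n).
    The slope-comparison p is the per-subject-slope two-sample t-test where
    available, falling back to the pooled homogeneity-of-slopes interaction:
    with repeated measures per dam the pooled ANCOVA residual absorbs the
    between-dam intercept variance and the interaction F becomes conservative,
    whereas the subject-slope test is calibrated (both are reported in the
    stats table).
    """
    rows = []
    alpha = config.analysis.alpha
    for cal in config.markers:
        msub = metrics[metrics["marker"] == cal.name]
        by_group = {g: s for g, s in msub.groupby("group")}
        sl_d = by_group["disease"]["beta_raw"].to_numpy()
        sl_t = by_group["treated"]["beta_raw"].to_numpy()
        pair = measured[(measured["marker"] == cal.name)
                        & measured["group"].isin(["disease", "treated"])].dropna(subset=["value"])
        comp = ancova_slopes(pair.rename(columns={"dam_id": "subject"})
                             [["subject", "group", "gd", "value"]])
        slope_p = comp.p_subject if comp.p_subject is not None else comp.p
        sign = 1.0 if cal.increase_is_recovery else -1.0
        fri_t = by_group["treated"]["fri_percent"].to_numpy()
        fri_t = fri_t[np.isfinite(fri_t)]
        label = classify_response(sign * sl_d.mean(), sign * sl_t.mean(), slope_p,
                                  alpha=alpha, strong_alpha=config.analysis.strong_alpha)
        rows.append({
            "marker": cal.name,
            "slope_disease": sl_d.mean(), "slope_disease_sem": _sem(sl_d),
            "slope_treated": sl_t.mean(), "slope_treated_sem": _sem(sl_t),
            "slope_p": slope_p,
            "fri_mean": fri_t.mean() if len(fri_t) else np.nan,
            "fri_sem": _sem(fri_t),
            "response_pattern": label,
        })
    return pd.DataFrame(rows, columns=pio.SUMMARY_SCHEMA)


def run_single(config: StudyConfig, seed: int | None = None,
               full_stats: bool = True) -> SingleRun:
    """One complete simulate -> measure -> metrics -> inference pass.

    ``full_stats=False`` skips the detailed inference table (RM-ANOVA rows,
    Tukey, correlations) and keeps only what Monte-Carlo aggregation needs:
    the summary and the per-GD detection contrasts.
    """
    manifest = RunManifest(config_hash=config.config_hash, seed=seed, replicates=1,
                           version=_version())
    stages = {}
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(seed)
    seed_cohort, seed_measure = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    cohort = generate_cohort(config, seed=seed_cohort)
    stages["simulate"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    measured = measure_cohort(cohort, config, seed=seed_measure)
    cohort.measured = measured
    stages["measure"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    metrics = compute_pd_metrics(measured, config)
    stages["metrics"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    if full_stats:
        stats = _marker_stats(measured, metrics, cohort.endpoints, config)
    else:
        stats = pd.DataFrame(columns=pio.STATS_SCHEMA)
    summary = summarize(measured, metrics, config)
    detection = temporal_detection(measured, config)
    stages["stats"] = time.perf_counter() - t3

    manifest.stage_seconds = {k: round(v, 4) for k, v in stages.items()}
    manifest.stage_rows = {"truths": len(cohort.truths), "measured": len(measured),
                           "metrics": len(metrics), "stats": len(stats),
                           "summary": len(summary)}
    return SingleRun(cohort=cohort, measured=measured, metrics=metrics, stats=stats,
                     summary=summary, detection=detection, manifest=manifest)


def run_study(config: StudyConfig, seed: int | None = None,
              replicates: int = 1) -> StudyResult:
    """Run the study once or as a Monte-Carlo ensemble of replicate cohorts.

    With ``replicates > 1`` every numeric summary cell is reported as the
    Monte-Carlo mean across replicates with its Monte-Carlo standard error,
    the slope-comparison column becomes the rejection rate at alpha, and the
    response pattern is the modal label.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in np.random.SeedSequence(seed).spawn(replicates)]
    runs: list[SingleRun] = []
    summaries: list[pd.DataFrame] = []
    detections: list[pd.DataFrame] = []
    first: SingleRun | None = None
    for i, child in enumerate(child_seeds):
        run = run_single(config, seed=child, full_stats=(i == 0))
        summaries.append(run.summary)
        detections.append(run.detection)
        if i == 0:
            first = run
    manifest = RunManifest(config_hash=config.config_hash, seed=seed,
                           replicates=replicates, version=_version())
    if replicates == 1:
        return StudyResult(summary=first.summary, replicate_summaries=summaries,
                           detection_frequency=None, manifest=manifest, first_run=first)

    stacked = pd.concat(summaries, ignore_index=True)
    alpha = config.analysis.alpha
    agg_rows = []
    for marker, sub in stacked.groupby("marker", sort=False):
        row = {"marker": marker}
        for col in ("slope_disease", "slope_treated", "fri_mean"):
            vals = sub[col].to_numpy(dtype=float)
            row[col] = float(np.nanmean(vals))
            row[f"{col}_mc_se"] = _sem(vals)
        row["slope_reject_rate"] = float((sub["slope_p"] < alpha).mean())
        row["response_pattern"] = sub["response_pattern"].mode().iloc[0]
        agg_rows.append(row)
    agg = pd.DataFrame(agg_rows)
    agg = agg.set_index("marker").loc[list(config.marker_names)].reset_index()

    det = pd.concat(detections, ignore_index=True)
    det_freq = (det.groupby(["marker", "gd"])["significant"].mean()
                .rename("detection_frequency").reset_index())
    return StudyResult(summary=agg, replicate_summaries=summaries,
                       detection_frequency=det_freq, manifest=manifest, first_run=first)


def write_run(run: SingleRun, outdir) -> None:
    """Persist every table of a single run under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_cohort(run.cohort.truths, outdir / "cohort.csv", run.measured)
    pio.write_table(run.cohort.endpoints, outdir / "endpoints.csv", pio.ENDPOINT_SCHEMA)
    pio.write_table(run.metrics, outdir / "metrics.csv", pio.METRICS_SCHEMA)
    pio.write_table(run.stats, outdir / "stats.csv", pio.STATS_SCHEMA)
    pio.write_table(run.summary, outdir / "summary.csv", pio.SUMMARY_SCHEMA)
    (outdir / "manifest.json").write_text(run.manifest.to_json() + "\n")


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("placentapd")
    except Exception:
        return "0.0.0+local"
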