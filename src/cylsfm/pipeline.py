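"""End-to-end pipeline: simulate -> score -> statistics -> report.

``run_battery`` assembles the full statistical battery from scored
metrics; ``run_pipeline`` drives the whole chain from a config, writing
events/metrics CSVs, a machine-readable ``stats_report.json``, figures and
a Markdown report, plus a manifest with seeds and inclusion counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as cio
from .observer import CohortSpec, generate_cohort
from .records import Cohort, GROUPS
from .scoring import (
    DEFAULT_WINDOW,
    MIN_CORRECT,
    cohort_metrics,
    pooled_durations_by_group,
)
from .stats import (
    StatsReport,
    block_effect,
    cohens_d,
    duration_histogram,
    exclusion_contingency,
    icc_3k,
    kruskal_wallis,
    ks_two_sample,
    metabolite_correlations,
    posthoc_pairwise,
    spearman,
)
from .stimulus import CylinderParams, make_real_switch_schedule

logger = logging.getLogger(__name__)

CLINICAL_SCALES = ("BPRS", "SPQ", "BACS", "SGI", "BPRS_D", "SPQ_CP")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    cohort: Mapping = field(default_factory=dict)  # CohortSpec overrides
    cylinder: Mapping = field(default_factory=dict)  # CylinderParams overrides
    window: float = DEFAULT_WINDOW
    min_correct: int = MIN_CORRECT
    apply_exclusion: bool = True
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, **self.cohort)

    def cylinder_params(self) -> CylinderParams:
        return CylinderParams(**self.cylinder)


def run_battery(
    metrics: pd.DataFrame,
    durations_by_group: Optional[Mapping[str, np.ndarray]] = None,
    sessions_meta: Optional[pd.DataFrame] = None,
    apply_exclusion: bool = True,
) -> StatsReport:
    """Full statistical battery over a scored metrics table.

    Group comparisons use session 1 of included participants (repeat
    sessions violate independence); reliability uses subjects with both
    sessions. Bonferroni families: 3 pairwise group tests, 6 clinical
    correlations, 3 metabolites.
    """
    report = StatsReport()
    m1 = metrics[metrics["session"] == 1]
    if apply_exclusion:
        included = m1[m1["included"]]
    else:
        included = m1
    by_group = {
        g: included.loc[included["group"] == g, "mean_log10_rate"].to_numpy()
        for g in GROUPS
        if (included["group"] == g).sum() >= 2
    }
    if len(by_group) < len(GROUPS):
        logger.warning("only %d groups with n >= 2; running on those", len(by_group))

    if len(by_group) >= 2:
        report.add(
            kruskal_wallis(*by_group.values(), name="bistable_rate_kw")
        )
        names = list(by_group)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        for a, b in pairs:
            report.add(
                posthoc_pairwise(
                    by_group[a], by_group[b], name=f"bistable_rate_{a}_vs_{b}", m=len(pairs)
                )
            )
        if "control" in by_group and "pwpp" in by_group:
            d = cohens_d(by_group["pwpp"], by_group["control"])
            report.add(_effect_entry("cohens_d_pwpp_vs_control", d))

    # CV comparison across groups
    cv_by_group = {
        g: included.loc[(included["group"] == g) & included["cv"].notna(), "cv"].to_numpy()
        for g in by_group
    }
    if all(v.size >= 2 for v in cv_by_group.values()) and len(cv_by_group) >= 2:
        report.add(kruskal_wallis(*cv_by_group.values(), name="duration_cv_kw"))

    # Exclusion contingency (included/excluded x group), session 1
    if apply_exclusion and m1["rs_accuracy"].notna().any():
        table = []
        for g in GROUPS:
            sel = m1["group"] == g
            if sel.sum():
                table.append(
                    [int(m1.loc[sel, "included"].sum()), int((~m1.loc[sel, "included"]).sum())]
                )
        table_arr = np.asarray(table)
        if table_arr.shape[0] >= 2 and table_arr.sum(axis=0).min() > 0:
            report.add(exclusion_contingency(table_arr.T, name="exclusion_contingency"))

    # Test-retest ICC on mean rates across sessions (Hz scale and log10 scale)
    if (metrics["session"] > 1).any():
        inc_ids = set(included["subject_id"]) if apply_exclusion else set(metrics["subject_id"])
        both = metrics[metrics["subject_id"].isin(inc_ids)]
        for col, name in (("mean_switch_rate", "retest_icc_rate"), ("mean_log10_rate", "retest_icc_log10")):
            wide = both.pivot_table(index="subject_id", columns="session", values=col)
            if wide.shape[1] >= 2 and wide.dropna().shape[0] >= 2:
                report.add(icc_3k(wide.to_numpy(), name=name))

    # Block-order effect (repeated measures over the 5 bi-stable blocks)
    block_cols = sorted(c for c in metrics.columns if c.startswith("log10_rate_block"))
    if len(block_cols) >= 2:
        report.add(block_effect(included[block_cols].to_numpy(), name="block_effect"))

    # Pooled-duration KS tests between groups
    if durations_by_group:
        names = [g for g in GROUPS if g in durations_by_group and len(durations_by_group[g])]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                report.add(
                    ks_two_sample(
                        durations_by_group[a], durations_by_group[b], name=f"durations_ks_{a}_vs_{b}"
                    )
                )

    # Clinical symptom correlations (Bonferroni over the 6 scales)
    if sessions_meta is not None:
        meta1 = sessions_meta[sessions_meta["session"] == 1]
        joined = included.merge(meta1, on=["subject_id", "session"], suffixes=("", "_meta"))
        scales = [s for s in CLINICAL_SCALES if s in joined.columns]
        for scale in scales:
            pair = joined[["mean_log10_rate", scale]].dropna()
            if len(pair) >= 4:
                report.add(
                    spearman(
                        pair["mean_log10_rate"], pair[scale],
                        name=f"clinical_{scale}", m=len(scales),
                    )
                )
        mets = [c for c in ("GABA", "glutamate", "glutamine") if c in joined.columns]
        if mets:
            met_report = metabolite_correlations(
                joined["mean_log10_rate"], joined[mets], groups=joined["group"], metabolites=mets
            )
            for entry in met_report.entries.values():
                report.add(entry)
    return report


def _effect_entry(name: str, d: float):
    from .stats import TestResult

    return TestResult(test_name=name, statistic=d, effect_size=d, note="Cohen's d on log10 rates")


def durations_long_frame(cohort: Cohort, metrics: pd.DataFrame) -> pd.DataFrame:
    """Long-format completed percept durations for included session-1 subjects."""
    from .scoring import subject_metrics

    rows = []
    keep = set(metrics.loc[metrics["included"], "subject_id"])
    for s in cohort:
        if s.subject_id not in keep:
            continue
        sm = subject_metrics(s)
        for d in sm.pooled_durations:
            rows.append(
                {"subject_id": s.subject_id, "session": s.session_index, "group": s.group, "duration": d}
            )
    return pd.DataFrame(rows)


def make_figures(
    metrics: pd.DataFrame,
    durations_by_group: Mapping[str, np.ndarray],
    outdir: Path,
) -> list[Path]:
    """Box plots of switch rates, normalized duration histograms, and the
    session-1 vs session-2 scatter. Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    colors = {"control": "tab:green", "relative": "tab:blue", "pwpp": "tab:red"}

    m1 = metrics[(metrics["session"] == 1) & metrics["included"]]
    groups = [g for g in GROUPS if (m1["group"] == g).any()]

    fig, ax = plt.subplots(figsize=(5, 4))
    data = [m1.loc[m1["group"] == g, "mean_switch_rate"] for g in groups]
    bp = ax.boxplot(data, tick_labels=groups, whis=1.5, sym="+")
    ax.set_ylabel("bi-stable switch rate (Hz)")
    fig.tight_layout()
    p = outdir / "switch_rates_box.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    if durations_by_group:
        fig, ax = plt.subplots(figsize=(5, 4))
        edges = np.arange(0.0, 30.5, 1.0)
        from .stats import duration_histogram as dh

        hist = dh(durations_by_group, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for g, prop in hist.proportions.items():
            ax.plot(centers, prop, label=g, color=colors.get(g))
        ax.set_xlabel("percept duration (s)")
        ax.set_ylabel("proportion of responses")
        ax.legend()
        fig.tight_layout()
        p = outdir / "duration_histograms.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    if (metrics["session"] > 1).any():
        wide = metrics[metrics["included"]].pivot_table(
            index=["subject_id", "group"], columns="session", values="mean_switch_rate"
        ).dropna()
        if wide.shape[1] >= 2:
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            for g in groups:
                sel = wide.index.get_level_values("group") == g
                ax.scatter(wide.iloc[:, 0][sel], wide.iloc[:, 1][sel], s=12, color=colors.get(g), label=g)
            lim = max(wide.to_numpy().max() * 1.1, 0.1)
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
            ax.set_xlabel("session 1 switch rate (Hz)")
            ax.set_ylabel("session 2 switch rate (Hz)")
            ax.legend()
            fig.tight_layout()
            p = outdir / "retest_scatter.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
    return paths


def write_markdown_report(report: StatsReport, outpath: Path, figures: list[Path]) -> None:
    lines = ["# Rotating-cylinder bi-stable perception: statistical report", ""]
    lines += ["| test | statistic | df | p | p (Bonferroni) | effect size |", "|---|---|---|---|---|---|"]
    for name, r in report.entries.items():
        fmt = lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.4g}"
        lines.append(
            f"| {name} | {fmt(r.statistic)} | {fmt(r.df)} | {fmt(r.p)} | "
            f"{fmt(r.p_bonferroni)} | {fmt(r.effect_size)} |"
        )
    if figures:
        lines += ["", "## Figures", ""]
        lines += [f"![{p.stem}]({p.name})" for p in figures]
    outpath.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> StatsReport:
    """Simulate a cohort, score it, run the battery, and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cyl = config.cylinder_params()
    spec = config.cohort_spec()
    schedule = make_real_switch_schedule(cyl, "paper")

    logger.info("simulating cohort (seed=%d)", spec.seed)
    cohort = generate_cohort(spec, cyl, schedule)
    cio.write_cohort(cohort, outdir)

    logger.info("scoring %d sessions", len(cohort))
    metrics = cohort_metrics(cohort, config.window, config.min_correct)
    if not config.apply_exclusion:
        metrics["included"] = True
        logger.info("exclusion bypassed: all subjects pass inclusion")
    metrics.to_csv(outdir / "metrics.csv", index=False)

    durations = pooled_durations_by_group(cohort, metrics)
    durations_long_frame(cohort, metrics).to_csv(outdir / "durations.csv", index=False)

    report = run_battery(
        metrics,
        durations_by_group=durations,
        sessions_meta=cohort.sessions_frame(),
        apply_exclusion=config.apply_exclusion,
    )
    report.to_json(outdir / "stats_report.json")

    figures = []
    if config.make_figures:
        figures = make_figures(metrics, durations, outdir)
    write_markdown_report(report, outdir / "report.md", figures)

    m1 = metrics[metrics["session"] == 1]
    manifest = {
        "seed": spec.seed,
        "n_sessions_total": len(cohort),
        "groups": {
            g: {
                "generated": int((m1["group"] == g).sum()),
                "included": int(m1.loc[m1["group"] == g, "included"].sum()),
                "excluded": int((~m1.loc[m1["group"] == g, "included"]).sum()),
            }
            for g in GROUPS
        },
        "window_s": config.window,
        "min_correct": config.min_correct,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
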