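"""End-to-end analysis pipeline: tabulate -> indices -> GLM -> regressions
-> stability -> mediation -> power, with a structured report bundle.

Optional stages degrade gracefully: stability needs second-task indices,
mediation needs stress scores, and the power stage needs a successful
mediation-side summary; when inputs are absent the section is marked
skipped with the reason rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    DEFAULT_TERMS,
    CorrelationResult,
    GroupComparison,
    compare_groups,
    regress_index,
    stability_correlation,
)
from .datamodel import Gender, StudyDataset, read_study, tabulate_decisions
from .glm import GlmSdtResult, GlmSdtSpec, RandomEffects, fit_probit_sdt
from .mediation import MediationResult, fit_mediation
from .power import PowerResult, PowerSpec, derive_correlations_from_summaries, mc_power_indirect
from .sdt import compute_indices, pooled_rates, summarize_indices

log = logging.getLogger("sdtrefer")


@dataclass
class AnalysisOptions:
    glm_random_effects: RandomEffects = RandomEffects.INTERCEPT_AND_SIGNAL_SLOPE
    glm_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_TERMS))
    run_glm: bool = True
    run_mediation: bool = True
    run_power: bool = True
    n_boot: int = 5000
    power_reps: int = 5000
    power_draws: int = 20000
    seed: int = 1234


@dataclass
class AnalysisReport:
    decision_table: object = None
    pooled_rates: tuple | None = None
    index_summaries: dict | None = None
    indices: pd.DataFrame | None = None
    glm_sdt: GlmSdtResult | None = None
    regressions: dict[str, object] = field(default_factory=dict)
    stability: dict[str, CorrelationResult] = field(default_factory=dict)
    group_comparison: GroupComparison | None = None
    mediation: MediationResult | None = None
    power: PowerResult | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _config_hash(options: AnalysisOptions) -> str:
    payload = json.dumps(
        {k: (v.value if isinstance(v, RandomEffects) else v)
         for k, v in vars(options).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_analysis(
    study: StudyDataset | tuple[str, str, str],
    options: AnalysisOptions | None = None,
    second_task_indices: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run every analysis stage on a study and optionally write the
    results bundle (CSV tables plus report.md) to ``out_dir``."""
    opts = options or AnalysisOptions()
    if not isinstance(study, StudyDataset):
        study = read_study(*study)
    report = AnalysisReport()
    report.provenance = {
        "seed": opts.seed,
        "config_hash": _config_hash(opts),
        "version": __version__,
        "n_responders": study.n_responders,
        "n_responses": study.n_responses,
    }

    log.info("tabulating %d decisions", study.n_responses)
    report.decision_table = tabulate_decisions(study)
    report.pooled_rates = pooled_rates(study)

    log.info("computing per-responder indices")
    report.indices = compute_indices(study)
    d_sum, c_sum = summarize_indices(report.indices)
    report.index_summaries = {"d_prime": d_sum, "criterion": c_sum}

    if opts.run_glm:
        log.info("fitting probit GLM-SDT (%s)", opts.glm_random_effects.value)
        try:
            report.glm_sdt = fit_probit_sdt(
                study,
                GlmSdtSpec(covariates=list(opts.glm_covariates),
                           random_effects=opts.glm_random_effects),
            )
        except Exception as exc:  # stage failure aborts with the stage name
            raise RuntimeError(f"stage glm_sdt failed: {exc}") from exc
    else:
        report.skipped["glm_sdt"] = "disabled by options"

    log.info("regressing indices on covariates")
    profiles = study.responders
    for outcome in ("d_prime", "criterion"):
        report.regressions[outcome] = regress_index(report.indices, profiles, outcome)

    if second_task_indices is not None:
        log.info("cross-task stability on %d shared responders",
                 len(second_task_indices))
        for col in ("d_prime", "criterion"):
            report.stability[col] = stability_correlation(
                report.indices, second_task_indices, col
            )
    else:
        report.skipped["stability"] = "no second-task indices supplied"

    has_stress = profiles["stress_score"].notna().any()
    if has_stress and profiles["stress_score"].dropna().nunique() > 1:
        report.group_comparison = compare_groups(
            profiles["stress_score"], profiles["gender"]
        )
    if opts.run_mediation and has_stress:
        log.info("fitting gender -> stress -> criterion mediation")
        med_data = profiles.merge(
            report.indices[["responder_id", "criterion"]], on="responder_id"
        )
        try:
            report.mediation = fit_mediation(
                med_data, n_boot=opts.n_boot, seed=opts.seed
            )
        except ValueError as exc:
            report.skipped["mediation"] = str(exc)
    elif not has_stress:
        report.skipped["mediation"] = "no stress scores in the responder table"
    else:
        report.skipped["mediation"] = "disabled by options"

    if opts.run_power and report.mediation is not None:
        log.info("Monte Carlo power analysis for the indirect effect")
        report.power = _power_from_data(profiles, report.indices, opts)
    elif "mediation" in report.skipped:
        report.skipped["power"] = "mediation unavailable: " + report.skipped["mediation"]
    else:
        report.skipped["power"] = "disabled by options"

    if out_dir is not None:
        _write_bundle(report, Path(out_dir))
    return report


def _power_from_data(profiles: pd.DataFrame, indices: pd.DataFrame,
                     opts: AnalysisOptions) -> PowerResult:
    """Build the trivariate power spec from the study's own summaries."""
    df = profiles.merge(indices[["responder_id", "criterion"]], on="responder_id")
    df = df.dropna(subset=["stress_score"])
    female = (df["gender"] == Gender.FEMALE.name).to_numpy(float)
    stress = df["stress_score"].to_numpy(float)
    crit = df["criterion"].to_numpy(float)
    gc = compare_groups(stress, np.where(female == 1, "F", "M"))
    slope_my = np.polyfit(stress, crit, 1)[0]
    slope_xy = np.polyfit(female, crit, 1)[0]
    n_f = int(female.sum())
    R, sds = derive_correlations_from_summaries(
        t_stat=abs(gc.t), df=gc.df, group_ns=(n_f, len(df) - n_f),
        slope_mediator_outcome=slope_my, slope_predictor_outcome=slope_xy,
        sds=(float(stress.std(ddof=1)), float(crit.std(ddof=1))),
    )
    spec = PowerSpec(correlations=R, sds=sds, n=len(df),
                     n_reps=opts.power_reps, n_draws=opts.power_draws,
                     seed=opts.seed)
    return mc_power_indirect(spec)


def _write_bundle(report: AnalysisReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.decision_table.to_frame().to_csv(out / "decision_table.csv")
    report.indices.to_csv(out / "indices.csv", index=False)

    rows = []
    for name, s in report.index_summaries.items():
        rows.append({"index": name, **vars(s)})
    pd.DataFrame(rows).to_csv(out / "summaries.csv", index=False)

    if report.glm_sdt is not None:
        report.glm_sdt.to_csv(out / "glm_sdt.csv")
    reg = []
    for outcome, res in report.regressions.items():
        t = res.terms.copy()
        t.insert(0, "outcome", outcome)
        reg.append(t)
    pd.concat(reg).to_csv(out / "regressions.csv", index=False)
    if report.stability:
        pd.DataFrame(
            [{"index": k, **vars(v)} for k, v in report.stability.items()]
        ).to_csv(out / "stability.csv", index=False)
    if report.mediation is not None:
        report.mediation.to_frame().to_csv(out / "mediation.csv", index=False)
    if report.power is not None:
        pd.DataFrame(
            [{"n": report.power.spec.n, "power": report.power.power,
              "mc_se": report.power.mc_se}]
        ).to_csv(out / "power.csv", index=False)
    (out / "report.md").write_text(render_report(report))


def render_report(report: AnalysisReport) -> str:
    """Human-readable summary of every section (or why it was skipped)."""
    lines = ["# Referral signal-detection analysis", ""]
    prov = report.provenance
    lines += [
        f"version {prov.get('version')} | seed {prov.get('seed')} | "
        f"config {prov.get('config_hash')} | {prov.get('n_responders')} responders, "
        f"{prov.get('n_responses')} decisions",
        "",
        "## Decision tabulation",
        report.decision_table.to_frame().to_string(),
        "",
        "percent of all decisions: "
        + ", ".join(f"{k} {v:.2f}%" for k, v in
                    report.decision_table.decision_percent.items()),
        f"pooled hit rate {report.pooled_rates[0]:.4f}, "
        f"pooled false-alarm rate {report.pooled_rates[1]:.4f}",
        "",
        "## Index distributions",
    ]
    for name, s in report.index_summaries.items():
        lines.append(
            f"{name}: mean {s.mean:.2f} (SD {s.sd:.2f}), median {s.median:.2f}, "
            f"range {s.min:.2f} to {s.max:.2f}, n={s.n}"
        )
    if report.glm_sdt is not None:
        lines += ["", "## Probit GLM-SDT", report.glm_sdt.coefficients.to_string()]
        if report.glm_sdt.re_sd:
            lines.append(f"random-effect SDs: {report.glm_sdt.re_sd}")
    for outcome, res in report.regressions.items():
        lines += ["", f"## Regression of {outcome} (n={res.n}, R2={res.r_squared:.3f})",
                  res.terms.to_string()]
    if report.stability:
        lines += ["", "## Cross-task stability"]
        for k, v in report.stability.items():
            lines.append(f"{k}: r={v.r:.3f}, p={v.p:.3g}, n={v.n}")
    if report.group_comparison is not None:
        g = report.group_comparison
        lines += ["", "## Stress by gender",
                  f"means {g.mean_a:.2f} vs {g.mean_b:.2f}, t({g.df})={g.t:.2f}, "
                  f"p={g.p:.3g}"]
    if report.mediation is not None:
        lines += ["", "## Mediation (gender -> stress -> criterion)",
                  report.mediation.to_frame().to_string(),
                  f"n={report.mediation.n}, bootstrap n={report.mediation.n_boot}, "
                  f"seed {report.mediation.seed}"]
    if report.power is not None:
        lines += ["", "## Monte Carlo power (indirect effect)",
                  f"power {report.power.power:.3f} (MC SE {report.power.mc_se:.4f}) "
                  f"at n={report.power.spec.n}"]
    if report.skipped:
        lines += ["", "## Skipped stages"]
        for k, v in report.skipped.items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
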