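"""Pipeline orchestration: config, file formats, stage running, reporting.

Stages run in the order simulate -> fit -> equivnoise -> stats -> predict ->
report, with every intermediate written to the output directory as plain
text (CSV/TSV for tables, JSON for nested results).  One global seed
deterministically derives a child seed per stage (via numpy SeedSequence),
so re-running an identical config reproduces identical artifacts, and
changing, say, only the predict stage's behaviour leaves the simulated data
untouched.  A run manifest records the config hash and a SHA-256 digest per
artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import equivnoise, predict, psychometric, stats
from .cohort import CohortSpec, generate_study_dataset
from .observer import TRIAL_COLUMNS

__all__ = [
    "PipelineConfig",
    "read_trials",
    "write_trials",
    "run_pipeline",
    "render_report",
    "STAGES",
]

log = logging.getLogger("oridisc")

STAGES = ["simulate", "fit", "equivnoise", "stats", "predict", "report"]

_STAGE_OUTPUTS = {
    "simulate": ["trials.csv", "truth.csv"],
    "fit": ["thresholds.csv", "fits.jsonl"],
    "equivnoise": ["efficiency.csv"],
    "stats": ["stats.json"],
    "predict": ["cv.json", "importance.tsv"],
    "report": ["report.txt"],
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "oridisc_out"
    cohort: dict = dataclasses.field(default_factory=dict)
    design: dict = dataclasses.field(default_factory=dict)
    fit: dict = dataclasses.field(default_factory=dict)
    stats: dict = dataclasses.field(default_factory=dict)
    predict: dict = dataclasses.field(default_factory=dict)

    _ALLOWED = {
        "cohort": set(f.name for f in dataclasses.fields(CohortSpec)),
        "design": {
            "noise_levels", "eccentricities", "offsets_deg", "reps_per_cell",
            "catch_fraction", "practice_fraction", "catch_offset_deg",
        },
        "fit": {"lapse_rate", "free_lapse"},
        "stats": {"n_boot", "alpha", "with_cis"},
        "predict": {"k", "model", "ridge_alpha", "n_shuffles"},
    }

    def __post_init__(self) -> None:
        for section, allowed in self._ALLOWED.items():
            given = set(getattr(self, section))
            unknown = given - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys in config section '{section}': {sorted(unknown)}"
                )
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Derive the stage's generator from the global seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed)
        return np.random.default_rng(ss.spawn(len(STAGES))[idx])


# ---------------------------------------------------------------------------
# trial-table CSV interchange
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trial table with the fixed documented column order."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (lossless round-trip).

    Malformed rows — zero offsets, responses outside {CW, CCW} — are
    reported with 1-based data line numbers.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schema mismatch in {path}: missing {sorted(missing)}")
    bad_offset = df.index[df.offset_deg == 0].tolist()
    bad_resp = df.index[~df.response.isin(["CW", "CCW"])].tolist()
    problems = []
    if bad_offset:
        problems.append(f"zero offsets at data line(s) {[i + 1 for i in bad_offset]}")
    if bad_resp:
        problems.append(f"invalid responses at data line(s) {[i + 1 for i in bad_resp]}")
    if problems:
        raise ValueError(f"malformed trial rows in {path}: " + "; ".join(problems))
    df["is_catch"] = df.is_catch.astype(bool)
    df["is_practice"] = df.is_practice.astype(bool)
    return df[TRIAL_COLUMNS]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    rng = cfg.stage_rng("simulate")
    spec = CohortSpec(**cfg.cohort)
    trials, truth = generate_study_dataset(spec, rng, design_kwargs=cfg.design)
    write_trials(trials, outdir / "trials.csv")
    truth.to_csv(outdir / "truth.csv", index=False, float_format="%.10g")
    log.info("simulate: %d trials, %d subjects", len(trials),
             trials.subject_id.nunique())


def _stage_fit(cfg: PipelineConfig, outdir: Path) -> None:
    trials = read_trials(outdir / "trials.csv")
    tbl = psychometric.fit_threshold_table(trials, **cfg.fit)
    tbl.to_csv(outdir / "thresholds.csv", index=False, float_format="%.10g")
    with open(outdir / "fits.jsonl", "w") as fh:
        for _, row in tbl.iterrows():
            fh.write(json.dumps(row.to_dict()) + "\n")
    log.info("fit: %d cells, %d converged", len(tbl), int(tbl.converged.sum()))


def _stage_equivnoise(cfg: PipelineConfig, outdir: Path) -> None:
    tbl = pd.read_csv(outdir / "thresholds.csv")
    calibration = cfg.cohort.get("calibration_deg_per_scale", 1.0)
    eff = equivnoise.efficiency_table(tbl, calibration=calibration)
    eff.to_csv(outdir / "efficiency.csv", index=False, float_format="%.10g")
    log.info("equivnoise: %d fits", len(eff))


def _stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    rng = cfg.stage_rng("stats")
    trials = read_trials(outdir / "trials.csv")
    tbl = pd.read_csv(outdir / "thresholds.csv")
    n_boot = int(cfg.stats.get("n_boot", 2000))
    with_cis = bool(cfg.stats.get("with_cis", True))
    ci_rng = rng if with_cis else None

    t_main = trials[~trials.is_practice & ~trials.is_catch]
    per_subj = t_main.groupby("subject_id")["correct"].mean().to_numpy()
    overall = {
        "accuracy": float(per_subj.mean()),
        "sd": float(per_subj.std(ddof=1)),
    }
    if ci_rng is not None:
        overall["ci"] = list(
            stats.bca_interval(per_subj, np.mean, rng=ci_rng, n_boot=n_boot)
        )

    acc_noise = psychometric.accuracy_summary(
        trials, by="noise_scale", rng=ci_rng, n_boot=n_boot
    )
    trials_abs = trials.assign(abs_offset=trials.offset_deg.abs())
    acc_offset = psychometric.accuracy_summary(
        trials_abs, by="abs_offset", rng=ci_rng, n_boot=n_boot
    )
    catch = psychometric.catch_trial_check(trials)

    anova_noise = stats.rm_anova_omega2(tbl, within="noise_scale",
                                        rng=ci_rng, n_boot=n_boot)
    anova_ecc = stats.rm_anova_omega2(tbl, within="eccentricity_deg",
                                      rng=ci_rng, n_boot=n_boot)
    posthoc_noise = stats.pairwise_contrasts(tbl, within="noise_scale",
                                             rng=ci_rng, n_boot=n_boot)
    posthoc_ecc = stats.pairwise_contrasts(tbl, within="eccentricity_deg",
                                           rng=ci_rng, n_boot=n_boot)

    mixed = stats.random_intercept_fit(tbl)
    mixed_age = stats.random_intercept_fit(tbl, age="age_years")

    subj_ecc = tbl.groupby(["subject_id", "eccentricity_deg"]).agg(
        threshold=("threshold_sigma_deg", "mean"), age=("age_years", "first")
    ).reset_index()
    correlations = {}
    for e, grp in subj_ecc.groupby("eccentricity_deg"):
        r, p = stats.pearson_r(grp.age, grp.threshold)
        correlations[str(e)] = {"r": r, "p": p, "n": len(grp)}

    def _vc(res):
        return {
            "fe_params": res.fe_params.to_dict(),
            "bse": res.bse.to_dict(),
            "zvalues": res.zvalues.to_dict(),
            "pvalues": res.pvalues.to_dict(),
            "sigma2_subject": res.sigma2_subject,
            "sigma2_residual": res.sigma2_residual,
            "method": res.method,
        }

    def _effect(rep):
        d = dataclasses.asdict(rep)
        if d["ci"] is not None:
            d["ci"] = list(d["ci"])
        return d

    payload = {
        "accuracy": {
            "overall": overall,
            "by_noise": acc_noise.to_dict(orient="records"),
            "by_abs_offset": acc_offset.to_dict(orient="records"),
            "catch": {
                "mean": float(catch.catch_accuracy.mean()),
                "min": float(catch.catch_accuracy.min()),
                "n_flagged": int(catch.flagged.sum()),
            },
        },
        "anova": {
            "noise": _effect(anova_noise),
            "eccentricity": _effect(anova_ecc),
        },
        "posthoc": {
            "noise": posthoc_noise.to_dict(orient="records"),
            "eccentricity": posthoc_ecc.to_dict(orient="records"),
        },
        "mixed_model": {
            "base": _vc(mixed),
            "with_age": _vc(mixed_age),
            "delta_sigma2_subject": mixed.sigma2_subject - mixed_age.sigma2_subject,
        },
        "age_threshold_correlations": correlations,
    }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    log.info("stats: omega2 noise=%.3f ecc=%.3f", anova_noise.omega_sq,
             anova_ecc.omega_sq)


def _stage_predict(cfg: PipelineConfig, outdir: Path) -> None:
    rng = cfg.stage_rng("predict")
    tbl = pd.read_csv(outdir / "thresholds.csv")
    eff = pd.read_csv(outdir / "efficiency.csv")
    feats = predict.build_feature_table(tbl, eff)
    cv = predict.kfold_cv_regression(
        feats, rng,
        k=int(cfg.predict.get("k", 10)),
        model=cfg.predict.get("model", "ridge"),
        ridge_alpha=float(cfg.predict.get("ridge_alpha", 1.0)),
    )
    imp = predict.permutation_importance(
        cv, feats, rng, n_shuffles=int(cfg.predict.get("n_shuffles", 50))
    )
    with open(outdir / "cv.json", "w") as fh:
        fh.write(cv.to_json())
    imp.to_csv(outdir / "importance.tsv", sep="\t", index=False,
               float_format="%.6g")
    log.info("predict: CV R2=%.3f baseline=%.3f", cv.mean_r2,
             float(np.mean(cv.baseline_r2)))


def _stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    text = render_report(outdir)
    (outdir / "report.txt").write_text(text)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "equivnoise": _stage_equivnoise,
    "stats": _stage_stats,
    "predict": _stage_predict,
    "report": _stage_report,
}


def run_pipeline(
    cfg: PipelineConfig,
    stages: list[str] | None = None,
    resume: bool = False,
) -> dict:
    """Run the pipeline stages in order, writing artifacts and a manifest.

    With ``resume``, stages whose outputs already exist are skipped; because
    stage seeds derive deterministically from the global seed, a deleted
    intermediate is re-created identically.  A stage failure persists the
    partial manifest before re-raising.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "stages": [],
    }
    manifest_path = outdir / "manifest.json"
    for stage in STAGES:
        if stage not in stages:
            continue
        outputs = [outdir / f for f in _STAGE_OUTPUTS[stage]]
        if resume and all(p.exists() for p in outputs):
            status = "skipped (resume)"
        else:
            t0 = time.time()
            try:
                _STAGE_FNS[stage](cfg, outdir)
            except Exception:
                manifest["stages"].append({"stage": stage, "status": "failed"})
                manifest_path.write_text(json.dumps(manifest, indent=2))
                raise
            status = f"ran in {time.time() - t0:.2f}s"
        manifest["stages"].append(
            {
                "stage": stage,
                "status": status,
                "outputs": {p.name: _digest(p) for p in outputs if p.exists()},
            }
        )
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def render_report(outdir: str | Path) -> str:
    """Assemble the human-readable summary from on-disk artifacts only.

    Numbers are read back from the JSON/CSV artifacts (a single source of
    truth — nothing is recomputed); missing artifacts mark their section
    absent instead of crashing.
    """
    outdir = Path(outdir)
    lines = ["oridisc pipeline report", "=" * 60]

    stats_path = outdir / "stats.json"
    if stats_path.exists():
        s = json.loads(stats_path.read_text())
        acc = s["accuracy"]
        lines += ["", "Accuracy (descriptive)", "-" * 30]
        lines.append(
            f"overall: M = {acc['overall']['accuracy']:.3f} "
            f"(SD = {acc['overall']['sd']:.3f})"
        )
        for row in acc["by_noise"]:
            lines.append(
                f"  noise {row['noise_scale']:<4}: {row['accuracy']:.3f}"
            )
        for row in acc["by_abs_offset"]:
            lines.append(
                f"  |offset| {row['abs_offset']:<4}: {row['accuracy']:.3f}"
            )
        lines.append(
            f"catch trials: M = {acc['catch']['mean']:.3f} "
            f"(min {acc['catch']['min']:.3f}, {acc['catch']['n_flagged']} flagged)"
        )
        lines += ["", "Thresholds (inferential)", "-" * 30]
        for name in ("noise", "eccentricity"):
            a = s["anova"][name]
            ci = a.get("ci")
            ci_txt = (f", 95% BCa [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else "")
            lines.append(
                f"{name}: F({a['df_effect']:.2f}, {a['df_error']:.2f}) = "
                f"{a['F']:.2f}, p = {a['p']:.4g}, omega2 = {a['omega_sq']:.3f}"
                + ci_txt
            )
            for c in s["posthoc"][name]:
                lines.append(
                    f"  {c['level_a']} vs {c['level_b']}: g = {c['hedges_g']:.2f},"
                    f" p_holm = {c['p_holm']:.4g}"
                )
        mm = s["mixed_model"]
        lines += ["", "Variance components", "-" * 30]
        for label, key in (("base model", "base"), ("with age", "with_age")):
            v = mm[key]
            lines.append(
                f"{label}: sigma2_subject = {v['sigma2_subject']:.4f}, "
                f"sigma2_residual = {v['sigma2_residual']:.4f}"
            )
            for nm, b in v["fe_params"].items():
                if nm == "const":
                    continue
                lines.append(
                    f"    {nm:<16} beta = {b:+.4f} (SE {v['bse'][nm]:.4f})"
                )
        lines.append(
            f"delta sigma2_subject (age) = {mm['delta_sigma2_subject']:.4f}"
        )
        lines += ["", "Age-threshold correlations by eccentricity", "-" * 30]
        for e, c in s["age_threshold_correlations"].items():
            lines.append(f"  {e} deg: r = {c['r']:.3f}, p = {c['p']:.4g}")
    else:
        lines += ["", "[stats section absent]"]

    cv_path = outdir / "cv.json"
    if cv_path.exists():
        m = json.loads(cv_path.read_text())
        lines += ["", "Cross-validated prediction", "-" * 30]
        lines.append(
            f"{m['k']}-fold CV R^2 = {m['r2']['mean']:.3f} "
            f"(SD {m['r2']['sd']:.3f}), RMSE = {m['rmse_deg']['mean']:.3f} deg, "
            f"MAE = {m['mae_deg']['mean']:.3f} deg"
        )
        lines.append(
            f"null baseline R^2 = {m['baseline_r2']['mean']:.3f}, "
            f"RMSE = {m['baseline_rmse_deg']['mean']:.3f} deg"
        )
    else:
        lines += ["", "[prediction section absent]"]

    imp_path = outdir / "importance.tsv"
    if imp_path.exists():
        imp = pd.read_csv(imp_path, sep="\t")
        lines += ["", "Permutation importance (normalized)", "-" * 30]
        for _, row in imp.iterrows():
            lines.append(
                f"  {row.feature:<12} {row.importance:.3f} "
                f"[{row.ci_low:.3f}, {row.ci_high:.3f}]"
            )
    else:
        lines += ["", "[importance section absent]"]
    return "\n".join(lines) + "\n"
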