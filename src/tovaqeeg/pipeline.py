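"""End-to-end orchestration: simulate/load -> preprocess -> epochs ->
band power + covariance images -> entropy scores -> statistics.

Every stage's outputs are flat files under the output directory, reusable
independently; a manifest records the configuration hash, seed and package
version so any run can be regenerated exactly.  Logging is one structured
line per stage per subject with timing and row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .apen import ApEnConfig, apen_score
from .containers import (
    NONTARGET_CORRECT,
    RESTING,
    STATE_RESTING,
    TARGET_CORRECT,
    EEGRecording,
)
from .covimg import covariance_image
from .epochs import resting_segment, score_tova, segment
from .montage import CHANNELS_19
from .preprocess import FilterConfig, preprocess
from .spectral import CONDITION_CLASSES, band_power_table
from .stats import (
    bootstrap_means,
    channelwise_ttests,
    mann_whitney,
    roc,
    spearman,
    sweep_combination_weights,
    two_way_anova_bonferroni,
)
from .synth import Cohort, CohortSpec, generate_cohort

log = logging.getLogger("tovaqeeg")

CONDITIONS = ("resting", "target", "nontarget")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    With input_dir=None a synthetic cohort is generated from `cohort`;
    otherwise recordings/sessions/clinical scores are loaded from the
    directory's manifest.json (the layout write_cohort produces).
    """

    output_dir: str = "tovaqeeg_out"
    input_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    apen: ApEnConfig = field(default_factory=ApEnConfig)
    adjacency: dict[str, tuple[str, ...]] | None = None
    do_preprocess: bool = True
    alpha: float = 0.05
    bootstrap_B: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for name, sub_cls in (("cohort", CohortSpec),
                              ("filters", FilterConfig),
                              ("apen", ApEnConfig)):
            if name in raw:
                kw[name] = sub_cls(**raw.pop(name))
        if isinstance(raw.get("adjacency"), str):
            kw["adjacency"] = tio.read_adjacency_json(raw.pop("adjacency"))
        kw.update(raw)
        return cls(**kw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(paths: dict[str, str | Path],
                    fs_expected: float = 256.0) -> dict:
    """Check recordings / event logs / clinical files; returns a
    machine-readable report with a `failures` list (never raises)."""
    failures: list[str] = []
    checked: list[str] = []
    rec = None
    if "recording" in paths:
        p = Path(paths["recording"])
        checked.append(str(p))
        if not p.exists():
            failures.append(f"recording file missing: {p}")
        else:
            try:
                rec = tio.read_recording(p)
                missing = [c for c in CHANNELS_19 if c not in rec.labels]
                for ch in missing:
                    failures.append(f"missing channel label: {ch}")
                if abs(rec.fs - fs_expected) > 1e-6:
                    failures.append(
                        f"sampling rate {rec.fs} Hz != expected "
                        f"{fs_expected} Hz")
            except Exception as exc:
                failures.append(f"recording unreadable: {exc}")
    if "session" in paths:
        p = Path(paths["session"])
        checked.append(str(p))
        if not p.exists():
            failures.append(f"session file missing: {p}")
        else:
            try:
                session = tio.read_session_csv(p)
                if rec is not None:
                    spt = session.trial_period
                    over = (session.trials["onset_s"] + spt
                            > rec.duration + 1e-9)
                    for idx in session.trials.loc[over, "trial_index"]:
                        failures.append(
                            f"trial {int(idx)} onset past recording end")
            except Exception as exc:
                failures.append(f"session unreadable: {exc}")
    if "clinical" in paths:
        p = Path(paths["clinical"])
        checked.append(str(p))
        if not p.exists():
            failures.append(f"clinical file missing: {p}")
        else:
            try:
                tio.read_clinical_csv(p)
            except Exception as exc:
                failures.append(f"clinical table invalid: {exc}")
    return {"checked": checked, "failures": failures, "ok": not failures}


def _load_cohort(input_dir: str | Path, spec: CohortSpec) -> Cohort:
    from .synth import Subject

    root = Path(input_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    clinical = tio.read_clinical_csv(root / "clinical.csv")
    bdi = dict(zip(clinical["subject_id"], clinical["bdi"]))
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        files = entry["files"]
        for key in ("resting", "tova", "session"):
            if not (root / files[key]).exists():
                raise FileNotFoundError(
                    f"subject {sid}: missing {key} file {files[key]}")
        resting = tio.read_recording(root / files["resting"],
                                     state_tag=STATE_RESTING, subject_id=sid)
        tova = tio.read_recording(root / files["tova"], state_tag="tova",
                                  subject_id=sid)
        session = tio.read_session_csv(root / files["session"],
                                       trial_period=spec.trial_period,
                                       subject_id=sid)
        subjects.append(Subject(sid, entry["group"], resting, tova, session,
                                float(bdi[sid]), entry.get("seeds", {})))
    return Cohort(spec, subjects)


def analyze_subject(subject, config: PipelineConfig) -> dict:
    """All per-subject biomarkers: TOVA scores, cordance, entropy scores."""
    t0 = time.time()
    resting: EEGRecording = subject.resting
    tova: EEGRecording = subject.tova
    if config.do_preprocess:
        resting = preprocess(resting, config.filters)
        tova = preprocess(tova, config.filters)
    rest_set = resting_segment(resting, config.cohort.trial_period)
    task_set = segment(tova, subject.session)
    scores = score_tova(subject.session)
    trialsets = {"resting": rest_set, "target": task_set,
                 "nontarget": task_set}
    cordance_rows = []
    apen_rows = []
    for cond in CONDITIONS:
        ts = trialsets[cond]
        bpt = band_power_table(ts, cond, adjacency=config.adjacency)
        tidy = bpt.to_tidy()
        tidy["group"] = subject.group
        cordance_rows.append(tidy)
        img = covariance_image(ts, CONDITION_CLASSES[cond], condition=cond)
        sc = apen_score(img, config.apen)
        apen_rows.append({"subject_id": subject.subject_id,
                          "group": subject.group, "condition": cond,
                          "apen": sc.value,
                          "component_m1": sc.component_m1,
                          "component_m2": sc.component_m2,
                          "r": sc.r_used, "m1": config.apen.m1,
                          "m2": config.apen.m2, "norm": config.apen.norm,
                          "source": config.apen.source,
                          "n_trials_used": img.n_trials_used})
    log.info("subject=%s stage=biomarkers conditions=%d elapsed=%.2fs",
             subject.subject_id, len(CONDITIONS), time.time() - t0)
    return {"tova": {"subject_id": subject.subject_id,
                     "group": subject.group,
                     "bdi": subject.bdi,
                     "omission_rate": scores.omission_rate,
                     "commission_rate": scores.commission_rate,
                     "mean_rt": scores.mean_rt,
                     "rt_variability": scores.rt_variability,
                     "d_prime": scores.d_prime},
            "cordance": pd.concat(cordance_rows, ignore_index=True),
            "apen": apen_rows}


def group_statistics(tova_df: pd.DataFrame, cordance_df: pd.DataFrame,
                     apen_df: pd.DataFrame, config: PipelineConfig) -> dict:
    """The cross-subject statistical layer; returns a JSON-able dict."""
    out: dict = {}
    groups = sorted(tova_df["group"].unique())
    if len(groups) == 2:
        g0, g1 = groups
        for metric in ("omission_rate", "commission_rate", "mean_rt",
                       "rt_variability", "d_prime", "bdi"):
            a = tova_df.loc[tova_df["group"] == g0, metric].dropna()
            b = tova_df.loc[tova_df["group"] == g1, metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = mann_whitney(a, b, alpha=config.alpha)
                out[f"mann_whitney_{metric}"] = {
                    "U": res.statistic, "p": res.pvalue,
                    "median_" + g0: res.estimates["median_a"],
                    "median_" + g1: res.estimates["median_b"]}

    # F7 theta cordance: two-way ANOVA + per-condition contrasts
    f7 = cordance_df[(cordance_df["channel"] == "F7")
                     & (cordance_df["band"] == "theta")
                     & (cordance_df["metric"] == "cordance")]
    if len(groups) == 2 and len(f7):
        res = two_way_anova_bonferroni(f7["value"], f7["group"],
                                       f7["condition"], alpha=config.alpha)
        out["anova_f7_theta_cordance"] = {
            "effects": res.estimates,
            "posthoc": res.posthoc.to_dict("records")}

    # ApEn: two-way ANOVA + per-condition contrasts + ROC per condition
    if len(groups) == 2 and len(apen_df):
        res = two_way_anova_bonferroni(apen_df["apen"], apen_df["group"],
                                       apen_df["condition"],
                                       alpha=config.alpha)
        out["anova_apen"] = {"effects": res.estimates,
                             "posthoc": res.posthoc.to_dict("records")}
        rocs = {}
        for cond in CONDITIONS:
            sub = apen_df[apen_df["condition"] == cond]
            labels = (sub["group"] == groups[1]).astype(int)
            if labels.nunique() == 2:
                r = roc(sub["apen"], labels, score_def=f"apen ({cond})")
                rocs[cond] = {"auc": r.auc, "se": r.auc_se,
                              "ci95": list(r.auc_ci95), "cutoff": r.cutoff,
                              "sensitivity": r.cutoff_sensitivity,
                              "specificity": r.cutoff_specificity}
        out["roc_apen"] = rocs
        # omission-rate ROC and the combination sweep on the target condition
        tgt = apen_df[apen_df["condition"] == "target"].merge(
            tova_df[["subject_id", "omission_rate"]], on="subject_id")
        labels = (tgt["group"] == groups[1]).astype(int)
        if labels.nunique() == 2:
            r_om = roc(tgt["omission_rate"], labels, score_def="omission %")
            out["roc_omission"] = {"auc": r_om.auc, "se": r_om.auc_se,
                                   "ci95": list(r_om.auc_ci95)}
            sweep = sweep_combination_weights(tgt["apen"],
                                              tgt["omission_rate"], labels)
            out["combination_sweep"] = sweep.to_dict("records")

        # Spearman: BDI vs mean ApEn across conditions, per group
        mean_apen = apen_df.groupby("subject_id")["apen"].mean()
        merged = tova_df.set_index("subject_id").join(
            mean_apen.rename("mean_apen"))
        out["spearman_bdi_apen"] = {}
        for g in groups:
            sub = merged[merged["group"] == g]
            if len(sub) >= 3:
                res = spearman(sub["bdi"], sub["mean_apen"])
                out["spearman_bdi_apen"][g] = {"r": res.statistic,
                                               "p": res.pvalue}

        # bootstrap of means over the six group x condition cells
        cells = {(g, c): apen_df[(apen_df["group"] == g)
                                 & (apen_df["condition"] == c)]
                 ["apen"].to_numpy()
                 for g in groups for c in CONDITIONS}
        if all(v.size >= 2 for v in cells.values()):
            boot = bootstrap_means(cells, B=config.bootstrap_B,
                                   seed=config.seed, alpha=config.alpha)
            out["bootstrap"] = {
                "anova_F": boot.anova.statistic,
                "anova_p": boot.anova.pvalue,
                "pairwise": boot.pairwise.to_dict("records"),
                "roc": {c: {"auc": r.auc, "se": r.auc_se,
                            "ci95": list(r.auc_ci95)}
                        for c, r in boot.roc.items()}}

    # channelwise theta-cordance t-tests
    cord = cordance_df[cordance_df["metric"] == "cordance"]
    if len(groups) == 2 and len(cord):
        tt = channelwise_ttests(cord, band="theta", alpha=config.alpha)
        out["ttests_theta_cordance"] = tt.to_dict("records")
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns {"manifest": ..., "stats": ...}."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.input_dir is None:
        log.info("stage=simulate subjects=%d+%d seed=%d",
                 config.cohort.n_control, config.cohort.n_patient,
                 config.cohort.seed)
        cohort = generate_cohort(config.cohort)
    else:
        cohort = _load_cohort(config.input_dir, config.cohort)

    tova_rows, cordance_frames, apen_rows = [], [], []
    for subject in cohort.subjects:
        try:
            result = analyze_subject(subject, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at subject {subject.subject_id}: {exc}"
            ) from exc
        tova_rows.append(result["tova"])
        cordance_frames.append(result["cordance"])
        apen_rows.extend(result["apen"])

    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    tova_df = pd.DataFrame(tova_rows)
    cordance_df = pd.concat(cordance_frames, ignore_index=True)
    apen_df = pd.DataFrame(apen_rows)
    for name, df in (("tova_scores", tova_df), ("cordance", cordance_df),
                     ("apen_scores", apen_df)):
        df = df.copy()
        for k, v in meta.items():
            df[k] = v
        df.to_csv(out_dir / f"{name}.csv", index=False)

    stats = group_statistics(tova_df, cordance_df, apen_df, config)
    stats["_meta"] = meta
    (out_dir / "stats.json").write_text(json.dumps(stats, indent=2,
                                                   default=float))
    from . import __version__
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": len(cohort.subjects),
        "subjects": [s.subject_id for s in cohort.subjects],
        "outputs": ["tova_scores.csv", "cordance.csv", "apen_scores.csv",
                    "stats.json"],
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    log.info("stage=done subjects=%d elapsed=%.1fs", len(cohort.subjects),
             time.time() - t0)
    return {"manifest": manifest, "stats": stats, "tova": tova_df,
            "cordance": cordance_df, "apen": apen_df}
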