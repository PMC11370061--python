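"""End-to-end orchestration of the synthetic motor-stratification study.

Stages (each readable/writable on its own, chained by ``run_full_pipeline``):

1. ``simulate``   — profile, phenotype and trajectory files from the
                    synthetic generator;
2. ``preprocess`` — merge/filter and batch-correct the profile table;
3. ``subtype``    — stability-validated clustering of the autism rows plus
                    the single-Gaussian significance test;
4. ``noise``      — per-subject motor-noise scores on every segment;
5. ``stats``      — subtype phenotype contrasts, ANOVA + post hoc tests on
                    motor noise, AIC model comparison, and the group x phase
                    mixed model.

All stage randomness derives from one global seed through named
substreams, so reruns with the same config are bit-reproducible and
changing the repetitions of one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeding import substream_seed
from .inference import aic_compare, anova_posthoc, compare_groups, fit_group_phase_lmm
from .io import read_trajectories, write_trajectories
from .kinematics import SEGMENTS, pairwise_dtw_matrix, score_subject
from .preprocess import batch_correct, merge_and_filter
from .subtyping import FEATURES, RevalConfig, run_subtype_discovery, sigclust
from .synthetic import (
    KinematicSimConfig,
    ProfileSimConfig,
    simulate_kinematic_cohort,
    simulate_phenotypes,
    simulate_profiles,
)

logger = logging.getLogger(__name__)


class StageError(Exception):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    seed: int = 0
    profile: ProfileSimConfig = field(default_factory=ProfileSimConfig)
    kinematic: KinematicSimConfig = field(default_factory=KinematicSimConfig)
    reval: RevalConfig = field(default_factory=RevalConfig)
    iq_gap_d: float = 0.7
    walk_delay_d: float = 0.67
    age_range: tuple = (3.0, 16.0)
    sigclust_n_sim: int = 10000

    def __post_init__(self) -> None:
        # fan the global seed out to every stage by named substream
        self.profile.seed = substream_seed(self.seed, "stage:profiles")
        self.kinematic.seed = substream_seed(self.seed, "stage:kinematics")
        self.reval.seed = substream_seed(self.seed, "stage:reval")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(dataclasses.asdict(self))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data):
            names = {f.name for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in (data or {}).items():
                if k not in names:
                    raise ValueError(f"unknown {klass.__name__} field: {k}")
                kwargs[k] = v
            obj = klass(**kwargs)
            return obj

        cfg = cls(
            seed=raw.get("seed", 0),
            profile=build(ProfileSimConfig, raw.get("profile")),
            kinematic=build(KinematicSimConfig, raw.get("kinematic")),
            reval=_coerce_reval(build(RevalConfig, _coerce_reval_raw(raw.get("reval")))),
            iq_gap_d=raw.get("iq_gap_d", 0.7),
            walk_delay_d=raw.get("walk_delay_d", 0.67),
            age_range=tuple(raw.get("age_range", (3.0, 16.0))),
            sigclust_n_sim=raw.get("sigclust_n_sim", 10000),
        )
        return cfg


def _coerce_reval_raw(data):
    data = dict(data or {})
    if "k_range" in data:
        data["k_range"] = tuple(data["k_range"])
    if "stratify_on" in data:
        data["stratify_on"] = tuple(data["stratify_on"])
    return data


def _coerce_reval(cfg: RevalConfig) -> RevalConfig:
    return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, (str, int, float, bool)) else str(k)): _plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    profiles = simulate_profiles(cfg.profile)
    profiles.to_csv(outdir / "profiles.csv", index=False)
    phenos = simulate_phenotypes(
        profiles, cfg.iq_gap_d, cfg.walk_delay_d, seed=substream_seed(cfg.seed, "stage:phenotypes")
    )
    phenos.to_csv(outdir / "phenotypes.csv", index=False)

    # kinematic sub-cohort: ids drawn from the profile table's ground truth
    aut = profiles[profiles["diagnosis"] == "autism"]
    td = profiles[profiles["diagnosis"] == "td"]
    want = cfg.kinematic.n_subjects_per_group
    ids = {
        "autism_high": aut.loc[aut["true_subtype"] == "High", "subject_id"].tolist()[: want.get("autism_high", 0)],
        "autism_low": aut.loc[aut["true_subtype"] == "Low", "subject_id"].tolist()[: want.get("autism_low", 0)],
        "td": td["subject_id"].tolist()[: want.get("td", 0)],
    }
    kin_table, trials = simulate_kinematic_cohort(cfg.kinematic, subject_ids=ids)
    kin_table.to_csv(outdir / "kinematic_subjects.csv", index=False)
    write_trajectories(trials, outdir / "trajectories.csv", sidecar={"config": cfg.kinematic})
    return {"n_profiles": len(profiles), "n_kinematic_subjects": len(kin_table)}


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> dict:
    profiles = pd.read_csv(outdir / "profiles.csv")
    merged = merge_and_filter([profiles], age_range=cfg.age_range)
    merged.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    corrected = batch_correct(merged.table)
    corrected.table.to_csv(outdir / "corrected_profiles.csv", index=False)
    (outdir / "correction_betas.json").write_text(json.dumps(corrected.correction_betas, indent=2))
    return {"n_after_filter": len(merged.table), "n_excluded": len(merged.exclusions)}


def stage_subtype(cfg: PipelineConfig, outdir: Path) -> dict:
    corrected = pd.read_csv(outdir / "corrected_profiles.csv")
    autism = corrected[corrected["diagnosis"] == "autism"]
    model, labels = run_subtype_discovery(autism, cfg.reval)
    labels.to_csv(outdir / "subtype_labels.csv", index=False)
    model.stability_curve.to_csv(outdir / "stability_curve.csv", index=False)

    complete = autism.dropna(subset=list(FEATURES))
    X = complete[list(FEATURES)].to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    sig = sigclust(Xs, n_sim=cfg.sigclust_n_sim, seed=substream_seed(cfg.seed, "stage:sigclust"))
    card = {
        "best_k": model.best_k,
        "generalization_accuracy": model.generalization_accuracy,
        "n_train": int(len(model.train_labels)),
        "n_validation": int(len(model.validation_labels)),
        "label_semantics": {str(k): v for k, v in model.label_semantics.items()},
        "sigclust": {
            "cluster_index": sig.cluster_index,
            "p_value": sig.p_value,
            "null_samples": sig.null_samples,
        },
        "config": _plain(dataclasses.asdict(cfg.reval)),
    }
    (outdir / "subtype_model.json").write_text(json.dumps(card, indent=2))
    return card


def stage_noise(cfg: PipelineConfig, outdir: Path, write_matrices: bool = True) -> dict:
    trials_by_subject = read_trajectories(outdir / "trajectories.csv")
    rows, pair_rows = [], []
    for sid, trials in sorted(trials_by_subject.items()):
        res = score_subject(trials, segments=SEGMENTS, n_required=cfg.kinematic.n_trials)
        row = {"subject_id": sid, **{s: res.scores.get(s, np.nan) for s in SEGMENTS}}
        row["excluded_segments"] = ";".join(
            f"{k}:{v}" for k, v in res.excluded_segments.items()
        )
        rows.append(row)
        if write_matrices and "whole" in res.scores:
            from .kinematics import lowpass_filter

            filtered = [lowpass_filter(t) for t in trials]
            mat = pairwise_dtw_matrix([t.data for t in filtered])
            iu = np.triu_indices(len(filtered), k=1)
            for i, j in zip(*iu):
                pair_rows.append(
                    {"subject_id": sid, "segment": "whole", "trial_i": i + 1, "trial_j": j + 1, "distance": mat[i, j]}
                )
    noise = pd.DataFrame(rows)
    noise.to_csv(outdir / "motor_noise.csv", index=False)
    if pair_rows:
        pd.DataFrame(pair_rows).to_csv(outdir / "dtw_pairs.csv", index=False)
    return {"n_scored": int(noise["whole"].notna().sum()), "n_subjects": len(noise)}


def stage_stats(cfg: PipelineConfig, outdir: Path) -> dict:
    labels = pd.read_csv(outdir / "subtype_labels.csv")
    corrected = pd.read_csv(outdir / "corrected_profiles.csv")
    phenos = pd.read_csv(outdir / "phenotypes.csv")
    noise = pd.read_csv(outdir / "motor_noise.csv")
    results: list[dict] = []

    # analysis groups: discovered subtype for autism, TD otherwise
    subtype_of = labels.set_index("subject_id")["subtype"]
    merged = corrected.merge(noise, on="subject_id", how="inner")
    merged["group"] = np.where(
        merged["diagnosis"] == "td", "TD", merged["subject_id"].map(subtype_of)
    )
    merged = merged.dropna(subset=["group"])

    # whole-movement ANOVA + post hoc
    whole = merged.dropna(subset=["whole"])
    anova = anova_posthoc(whole["whole"].to_numpy(), whole["group"].to_numpy())
    results.append({"analysis": "anova_whole", "statistic": anova.f_statistic, "p_value": anova.p_value})
    for c in anova.pairwise:
        results.append(
            {
                "analysis": f"whole:{c.groups[0]}_vs_{c.groups[1]}",
                "statistic": c.statistic,
                "p_value": c.p_value,
                "cohens_d": c.cohens_d,
            }
        )

    # phase-resolved mixed model
    phased = merged.dropna(subset=["reach_feedforward", "reach_feedback"])
    long = pd.concat(
        [
            phased[["subject_id", "group"]].assign(phase="feedforward", value=phased["reach_feedforward"]),
            phased[["subject_id", "group"]].assign(phase="feedback", value=phased["reach_feedback"]),
        ]
    ).rename(columns={"subject_id": "subject"})
    lmm = fit_group_phase_lmm(long)
    results.append(
        {"analysis": "lmm_group_phase_interaction", "statistic": lmm.interaction_f, "p_value": lmm.interaction_p}
    )
    for c in lmm.per_phase_contrasts:
        results.append(
            {
                "analysis": f"{c.variable}:{c.groups[0]}_vs_{c.groups[1]}",
                "statistic": c.statistic,
                "p_value": c.p_value,
                "cohens_d": c.cohens_d,
            }
        )

    # AIC: diagnosis grouping vs subtype-resolved grouping of corrected Total
    ct = corrected.copy()
    ct["subtype_group"] = np.where(
        ct["diagnosis"] == "autism", ct["subject_id"].map(subtype_of), ct["diagnosis"]
    )
    ct = ct.dropna(subset=["total", "subtype_group"])
    delta_aic = aic_compare(ct["total"].to_numpy(), ct["diagnosis"].to_numpy(), ct["subtype_group"].to_numpy())
    results.append({"analysis": "delta_aic_diagnosis_minus_subtype", "statistic": delta_aic})

    # phenotype contrasts between discovered subtypes
    ph = phenos.merge(labels[["subject_id", "subtype"]], on="subject_id")
    for var in ("iq", "age_walk_months", "age_words_months", "ados_css_total", "ados_css_sa", "ados_css_rrb", "srs"):
        c = compare_groups(ph[var].to_numpy(), ph["subtype"].to_numpy(), variable=var)
        results.append(
            {
                "analysis": f"phenotype:{var}:{c.groups[0]}_vs_{c.groups[1]}",
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "cohens_d": c.cohens_d,
            }
        )

    out = pd.DataFrame(results)
    out.to_csv(outdir / "stats_results.csv", index=False)
    _write_report(outdir, out)
    return {"n_results": len(out), "delta_aic": delta_aic, "anova_f": anova.f_statistic, "lmm_p": lmm.interaction_p}


def _write_report(outdir: Path, results: pd.DataFrame) -> None:
    lines = ["# Synthetic study report", ""]
    for section, prefixes in [
        ("Motor noise (whole movement)", ("whole", "anova_whole")),
        ("Mixed model (group x phase)", ("lmm",)),
        ("Phase contrasts", ("noise[",)),
        ("Model comparison", ("delta_aic",)),
        ("Phenotype contrasts", ("phenotype",)),
    ]:
        sub = results[results["analysis"].str.startswith(prefixes)]
        if sub.empty:
            continue
        lines.append(f"## {section}\n")
        lines.append(sub.to_markdown(index=False))
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))


STAGES = ("simulate", "preprocess", "subtype", "noise", "stats")


def run_full_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; returns the merged stage summaries.

    Writes a manifest with versions, the global seed and SHA-256 hashes of
    all emitted files, sufficient to reproduce the run exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    summary: dict = {"seed": cfg.seed}
    for stage in STAGES:
        fn = globals()[f"stage_{stage}"]
        try:
            summary[stage] = fn(cfg, outdir)
            logger.info("stage %s done", stage)
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "files": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
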