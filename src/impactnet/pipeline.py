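"""End-to-end orchestration: generate -> lesion -> rank -> test -> predict.

A run takes a :class:`RunConfig`, generates a synthetic dataset, computes
efficiency metrics and lesion sweeps per subject, aggregates cohort and
per-subject importance rankings, ranks regions by strain, correlates the
two rankings, runs the group tests, and evaluates incremental predictor
sets under both rankings with leave-one-out cross-validation.  Every
artifact is a TSV or JSON file stamped with the seed and a hash of the
resolved configuration; rerunning an identical configuration reproduces
all numeric outputs byte for byte.  All randomness flows from the single
root seed through per-stage derived streams — there is no global random
state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import lesion, riskmodel, strain, synthdata
from .netcore import global_efficiency

log = logging.getLogger("impactnet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults are the study's native scale (129 regions, 30 subjects, 53
    impacts with 20 concussive) with single-node deletion sweeps; pair and
    triple sweeps are opt-in via ``lesion_ks`` because their cost grows as
    C(n, k) efficiency evaluations per subject.
    """

    seed: int = 0
    n_regions: int = 129
    n_subjects: int = 30
    n_cases: int = 53
    n_concussive: int = 20
    n_hubs: int = 10
    n_strain_regions: int = 10
    density: float = 0.15
    hub_weight_boost: float = 3.0
    intra_module_bias: float = 2.0
    between_subject_noise: float = 0.3
    concussion_strain_shift: float = 1.5
    kinematic_strain_coupling: float = 0.83
    lesion_ks: tuple[int, ...] = (1,)
    aggregation: str = "linear"
    alpha: float = 0.05
    bonferroni_n: int | None = None
    max_predictors: int = 4
    out_dir: str = "runs/demo"

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "lesion_ks":
                v = ",".join(str(k) for k in v)
            lines.append(f"{f.name}={'' if v is None else v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "lesion_ks":
                kwargs[f.name] = tuple(int(x) for x in v.split(",") if x)
            elif f.name == "bonferroni_n":
                kwargs[f.name] = None if v == "" else int(v)
            elif f.name in ("aggregation", "out_dir"):
                kwargs[f.name] = v
            elif f.name in (
                "seed", "n_regions", "n_subjects", "n_cases", "n_concussive",
                "n_hubs", "n_strain_regions", "max_predictors",
            ):
                kwargs[f.name] = int(v)
            else:
                kwargs[f.name] = float(v)
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        lines = [
            line for line in self.to_text().splitlines()
            if not line.startswith("out_dir=")
        ]
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:12]


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# impactnet seed={config.seed} config_sha256={config.config_hash}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _write_json(obj, path: Path, config: RunConfig) -> None:
    payload = {
        "seed": config.seed,
        "config_sha256": config.config_hash,
        **obj,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def setup_logging(run_dir: Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr, and to ``run.log`` inside the run directory if given."""
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(sh)
    if run_dir is not None:
        for handler in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
            handler.close()
            log.removeHandler(handler)
        fh = logging.FileHandler(run_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


def run_pipeline(config: RunConfig, full_scale: bool = False) -> Path:
    """Execute the full workflow; returns the run directory.

    ``full_scale`` unlocks triple-deletion sweeps on networks above the
    desk-scale node limit.  A stage failure aborts with a :class:`StageError`
    after writing a partial manifest listing the stages that completed.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(run_dir)
    (run_dir / "config.txt").write_text(config.to_text())
    manifest: dict = {"stages": [], "config_sha256": config.config_hash}
    timings: dict[str, float] = {}

    def stage(name):
        def decorator(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:
                manifest["failed_stage"] = name
                (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise StageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            manifest["stages"].append(name)
            log.info("stage %s done in %.2fs", name, timings[name])
            return result

        return decorator

    @stage("generate")
    def _generate():
        atlas = synthdata.gen_atlas(
            config.n_regions, config.n_hubs, config.n_strain_regions, config.seed
        )
        truth = synthdata.make_ground_truth(
            atlas, config.concussion_strain_shift,
            config.kinematic_strain_coupling, config.seed,
        )
        cohort = synthdata.gen_cohort(
            atlas, config.n_subjects, config.between_subject_noise, config.seed,
            density=config.density, hub_weight_boost=config.hub_weight_boost,
            intra_module_bias=config.intra_module_bias,
        )
        impacts = synthdata.gen_impacts(
            atlas, config.n_cases, config.n_concussive, truth, config.seed
        )
        synthdata.write_dataset(run_dir / "dataset", atlas, truth, cohort, impacts)
        return atlas, truth, cohort, impacts

    atlas, truth, cohort, impacts = _generate

    @stage("metrics")
    def _metrics():
        rows = []
        for i, conn in enumerate(cohort):
            eff = global_efficiency(conn)
            rows.append(
                {
                    "subject": i,
                    "raw_efficiency": eff.raw_efficiency,
                    "ideal_efficiency": eff.ideal_efficiency,
                    "global_efficiency": eff.global_efficiency,
                }
            )
        _write_tsv(pd.DataFrame(rows), run_dir / "metrics.tsv", config)

    _metrics

    @stage("lesion_sweeps")
    def _sweeps():
        sweeps: dict[int, list[lesion.DeletionSweep]] = {}
        for k in config.lesion_ks:
            sweeps[k] = []
            for i, conn in enumerate(cohort):
                sw = lesion.sweep(
                    conn, k, subject_id=f"subject_{i:02d}", allow_large=full_scale
                )
                sweeps[k].append(sw)
        return sweeps

    sweeps = _sweeps

    @stage("cohort_importance")
    def _importance():
        by_k = {}
        for k, subject_sweeps in sweeps.items():
            imp = lesion.cohort_importance(subject_sweeps, config.aggregation)
            by_k[k] = imp
            _write_tsv(
                lesion.importance_to_frame(imp),
                run_dir / f"importance_k{k}.tsv", config,
            )
        return by_k

    importance_by_k = _importance

    @stage("strain_ranking")
    def _strain_rank():
        imp = strain.rank_by_strain(impacts, atlas.region_ids)
        _write_tsv(
            lesion.importance_to_frame(imp), run_dir / "strain_importance.tsv", config
        )
        return imp

    strain_ranking = _strain_rank

    dge_ranking = importance_by_k[min(importance_by_k)]

    @stage("ranking_correlation")
    def _correlate():
        rho_s, p_s = strain.ranking_correlation(strain_ranking, dge_ranking, "scores")
        rho_r, p_r = strain.ranking_correlation(strain_ranking, dge_ranking, "ranks")
        payload = {
            "scores": {"rho": rho_s, "p_value": p_s},
            "ranks": {"rho": rho_r, "p_value": p_r},
            "overlap_top10": len(
                set(strain_ranking.top(10)) & set(dge_ranking.top(10))
            ),
        }
        _write_json(payload, run_dir / "correlation.json", config)

    _correlate

    @stage("group_tests")
    def _tests():
        results = strain.regional_tests(
            impacts, config.alpha, config.bonferroni_n, atlas.region_ids
        )
        frame = pd.DataFrame(
            {
                "region_id": [r.region_id for r in results],
                "statistic": [r.statistic for r in results],
                "p_value": [r.p_value for r in results],
                "significant_bonferroni": [
                    r.significant_bonferroni for r in results
                ],
            }
        )
        _write_tsv(frame, run_dir / "regional_tests.tsv", config)
        kin = strain.kinematic_tests(impacts)
        kin_frame = pd.DataFrame(
            {
                "predictor": list(kin),
                "statistic": [kin[k][0] for k in kin],
                "p_value": [kin[k][1] for k in kin],
            }
        )
        _write_tsv(kin_frame, run_dir / "kinematic_tests.tsv", config)

    _tests

    max_k = min(config.max_predictors, riskmodel.epv_cap(config.n_concussive))
    if max_k < config.max_predictors:
        log.info(
            "clamping predictor count to the events-per-variable cap: %d", max_k
        )

    @stage("predictor_sets")
    def _predict():
        payload = {"max_predictors": max_k}
        for label, ranking in (
            ("high_rmps", strain_ranking), ("high_dge", dge_ranking),
        ):
            reports = riskmodel.evaluate_predictor_sets(
                impacts, ranking, max_k,
                include_baselines=(label == "high_rmps"),
            )
            payload[label] = [r.as_dict() for r in reports]
        _write_json(payload, run_dir / "report.json", config)

    _predict

    @stage("per_subject")
    def _per_subject():
        k1 = min(sweeps)
        rankings = [
            lesion.aggregate_importance(sw, config.aggregation) for sw in sweeps[k1]
        ]
        summary = riskmodel.per_subject_evaluation(impacts, rankings, max_k)
        _write_json(summary.as_dict(), run_dir / "per_subject.json", config)

    _per_subject

    manifest["timings_s"] = timings
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %s", run_dir)
    return run_dir
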