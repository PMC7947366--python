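"""End-to-end orchestration: phantom -> T2 maps -> features -> cutoffs ->
logistic model -> nomogram scoring.

Every stage reads and writes files in a run directory, so stages can also
be executed individually from the command line. A manifest records the
configuration hash, software versions, per-stage row counts and the
checksums of all tabular outputs; a rerun with the same configuration
reproduces identical CSV/JSON outputs.
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
from scipy import stats as sps

from . import __version__
from .errors import PipelineError, SchemaError
from .features import FEATURES_12, extract_features
from .io import (read_echo_stack, read_mask, read_t2map, read_table,
                 write_echo_stack, write_mask, write_t2map, write_table)
from .model import (LogisticFit, NomogramModel, build_nomogram, c_index,
                    fit_logistic, or_forest_table, score_nomogram)
from .phantom import PhantomConfig, simulate_cohort
from .relaxometry import T2_WINDOW_MS, fit_t2_map
from .stats import chi_square_2x2, table_from_flags, youden_cutoff

log = logging.getLogger("t2nomo")

__all__ = ["PipelineConfig", "run_pipeline",
           "stage_simulate", "stage_fit_t2", "stage_features",
           "stage_cutoffs", "stage_model", "stage_score"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    fit_method: str = "loglinear_wls"
    t2_window_ms: tuple[float, float] = T2_WINDOW_MS
    aggregation: str = "pooled_all_eoms"
    bin_width_ms: float = 1.0
    yates_correction: bool = False
    icc_form: str = "icc2"
    univariate_alpha: float = 0.05
    retain_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed,
            phantom=self.phantom.replace(seed=seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["t2_window_ms"] = list(self.t2_window_ms)
        ph = d["phantom"]
        ph["grid_shape"] = list(self.phantom.grid_shape)
        ph["voxel_size_mm"] = list(self.phantom.voxel_size_mm)
        ph["echo_times_ms"] = list(self.phantom.echo_times_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        for key in ("grid_shape", "voxel_size_mm", "echo_times_ms"):
            if key in ph:
                ph[key] = tuple(ph[key])
        if "t2_window_ms" in d:
            d["t2_window_ms"] = tuple(d["t2_window_ms"])
        return cls(phantom=PhantomConfig(**ph), **d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subjects(run_dir: Path) -> list[str]:
    clin = read_table(run_dir / "clinical.csv", required=["patient_id"])
    return list(clin["patient_id"])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, run_dir: Path) -> int:
    """Generate the cohort and persist images, masks and clinical tables."""
    cohort = simulate_cohort(config.phantom)
    img_dir = run_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    clin_rows, delta_rows = [], []
    for p in cohort:
        write_echo_stack(img_dir / f"{p.patient_id}_echoes.nii.gz", p.echoes)
        write_mask(img_dir / f"{p.patient_id}_mask.nii.gz", p.mask)
        clin_rows.append({**dataclasses.asdict(p.clinical),
                          "outcome": p.outcome})
        for side, delta in zip(("left", "right"), p.deltas):
            delta_rows.append({"patient_id": p.patient_id, "side": side,
                               **dataclasses.asdict(delta)})
    write_table(run_dir / "clinical.csv", pd.DataFrame(clin_rows))
    write_table(run_dir / "therapy_deltas.csv", pd.DataFrame(delta_rows))
    log.info("simulate: %d patients", len(cohort))
    return len(cohort)


def stage_fit_t2(config: PipelineConfig, run_dir: Path) -> int:
    img_dir = run_dir / "images"
    map_dir = run_dir / "maps"
    map_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for pid in _subjects(run_dir):
        echoes = read_echo_stack(img_dir / f"{pid}_echoes.nii.gz")
        mask = read_mask(img_dir / f"{pid}_mask.nii.gz")
        t2map = fit_t2_map(echoes, mask, method=config.fit_method,
                           t2_window_ms=config.t2_window_ms)
        write_t2map(map_dir / pid, t2map)
        n += 1
    log.info("fit-t2: %d subjects (%s)", n, config.fit_method)
    return n


def stage_features(config: PipelineConfig, run_dir: Path) -> int:
    img_dir = run_dir / "images"
    map_dir = run_dir / "maps"
    frames = []
    for pid in _subjects(run_dir):
        mask = read_mask(img_dir / f"{pid}_mask.nii.gz")
        t2map = read_t2map(map_dir / pid)
        df = extract_features(t2map, mask, aggregation=config.aggregation,
                              bin_width_ms=config.bin_width_ms)
        df.insert(0, "patient_id", pid)
        df.insert(2, "aggregation", config.aggregation)
        frames.append(df)
    feats = pd.concat(frames, ignore_index=True)
    write_table(run_dir / "features.csv", feats)
    meta = {"aggregation": config.aggregation,
            "bin_width_ms": config.bin_width_ms,
            "percentile_convention": "linear interpolation, inclusive",
            "software_version": __version__}
    (run_dir / "features.json").write_text(json.dumps(meta, indent=2))
    log.info("features: %d rows", len(feats))
    return len(feats)


def _orbit_table(run_dir: Path) -> pd.DataFrame:
    feats = read_table(run_dir / "features.csv",
                       required=["patient_id", "side", *FEATURES_12])
    clin = read_table(run_dir / "clinical.csv", required=["patient_id"])
    if "outcome" not in clin.columns:
        raise SchemaError("clinical.csv: missing column(s) ['outcome']")
    merged = feats.merge(clin[["patient_id", "outcome"]], on="patient_id",
                         validate="many_to_one")
    merged["response"] = (merged["outcome"] == "responsive").astype(int)
    return merged


def stage_cutoffs(config: PipelineConfig, run_dir: Path) -> int:
    orbits = _orbit_table(run_dir)
    y = orbits["response"].to_numpy()
    roc_rows, uni_rows, flags = [], [], {}
    for feat in FEATURES_12:
        cut = youden_cutoff(orbits[feat].to_numpy(), y, feature=feat)
        sign = ">" if cut.direction == "greater" else "<="
        roc_rows.append({
            "feature": feat, "auc": cut.auc,
            "auc_ci_lower": cut.auc_ci[0], "auc_ci_upper": cut.auc_ci[1],
            "p": cut.auc_p, "youden": cut.youden,
            "cutoff": f"{sign}{cut.cutoff:g}",
            "sensitivity_pct": cut.sensitivity,
            "specificity_pct": cut.specificity,
        })
        flag = cut.flag(orbits[feat].to_numpy())
        flags[feat] = flag
        t = table_from_flags(flag, y)
        stat, p = chi_square_2x2(t, yates=config.yates_correction)
        pct = t.row_percentages()
        uni_rows.append({
            "feature": feat, "category": f"{sign}{cut.cutoff:g}",
            "responsive_n": t.a, "unresponsive_n": t.b,
            "responsive_pct": pct[0, 0], "unresponsive_pct": pct[0, 1],
            "ref_responsive_n": t.c, "ref_unresponsive_n": t.d,
            "ref_responsive_pct": pct[1, 0], "ref_unresponsive_pct": pct[1, 1],
            "chi2": stat, "p": p,
        })
    write_table(run_dir / "roc_cutoffs.csv", pd.DataFrame(roc_rows))
    write_table(run_dir / "univariate.csv", pd.DataFrame(uni_rows))
    dich = orbits[["patient_id", "side", "response"]].copy()
    for feat in FEATURES_12:
        dich[feat] = flags[feat]
    write_table(run_dir / "dichotomized.csv", dich)
    log.info("cutoffs: %d features over %d orbits", len(FEATURES_12), len(orbits))
    return len(roc_rows)


def stage_model(config: PipelineConfig, run_dir: Path) -> int:
    uni = read_table(run_dir / "univariate.csv", required=["feature", "p"])
    dich = read_table(run_dir / "dichotomized.csv",
                      required=["patient_id", "side", "response"])
    predictors = list(uni.loc[uni["p"] < config.univariate_alpha, "feature"])
    if not predictors:
        raise PipelineError("model", "no univariately significant predictors")
    # drop aliased predictors: any flag linearly dependent on the intercept
    # and earlier flags carries no separate information and makes the design
    # singular (exact duplicates and complementary flags included)
    kept, aliased = [], []
    design = np.ones((len(dich), 1))
    for feat in predictors:
        cand = np.column_stack([design, dich[feat].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            kept.append(feat)
            design = cand
        else:
            aliased.append(feat)
    y = dich["response"].to_numpy()
    fit = fit_logistic(dich[kept], y)
    # Perfect separation (possible at this cohort size) is detected and
    # reported: the offending predictor has no finite ML odds ratio, so it
    # is removed from the multivariable model and listed in model_notes.json.
    dropped = []
    while not fit.converged and len(kept) > 1:
        worst = kept[int(np.argmax(np.abs(fit.beta)))]
        kept.remove(worst)
        dropped.append(worst)
        fit = fit_logistic(dich[kept], y)
    if not fit.converged:
        raise PipelineError("model", "logistic fit did not converge")
    table = or_forest_table(fit)
    table["retained"] = table["p_value"] < config.retain_alpha
    table.loc[len(table)] = {
        "predictor": "(intercept)", "beta": fit.intercept,
        "se": fit.intercept_se, "or": np.exp(fit.intercept),
        "ci_lower": np.nan, "ci_upper": np.nan,
        "p_value": 2 * sps.norm.sf(abs(fit.intercept / fit.intercept_se)),
        "retained": True,
    }
    write_table(run_dir / "logistic_model.csv", table)
    (run_dir / "model_notes.json").write_text(json.dumps(
        {"aliased": aliased, "dropped_for_separation": dropped},
        indent=2, sort_keys=True))
    write_table(run_dir / "forest.csv", table[table["predictor"] != "(intercept)"])

    retained = [n for n, p in zip(fit.names, fit.p_values)
                if p < config.retain_alpha and
                fit.beta[fit.names.index(n)] > 0]
    if retained and len(retained) < len(fit.names):
        nomo_fit = fit_logistic(dich[retained], y)
    else:
        nomo_fit, retained = fit, fit.names
    nomogram = build_nomogram(nomo_fit)
    (run_dir / "nomogram.json").write_text(nomogram.to_json())
    log.info("model: %d predictors, %d retained for the nomogram",
             len(predictors), len(retained))
    return len(predictors)


def stage_score(config: PipelineConfig, run_dir: Path) -> float:
    dich = read_table(run_dir / "dichotomized.csv",
                      required=["patient_id", "side", "response"])
    nomogram = NomogramModel.from_json((run_dir / "nomogram.json").read_text())
    rows = []
    for _, r in dich.iterrows():
        values = {n: r[n] for n in nomogram.fit.names}
        points, prob = score_nomogram(nomogram, values)
        rows.append({"patient_id": r["patient_id"], "side": r["side"],
                     "total_points": points, "probability": prob,
                     "response": r["response"]})
    scores = pd.DataFrame(rows)
    write_table(run_dir / "scores.csv", scores)
    cidx = c_index(scores["probability"], scores["response"])
    log.info("score: C-index %.3f over %d orbits", cidx, len(scores))
    return cidx


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_TABULAR_OUTPUTS = ("clinical.csv", "therapy_deltas.csv", "features.csv",
                    "features.json", "roc_cutoffs.csv", "univariate.csv",
                    "dichotomized.csv", "logistic_model.csv", "forest.csv",
                    "model_notes.json", "nomogram.json", "scores.csv")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir`` and write a manifest.

    Any stage failure is re-raised as :class:`PipelineError` carrying the
    stage name. Returns the run directory.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    fh = logging.FileHandler(run_dir / "run.log")
    log.addHandler(fh)
    counts: dict[str, float] = {}
    try:
        stages = (("simulate", stage_simulate), ("fit_t2", stage_fit_t2),
                  ("features", stage_features), ("cutoffs", stage_cutoffs),
                  ("model", stage_model))
        for name, fn in stages:
            try:
                counts[name] = fn(config, run_dir)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
        try:
            counts["c_index"] = stage_score(config, run_dir)
        except Exception as err:
            raise PipelineError("score", str(err)) from err
    finally:
        log.removeHandler(fh)
        fh.close()

    checksums = {}
    for name in _TABULAR_OUTPUTS:
        p = run_dir / name
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "software_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stage_counts": counts,
        "output_sha256": checksums,
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return run_dir
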