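"""Pipeline orchestration: configuration, staged execution, provenance.

The pipeline mirrors the labeling-to-model workflow: quantify oxidation from
intensity tables (quant), fit dose responses and convert to lnPF (lnpf),
compute structure neighbor counts (nc), score and rank candidate models
(score/rank), and report accuracy funnels against a reference (report).
Each stage reads and writes delimited-text intermediates, so the composed
stages and the one-shot :func:`run_pipeline` produce identical outputs, and
every run emits a manifest recording input hashes, the fully resolved
configuration (including the constants that are design choices rather than
measurements: reward and neighbor-count parameters), and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import hrpfkit
from hrpfkit import doseresp, modelrank, oxquant, topography
from hrpfkit.errors import ComputationError, ConfigError, HrpfKitError, InputError

logger = logging.getLogger("hrpfkit")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration.

    Paths may be None when a stage is not run.  ``residue_offset`` maps
    labeling residue numbering onto structure numbering
    (structure position = labeling residue + offset) for construct-tag
    differences.
    """

    # inputs
    isotopologue_table: str | None = None
    fragment_table: str | None = None
    dose_table: str | None = None
    reactivity_table: str | None = None
    structures: str | None = None
    base_scores: str | None = None
    reference_structure: str | None = None
    chain: str | None = None
    # calibration NC = m * lnPF + b
    calibration_m: float = -1.5
    calibration_b: float = 10.0
    # scoring constants
    weight: float = modelrank.DEFAULT_HRF_WEIGHT
    score_d0: float = 4.0
    score_tau: float = 1.0
    nc_dist_midpoint: float = 9.0
    nc_dist_steepness: float = 1.0
    nc_angle_midpoint: float = math.pi / 2
    nc_angle_steepness: float = 2 * math.pi
    # selection / reporting
    residue_offset: int = 0
    modelable: list[str] | None = None
    top_n: int = 20
    funnel_top_n: int = 250
    funnel_cutoff: float = 5.0
    funnel_bin: float = 0.5
    seed: int = 0

    @property
    def nc_params(self) -> topography.NeighborCountParams:
        return topography.NeighborCountParams(
            dist_midpoint=self.nc_dist_midpoint,
            dist_steepness=self.nc_dist_steepness,
            angle_midpoint=self.nc_angle_midpoint,
            angle_steepness=self.nc_angle_steepness,
        )

    @property
    def score_params(self) -> modelrank.HrfScoreParams:
        return modelrank.HrfScoreParams(d0=self.score_d0, tau=self.score_tau)

    @property
    def calibration(self) -> topography.CalibrationLine:
        return topography.CalibrationLine(m=self.calibration_m, b=self.calibration_b)

    @property
    def modelable_set(self):
        if self.modelable is None:
            return doseresp.MODELABLE_TYPES
        return frozenset(doseresp.normalize_restype(t) for t in self.modelable)


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(config: RunConfig, *names: str) -> None:
    for name in names:
        value = getattr(config, name)
        if value is None:
            raise ConfigError(f"config field {name!r} is required for this stage")
        if not Path(value).exists():
            raise ConfigError(f"{name}: file not found: {value}")


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> str:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    # %.17g round-trips float64 exactly, so staged and composed runs agree
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_quant(config: RunConfig, out_dir) -> pd.DataFrame:
    """Quantify background-corrected residue oxidation from intensity tables.

    Reads the isotopologue and fragment tables, computes peptide-level events
    per (peptide, condition, dose, replicate), distributes them along each
    fragment ladder, and subtracts the mean no-laser control per residue
    group.  Writes ``residue_oxidation.csv``.
    """
    _require(config, "isotopologue_table", "fragment_table")
    distributions = oxquant.read_isotopologue_table(config.isotopologue_table)
    ladders = oxquant.read_fragment_table(config.fragment_table)
    labeled, control = [], []
    for ladder in ladders:
        key = (ladder.peptide_id, ladder.condition, ladder.dose_id, ladder.replicate)
        if key not in distributions:
            raise InputError(f"no isotopologue distribution for {key}")
        p = oxquant.peptide_mean_oxidation(distributions[key])
        records = oxquant.residue_oxidation_from_ladder(ladder, p)
        (labeled if ladder.condition == "labeled" else control).extend(records)
    corrected = oxquant.background_subtract(labeled, control)
    n_flagged = sum(r.noise_flag for r in corrected)
    if n_flagged:
        logger.info("quant: %d negative corrected records retained (noise)", n_flagged)
    df = oxquant.residue_table(corrected)
    _write(df, Path(out_dir), "residue_oxidation.csv")
    return df


def _restype_map(config: RunConfig) -> dict[int, str]:
    """Labeling residue number -> residue type, from the first structure model."""
    _require(config, "structures")
    first = topography.read_structures(config.structures, chain=config.chain)[0]
    return {
        r.position - config.residue_offset: doseresp.normalize_restype(r.restype)
        for r in first.residues
    }


def stage_lnpf(config: RunConfig, residue_events: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Fit per-residue dose responses and convert to lnPF.

    Group records spanning several residues are used only when exactly one
    residue of the group is of a modelable type (the events are then assigned
    to it); all other groups are logged and dropped — scoring is strictly
    per-residue.  Writes ``protection_factors.csv``.
    """
    _require(config, "dose_table", "reactivity_table")
    doses = pd.read_csv(config.dose_table, float_precision="round_trip")
    if not {"dose_id", "x"} <= set(doses.columns):
        raise InputError("dose table needs columns: dose_id, x")
    dose_x = dict(zip(doses["dose_id"].astype(str), doses["x"].astype(float)))
    reactivity = doseresp.load_reactivity_table(config.reactivity_table)
    restypes = _restype_map(config)
    modelable = config.modelable_set

    points: dict[int, list[doseresp.DoseResponsePoint]] = {}
    dropped_groups = 0
    for _, row in residue_events.iterrows():
        start, end = int(row["res_start"]), int(row["res_end"])
        if start == end:
            residue = start
        else:
            members = [
                p for p in range(start, end + 1)
                if restypes.get(p) in modelable
            ]
            if len(members) != 1:
                dropped_groups += 1
                continue
            residue = members[0]
        dose_id = str(row["dose_id"])
        if dose_id not in dose_x:
            raise InputError(f"dose_id {dose_id!r} missing from dose table")
        points.setdefault(residue, []).append(
            doseresp.DoseResponsePoint(
                residue=residue,
                x=dose_x[dose_id],
                y=float(row["events"]),
                dose_id=dose_id,
                replicate=int(row["replicate"]),
            )
        )
    if dropped_groups:
        logger.info("lnpf: dropped %d multi-residue groups without a unique "
                    "modelable member", dropped_groups)

    fits: dict[int, doseresp.SlopeFit] = {}
    records = []
    for residue in sorted(points):
        restype = restypes.get(residue)
        if restype is None:
            logger.info("lnpf: residue %d absent from structure; skipped", residue)
            continue
        if restype not in reactivity:
            raise InputError(f"no intrinsic reactivity for {restype} (residue {residue})")
        fit = doseresp.fit_dose_response(points[residue])
        fits[residue] = fit
        records.append(doseresp.lnpf(restype, reactivity[restype], fit))
    kept, excluded = doseresp.select_modelable(records, modelable)
    for rec, reason in excluded:
        logger.info("lnpf: residue %d (%s) excluded: %s", rec.residue, rec.restype, reason)
    df = doseresp.protection_table(records, fits)
    df["modelable"] = [r.residue in {k.residue for k in kept} for r in records]
    _write(df, Path(out_dir), "protection_factors.csv")
    return df


def stage_nc(config: RunConfig, out_dir) -> pd.DataFrame:
    """Neighbor-count profiles for every model in the structures file."""
    _require(config, "structures")
    models = topography.read_structures(config.structures, chain=config.chain)
    profiles = {
        m.model_id: topography.neighbor_count_profile(m, config.nc_params)
        for m in models
    }
    df = topography.nc_profile_table(profiles)
    _write(df, Path(out_dir), "neighbor_counts.csv")
    return df


def predictions_from_lnpf(config: RunConfig, protection: pd.DataFrame) -> dict[int, float]:
    """Labeling-predicted NC per structure position, from modelable lnPF."""
    calib = config.calibration
    predictions: dict[int, float] = {}
    usable = protection[protection["modelable"]]
    for _, row in usable.iterrows():
        nc, clamped = topography.predict_nc(float(row["lnpf"]), calib)
        if clamped:
            logger.info("predict: residue %d NC clamped to 0", int(row["residue"]))
        predictions[int(row["residue"]) + config.residue_offset] = nc
    if not predictions:
        raise ComputationError("no modelable residues with usable lnPF")
    return predictions


def stage_score_rank(config: RunConfig, protection: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Score every candidate model and rank by total score.

    Base scores come from the configured CSV (model_id, score); models absent
    from it score base 0 and the run is labeled hrf-only in the manifest.
    Writes ``ranked_models.csv`` (all models, ranked).
    """
    _require(config, "structures")
    models = topography.read_structures(config.structures, chain=config.chain)
    predictions = predictions_from_lnpf(config, protection)
    base: dict[str, float] = {}
    if config.base_scores is not None:
        bdf = pd.read_csv(config.base_scores, float_precision="round_trip")
        if not {"model_id", "score"} <= set(bdf.columns):
            raise InputError("base scores table needs columns: model_id, score")
        base = dict(zip(bdf["model_id"].astype(str), bdf["score"].astype(float)))
    ranked = []
    for model in models:
        _, rm = score_one(config, model, predictions, base.get(model.model_id, 0.0))
        ranked.append(rm)
    ranked = modelrank.rank_and_select(ranked, top_n=None)
    rmsds = _reference_rmsds(config, models) if config.reference_structure else {}
    df = pd.DataFrame(
        {
            "model_id": [m.model_id for m in ranked],
            "rank": [m.rank for m in ranked],
            "base_score": [m.base_score for m in ranked],
            "hrf_sum": [m.hrf_sum for m in ranked],
            "weight": [m.weight for m in ranked],
            "total_score": [m.total for m in ranked],
            "rmsd_to_reference": [rmsds.get(m.model_id) for m in ranked],
        }
    )
    _write(df, Path(out_dir), "ranked_models.csv")
    return df


def score_one(config, model, predictions, base_score):
    return modelrank.score_model(
        model,
        predictions,
        base_score=base_score,
        weight=config.weight,
        score_params=config.score_params,
        nc_params=config.nc_params,
    )


def _reference_rmsds(config: RunConfig, models) -> dict[str, float]:
    _require(config, "reference_structure")
    reference = topography.read_structures(config.reference_structure, chain=config.chain)[0]
    return {m.model_id: modelrank.kabsch_rmsd_ca(m, reference)[0] for m in models}


def stage_report(config: RunConfig, ranked: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Funnel summary of the top-scoring models vs the reference structure."""
    if ranked["rmsd_to_reference"].isna().any():
        raise InputError("funnel report needs a reference structure (RMSDs missing)")
    models = [
        modelrank.RankedModel(
            model_id=str(r["model_id"]),
            base_score=float(r["base_score"]),
            hrf_sum=float(r["hrf_sum"]),
            weight=float(r["weight"]),
            rmsd_to_reference=float(r["rmsd_to_reference"]),
        )
        for _, r in ranked.iterrows()
    ]
    report = modelrank.funnel_report(
        models,
        top_n=config.funnel_top_n,
        cutoff=config.funnel_cutoff,
        bin_width=config.funnel_bin,
    )
    out = Path(out_dir)
    _write(report.table, out, "funnel_models.csv")
    hist = pd.DataFrame(report.histogram, columns=["bin_left", "count"])
    _write(hist, out, "funnel_histogram.csv")
    summary = pd.DataFrame(
        [
            {
                "top_n": report.top_n,
                "mean_rmsd": report.mean_rmsd,
                "fraction_under_cutoff": report.fraction_under_cutoff,
                "cutoff": report.cutoff,
                "bin_width": report.bin_width,
            }
        ]
    )
    _write(summary, out, "funnel_summary.csv")
    return summary


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

_INPUT_FIELDS = (
    "isotopologue_table",
    "fragment_table",
    "dose_table",
    "reactivity_table",
    "structures",
    "base_scores",
    "reference_structure",
)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run quant -> lnpf -> nc -> score/rank [-> report]; write a manifest.

    Deterministic given the inputs and configuration.  Stage failures abort
    with the failing stage named; intermediates written before the failure are
    preserved.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require(
        config,
        "isotopologue_table",
        "fragment_table",
        "dose_table",
        "reactivity_table",
        "structures",
    )
    manifest = {
        "package": "hrpfkit",
        "version": hrpfkit.__version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in _INPUT_FIELDS
            if getattr(config, name) is not None
        },
        "hrf_only": config.base_scores is None,
        "stages": [],
    }
    stages = [
        ("quant", lambda state: stage_quant(config, out)),
        ("lnpf", lambda state: stage_lnpf(config, state["quant"], out)),
        ("nc", lambda state: stage_nc(config, out)),
        ("score_rank", lambda state: stage_score_rank(config, state["lnpf"], out)),
    ]
    if config.reference_structure is not None:
        stages.append(("report", lambda state: stage_report(config, state["score_rank"], out)))
    state: dict[str, pd.DataFrame] = {}
    for name, fn in stages:
        logger.info("stage %s: running", name)
        try:
            state[name] = fn(state)
        except Exception as exc:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            if isinstance(exc, HrpfKitError):
                exc.args = (f"stage {name!r} failed: {exc}",)
                raise
            raise ComputationError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
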