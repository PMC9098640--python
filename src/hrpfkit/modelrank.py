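"""Covalent-labeling-guided scoring, ranking and RMSD reporting of models.

Each modelable residue with a measured lnPF contributes a strictly negative
reward that is most negative when the model's observed neighbor count matches
the neighbor count predicted from the labeling data; the summed per-residue
reward, weighted (default 9.0), is added to an external base score (e.g. an
ab initio package's all-atom energy) to give the total score used for ranking.
Ensembles produced by perturbing top-ranked parents ("mover models") are
rescored under identical settings and merged into the ranked distribution.
Model accuracy is reported as Cα RMSD after optimal (Kabsch) superposition
with no outlier rejection, summarized as score-vs-RMSD funnels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hrpfkit.errors import ComputationError, InputError
from hrpfkit.topography import (
    NeighborCountParams,
    StructureModel,
    neighbor_count_profile,
)

__all__ = [
    "HrfScoreParams",
    "HrfScore",
    "RankedModel",
    "hrf_residue_score",
    "score_model",
    "rank_and_select",
    "merge_rescore",
    "kabsch_rmsd_ca",
    "funnel_report",
    "FunnelReport",
]

#: Weight applied to the summed per-residue labeling reward in the total score.
DEFAULT_HRF_WEIGHT = 9.0


@dataclass(frozen=True)
class HrfScoreParams:
    """Logistic reward constants: s(Δ) = −1/(1 + exp((Δ − d0)/τ)).

    Δ is |observed NC − predicted NC|; d0 (neighbors) is the midpoint where
    the reward is −0.5, τ the softness.  Strictly in (−1, 0), most negative
    at Δ = 0.
    """

    d0: float = 4.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InputError("tau must be > 0")


@dataclass(frozen=True)
class HrfScore:
    """Per-model labeling reward: per-residue scores in (−1, 0) and their sum."""

    model_id: str
    residue_scores: tuple[tuple[int, float], ...]
    weight: float = DEFAULT_HRF_WEIGHT

    def __post_init__(self) -> None:
        if any(not (-1.0 < s < 0.0) for _, s in self.residue_scores):
            raise ComputationError("per-residue scores must lie strictly in (-1, 0)")

    @property
    def total(self) -> float:
        return float(sum(s for _, s in self.residue_scores))


@dataclass(frozen=True)
class RankedModel:
    """A scored candidate model; total = base + weight * hrf_sum."""

    model_id: str
    base_score: float
    hrf_sum: float
    weight: float = DEFAULT_HRF_WEIGHT
    rank: int | None = None
    rmsd_to_reference: float | None = None

    @property
    def total(self) -> float:
        return self.base_score + self.weight * self.hrf_sum


def hrf_residue_score(
    nc_observed: float,
    nc_predicted: float,
    params: HrfScoreParams = HrfScoreParams(),
) -> float:
    """Per-residue labeling reward, strictly in (−1, 0).

    s(Δ) = −1/(1 + exp((Δ − d0)/τ)) with Δ = |observed − predicted|: a model
    whose neighbor count matches the labeling-predicted one earns the most
    negative (best) reward; the reward decays toward 0 as the mismatch grows.
    """
    if not (math.isfinite(nc_observed) and math.isfinite(nc_predicted)):
        raise InputError("neighbor counts must be finite")
    if nc_observed < 0 or nc_predicted < 0:
        raise InputError("neighbor counts must be >= 0")
    delta = abs(nc_observed - nc_predicted)
    return -1.0 / (1.0 + math.exp((delta - params.d0) / params.tau))


def score_model(
    model: StructureModel,
    predictions: Mapping[int, float],
    base_score: float = 0.0,
    weight: float = DEFAULT_HRF_WEIGHT,
    score_params: HrfScoreParams = HrfScoreParams(),
    nc_params: NeighborCountParams = NeighborCountParams(),
) -> tuple[HrfScore, RankedModel]:
    """Score one model against labeling-predicted neighbor counts.

    Every residue with a prediction must exist in the model (missing positions
    are listed in the error); the labeling reward sums over exactly those
    residues and the total adds the weighted sum to the external base score.
    """
    if not predictions:
        raise InputError(f"{model.model_id}: no predicted neighbor counts supplied")
    positions = set(model.positions)
    missing = sorted(set(predictions) - positions)
    if missing:
        raise InputError(
            f"{model.model_id}: predicted residues missing from model: {missing}"
        )
    observed = neighbor_count_profile(model, nc_params)
    residue_scores = tuple(
        (pos, hrf_residue_score(observed[pos], predictions[pos], score_params))
        for pos in sorted(predictions)
    )
    hrf = HrfScore(model_id=model.model_id, residue_scores=residue_scores, weight=weight)
    ranked = RankedModel(
        model_id=model.model_id,
        base_score=base_score,
        hrf_sum=hrf.total,
        weight=weight,
    )
    return hrf, ranked


def rank_and_select(
    models: Sequence[RankedModel], top_n: int | None = 20
) -> list[RankedModel]:
    """Rank models by total score (ascending: more negative is better).

    Ties break lexicographically on model_id for reproducibility.  Returns the
    top_n best with 1-based ranks assigned; top_n=None ranks everything.
    A top_n larger than the set returns the whole ranked set with a warning.
    """
    ordered = sorted(models, key=lambda m: (m.total, m.model_id))
    if top_n is not None and top_n > len(ordered):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(ordered)} available models; returning all",
            stacklevel=2,
        )
    if top_n is not None:
        ordered = ordered[:top_n]
    return [
        RankedModel(
            model_id=m.model_id,
            base_score=m.base_score,
            hrf_sum=m.hrf_sum,
            weight=m.weight,
            rank=k,
            rmsd_to_reference=m.rmsd_to_reference,
        )
        for k, m in enumerate(ordered, start=1)
    ]


def merge_rescore(
    base_set: Sequence[tuple[StructureModel, float]],
    ensemble_set: Sequence[tuple[StructureModel, float]],
    predictions: Mapping[int, float],
    weight: float = DEFAULT_HRF_WEIGHT,
    score_params: HrfScoreParams = HrfScoreParams(),
    nc_params: NeighborCountParams = NeighborCountParams(),
) -> list[RankedModel]:
    """Score a primary model set and a rescored ensemble under one config.

    Both sets are (model, base_score) pairs; the union is scored with
    identical weight and reward/NC constants and ranked together, so ensemble
    members compete directly with the primary distribution.  Duplicate
    model_ids across the union are an error.
    """
    combined = list(base_set) + list(ensemble_set)
    ids = [m.model_id for m, _ in combined]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate model_ids across sets: {dupes}")
    ranked = [
        score_model(m, predictions, base, weight, score_params, nc_params)[1]
        for m, base in combined
    ]
    return rank_and_select(ranked, top_n=None)


def _kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered p onto centered q."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def kabsch_rmsd_ca(a: StructureModel, b: StructureModel) -> tuple[float, int]:
    """Cα RMSD after optimal rigid superposition, no outlier rejection.

    Residues are matched by sequence position (intersection); all matched
    atoms are retained in both the superposition and the RMSD.  Returns
    ``(rmsd_Å, n_matched)``; fewer than 3 matched pairs is an error.
    """
    common = sorted(set(a.positions) & set(b.positions))
    if len(common) < 3:
        raise InputError(
            f"only {len(common)} matched residues between {a.model_id} and {b.model_id}"
        )
    pa = np.array([a.residue(p).ca for p in common], dtype=float)
    pb = np.array([b.residue(p).ca for p in common], dtype=float)
    pa_c = pa - pa.mean(axis=0)
    pb_c = pb - pb.mean(axis=0)
    rot = _kabsch_rotation(pa_c, pb_c)
    aligned = pa_c @ rot.T
    diff = aligned - pb_c
    rmsd = float(np.sqrt((diff**2).sum() / len(common)))
    return rmsd, len(common)


@dataclass(frozen=True)
class FunnelReport:
    """Summary of score vs model accuracy for the top-scoring models."""

    top_n: int
    mean_rmsd: float
    fraction_under_cutoff: float
    cutoff: float
    bin_width: float
    histogram: tuple[tuple[float, int], ...]  # (bin left edge, count)
    table: pd.DataFrame  # model_id, rank, total, rmsd


def funnel_report(
    models: Sequence[RankedModel],
    top_n: int = 250,
    cutoff: float = 5.0,
    bin_width: float = 0.5,
) -> FunnelReport:
    """Accuracy summary of the top-scoring models.

    Ranks by total score, keeps the best ``top_n``, and reports their mean
    RMSD to the reference, the fraction under ``cutoff`` Å, and an RMSD
    histogram with fixed half-open bins [k·w, (k+1)·w).  Every model must
    carry ``rmsd_to_reference``.
    """
    if any(m.rmsd_to_reference is None for m in models):
        raise InputError("every model needs rmsd_to_reference for a funnel report")
    top = rank_and_select(models, top_n=min(top_n, len(models)))
    rmsds = np.array([m.rmsd_to_reference for m in top], dtype=float)
    n_bins = int(np.floor(rmsds.max() / bin_width)) + 1 if len(rmsds) else 0
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(rmsds, bins=edges) if n_bins else (np.array([], int), None)
    table = pd.DataFrame(
        {
            "model_id": [m.model_id for m in top],
            "rank": [m.rank for m in top],
            "total_score": [m.total for m in top],
            "rmsd": rmsds,
        }
    )
    return FunnelReport(
        top_n=len(top),
        mean_rmsd=float(rmsds.mean()),
        fraction_under_cutoff=float((rmsds < cutoff).mean()),
        cutoff=cutoff,
        bin_width=bin_width,
        histogram=tuple((float(edges[i]), int(counts[i])) for i in range(n_bins)),
        table=table,
    )
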