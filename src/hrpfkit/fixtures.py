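"""Deterministic synthetic data: toy folds, decoys, and simulated labeling.

Everything downstream of the mass spectrometer and of the external modeling
package can be exercised with data generated here: a compact ideal-geometry
fold of configurable size, Gaussian-perturbation decoy ensembles of known
accuracy, and labeling tables constructed by inverting the full quantification
chain — the toy fold's actual conical neighbor counts are pushed through an
inverse calibration to ground-truth lnPF, converted to dose-response slopes
via the intrinsic reactivities, and rendered as peptide isotopologue and
fragment-ion intensity tables that the quantification modules read back.
With zero noise the round trip is exact, so parameter-recovery tests have an
unambiguous target; with noise, the additive Gaussian error on labeled
oxidation events emulates triplicate measurement scatter.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hrpfkit.doseresp import MODELABLE_TYPES, normalize_restype
from hrpfkit.errors import InputError
from hrpfkit.modelrank import kabsch_rmsd_ca
from hrpfkit.topography import (
    CalibrationLine,
    NeighborCountParams,
    Residue,
    StructureModel,
    neighbor_count_profile,
    pseudo_cb,
)

__all__ = [
    "SimulationSpec",
    "make_toy_structure",
    "make_decoys",
    "simulate_labeling",
    "LabelingDataset",
]

_CA_SPACING = 3.8  # Å, consecutive CA-CA
_HELIX_RADIUS = 2.3  # Å, CA distance from helix axis
_HELIX_RISE = 1.5  # Å per residue along the axis
_HELIX_PITCH = 3.6 * _HELIX_RISE  # Å of axis per full coil turn
_ARC_RADIUS = 5.5  # Å, U-turn radius of the fold's axis path

# Residue alphabet for synthetic sequences; modelable aromatic/His/Leu types
# are well represented so labeling simulations always have usable probes.
_ALPHABET = (
    "TRP", "PHE", "TYR", "HIS", "LEU", "LEU", "PHE",
    "ALA", "GLY", "SER", "VAL", "ILE", "THR", "GLU", "LYS", "ASN",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic labeling study.

    Defaults mirror a four-dose triplicate FPOP experiment with an adenine
    dosimeter: four peroxide doses with increasing absorbance-change readouts,
    three replicates, small additive Gaussian noise on labeled oxidation
    events, and a constant background oxidation level seen in no-laser
    controls.
    """

    seed: int = 0
    n_residues: int = 64
    decoy_count: int = 100
    decoy_sigma: float = 1.0  # Å per-atom Gaussian displacement
    calibration_m: float = -1.5  # NC per lnPF unit
    calibration_b: float = 10.0  # NC at lnPF = 0
    reactivity: dict[str, float] = field(
        default_factory=lambda: {
            "TRP": 1.0, "TYR": 0.78, "PHE": 0.60, "HIS": 0.55, "LEU": 0.35,
            "ILE": 0.33, "VAL": 0.20, "THR": 0.12, "LYS": 0.12, "GLU": 0.09,
            "SER": 0.07, "ASN": 0.07, "ALA": 0.05, "GLY": 0.04,
        }
    )
    dose_levels: dict[str, float] = field(
        default_factory=lambda: {
            "p010mM": 0.10, "p025mM": 0.20, "p050mM": 0.32, "p100mM": 0.45,
        }
    )
    n_replicates: int = 3
    noise_sigma: float = 0.005  # events, additive on labeled measurements
    background: float = 0.05  # events per residue, dose-independent (no-laser)
    peptide_length: int = 10
    nc_params: NeighborCountParams = NeighborCountParams()

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.decoy_sigma < 0:
            raise InputError("noise/decoy sigma must be >= 0")
        if len(self.dose_levels) < 2:
            raise InputError("need at least 2 dose levels")
        if self.calibration_m == 0:
            raise InputError("calibration slope must be non-zero (non-invertible)")

    @property
    def calibration(self) -> CalibrationLine:
        return CalibrationLine(m=self.calibration_m, b=self.calibration_b)


def _axis_frame(s: float, leg: float):
    """Point + transverse frame of the fold's axis path at axis coordinate s.

    The path rises along +z for ``leg`` Å, U-turns through a half circle of
    radius ``_ARC_RADIUS`` in the x-z plane, then descends along -z.  The
    transverse frame (e1, e2) is continuous along the whole path.
    """
    arc_len = math.pi * _ARC_RADIUS
    if s <= leg:
        point = np.array([0.0, 0.0, s])
        tangent = np.array([0.0, 0.0, 1.0])
    elif s <= leg + arc_len:
        phi = (s - leg) / _ARC_RADIUS  # 0..pi around the turn
        center = np.array([_ARC_RADIUS, 0.0, leg])
        point = center + _ARC_RADIUS * np.array([-math.cos(phi), 0.0, math.sin(phi)])
        tangent = np.array([math.sin(phi), 0.0, math.cos(phi)])
    else:
        t = s - leg - arc_len
        point = np.array([2 * _ARC_RADIUS, 0.0, leg - t])
        tangent = np.array([0.0, 0.0, -1.0])
    e1 = np.array([0.0, 1.0, 0.0])  # y is transverse everywhere (path in x-z)
    e2 = np.cross(tangent, e1)
    return point, e1, e2


def make_toy_structure(
    n: int = 64, seed: int = 0, model_id: str = "toy"
) -> StructureModel:
    """Compact ideal-geometry helix-turn-helix fold of ``n`` residues.

    CA positions coil (3.6 residues/turn, 1.5 Å rise, 2.3 Å radius) around an
    axis path that rises, U-turns, and descends, packing two antiparallel
    helices ~11 Å apart; consecutive CA-CA distances are ~3.8 Å.  Backbone N
    and C atoms point toward the flanking CAs and every residue gets an
    ideal-geometry CB, so mid-fold residues bury their side chains against the
    partner helix while termini stay exposed.  The sequence is drawn from a
    fixed alphabet; coordinates depend only on ``n``, the sequence only on
    ``seed``.
    """
    if n < 8:
        raise InputError(f"toy structure needs n >= 8, got {n}")
    total_axis = _HELIX_RISE * (n - 1)
    leg = max((total_axis - math.pi * _ARC_RADIUS) / 2.0, 0.0)
    ca = np.empty((n, 3))
    for i in range(n):
        s = _HELIX_RISE * i
        point, e1, e2 = _axis_frame(s, leg)
        phase = 2.0 * math.pi * s / _HELIX_PITCH
        ca[i] = point + _HELIX_RADIUS * (math.cos(phase) * e1 + math.sin(phase) * e2)

    rng = np.random.default_rng(seed)
    sequence = [str(rng.choice(_ALPHABET)) for _ in range(n)]
    if not any(t in MODELABLE_TYPES for t in sequence):
        sequence[2] = "LEU"  # guarantee at least one labeling probe

    residues = []
    for i in range(n):
        prev_dir = ca[i - 1] - ca[i] if i > 0 else ca[1] - ca[2]
        next_dir = ca[i + 1] - ca[i] if i < n - 1 else ca[n - 2] - ca[n - 3]
        n_at = ca[i] + 1.46 * prev_dir / np.linalg.norm(prev_dir)
        c_at = ca[i] + 1.52 * next_dir / np.linalg.norm(next_dir)
        cb = pseudo_cb(tuple(n_at), tuple(ca[i]), tuple(c_at))
        residues.append(
            Residue(
                position=i + 1,
                restype=sequence[i],
                ca=tuple(ca[i]),
                cb=cb,
                n=tuple(n_at),
                c=tuple(c_at),
            )
        )
    return StructureModel(model_id=model_id, residues=tuple(residues))


def make_decoys(
    model: StructureModel, sigma: float, count: int, seed: int = 0
) -> list[tuple[StructureModel, float]]:
    """Gaussian-perturbation decoys with their realized accuracy.

    Each decoy displaces every atom of every residue independently by
    N(0, sigma^2) per coordinate; the returned pairs carry the post-
    superposition CA RMSD to the parent, so discrimination tests know each
    decoy's true deviation.
    """
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    decoys = []
    for k in range(count):
        residues = []
        for r in model.residues:
            coords = {}
            for name, value in (("ca", r.ca), ("cb", r.cb), ("n", r.n), ("c", r.c)):
                if value is None:
                    coords[name] = None
                else:
                    coords[name] = tuple(np.asarray(value) + rng.normal(0.0, sigma, 3))
            residues.append(
                Residue(position=r.position, restype=r.restype, **coords)
            )
        decoy = StructureModel(
            model_id=f"{model.model_id}_s{sigma:g}_{k:04d}", residues=tuple(residues)
        )
        rmsd, _ = kabsch_rmsd_ca(decoy, model)
        decoys.append((decoy, rmsd))
    return decoys


@dataclass(frozen=True)
class LabelingDataset:
    """Synthetic labeling study: input tables plus their ground truth."""

    isotopologue_table: pd.DataFrame
    fragment_table: pd.DataFrame
    dose_table: pd.DataFrame  # dose_id, x (|ΔA| of the adenine dosimeter)
    ground_truth: pd.DataFrame  # residue, restype, nc, lnpf, slope

    def write(self, out_dir) -> dict[str, str]:
        """Write all tables as CSV into ``out_dir``; returns name -> path."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("isotopologues", self.isotopologue_table),
            ("fragments", self.fragment_table),
            ("doses", self.dose_table),
            ("ground_truth", self.ground_truth),
        ):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = str(path)
        return paths


def _peptide_spans(n: int, length: int) -> list[tuple[int, int]]:
    """Partition 1..n into contiguous peptides of ~length residues."""
    spans = []
    start = 1
    while start <= n:
        end = min(start + length - 1, n)
        if n - end < 4 and end < n:  # avoid a tiny terminal peptide
            end = n
        spans.append((start, end))
        start = end + 1
    return spans


def simulate_labeling(model: StructureModel, spec: SimulationSpec) -> LabelingDataset:
    """Forward-simulate a labeling study from a structure's neighbor counts.

    Inverts the analysis chain: NC -> ground-truth lnPF through the inverse
    calibration, lnPF -> dose-response slope via slope = R * exp(-lnPF), then
    labeled oxidation events y = slope * x + background (+ Gaussian noise) per
    dose and replicate.  Events are rendered as peptide isotopologue areas
    (recoverable peptide-level mean) and complete adjacent z-ion ladders
    (telescoping by construction), with no-laser controls at the constant
    background level.  With ``noise_sigma = 0`` the full quantification
    pipeline recovers the ground-truth lnPF exactly.
    """
    rng = np.random.default_rng(spec.seed)
    nc = neighbor_count_profile(model, spec.nc_params)
    rows_truth = []
    slopes: dict[int, float] = {}
    for r in model.residues:
        restype = normalize_restype(r.restype)
        reactivity = spec.reactivity.get(restype)
        if reactivity is None:
            raise InputError(f"no reactivity for residue type {restype}")
        lnpf_true = (nc[r.position] - spec.calibration_b) / spec.calibration_m
        slope = reactivity * math.exp(-lnpf_true)
        slopes[r.position] = slope
        rows_truth.append(
            {
                "residue": r.position,
                "restype": restype,
                "nc": nc[r.position],
                "lnpf": lnpf_true,
                "slope": slope,
            }
        )

    spans = _peptide_spans(len(model), spec.peptide_length)
    iso_rows, frag_rows = [], []
    scale = 1000.0  # arbitrary area unit; all ratios are scale-invariant
    for span_start, span_end in spans:
        pid = f"pep{span_start:03d}_{span_end:03d}"
        positions = list(range(span_start, span_end + 1))
        for condition in ("labeled", "control"):
            for dose_id, x in spec.dose_levels.items():
                for rep in range(1, spec.n_replicates + 1):
                    if condition == "labeled":
                        events = np.array(
                            [
                                slopes[p] * x
                                + spec.background
                                + rng.normal(0.0, spec.noise_sigma)
                                for p in positions
                            ]
                        )
                        events = np.maximum(events, 0.0)
                    else:
                        # controls carry the systematic background only
                        events = np.full(len(positions), spec.background)
                    total = float(events.sum())
                    k = max(1, math.ceil(total)) if total > 0 else 1
                    meta = {
                        "peptide_id": pid,
                        "span_start": span_start,
                        "span_end": span_end,
                        "condition": condition,
                        "dose_id": dose_id,
                        "replicate": rep,
                    }
                    iso_rows.append({**meta, "n_ox": 0, "area": (1.0 - total / k) * scale})
                    iso_rows.append({**meta, "n_ox": k, "area": (total / k) * scale})
                    # complete adjacent z ladder: f_i covers the last i residues
                    cum = np.cumsum(events[::-1])
                    for i, c in enumerate(cum, start=1):
                        f = min(max(c / total, 0.0), 1.0) if total > 0 else 0.0
                        frag_rows.append(
                            {
                                **meta,
                                "series": "z",
                                "index": i,
                                "oxidized_area": f * scale,
                                "unoxidized_area": (1.0 - f) * scale,
                            }
                        )

    return LabelingDataset(
        isotopologue_table=pd.DataFrame(iso_rows),
        fragment_table=pd.DataFrame(frag_rows),
        dose_table=pd.DataFrame(
            {"dose_id": list(spec.dose_levels), "x": list(spec.dose_levels.values())}
        ),
        ground_truth=pd.DataFrame(rows_truth),
    )
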