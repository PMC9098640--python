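"""Conical neighbor counts and the lnPF <-> burial calibration.

The conical neighbor count (NC) is a side-chain burial metric: each other
residue j contributes the product of a logistic distance weight on the
CB_i-CB_j separation and a logistic angular weight on the angle between
residue i's side-chain direction (CA_i -> CB_i) and the direction to the
neighbor, so only neighbors roughly within a cone around the side chain count.
Because hydroxyl radical labeling probes side-chain solvent exposure, lnPF
correlates linearly with NC; the calibration line fitted (or supplied) here
converts measured lnPF into a predicted NC that candidate models are scored
against.

Distance/angle weight constants live in :class:`NeighborCountParams` so
alternative parameterizations can be swapped without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

from hrpfkit.errors import (
    ComputationError,
    DegenerateDesignError,
    DegenerateGeometryError,
    InputError,
)

__all__ = [
    "Residue",
    "StructureModel",
    "CalibrationLine",
    "NeighborCountParams",
    "pseudo_cb",
    "conical_neighbor_count",
    "neighbor_count_profile",
    "fit_calibration",
    "predict_nc",
    "read_structures",
    "write_structures",
]

_CA_CB_LENGTH = 1.53  # Å, ideal CA-CB bond
_TETRAHEDRAL = math.acos(-1.0 / 3.0)  # 109.47°


@dataclass(frozen=True)
class Residue:
    """One residue's coordinates (Å). CB may be a pseudo-CB (Gly)."""

    position: int
    restype: str
    ca: tuple[float, float, float]
    cb: tuple[float, float, float]
    n: tuple[float, float, float] | None = None
    c: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class StructureModel:
    """A candidate structural model: ordered unique residue positions."""

    model_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if len(set(positions)) != len(positions):
            raise InputError(f"{self.model_id}: duplicate residue positions")
        if positions != sorted(positions):
            raise InputError(f"{self.model_id}: residue positions not ordered")
        for r in self.residues:
            for coord in (r.ca, r.cb):
                if not all(math.isfinite(v) for v in coord):
                    raise InputError(f"{self.model_id}: non-finite coordinate at {r.position}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def residue(self, position: int) -> Residue:
        for r in self.residues:
            if r.position == position:
                return r
        raise InputError(f"{self.model_id}: no residue at position {position}")

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def cb_array(self) -> np.ndarray:
        return np.array([r.cb for r in self.residues], dtype=float)


@dataclass(frozen=True)
class CalibrationLine:
    """Linear relation NC = m * lnPF + b (m in NC per lnPF unit)."""

    m: float
    b: float
    r: float | None = None  # Pearson r when fitted from data

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and math.isfinite(self.b)):
            raise InputError("calibration coefficients must be finite")
        if self.m == 0:
            raise InputError("calibration slope must be non-zero")


@dataclass(frozen=True)
class NeighborCountParams:
    """Logistic weight constants for the conical neighbor count.

    Distance weight D(d) = 1/(1 + exp(k_d * (d - d_mid))), midpoint 9 Å;
    angle weight A(θ) = 1/(1 + exp(k_a * (θ - θ_mid))), cone midpoint 90°
    with steepness 2π per radian.
    """

    dist_midpoint: float = 9.0  # Å
    dist_steepness: float = 1.0  # per Å
    angle_midpoint: float = math.pi / 2  # rad
    angle_steepness: float = 2 * math.pi  # per rad


def pseudo_cb(
    n: tuple[float, float, float],
    ca: tuple[float, float, float],
    c: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Ideal side-chain (CB) position from backbone N, CA, C geometry.

    Places CB 1.53 Å from CA along the tetrahedral direction making equal
    angles (109.47°) with the CA->N and CA->C bonds, on the L-amino-acid side
    of the backbone plane.  Used for Gly, which has no real CB.

    Raises :class:`DegenerateGeometryError` for collinear backbone atoms.
    """
    n_v = np.asarray(n, dtype=float)
    ca_v = np.asarray(ca, dtype=float)
    c_v = np.asarray(c, dtype=float)
    u = n_v - ca_v
    v = c_v - ca_v
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("coincident backbone atoms")
    u /= nu
    v /= nv
    perp = np.cross(u, v)
    nperp = np.linalg.norm(perp)
    if nperp < 1e-8:
        raise DegenerateGeometryError("collinear backbone atoms N-CA-C")
    perp /= nperp
    bisector = u + v
    bisector /= np.linalg.norm(bisector)
    # cos of the half N-CA-C angle; CB direction d = -cosw*bisector - sinw*perp
    # satisfies angle(d, u) = angle(d, v) = tetrahedral when
    # cosw * cos(half_angle) = -cos(tetrahedral) = 1/3.
    cos_half = float(u @ bisector)
    cos_w = -math.cos(_TETRAHEDRAL) / cos_half
    if not -1.0 <= cos_w <= 1.0:
        raise DegenerateGeometryError("backbone angle too close to linear for CB")
    sin_w = math.sqrt(1.0 - cos_w * cos_w)
    direction = -cos_w * bisector + sin_w * perp
    cb = ca_v + _CA_CB_LENGTH * direction
    return (float(cb[0]), float(cb[1]), float(cb[2]))


def conical_neighbor_count(
    model: StructureModel,
    position: int,
    params: NeighborCountParams = NeighborCountParams(),
) -> float:
    """Conical neighbor count of one residue.

    NC_i = Σ_{j≠i} D(|CB_j − CB_i|) · A(θ_ij) with θ_ij the angle between the
    side-chain vector CB_i − CA_i and the neighbor direction CB_j − CB_i.
    Each term lies in (0, 1), so 0 ≤ NC ≤ N−1.
    """
    profile = neighbor_count_profile(model, params)
    try:
        return profile[position]
    except KeyError:
        raise InputError(f"{model.model_id}: no residue at position {position}") from None


def neighbor_count_profile(
    model: StructureModel, params: NeighborCountParams = NeighborCountParams()
) -> dict[int, float]:
    """Conical neighbor counts for every residue of a model (vectorized)."""
    n = len(model)
    if n == 0:
        return {}
    ca = model.ca_array()
    cb = model.cb_array()
    side = cb - ca  # (n, 3) side-chain vectors
    side_norm = np.linalg.norm(side, axis=1)
    if np.any(side_norm == 0):
        bad = [model.residues[i].position for i in np.nonzero(side_norm == 0)[0]]
        raise ComputationError(f"{model.model_id}: zero-length side-chain vector at {bad}")
    diff = cb[None, :, :] - cb[:, None, :]  # diff[i, j] = CB_j - CB_i
    dist = np.linalg.norm(diff, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.einsum("ijk,ik->ij", diff, side) / (dist * side_norm[:, None])
    cosang = np.clip(cosang, -1.0, 1.0)
    theta = np.arccos(cosang)
    d_w = 1.0 / (1.0 + np.exp(params.dist_steepness * (dist - params.dist_midpoint)))
    a_w = 1.0 / (1.0 + np.exp(params.angle_steepness * (theta - params.angle_midpoint)))
    contrib = d_w * a_w
    np.fill_diagonal(contrib, 0.0)
    # coincident CBs (dist 0 off-diagonal) have undefined angle; count fully
    off_diag_zero = (dist == 0) & ~np.eye(n, dtype=bool)
    contrib[off_diag_zero] = 0.5  # D(0)≈1, angle undefined -> neutral A weight
    nc = contrib.sum(axis=1)
    return {model.residues[i].position: float(nc[i]) for i in range(n)}


def fit_calibration(pairs: list[tuple[float, float]]) -> CalibrationLine:
    """Ordinary least-squares line NC = m·lnPF + b from (lnPF, NC) pairs.

    Reports the Pearson correlation alongside.  Raises
    :class:`DegenerateDesignError` when all lnPF values coincide.
    """
    if len(pairs) < 2:
        raise InputError("need at least 2 calibration pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]):
        raise DegenerateDesignError("all lnPF values identical; line undefined")
    res = stats.linregress(x, y)
    return CalibrationLine(m=float(res.slope), b=float(res.intercept), r=float(res.rvalue))


def predict_nc(lnpf_value: float, calib: CalibrationLine) -> tuple[float, bool]:
    """Predicted neighbor count for a measured lnPF.

    Evaluates m·lnPF + b; a negative prediction (outside the physical range)
    is clamped to 0 and flagged.  Returns ``(nc, clamped)``.
    """
    if not math.isfinite(lnpf_value):
        raise InputError("lnPF must be finite")
    value = calib.m * lnpf_value + calib.b
    if value < 0:
        return 0.0, True
    return value, False


# ---------------------------------------------------------------------------
# PDB I/O (gemmi)
# ---------------------------------------------------------------------------


def _pick_atom(res: gemmi.Residue, name: str):
    atom = res.find_atom(name, "*")
    if atom is None:
        return None
    return (atom.pos.x, atom.pos.y, atom.pos.z)


def read_structures(path, chain: str | None = None) -> list[StructureModel]:
    """Read single- or multi-MODEL PDB into :class:`StructureModel` objects.

    Takes the first chain unless ``chain`` names one.  Gly (or any residue
    missing CB) gets a pseudo-CB from backbone geometry; residues lacking both
    CB and a complete backbone are skipped.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models = []
    for gm in st:
        if chain is None:
            if len(gm) == 0:
                continue
            gchain = gm[0]
        else:
            gchain = gm.find_chain(chain)
            if gchain is None:
                raise InputError(f"chain {chain!r} not found in {path}")
        residues = []
        for res in gchain:
            ca = _pick_atom(res, "CA")
            if ca is None:
                continue
            cb = _pick_atom(res, "CB")
            n_at = _pick_atom(res, "N")
            c_at = _pick_atom(res, "C")
            if cb is None:
                if n_at is None or c_at is None:
                    continue
                cb = pseudo_cb(n_at, ca, c_at)
            residues.append(
                Residue(
                    position=res.seqid.num,
                    restype=res.name.upper(),
                    ca=ca,
                    cb=cb,
                    n=n_at,
                    c=c_at,
                )
            )
        models.append(
            StructureModel(model_id=str(gm.num), residues=tuple(residues))
        )
    if not models:
        raise InputError(f"no models found in {path}")
    return models


def write_structures(models: list[StructureModel], path) -> None:
    """Write models as a multi-MODEL PDB file (chain A, backbone + CB)."""
    st = gemmi.Structure()
    st.name = "hrpfkit"
    for k, model in enumerate(models, start=1):
        gm = gemmi.Model(k)
        chain = gemmi.Chain("A")
        for r in model.residues:
            res = gemmi.Residue()
            res.name = r.restype
            res.seqid = gemmi.SeqId(r.position, " ")
            for name, coord, element in (
                ("N", r.n, "N"),
                ("CA", r.ca, "C"),
                ("C", r.c, "C"),
                ("CB", r.cb, "C"),
            ):
                if coord is None:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*coord)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
        st.add_model(gm)
    st.write_pdb(str(path))


def nc_profile_table(profiles: dict[str, dict[int, float]]) -> pd.DataFrame:
    """Tidy NC table: model_id, residue, nc."""
    rows = [
        {"model_id": mid, "residue": pos, "nc": nc}
        for mid, profile in profiles.items()
        for pos, nc in sorted(profile.items())
    ]
    return pd.DataFrame(rows)
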