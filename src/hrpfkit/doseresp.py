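"""Radical dose-response fitting and protection factors.

Under FPOP conditions the oxidation of a residue is proportional to the
effective radical dose, reported by the change in adenine dosimeter absorbance.
The per-residue dose response is therefore fit as a straight line through the
origin (no dose, no labeling beyond background); the protection factor is the
residue type's intrinsic reactivity divided by that slope,

    lnPF_i = ln(R_i / Slope_i),

so a buried residue (small slope relative to its intrinsic reactivity) has a
large lnPF.  Only Trp, Phe, Tyr, His and Leu carry lnPF into structural
scoring: sulfur-containing residues suffer uncontrolled secondary oxidation
and low-reactivity types are dominated by sequence-context effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hrpfkit.errors import ComputationError, DegenerateDesignError, InputError

__all__ = [
    "DoseResponsePoint",
    "SlopeFit",
    "ProtectionRecord",
    "MODELABLE_TYPES",
    "EXCLUDED_SULFUR_TYPES",
    "fit_dose_response",
    "lnpf",
    "select_modelable",
    "load_reactivity_table",
    "protection_table",
]

#: Residue types whose lnPF is carried into structural scoring.
MODELABLE_TYPES = frozenset({"TRP", "PHE", "TYR", "HIS", "LEU"})

#: Always removed: prone to uncontrolled secondary oxidation.
EXCLUDED_SULFUR_TYPES = frozenset({"MET", "CYS"})

_THREE_FROM_ONE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def normalize_restype(name: str) -> str:
    """Canonical three-letter upper-case residue type from 1- or 3-letter code."""
    name = name.strip().upper()
    if len(name) == 1:
        try:
            return _THREE_FROM_ONE[name]
        except KeyError:
            raise InputError(f"unknown residue code {name!r}") from None
    if name not in _THREE_FROM_ONE.values():
        raise InputError(f"unknown residue type {name!r}")
    return name


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (dose, response) observation for one residue.

    ``x`` is the magnitude of the adenine absorbance change for that dose
    condition (absorbance units); ``y`` is the background-corrected oxidation
    events of the residue.
    """

    residue: int
    x: float
    y: float
    dose_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.x < 0:
            raise InputError("dosimeter response x must be >= 0")


@dataclass(frozen=True)
class SlopeFit:
    """Through-origin regression slope with its 95% confidence interval."""

    residue: int
    slope: float
    ci_low: float
    ci_high: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ComputationError("slope CI must bracket the estimate")
        if self.n_points < 2:
            raise ComputationError("slope fit needs >= 2 points")


@dataclass(frozen=True)
class ProtectionRecord:
    """Per-residue protection factor on the natural-log scale.

    ``excluded_reason`` is non-empty for residues that carry no usable lnPF
    (non-positive slope); such records hold NaN lnPF and are dropped by
    :func:`select_modelable`.
    """

    residue: int
    restype: str
    lnpf: float
    ci_low: float
    ci_high: float
    excluded_reason: str = ""

    def __post_init__(self) -> None:
        if not self.excluded_reason and not (self.ci_low <= self.lnpf <= self.ci_high):
            raise ComputationError("lnPF CI must bracket the estimate")


def fit_dose_response(points: Sequence[DoseResponsePoint]) -> SlopeFit:
    """Least-squares line through the origin with a t-based 95% CI.

    slope = Σxy / Σx²; the residual variance s² = Σ(y − slope·x)²/(n−1) gives
    SE(slope) = sqrt(s²/Σx²) and the CI uses the t distribution with n−1
    degrees of freedom (one parameter estimated).

    Raises :class:`DegenerateDesignError` when every x is zero.
    """
    if len(points) < 2:
        raise InputError("need at least 2 dose-response points")
    residues = {p.residue for p in points}
    if len(residues) != 1:
        raise InputError(f"points span multiple residues: {sorted(residues)}")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateDesignError("all dosimeter responses are zero")
    slope = float(x @ y) / sxx
    n = len(points)
    resid = y - slope * x
    s2 = float(resid @ resid) / (n - 1)
    se = math.sqrt(s2 / sxx)
    half = stats.t.ppf(0.975, n - 1) * se
    return SlopeFit(
        residue=points[0].residue,
        slope=slope,
        ci_low=slope - half,
        ci_high=slope + half,
        n_points=n,
    )


def lnpf(restype: str, reactivity: float, fit: SlopeFit) -> ProtectionRecord:
    """Protection factor lnPF = ln(R / slope) with a transformed CI.

    The slope CI maps through the strictly decreasing x -> ln(R/x), so
    [slope_lo, slope_hi] becomes [ln(R/slope_hi), ln(R/slope_lo)] exactly —
    no delta-method approximation.  A non-positive slope (no measurable dose
    response) yields an excluded record rather than an exception; a CI bound
    at or below zero maps to an infinite lnPF bound.
    """
    restype = normalize_restype(restype)
    if reactivity <= 0:
        raise InputError(f"intrinsic reactivity must be > 0, got {reactivity}")
    if fit.slope <= 0:
        return ProtectionRecord(
            residue=fit.residue,
            restype=restype,
            lnpf=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            excluded_reason="non-positive dose-response slope: PF undefined",
        )
    value = math.log(reactivity / fit.slope)
    ci_low = math.log(reactivity / fit.ci_high) if fit.ci_high > 0 else float("-inf")
    ci_high = math.log(reactivity / fit.ci_low) if fit.ci_low > 0 else float("inf")
    return ProtectionRecord(
        residue=fit.residue,
        restype=restype,
        lnpf=value,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def select_modelable(
    records: Iterable[ProtectionRecord],
    modelable: frozenset[str] | set[str] = MODELABLE_TYPES,
) -> tuple[list[ProtectionRecord], list[tuple[ProtectionRecord, str]]]:
    """Filter protection records to the modelable residue types.

    Keeps exactly the modelable set (default Trp/Phe/Tyr/His/Leu); Met and Cys
    are removed regardless of the override.  Returns ``(kept, excluded)`` where
    each exclusion carries its reason, so runs can log why residues dropped out.
    """
    modelable = {normalize_restype(t) for t in modelable} - EXCLUDED_SULFUR_TYPES
    kept: list[ProtectionRecord] = []
    excluded: list[tuple[ProtectionRecord, str]] = []
    for rec in records:
        if rec.excluded_reason:
            excluded.append((rec, rec.excluded_reason))
        elif rec.restype in EXCLUDED_SULFUR_TYPES:
            excluded.append((rec, "sulfur-containing type (secondary oxidation)"))
        elif rec.restype not in modelable:
            excluded.append((rec, f"{rec.restype} not in modelable set"))
        else:
            kept.append(rec)
    return kept, excluded


def load_reactivity_table(path=None) -> dict[str, float]:
    """Load an intrinsic-reactivity table: residue type -> R (> 0).

    With no path, loads the synthetic placeholder table shipped with the
    package (``data/intrinsic_reactivity_synthetic.csv``) — an internally
    consistent set of made-up values for demonstration only; real analyses
    must supply measured free-amino-acid reactivities.
    """
    if path is None:
        path = resources.files("hrpfkit.data").joinpath(
            "intrinsic_reactivity_synthetic.csv"
        )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"restype", "reactivity"} <= set(df.columns):
        raise InputError("reactivity table needs columns: restype, reactivity")
    table: dict[str, float] = {}
    for _, row in df.iterrows():
        r = float(row["reactivity"])
        if r <= 0:
            raise InputError(f"reactivity must be > 0 ({row['restype']}: {r})")
        table[normalize_restype(str(row["restype"]))] = r
    return table


def protection_table(
    records: Sequence[ProtectionRecord],
    fits: Mapping[int, SlopeFit] | None = None,
) -> pd.DataFrame:
    """Tidy lnPF table: residue, type, slope + CI, lnPF + CI, exclusion."""
    rows = []
    for rec in records:
        fit = fits.get(rec.residue) if fits else None
        rows.append(
            {
                "residue": rec.residue,
                "restype": rec.restype,
                "slope": fit.slope if fit else np.nan,
                "slope_ci_low": fit.ci_low if fit else np.nan,
                "slope_ci_high": fit.ci_high if fit else np.nan,
                "lnpf": rec.lnpf,
                "lnpf_ci_low": rec.ci_low,
                "lnpf_ci_high": rec.ci_high,
                "excluded_reason": rec.excluded_reason,
            }
        )
    return pd.DataFrame(rows)
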