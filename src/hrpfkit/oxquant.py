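"""Peptide- and residue-level oxidation quantification from intensity tables.

FPOP labeling installs net +16 Da (and multiples) on side chains.  Peptide-level
extent is quantified from the isotopologue intensity distribution (area under
the curve of the k-times-oxidized forms); residue-level extent is localized with
ETD c/z sequence ions, whose oxidation fractions telescope along the ladder:
the difference between two consecutive ions' fractions, times the peptide-level
events, is the oxidation carried by the residues that separate them.  Background
oxidation (no-laser controls) is subtracted per residue per dose.

All intensities are taken as already-integrated areas; no spectral processing
happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hrpfkit.errors import (
    EmptySignalError,
    InputError,
    MissingIonError,
    UnmatchedControlError,
)

__all__ = [
    "OxidationStateDistribution",
    "FragmentLadder",
    "ResidueOxidation",
    "peptide_mean_oxidation",
    "ion_oxidation_fraction",
    "residue_oxidation_from_ladder",
    "background_subtract",
    "read_isotopologue_table",
    "read_fragment_table",
    "residue_table",
]


@dataclass(frozen=True)
class OxidationStateDistribution:
    """Isotopologue intensity distribution of one peptide.

    ``intensities[k]`` is the integrated area of the k-times-oxidized form;
    index 0 is the unoxidized peptide.  ``span`` is the 1-based inclusive
    residue interval of the peptide in the protein.
    """

    peptide_id: str
    span: tuple[int, int]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        start, end = self.span
        if end < start or start < 1:
            raise InputError(f"invalid span {self.span} for {self.peptide_id}")
        if len(self.intensities) == 0:
            raise InputError(f"empty intensity list for {self.peptide_id}")
        if any(v < 0 for v in self.intensities):
            raise InputError(f"negative intensity for {self.peptide_id}")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass(frozen=True)
class FragmentLadder:
    """c- or z-ion ladder of one peptide in one condition.

    Each entry is ``(index, oxidized_area, unoxidized_area)``; ``index`` i is
    the number of residues the ion covers counted from the series' terminus
    (c ions from the N-terminus, z ions from the C-terminus).  ``span`` is the
    peptide's 1-based inclusive interval in the protein, needed to map ion
    indices to protein positions.
    """

    peptide_id: str
    ion_series: str
    span: tuple[int, int]
    entries: tuple[tuple[int, float, float], ...]
    condition: str = "labeled"
    dose_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ion_series not in ("c", "z"):
            raise InputError(f"ion series must be 'c' or 'z', got {self.ion_series!r}")
        if self.condition not in ("labeled", "control"):
            raise InputError(f"condition must be labeled/control, got {self.condition!r}")
        if self.replicate < 1:
            raise InputError("replicate must be >= 1")
        length = self.span[1] - self.span[0] + 1
        indices = [e[0] for e in self.entries]
        if any(i2 <= i1 for i1, i2 in zip(indices, indices[1:])):
            raise InputError(f"{self.peptide_id}: ion indices must be strictly increasing")
        if indices and (indices[0] < 1 or indices[-1] > length):
            raise InputError(
                f"{self.peptide_id}: ion index outside 1..{length} (peptide length)"
            )
        if any(e[1] < 0 or e[2] < 0 for e in self.entries):
            raise InputError(f"{self.peptide_id}: negative fragment intensity")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass(frozen=True)
class ResidueOxidation:
    """Oxidation events assigned to one residue or a contiguous residue group.

    ``residues`` is the 1-based inclusive protein interval the events cover;
    single-residue records have ``residues[0] == residues[1]``.  ``noise_flag``
    marks negative event counts (measurement noise), which are preserved.
    """

    residues: tuple[int, int]
    events: float
    condition: str
    dose_id: str
    replicate: int
    peptide_id: str = ""
    noise_flag: bool = False

    def __post_init__(self) -> None:
        if self.residues[1] < self.residues[0]:
            raise InputError(f"invalid residue group {self.residues}")
        if self.replicate < 1:
            raise InputError("replicate must be >= 1")

    @property
    def is_single(self) -> bool:
        return self.residues[0] == self.residues[1]


def peptide_mean_oxidation(dist: OxidationStateDistribution) -> float:
    """Average oxidation events per peptide.

    Computes sum_k k*I_k / sum_k I_k over the isotopologue distribution:
    each oxidized form's area is weighted by the number of oxidation events
    needed to produce it.  Invariant under uniform rescaling of all areas.

    Raises :class:`EmptySignalError` when all intensities are zero.
    """
    areas = np.asarray(dist.intensities, dtype=float)
    total = areas.sum()
    if total <= 0.0:
        raise EmptySignalError(f"all-zero intensities for {dist.peptide_id}")
    k = np.arange(len(areas), dtype=float)
    return float((k * areas).sum() / total)


def ion_oxidation_fraction(oxidized: float, unoxidized: float) -> float:
    """Oxidation fraction of one sequence ion: ox / (ox + unox).

    Raises :class:`MissingIonError` when both areas are zero — the ion is
    absent from the spectra, which is distinct from an ion observed fully
    unoxidized.
    """
    if oxidized < 0 or unoxidized < 0:
        raise InputError("fragment intensities must be non-negative")
    total = oxidized + unoxidized
    if total == 0:
        raise MissingIonError("both oxidized and unoxidized intensities are zero")
    return oxidized / total


def _group_span(ladder: FragmentLadder, j: int, i: int) -> tuple[int, int]:
    """Protein interval covered by ion i but not ion j (j < i)."""
    start, end = ladder.span
    if ladder.ion_series == "c":
        return (start + j, start + i - 1)
    return (end - i + 1, end - j)


def residue_oxidation_from_ladder(
    ladder: FragmentLadder, peptide_events: float
) -> list[ResidueOxidation]:
    """Distribute peptide-level oxidation onto residues via the ion ladder.

    For consecutive available ion indices i > j, the residue group separating
    them receives events = [f(ion_i) - f(ion_j)] * P, with f(ion_0) == 0
    anchoring the ladder.  Adjacent indices give single-residue records;
    gaps give contiguous-group records.  The emitted events telescope:
    their sum equals f(ion_imax) * P.

    Negative differences (f decreasing along the ladder — measurement noise)
    are emitted with ``noise_flag=True``, never clamped.
    """
    if peptide_events < 0:
        raise InputError("peptide-level events must be non-negative")
    records: list[ResidueOxidation] = []
    prev_index = 0
    prev_fraction = 0.0
    for index, oxidized, unoxidized in ladder.entries:
        fraction = ion_oxidation_fraction(oxidized, unoxidized)
        events = (fraction - prev_fraction) * peptide_events
        records.append(
            ResidueOxidation(
                residues=_group_span(ladder, prev_index, index),
                events=events,
                condition=ladder.condition,
                dose_id=ladder.dose_id,
                replicate=ladder.replicate,
                peptide_id=ladder.peptide_id,
                noise_flag=events < 0,
            )
        )
        prev_index, prev_fraction = index, fraction
    return records


def background_subtract(
    labeled: Iterable[ResidueOxidation], control: Iterable[ResidueOxidation]
) -> list[ResidueOxidation]:
    """Subtract mean background (no-laser control) oxidation per residue group.

    Records are matched on (residue group, dose_id); control replicates are
    averaged before subtraction.  Negative corrected events are retained and
    flagged rather than clamped, so downstream zero-intercept regression sees
    noise symmetrically.

    Raises :class:`UnmatchedControlError` listing every labeled group that has
    no control counterpart.
    """
    control_sums: dict[tuple[tuple[int, int], str], list[float]] = {}
    for rec in control:
        control_sums.setdefault((rec.residues, rec.dose_id), []).append(rec.events)
    control_means = {key: float(np.mean(v)) for key, v in control_sums.items()}

    labeled = list(labeled)
    missing = {
        rec.residues
        for rec in labeled
        if (rec.residues, rec.dose_id) not in control_means
    }
    if missing:
        raise UnmatchedControlError(missing)

    corrected = []
    for rec in labeled:
        events = rec.events - control_means[(rec.residues, rec.dose_id)]
        corrected.append(
            replace(rec, events=events, noise_flag=events < 0)
        )
    return corrected


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

ISOTOPOLOGUE_COLUMNS = [
    "peptide_id",
    "span_start",
    "span_end",
    "n_ox",
    "area",
    "condition",
    "dose_id",
    "replicate",
]
FRAGMENT_COLUMNS = [
    "peptide_id",
    "series",
    "span_start",
    "span_end",
    "index",
    "oxidized_area",
    "unoxidized_area",
    "condition",
    "dose_id",
    "replicate",
]


def read_isotopologue_table(
    path,
) -> dict[tuple[str, str, str, int], OxidationStateDistribution]:
    """Read a peptide isotopologue area table (CSV) into distributions.

    Expected columns: peptide_id, span_start, span_end, n_ox, area, condition,
    dose_id, replicate.  One distribution is built per (peptide, condition,
    dose, replicate); absent oxidation states are zero.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(ISOTOPOLOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"isotopologue table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str, str, int], OxidationStateDistribution] = {}
    keys = ["peptide_id", "condition", "dose_id", "replicate"]
    for (pid, condition, dose_id, rep), grp in df.groupby(keys, sort=True):
        spans = grp[["span_start", "span_end"]].drop_duplicates()
        if len(spans) != 1:
            raise InputError(f"inconsistent span for peptide {pid}")
        span = (int(spans.iloc[0, 0]), int(spans.iloc[0, 1]))
        k_max = int(grp["n_ox"].max())
        areas = np.zeros(k_max + 1)
        for _, row in grp.iterrows():
            areas[int(row["n_ox"])] += float(row["area"])
        out[(str(pid), str(condition), str(dose_id), int(rep))] = (
            OxidationStateDistribution(
                peptide_id=str(pid), span=span, intensities=tuple(areas)
            )
        )
    return out


def read_fragment_table(path) -> list[FragmentLadder]:
    """Read a fragment-ion area table (CSV) into per-condition ladders.

    Expected columns: peptide_id, series, span_start, span_end, index,
    oxidized_area, unoxidized_area, condition, dose_id, replicate.  One ladder
    is built per (peptide, series, condition, dose, replicate).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FRAGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"fragment table missing columns: {sorted(missing)}")
    ladders = []
    keys = ["peptide_id", "series", "condition", "dose_id", "replicate"]
    for (pid, series, condition, dose_id, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("index")
        spans = grp[["span_start", "span_end"]].drop_duplicates()
        if len(spans) != 1:
            raise InputError(f"inconsistent span for peptide {pid}")
        ladders.append(
            FragmentLadder(
                peptide_id=str(pid),
                ion_series=str(series),
                span=(int(spans.iloc[0, 0]), int(spans.iloc[0, 1])),
                entries=tuple(
                    (int(r["index"]), float(r["oxidized_area"]), float(r["unoxidized_area"]))
                    for _, r in grp.iterrows()
                ),
                condition=str(condition),
                dose_id=str(dose_id),
                replicate=int(rep),
            )
        )
    return ladders


def residue_table(records: Sequence[ResidueOxidation]) -> pd.DataFrame:
    """Tidy per-residue oxidation table (one row per record)."""
    return pd.DataFrame(
        {
            "res_start": [r.residues[0] for r in records],
            "res_end": [r.residues[1] for r in records],
            "events": [r.events for r in records],
            "condition": [r.condition for r in records],
            "dose_id": [r.dose_id for r in records],
            "replicate": [r.replicate for r in records],
            "peptide_id": [r.peptide_id for r in records],
            "noise_flag": [r.noise_flag for r in records],
        }
    )
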