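"""Matching peak lists to theoretical ions: deisotoping, internal
recalibration, and abundance extraction.

A candidate ion is accepted when at least ``min_isotopologues``
consecutive isotopologue peaks are found within the ppm tolerance and
their intensities correlate with the theoretical envelope (cosine
similarity).  Heavy species whose monoisotopic peak is below the noise
floor may match starting at an isotopologue k > 0, up to the envelope
apex.  Peaks claimed by more than one candidate flag all involved
assignments as ambiguous; ambiguous assignments are excluded from the
statistics by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import PROTON_MASS
from .isotopes import ISOTOPE_SPACING, aggregated_pattern, isotope_pattern
from .peaks import PeakList

__all__ = [
    "FragmentAssignment",
    "CalibrationResult",
    "match_fragments",
    "recalibrate_internal",
    "aggregate_charge_states",
]


@dataclass
class FragmentAssignment:
    """A matched peak-cluster/ion pair: the unit of all statistics."""

    ion: object  # FragmentIon or any candidate with ion_type/index/charge
    abundance: float
    mass_error_ppm: float
    n_isotopologues: int
    mz_obs: float
    mz_theo: float
    flags: set = field(default_factory=set)
    peak_indices: tuple = ()

    @property
    def is_ambiguous(self) -> bool:
        return "ambiguous" in self.flags


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _candidate_pattern(candidate):
    comp = getattr(candidate, "composition", None)
    if comp is not None:
        return aggregated_pattern(comp)
    return isotope_pattern(candidate.neutral_mass, mode="averagine")


def match_fragments(
    peaks: PeakList,
    candidates: list,
    tol_ppm: float = 3.0,
    min_isotopologues: int = 2,
    min_cosine: float = 0.9,
) -> list[FragmentAssignment]:
    """Match a centroided peak list against theoretical candidate ions.

    For each candidate the peak cluster at ``mz + k*1.0033548/z`` is
    located; the assignment's abundance is the sum of matched
    isotopologue intensities and its mass error the intensity-weighted
    mean ppm deviation.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if len(peaks) == 0:
        return []

    mz = peaks.mz
    inten = peaks.intensity
    claims: dict[int, list[int]] = defaultdict(list)
    out: list[FragmentAssignment] = []

    for cand in candidates:
        z = cand.charge
        pattern = _candidate_pattern(cand)
        theo = (cand.neutral_mass + pattern.offsets - z * PROTON_MASS) / z
        # nearest peak per isotopologue, within tolerance
        idx = np.searchsorted(mz, theo)
        nearest = np.empty(len(theo), dtype=int)
        dist = np.empty(len(theo))
        for k in range(len(theo)):
            best, bestd = -1, np.inf
            for j in (idx[k] - 1, idx[k]):
                if 0 <= j < len(mz):
                    d = abs(mz[j] - theo[k])
                    if d < bestd:
                        best, bestd = j, d
            nearest[k] = best
            dist[k] = bestd
        matched = (nearest >= 0) & (dist <= tol_ppm * 1e-6 * theo)

        # maximal consecutive runs of matches; keep the longest whose
        # start does not exceed the envelope apex
        runs = []
        k = 0
        while k < len(matched):
            if matched[k]:
                start = k
                while k < len(matched) and matched[k]:
                    k += 1
                runs.append((start, k))
            else:
                k += 1
        runs = [r for r in runs if r[0] <= pattern.apex and r[1] - r[0] >= min_isotopologues]
        if not runs:
            continue
        start, stop = max(runs, key=lambda r: r[1] - r[0])
        sel = nearest[start:stop]
        obs_int = inten[sel]
        theo_frac = pattern.fractions[start:stop]
        if _cosine(obs_int, theo_frac) < min_cosine:
            continue
        err_ppm = (mz[sel] - theo[start:stop]) / theo[start:stop] * 1e6
        weights = obs_int if obs_int.sum() > 0 else np.ones_like(obs_int)
        mean_err = float(np.average(err_ppm, weights=weights))
        # observed monoisotopic m/z extrapolated from the first matched peak
        mz_obs = float(mz[sel[0]] - start * ISOTOPE_SPACING / z)
        assignment = FragmentAssignment(
            ion=cand,
            abundance=float(obs_int.sum()),
            mass_error_ppm=mean_err,
            n_isotopologues=stop - start,
            mz_obs=mz_obs,
            mz_theo=float(cand.mz),
            peak_indices=tuple(int(j) for j in sel),
        )
        a_i = len(out)
        out.append(assignment)
        for j in sel:
            claims[int(j)].append(a_i)

    for peak_idx, owners in claims.items():
        if len(owners) > 1:
            for a_i in owners:
                out[a_i].flags.add("ambiguous")
    return out


@dataclass
class CalibrationResult:
    """Recalibrated peaks plus the linear model and calibrant residuals."""

    peaks: PeakList
    slope: float
    intercept: float
    residual_ppm_before: np.ndarray
    residual_ppm_after: np.ndarray


def recalibrate_internal(
    peaks: PeakList, calibrant_assignments: list[FragmentAssignment]
) -> CalibrationResult:
    """Internal linear recalibration against assigned calibrant ions.

    Fits theoretical vs observed m/z of the calibrants by least squares
    and applies the correction to every peak.  Requires at least two
    calibrants spanning a non-degenerate m/z range.
    """
    if len(calibrant_assignments) < 2:
        raise ValueError("need >= 2 calibrant assignments")
    obs = np.array([a.mz_obs for a in calibrant_assignments])
    theo = np.array([a.mz_theo for a in calibrant_assignments])
    if np.ptp(obs) < 1e-6:
        raise ValueError("degenerate fit: calibrants span no m/z range")
    slope, intercept = np.polyfit(obs, theo, 1)
    before = (obs - theo) / theo * 1e6
    after = (slope * obs + intercept - theo) / theo * 1e6
    for a in calibrant_assignments:
        a.flags.add("calibrant")
    new_peaks = PeakList(
        slope * peaks.mz + intercept, peaks.intensity.copy(), dict(peaks.metadata)
    )
    return CalibrationResult(
        peaks=new_peaks,
        slope=float(slope),
        intercept=float(intercept),
        residual_ppm_before=before,
        residual_ppm_after=after,
    )


def aggregate_charge_states(
    assignments: list[FragmentAssignment], include_ambiguous: bool = False
) -> pd.DataFrame:
    """Total abundance per (ion_type, index, base_loss) with the
    charge-state breakdown retained for charge-value analysis."""
    rows: dict[tuple, dict] = {}
    for a in assignments:
        if a.is_ambiguous and not include_ambiguous:
            continue
        key = (a.ion.ion_type, a.ion.index, a.ion.base_loss)
        entry = rows.setdefault(
            key,
            {"ion_type": key[0], "index": key[1], "base_loss": key[2],
             "abundance": 0.0, "by_charge": {}},
        )
        entry["abundance"] += a.abundance
        entry["by_charge"][a.ion.charge] = (
            entry["by_charge"].get(a.ion.charge, 0.0) + a.abundance
        )
    df = pd.DataFrame(
        list(rows.values()),
        columns=["ion_type", "index", "base_loss", "abundance", "by_charge"],
    )
    if len(df):
        df = df.sort_values(["ion_type", "index"], ignore_index=True)
    return df
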