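"""Cleavage-yield statistics for CAD of RNA (M - nH)^n- ions.

Site-specific c/y yields (base-loss variants pooled into their parent
fragments), the overall guanosine cleavage yield against its
random-cleavage null, charge-density bookkeeping, the effective
preference factor, fold-change correlation between a modified RNA and
its reference, charge-value distributions, and the overall dissociation
yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import G_FAMILY, RnaSequence
from .fragments import FIVE_PRIME_TYPES, THREE_PRIME_TYPES

__all__ = [
    "CleavageYieldTable",
    "g_sites",
    "site_specific_yields",
    "overall_g_yield",
    "charge_density",
    "deprotonated_fraction",
    "effective_preference_factor",
    "fold_change_correlation",
    "charge_value_distribution",
    "mean_charge_difference",
    "dissociation_yield",
    "render_cleavage_map",
]


def g_sites(
    seq: RnaSequence,
    include_modified: bool = True,
    include_inosine: bool = False,
) -> list[int]:
    """Cleavage sites immediately 5' of a guanosine(-family) residue.

    Site ``k`` is the phosphodiester between residues k and k+1, so a G
    at position p >= 2 marks site p - 1.  Modified guanosines (deaza,
    N2-methyl) count by default; inosine only on request.
    """
    family = set(G_FAMILY) if include_modified else {"G"}
    if include_inosine:
        family.add("I")
    return [p - 1 for p in seq.positions_of(family) if p >= 2]


@dataclass
class CleavageYieldTable:
    """Per-site c/y yields (% of total c+y signal) and derived statistics."""

    data: pd.DataFrame  # columns: site, yield_c, yield_y, g_site
    sequence: RnaSequence
    precursor_charge: int

    @property
    def overall_g_yield(self) -> float:
        """Summed yield over sites 5' of guanosine, in %."""
        return float(
            self.data.loc[self.data["g_site"], ["yield_c", "yield_y"]].sum().sum()
        )

    @property
    def random_expectation(self) -> float:
        """Random-cleavage null: 100 x (sites 5' of G) / (N - 1), in %."""
        n_g = int(self.data["g_site"].sum())
        return 100.0 * n_g / self.sequence.n_sites

    @property
    def charges_per_nt(self) -> float:
        return charge_density(self.precursor_charge, len(self.sequence))


def _aggregated_frame(assignments_or_table) -> pd.DataFrame:
    if isinstance(assignments_or_table, pd.DataFrame):
        return assignments_or_table
    from .assign import aggregate_charge_states

    return aggregate_charge_states(assignments_or_table)


def site_specific_yields(
    aggregated,
    seq: RnaSequence,
    n: int,
    include_modified: bool = True,
    include_inosine: bool = False,
) -> CleavageYieldTable:
    """Per-site yields of c and y fragments relative to all c/y signal.

    ``yield_c(k)`` pools c_k with its base-loss variants; ``yield_y(k)``
    analogously pools y_(N-k).  Other ion types are excluded from the
    normalization.  Raises if no c/y signal was assigned.
    """
    agg = _aggregated_frame(aggregated)
    cy = agg[agg["ion_type"].isin(["c", "y"])] if len(agg) else agg
    total = float(cy["abundance"].sum()) if len(cy) else 0.0
    if total <= 0:
        raise ValueError("no c/y fragments assigned")
    pooled = cy.groupby(["ion_type", "index"])["abundance"].sum()
    marked = set(g_sites(seq, include_modified, include_inosine))
    rows = []
    for k in range(1, seq.n_sites + 1):
        yc = 100.0 * pooled.get(("c", k), 0.0) / total
        yy = 100.0 * pooled.get(("y", len(seq) - k), 0.0) / total
        rows.append(
            {"site": k, "yield_c": yc, "yield_y": yy, "g_site": k in marked}
        )
    return CleavageYieldTable(pd.DataFrame(rows), seq, n)


def overall_g_yield(table: CleavageYieldTable) -> tuple[float, float]:
    """(observed %, random expectation %) of cleavage 5' of guanosine."""
    return table.overall_g_yield, table.random_expectation


def charge_density(n: int, big_n: int) -> float:
    """Precursor charges per nucleotide, rounded to 2 decimals."""
    if big_n < 1:
        raise ValueError("N must be >= 1")
    return round(n / big_n, 2)


def deprotonated_fraction(n: int, big_n: int) -> float:
    """Percentage of phosphodiester moieties deprotonated in (M - nH)^n-.

    The chain has N - 1 phosphodiesters carrying the n charges.
    """
    if big_n < 2:
        raise ValueError("need at least one phosphodiester")
    return 100.0 * n / (big_n - 1)


def effective_preference_factor(
    observed_g_yield: float,
    seq: RnaSequence,
    include_modified: bool = True,
    include_inosine: bool = False,
) -> float:
    """Invert the random-cleavage null into a per-site preference factor.

    ``gamma = [Y/(100-Y)] * [(S - n_G)/n_G]`` with S = N-1 total sites
    and n_G sites 5' of G; gamma = 1 exactly when Y equals the random
    expectation.
    """
    if not 0.0 < observed_g_yield < 100.0:
        raise ValueError("observed yield must lie strictly between 0 and 100")
    n_g = len(g_sites(seq, include_modified, include_inosine))
    s = seq.n_sites
    if n_g == 0 or n_g == s:
        raise ValueError("preference factor undefined without both site classes")
    return (observed_g_yield / (100.0 - observed_g_yield)) * ((s - n_g) / n_g)


def _normalized_cy_signals(assignments) -> dict[tuple, float]:
    sig: dict[tuple, float] = {}
    for a in assignments:
        if a.is_ambiguous:
            continue
        if a.ion.ion_type not in ("c", "y"):
            continue
        key = (a.ion.ion_type, a.ion.index, a.ion.charge, a.ion.base_loss)
        sig[key] = sig.get(key, 0.0) + a.abundance
    total = sum(sig.values())
    if total <= 0:
        raise ValueError("no c/y signal in run")
    return {k: v / total for k, v in sig.items()}


def fold_change_correlation(
    assignments_ref, assignments_mod, site: int, big_n: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Correlate individual c/y fragment signals of two runs and report the
    fold change at one cleavage site.

    Fragments are matched by (ion_type, index, charge, base_loss) after
    per-run normalization to total c/y signal; the fold change is the
    ref/mod ratio of the pooled, normalized (c_k + y_(N-k)) signal.
    """
    ref = _normalized_cy_signals(assignments_ref)
    mod = _normalized_cy_signals(assignments_mod)
    if big_n is None:
        idx = [a.ion.index for a in list(assignments_ref) + list(assignments_mod)]
        big_n = max(idx) + 1 if idx else 0
    keys = sorted(set(ref) | set(mod), key=lambda k: (k[0], k[1], k[2], str(k[3])))
    pairs = pd.DataFrame(
        [
            {
                "ion_type": t, "index": i, "charge": z, "base_loss": bl,
                "signal_ref": ref.get((t, i, z, bl), 0.0),
                "signal_mod": mod.get((t, i, z, bl), 0.0),
            }
            for (t, i, z, bl) in keys
        ]
    )

    def site_sum(sig: dict[tuple, float]) -> float:
        return sum(
            v
            for (t, i, _z, _bl), v in sig.items()
            if (t == "c" and i == site) or (t == "y" and i == big_n - site)
        )

    num, den = site_sum(ref), site_sum(mod)
    if num == 0.0 and den == 0.0:
        raise ValueError(f"site {site} fragments absent in both runs")
    fold = np.inf if den == 0.0 else num / den
    return pairs, float(fold)


def charge_value_distribution(assignments) -> pd.DataFrame:
    """Charge histogram per (ion_type, index): abundance and ion count."""
    rows: dict[tuple, dict] = {}
    for a in assignments:
        if a.is_ambiguous:
            continue
        key = (a.ion.ion_type, a.ion.index, a.ion.charge)
        entry = rows.setdefault(
            key,
            {"ion_type": key[0], "index": key[1], "charge": key[2],
             "abundance": 0.0, "n": 0},
        )
        entry["abundance"] += a.abundance
        entry["n"] += 1
    return pd.DataFrame(
        list(rows.values()), columns=["ion_type", "index", "charge", "abundance", "n"]
    )


def _mean_charge_per_site(dist: pd.DataFrame) -> pd.Series:
    def mean_z(group: pd.DataFrame) -> float:
        return float(np.average(group["charge"], weights=group["abundance"]))

    return dist.groupby(["ion_type", "index"]).apply(mean_z, include_groups=False)


def mean_charge_difference(dist_a: pd.DataFrame, dist_b: pd.DataFrame) -> float:
    """Max absolute difference of abundance-weighted mean fragment charge
    per (ion_type, index) between two runs; compares only shared sites."""
    ma, mb = _mean_charge_per_site(dist_a), _mean_charge_per_site(dist_b)
    shared = ma.index.intersection(mb.index)
    if len(shared) == 0:
        raise ValueError("no shared fragments between runs")
    return float((ma[shared] - mb[shared]).abs().max())


_COMPLEMENT = {"a": "w", "b": "x", "c": "y", "d": "z"}


def dissociation_yield(assignments, big_n: int | None = None) -> float:
    """Fraction of ions dissociated by backbone cleavage, in %.

    Each cleavage event produces a complementary fragment pair, so the
    per-site event signal is estimated as the larger of the two pooled
    pair members (the longer fragment is almost always visible; summing
    both would double-count events).  Precursor ions and their base-loss
    variants count as undissociated.
    """
    five: dict[tuple, float] = {}
    three: dict[tuple, float] = {}
    precursor = 0.0
    max_index = 0
    for a in assignments:
        if a.is_ambiguous:
            continue
        t = a.ion.ion_type
        if t == "precursor":
            precursor += a.abundance
            if big_n is None:
                big_n = a.ion.index
        elif t in FIVE_PRIME_TYPES:
            key = (t, a.ion.index)
            five[key] = five.get(key, 0.0) + a.abundance
            max_index = max(max_index, a.ion.index)
        elif t in THREE_PRIME_TYPES:
            key = (t, a.ion.index)
            three[key] = three.get(key, 0.0) + a.abundance
            max_index = max(max_index, a.ion.index)
    if big_n is None:
        big_n = max_index + 1
    backbone = 0.0
    for t5, t3 in _COMPLEMENT.items():
        for k in range(1, big_n):
            ab5 = five.get((t5, k), 0.0)
            ab3 = three.get((t3, big_n - k), 0.0)
            backbone += max(ab5, ab3)
    total = backbone + precursor
    if total <= 0:
        raise ValueError("no species assigned")
    return 100.0 * backbone / total


def render_cleavage_map(table: CleavageYieldTable, width: int = 40) -> str:
    """Plain-text cleavage map: sequence with per-site c/y yield bars,
    guanosine sites marked."""
    seq = table.sequence
    lines = [f"5'-{seq}-3'  (n = {table.precursor_charge}, "
             f"{table.charges_per_nt:.2f} charges/nt)"]
    max_y = max(
        float((table.data["yield_c"] + table.data["yield_y"]).max()), 1e-9
    )
    for _, row in table.data.iterrows():
        k = int(row["site"])
        combined = row["yield_c"] + row["yield_y"]
        bar = "#" * int(round(width * combined / max_y))
        mark = "G" if row["g_site"] else " "
        res = seq.residue(k + 1)
        lines.append(
            f"site {k:>2} ({res:>4}) {mark} "
            f"c {row['yield_c']:6.2f}%  y {row['yield_y']:6.2f}%  {bar}"
        )
    lines.append(
        f"overall 5'-of-G yield {table.overall_g_yield:.1f}% "
        f"(random {table.random_expectation:.1f}%)"
    )
    return "\n".join(lines)
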