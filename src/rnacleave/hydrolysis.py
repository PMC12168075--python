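"""Alkaline-hydrolysis products h_i-j and their site-specific kinetics.

Backbone hydrolysis at site k produces a 5' piece h_1-k (retaining the
original 5' terminus, with a 2',3'-cyclic or further-hydrolyzed linear
phosphate) and a 3' piece h_(k+1)-N (5'-OH, original 3' terminus).  Only
products retaining an original terminus enter the yield statistics;
interior pieces from multiple cuts are representable but flagged
excluded.  Site rates are pseudo-first-order and compete for the first
cut of each molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chem import HPO3, WATER, Composition, RnaSequence, composition_of
from .fragments import PROTON_MASS, mz_negative
from .peaks import PeakList

__all__ = [
    "HydrolysisProduct",
    "enumerate_h_products",
    "product_composition",
    "assign_hydrolysis_spectrum",
    "site_yield_timecourse",
    "rate_estimate",
    "RateFit",
]

THREE_PRIME_FORMS = ("cyclic_phosphate", "linear_phosphate", "OH", "original")


def product_composition(
    seq: RnaSequence, i: int, j: int, form: str
) -> Composition:
    """Composition of the hydrolysis piece retaining residues i..j.

    ``form`` is the 3'-end chemistry of the piece: ``cyclic_phosphate``
    or ``linear_phosphate`` for 5' pieces, ``OH`` for 3' pieces, or
    ``original`` for the intact chain (keeps the parent termini).
    """
    if form == "original":
        return composition_of(seq)
    comp = composition_of(seq.subsequence(i, j))
    if form == "cyclic_phosphate":
        return comp + HPO3 - WATER
    if form == "linear_phosphate":
        return comp + HPO3
    if form == "OH":
        return comp
    raise ValueError(f"unknown 3' form {form!r}")


@dataclass(frozen=True)
class HydrolysisProduct:
    """One hydrolysis species, indexed by the residues it retains."""

    i: int
    j: int
    three_prime_form: str
    neutral_mass: float
    composition: Composition = field(compare=False, repr=False)

    @property
    def label(self) -> str:
        return f"h_{self.i}-{self.j}"

    @property
    def length(self) -> int:
        return self.j - self.i + 1

    def retains_terminus(self, big_n: int) -> bool:
        return self.i == 1 or self.j == big_n


def enumerate_h_products(seq: RnaSequence) -> list[HydrolysisProduct]:
    """All single-cut products: h_1-k in cyclic and linear 3'-phosphate
    form plus h_(k+1)-N with 5'-OH, for every site k — 3(N-1) species."""
    out: list[HydrolysisProduct] = []
    big_n = len(seq)
    for k in range(1, big_n):
        for form in ("cyclic_phosphate", "linear_phosphate"):
            comp = product_composition(seq, 1, k, form)
            out.append(HydrolysisProduct(1, k, form, comp.mass, comp))
        comp = product_composition(seq, k + 1, big_n, "OH")
        out.append(HydrolysisProduct(k + 1, big_n, "OH", comp.mass, comp))
    return out


@dataclass(frozen=True)
class _ProductIon:
    """A charged hydrolysis species, shaped like a FragmentIon for the
    matcher."""

    product: HydrolysisProduct
    charge: int
    neutral_mass: float
    mz: float
    composition: Composition = field(compare=False, repr=False)

    @property
    def ion_type(self) -> str:
        return "hydrolysis"

    @property
    def index(self) -> int:
        return self.product.i

    @property
    def base_loss(self):
        return None


def _product_ions(
    products: list[HydrolysisProduct], max_charge: int
) -> list[_ProductIon]:
    ions = []
    for p in products:
        z_max = min(max_charge, max(1, p.composition.get("P", 0)))
        for z in range(1, z_max + 1):
            ions.append(
                _ProductIon(p, z, p.neutral_mass, mz_negative(p.neutral_mass, z),
                            p.composition)
            )
    return ions


def assign_hydrolysis_spectrum(
    peaks: PeakList,
    seq: RnaSequence,
    products: list[HydrolysisProduct] | None = None,
    tol_ppm: float = 3.0,
    max_charge: int = 8,
    min_isotopologues: int = 2,
) -> tuple[list, pd.DataFrame]:
    """Assign a hydrolysis spectrum and compute site-specific yields.

    Per-site yield = 100 x (both terminal products of that site, 3'
    forms pooled) / (all assigned product + intact abundance).  Raises if
    nothing at all is assigned.
    """
    from .assign import match_fragments

    if products is None:
        products = enumerate_h_products(seq)
    big_n = len(seq)
    intact = HydrolysisProduct(
        1, big_n, "original", composition_of(seq).mass, composition_of(seq)
    )
    candidates = _product_ions(products + [intact], max_charge)
    assignments = match_fragments(
        peaks, candidates, tol_ppm=tol_ppm, min_isotopologues=min_isotopologues
    )
    by_species: dict[tuple, float] = {}
    for a in assignments:
        if a.is_ambiguous:
            continue
        p = a.ion.product
        key = (p.i, p.j, p.three_prime_form == "original")
        by_species[key] = by_species.get(key, 0.0) + a.abundance
    total = sum(by_species.values())
    if total <= 0:
        raise ValueError("no hydrolysis species assigned")
    rows = []
    for k in range(1, big_n):
        ab = by_species.get((1, k, False), 0.0) + by_species.get(
            (k + 1, big_n, False), 0.0
        )
        rows.append({"site": k, "yield_pct": 100.0 * ab / total})
    return assignments, pd.DataFrame(rows)


def site_yield_timecourse(abundances: pd.DataFrame) -> pd.DataFrame:
    """Convert a simulated abundance table into per-site yield fractions.

    Yield fraction of site k at time t = (molecules first cut at k) /
    (all molecules), computed from the 5' piece counts.
    """
    rows = []
    for t, sub in abundances.groupby("time"):
        five = sub[(sub["i"] == 1) & (sub["species"] != "intact")]
        intact = int(sub.loc[sub["species"] == "intact", "count"].sum())
        n_total = intact + int(five["count"].sum())
        for _, row in five.iterrows():
            rows.append(
                {"time": t, "site": int(row["j"]),
                 "yield_frac": row["count"] / n_total}
            )
    return pd.DataFrame(rows)


@dataclass
class RateFit:
    """Per-site pseudo-first-order rate constants with asymptotic errors."""

    rates: pd.DataFrame  # columns: site, k, k_se
    k_total: float
    warn_nonmonotone: bool


def rate_estimate(timecourse: pd.DataFrame) -> RateFit:
    """Fit per-site rate constants to a yield time course.

    Under the competing-risks single-cut model the yield of site k is
    ``y_k(t) = (k_k / k_tot) (1 - exp(-k_tot t))`` with
    ``k_tot = sum(k)``.  All sites are fitted jointly by least squares;
    standard errors come from the Jacobian at the solution.  Gross
    non-monotone yield trajectories set a warning flag but the fit is
    still returned.
    """
    times = np.sort(timecourse["time"].unique())
    if len(times) < 3:
        raise ValueError("need >= 3 time points")
    sites = np.sort(timecourse["site"].unique())
    pivot = timecourse.pivot_table(
        index="time", columns="site", values="yield_frac", fill_value=0.0
    ).reindex(index=times, columns=sites, fill_value=0.0)
    y = pivot.to_numpy()  # (T, S)

    if float(y.sum()) == 0.0:
        rates = pd.DataFrame({"site": sites, "k": 0.0, "k_se": 0.0})
        return RateFit(rates, 0.0, False)

    def model(k: np.ndarray) -> np.ndarray:
        k_tot = k.sum()
        if k_tot <= 0:
            return np.zeros_like(y)
        return np.outer(1.0 - np.exp(-k_tot * times), k / k_tot)

    # crude initialization from the last time point
    f_last = min(float(y[-1].sum()), 0.99)
    t_last = times[-1] if times[-1] > 0 else 1.0
    k_tot0 = -np.log(1.0 - f_last) / t_last if f_last > 0 else 1e-3
    share = y[-1] / y[-1].sum() if y[-1].sum() > 0 else np.full(len(sites), 1 / len(sites))
    x0 = np.maximum(k_tot0 * share, 1e-9)

    res = least_squares(
        lambda k: (model(k) - y).ravel(), x0, bounds=(0.0, np.inf)
    )
    dof = max(y.size - len(sites), 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    cov = s2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    sigma = np.sqrt(s2)
    drops = np.diff(y, axis=0)
    warn = bool(np.any(drops < -(3.0 * sigma + 0.01)))

    rates = pd.DataFrame({"site": sites, "k": res.x, "k_se": se})
    return RateFit(rates, float(res.x.sum()), warn)
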