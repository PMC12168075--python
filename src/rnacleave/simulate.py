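"""Synthetic CAD spectra and hydrolysis time courses with known ground truth.

The generator emulates negative-mode CAD of RNA (M - nH)^n- ions on an
FT-ICR instrument: a per-site cleavage-propensity model with a guanosine
preference factor, complementary c/y (and optionally a/w) fragment
pairs, binomial charge partitioning between the pair, neutral base-loss
channels, exact isotope envelopes, log-normal intensity noise, ppm-scale
mass error, and uniform chemical-noise peaks.  Every simulation returns
a ground-truth record so downstream assignment and statistics can be
validated without any experimental data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import G_FAMILY, RESIDUES, RnaSequence, composition_of
from .fragments import PROTON_MASS, fragment_composition
from .isotopes import aggregated_pattern
from .peaks import PeakList

__all__ = [
    "CleavagePropensityModel",
    "NoiseModel",
    "GroundTruth",
    "simulate_cad_spectrum",
    "simulate_hydrolysis_timecourse",
    "render_hydrolysis_spectrum",
    "DEFAULT_MODIFICATION_FACTORS",
]

#: Reduction of the guanosine preference by base modification, relative to
#: unmodified G: N3-deaza removes the dominant hydrogen-bond acceptor
#: (~10-fold), inosine and N2-methylation remove/block the exocyclic amino
#: donor (~3-fold), N2,N2-dimethylation blocks both sterically (~20-fold);
#: N1- and N7-deaza leave the interaction intact.
DEFAULT_MODIFICATION_FACTORS: Mapping[str, float] = {
    "G": 1.0,
    "c1G": 1.0,
    "c7G": 1.0,
    "c3G": 1.0 / 10.0,
    "m2G": 1.0 / 3.0,
    "m22G": 1.0 / 20.0,
    "I": 1.0 / 3.0,
}


@dataclass
class CleavagePropensityModel:
    """Per-site cleavage propensities for the simulator.

    The propensity of cleavage site ``k`` (the phosphodiester between
    residues k and k+1) is ``baseline``, multiplied by
    ``g_preference * modification_factors[code]`` when residue ``k+1`` is
    a guanosine-family residue or inosine, and by any per-site override.
    The default ``g_preference`` of 2.75 reproduces a 60% overall
    G-cleavage yield on the unmodified 18-mer topology at n = 7.
    """

    baseline: float = 1.0
    g_preference: float = 2.75
    modification_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODIFICATION_FACTORS)
    )
    site_overrides: dict[int, float] = field(default_factory=dict)
    ay_channel_fraction: float = 0.0
    base_loss_fraction: float = 0.1
    precursor_survival: float = 0.35

    def __post_init__(self):
        if self.baseline <= 0 or self.g_preference <= 0:
            raise ValueError("propensities must be positive")
        for name in ("ay_channel_fraction", "base_loss_fraction", "precursor_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def site_propensities(self, seq: RnaSequence) -> np.ndarray:
        """Unnormalized cleavage propensity per site (1..N-1)."""
        props = np.empty(seq.n_sites)
        for k in range(1, seq.n_sites + 1):
            nxt = seq.residue(k + 1)
            w = self.baseline
            if nxt in G_FAMILY or nxt == "I":
                w *= self.g_preference * self.modification_factors.get(nxt, 1.0)
            w *= self.site_overrides.get(k, 1.0)
            props[k - 1] = w
        return props

    def site_probabilities(self, seq: RnaSequence) -> np.ndarray:
        """Per-site cleavage probability; sums to 1 - precursor_survival."""
        props = self.site_propensities(seq)
        return props / props.sum() * (1.0 - self.precursor_survival)

    def expected_site_shares(
        self, seq: RnaSequence, n: int | None = None
    ) -> np.ndarray:
        """Expected share of total c/y *signal* per site (sums to 1).

        With ``n`` given, shares are weighted by per-event fragment
        visibility under clamped binomial charge partitioning: a terminal
        fragment that draws zero charge renders no peaks, so short
        fragments contribute less signal than interior ones.  Without
        ``n``, shares are the raw event probabilities.
        """
        props = self.site_propensities(seq)
        if n is not None:
            big_n = len(seq)
            visible = np.array(
                [
                    2.0 - _p_invisible_5(k, big_n, n) - _p_invisible_3(k, big_n, n)
                    for k in range(1, seq.n_sites + 1)
                ]
            )
            props = props * visible
        return props / props.sum()


@dataclass
class NoiseModel:
    """FT-ICR-style measurement noise: multiplicative log-normal intensity
    scatter, Gaussian m/z error in ppm, and spurious low-level peaks."""

    intensity_cv: float = 0.1
    mz_ppm_sd: float = 1.0
    chemical_noise_peaks: int = 50

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0)


@dataclass
class GroundTruth:
    """What actually happened in a simulated CAD experiment."""

    sequence: str
    precursor_charge: int
    n_ions: int
    seed: int
    model: CleavagePropensityModel
    #: events per site split by channel; index = site 1..N-1
    site_counts: pd.DataFrame
    #: (ion_type, index, base_loss, charge) -> ion count (charge 0 included)
    fragment_counts: Counter
    n_survived: int
    n_survived_base_loss: int

    @property
    def gamma(self) -> float:
        return self.model.g_preference

    def visible_fragment_keys(self) -> set[tuple]:
        """Distinct rendered species: (ion_type, index, base_loss, charge>=1)."""
        return {k for k, v in self.fragment_counts.items() if k[3] >= 1 and v > 0}

    def site_event_counts(self) -> np.ndarray:
        return self.site_counts[["n_cy", "n_aw"]].sum(axis=1).to_numpy()


def _lost_base(seq: RnaSequence, pos: int) -> str:
    return seq.residue(pos)


def _charge_caps(k: int, big_n: int) -> tuple[int, int]:
    """Maximum deprotonations of the complementary pair at site k.

    Approximated by phosphate counts: the 5' (c-type) fragment carries k
    phosphates, the 3' (y-type) fragment N-k-1; every fragment can hold
    at least one charge.
    """
    return max(1, k), max(1, big_n - k - 1)


def _partition_charges(
    rng: np.random.Generator,
    n: int,
    k: int,
    big_n: int,
    size: int,
    caps: tuple[int, int] | None = None,
) -> np.ndarray:
    """Charge of the 5' fragment per event: Binomial(n, k/N) clamped so
    neither fragment exceeds its deprotonation capacity."""
    cap5, cap3 = caps if caps is not None else _charge_caps(k, big_n)
    z5 = rng.binomial(n, k / big_n, size=size)
    return np.clip(z5, max(0, n - cap3), min(n, cap5))


def _p_invisible_5(k: int, big_n: int, n: int) -> float:
    from scipy.stats import binom

    cap5, cap3 = _charge_caps(k, big_n)
    if n - cap3 > 0:  # clamp forces at least one charge onto the 5' piece
        return 0.0
    return float(binom.pmf(0, n, k / big_n))


def _p_invisible_3(k: int, big_n: int, n: int) -> float:
    from scipy.stats import binom

    cap5, _cap3 = _charge_caps(k, big_n)
    if cap5 < n:  # 5' piece can never soak up all n charges
        return 0.0
    return float(binom.pmf(n, n, k / big_n))


def simulate_cad_spectrum(
    seq: RnaSequence,
    n: int,
    model: CleavagePropensityModel | None = None,
    n_ions: int = 100_000,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[PeakList, GroundTruth]:
    """Simulate one CAD spectrum of the (M - nH)^n- ions of ``seq``.

    ``n_ions`` precursor ions either survive or cleave at one site drawn
    from the propensity model.  Each cleavage yields a complementary
    fragment pair (c/y, or a/w for the minor channel); the precursor
    charge is partitioned by ``z5 ~ Binomial(n, i/N)`` (charge roughly
    proportional to fragment length), the 3' fragment taking ``n - z5``.
    Fragments drawing zero charge are invisible.  Base loss converts a
    fragment (or surviving precursor) into its -BH variant.  Every
    visible species is rendered as its exact aggregated isotope pattern
    scaled by ion count, with noise per :class:`NoiseModel`.
    """
    big_n = len(seq)
    if not 1 <= n <= big_n - 1:
        raise ValueError(
            f"precursor charge {n} exceeds the {big_n - 1} phosphodiesters"
        )
    if n_ions < 1:
        raise ValueError("n_ions must be >= 1")
    model = model if model is not None else CleavagePropensityModel()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    p_sites = model.site_probabilities(seq)
    counts = rng.multinomial(n_ions, np.concatenate(([model.precursor_survival], p_sites)))
    n_surv, site_events = int(counts[0]), counts[1:]

    species: Counter = Counter()
    fragment_counts: Counter = Counter()

    # Surviving precursor, with its own base-loss channel.
    n_bl_surv = int(rng.binomial(n_surv, model.base_loss_fraction)) if n_surv else 0
    species[("precursor", big_n, None, n)] += n_surv - n_bl_surv
    if n_bl_surv:
        pos = rng.integers(1, big_n + 1, size=n_bl_surv)
        for p in pos:
            species[("precursor", big_n, _lost_base(seq, int(p)), n)] += 1
    fragment_counts.update(
        {k: v for k, v in species.items()}
    )

    site_rows = []
    for k, m in enumerate(site_events, start=1):
        m = int(m)
        n_aw = int(rng.binomial(m, model.ay_channel_fraction)) if m else 0
        n_cy = m - n_aw
        n_bl_site = 0
        for (t5, t3), cnt in ((("c", "y"), n_cy), (("a", "w"), n_aw)):
            if cnt == 0:
                continue
            # phosphate capacities differ between the c/y and a/w pairs
            caps = (
                (max(1, k), max(1, big_n - k - 1))
                if t5 == "c"
                else (max(1, k - 1), max(1, big_n - k))
            )
            z5 = _partition_charges(rng, n, k, big_n, cnt, caps)
            bl = rng.random(cnt) < model.base_loss_fraction
            on5 = rng.random(cnt) < k / big_n
            pos5 = rng.integers(1, k + 1, size=cnt)
            pos3 = rng.integers(k + 1, big_n + 1, size=cnt)
            n_bl_site += int(bl.sum())
            for ev in range(cnt):
                loss5 = _lost_base(seq, int(pos5[ev])) if bl[ev] and on5[ev] else None
                loss3 = _lost_base(seq, int(pos3[ev])) if bl[ev] and not on5[ev] else None
                key5 = (t5, k, loss5, int(z5[ev]))
                key3 = (t3, big_n - k, loss3, n - int(z5[ev]))
                species[key5] += 1
                species[key3] += 1
                fragment_counts[key5] += 1
                fragment_counts[key3] += 1
        site_rows.append({"site": k, "n_cy": n_cy, "n_aw": n_aw, "n_base_loss": n_bl_site})

    # Render every visible species as its isotope envelope.
    mz_parts: list[np.ndarray] = []
    int_parts: list[np.ndarray] = []
    for (ion_type, index, base_loss, z), count in sorted(
        species.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]), kv[0][3])
    ):
        if z < 1 or count == 0:
            continue
        comp = (
            composition_of(seq)
            if ion_type == "precursor"
            else fragment_composition(seq, ion_type, index)
        )
        if base_loss is not None:
            comp = comp - RESIDUES[base_loss].base
        pattern = aggregated_pattern(comp)
        mz = (comp.mass + pattern.offsets - z * PROTON_MASS) / z
        inten = count * pattern.fractions
        if noise.intensity_cv > 0:
            sigma = np.sqrt(np.log1p(noise.intensity_cv**2))
            inten = inten * rng.lognormal(-0.5 * sigma**2, sigma, size=inten.shape)
        if noise.mz_ppm_sd > 0:
            mz = mz + rng.normal(0.0, noise.mz_ppm_sd * 1e-6 * mz)
        mz_parts.append(mz)
        int_parts.append(inten)

    if mz_parts:
        all_mz = np.concatenate(mz_parts)
        all_int = np.concatenate(int_parts)
    else:
        all_mz = np.array([])
        all_int = np.array([])

    if noise.chemical_noise_peaks > 0 and len(all_mz):
        lo, hi = all_mz.min() * 0.9, all_mz.max() * 1.05
        noise_mz = rng.uniform(lo, hi, size=noise.chemical_noise_peaks)
        noise_int = rng.exponential(
            0.01 * all_int.max(), size=noise.chemical_noise_peaks
        )
        all_mz = np.concatenate([all_mz, noise_mz])
        all_int = np.concatenate([all_int, noise_int])

    peaks = PeakList(
        all_mz,
        all_int,
        metadata={
            "sequence": str(seq),
            "precursor_charge": n,
            "seed": seed,
            "n_ions": n_ions,
        },
    )
    truth = GroundTruth(
        sequence=str(seq),
        precursor_charge=n,
        n_ions=n_ions,
        seed=seed,
        model=model,
        site_counts=pd.DataFrame(site_rows).set_index("site"),
        fragment_counts=fragment_counts,
        n_survived=n_surv,
        n_survived_base_loss=n_bl_surv,
    )
    return peaks, truth


def simulate_hydrolysis_timecourse(
    seq: RnaSequence,
    site_rate_constants: Sequence[float],
    times: Sequence[float],
    n_molecules: int = 10_000,
    seed: int = 0,
    three_prime_form: str = "cyclic_phosphate",
) -> pd.DataFrame:
    """Single-cut alkaline-hydrolysis kinetics under competing exponentials.

    Site ``k`` has pseudo-first-order rate constant ``k_k`` (1/h); the
    probability that a molecule has been cut first at site ``k`` by time
    ``t`` is ``(k_k / k_tot) * (1 - exp(-k_tot t))``.  Each time point is
    an independent aliquot of ``n_molecules``.  The two products of a cut
    at site k are ``h_1-k`` (retaining the original 5' end, 3' cyclic or
    linear phosphate) and ``h_(k+1)-N`` (5'-OH, original 3' end).

    Returns a tidy table with columns time, species, i, j, form, count.
    """
    rates = np.asarray(site_rate_constants, dtype=float)
    if len(rates) != seq.n_sites:
        raise ValueError(f"expected {seq.n_sites} site rates, got {len(rates)}")
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    rng = np.random.default_rng(seed)
    big_n = len(seq)
    k_tot = rates.sum()

    rows = []
    for t in times:
        if k_tot > 0 and t > 0:
            p_cut = (1.0 - np.exp(-k_tot * t)) * rates / k_tot
        else:
            p_cut = np.zeros_like(rates)
        counts = rng.multinomial(
            n_molecules, np.concatenate(([1.0 - p_cut.sum()], p_cut))
        )
        rows.append(
            {"time": t, "species": "intact", "i": 1, "j": big_n,
             "form": "original", "count": int(counts[0])}
        )
        for k in range(1, seq.n_sites + 1):
            c = int(counts[k])
            rows.append(
                {"time": t, "species": f"h_1-{k}", "i": 1, "j": k,
                 "form": three_prime_form, "count": c}
            )
            rows.append(
                {"time": t, "species": f"h_{k + 1}-{big_n}", "i": k + 1,
                 "j": big_n, "form": "OH", "count": c}
            )
    return pd.DataFrame(rows)


def render_hydrolysis_spectrum(
    seq: RnaSequence,
    abundances: pd.DataFrame,
    time: float,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> PeakList:
    """Render one time point of a hydrolysis table as an ESI peak list.

    Each species is rendered at a single deterministic charge
    (``max(1, length // 4)`` deprotonations) with its exact isotope
    envelope, so the result is matchable by the hydrolysis assigner.
    """
    from .hydrolysis import product_composition

    noise = noise if noise is not None else NoiseModel.none()
    rng = np.random.default_rng(seed)
    sub = abundances[abundances["time"] == time]
    if sub.empty:
        raise ValueError(f"no rows at time {time}")
    mz_parts, int_parts = [], []
    for _, row in sub.iterrows():
        if row["count"] == 0:
            continue
        comp = product_composition(seq, int(row["i"]), int(row["j"]), row["form"])
        length = int(row["j"]) - int(row["i"]) + 1
        z = max(1, length // 4)
        pattern = aggregated_pattern(comp)
        mz = (comp.mass + pattern.offsets - z * PROTON_MASS) / z
        inten = row["count"] * pattern.fractions
        if noise.intensity_cv > 0:
            sigma = np.sqrt(np.log1p(noise.intensity_cv**2))
            inten = inten * rng.lognormal(-0.5 * sigma**2, sigma, size=inten.shape)
        if noise.mz_ppm_sd > 0:
            mz = mz + rng.normal(0.0, noise.mz_ppm_sd * 1e-6 * mz)
        mz_parts.append(mz)
        int_parts.append(inten)
    if not mz_parts:
        return PeakList.empty(sequence=str(seq), time=time)
    return PeakList(
        np.concatenate(mz_parts),
        np.concatenate(int_parts),
        metadata={"sequence": str(seq), "time": time, "seed": seed},
    )
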