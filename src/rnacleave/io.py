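"""Delimited-text readers and writers binding the pipeline together.

All formats are plain text: 2-column peak lists with ``#`` metadata
headers, tab-separated fragment/assignment/yield/pair tables, JSON
ground-truth sidecars, and YAML run configuration.  Every writer's
output is re-readable by the corresponding reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assign import FragmentAssignment
from .fragments import FragmentIon
from .peaks import PeakList
from .simulate import GroundTruth

__all__ = [
    "write_peaklist",
    "read_peaklist",
    "write_fragment_table",
    "write_assignment_table",
    "read_assignment_table",
    "write_yield_table",
    "write_pair_table",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
]


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    """Write m/z-intensity centroids with a ``# key = value`` header."""
    with open(path, "w") as fh:
        for key in sorted(peaks.metadata):
            fh.write(f"# {key} = {peaks.metadata[key]}\n")
        for mz, inten in zip(peaks.mz, peaks.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


def read_peaklist(path: str | Path) -> PeakList:
    metadata: dict = {}
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = _coerce(value.strip())
                continue
            fields = line.split()
            mz.append(float(fields[0]))
            inten.append(float(fields[1]))
    return PeakList(np.array(mz), np.array(inten), metadata)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def write_fragment_table(ions: list[FragmentIon], path: str | Path) -> None:
    """Theoretical fragment table with 6-decimal masses."""
    df = pd.DataFrame(
        [
            {
                "ion_type": ion.ion_type,
                "index": ion.index,
                "base_loss": ion.base_loss if ion.base_loss else "-",
                "charge": ion.charge,
                "neutral_mass": f"{ion.neutral_mass:.6f}",
                "mz": f"{ion.mz:.6f}",
            }
            for ion in ions
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_assignment_table(
    assignments: list[FragmentAssignment], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "ion_type": a.ion.ion_type,
                "index": a.ion.index,
                "base_loss": a.ion.base_loss if a.ion.base_loss else "-",
                "charge": a.ion.charge,
                "mz_obs": f"{a.mz_obs:.6f}",
                "mz_theo": f"{a.mz_theo:.6f}",
                "error_ppm": f"{a.mass_error_ppm:.3f}",
                "abundance": f"{a.abundance:.6f}",
                "n_isotopologues": a.n_isotopologues,
                "flags": ",".join(sorted(a.flags)) if a.flags else "-",
            }
            for a in assignments
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> list[FragmentAssignment]:
    """Rebuild assignments (without compositions) from a written table."""
    df = pd.read_csv(path, sep="\t")
    out: list[FragmentAssignment] = []
    for _, row in df.iterrows():
        z = int(row["charge"])
        mz_theo = float(row["mz_theo"])
        from .chem import PROTON_MASS

        ion = FragmentIon(
            ion_type=str(row["ion_type"]),
            index=int(row["index"]),
            charge=z,
            neutral_mass=mz_theo * z + z * PROTON_MASS,
            mz=mz_theo,
            base_loss=None if row["base_loss"] == "-" else str(row["base_loss"]),
        )
        flags = set() if row["flags"] == "-" else set(str(row["flags"]).split(","))
        out.append(
            FragmentAssignment(
                ion=ion,
                abundance=float(row["abundance"]),
                mass_error_ppm=float(row["error_ppm"]),
                n_isotopologues=int(row["n_isotopologues"]),
                mz_obs=float(row["mz_obs"]),
                mz_theo=mz_theo,
                flags=flags,
            )
        )
    return out


def write_yield_table(table, path: str | Path) -> None:
    """CleavageYieldTable as TSV with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# sequence = {table.sequence}\n")
        fh.write(f"# precursor_charge = {table.precursor_charge}\n")
        fh.write(f"# charges_per_nt = {table.charges_per_nt:.2f}\n")
        fh.write(f"# overall_g_yield_pct = {table.overall_g_yield:.4f}\n")
        fh.write(f"# random_expectation_pct = {table.random_expectation:.4f}\n")
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_pair_table(pairs: pd.DataFrame, path: str | Path, fold_change: float | None = None) -> None:
    with open(path, "w") as fh:
        if fold_change is not None:
            fh.write(f"# fold_change = {fold_change:.6f}\n")
        pairs.to_csv(fh, sep="\t", index=False, float_format="%.8f")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth sidecar as JSON."""
    payload = {
        "sequence": truth.sequence,
        "precursor_charge": truth.precursor_charge,
        "n_ions": truth.n_ions,
        "seed": truth.seed,
        "gamma": truth.gamma,
        "n_survived": truth.n_survived,
        "n_survived_base_loss": truth.n_survived_base_loss,
        "site_counts": truth.site_counts.reset_index().to_dict(orient="records"),
        "fragment_counts": [
            {"ion_type": t, "index": i, "base_loss": bl, "charge": z, "count": c}
            for (t, i, bl, z), c in sorted(
                truth.fragment_counts.items(),
                key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]), kv[0][3]),
            )
        ],
        "model": {
            "baseline": truth.model.baseline,
            "g_preference": truth.model.g_preference,
            "modification_factors": truth.model.modification_factors,
            "site_overrides": truth.model.site_overrides,
            "ay_channel_fraction": truth.model.ay_channel_fraction,
            "base_loss_fraction": truth.model.base_loss_fraction,
            "precursor_survival": truth.model.precursor_survival,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    sequence: str = ""
    precursor_charge: int = 1
    ion_types: str = "cy"
    tol_ppm: float = 3.0
    gamma: float = 2.75
    n_ions: int = 100_000
    intensity_cv: float = 0.1
    mz_ppm_sd: float = 1.0
    chemical_noise_peaks: int = 50
    seed: int = 0
    output_dir: str = "."
    report_decimals: int = 3
    extra: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.tol_ppm <= 0:
            raise ValueError("tolerance must be > 0")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if self.n_ions < 1:
            raise ValueError("n_ions must be >= 1")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data).validate()
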