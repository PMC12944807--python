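"""Packaged benchmark data: 25 floral odorants and reference clusterings.

The data set covers the aroma-active compounds of six flower species —
three Orchidaceae (sweet/fruity scents dominated by terpenes) and three
Apocynaceae (carrion-like scents dominated by sulfides, aldehydes and
acids). Each compound carries a literature odor descriptor from a
seven-word vocabulary (fruit, wood, sweet, spices, flower, garlic,
decayed) and a relative content in each species' volatile profile.

Also packaged are the literature-reported spectral-clustering partitions of
these 25 compounds obtained from DFT-computed IR, Raman and VDOS spectra
(the spectra themselves are not redistributed). Comparing those partitions
against the odor descriptors with AMI quantifies how much odor-relevant
information each spectroscopy carries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .labeling import Labeling
from .metrics import ami_all_normalizations

__all__ = [
    "SPECIES",
    "ODOR_DESCRIPTORS",
    "OdorantRecord",
    "ReferenceClustering",
    "load_odorants",
    "odor_labeling",
    "load_reference_clustering",
    "reference_labeling",
    "reference_ami",
]

SPECIES = ("D_lin", "M_ten", "C_ari", "H_ken", "P_cub", "O_var")
ODOR_DESCRIPTORS = ("fruit", "wood", "sweet", "spices", "flower", "garlic", "decayed")


@dataclass(frozen=True)
class OdorantRecord:
    number: int  # 1..25
    name: str
    odor_descriptor: str
    relative_content: dict  # species -> percent, only where detected


@dataclass(frozen=True)
class ReferenceClustering:
    kind: str  # IR | Raman | VDOS
    groups: dict  # group letter -> list of compound numbers

    def labeling(self) -> Labeling:
        mapping = {}
        for letter, members in self.groups.items():
            for number in members:
                mapping[number] = letter
        return Labeling.from_dict({n: mapping[n] for n in sorted(mapping)})


def _data_text(name: str) -> str:
    return resources.files("vibroclust.data").joinpath(name).read_text(encoding="utf-8")


def load_odorants() -> list[OdorantRecord]:
    """The 25 odorant records (number, name, descriptor, relative contents)."""
    import io

    df = pd.read_csv(io.StringIO(_data_text("odorants.csv")), comment="#")
    records = []
    for row in df.itertuples(index=False):
        content = {
            sp: float(getattr(row, sp))
            for sp in SPECIES
            if pd.notna(getattr(row, sp))
        }
        if row.odor_descriptor not in ODOR_DESCRIPTORS:
            raise ValueError(f"unknown odor descriptor {row.odor_descriptor!r}")
        records.append(
            OdorantRecord(int(row.number), row.name, row.odor_descriptor, content)
        )
    numbers = sorted(r.number for r in records)
    if numbers != list(range(1, 26)):
        raise ValueError("odorant numbers must be exactly 1..25")
    return records


def odor_labeling() -> Labeling:
    """Compound number -> odor descriptor, for all 25 compounds."""
    return Labeling.from_dict(
        {r.number: r.odor_descriptor for r in sorted(load_odorants(), key=lambda r: r.number)}
    )


def load_reference_clustering(kind: str) -> ReferenceClustering:
    """Reference partition of the 25 compounds for one spectroscopy.

    Validates that the groups are disjoint and cover 1..25 exactly.
    """
    payload = json.loads(_data_text("reference_clusterings.json"))
    if kind not in ("IR", "Raman", "VDOS"):
        raise ValueError("kind must be 'IR', 'Raman' or 'VDOS'")
    groups = payload[kind]
    members = [n for ms in groups.values() for n in ms]
    if sorted(members) != list(range(1, 26)):
        raise ValueError(f"{kind} groups do not partition compounds 1..25")
    return ReferenceClustering(kind, {g: list(ms) for g, ms in groups.items()})


def reference_labeling(kind: str) -> Labeling:
    return load_reference_clustering(kind).labeling()


def reference_ami(kind: str) -> dict[str, float]:
    """AMI between a spectroscopy's reference clustering and the odor labels.

    Returns the value under every normalization
    (arithmetic/max/min/geometric); the arithmetic mean of entropies is the
    conventional default.
    """
    return ami_all_normalizations(reference_labeling(kind), odor_labeling())
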