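"""Synthetic odorant line spectra with planted class structure.

No public repository deposits DFT vibrational spectra for the benchmark
odorants, so end-to-end validation uses synthetic line spectra instead:
each of five structural classes (sulfides, aromatic carbonyls, aliphatic
aldehydes, terpenes, N-heterocycles) is defined by the characteristic
fingerprint-region bands of its functional groups, and individual
"compounds" are drawn by jittering band positions (Gaussian), band
intensities (lognormal, keeping positivity) and adding weak background
modes uniformly over the grid range. The generator is fully deterministic
given its seed, which makes planted-partition recovery a reproducible
experiment: at low frequency jitter the clustering pipeline must recover
the classes, and recovery must degrade as jitter grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .labeling import Labeling
from .spectra import LineSpectrum

__all__ = [
    "BandTemplate",
    "ClassTemplate",
    "SyntheticDataset",
    "default_templates",
    "noiseless",
    "sample_spectrum",
    "generate_dataset",
]

DEFAULT_FREQ_RANGE = (400.0, 1800.0)


@dataclass(frozen=True)
class BandTemplate:
    """One characteristic band: where it sits and how variable it is."""

    center: float  # cm^-1
    center_jitter_sd: float  # cm^-1
    intensity_mean: float
    intensity_rel_sd: float = 0.3
    presence_prob: float = 1.0

    def __post_init__(self):
        if not self.center > 0:
            raise ValueError("band center must be > 0 cm^-1")
        if self.center_jitter_sd < 0 or self.intensity_mean <= 0 or self.intensity_rel_sd < 0:
            raise ValueError("invalid band template parameters")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must lie in [0, 1]")


@dataclass(frozen=True)
class ClassTemplate:
    class_name: str
    odor_label: str
    bands: tuple
    background_mode_count: int = 10
    background_intensity_scale: float = 2.0

    def __post_init__(self):
        if not self.bands:
            raise ValueError("a class template needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))


@dataclass(frozen=True)
class SyntheticDataset:
    spectra: tuple  # LineSpectrum, shuffled order
    truth: Labeling  # compound_id -> class_name
    seed: int
    params: dict

    def __post_init__(self):
        if len(self.spectra) != len(self.truth):
            raise ValueError("one truth label per spectrum required")


def default_templates() -> list[ClassTemplate]:
    """The five packaged odorant class templates (see data/class_templates.yaml)."""
    text = resources.files("vibroclust.data").joinpath("class_templates.yaml").read_text(
        encoding="utf-8"
    )
    payload = yaml.safe_load(text)
    templates = []
    for entry in payload["classes"]:
        bands = tuple(BandTemplate(**b) for b in entry["bands"])
        templates.append(
            ClassTemplate(
                class_name=entry["class_name"],
                odor_label=entry["odor_label"],
                bands=bands,
                background_mode_count=int(entry.get("background_mode_count", 10)),
                background_intensity_scale=float(
                    entry.get("background_intensity_scale", 2.0)
                ),
            )
        )
    names = [t.class_name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("class names must be unique")
    return templates


def noiseless(templates: list[ClassTemplate]) -> list[ClassTemplate]:
    """Strip every stochastic element from the templates.

    Jitter and intensity spread become 0, every band is always present and
    background modes are removed, so all compounds of a class are
    identical; clustering at k = number of classes must then recover the
    classes exactly.
    """
    out = []
    for t in templates:
        bands = tuple(
            replace(b, center_jitter_sd=0.0, intensity_rel_sd=0.0, presence_prob=1.0)
            for b in t.bands
        )
        out.append(replace(t, bands=bands, background_mode_count=0))
    return out


def _override_jitter(template: ClassTemplate, jitter_sd: float | None) -> ClassTemplate:
    if jitter_sd is None:
        return template
    bands = tuple(replace(b, center_jitter_sd=float(jitter_sd)) for b in template.bands)
    return replace(template, bands=bands)


def sample_spectrum(
    template: ClassTemplate,
    seed: int,
    compound_id: str | None = None,
    kind: str = "IR",
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    jitter_sd: float | None = None,
) -> LineSpectrum:
    """Draw one synthetic compound from a class template.

    Each band appears with its ``presence_prob``; its frequency is
    center + N(0, jitter) (redrawn in the vanishingly rare case it lands
    at <= 0 cm^-1) and its intensity is intensity_mean x LogNormal(0,
    rel_sd). ``background_mode_count`` weak modes are placed uniformly over
    ``freq_range``. ``jitter_sd`` overrides every band's frequency jitter.
    ``kind="VDOS"`` discards activities (unit weights).
    """
    template = _override_jitter(template, jitter_sd)
    rng = np.random.default_rng(seed)
    freqs: list[float] = []
    intens: list[float] = []
    for band in template.bands:
        present = rng.random() < band.presence_prob
        f = band.center + rng.normal(0.0, band.center_jitter_sd)
        for _ in range(100):
            if f > 0:
                break
            f = band.center + rng.normal(0.0, band.center_jitter_sd)
        amp = band.intensity_mean * rng.lognormal(0.0, band.intensity_rel_sd)
        if present and f > 0:
            freqs.append(float(f))
            intens.append(float(amp))
    lo, hi = freq_range
    for _ in range(template.background_mode_count):
        freqs.append(float(rng.uniform(lo, hi)))
        intens.append(float(template.background_intensity_scale * rng.uniform(0.5, 1.5)))
    spectrum = LineSpectrum(
        compound_id=compound_id or template.class_name,
        frequencies=np.array(freqs),
        intensities=np.array(intens),
        kind="IR",
        compound_name=template.class_name,
    )
    return spectrum.as_vdos() if kind == "VDOS" else replace(spectrum, kind=kind)


def generate_dataset(
    templates: list[ClassTemplate] | None = None,
    n_per_class: int = 5,
    seed: int = 0,
    jitter_sd: float | None = None,
    kind: str = "IR",
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
) -> SyntheticDataset:
    """Sample ``n_per_class`` compounds per class, with ground-truth labels.

    The default 5 classes x 5 compounds matches the 25-compound benchmark.
    Compound order is shuffled; everything is reproducible from (params,
    seed).
    """
    if templates is None:
        templates = default_templates()
    master = np.random.default_rng(seed)
    spectra: list[LineSpectrum] = []
    truth: dict[str, str] = {}
    for template in templates:
        for i in range(n_per_class):
            cid = f"{template.class_name}_{i:02d}"
            child_seed = int(master.integers(2**31))
            spectra.append(
                sample_spectrum(
                    template,
                    seed=child_seed,
                    compound_id=cid,
                    kind=kind,
                    freq_range=freq_range,
                    jitter_sd=jitter_sd,
                )
            )
            truth[cid] = template.class_name
    order = master.permutation(len(spectra))
    spectra = [spectra[i] for i in order]
    truth_labeling = Labeling.from_dict({s.compound_id: truth[s.compound_id] for s in spectra})
    params = {
        "n_per_class": n_per_class,
        "classes": [t.class_name for t in templates],
        "jitter_sd": jitter_sd,
        "kind": kind,
        "freq_range": list(freq_range),
    }
    return SyntheticDataset(tuple(spectra), truth_labeling, seed, params)
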