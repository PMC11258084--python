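"""Tube spectra for the simulated scanner.

The three study tube voltages (80/120/135 kV) ship as plain-text fixtures
tabulating relative photon fluence per 1 keV bin, generated once from a
Kramers bremsstrahlung model for a tungsten anode behind 6 mm of inherent
aluminum filtration -- a typical total (tube + bowtie centre) filtration for
a clinical CT scanner (see ``scripts/make_spectra.py``).  ``generate_spectrum``
loads the fixture and can apply additional Al filtration bin-by-bin via
Beer-Lambert attenuation; non-fixture voltages inside 40-150 kV are computed
from the same analytic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .materials import load_attenuation_table

__all__ = ["Spectrum", "generate_spectrum", "kramers_spectrum"]

INHERENT_FILTRATION_MM_AL = 6.0
_FIXTURE_KV = (80, 120, 135)


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon spectrum: relative fluence per energy bin for one kV."""

    kv: float
    energies: np.ndarray  # keV, ascending
    fluence: np.ndarray   # relative photon counts, >= 0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.fluence, dtype=float)
        if e.shape != w.shape or e.ndim != 1:
            raise ValueError("energies and fluence must be matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("fluence must be non-negative")
        if np.any(w[e > self.kv] > 0):
            raise ValueError("fluence must vanish above the tube voltage")
        if w.sum() <= 0:
            raise ValueError("spectrum must contain photons")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", w)

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.fluence) / np.sum(self.fluence))

    def normalized(self) -> "Spectrum":
        """Copy with fluence summing to 1."""
        return Spectrum(self.kv, self.energies, self.fluence / self.fluence.sum())

    def filtered(self, mm_al: float) -> "Spectrum":
        """Attenuate each bin by ``mm_al`` of aluminum (Beer-Lambert)."""
        if mm_al < 0:
            raise ValueError("filtration must be non-negative")
        if mm_al == 0:
            return self
        al = load_attenuation_table("aluminum")
        mu = al(self.energies) * al.nominal_density  # cm^-1
        return Spectrum(self.kv, self.energies, self.fluence * np.exp(-mu * mm_al / 10.0))

    def rebinned(self, step_kev: int) -> "Spectrum":
        """Merge adjacent 1 keV bins into ``step_kev``-wide bins (fluence-weighted)."""
        if step_kev <= 1:
            return self
        n = len(self.energies) // step_kev * step_kev
        e = self.energies[:n].reshape(-1, step_kev)
        w = self.fluence[:n].reshape(-1, step_kev)
        wsum = w.sum(axis=1)
        centers = np.where(wsum > 0, (e * w).sum(axis=1) / np.where(wsum > 0, wsum, 1), e.mean(axis=1))
        keep = wsum > 0
        return Spectrum(self.kv, centers[keep], wsum[keep])


def kramers_spectrum(kv: float, inherent_mm_al: float = INHERENT_FILTRATION_MM_AL) -> Spectrum:
    """Analytic filtered-Kramers bremsstrahlung spectrum on a 1 keV grid."""
    energies = np.arange(10.0, float(kv) + 0.5, 1.0)
    photons = np.clip(kv / energies - 1.0, 0.0, None)
    spec = Spectrum(kv, energies, photons).filtered(inherent_mm_al)
    w = spec.fluence / spec.fluence.max()
    return Spectrum(kv, energies, w)


def generate_spectrum(kv: float, filtration_mm_al: float = 0.0) -> Spectrum:
    """Spectrum for tube voltage ``kv`` with optional added Al filtration (mm)."""
    if not 40.0 <= kv <= 150.0:
        raise ValueError(f"tube voltage {kv} kV unsupported (40-150 kV)")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be non-negative")
    kv_int = int(round(kv))
    if kv_int in _FIXTURE_KV and abs(kv - kv_int) < 1e-9:
        path = resources.files("cacsim").joinpath(f"data/spectra/spectrum_{kv_int:03d}kv.txt")
        rows = [
            line.split()
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        arr = np.array(rows, dtype=float)
        spec = Spectrum(float(kv_int), arr[:, 0], arr[:, 1])
    else:
        spec = kramers_spectrum(kv)
    return spec.filtered(filtration_mm_al)
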