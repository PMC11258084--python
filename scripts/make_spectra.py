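"""Regenerate the bundled tube-spectrum fixtures.

Writes relative-fluence tables for the three study tube voltages from the
filtered-Kramers model in ``cacsim.spectra``.  Run from the repository root:

    python scripts/make_spectra.py
"""

from pathlib import Path

from cacsim.spectra import INHERENT_FILTRATION_MM_AL, kramers_spectrum

OUT = Path(__file__).resolve().parents[1] / "src" / "cacsim" / "data" / "spectra"

HEADER = """\
# Relative photon fluence per 1 keV bin for a tungsten-anode tube at {kv} kV,
# filtered-Kramers bremsstrahlung model with {filt} mm Al inherent filtration.
# energy_keV  relative_fluence
"""


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for kv in (80, 120, 135):
        spec = kramers_spectrum(kv)
        path = OUT / f"spectrum_{kv:03d}kv.txt"
        with path.open("w") as fh:
            fh.write(HEADER.format(kv=kv, filt=INHERENT_FILTRATION_MM_AL))
            for e, w in zip(spec.energies, spec.fluence):
                fh.write(f"{e:<8.1f} {w:.6e}\n")
        print(f"wrote {path} (mean energy {spec.mean_energy:.2f} keV)")


if __name__ == "__main__":
    main()
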