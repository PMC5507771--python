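"""Metabolite peak library for synthetic urinary 1H-NMR spectra.

Each :class:`MetaboliteSpec` describes a urinary metabolite as a set of
Lorentzian resonances (chemical-shift center in ppm, relative intensity,
half-width at half-maximum in ppm), a log-normal baseline excretion level,
and a ``marker_loading`` in [-1, 1] coupling the metabolite's baseline
excretion to the latent outcome driver of the cohort simulator.

The default library covers the microbial-host co-metabolites that dominate
the urinary signature of high-fat feeding in the C57BL/6J mouse
(trimethylamine-N-oxide and the other methylamines, choline, hippurate,
phenylacetylglycine) together with TCA-cycle intermediates and common
urinary metabolites used as unplanted controls.  Chemical-shift centers are
standard literature values for urine at pH ~7.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = ["MetaboliteSpec", "default_library", "load_library", "dump_library"]


@dataclass
class MetaboliteSpec:
    """One metabolite: Lorentzian peak list plus excretion model.

    Parameters
    ----------
    name : str
        Metabolite name, unique within a library.
    peaks : list of (center, relative_intensity, half_width)
        Resonances; ``center`` in ppm, ``relative_intensity`` > 0
        (dimensionless, apex height per unit concentration),
        ``half_width`` > 0 in ppm (half-width at half-maximum).
    baseline_mean, baseline_sd : float
        Mean and SD (arbitrary concentration units) of baseline excretion.
    marker_loading : float in [-1, 1]
        Coupling of baseline log-excretion to the latent outcome driver.
    extreme_loading : float
        Coupling to the planted extreme-responder indicator (log-scale
        shift applied to planted extreme animals, scaled by effect size).
    """

    name: str
    peaks: list[tuple[float, float, float]]
    baseline_mean: float = 1.0
    baseline_sd: float = 0.0
    marker_loading: float = 0.0
    extreme_loading: float = 0.0

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"metabolite {self.name!r} needs at least one peak")
        for center, rel, hw in self.peaks:
            if rel <= 0:
                raise ValueError(
                    f"metabolite {self.name!r}: relative_intensity must be > 0"
                )
            if hw <= 0:
                raise ValueError(f"metabolite {self.name!r}: half_width must be > 0")
        if not -1.0 <= self.marker_loading <= 1.0:
            raise ValueError(
                f"metabolite {self.name!r}: marker_loading must lie in [-1, 1]"
            )

    def validate_window(self, ppm_lo: float, ppm_hi: float) -> None:
        """Raise if any peak center falls outside [ppm_lo, ppm_hi]."""
        for center, _, _ in self.peaks:
            if not ppm_lo <= center <= ppm_hi:
                raise ValueError(
                    f"metabolite {self.name!r}: peak at {center} ppm outside "
                    f"window [{ppm_lo}, {ppm_hi}]"
                )


_HW = 0.006  # default half-width at half-maximum, ppm (~3.6 Hz at 600 MHz)


def default_library() -> list[MetaboliteSpec]:
    """Default urinary metabolite library.

    Marker loadings encode the planted prodromal structure: TMAO is the
    strongest positive marker of the latent disease driver, followed by
    PAG, hippurate, DMA, choline and MMA; TMA is weakly negative.
    TCA-cycle intermediates (citrate, 2-oxoglutarate, fumarate) carry the
    extreme-responder signature instead; the remaining metabolites are
    unplanted controls.
    """
    mk = MetaboliteSpec
    return [
        mk("TMAO", [(3.27, 9.0, _HW)], 6.0, 0.9, marker_loading=0.90),
        mk("TMA", [(2.88, 9.0, _HW)], 1.5, 0.0, marker_loading=-0.22),
        mk("DMA", [(2.72, 6.0, _HW)], 3.0, 0.0, marker_loading=0.33),
        mk("MMA", [(2.61, 3.0, _HW)], 1.0, 0.0, marker_loading=0.26),
        mk(
            "choline",
            [(3.20, 9.0, _HW), (3.52, 2.0, _HW), (4.07, 2.0, _HW)],
            2.0,
            0.0,
            marker_loading=0.30,
        ),
        mk(
            "hippurate",
            [(3.97, 2.0, _HW), (7.55, 2.0, _HW), (7.64, 1.0, _HW), (7.83, 2.0, _HW)],
            5.0,
            0.0,
            marker_loading=0.40,
        ),
        mk(
            "PAG",
            [(3.68, 2.0, _HW), (3.75, 2.0, _HW), (7.36, 3.0, _HW), (7.42, 2.0, _HW)],
            2.5,
            0.0,
            marker_loading=0.42,
        ),
        mk(
            "citrate",
            [(2.54, 2.0, _HW), (2.66, 2.0, _HW)],
            4.0,
            0.0,
            extreme_loading=0.9,
        ),
        mk(
            "2-oxoglutarate",
            [(2.44, 2.0, _HW), (3.01, 2.0, _HW)],
            3.0,
            0.0,
            extreme_loading=0.8,
        ),
        mk("fumarate", [(6.52, 4.0, _HW)], 0.8, 0.0, extreme_loading=0.7),
        mk("succinate", [(2.41, 4.0, _HW)], 1.5, 0.0),
        mk("creatinine", [(3.05, 3.0, _HW), (4.06, 2.0, _HW)], 5.0, 0.0),
        mk("lactate", [(1.33, 3.0, _HW), (4.11, 1.0, _HW)], 1.2, 0.0),
        mk("alanine", [(1.48, 3.0, _HW)], 1.0, 0.0),
        mk("taurine", [(3.43, 2.0, _HW)], 2.0, 0.0),
    ]


def dump_library(library: list[MetaboliteSpec], path) -> None:
    """Write a library to a YAML file."""
    payload = [
        {
            "name": m.name,
            "peaks": [list(p) for p in m.peaks],
            "baseline_mean": m.baseline_mean,
            "baseline_sd": m.baseline_sd,
            "marker_loading": m.marker_loading,
            "extreme_loading": m.extreme_loading,
        }
        for m in library
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_library(path) -> list[MetaboliteSpec]:
    """Read a library from a YAML file written by :func:`dump_library`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        MetaboliteSpec(
            name=entry["name"],
            peaks=[tuple(p) for p in entry["peaks"]],
            baseline_mean=entry.get("baseline_mean", 1.0),
            baseline_sd=entry.get("baseline_sd", 0.0),
            marker_loading=entry.get("marker_loading", 0.0),
            extreme_loading=entry.get("extreme_loading", 0.0),
        )
        for entry in payload
    ]
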