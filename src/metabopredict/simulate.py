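"""Synthetic isogenic-mouse cohort generator.

Emulates an HFD-challenge study on ~50 isogenic mice: urinary 1H-NMR
spectra collected at four timepoints (days 0, 1, 2, 20 of the dietary
intervention) plus a day-20 quantitative phenotype table (body weight and
composition, IP-GTT glycemia/insulinemia curves, organ weights, feeding and
behavioral traits).

The statistical backbone is a single latent "disease driver" z per animal
(standard normal).  Baseline log-excretion of marker metabolites is coupled
to z through each metabolite's ``marker_loading`` scaled by
``effect_size``; day-20 phenotypes are monotone functions of z plus
independent noise.  A small number of planted extreme responders (obese
glucose-intolerant, lean glucose-intolerant, and lean normoglycemic
non-responders) receive phenotype boosts that push cumulative glycemia
and/or body weight beyond mean + 2 SD, together with an
"extreme-responder" metabotype shift on TCA-cycle metabolites (scaled by
``effect_size`` so that a zero effect size yields a completely null
metabolome).  Spectra receive per-sample multiplicative dilution
(log-normal), an integer chemical-shift jitter (edge-padded segment shift),
additive Gaussian noise and a smooth baseline.

Every observable is a deterministic function of the configuration and seed;
the full ground truth (z, true concentrations, dilutions, jitters, planted
and realized group labels) is returned alongside the observables.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import MetaboliteSpec, default_library
from .spectra import SpectralDataset
from .stratify import stratify

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "synthesize_spectrum",
    "simulate_cohort",
    "derive_phenotypes",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study design: 50 animals, urine at days
    0/1/2/20, IP-GTT sampling at 0/15/30/75 min, and an effect size
    calibrated so the planted TMAO -> day-20 cumulative-glycemia Spearman
    correlation is ~0.6.
    """

    n_animals: int = 50
    timepoints: tuple[int, ...] = (0, 1, 2, 20)
    n_ppm_points: int = 3000
    ppm_range: tuple[float, float] = (0.5, 9.5)
    noise_sd: float = 0.30
    baseline_amplitude: float = 0.5
    dilution_log_sd: float = 0.30
    jitter_max: int = 4
    effect_size: float = 0.5
    conc_log_sd: float = 0.25
    extreme_shift: float = 2.4
    group_fractions: dict = field(
        default_factory=lambda: {"ob_igt": 0.04, "l_igt": 0.04, "lng": 0.08}
    )
    gtt_times: tuple[float, ...] = (0.0, 15.0, 30.0, 75.0)
    pheno_noise: float = 1.0
    two_drivers: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 14:
            raise ValueError("n_animals must be >= 14 (7-fold CV needs >= 2 per fold)")
        lo, hi = self.ppm_range
        if not lo < hi:
            raise ValueError("ppm_range must satisfy low < high")
        for name in ("noise_sd", "dilution_log_sd", "conc_log_sd", "pheno_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")
        for grp, frac in self.group_fractions.items():
            if int(np.floor(frac * self.n_animals)) < 1:
                raise ValueError(
                    f"infeasible group fraction for {grp!r}: "
                    f"{frac} of {self.n_animals} animals is fewer than 1"
                )

    @property
    def ppm_axis(self) -> np.ndarray:
        lo, hi = self.ppm_range
        return np.linspace(lo, hi, self.n_ppm_points)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyst is meant to recover."""

    z: pd.Series
    z_adiposity: pd.Series
    planted_group: pd.Series
    group_label: pd.Series
    concentrations: dict
    dilutions: dict
    jitters: dict
    noiseless_phenotypes: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: CohortConfig
    library: list[MetaboliteSpec]
    spectra: dict
    phenotypes: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def animal_ids(self) -> list[str]:
        return list(self.phenotypes.index)


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def lorentzian(axis: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Lorentzian line with unit apex and half-width at half-maximum hw."""
    return half_width**2 / ((axis - center) ** 2 + half_width**2)


def mixture_spectrum(
    concentrations: dict, library: list[MetaboliteSpec], axis: np.ndarray
) -> np.ndarray:
    """Noise-free mixture: sum over metabolites of conc x Lorentzian peaks."""
    by_name = {m.name: m for m in library}
    out = np.zeros_like(axis, dtype=float)
    for name, conc in concentrations.items():
        if name not in by_name:
            raise KeyError(f"unknown metabolite {name!r} not in library")
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}: {conc}")
        spec = by_name[name]
        for center, rel, hw in spec.peaks:
            out += conc * rel * lorentzian(axis, center, hw)
    return out


def _smooth_baseline(axis: np.ndarray, amplitude: float, rng) -> np.ndarray:
    """Non-negative smooth baseline from three low-frequency cosines."""
    if amplitude == 0:
        return np.zeros_like(axis)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    out = np.ones_like(u)
    for k in (1, 2, 3):
        out += (rng.uniform(0.2, 0.6) / k) * np.cos(2 * np.pi * k * u + rng.uniform(0, 2 * np.pi))
    out -= out.min()
    return amplitude * out / max(out.max(), 1e-12)


def synthesize_spectrum(
    concentrations: dict,
    library: list[MetaboliteSpec],
    axis: np.ndarray,
    noise_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate one spectrum: mixture + smooth baseline + Gaussian noise.

    Deterministic given ``seed``.  Raises ``KeyError`` for a metabolite name
    absent from the library and ``ValueError`` for a negative concentration
    or a non-monotone axis.
    """
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone")
    rng = np.random.default_rng(seed)
    out = mixture_spectrum(concentrations, library, axis)
    out += _smooth_baseline(axis, baseline_amplitude, rng)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, axis.size)
    return out


def _edge_shift(row: np.ndarray, s: int) -> np.ndarray:
    """Shift a vector by s points, padding with the edge value (no wrap)."""
    if s == 0:
        return row.copy()
    out = np.empty_like(row)
    if s > 0:
        out[s:] = row[:-s]
        out[:s] = row[0]
    else:
        out[:s] = row[-s:]
        out[s:] = row[-1]
    return out


# ---------------------------------------------------------------------------
# phenotype generation
# ---------------------------------------------------------------------------

# trait = intercept + slope * z(driver) + noise_sd * eps [+ boost * indicator]
# Glycemia-axis noise ratios are calibrated jointly with effect_size so the
# TMAO -> cumulative glycemia Spearman rho is ~0.6; BW tracks its driver
# much more tightly (corr ~0.93).

def _raw_phenotypes(cfg: CohortConfig, z_g, z_a, igt, ob, lng, rng, noise=1.0):
    n = len(z_g)

    def tr(intercept, slope, sd, driver, boost=0.0, flag=None, floor=None, count=False):
        vals = intercept + slope * driver + noise * sd * rng.normal(size=n)
        if flag is not None:
            vals = vals + boost * flag
        if floor is not None:
            vals = np.maximum(vals, floor)
        if count:
            vals = np.round(vals)
        return vals

    # planted non-responders (lng) keep CHD-like glycemia and gain no weight
    fg = tr(6.0, 0.3, 0.45, z_g, 0.8, igt, floor=0.5) - 1.2 * lng
    amp_g = tr(8.0, 1.2, 2.0, z_g, 10.2, igt, floor=0.5) - 4.0 * lng
    fi = tr(0.5, 0.10, 0.12, z_g, 0.2, igt, floor=0.02)
    amp_i = tr(1.0, 0.25, 0.30, z_g, 0.5, igt, floor=0.02)

    times = np.asarray(cfg.gtt_times)
    shape_g = np.interp(times, [0, 15, 30, 75], [0.0, 1.0, 0.75, 0.25])
    shape_i = np.interp(times, [0, 15, 30, 75], [0.0, 1.0, 0.60, 0.20])
    gly = fg[:, None] + amp_g[:, None] * shape_g[None, :]
    ins = fi[:, None] + amp_i[:, None] * shape_i[None, :]
    gly += noise * 0.2 * rng.normal(size=gly.shape) * (shape_g > 0)
    ins += noise * 0.05 * rng.normal(size=ins.shape) * (shape_i > 0)
    gly = np.maximum(gly, 0.5)
    ins = np.maximum(ins, 0.02)

    bw0 = tr(20.0, 0.4, 0.5, z_a, floor=10.0)
    bw = tr(28.0, 2.0, 0.8, z_a, 9.0, ob, floor=12.0) - 3.0 * lng
    length = tr(9.5, 0.05, 0.08, z_a, floor=8.0)

    weights = pd.DataFrame(
        {
            "BW_baseline": bw0,
            "BW": bw,
            "body_length": length,
            "EPD": tr(0.45, 0.08, 0.06, z_a, 0.30, ob, floor=0.01),
            "RFP": tr(0.20, 0.04, 0.03, z_a, 0.15, ob, floor=0.005),
            "BAT": tr(0.12, 0.010, 0.02, z_a, floor=0.005),
            "heart": tr(0.15, 0.005, 0.010, z_a, floor=0.02),
            "liver": tr(1.30, 0.06, 0.08, z_a, floor=0.3),
        }
    )

    other = pd.DataFrame(
        {
            "food_intake": tr(3.2, 0.15, 0.30, z_a, floor=0.5),
            "water_intake": tr(4.0, 0.0, 0.5, z_a, floor=0.5),
            "lean_mass": np.maximum(bw * 0.75 + noise * 0.4 * rng.normal(size=n), 5.0),
            "rearings": tr(35.0, -4.0, 8.0, z_a, floor=0.0, count=True),
            "open_arm_entries": tr(8.0, -1.2, 3.0, z_g, floor=0.0, count=True),
            "time_to_open_arm": tr(30.0, 5.0, 15.0, z_g, floor=0.0),
            "distance_OF": tr(2200.0, -150.0, 400.0, z_a, floor=0.0),
            "grooming": tr(6.0, 0.0, 2.0, z_g, floor=0.0, count=True),
            "tail_length": tr(8.2, 0.0, 0.15, z_a, floor=6.0),
        }
    )
    other["dig_energy"] = other["food_intake"] * 15.5 + noise * 0.5 * rng.normal(size=n)
    return times, gly, ins, fg, fi, weights, other


def derive_phenotypes(
    times,
    glycemia: pd.DataFrame,
    insulinemia: pd.DataFrame | None = None,
    weights: pd.DataFrame | None = None,
    bw_col: str = "BW",
    organ_cols: tuple[str, ...] = ("EPD", "RFP", "BAT", "heart", "liver"),
) -> pd.DataFrame:
    """Assemble the quantitative phenotype table from GTT curves + weights.

    Cumulative glycemia (CG) is the trapezoidal area under the glycemia
    curve over the sampling times (mM*min); dG subtracts baseline x
    duration.  Organ-to-BW ratios are appended for every organ column.
    Raises if time 0 is missing or any glycemia value is negative.
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("GTT sampling times must include time 0 as the first point")
    g = np.asarray(glycemia, dtype=float)
    if g.shape[1] != times.size:
        raise ValueError("glycemia columns must match sampling times")
    if np.any(g < 0):
        raise ValueError("negative glycemia value encountered")
    duration = times[-1] - times[0]
    out = pd.DataFrame(index=glycemia.index)
    out["FG"] = g[:, 0]
    for j, t in enumerate(times[1:], start=1):
        out[f"G{int(t)}"] = g[:, j]
    cg = np.trapezoid(g, times, axis=1)
    out["CG"] = cg
    out["dG"] = cg - g[:, 0] * duration
    i15 = np.searchsorted(times, 15.0)
    i30 = np.searchsorted(times, 30.0)
    if i15 < times.size and i30 < times.size and times[i15] == 15 and times[i30] == 30:
        out["K_gly"] = np.log(g[:, i15] / g[:, i30]) / (times[i30] - times[i15]) * 100

    if insulinemia is not None:
        ins = np.asarray(insulinemia, dtype=float)
        out["FI"] = ins[:, 0]
        for j, t in enumerate(times[1:], start=1):
            out[f"I{int(t)}"] = ins[:, j]
        ci = np.trapezoid(ins, times, axis=1)
        out["CI"] = ci
        out["dI"] = ci - ins[:, 0] * duration
        if "K_gly" in out:
            out["K_ins"] = np.log(ins[:, i15] / ins[:, i30]) / (times[i30] - times[i15]) * 100
        out["CI_CG_ratio"] = ci / cg

    if weights is not None:
        for col in weights.columns:
            out[col] = weights[col].to_numpy()
        bw = weights[bw_col].to_numpy(dtype=float)
        for organ in organ_cols:
            if organ in weights.columns:
                out[f"{organ}_ratio"] = weights[organ].to_numpy() / bw
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _planted_groups(cfg: CohortConfig, z: np.ndarray) -> np.ndarray:
    """Assign planted extreme groups from the ranks of z."""
    n = len(z)
    n_ob = int(np.floor(cfg.group_fractions.get("ob_igt", 0) * n))
    n_ligt = int(np.floor(cfg.group_fractions.get("l_igt", 0) * n))
    n_lng = int(np.floor(cfg.group_fractions.get("lng", 0) * n))
    order = np.argsort(z)
    planted = np.array(["none"] * n, dtype=object)
    planted[order[::-1][:n_ob]] = "ob_igt"
    planted[order[::-1][n_ob : n_ob + n_ligt]] = "l_igt"
    planted[order[:n_lng]] = "lng"
    return planted


def _phenotype_table(cfg, ids, z_g, z_a, igt, ob, lng, rng, noise):
    times, gly, ins, fg, fi, weights, other = _raw_phenotypes(
        cfg, z_g, z_a, igt, ob, lng, rng, noise=noise
    )
    gly_df = pd.DataFrame(gly, index=ids)
    ins_df = pd.DataFrame(ins, index=ids)
    weights.index = ids
    other.index = ids
    pheno = derive_phenotypes(times, gly_df, ins_df, weights)
    pheno = pd.concat([pheno, other], axis=1)
    pheno["BW_gain"] = pheno["BW"] - pheno["BW_baseline"]
    pheno["BMI"] = pheno["BW"] / pheno["body_length"] ** 2
    return pheno


def simulate_cohort(
    config: CohortConfig | None = None, library: list[MetaboliteSpec] | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    All randomness flows from ``config.seed`` through a tree of
    ``numpy.random.SeedSequence`` children, so the result is bit-identical
    for identical configurations.
    """
    cfg = config or CohortConfig()
    lib = library if library is not None else default_library()
    lo, hi = cfg.ppm_range
    for m in lib:
        m.validate_window(lo, hi)
    axis = cfg.ppm_axis
    ids = [f"M{i + 1:02d}" for i in range(cfg.n_animals)]

    root = np.random.SeedSequence(cfg.seed)
    ss_z, ss_conc, ss_pheno, ss_spec = root.spawn(4)

    rng_z = np.random.default_rng(ss_z)
    z = rng_z.standard_normal(cfg.n_animals)
    z_a = rng_z.standard_normal(cfg.n_animals) if cfg.two_drivers else z
    planted = _planted_groups(cfg, z)
    igt = np.isin(planted, ["ob_igt", "l_igt"]).astype(float)
    ob = (planted == "ob_igt").astype(float)
    lng = (planted == "lng").astype(float)
    extreme = (planted != "none").astype(float)

    # --- metabolite concentrations per timepoint -----------------------
    rng_c = np.random.default_rng(ss_conc)
    es = cfg.effect_size
    conc: dict[int, pd.DataFrame] = {}
    log_c0 = {}
    for m in lib:
        sd = (m.baseline_sd / m.baseline_mean) if m.baseline_sd > 0 else cfg.conc_log_sd
        log_c0[m.name] = (
            np.log(m.baseline_mean)
            + es * m.marker_loading * z
            + es * cfg.extreme_shift * m.extreme_loading * extreme
            + sd * rng_c.standard_normal(cfg.n_animals)
        )
    for tp in cfg.timepoints:
        cols = {}
        for m in lib:
            trend = 0.5 * max(m.marker_loading, 0.0)
            drift = 0.1 * rng_c.standard_normal(cfg.n_animals) if tp > 0 else 0.0
            cols[m.name] = np.exp(log_c0[m.name] + trend * tp / 20.0 + drift)
        conc[tp] = pd.DataFrame(cols, index=ids)

    # --- phenotypes -----------------------------------------------------
    ss_p1, ss_p2 = ss_pheno.spawn(2)
    pheno = _phenotype_table(
        cfg, ids, z, z_a, igt, ob, lng, np.random.default_rng(ss_p1), cfg.pheno_noise
    )
    pheno_true = _phenotype_table(
        cfg, ids, z, z_a, igt, ob, lng, np.random.default_rng(ss_p2), 0.0
    )
    true_strat = stratify(pheno_true, "CG", "BW")

    # --- spectra --------------------------------------------------------
    spectra: dict[int, SpectralDataset] = {}
    dilutions: dict[int, pd.Series] = {}
    jitters: dict[int, pd.Series] = {}
    for tp, ss_tp in zip(cfg.timepoints, ss_spec.spawn(len(cfg.timepoints))):
        rng_s = np.random.default_rng(ss_tp)
        dil = np.exp(rng_s.normal(0.0, cfg.dilution_log_sd, cfg.n_animals))
        jit = (
            rng_s.integers(-cfg.jitter_max, cfg.jitter_max + 1, cfg.n_animals)
            if cfg.jitter_max > 0
            else np.zeros(cfg.n_animals, dtype=int)
        )
        rows = np.empty((cfg.n_animals, axis.size))
        for i, aid in enumerate(ids):
            clean = mixture_spectrum(conc[tp].loc[aid].to_dict(), lib, axis)
            clean += _smooth_baseline(axis, cfg.baseline_amplitude, rng_s)
            noisy = dil[i] * clean
            if cfg.noise_sd > 0:
                noisy = noisy + rng_s.normal(0.0, cfg.noise_sd, axis.size)
            rows[i] = _edge_shift(noisy, int(jit[i]))
        meta = pd.DataFrame(
            {"animal": ids, "timepoint": tp, "diet": "HFD"}, index=ids
        )
        spectra[tp] = SpectralDataset(axis.copy(), rows, ids, meta)
        dilutions[tp] = pd.Series(dil, index=ids)
        jitters[tp] = pd.Series(jit, index=ids)

    gt = GroundTruth(
        z=pd.Series(z, index=ids, name="z"),
        z_adiposity=pd.Series(z_a, index=ids, name="z_adiposity"),
        planted_group=pd.Series(planted, index=ids, name="planted_group"),
        group_label=true_strat.labels.rename("group_label"),
        concentrations=conc,
        dilutions=dilutions,
        jitters=jitters,
        noiseless_phenotypes=pheno_true,
    )
    return SyntheticCohort(cfg, lib, spectra, pheno, gt)


def write_cohort(cohort: SyntheticCohort, outdir, sep: str = "\t") -> None:
    """Write spectra, phenotypes and ground truth as plain-text files."""
    os.makedirs(outdir, exist_ok=True)
    for tp, ds in cohort.spectra.items():
        ds.write(os.path.join(outdir, f"spectra_day{tp}.tsv"), sep=sep)
    cohort.phenotypes.to_csv(
        os.path.join(outdir, "phenotypes_day20.tsv"), sep=sep, index_label="animal"
    )
    gt = cohort.ground_truth
    truth = {
        "z": gt.z.round(10).to_dict(),
        "planted_group": gt.planted_group.to_dict(),
        "group_label": gt.group_label.to_dict(),
        "dilutions": {str(tp): s.round(10).to_dict() for tp, s in gt.dilutions.items()},
        "jitters": {str(tp): {k: int(v) for k, v in s.items()} for tp, s in gt.jitters.items()},
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    for tp, df in gt.concentrations.items():
        df.to_csv(
            os.path.join(outdir, f"true_concentrations_day{tp}.tsv"),
            sep=sep,
            index_label="animal",
        )
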