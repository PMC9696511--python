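"""Synthetic drug-polymer solubility corpora for testing the pipeline.

Noise-free solubility curves come from the Flory-Huggins melting-point
depression relation

    1/T_mix - 1/T_m = -(R / dH_fus) * [ ln(phi_d) + (1 - 1/m) * phi_p
                                        + chi * phi_p^2 ]

with phi the drug/polymer volume fractions (equal densities assumed, so the
weight fraction doubles as the volume fraction), m the polymer chain length
(polymer Mw over repeat-unit Mw) and chi the interaction parameter.  The
relation is explicit in 1/T, so T_mix has a closed form; at 100 wt% drug it
reduces exactly to the pure-drug melting temperature.  The generator is a
test fixture that reproduces the qualitative structure of measured
drug-polymer phase diagrams (monotone-increasing T_sol vs load, strong
positive load effect, weak positive polymer-Mw effect, negative drug-Mw
effect); it is not a physically validated phase-diagram predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, SolubilityRecord

R_GAS = 8.314  # J/(mol K)
_ZERO_C = 273.15


@dataclass(frozen=True)
class SyntheticDrug:
    name: str
    mw: float               # g/mol
    melt_temp: float        # degC
    fusion_enthalpy: float  # J/mol

    def __post_init__(self) -> None:
        if self.fusion_enthalpy <= 0:
            raise ValueError("fusion_enthalpy must be > 0")


@dataclass(frozen=True)
class SyntheticPolymer:
    name: str
    mw: float               # g/mol
    interaction_chi: float  # dimensionless Flory-Huggins parameter
    repeat_unit_mw: float   # g/mol

    def __post_init__(self) -> None:
        if not self.mw > self.repeat_unit_mw > 0:
            raise ValueError("require mw > repeat_unit_mw > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_systems: int = 20
    points_per_system: int = 8
    load_range: tuple[float, float] = (5.0, 100.0)
    noise_sd: float = 5.0   # degC measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.load_range
        if not (0.0 < lo <= hi <= 100.0):
            raise ValueError("load_range must lie within (0, 100]")
        if self.n_systems < 1 or self.points_per_system < 1:
            raise ValueError("n_systems and points_per_system must be >= 1")


def solubility_curve(drug: SyntheticDrug, polymer: SyntheticPolymer, loads) -> np.ndarray:
    """Noise-free T_sol (degC) at the given drug loads (wt%, in (0, 100])."""
    loads = np.asarray(loads, dtype=float)
    if np.any(loads <= 0) or np.any(loads > 100):
        raise ValueError("loads must lie in (0, 100] wt% (ln(0) undefined at 0)")
    phi_d = loads / 100.0
    phi_p = 1.0 - phi_d
    m = polymer.mw / polymer.repeat_unit_mw
    t_m = drug.melt_temp + _ZERO_C
    bracket = np.log(phi_d) + (1.0 - 1.0 / m) * phi_p + polymer.interaction_chi * phi_p**2
    inv_t = 1.0 / t_m - (R_GAS / drug.fusion_enthalpy) * bracket
    return 1.0 / inv_t - _ZERO_C


def _sample_drug(rng: np.random.Generator, name: str) -> SyntheticDrug:
    mw = rng.uniform(150.0, 700.0)
    # higher-Mw drugs get lower melting points, giving the corpus its
    # negative drug-Mw association with T_sol
    melt = np.clip(260.0 - 0.28 * (mw - 150.0) + rng.normal(0.0, 4.0), 80.0, 260.0)
    dh = max(24000.0 + 20.0 * (mw - 150.0) + rng.normal(0.0, 1000.0), 15000.0)
    return SyntheticDrug(name, mw, float(melt), float(dh))


def _sample_polymer(rng: np.random.Generator, name: str) -> SyntheticPolymer:
    # oligomer-to-polymer span (the compiled literature includes a VP dimer),
    # so the chain-length term (1 - 1/m) genuinely varies across carriers
    log_mw = rng.uniform(2.4, 5.1)
    mw = 10.0 ** log_mw
    repeat = float(np.clip(100.0 + rng.normal(0.0, 10.0), 80.0, 120.0))
    # heavier carriers also get a slightly larger chi, giving the corpus its
    # weak positive polymer-Mw association with T_sol (the chain-length term
    # alone saturates once m >> 1)
    chi = rng.uniform(-0.1, 0.05) + 0.7 * (log_mw - 2.4) / 2.7
    return SyntheticPolymer(name, float(mw), float(chi), repeat)


def generate_corpus(config: GeneratorConfig) -> Dataset:
    """Random corpus of ``n_systems`` drug-polymer systems, Gaussian noise on T_sol."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.load_range
    records = []
    for s in range(config.n_systems):
        drug = _sample_drug(rng, f"drug{s + 1:02d}")
        polymer = _sample_polymer(rng, f"polymer{s + 1:02d}")
        loads = np.linspace(lo, hi, config.points_per_system)
        t_clean = solubility_curve(drug, polymer, loads)
        noise = rng.normal(0.0, config.noise_sd, size=len(loads)) if config.noise_sd > 0 else 0.0
        t_obs = t_clean + noise
        for load, t in zip(loads, np.atleast_1d(t_obs)):
            records.append(
                SolubilityRecord(drug.name, polymer.name, drug.mw, polymer.mw,
                                 float(load), float(t))
            )
    return Dataset(records, provenance=f"synthetic corpus (seed={config.seed})")


# ---------------------------------------------------------------------------
# Synthetic stand-in for the published 278-record literature compilation
# ---------------------------------------------------------------------------

# (name, Mw g/mol, melting temperature degC, fusion enthalpy J/mol);
# Mw and melting points are realistic literature-style values, enthalpies typical
_DRUGS = {
    "Acetaminophen":    (151.16, 169.0, 27600.0),
    "Celecoxib":        (381.37, 162.5, 36000.0),
    "Chloramphenicol":  (323.13, 150.5, 41000.0),
    "D-Mannitol":       (182.17, 166.0, 53500.0),
    "Felodipine":       (384.25, 145.0, 30800.0),
    "Ibuprofen":        (206.28,  76.0, 25500.0),
    "Ibuprofen Sodium": (228.26, 198.3, 24000.0),
    "Indomethacin":     (357.79, 160.0, 39300.0),
    "Itraconazole":     (705.63, 166.0, 57000.0),
    "Naproxen":         (230.26, 156.0, 31500.0),
    "Nifedipine":       (346.33, 173.0, 39000.0),
    "Paracetamol":      (151.16, 169.0, 27600.0),
    "Sulfadiazine":     (250.28, 252.7, 44000.0),
    "Sulfadimidine":    (278.33, 197.5, 38600.0),
    "Sulfamerazine":    (264.30, 236.0, 41300.0),
    "Sulfathiazole":    (255.32, 202.5, 38000.0),
}

# (name, Mw g/mol, repeat-unit Mw g/mol)
_POLYMERS = {
    "VP dimer":   (224.30, 112.15),
    "PVAc":       (90000.0, 86.09),
    "PVP K12":    (4000.0, 111.14),
    "PVP K15":    (8000.0, 111.14),
    "PVP K17":    (10000.0, 111.14),
    "PVP K25":    (29000.0, 111.14),
    "PVP":        (50000.0, 111.14),
    "PVP/VA":     (51000.0, 98.0),
    "PVP/VA 335": (28000.0, 98.0),
    "PVP/VA 535": (38000.0, 98.0),
    "PVP/VA 635": (45000.0, 98.0),
    "PVP/VA 735": (55000.0, 98.0),
    "Soluplus":   (118000.0, 115.0),
}

# six literature study groups: (drugs, polymers, load range wt%, total records)
_STUDY_GROUPS = [
    (["Sulfadiazine", "Sulfadimidine", "Sulfamerazine", "Sulfathiazole"],
     ["PVP", "Soluplus"], (1.0, 100.0), 56),
    (["Acetaminophen", "Ibuprofen", "Ibuprofen Sodium", "Itraconazole",
      "Naproxen", "Nifedipine"],
     ["PVP/VA", "Soluplus"], (20.0, 100.0), 56),
    (["D-Mannitol", "Indomethacin", "Nifedipine"],
     ["PVAc", "PVP K12", "PVP K15", "PVP K25", "PVP/VA", "VP dimer"],
     (5.0, 100.0), 59),
    (["Celecoxib", "Chloramphenicol", "Paracetamol"],
     ["PVAc", "PVP", "Soluplus"], (8.0, 95.0), 53),
    (["Celecoxib", "Chloramphenicol", "Felodipine", "Indomethacin", "Paracetamol"],
     ["PVP K17", "PVP/VA 335", "PVP/VA 535", "PVP/VA 635", "PVP/VA 735"],
     (60.0, 95.0), 35),
    (["D-Mannitol", "Indomethacin", "Nifedipine"],
     ["PVP K15", "PVP/VA"], (22.2, 100.0), 19),
]

_CHI_SEED = 1405  # fixed: interaction parameters are part of the corpus definition


def literature_like_corpus(seed: int, noise_sd: float = 10.0) -> Dataset:
    """SYNTHETIC stand-in for the 278-record literature compilation of drug
    solubility temperatures in polymers.

    The published compilation itself is not redistributed here; this function
    regenerates a corpus with the same structure — the same six study groups
    (drug and polymer sets, drug-load ranges, per-group record counts summing
    to 278), 16 drugs, 13 polymers, loads 1-100 wt% and solubility
    temperatures topping out at 252.7 degC (pure sulfadiazine) — from
    Flory-Huggins curves over realistic drug/polymer properties plus Gaussian
    measurement noise.  Pure-drug records (100 wt%) carry no noise: melting
    temperatures are tabulated reference values.

    ``seed`` controls only the noise realization; the systems, loads and
    interaction parameters are fixed so the corpus is the same study design
    every time.
    """
    # one chi per distinct physical system, fixed across study groups and seeds
    chi_rng = np.random.default_rng(_CHI_SEED)
    chi_table: dict[tuple[str, str], float] = {}
    for drugs, polymers, _, _ in _STUDY_GROUPS:
        for pair in ((d, p) for d in drugs for p in polymers):
            if pair not in chi_table:
                chi_table[pair] = float(chi_rng.uniform(-0.3, 0.2))
    noise_rng = np.random.default_rng(seed)
    records = []
    for drugs, polymers, (lo, hi), n_total in _STUDY_GROUPS:
        systems = [(d, p) for d in drugs for p in polymers]
        k = len(systems)
        base, extra = divmod(n_total, k)
        for i, (dname, pname) in enumerate(systems):
            n_pts = base + (1 if i < extra else 0)
            if n_pts == 0:
                continue
            dmw, melt, dh = _DRUGS[dname]
            pmw, repeat = _POLYMERS[pname]
            chi = chi_table[(dname, pname)]
            drug = SyntheticDrug(dname, dmw, melt, dh)
            polymer = SyntheticPolymer(pname, pmw, chi, repeat)
            loads = np.linspace(lo, hi, n_pts) if n_pts > 1 else np.array([hi])
            t_clean = solubility_curve(drug, polymer, loads)
            for load, t in zip(loads, t_clean):
                t_obs = t if load == 100.0 or noise_sd == 0 else t + noise_rng.normal(0.0, noise_sd)
                records.append(
                    SolubilityRecord(dname, pname, dmw, pmw, float(load), float(t_obs))
                )
    return Dataset(records, provenance=f"synthetic literature-like corpus (seed={seed})")
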