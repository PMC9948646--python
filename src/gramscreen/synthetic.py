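"""Synthetic LUV populations, stopped-flow traces, and drug libraries.

The generator emulates the study conditions of the screen: extruded
DC22:1PC vesicles with mean hydrodynamic diameter 130 nm and
polydispersity index (PDI, (σ/d)²) 0.09, doped with gramicidin at a
1:2,000 peptide:lipid molar ratio; Tl⁺ quench traces sampled at 5,000
points/s over 1 s with a ~1.2 ms instrument dead time; and a 400-drug
library whose HepG2 CC20 cytotoxicity is stochastically coupled to the
true bilayer-modifying potency through a logistic link so the
odds-ratio stage has recoverable structure.

Per-vesicle kinetics are single-exponential filling with rate
proportional to conducting-channel count over vesicle volume; the
aggregate trace is the fluorophore-weighted Stern–Volmer mixture of
those filling curves.  Drug action is modelled as a multiplicative
scaling of the conducting-dimer density (the monomer↔dimer equilibrium
shift) applied before Poisson sampling of per-vesicle channel counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import FluorescenceTrace

__all__ = [
    "LUVPopulation",
    "SyntheticDrug",
    "simulate_luv_population",
    "simulate_quench_trace",
    "simulate_drug_library",
    "compute_pdi",
    "analytic_initial_rate",
]

# Bilayer / assay constants used by the generator defaults.
AREA_PER_LIPID_NM2 = 0.7          # headgroup area, both-leaflet count uses 2x
GRAMICIDIN_RATIO = 1.0 / 2000.0   # gD : lipid molar ratio
DIMER_FRACTION = 0.3              # conducting dimers per gD monomer (1-s average)
CHANNEL_PERMEABILITY = 7e-20      # per-channel volume clearance (L/s)
MLV_FRAC = 0.05                   # unquenchable multilamellar-vesicle fraction
KSV = 60.0                        # Stern-Volmer coefficient (1/M)
TL_EXT = 0.025                    # extravesicular Tl+ after mixing (M)
SAMPLE_RATE = 5000.0              # points/s
DURATION = 1.0                    # s
DEADTIME = 1.2e-3                 # s
EXTRA_FRAC = 0.05                 # extravesicular ANTS fraction of F(0,b)


@dataclass(frozen=True)
class LUVPopulation:
    """A dispersed population of fluorophore-loaded vesicles.

    ``channel_mean`` is the Poisson mean conducting-dimer count per
    vesicle (proportional to surface area × gramicidin ratio × dimer
    fraction); ``channel_counts`` is one Poisson draw from it.
    ``fluor_load`` is proportional to vesicle volume (encapsulated dye).
    ``d_mean`` and ``pdi`` are the empirical moments of ``diameters``.
    """

    diameters: np.ndarray          # nm
    channel_mean: np.ndarray       # expected conducting dimers per vesicle
    channel_counts: np.ndarray     # integer >= 0
    fluor_load: np.ndarray         # arb. units, ∝ volume
    d_mean: float                  # nm
    pdi: float

    def __post_init__(self) -> None:
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        if np.any(self.channel_counts < 0):
            raise ValueError("channel counts must be >= 0")

    def __len__(self) -> int:
        return self.diameters.size

    @property
    def volumes_l(self) -> np.ndarray:
        """Per-vesicle internal volume in liters."""
        return (math.pi / 6.0) * self.diameters**3 * 1e-24


@dataclass(frozen=True)
class SyntheticDrug:
    """One synthetic library entry mirroring the per-drug table schema."""

    id: str
    alogp: float
    psa: float
    qed: float
    pscore: float
    cc20: float | None            # µM in (0, 80], or None (missing)
    fu_mouse: float
    fu_mic: float
    normrate: float               # measured (noisy) NormRate
    normrate_disp: float
    disp_kind: str
    true_normrate: float          # ground-truth equilibrium shift

    def __post_init__(self) -> None:
        if self.true_normrate <= 0:
            raise ValueError("true_normrate must be > 0")
        if self.cc20 is not None and not 0 < self.cc20 <= 80:
            raise ValueError(f"cc20 must be in (0, 80], got {self.cc20}")


def compute_pdi(diameters: np.ndarray) -> float:
    """Polydispersity index (σ/mean)² of a diameter sample."""
    d = np.asarray(diameters, dtype=float)
    return float(np.var(d) / np.mean(d) ** 2)


def simulate_luv_population(
    n: int,
    d_mean: float = 130.0,
    pdi: float = 0.09,
    gramicidin_ratio: float = GRAMICIDIN_RATIO,
    dimer_fraction: float = DIMER_FRACTION,
    seed: int = 0,
) -> LUVPopulation:
    """Draw a lognormal LUV population with Poisson channel counts.

    The lognormal family guarantees positive diameters and matches the
    single-peak size distributions seen in dynamic light scattering of
    extruded vesicles; its parameters are solved so the sample mean is
    ``d_mean`` and the squared coefficient of variation is ``pdi``.
    Channel counts are Poisson with mean proportional to vesicle surface
    area (both leaflets) × gramicidin mole fraction × dimer fraction;
    vesicles drawing 0 channels feed the unquenchable compartment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pdi < 0:
        raise ValueError("pdi must be >= 0")
    rng = np.random.default_rng(seed)
    if pdi == 0:
        diameters = np.full(n, float(d_mean))
    else:
        sigma2 = math.log1p(pdi)
        mu = math.log(d_mean) - sigma2 / 2.0
        diameters = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    lipids = 2.0 * math.pi * diameters**2 / AREA_PER_LIPID_NM2  # both leaflets
    channel_mean = lipids * gramicidin_ratio * dimer_fraction
    channel_counts = rng.poisson(channel_mean)
    volumes = (math.pi / 6.0) * diameters**3  # nm^3; arb. fluorophore units
    return LUVPopulation(
        diameters=diameters,
        channel_mean=channel_mean,
        channel_counts=channel_counts,
        fluor_load=volumes,
        d_mean=float(np.mean(diameters)),
        pdi=compute_pdi(diameters),
    )


def _vesicle_rates(
    counts: np.ndarray, pop: LUVPopulation, channel_permeability: float
) -> np.ndarray:
    """Per-vesicle Tl⁺ filling rate constants (1/s), ∝ channels/volume."""
    return channel_permeability * counts / pop.volumes_l


def analytic_initial_rate(
    pop: LUVPopulation,
    drug_normrate: float = 1.0,
    channel_permeability: float = CHANNEL_PERMEABILITY,
    ksv: float = KSV,
    tl_ext: float = TL_EXT,
    use_expected_counts: bool = True,
) -> float:
    """Ground-truth initial quench rate of the aggregate trace (1/s).

    The aggregate signal of the quenchable vesicles is
    Σ_v f_v / (1 + K_SV·[Tl+]_i,v(t)); differentiating at t = 0 and
    normalizing by F(0,q) − F(∞,q) gives the fluorophore-weighted mean
    (1 + K_SV[Tl+]_e)·⟨k_v⟩_f.  This is the independent oracle against
    which fitted rates are judged.  With ``use_expected_counts`` the
    Poisson sampling noise is marginalized out (counts replaced by their
    means, scaled by the drug's equilibrium shift).
    """
    counts = (
        pop.channel_mean * drug_normrate
        if use_expected_counts
        else pop.channel_counts.astype(float)
    )
    k = _vesicle_rates(counts, pop, channel_permeability)
    quenchable = counts > 0 if not use_expected_counts else np.ones(len(pop), bool)
    w = pop.fluor_load[quenchable]
    if w.sum() == 0:
        raise ValueError("population has no quenchable vesicles")
    mean_k = float(np.average(k[quenchable], weights=w))
    return (1.0 + ksv * tl_ext) * mean_k


def simulate_quench_trace(
    pop: LUVPopulation,
    drug_normrate: float = 1.0,
    duration: float = DURATION,
    sample_rate: float = SAMPLE_RATE,
    deadtime: float = DEADTIME,
    noise_sd: float | None = None,
    seed: int = 0,
    mix_type: str = "quencher",
    replicate_id: str = "r0",
    ksv: float = KSV,
    tl_ext: float = TL_EXT,
    channel_permeability: float = CHANNEL_PERMEABILITY,
    extra_frac: float = EXTRA_FRAC,
    mlv_frac: float = MLV_FRAC,
    resample_channels: bool = False,
) -> FluorescenceTrace:
    """Simulate one stopped-flow mixing reaction.

    The drug shifts the gramicidin monomer↔dimer equilibrium, so vesicle
    channel-count means are scaled by ``drug_normrate`` before Poisson
    sampling; at drug_normrate == 1 the population's stored counts are
    reused by default (``resample_channels=True`` forces a fresh
    Poisson draw).  The total signal is
    normalized so F(0,b) = 1: a fraction ``extra_frac`` is extravesicular
    dye, ``mlv_frac`` is dye in multilamellar vesicles, and the rest is
    distributed over vesicles ∝ volume.  Gaussian noise (default 1% of
    F(0,b)) is added, and samples before the dead time are removed.
    """
    if len(pop) == 0:
        raise ValueError("empty vesicle population")
    if duration <= deadtime:
        raise ValueError("duration must exceed the dead time")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sample_rate))
    t_all = np.arange(n_samples) / sample_rate
    keep = t_all >= deadtime
    t = t_all[keep]

    f0b = 1.0
    if noise_sd is None:
        noise_sd = 0.01 * f0b

    if mix_type == "buffer":
        signal = np.full(t.size, f0b) + rng.normal(0.0, noise_sd, t.size)
        return FluorescenceTrace(time=t, signal=signal, mix_type="buffer",
                                 replicate_id=replicate_id)
    if mix_type != "quencher":
        raise ValueError(f"unknown mix_type {mix_type!r}")

    if resample_channels or drug_normrate != 1.0:
        counts = rng.poisson(pop.channel_mean * drug_normrate)
    else:
        counts = pop.channel_counts
    k = _vesicle_rates(counts, pop, channel_permeability)

    intrav_total = f0b * (1.0 - extra_frac - mlv_frac)
    f_v = pop.fluor_load / pop.fluor_load.sum() * intrav_total
    x = ksv * tl_ext

    signal = np.zeros(t.size)
    chunk = 512  # bound the vesicle x time work array
    for i in range(0, len(pop), chunk):
        ki = k[i : i + chunk, None]
        tli = tl_ext * (1.0 - np.exp(-ki * t[None, :]))
        signal += (f_v[i : i + chunk, None] / (1.0 + ksv * tli)).sum(axis=0)
    signal += extra_frac * f0b / (1.0 + x)   # quenched within dead time
    signal += mlv_frac * f0b                  # unquenchable multilamellar pool
    signal += rng.normal(0.0, noise_sd, t.size)
    return FluorescenceTrace(time=t, signal=signal, mix_type="quencher",
                             replicate_id=replicate_id)


# --- drug library ---------------------------------------------------------

#: Default potency mixture: shares of inert/low, moderate, and high
#: bilayer-modifying drugs matching the screened library (199/74/127 of 400).
DEFAULT_POTENCY_MIX: dict[str, float] = {
    "low": 199 / 400,
    "moderate": 74 / 400,
    "high": 127 / 400,
}

#: Logistic link P(CC20 < 50 µM) = expit(intercept + slope·ln NormRate).
#: Chosen so a low-potency drug has ~60% and the high-potency bin ~90%
#: probability of being likely-cytotoxic, with ~71% overall.
COUPLING_INTERCEPT = 0.3
COUPLING_SLOPE = 1.5


def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Apportion ``n`` into integer counts ∝ fractions, deterministically."""
    raw = fractions / fractions.sum() * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def simulate_drug_library(
    n_drugs: int = 400,
    potency_mix: dict[str, float] | None = None,
    coupling: float = COUPLING_SLOPE,
    coupling_intercept: float = COUPLING_INTERCEPT,
    missing_fraction: float = 3 / 400,
    measurement_cv: float = 0.05,
    seed: int = 0,
) -> list[SyntheticDrug]:
    """Generate a drug library with potency-coupled cytotoxicity.

    True NormRates are drawn from a three-component mixture (uniform on
    [0.85, 1.25) / [1.25, 1.5) / log-uniform on [1.5, 15]); the chance a
    drug is likely cytotoxic (CC20 < 50 µM) follows a logistic link in
    ln(true NormRate) with slope ``coupling`` (0 decouples the two).
    CC20 values are truncated at 80 µM and exactly
    ``round(missing_fraction * n_drugs)`` drugs lack CC20.  Descriptor
    columns carry only weak, configured correlation with potency
    (hydrophobicity mildly positive, drug-likeness mildly negative).
    Measured NormRate is the ground truth with lognormal duplicate
    noise, reported as mean ± half-range of two pseudo-replicates.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    mix = dict(DEFAULT_POTENCY_MIX if potency_mix is None else potency_mix)
    unknown = set(mix) - {"low", "moderate", "high"}
    if unknown or not mix:
        raise ValueError(f"invalid potency mix components: {sorted(unknown)}")
    if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError("potency mix fractions must be non-negative, sum > 0")

    rng = np.random.default_rng(seed)
    names = ["low", "moderate", "high"]
    fracs = np.array([mix.get(k, 0.0) for k in names], float)
    counts = _largest_remainder_counts(fracs, n_drugs)

    parts = []
    n_low, n_mod, n_high = counts
    parts.append(rng.uniform(0.85, 1.25, n_low))
    parts.append(rng.uniform(1.25, 1.5, n_mod))
    parts.append(np.exp(rng.uniform(math.log(1.5), math.log(15.0), n_high)))
    true_nr = np.concatenate(parts)
    rng.shuffle(true_nr)

    log_nr = np.log(true_nr)
    from scipy.special import expit

    p_toxic = expit(coupling_intercept + coupling * log_nr)
    toxic = rng.random(n_drugs) < p_toxic
    cc20 = np.where(
        toxic,
        np.exp(rng.uniform(0.0, math.log(50.0), n_drugs)),     # (1, 50) µM
        np.minimum(rng.uniform(50.0, 95.0, n_drugs), 80.0),    # truncated at 80
    )
    n_missing = int(round(missing_fraction * n_drugs))
    missing_idx = set(rng.choice(n_drugs, size=n_missing, replace=False).tolist())

    alogp = 1.8 + 0.9 * log_nr + rng.normal(0.0, 1.3, n_drugs)
    psa = np.clip(rng.normal(85.0, 30.0, n_drugs), 3.0, 250.0)
    qed = np.clip(0.55 - 0.05 * log_nr + rng.normal(0.0, 0.18, n_drugs), 0.01, 0.99)
    pscore = np.clip(np.exp(rng.normal(3.5, 1.5, n_drugs)), 0.0, 600.0)
    fu_mouse = np.clip(rng.beta(2.0, 2.0, n_drugs), 0.0, 1.0)
    fu_mic = np.clip(rng.beta(2.0, 2.0, n_drugs), 0.0, 1.0)

    # two pseudo-replicate measurements -> mean ± half-range (duplicate rule)
    reps = true_nr[:, None] * np.exp(rng.normal(0.0, measurement_cv, (n_drugs, 2)))
    nr_meas = reps.mean(axis=1)
    nr_disp = np.abs(reps[:, 0] - reps[:, 1]) / 2.0

    drugs = []
    for i in range(n_drugs):
        drugs.append(
            SyntheticDrug(
                id=f"SYN{i + 1:06d}",
                alogp=float(alogp[i]),
                psa=float(psa[i]),
                qed=float(qed[i]),
                pscore=float(pscore[i]),
                cc20=None if i in missing_idx else float(cc20[i]),
                fu_mouse=float(fu_mouse[i]),
                fu_mic=float(fu_mic[i]),
                normrate=float(nr_meas[i]),
                normrate_disp=float(nr_disp[i]),
                disp_kind="half_range",
                true_normrate=float(true_nr[i]),
            )
        )
    return drugs
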