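"""Per-drug bilayer-modifying-potency quantities.

The screen's central statistic is *NormRate*, the initial quench rate in
the presence of a drug divided by the drug-free control rate.  Because
the quench rate tracks the number of conducting gramicidin dimers, the
drug-induced change in the bilayer contribution to the dimerization free
energy is, to first order,

    ddG_bilayer ≈ -R·T·ln(NormRate)    (kcal/mol)

valid when the monomer pool is essentially unperturbed (equilibrium
biased toward monomers, as in thick DC22:1PC bilayers).  A softening
drug (NormRate > 1) gives ddG < 0; a stiffening drug gives ddG > 0.

Drugs partition between the aqueous and membrane phases; with partition
coefficient K1 = [Drug]_m/[Drug]_a and lipid/aqueous volume ratio
V_lip/V_aq, the nominal concentration splits as

    [Drug]_a = [Drug]_nom / (1 + K1·V_lip/V_aq),  [Drug]_m = K1·[Drug]_a.

K1 is approximated from the hydrophobicity descriptor as 10**ALogP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_VLIP_OVER_VAQ",
    "PotencyResult",
    "PartitionParams",
    "norm_rate",
    "norm_rate_bsa",
    "delta_delta_g",
    "categorize",
    "display_normrate",
    "partition_concentrations",
    "k1_from_alogp",
    "scale_normrate",
    "evaluate_drug",
]

R_KCAL_PER_MOL_K = 1.9872e-3     # gas constant, kcal/(mol·K)
DEFAULT_TEMPERATURE_K = 298.15   # 25 °C, the assay temperature
DEFAULT_VLIP_OVER_VAQ = 3.6e-5   # lipid/aqueous volume ratio of the assay

#: Potency category edges: low [<1.25), moderate [1.25, 1.5), high [1.5, inf).
CATEGORY_EDGES = (1.25, 1.5)


@dataclass(frozen=True)
class PartitionParams:
    """Membrane/water partitioning inputs for one drug."""

    k1: float                    # partition coefficient [Drug]_m/[Drug]_a
    vlip_over_vaq: float = DEFAULT_VLIP_OVER_VAQ
    nominal: float = 10e-6       # total drug concentration (M)

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("k1 must be >= 0")
        if self.vlip_over_vaq <= 0:
            raise ValueError("vlip_over_vaq must be > 0")


@dataclass(frozen=True)
class PotencyResult:
    """All potency quantities for one drug at one nominal concentration."""

    normrate: float
    ddg: float                   # kcal/mol
    category: str                # 'low' | 'moderate' | 'high'
    drug_aq: float               # M
    drug_mem: float              # M
    normrate_bsa: float | None = None


def norm_rate(rate_drug: float, rate_cntrl: float) -> float:
    """Quench rate normalized to the drug-free control."""
    if rate_cntrl <= 0:
        raise ValueError("control rate must be > 0")
    return rate_drug / rate_cntrl


def norm_rate_bsa(rate_drug_bsa: float, rate_bsa: float) -> float:
    """NormRate with the albumin-only measurement as the control.

    Comparing this with the BSA-free NormRate screens for albumin
    binding: a bound drug has a smaller free concentration and a
    correspondingly smaller equilibrium shift.
    """
    if rate_bsa <= 0:
        raise ValueError("BSA control rate must be > 0")
    return rate_drug_bsa / rate_bsa


def delta_delta_g(
    normrate: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Drug-induced change in bilayer dimerization energy, -RT·ln(NormRate)."""
    if normrate <= 0:
        raise ValueError("normrate must be > 0")
    return -R_KCAL_PER_MOL_K * temperature * math.log(normrate)


def categorize(normrate: float) -> str:
    """Potency category with the half-open edges 1.25 and 1.5.

    NormRate < 1.25 (including stiffening drugs with NormRate < 1) is
    'low'; [1.25, 1.5) is 'moderate'; >= 1.5 is 'high'.
    """
    if normrate <= 0:
        raise ValueError("normrate must be > 0")
    if normrate < CATEGORY_EDGES[0]:
        return "low"
    if normrate < CATEGORY_EDGES[1]:
        return "moderate"
    return "high"


def display_normrate(normrate: float) -> float:
    """Display transform: 1/NormRate for stiffening drugs (NormRate < 1)."""
    if normrate <= 0:
        raise ValueError("normrate must be > 0")
    return 1.0 / normrate if normrate < 1.0 else normrate


def k1_from_alogp(alogp: float) -> float:
    """Partition coefficient as the antilog of the log-partition descriptor."""
    return 10.0**alogp


def partition_concentrations(p: PartitionParams) -> tuple[float, float]:
    """Aqueous and membrane drug concentrations (M) at equilibrium.

    Mass balance holds exactly: drug_aq + drug_mem·(V_lip/V_aq) equals
    the nominal concentration.  As k1 → ∞ the membrane concentration
    approaches nominal/(V_lip/V_aq).
    """
    drug_aq = p.nominal / (1.0 + p.k1 * p.vlip_over_vaq)
    drug_mem = p.k1 * drug_aq
    return drug_aq, drug_mem


def scale_normrate(normrate_at_c1: float, c1: float, c2: float) -> float:
    """Extrapolate NormRate to another aqueous concentration (linearized).

    The equilibrium shift in excess of 1 is treated as linear in the
    aqueous drug concentration: 1 + (NormRate(c1) - 1)·c2/c1.  This is
    an explicit linearization of the concentration dependence, valid for
    modest extrapolations.
    """
    if c1 <= 0:
        raise ValueError("c1 must be > 0")
    return 1.0 + (normrate_at_c1 - 1.0) * (c2 / c1)


def evaluate_drug(
    rate_drug: float,
    rate_cntrl: float,
    alogp: float,
    nominal: float = 10e-6,
    temperature: float = DEFAULT_TEMPERATURE_K,
    vlip_over_vaq: float = DEFAULT_VLIP_OVER_VAQ,
    rate_drug_bsa: float | None = None,
    rate_bsa: float | None = None,
) -> PotencyResult:
    """Compute the full per-drug potency record from fitted rates."""
    nr = norm_rate(rate_drug, rate_cntrl)
    nr_bsa = None
    if rate_drug_bsa is not None and rate_bsa is not None:
        nr_bsa = norm_rate_bsa(rate_drug_bsa, rate_bsa)
    aq, mem = partition_concentrations(
        PartitionParams(k1_from_alogp(alogp), vlip_over_vaq, nominal)
    )
    return PotencyResult(
        normrate=nr,
        ddg=delta_delta_g(nr, temperature),
        category=categorize(nr),
        drug_aq=aq,
        drug_mem=mem,
        normrate_bsa=nr_bsa,
    )
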