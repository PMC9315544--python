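"""Henderson-Hasselbalch ionization arithmetic and calibration of the
binding association constants from plasma and blood-cell data.

For a monoprotic base at ambient pH, the protonated fraction is
``1 / (1 + 10**(pH - pKa))``; a strong base (pKa > 7) is therefore mostly
protonated at plasma pH while a weak base is mostly neutral.  The ratio of
total (protonated + neutral) drug between two compartments at equal unbound
neutral concentration is the ionization factor
``(1 + 10**(pKa - pH1)) / (1 + 10**(pKa - pH2))`` — the workhorse of every
pH-gradient term in the partition model.

Two calibrations turn measurable plasma/blood quantities into association
constants:

* albumin: with all plasma binding attributed to albumin,
  ``Ka_ALB * [ALB]_plasma = 1/fu - 1``;
* acidic phospholipids (AP-): the blood-cell-to-plasma unbound partition
  coefficient implied by the blood:plasma ratio and hematocrit is stripped
  of its intracellular-water and neutral-lipid parts, and the remainder is
  attributed to AP- binding of the protonated species, yielding ``Ka_AP``
  per (mg/g).
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import BloodParams, CompoundParams

__all__ = [
    "BindingConstants",
    "CalibrationError",
    "ModelMismatchError",
    "albumin_binding_capacity",
    "ap_association_constant",
    "blood_cell_partition",
    "fraction_protonated",
    "ionization_factor",
    "lipid_affinity",
]


class ModelMismatchError(ValueError):
    """An operation specific to one base class was called for the other."""


class CalibrationError(ValueError):
    """Blood data are inconsistent with the requested calibration."""


def fraction_protonated(pka: float, ph: float, *, printed_orientation: bool = False) -> float:
    """Protonated fraction of a monoprotic base at ambient ``ph``.

    Default orientation is Henderson-Hasselbalch for bases,
    ``1/(1 + 10**(ph - pka))``: a weak base such as erlotinib (pKa 5.5) is
    ~99% neutral at plasma pH 7.4, while osimertinib (pKa 9.0) is ~98%
    protonated.  ``printed_orientation=True`` evaluates the transposed form
    ``1/(1 + 10**(pka - ph))`` for forensic comparison with sources that
    print the exponent the other way around.
    """
    if printed_orientation:
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def ionization_factor(pka: float, ph_num: float, ph_den: float) -> float:
    """Total-drug concentration ratio between compartments at pH ``ph_num``
    and ``ph_den`` for equal unbound neutral drug:
    ``(1 + 10**(pka - ph_num)) / (1 + 10**(pka - ph_den))``.

    Strictly positive; 1 when the two pH values coincide; satisfies the
    reciprocal identity ``f(pka, a, b) * f(pka, b, a) == 1``.
    """
    return (1.0 + 10.0 ** (pka - ph_num)) / (1.0 + 10.0 ** (pka - ph_den))


def lipid_affinity(log_p: float, convention: str = "logp") -> float:
    """Lipid-binding affinity ``P`` entering the neutral-lipid terms.

    ``"logp"`` (default) uses the printed log P value directly as P — the
    convention the partitioning model was calibrated with.  ``"antilog"``
    uses ``10**log_p`` for comparison with the standard octanol/water
    partition coefficient.
    """
    if convention == "logp":
        return log_p
    if convention == "antilog":
        return 10.0 ** log_p
    raise ValueError(f"unknown log P convention {convention!r}")


def albumin_binding_capacity(fu_plasma: float) -> float:
    """Scaled albumin association constant ``Ka_ALB * [ALB]_plasma``.

    Attributing all plasma protein binding to albumin, the bound:unbound
    ratio in plasma is ``1/fu - 1``; multiplying by the albumin
    tissue-to-plasma ratio gives the tissue albumin term.
    """
    if not (0.0 < fu_plasma <= 1.0):
        raise ValueError(f"fu_plasma must be in (0, 1], got {fu_plasma}")
    return 1.0 / fu_plasma - 1.0


def blood_cell_partition(bp_ratio: float, hematocrit: float, fu_plasma: float) -> float:
    """Unbound blood-cell-to-plasma partition coefficient ``Kpu_BC``.

    From the whole-blood mass balance
    ``B:P = (1 - H) + H * Kpu_BC * fu``, so
    ``Kpu_BC = (B:P - (1 - H)) / (H * fu)``.
    """
    plasma_part = 1.0 - hematocrit
    if bp_ratio <= plasma_part:
        raise CalibrationError(
            f"blood:plasma ratio {bp_ratio} <= 1 - hematocrit ({plasma_part:.2f}) "
            "implies a non-positive blood-cell concentration"
        )
    return (bp_ratio - plasma_part) / (hematocrit * fu_plasma)


def ap_association_constant(
    compound: CompoundParams,
    blood: BloodParams,
    *,
    p_convention: str = "logp",
) -> float:
    """Acidic-phospholipid association constant ``Ka_AP`` (per mg/g),
    calibrated from the blood-cell partitioning of a strong base.

    The blood-cell unbound partition coefficient is decomposed into an
    intracellular-water term (pH gradient plasma -> blood cell), a
    neutral-lipid term (neutral species only) and an AP- binding term of
    the protonated species; ``Ka_AP`` is solved from the remainder.
    """
    if not compound.is_strong_base:
        raise ModelMismatchError(
            f"{compound.name} is a weak base; the AP- calibration applies to strong bases"
        )
    pka = compound.pka
    kpu_bc = blood_cell_partition(compound.bp_ratio, blood.hematocrit, compound.fu_plasma)
    iw_term = ionization_factor(pka, blood.ph_bc, blood.ph_plasma) * blood.bc_f_iw
    p = lipid_affinity(compound.log_p, p_convention)
    nl_term = (p * blood.bc_f_nl + (0.3 * p + 0.7) * blood.bc_f_np) / (
        1.0 + 10.0 ** (pka - blood.ph_plasma)
    )
    remainder = kpu_bc - iw_term - nl_term
    if remainder < 0.0:
        raise CalibrationError(
            f"{compound.name}: blood-cell binding over-explained without AP- "
            f"(remainder {remainder:.4g})"
        )
    return remainder * (1.0 + 10.0 ** (pka - blood.ph_plasma)) / (
        blood.bc_ap_mg_g * 10.0 ** (pka - blood.ph_bc)
    )


@dataclass(frozen=True)
class BindingConstants:
    """Calibrated association constants for one compound.

    ``ka_alb_scaled`` is ``Ka_ALB * [ALB]_plasma``; ``ka_ap`` and ``kpu_bc``
    are None for weak bases (no AP-/lysosome machinery in their model).
    """

    ka_alb_scaled: float
    ka_ap: float | None
    kpu_bc: float | None

    @classmethod
    def calibrate(
        cls,
        compound: CompoundParams,
        blood: BloodParams,
        *,
        p_convention: str = "logp",
    ) -> "BindingConstants":
        ka_alb = albumin_binding_capacity(compound.fu_plasma)
        if compound.is_strong_base:
            return cls(
                ka_alb_scaled=ka_alb,
                ka_ap=ap_association_constant(compound, blood, p_convention=p_convention),
                kpu_bc=blood_cell_partition(
                    compound.bp_ratio, blood.hematocrit, compound.fu_plasma
                ),
            )
        return cls(ka_alb_scaled=ka_alb, ka_ap=None, kpu_bc=None)
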