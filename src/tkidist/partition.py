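"""Steady-state unbound tissue partitioning (Kpu) and tissue-to-blood
ratios for weak- and strong-base EGFR-TKI tracers.

The unbound tissue-to-plasma partition coefficient is assembled from
additive component terms:

* both base classes: intracellular water (``iw``), extracellular water
  (``ew``), neutral lipids/phospholipids (``nl_np``) and EGFR target
  binding (``egfr``);
* weak bases only: albumin binding (``albumin``);
* strong bases only: acidic-phospholipid binding (``ap_minus``) and
  lysosomal sequestration (``lysosome``), the latter summed over the
  tissue's lysosome-bearing cell populations.

The blood-referenced prediction is
``pTBR = coeff * (sum of terms) * fu / B:P`` where ``coeff`` is 1
everywhere except the tumor under the vascularization scenario.  The model
is a closed form: the drug is assumed at steady state, well-stirred,
transported passively and non-saturating, with no metabolism or
elimination over the scan window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

from .ionization import (
    ModelMismatchError,
    albumin_binding_capacity,
    ap_association_constant,
    ionization_factor,
    lipid_affinity,
)
from .params import BloodParams, CellType, CompoundParams, TissueComposition

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .scenarios import ScenarioConfig

__all__ = [
    "COMPONENTS",
    "ComponentBreakdown",
    "PredictionRecord",
    "decompose",
    "lysosome_partition",
    "predict_tbr",
    "term_acidic_phospholipids",
    "term_albumin",
    "term_egfr",
    "term_extracellular_water",
    "term_intracellular_water",
    "term_lysosome",
    "term_neutral_lipids",
    "tumor_to_lung_contrast",
]

#: Canonical component order used in decomposition tables.
COMPONENTS = ("egfr", "lysosome", "nl_np", "albumin", "ap_minus", "iw", "ew")

LYSOSOME_MODES = ("membrane", "ph_only")


# ---------------------------------------------------------------------------
# component terms (all on the unbound-partition scale, i.e. additive parts
# of Kpu before the fu/B:P scaling)


def term_intracellular_water(compound: CompoundParams, tissue: TissueComposition,
                             blood: BloodParams) -> float:
    """pH-gradient partitioning into intracellular water:
    ``ionization_factor(pKa, pH_iw, pH_p) * f_iw``."""
    return ionization_factor(compound.pka, tissue.ph_iw, blood.ph_plasma) * tissue.f_iw


def term_extracellular_water(compound: CompoundParams, tissue: TissueComposition,
                             blood: BloodParams) -> float:
    """Partitioning into extracellular water; deviates from ``f_ew`` only
    where the extracellular pH differs from plasma (acidic tumor
    microenvironment)."""
    return ionization_factor(compound.pka, tissue.ph_ew, blood.ph_plasma) * tissue.f_ew


def term_neutral_lipids(compound: CompoundParams, tissue: TissueComposition,
                        blood: BloodParams, *, p_convention: str = "logp") -> float:
    """Binding of the neutral species to neutral lipids and phospholipids:
    ``(P*f_nl + (0.3P + 0.7)*f_np) / (1 + 10**(pKa - pH_p))``."""
    p = lipid_affinity(compound.log_p, p_convention)
    return (p * tissue.f_nl + (0.3 * p + 0.7) * tissue.f_np) / (
        1.0 + 10.0 ** (compound.pka - blood.ph_plasma)
    )


def term_albumin(compound: CompoundParams, tissue: TissueComposition) -> float:
    """Albumin binding (weak-base model only):
    ``(1/fu - 1) * albumin tissue-to-plasma ratio``."""
    if compound.is_strong_base:
        raise ModelMismatchError(
            f"{compound.name} is a strong base; its model has no albumin term"
        )
    return albumin_binding_capacity(compound.fu_plasma) * tissue.alb_ratio


def term_acidic_phospholipids(compound: CompoundParams, tissue: TissueComposition,
                              blood: BloodParams, *, p_convention: str = "logp") -> float:
    """Acidic-phospholipid binding of the protonated species (strong-base
    model only): ``Ka_AP * [AP-] * 10**(pKa - pH_iw) / (1 + 10**(pKa - pH_p))``."""
    if not compound.is_strong_base:
        raise ModelMismatchError(
            f"{compound.name} is a weak base; its model has no AP- term"
        )
    ka = ap_association_constant(compound, blood, p_convention=p_convention)
    return (
        ka
        * tissue.ap_conc_mg_g
        * 10.0 ** (compound.pka - tissue.ph_iw)
        / (1.0 + 10.0 ** (compound.pka - blood.ph_plasma))
    )


def term_egfr(compound: CompoundParams, tissue: TissueComposition,
              blood: BloodParams) -> float:
    """Intracellular EGFR target binding:
    ``([EGFR]/Kd) * ionization_factor(pKa, pH_iw, pH_p) * f_iw``;
    zero where the receptor is absent."""
    if compound.kd_egfr_nM <= 0:
        raise ValueError(f"{compound.name}: EGFR Kd must be positive")
    if tissue.egfr_nM == 0.0:
        return 0.0
    return (
        (tissue.egfr_nM / compound.kd_egfr_nM)
        * ionization_factor(compound.pka, tissue.ph_iw, blood.ph_plasma)
        * tissue.f_iw
    )


def lysosome_partition(
    compound: CompoundParams,
    cell: CellType,
    blood: BloodParams,
    mode: str = "membrane",
    *,
    membrane_ap_mg_g: float = 0.57,
    ph_iw: float = 7.0,
    p_convention: str = "logp",
) -> float:
    """Lysosome-to-cytosol partition coefficient ``Kpu_lys`` of one cell type.

    ``ph_only`` mode is pure ion trapping across the cytosol/lysosome pH
    gradient.  ``membrane`` mode (default) additionally binds the protonated
    species to the lysosomal membrane, which is assumed to share the
    acidic-phospholipid composition of the cell's outer membrane
    (``membrane_ap_mg_g``, the tissue's own AP- concentration).
    """
    if not compound.is_strong_base:
        raise ModelMismatchError(
            f"{compound.name} is a weak base; lysosomal sequestration does not apply"
        )
    if mode not in LYSOSOME_MODES:
        raise ValueError(f"unknown lysosome mode {mode!r}; expected {LYSOSOME_MODES}")
    pka = compound.pka
    kpu = ionization_factor(pka, cell.ph_lys, ph_iw)
    if mode == "membrane":
        ka = ap_association_constant(compound, blood, p_convention=p_convention)
        kpu += (
            ka
            * membrane_ap_mg_g
            * 10.0 ** (pka - cell.ph_lys)
            / (1.0 + 10.0 ** (pka - ph_iw))
        )
    return kpu


def term_lysosome(compound: CompoundParams, tissue: TissueComposition,
                  blood: BloodParams, mode: str = "membrane",
                  *, p_convention: str = "logp") -> float:
    """Lysosomal sequestration summed over the tissue's cell populations:
    ``ionization_factor(pKa, pH_iw, pH_p) * sum_c F_cell * F_lys * Kpu_lys``.
    Zero for tissues without lysosome data (empty ``cell_types``)."""
    if not compound.is_strong_base:
        raise ModelMismatchError(
            f"{compound.name} is a weak base; its model has no lysosome term"
        )
    total = 0.0
    for cell in tissue.cell_types:
        total += cell.fraction * cell.f_lys * lysosome_partition(
            compound,
            cell,
            blood,
            mode,
            membrane_ap_mg_g=tissue.ap_conc_mg_g,
            ph_iw=tissue.ph_iw,
            p_convention=p_convention,
        )
    return ionization_factor(compound.pka, tissue.ph_iw, blood.ph_plasma) * total


# ---------------------------------------------------------------------------
# assembly


@dataclass(frozen=True)
class ComponentBreakdown:
    """Additive decomposition of one prediction.

    ``terms`` maps component name to its unbound-partition contribution;
    components not applicable to the compound's model (albumin for strong
    bases; AP-/lysosome for weak bases; EGFR when ablated) are listed in
    ``not_applicable`` instead.  ``tbr = coefficient * total_unbound * fu/B:P``.
    """

    terms: Mapping[str, float]
    not_applicable: tuple[str, ...]
    fu_over_bp: float
    coefficient: float = 1.0

    @property
    def total_unbound(self) -> float:
        return sum(self.terms.values())

    @property
    def tbr(self) -> float:
        return self.coefficient * self.total_unbound * self.fu_over_bp

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total_unbound
        return {name: 100.0 * value / total for name, value in self.terms.items()}


@dataclass(frozen=True)
class PredictionRecord:
    """A predicted tissue-to-blood ratio with its component breakdown."""

    compound: str
    tissue: str
    scenario: str
    tbr: float
    breakdown: ComponentBreakdown = field(repr=False)


def _scenario_settings(scenario: "ScenarioConfig | None") -> tuple[bool, str, float, float, str]:
    if scenario is None:
        return True, "membrane", 1.0, 1.0, "final"
    return (
        getattr(scenario, "egfr_enabled", True),
        getattr(scenario, "lysosome_mode", "membrane"),
        getattr(scenario, "f_vasc", 1.0),
        getattr(scenario, "f_perf", 1.0),
        getattr(scenario, "name", "scenario"),
    )


def predict_tbr(
    compound: CompoundParams,
    tissue: TissueComposition,
    blood: BloodParams,
    scenario: "ScenarioConfig | None" = None,
    *,
    p_convention: str = "logp",
) -> PredictionRecord:
    """Predict the steady-state tissue-to-blood ratio of one tracer in one
    tissue, with the per-component breakdown.

    The scenario contributes the EGFR on/off switch, the lysosome mode and
    the tumor flow coefficients (``f_vasc``/``f_perf``, applied to the
    tumor only; both 1 in the final model).  Tumor-composition overrides
    (acidic extracellular water, immune deprivation) are part of the tissue
    object itself — see :func:`tkidist.scenarios.realize`.
    """
    egfr_on, lyso_mode, f_vasc, f_perf, scenario_name = _scenario_settings(scenario)

    terms: dict[str, float] = {}
    na: list[str] = []
    terms["iw"] = term_intracellular_water(compound, tissue, blood)
    terms["ew"] = term_extracellular_water(compound, tissue, blood)
    terms["nl_np"] = term_neutral_lipids(compound, tissue, blood, p_convention=p_convention)
    if compound.is_strong_base:
        terms["ap_minus"] = term_acidic_phospholipids(
            compound, tissue, blood, p_convention=p_convention
        )
        terms["lysosome"] = term_lysosome(
            compound, tissue, blood, lyso_mode, p_convention=p_convention
        )
        na.append("albumin")
    else:
        terms["albumin"] = term_albumin(compound, tissue)
        na.extend(["ap_minus", "lysosome"])
    if egfr_on:
        terms["egfr"] = term_egfr(compound, tissue, blood)
    else:
        na.append("egfr")

    coefficient = f_vasc * f_perf if tissue.name == "tumor" else 1.0
    breakdown = ComponentBreakdown(
        terms={k: terms[k] for k in COMPONENTS if k in terms},
        not_applicable=tuple(k for k in COMPONENTS if k in na),
        fu_over_bp=compound.fu_plasma / compound.bp_ratio,
        coefficient=coefficient,
    )
    return PredictionRecord(
        compound=compound.name,
        tissue=tissue.name,
        scenario=scenario_name,
        tbr=breakdown.tbr,
        breakdown=breakdown,
    )


def decompose(
    compound: CompoundParams,
    tissue: TissueComposition,
    blood: BloodParams,
    scenario: "ScenarioConfig | None" = None,
    *,
    p_convention: str = "logp",
) -> ComponentBreakdown:
    """Component decomposition of a prediction (percentage shares of the
    summed unbound-partition terms)."""
    return predict_tbr(
        compound, tissue, blood, scenario, p_convention=p_convention
    ).breakdown


def tumor_to_lung_contrast(
    compound: CompoundParams,
    lung: TissueComposition,
    tumor: TissueComposition,
    blood: BloodParams,
    scenario: "ScenarioConfig | None" = None,
    *,
    p_convention: str = "logp",
) -> float:
    """Predicted tumor-to-lung contrast ``pTBR_tumor / pTBR_lung`` — the
    model's surrogate for PET image quality."""
    tumor_tbr = predict_tbr(compound, tumor, blood, scenario, p_convention=p_convention).tbr
    lung_tbr = predict_tbr(compound, lung, blood, scenario, p_convention=p_convention).tbr
    return tumor_tbr / lung_tbr
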