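"""Tumor-hallmark construction and component-ablation scenarios.

The final model encodes four NSCLC-tumor hallmarks on top of the
physicochemical base models: EGFR target binding, membrane-inclusive
lysosomal sequestration, immune deprivation of the tumor (residual cells
only, no lysosome-rich macrophages/type II cells) and an acidic tumor
extracellular water (pH 6.7), with unaltered tumor perfusion (coefficient
1) and no vasculature penalty.  The ablation suite removes exactly one of
these components at a time; the vascularization variant instead multiplies
the tumor prediction by the histology-derived microvessel-density ratio
0.36.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import partition
from .params import ObservedTBR, ParameterSet, TissueComposition

__all__ = [
    "ScenarioConfig",
    "VASCULATURE_COEFFICIENT",
    "ablation_suite",
    "final_model_scenario",
    "predict_all",
    "realize",
    "run_sensitivity",
    "scenario_by_name",
]

logger = logging.getLogger(__name__)

#: Tumor/lung microvessel-density ratio from CD31+ histology.
VASCULATURE_COEFFICIENT = 0.36


class ScenarioConfig(BaseModel):
    """Declarative on/off switches and coefficients of one model variant."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    egfr_enabled: bool = True
    lysosome_mode: Literal["membrane", "ph_only"] = "membrane"
    immune_deprivation: bool = True
    tumor_ph_ew: float = 6.7
    f_vasc: float = Field(default=1.0, gt=0.0)
    f_perf: float = Field(default=1.0, gt=0.0)


def final_model_scenario() -> ScenarioConfig:
    """The final mechanistic model: every hallmark on, unaltered perfusion,
    no vasculature coefficient."""
    return ScenarioConfig(name="final")


def ablation_suite() -> list[ScenarioConfig]:
    """Five single-component ablations of the final model."""
    return [
        ScenarioConfig(name="no_egfr", egfr_enabled=False),
        ScenarioConfig(name="ph_only_lysosome", lysosome_mode="ph_only"),
        ScenarioConfig(name="no_immune_deprivation", immune_deprivation=False),
        ScenarioConfig(name="vascularized", f_vasc=VASCULATURE_COEFFICIENT),
        ScenarioConfig(name="neutral_tumor_ew", tumor_ph_ew=7.4),
    ]


def scenario_by_name(name: str) -> ScenarioConfig:
    """Look up the final scenario or an ablation by name."""
    table = {s.name: s for s in [final_model_scenario(), *ablation_suite()]}
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; known: {', '.join(table)}"
        ) from None


def realize(params: ParameterSet, scenario: ScenarioConfig) -> ParameterSet:
    """Return the parameter set with the scenario's tumor-composition
    overrides applied.

    ``tumor_ph_ew`` replaces the tumor extracellular pH; with
    ``immune_deprivation`` off, the tumor receives the lung cell-type mix
    (macrophages/type II/residual) instead of residual cells only.  All
    other tissues are untouched, so weak-base predictions are bitwise
    independent of these toggles.
    """
    if "tumor" not in params.tissues:
        return params
    tumor = params.tissues["tumor"]
    update: dict = {"ph_ew": scenario.tumor_ph_ew}
    if not scenario.immune_deprivation:
        update["cell_types"] = params.tissues["lung"].cell_types
    new_tumor = TissueComposition(**{**tumor.model_dump(), **update})
    tissues = dict(params.tissues)
    tissues["tumor"] = new_tumor
    return ParameterSet(compounds=params.compounds, tissues=tissues, blood=params.blood)


def predict_all(
    params: ParameterSet,
    scenario: ScenarioConfig,
    compounds: Iterable[str] | None = None,
    tissues: Iterable[str] | None = None,
) -> list[partition.PredictionRecord]:
    """Predict TBR for a compound x tissue grid under one scenario."""
    eff = realize(params, scenario)
    records = []
    for cname in compounds or eff.compounds:
        compound = eff.compound(cname)
        for tname in tissues or eff.tissues:
            records.append(
                partition.predict_tbr(compound, eff.tissue(tname), eff.blood, scenario)
            )
    return records


def _contrast(params: ParameterSet, scenario: ScenarioConfig, compound: str) -> float:
    eff = realize(params, scenario)
    return partition.tumor_to_lung_contrast(
        eff.compound(compound), eff.tissue("lung"), eff.tissue("tumor"), eff.blood, scenario
    )


def run_sensitivity(
    params: ParameterSet,
    observed: Sequence[ObservedTBR],
    scenarios: Sequence[ScenarioConfig] | None = None,
    compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Final-vs-ablation prediction errors for tumor, lung and the
    tumor-to-lung contrast.

    Returns one row per (scenario, compound, quantity) with the predicted
    values and the PEs against the observed fixture; the final-model column
    is recomputed alongside each scenario.  Pairs without an observation
    are skipped with a logged notice.
    """
    from .validation import prediction_error

    scenarios = list(scenarios) if scenarios is not None else ablation_suite()
    compounds = list(compounds) if compounds is not None else list(params.compounds)
    obs = {(r.compound, r.tissue): r for r in observed}
    final = final_model_scenario()

    rows = []
    for scenario in scenarios:
        for cname in compounds:
            quantities: dict[str, tuple[float, float, float | None]] = {}
            for tname in ("lung", "tumor"):
                pred_f = predict_all(params, final, [cname], [tname])[0].tbr
                pred_s = predict_all(params, scenario, [cname], [tname])[0].tbr
                rec = obs.get((cname, tname))
                if rec is None or not rec.available:
                    logger.info("no observed TBR for %s/%s; pair skipped", cname, tname)
                    continue
                quantities[tname] = (pred_f, pred_s, rec.mean)
            lung_rec = obs.get((cname, "lung"))
            tumor_rec = obs.get((cname, "tumor"))
            if (
                lung_rec is not None and lung_rec.available
                and tumor_rec is not None and tumor_rec.available
            ):
                quantities["contrast"] = (
                    _contrast(params, final, cname),
                    _contrast(params, scenario, cname),
                    tumor_rec.mean / lung_rec.mean,
                )
            for qname, (pred_f, pred_s, target) in quantities.items():
                rows.append(
                    {
                        "scenario": scenario.name,
                        "compound": cname,
                        "quantity": qname,
                        "predicted_final": pred_f,
                        "predicted_scenario": pred_s,
                        "observed": target,
                        "pe_final": prediction_error(pred_f, target),
                        "pe_scenario": prediction_error(pred_s, target),
                    }
                )
    return pd.DataFrame(rows)
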