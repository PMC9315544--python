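"""Parameter registry: physicochemical constants, tissue compositions and
the observed-TBR validation fixture.

All numeric defaults live in :mod:`tkidist.data` as plain-text files
(``parameters.yaml``, ``observed_tbr.csv``, ``reference_predictions.csv``)
and are validated against the domain invariants on load.  Every default
carries a provenance string naming the literature source of the value,
retrievable with :func:`provenance_of`.

User overrides are deep-merged onto the defaults with
:func:`apply_overrides`; unknown names or out-of-range values are rejected
with a descriptive :class:`ParameterError`.
"""

from __future__ import annotations

import csv
import math
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Any, Iterator, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "BaseClass",
    "BloodParams",
    "CellType",
    "CompoundParams",
    "ObservedTBR",
    "ParameterError",
    "ParameterSet",
    "TissueComposition",
    "apply_overrides",
    "load_default_parameters",
    "load_observed_tbr",
    "load_parameters",
    "load_reference_predictions",
    "observed_to_frame",
    "provenance_of",
    "to_yaml",
]

#: Tissue ordering used by every tabular output (whole-body scan order).
TISSUE_ORDER = ("brain", "lung", "spleen", "kidney", "bone", "tumor")
COMPOUND_ORDER = ("erlotinib", "afatinib", "osimertinib")


class ParameterError(ValueError):
    """A parameter document names an unknown field or violates an invariant."""


class BaseClass(str, Enum):
    """Ionization class of a basic drug: weak (pKa <= 7) or strong (pKa > 7)."""

    weak = "weak"
    strong = "strong"


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CompoundParams(_Frozen):
    """Physicochemical and target-binding constants for one tracer.

    ``log_p`` is the octanol/water log partition value, ``pka`` the basic
    dissociation constant, ``fu_plasma`` the fraction unbound in plasma,
    ``bp_ratio`` the whole-blood to plasma concentration ratio and
    ``kd_egfr_nM`` the wild-type EGFR dissociation constant in nM.
    """

    name: str
    log_p: float
    pka: float
    fu_plasma: float = Field(gt=0.0, le=1.0)
    bp_ratio: float = Field(gt=0.0)
    kd_egfr_nM: float = Field(gt=0.0)
    base_class: BaseClass

    @model_validator(mode="after")
    def _class_matches_pka(self) -> "CompoundParams":
        expected = BaseClass.strong if self.pka > 7.0 else BaseClass.weak
        if self.base_class is not expected:
            raise ValueError(
                f"{self.name}: base_class {self.base_class.value!r} inconsistent "
                f"with pKa {self.pka} (expected {expected.value!r})"
            )
        return self

    @property
    def is_strong_base(self) -> bool:
        return self.base_class is BaseClass.strong


class CellType(_Frozen):
    """A lysosome-bearing cell population of a tissue."""

    name: str
    fraction: float = Field(ge=0.0, le=1.0)
    f_lys: float = Field(ge=0.0, le=1.0)
    ph_lys: float = Field(lt=7.0)


class TissueComposition(_Frozen):
    """Fractional volumes, binding-site concentrations and pH of one tissue.

    ``f_nl``/``f_np``/``f_ew``/``f_iw`` are the fractional volumes of
    neutral lipids, neutral phospholipids, extra- and intracellular water.
    ``ap_conc_mg_g`` is the acidic-phospholipid concentration (mg/g),
    ``alb_ratio`` the albumin tissue-to-plasma ratio and ``egfr_nM`` the
    tissue EGFR concentration (0 where the receptor is assumed absent).
    ``cell_types`` lists the lysosome-bearing populations used by the
    strong-base model; an empty list disables the lysosome term.
    """

    name: str
    f_nl: float = Field(ge=0.0, le=1.0)
    f_np: float = Field(ge=0.0, le=1.0)
    f_ew: float = Field(ge=0.0, le=1.0)
    f_iw: float = Field(ge=0.0, le=1.0)
    ap_conc_mg_g: float = Field(ge=0.0)
    alb_ratio: float = Field(ge=0.0)
    egfr_nM: float = Field(ge=0.0)
    ph_ew: float
    ph_iw: float
    cell_types: tuple[CellType, ...] = ()

    @model_validator(mode="after")
    def _volumes_consistent(self) -> "TissueComposition":
        if self.f_ew + self.f_iw > 1.0 + 1e-9:
            raise ValueError(
                f"{self.name}: f_ew + f_iw = {self.f_ew + self.f_iw:.3f} exceeds 1"
            )
        if self.cell_types:
            total = sum(c.fraction for c in self.cell_types)
            if not math.isclose(total, 1.0, abs_tol=5e-3):
                raise ValueError(
                    f"{self.name}: cell-type fractions sum to {total:.4f}, not 1"
                )
        return self


class BloodParams(_Frozen):
    """Whole-blood composition anchoring the blood-referenced scale and the
    acidic-phospholipid calibration (``bc_*`` fields describe blood cells)."""

    hematocrit: float = Field(gt=0.0, lt=1.0)
    ph_plasma: float
    ph_bc: float
    bc_f_iw: float = Field(ge=0.0, le=1.0)
    bc_f_nl: float = Field(ge=0.0, le=1.0)
    bc_f_np: float = Field(ge=0.0, le=1.0)
    bc_ap_mg_g: float = Field(ge=0.0)


class ObservedTBR(_Frozen):
    """A PET-image-derived tissue-to-blood ratio (mean and SD over patients).

    ``available`` is False where the tissue was outside the scan field of
    view (brain for erlotinib); such records carry no mean/SD.
    """

    compound: str
    tissue: str
    mean: float | None = None
    sd: float | None = None
    available: bool = True

    @model_validator(mode="after")
    def _mean_when_available(self) -> "ObservedTBR":
        if self.available:
            if self.mean is None or self.mean <= 0:
                raise ValueError(
                    f"{self.compound}/{self.tissue}: available record needs mean > 0"
                )
            if self.sd is None or self.sd < 0:
                raise ValueError(
                    f"{self.compound}/{self.tissue}: available record needs sd >= 0"
                )
        return self


class ParameterSet(_Frozen):
    """The full model parameterization: compounds, tissues and blood."""

    compounds: dict[str, CompoundParams]
    tissues: dict[str, TissueComposition]
    blood: BloodParams

    def compound(self, name: str) -> CompoundParams:
        try:
            return self.compounds[name]
        except KeyError:
            raise ParameterError(
                f"unknown compound {name!r}; known: {', '.join(self.compounds)}"
            ) from None

    def tissue(self, name: str) -> TissueComposition:
        try:
            return self.tissues[name]
        except KeyError:
            raise ParameterError(
                f"unknown tissue {name!r}; known: {', '.join(self.tissues)}"
            ) from None


# ---------------------------------------------------------------------------
# loading


def _data_text(filename: str) -> str:
    return (resources.files("tkidist.data") / filename).read_text(encoding="utf-8")


def _inject_names(section: Mapping[str, dict]) -> dict[str, dict]:
    return {key: {"name": key, **value} for key, value in section.items()}


def _build_parameter_set(doc: Mapping[str, Any]) -> ParameterSet:
    try:
        return ParameterSet(
            compounds=_inject_names(doc["compounds"]),
            tissues=_inject_names(doc["tissues"]),
            blood=doc["blood"],
        )
    except ValidationError as exc:
        raise ParameterError(str(exc)) from exc
    except KeyError as exc:
        raise ParameterError(f"parameter document lacks section {exc}") from exc


@lru_cache(maxsize=1)
def _default_document() -> dict[str, Any]:
    return yaml.safe_load(_data_text("parameters.yaml"))


def load_default_parameters() -> ParameterSet:
    """Return the canonical parameter set shipped with the package."""
    return _build_parameter_set(_default_document())


def load_parameters(path: str) -> ParameterSet:
    """Load a full parameter document from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _build_parameter_set(yaml.safe_load(fh))


def to_yaml(params: ParameterSet) -> str:
    """Serialize a parameter set to the canonical YAML config format.

    Round-trip guarantee: ``load`` of the emitted text reproduces an
    identical parameter set.
    """
    doc = {
        "compounds": {k: _strip_name(v.model_dump(mode="json")) for k, v in params.compounds.items()},
        "tissues": {k: _strip_name(v.model_dump(mode="json")) for k, v in params.tissues.items()},
        "blood": params.blood.model_dump(mode="json"),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _strip_name(d: dict) -> dict:
    d = dict(d)
    d.pop("name", None)
    return d


def from_yaml(text: str) -> ParameterSet:
    """Parse a parameter set from YAML text (inverse of :func:`to_yaml`)."""
    return _build_parameter_set(yaml.safe_load(text))


def provenance_of(key: str) -> str:
    """Return the provenance string for a default, e.g. ``"compound.pka"``."""
    table = _default_document().get("provenance", {})
    if key not in table:
        raise ParameterError(f"no provenance recorded for {key!r}")
    return table[key]


def provenance_keys() -> tuple[str, ...]:
    return tuple(_default_document().get("provenance", {}))


@lru_cache(maxsize=1)
def load_observed_tbr() -> tuple[ObservedTBR, ...]:
    """The PET-image-derived TBR fixture (18 compound-tissue records, one
    unavailable: erlotinib brain was outside the scan field of view)."""
    records = []
    for row in csv.DictReader(_data_text("observed_tbr.csv").splitlines()):
        available = row["available"].strip().lower() == "true"
        records.append(
            ObservedTBR(
                compound=row["compound"],
                tissue=row["tissue"],
                mean=float(row["mean"]) if row["mean"] else None,
                sd=float(row["sd"]) if row["sd"] else None,
                available=available,
            )
        )
    return tuple(records)


def observed_lookup() -> dict[tuple[str, str], ObservedTBR]:
    return {(r.compound, r.tissue): r for r in load_observed_tbr()}


@lru_cache(maxsize=1)
def load_reference_predictions() -> dict[tuple[str, str], float]:
    """Reference predicted TBRs accompanying the observed fixture (the
    values reported by the original model implementation in the source
    clinical comparison).  Used to exercise the statistics layer
    independently of this package's partition model."""
    return {
        (row["compound"], row["tissue"]): float(row["predicted"])
        for row in csv.DictReader(_data_text("reference_predictions.csv").splitlines())
    }


def observed_to_frame():
    """Export the observed fixture as a pandas DataFrame
    (columns: compound, tissue, mean, sd, available)."""
    import pandas as pd

    return pd.DataFrame([r.model_dump() for r in load_observed_tbr()])


# ---------------------------------------------------------------------------
# overrides


def apply_overrides(
    defaults: ParameterSet, overrides: Mapping[str, Any] | None
) -> ParameterSet:
    """Deep-merge an override document onto ``defaults``.

    Overrides mirror the config structure, e.g.
    ``{"compounds": {"erlotinib": {"fu_plasma": 0.176}}}``.  Fields not
    named are returned unchanged.  Unknown compounds, tissues or fields and
    invariant violations raise :class:`ParameterError`.
    """
    if not overrides:
        return defaults
    data = {
        "compounds": {k: v.model_dump(mode="json") for k, v in defaults.compounds.items()},
        "tissues": {k: v.model_dump(mode="json") for k, v in defaults.tissues.items()},
        "blood": defaults.blood.model_dump(mode="json"),
    }
    for path, value in _flatten(overrides):
        _assign(data, path, value)
    try:
        return ParameterSet(**data)
    except ValidationError as exc:
        raise ParameterError(f"override violates a parameter invariant: {exc}") from exc


def _flatten(doc: Mapping[str, Any], prefix: tuple[str, ...] = ()) -> Iterator[tuple[tuple[str, ...], Any]]:
    for key, value in doc.items():
        path = prefix + (str(key),)
        # cell_types is replaced wholesale, not merged element-wise
        if isinstance(value, Mapping) and path[-1] != "cell_types":
            yield from _flatten(value, path)
        else:
            yield path, value


def _assign(data: dict, path: tuple[str, ...], value: Any) -> None:
    if path[0] not in ("compounds", "tissues", "blood"):
        raise ParameterError(f"unknown top-level section {path[0]!r}")
    node: Any = data
    for depth, key in enumerate(path[:-1]):
        if key not in node:
            raise ParameterError(f"unknown name {'.'.join(path[: depth + 1])!r}")
        node = node[key]
    leaf = path[-1]
    if leaf == "name":
        raise ParameterError("the 'name' field is fixed by the registry key")
    if leaf not in node:
        raise ParameterError(f"unknown field {'.'.join(path)!r}")
    node[leaf] = value
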