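"""Model parameter vocabulary, validation and JSON I/O.

The inflammation model is parameterized by 44 strictly positive constants:
per-minute rate constants, saturation constants in the concentration units
of the regulated species, dimensionless Hill coefficients (>= 1) and cell
carrying capacities. ``ModelParameters`` is an immutable named vector over
this vocabulary; it round-trips losslessly through the JSON parameter file
format (schema ``inflammode-params-v1``).
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Dict, Iterator, Mapping

from .exceptions import (
    MissingParameterError,
    PositivityError,
    SchemaError,
    UnknownParameterError,
)

PARAMS_SCHEMA = "inflammode-params-v1"

#: parameter name -> human-readable definition (biological meaning).
PARAM_DEFS: Dict[str, str] = {
    # endotoxin
    "kpe": "Elimination rate of endotoxin (LPS)",
    # activated macrophages
    "kmpe": "Activation of macrophages by LPS",
    "xmpe": "Saturation constant for influence of LPS on macrophage activation",
    "kmd": "Rate of activation of macrophages due to damage",
    "xmd": "Saturation constant for influence of damage on macrophage activation",
    "km6": "Activation of macrophages by IL-6",
    "xm6": "Saturation constant for IL-6's influence on macrophage activation",
    "kma": "Deactivation/death rate of activated macrophages",
    "Mmax": "Carrying capacity of activated macrophages",
    # activated neutrophils
    "knpe": "Activation of neutrophils by LPS",
    "xnpe": "Saturation constant for influence of LPS on neutrophil activation",
    "kn": "Death rate of neutrophils",
    "Nmax": "Carrying capacity of activated neutrophils",
    # IL-10 brake on leukocyte activation
    "hn10": "Influence of IL-10 on leukocyte activation (Hill coefficient)",
    "x10l": "Saturation constant for IL-10's inhibition of leukocyte activation",
    # iNOS / NO2-/NO3-
    "kinosm": "Induction of iNOS by activated macrophages",
    "kinosn": "Influence of neutrophils on iNOS",
    "kdinos": "Decay rate of iNOS activity",
    "knono": "Production of NO2-/NO3- per unit iNOS activity",
    "kno": "Clearance rate of NO2-/NO3-",
    # TNF
    "kcpm": "Production of TNF by activated macrophages",
    "kcp": "Decay rate of TNF",
    "xcp6": "Saturation constant for IL-6's influence on TNF",
    "hcp6": "Influence of IL-6 on TNF (Hill coefficient)",
    "xcp10": "Saturation constant for IL-10's influence on TNF",
    "hcp10": "Influence of IL-10 on TNF (Hill coefficient)",
    # IL-6
    "s6": "Propensity to produce and secrete IL-6 at rest",
    "k6m": "Production of IL-6 by activated macrophages",
    "k6n": "Influence of neutrophils on IL-6",
    "k6cp": "Enhancement of IL-6 production by TNF",
    "x6cp": "Saturation constant for TNF's influence on IL-6",
    "h6cp": "Influence of TNF on IL-6 (Hill coefficient)",
    "k6no": "Influence of NO2-/NO3- on IL-6",
    "x6no": "Saturation constant for NO2-/NO3-'s influence on IL-6",
    "kd6": "Decay rate of IL-6",
    # IL-10
    "s10": "Propensity to produce and secrete IL-10 at rest",
    "k10m0": "Rate of IL-10 production in response to other cytokines",
    "k10cp": "Enhancement of IL-10 production by TNF",
    "x10cp": "Saturation constant for TNF's influence on IL-10",
    "h10cp": "Influence of TNF on IL-10 (Hill coefficient)",
    "k10": "Regulates levels of IL-10 by modulating production/decay rates",
    # damage
    "kdn": "Damage generation by activated neutrophils",
    "xdn": "Saturation constant for neutrophil-driven damage",
    "kdd": "Damage repair rate",
}

#: canonical parameter order (also the array layout used by the solver).
PARAM_ORDER = tuple(PARAM_DEFS)

#: parameters constrained to be >= 1 (Hill coefficients).
HILL_PARAMS = ("hn10", "hcp6", "hcp10", "h6cp", "h10cp")


class ModelParameters(Mapping[str, float]):
    """Immutable named vector of the 44 model constants.

    Parameters
    ----------
    values : mapping of parameter name to strictly positive float.
        Every name in :data:`PARAM_ORDER` must be present; unknown names
        are rejected. Hill coefficients must additionally be >= 1.
    label : free-text provenance label carried through files and reports.
    """

    __slots__ = ("_values", "label")

    def __init__(self, values: Mapping[str, float], label: str = "unlabeled"):
        unknown = sorted(set(values) - set(PARAM_ORDER))
        if unknown:
            raise UnknownParameterError(
                f"unknown parameter name(s): {', '.join(unknown)}; "
                f"valid names are: {', '.join(PARAM_ORDER)}"
            )
        missing = [name for name in PARAM_ORDER if name not in values]
        if missing:
            raise MissingParameterError(
                f"missing parameter(s): {', '.join(missing)}"
            )
        clean = {}
        for name in PARAM_ORDER:
            v = float(values[name])
            if not math.isfinite(v) or v <= 0.0:
                raise PositivityError(
                    f"parameter {name!r} must be a finite positive number, got {v!r}"
                )
            clean[name] = v
        for name in HILL_PARAMS:
            if clean[name] < 1.0:
                raise PositivityError(
                    f"Hill coefficient {name!r} must be >= 1, got {clean[name]!r}"
                )
        object.__setattr__(self, "_values", clean)
        object.__setattr__(self, "label", str(label))

    # Mapping interface -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_ORDER)

    def __len__(self) -> int:
        return len(PARAM_ORDER)

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("ModelParameters is immutable")

    def __repr__(self) -> str:
        return f"ModelParameters(label={self.label!r}, n={len(self)})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelParameters) and self._values == other._values

    def __hash__(self):
        return hash(tuple(self._values[k] for k in PARAM_ORDER))

    # conversions -------------------------------------------------------
    def as_array(self):
        """Values as a float array in :data:`PARAM_ORDER` layout."""
        import numpy as np

        return np.array([self._values[k] for k in PARAM_ORDER], dtype=float)

    def to_dict(self) -> Dict[str, float]:
        return dict(self._values)

    def replace(self, label: str | None = None, **updates: float) -> "ModelParameters":
        """Return a copy with the named parameters replaced."""
        unknown = sorted(set(updates) - set(PARAM_ORDER))
        if unknown:
            raise UnknownParameterError(
                f"unknown parameter name(s): {', '.join(unknown)}"
            )
        values = dict(self._values)
        values.update(updates)
        return ModelParameters(values, label=self.label if label is None else label)


def read_params(path) -> ModelParameters:
    """Read a schema-validated JSON parameter file.

    The file must be ``{"schema": "inflammode-params-v1", "label": str,
    "parameters": {name: value, ...}}``; every model parameter is required
    and unknown names are rejected with the offending name.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != PARAMS_SCHEMA:
        raise SchemaError(
            f"{path}: expected a JSON object with schema == {PARAMS_SCHEMA!r}"
        )
    params = doc.get("parameters")
    if not isinstance(params, dict):
        raise SchemaError(f"{path}: missing 'parameters' object")
    return ModelParameters(params, label=doc.get("label", "unlabeled"))


def write_params(params: ModelParameters, path, note: str | None = None) -> None:
    """Write a parameter set as a schema-stamped JSON file (sorted keys)."""
    doc = {
        "schema": PARAMS_SCHEMA,
        "label": params.label,
        "parameters": {k: params[k] for k in PARAM_ORDER},
    }
    if note:
        doc["note"] = note
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def young_default() -> ModelParameters:
    """The shipped baseline ("young") parameterization.

    These values are engineering defaults chosen for a stable resting state,
    the characteristic post-LPS peak ordering (TNF before IL-6 before
    NO2-/NO3-) and damage resolution within 24 h; they are not fitted to any
    animal dataset.
    """
    ref = resources.files("inflammode.data").joinpath("young_params.json")
    with resources.as_file(ref) as path:
        return read_params(path)
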