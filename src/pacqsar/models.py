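"""Linear activity models: the two built-in rAhR equations plus user models.

The built-ins are the published multiple-linear-regression equations for rat
aryl-hydrocarbon-receptor activity of polycyclic aromatic compounds:

* ``rAhR_logIEQ_eq1`` — log IEQ (induction equivalent, pg/g, log scale) for
  PACs without halogen substitution; seven descriptors.  Larger log IEQ
  corresponds to *lower* receptor activity.
* ``rAhR_logTCDDmax_eq2`` — log %-TCDD-max for chlorinated/brominated PAHs;
  three descriptors.  Larger values correspond to *higher* potency.

Coefficients are stored exactly as published (two decimals) and never
re-derived here; refitting is the model-building module's business.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import math

from .chem_io import Molecule


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class LinearModel:
    """Intercept plus ordered (descriptor, coefficient) terms."""

    name: str
    intercept: float
    terms: tuple[tuple[str, float], ...]
    response: str = "y"
    n_train: int | None = None

    def __post_init__(self):
        names = [d for d, _ in self.terms]
        if len(set(names)) != len(names):
            raise ModelError(f"{self.name}: duplicate descriptor names in terms")

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def descriptor_names(self) -> list[str]:
        return [d for d, _ in self.terms]

    def predict(self, desc: Mapping[str, float]) -> float:
        """intercept + sum(coef * value); a missing descriptor is an error."""
        total = self.intercept
        for name, coef in self.terms:
            if name not in desc:
                raise ModelError(f"{self.name}: descriptor {name!r} missing from input")
            val = float(desc[name])
            if not math.isfinite(val):
                raise ModelError(f"{self.name}: non-finite value for {name!r}: {val}")
            total += coef * val
        return total

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "response": self.response,
            "intercept": self.intercept,
            "terms": [{"descriptor": d, "coef": c} for d, c in self.terms],
        }


def predict(model: LinearModel, desc: Mapping[str, float]) -> float:
    return model.predict(desc)


def _validate_schema(obj: dict, origin: str) -> None:
    for key in ("name", "response", "intercept", "terms"):
        if key not in obj:
            raise ModelError(f"{origin}: model JSON missing key {key!r}")
    if not isinstance(obj["terms"], list) or not obj["terms"]:
        raise ModelError(f"{origin}: 'terms' must be a non-empty list")
    for t in obj["terms"]:
        if not isinstance(t, dict) or "descriptor" not in t or "coef" not in t:
            raise ModelError(f"{origin}: each term needs 'descriptor' and 'coef'")


def load_model(path: str | Path) -> LinearModel:
    """Load a model from JSON (schema-validated)."""
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelError(f"{path}: malformed model JSON: {exc}") from exc
    _validate_schema(obj, str(path))
    return LinearModel(
        name=str(obj["name"]),
        intercept=float(obj["intercept"]),
        terms=tuple((str(t["descriptor"]), float(t["coef"])) for t in obj["terms"]),
        response=str(obj["response"]),
    )


def model_registry(extra_paths: list[str | Path] | None = None) -> dict[str, LinearModel]:
    """Built-in models (from packaged JSON) plus any user-supplied model files."""
    registry: dict[str, LinearModel] = {}
    data = resources.files("pacqsar.data")
    for fname in ("model_logIEQ.json", "model_logTCDDmax.json"):
        with resources.as_file(data.joinpath(fname)) as p:
            m = load_model(p)
        registry[m.name] = m
    for path in extra_paths or []:
        m = load_model(path)
        registry[m.name] = m
    return registry


def route_model(mol: Molecule, registry: dict[str, LinearModel] | None = None) -> LinearModel:
    """Dataset-split routing: Cl/Br-containing compounds go to the
    log %-TCDD-max model, everything else to the log IEQ model."""
    reg = registry if registry is not None else model_registry()
    key = "rAhR_logTCDDmax_eq2" if mol.contains("Cl", "Br") else "rAhR_logIEQ_eq1"
    return reg[key]
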