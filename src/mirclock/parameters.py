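"""Parameter registry for the miR-206-mediated circadian clock model.

The model is parameterised by 78 named rate constants: 76 independent
kinetic constants plus two pure scale factors (``k_stot`` for protein
synthesis, ``v_stot`` for transcription) that are absorbed into
``k_sB``/``k_sC`` and ``V_sB``/``V_sC`` respectively when a set is
loaded.  Four basal sets ship with the package; they are identical
except for ``C3``, the second-order rate constant for formation of the
miR-206·Clock-mRNA silencing complex (0, 0.5, 1.0 and 1.5 nM⁻¹·h⁻¹ for
Set1..Set4).  ``Set1`` therefore corresponds to a clock without
miR-206 feedback onto Clock mRNA and ``Set3`` is the default basal
condition with the coupling active.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PARAM_NAMES",
    "SCALE_FACTORS",
    "SENSITIVITY_PARAMS",
    "HILL_EXPONENTS",
    "SET_LABELS",
    "ParameterSet",
    "load_parameters",
]

_TABLE = json.loads(
    resources.files("mirclock.data").joinpath("table1.json").read_text()
)

#: canonical ordering of all 78 named constants (scale factors included)
PARAM_NAMES: tuple[str, ...] = tuple(_TABLE["base"].keys())

#: pure scale factors, excluded from sensitivity analysis
SCALE_FACTORS: tuple[str, ...] = ("k_stot", "v_stot")

#: the 76 independent constants perturbed by the sensitivity module
SENSITIVITY_PARAMS: tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n not in SCALE_FACTORS
)

#: cooperativity degrees, constrained to be >= 1
HILL_EXPONENTS: tuple[str, ...] = ("m1", "m2", "n1", "n2")

SET_LABELS: tuple[str, ...] = tuple(_TABLE["sets"].keys())

assert len(SENSITIVITY_PARAMS) == 76, "parameter registry must expose 76 constants"


def _resolve(raw: Mapping[str, float | str]) -> dict[str, float]:
    """Expand 'a*k_stot' / 'a*v_stot' style entries into absolute values."""
    out: dict[str, float] = {}
    for name, value in raw.items():
        if isinstance(value, str):
            factor_str, _, scale_name = value.partition("*")
            if scale_name not in SCALE_FACTORS:
                raise ValueError(
                    f"parameter {name!r}: unknown scale factor in {value!r}"
                )
            out[name] = float(factor_str) * float(raw[scale_name])
        else:
            out[name] = float(value)
    return out


class ParameterSet(Mapping[str, float]):
    """Immutable mapping of the 78 named rate constants, fully resolved.

    Values are accessible both as items (``p["V_sB"]``) and attributes
    (``p.V_sB``).  Construction validates that every constant is a
    finite non-negative number and that the Hill exponents are >= 1.
    """

    __slots__ = ("_values", "label")

    def __init__(self, values: Mapping[str, float], label: str = "custom"):
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown parameter name(s) {sorted(unknown)}; "
                f"valid names are {list(PARAM_NAMES)}"
            )
        missing = set(PARAM_NAMES) - set(values)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        resolved = {n: float(values[n]) for n in PARAM_NAMES}
        for name, v in resolved.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} = {v!r} must be finite and >= 0")
        for name in HILL_EXPONENTS:
            if resolved[name] < 1:
                raise ValueError(f"Hill exponent {name} = {resolved[name]} must be >= 1")
        object.__setattr__(self, "_values", resolved)
        object.__setattr__(self, "label", label)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self):
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return len(PARAM_NAMES)

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("ParameterSet is immutable; use .replace()")

    def __repr__(self) -> str:
        return f"ParameterSet(label={self.label!r}, C3={self.C3}, V_sB={self.V_sB})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __hash__(self) -> int:
        return hash(tuple(self._values[n] for n in PARAM_NAMES))

    # convenience -------------------------------------------------------
    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given constants overridden.

        Overrides are absolute values; the scale-factor expansion only
        applies when loading from the packaged table or a config file.
        """
        values = dict(self._values)
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown parameter name(s) {sorted(unknown)}; "
                f"valid names are {list(PARAM_NAMES)}"
            )
        values.update({k: float(v) for k, v in overrides.items()})
        label = self.label if not overrides else f"{self.label}+{len(overrides)}mod"
        return ParameterSet(values, label=label)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def sensitivity_values(self) -> dict[str, float]:
        """The 76 independent constants (scale factors excluded)."""
        return {n: self._values[n] for n in SENSITIVITY_PARAMS}


def _base_set(label: str) -> ParameterSet:
    raw = dict(_TABLE["base"])
    raw.update(_TABLE["sets"][label])
    return ParameterSet(_resolve(raw), label=label)


def load_parameters(
    source: str | Path = "Set3",
    overrides: Mapping[str, float] | None = None,
) -> ParameterSet:
    """Load a packaged parameter set or a user config file.

    Parameters
    ----------
    source
        One of ``Set1``..``Set4``, or a path to a JSON/YAML file of the
        form ``{"base": "Set3", "overrides": {name: value, ...}}`` (or a
        flat ``{name: value}`` mapping overriding the default base).
    overrides
        Additional overrides applied after loading, e.g.
        ``load_parameters("Set3", {"C1": 0.23})``.
    """
    if isinstance(source, str) and source in SET_LABELS:
        params = _base_set(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ValueError(
                f"{source!r} is neither a packaged set {list(SET_LABELS)} "
                "nor an existing config file"
            )
        cfg = yaml.safe_load(path.read_text())
        if not isinstance(cfg, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "base" in cfg or "overrides" in cfg:
            base = cfg.get("base", "Set3")
            file_overrides = cfg.get("overrides", {}) or {}
        else:
            base, file_overrides = "Set3", cfg
        params = _base_set(base)
        if file_overrides:
            params = params.replace(**file_overrides)
        params = ParameterSet(params.to_dict(), label=path.stem)
    if overrides:
        params = params.replace(**overrides)
    return params
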