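"""Bank of empirical sonographic formulas for estimated fetal weight (EFW).

Ultrasound biometry — biparietal diameter (BPD), middle abdominal diameter
(MAD) and femur length (FL), all in millimetres — is mapped to an estimated
fetal weight in grams by one of 26 published empirical formulas.  Formulas
that require abdominal circumference (AC) or head circumference (HC) obtain
them on the fly: AC = 3.1416 × MAD (the literal constant used in the source
compilation, not ``math.pi``) and HC from BPD through a configurable relation,
since the Scandinavian cohort recorded only BPD/MAD/FL.

The bank lives in ``data/efw_formulas.json``; coefficients are kept in the
units of the original publications and converted on evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "FormulaSpec",
    "abdominal_circumference",
    "head_circumference",
    "estimate_fetal_weight",
    "list_formulas",
    "get_formula",
    "DEFAULT_HC_COEFFICIENT",
]

#: The paper's circumference constant, used literally instead of math.pi.
AC_CONSTANT = 3.1416

#: Default head-circumference-to-BPD ratio: circumference of a prolate
#: ellipse with a typical cephalic index of ~1.27 (occipitofrontal diameter
#: 1.27 × BPD), HC ≈ π (BPD + OFD) / 2 ≈ 3.57 × BPD.
DEFAULT_HC_COEFFICIENT = 3.57

_DERIVED = {"AC", "HC"}
_RAW = {"BPD", "MAD", "FL"}
_VALID_INPUTS = _RAW | _DERIVED


@dataclass(frozen=True)
class FormulaSpec:
    """One empirical EFW formula.

    ``terms`` is a list of ``(coefficient, {measure: power})`` pairs; the
    formula value is their sum, evaluated on measurements expressed in
    ``unit_in``.  When ``loglog`` the products run over log10 of the
    measurements; ``log`` states whether the published left-hand side is
    log10/ln of the weight; ``scale`` is the published output unit.
    """

    id: int
    source: str
    required_inputs: frozenset[str]
    unit_in: str  # "mm" or "cm"
    scale: str  # "g" or "kg"
    log: str | None  # "log10", "ln" or None
    loglog: bool
    terms: tuple[tuple[float, tuple[tuple[str, float], ...]], ...] = field(repr=False)

    def evaluate(self, measures: Mapping[str, float]):
        """Evaluate the published expression on measurements in mm.

        Accepts scalars or numpy arrays (broadcast elementwise).
        """
        conv = 1.0 if self.unit_in == "mm" else 0.1
        vals = {}
        for name in self.required_inputs:
            m = np.asarray(measures[name], dtype=float) * conv
            vals[name] = np.log10(m) if self.loglog else m
        acc = 0.0
        for coef, powers in self.terms:
            t = coef
            for name, p in powers:
                t = t * vals[name] ** p
            acc = acc + t
        if self.log == "log10":
            w = 10.0**acc
        elif self.log == "ln":
            w = np.exp(acc)
        else:
            w = acc
        if self.scale == "kg":
            w = w * 1000.0
        return float(w) if np.ndim(w) == 0 else w


def _load_bank() -> tuple[FormulaSpec, ...]:
    raw = json.loads(
        resources.files("fetalens.data").joinpath("efw_formulas.json").read_text()
    )
    specs = []
    for entry in raw["formulas"]:
        terms = tuple(
            (float(t["c"]), tuple((k, float(v)) for k, v in t["p"].items()))
            for t in entry["terms"]
        )
        inputs = frozenset(entry["inputs"])
        if not inputs <= _VALID_INPUTS:
            raise ValueError(f"formula {entry['id']}: unknown inputs {inputs}")
        specs.append(
            FormulaSpec(
                id=int(entry["id"]),
                source=entry["source"],
                required_inputs=inputs,
                unit_in=entry["unit_in"],
                scale=entry["scale"],
                log=entry["log"],
                loglog=bool(entry["loglog"]),
                terms=terms,
            )
        )
    specs.sort(key=lambda s: s.id)
    ids = [s.id for s in specs]
    if ids != list(range(1, len(specs) + 1)):
        raise ValueError("formula ids must be 1..N without gaps")
    return tuple(specs)


_BANK: tuple[FormulaSpec, ...] | None = None


def list_formulas() -> list[FormulaSpec]:
    """Return all 26 formula specifications, ordered by id."""
    global _BANK
    if _BANK is None:
        _BANK = _load_bank()
    return list(_BANK)


def get_formula(formula_id: int) -> FormulaSpec:
    bank = list_formulas()
    if not 1 <= formula_id <= len(bank):
        raise KeyError(f"no EFW formula with id {formula_id}")
    return bank[formula_id - 1]


def abdominal_circumference(mad):
    """AC in mm from middle abdominal diameter in mm, as 3.1416 × MAD."""
    mad = np.asarray(mad, dtype=float)
    if np.any(mad < 0):
        raise ValueError("MAD must be non-negative")
    out = AC_CONSTANT * mad
    return float(out) if out.ndim == 0 else out


def head_circumference(bpd, params: Mapping[str, float] | None = None):
    """HC in mm from BPD in mm through a configured linear relation.

    The cohort recorded no direct head-circumference measurement, so HC is
    reconstructed as ``hc_coefficient × BPD``.  The default coefficient of
    3.57 corresponds to an elliptical head outline with a cephalic index of
    about 1.27; pass ``params={"hc_coefficient": c}`` to substitute any other
    published BPD→HC relation.
    """
    params = {} if params is None else dict(params)
    coef = params.pop("hc_coefficient", DEFAULT_HC_COEFFICIENT)
    if params:
        raise KeyError(
            f"unknown head_circumference config keys {sorted(params)}; "
            "expected 'hc_coefficient'"
        )
    if coef is None:
        raise KeyError(
            "head-circumference relation unconfigured: set 'hc_coefficient'"
        )
    bpd = np.asarray(bpd, dtype=float)
    if np.any(bpd <= 0):
        raise ValueError("BPD must be positive")
    out = float(coef) * bpd
    return float(out) if out.ndim == 0 else out


def _full_measures(biometry: Mapping[str, float], hc_params=None) -> dict[str, float]:
    out = {k.upper(): float(v) for k, v in biometry.items()}
    if "AC" not in out and "MAD" in out:
        out["AC"] = abdominal_circumference(out["MAD"])
    if "HC" not in out and "BPD" in out:
        out["HC"] = head_circumference(out["BPD"], hc_params)
    return out


def estimate_fetal_weight(
    spec: FormulaSpec | int,
    biometry: Mapping[str, float],
    t: float | None = None,
    hc_params: Mapping[str, float] | None = None,
) -> float:
    """Estimated fetal weight in grams for one biometry triple.

    Parameters
    ----------
    spec
        A :class:`FormulaSpec` or a formula id (1–26).
    biometry
        Mapping with ``bpd``, ``mad``, ``fl`` in mm (AC/HC are derived when a
        formula asks for them; they may also be supplied directly).
    t
        Gestational age in days; accepted for record-keeping symmetry with
        the rest of the pipeline but not used — the formulas are functions of
        biometry alone.
    """
    if isinstance(spec, int):
        spec = get_formula(spec)
    measures = _full_measures(biometry, hc_params)
    missing = sorted(spec.required_inputs - measures.keys())
    if missing:
        raise ValueError(
            f"formula {spec.id} ({spec.source}) missing inputs: {', '.join(missing)}"
        )
    w = spec.evaluate(measures)
    if not math.isfinite(w) or w <= 0:
        raise ValueError(
            f"formula {spec.id} ({spec.source}) produced non-physiologic "
            f"weight {w!r} for biometry {dict(measures)}"
        )
    return w


def efw_records(
    visits,
    formula_id: int,
    hc_params: Mapping[str, float] | None = None,
):
    """EFW in grams for every visit row, as a tidy table.

    ``visits`` is a DataFrame with columns ``id``, ``t``, ``bpd``, ``mad``,
    ``fl`` (mm); the result has columns ``id``, ``t``, ``formula_id``,
    ``efw``.  Raises if any row yields a non-finite or non-positive weight,
    naming the formula.
    """
    import pandas as pd

    spec = get_formula(formula_id) if isinstance(formula_id, int) else formula_id
    measures = {
        "BPD": visits["bpd"].to_numpy(dtype=float),
        "MAD": visits["mad"].to_numpy(dtype=float),
        "FL": visits["fl"].to_numpy(dtype=float),
    }
    measures["AC"] = abdominal_circumference(measures["MAD"])
    measures["HC"] = head_circumference(measures["BPD"], hc_params)
    w = np.asarray(spec.evaluate(measures), dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError(
            f"formula {spec.id} ({spec.source}) produced non-physiologic EFW"
        )
    return pd.DataFrame(
        {
            "id": visits["id"].to_numpy(),
            "t": visits["t"].to_numpy(dtype=float),
            "formula_id": spec.id,
            "efw": w,
        }
    )
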