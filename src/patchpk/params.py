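"""Per-hormone pharmacokinetic parameter sets.

The contraceptive patch delivers two hormones — norelgestromin (NGMN, the
progestin, tracked in ng/mL) and ethinylestradiol (EE, the estrogen,
tracked in pg/mL).  Each hormone is described by a release rate from the
patch at application time (``k_o``, printed in µg/day in the source
literature), a plasma clearance, a first-order elimination constant and
its equivalent half-life, an apparent volume of distribution, an
exponential attenuation constant of the absorption rate (``alpha`` for
NGMN, ``beta`` for EE, lumping patch depletion and skin saturation), and
a contraceptively effective serum band.

All internal time bookkeeping is in hours.  Printed per-day quantities
(``k_o`` and the attenuation constants) are divided by 24 on ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["DrugParams", "load_preset", "PRESET_NAMES", "ConsistencyError"]

LN2 = math.log(2.0)

#: mass-unit scale from µg to the serum concentration unit's mass
_MASS_SCALE = {"ng/mL": 1.0e3, "pg/mL": 1.0e6}

#: relative tolerance for the k_elim == ln2 / t_half cross-check
CONSISTENCY_RTOL = 0.02


class ConsistencyError(ValueError):
    """Raised when a parameter set violates a hard invariant."""


@dataclass(frozen=True)
class DrugParams:
    """Kinetic constants for one hormone.

    Parameters
    ----------
    name :
        Hormone label, e.g. ``"NGMN"`` or ``"EE"``.
    k_o :
        Release rate from a freshly applied patch, µg/day.
    clearance :
        Plasma clearance, L/h.
    t_half :
        Elimination half-life, h.
    k_elim :
        First-order elimination constant, 1/h.
    v_d :
        Apparent volume of distribution, mL.
    decay_const :
        Attenuation constant of the absorption rate, 1/h.  The printed
        table values (0.0028, 0.0034) are per day; use
        ``decay_const_per_day / 24`` or :func:`load_preset`.
    therapeutic_low, therapeutic_high :
        Effective serum band in ``conc_unit``.
    conc_unit :
        ``"ng/mL"`` (NGMN) or ``"pg/mL"`` (EE).
    """

    name: str
    k_o: float
    clearance: float
    t_half: float
    k_elim: float
    v_d: float
    decay_const: float
    therapeutic_low: float
    therapeutic_high: float
    conc_unit: str

    def __post_init__(self) -> None:
        for field in ("k_o", "clearance", "t_half", "k_elim", "v_d"):
            if getattr(self, field) <= 0:
                raise ConsistencyError(f"{self.name}: {field} must be strictly positive")
        if self.decay_const < 0:
            raise ConsistencyError(f"{self.name}: decay_const must be non-negative")
        if not self.therapeutic_low < self.therapeutic_high:
            raise ConsistencyError(
                f"{self.name}: therapeutic_low must be below therapeutic_high"
            )
        if self.conc_unit not in _MASS_SCALE:
            raise ConsistencyError(f"{self.name}: unknown concentration unit {self.conc_unit!r}")

    @property
    def is_consistent(self) -> bool:
        """Whether ``k_elim`` agrees with ``ln2 / t_half`` within 2%.

        The published EE row does not (0.0385/h printed vs 0.0456/h
        implied by a 15.2 h half-life); the flag surfaces this rather
        than silently reconciling it.
        """
        return math.isclose(self.k_elim, LN2 / self.t_half, rel_tol=CONSISTENCY_RTOL)

    @property
    def input_rate(self) -> float:
        """Absorption rate into serum from a fresh, fully attached patch.

        ``k_o / V_d`` converted to the serum concentration unit per hour.
        """
        return self.k_o * _MASS_SCALE[self.conc_unit] / self.v_d / 24.0

    def with_k_o(self, k_o: float) -> "DrugParams":
        return replace(self, k_o=k_o)

    def with_decay_const(self, decay_const: float) -> "DrugParams":
        return replace(self, decay_const=decay_const)


def _ngmn(k_o: float, k_elim: float, v_d: float) -> DrugParams:
    return DrugParams(
        name="NGMN", k_o=k_o, clearance=7.89, t_half=28.4, k_elim=k_elim,
        v_d=v_d, decay_const=0.0028 / 24.0,
        therapeutic_low=0.6, therapeutic_high=1.2, conc_unit="ng/mL",
    )


def _ee(k_o: float, k_elim: float, v_d: float) -> DrugParams:
    return DrugParams(
        name="EE", k_o=k_o, clearance=18.3, t_half=15.2, k_elim=k_elim,
        v_d=v_d, decay_const=0.0034 / 24.0,
        therapeutic_low=25.0, therapeutic_high=75.0, conc_unit="pg/mL",
    )


def _presets() -> dict[str, dict[str, DrugParams]]:
    # Verbatim published constants.  The EE row is internally inconsistent
    # (k_elim vs half-life); kept as printed and flagged via is_consistent.
    table1 = {
        "NGMN": _ngmn(150.0, 0.0244, 323_300.0),
        "EE": _ee(20.5, 0.0385, 401_385.0),
    }
    # Reconciled variant: k_elim derived from the half-life, V_d from Cl/k_elim.
    k_n = LN2 / 28.4
    k_e = LN2 / 15.2
    consistent = {
        "NGMN": _ngmn(150.0, k_n, 7.89e3 / k_n),
        "EE": _ee(20.5, k_e, 18.3e3 / k_e),
    }
    # Manufacturer-updated average daily release rates (200 / 35 µg per 24 h).
    updated = {
        "NGMN": table1["NGMN"].with_k_o(200.0),
        "EE": table1["EE"].with_k_o(35.0),
    }
    return {
        "table1-verbatim": table1,
        "halflife-consistent": consistent,
        "updated-k0": updated,
    }


PRESET_NAMES = ("table1-verbatim", "halflife-consistent", "updated-k0")


def load_preset(name: str = "table1-verbatim") -> dict[str, DrugParams]:
    """Return the ``{"NGMN": ..., "EE": ...}`` parameter pair for a preset."""
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    return presets[name]
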