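"""Model parameters and published presets.

The simulator is governed by a flat set of per-agent action probabilities
and integer capacities.  Two presets ship with the package, one per hormone
condition of the calibration experiments:

* ``"DCC DMSO"`` — hormone-deprived (vehicle) medium, emulating androgen
  deprivation therapy.
* ``"DCC R1881"`` — medium supplemented with the synthetic androgen R1881
  (hormone-proficient).

Naming convention: ``TU`` tumor cells, ``F`` fibroblasts, ``M1``/``M2``
macrophage polarizations; ``pprol``/``pmig``/``pdeath``/``pkill`` are per-tick
action probabilities, ``rwalk`` the random (vs. directed) share of migration
steps, ``pmax``/``kmax`` division/kill capacities, and the ``res`` suffix
marks the castration-resistant tumor phenotype.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "ParameterSet",
    "PRESETS",
    "NO_FIBROBLAST_REFITS",
    "get_preset",
    "UNLIMITED",
]

#: Sentinel division capacity meaning "no limit" (fibroblasts by default).
UNLIMITED = 10**9


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants of the simulator for one hormone condition.

    Probabilities are per 4-hour tick and must lie in [0, 1]; capacities are
    non-negative integers.  ``M1speed``/``M2speed`` and the engagement
    durations are expressed in sub-steps: a migrating macrophage makes up to
    ``speed`` single-cell moves within one tick, and a post-kill engagement
    of ``engagement_duration`` sub-steps is worked off at ``speed`` sub-steps
    per tick.
    """

    # -- tumor cells (androgen sensitive) --
    TUpprol: float = 0.1144
    TUpmig: float = 0.1167
    TUpdeath: float = 0.00248
    TUrwalk: float = 0.5
    TUpmax: int = 4
    # -- resistance mechanism --
    TUpres: float = 0.0
    TUpprolres: float = 0.0
    TUpmigres: float = 0.0
    TUpmaxres: int = 0
    # -- M1 macrophages --
    M1pkill: float = 0.1116
    M1pmig: float = 0.2667
    M1rwalk: float = 0.8
    M1kmax: int = 11
    M1speed: int = 40
    M1engagementDuration: int = 60
    # -- M2 macrophages --
    M2pkill: float = 0.0223
    M2pmig: float = 0.2667
    M2rwalk: float = 0.8
    M2kmax: int = 11
    M2speed: int = 40
    M2engagementDuration: int = 60
    M2TUadd: float = 0.0995
    # -- fibroblasts --
    Fpprol: float = 0.0838
    Fpmig: float = 0.4
    Fpdeath: float = 0.0018
    Frwalk: float = 0.5
    Fpmax: int = UNLIMITED
    # -- macrophage spontaneous death (no published value; off by default) --
    Mpdeath: float = 0.0

    _PROBABILITIES = (
        "TUpprol", "TUpmig", "TUpdeath", "TUrwalk", "TUpres", "TUpprolres",
        "TUpmigres", "M1pkill", "M1pmig", "M1rwalk", "M2pkill", "M2pmig",
        "M2rwalk", "M2TUadd", "Fpprol", "Fpmig", "Fpdeath", "Frwalk",
        "Mpdeath",
    )
    _CAPACITIES = (
        "TUpmax", "TUpmaxres", "M1kmax", "M1speed", "M1engagementDuration",
        "M2kmax", "M2speed", "M2engagementDuration", "Fpmax",
    )

    def __post_init__(self) -> None:
        for name in self._PROBABILITIES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v!r} must lie in [0, 1]")
        for name in self._CAPACITIES:
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} = {v!r} must be a non-negative integer")
        if self.TUpprol + self.M2TUadd > 1.0 + 1e-12:
            raise ValueError(
                "TUpprol + M2TUadd exceeds 1 "
                f"({self.TUpprol} + {self.M2TUadd})"
            )

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields changed (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())

    # ------------------------------------------------------------------
    # Packed layout consumed by the numba kernels; index order is fixed.
    _PACK_ORDER = (
        "TUpprol", "TUpmig", "TUpdeath", "TUrwalk", "TUpmax",
        "TUpres", "TUpprolres", "TUpmigres", "TUpmaxres",
        "M1pkill", "M1pmig", "M1rwalk", "M1kmax", "M1speed",
        "M1engagementDuration",
        "M2pkill", "M2pmig", "M2rwalk", "M2kmax", "M2speed",
        "M2engagementDuration", "M2TUadd",
        "Fpprol", "Fpmig", "Fpdeath", "Frwalk", "Fpmax",
        "Mpdeath",
    )

    def pack(self) -> np.ndarray:
        """Flatten into the float64 vector the simulation kernels read."""
        return np.array([float(getattr(self, n)) for n in self._PACK_ORDER])


# Fitted/calibrated values for the two hormone conditions (co-cultures with
# fibroblasts present).  Resistant-cell parameters are only active in the
# hormone-deprived condition: castration resistance has no selective meaning
# under androgen stimulation, so the resistant phenotype is switched off in
# the R1881 preset.
PRESETS: dict[str, ParameterSet] = {
    "DCC DMSO": ParameterSet(
        TUpprol=0.0389, TUpmig=0.1, TUpdeath=0.00248, TUrwalk=0.5, TUpmax=4,
        TUpres=0.002, TUpprolres=0.0596, TUpmigres=0.1167, TUpmaxres=50,
        M1pkill=0.005, M1pmig=0.2667, M1rwalk=0.8, M1kmax=11,
        M1speed=40, M1engagementDuration=60,
        M2pkill=0.0348, M2pmig=0.2667, M2rwalk=0.8, M2kmax=11,
        M2speed=40, M2engagementDuration=60, M2TUadd=0.0,
        Fpprol=0.0838, Fpmig=0.4, Fpdeath=0.0018, Frwalk=0.5,
    ),
    "DCC R1881": ParameterSet(
        TUpprol=0.1144, TUpmig=0.1167, TUpdeath=0.00248, TUrwalk=0.5, TUpmax=4,
        TUpres=0.0, TUpprolres=0.0, TUpmigres=0.0, TUpmaxres=0,
        M1pkill=0.1116, M1pmig=0.2667, M1rwalk=0.8, M1kmax=11,
        M1speed=40, M1engagementDuration=60,
        M2pkill=0.0223, M2pmig=0.2667, M2rwalk=0.8, M2kmax=11,
        M2speed=40, M2engagementDuration=60, M2TUadd=0.0995,
        Fpprol=0.0838, Fpmig=0.4, Fpdeath=0.0018, Frwalk=0.5,
    ),
}

# Refitted values from the tumor + macrophage cultures WITHOUT fibroblasts,
# used to disentangle tumor-intrinsic proliferation changes from macrophage
# tumoricidal activity.  Keys: (context, parameter, condition).
NO_FIBROBLAST_REFITS: dict[tuple[str, str, str], float] = {
    # M1 context: proliferation frozen at the vehicle value, kill refit.
    ("M1", "M1pkill", "DMSO"): 0.005,
    ("M1", "M1pkill", "R1881"): 0.2034,
    ("M1", "TUpprol", "DMSO"): 0.0389,
    # M1 context, alternative scheme: kill frozen, proliferation refit
    # (rejected by the original analysis on cost; kept for comparison).
    ("M1-altTUpprol", "TUpprol", "DMSO"): 0.1550,
    ("M1-altTUpprol", "TUpprol", "R1881"): 0.1144,
    # M2 context: proliferation and kill both refit.
    ("M2", "TUpprol", "DMSO"): 0.0384,
    ("M2", "TUpprol", "R1881"): 0.1128,
    ("M2", "M2pkill", "DMSO"): 0.0219,
    ("M2", "M2pkill", "R1881"): 0.0441,
}

_ALIASES = {
    "DMSO": "DCC DMSO",
    "R1881": "DCC R1881",
    "DCC DMSO": "DCC DMSO",
    "DCC R1881": "DCC R1881",
}


def get_preset(name: str) -> ParameterSet:
    """Look up a shipped parameter preset by condition name.

    Accepts the short condition labels ``"DMSO"`` / ``"R1881"`` as well as
    the full medium names ``"DCC DMSO"`` / ``"DCC R1881"``.
    """
    try:
        return PRESETS[_ALIASES[name]]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_ALIASES)}"
        ) from None
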