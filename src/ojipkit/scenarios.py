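"""Built-in simulation scenarios: named parameter/treatment/profile bundles.

Each scenario reproduces one of the canonical pulse experiments: a
dark-acclimated control, a saturating-DCMU pulse, dark-to-light transitions
(with or without methyl viologen), glycolaldehyde or cyanide addition under
actinic light, a low-to-high-light shift, and the SP-intensity x density grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

from .petc import CYANO_PARAMS, DEFAULT_PARAMS, KineticParams, TreatmentSpec

__all__ = ["Scenario", "BUILTIN_SCENARIOS", "get_scenario"]


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified simulation setup.

    kind 'single' produces one pulse; 'grid' an SP x density matrix;
    'timecourse' repeated pulses at fixed intervals under a treatment.
    """

    name: str
    kind: str  # {"single", "grid", "timecourse"}
    params: KineticParams = DEFAULT_PARAMS
    treatment: TreatmentSpec = TreatmentSpec()
    sp_pfd: float = 2000.0
    profile: str = "pam-like"
    mode: str = "dark"
    extra: dict[str, Any] = field(default_factory=dict)


_GA_PARAMS = replace(DEFAULT_PARAMS, k_TO=0.0, k_NDH=0.0)

BUILTIN_SCENARIOS: dict[str, Scenario] = {
    "dark_control": Scenario("dark_control", "single"),
    "dcmu": Scenario(
        "dcmu", "single", treatment=TreatmentSpec(dcmu_block=1.0)
    ),
    "dark_to_light": Scenario(
        "dark_to_light", "timecourse",
        treatment=TreatmentSpec(al_pfd=100.0), mode="light",
    ),
    "mv": Scenario(
        "mv", "timecourse",
        treatment=TreatmentSpec(mv_bypass=True, al_pfd=100.0), mode="light",
    ),
    "ga": Scenario(
        "ga", "timecourse", params=_GA_PARAMS,
        treatment=TreatmentSpec(ga_block=True, al_pfd=100.0), mode="light",
    ),
    "kcn": Scenario(
        "kcn", "timecourse", params=CYANO_PARAMS,
        treatment=TreatmentSpec(kcn_block=True, al_pfd=100.0), mode="light",
    ),
    "high_light": Scenario(
        "high_light", "timecourse",
        treatment=TreatmentSpec(al_pfd=1500.0), mode="light",
    ),
    "grid": Scenario(
        "grid", "grid",
        extra={
            "sp_intensities": [975.0, 2000.0, 4000.0, 7500.0],
            "densities": [0.1, 0.5, 2.0, 8.0, 24.6],
        },
    ),
}


def get_scenario(name: str) -> Scenario:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}"
        ) from None
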