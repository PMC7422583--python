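"""Named drive scenarios and YAML scenario-config handling.

The bundled scenarios cover the constructs and cost regimes studied for
the *doublesex* drive:

- ``ideal``: fully recessive drive, no parental effects (e=0.95, rho=0.5).
- ``kyrou``: parental-deposition costs measured for the dsx construct of
  Kyrou et al.: heterozygous daughters of transgenic fathers/mothers lose
  78% / 35% of fertility (d_p=0.78, d_m=0.35).
- ``simoni``: male-biasing dsx construct of Simoni et al.: heterozygous
  female fertility reduced 35% (s=0.35) and 93% of the progeny of
  transgenic males are male, mapped to male-bias extent m=0.86 since
  P(male) = (1+m)/2.
- ``medium`` / ``high``: somatic-cost variants (s=0.7, s=0.8) spanning
  moderate to weak suppression strength.
"""

from __future__ import annotations

from typing import Dict

import yaml

from .genetics import DriveParams

__all__ = ["SCENARIOS", "get_scenario", "load_drive_params", "dump_drive_params"]

SCENARIOS: Dict[str, DriveParams] = {
    "ideal": DriveParams(),
    "kyrou": DriveParams(d_p=0.78, d_m=0.35),
    "simoni": DriveParams(s=0.35, m=0.86),
    "medium": DriveParams(s=0.7),
    "high": DriveParams(s=0.8),
}


def get_scenario(name: str) -> DriveParams:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; bundled: {sorted(SCENARIOS)}"
        ) from None


def load_drive_params(path) -> DriveParams:
    """Read drive parameters from a YAML file with a flat ``drive:`` block."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("drive", doc) if isinstance(doc, dict) else doc
    return DriveParams.from_dict(block)


def dump_drive_params(params: DriveParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"drive": params.to_dict()}, fh, sort_keys=True)
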