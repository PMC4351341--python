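"""YAML simulation configuration.

A run is described by a small YAML document mirroring
:class:`~adbfsim.dynamics.SimulationConfig` plus the model mismatch, e.g.::

    dt: 0.5
    n_steps: 2000
    variant: AdBF
    mismatch_delta: 0.2
    temperature: 300.0
    thermostat: ad_langevin      # ad_langevin | ad_nhl | ad_nhc | ad_nhcl | none
    tau_langevin: 200.0
    tau_nh: 200.0
    momentum: {mode: mass_weighted, region: all}
    regions:
      fixed_core: [0, 1, 2]
      r_qm: [3.0, 3.5]
      r_buffer: [3.0, 3.5]
      species_filter: [O, O]
    restraints:
      - {kind: one_sided_distance, atoms: [0, 3], threshold: 3.0, k: 25.0}
    seed: 1
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .dynamics import RestraintSpec, SimulationConfig
from .mixing import MomentumCorrectionSpec
from .regions import RegionSpec

__all__ = ["load_config", "dump_config"]


def _region_spec(d: dict) -> RegionSpec:
    kw = dict(d)
    for key in ("fixed_core", "fixed_qm", "fixed_buffer"):
        if key in kw:
            kw[key] = tuple(kw[key])
    for key in ("r_core", "r_qm", "r_buffer"):
        if key in kw:
            kw[key] = tuple(float(v) for v in kw[key])
    if kw.get("species_filter") is not None:
        kw["species_filter"] = tuple(kw["species_filter"])
    return RegionSpec(**kw)


def load_config(path) -> tuple[SimulationConfig, float]:
    """Parse a YAML run description; returns (config, mismatch_delta)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    delta = float(doc.pop("mismatch_delta", 0.0))
    if "regions" in doc:
        doc["region_spec"] = _region_spec(doc.pop("regions"))
    if "momentum" in doc:
        doc["momentum"] = MomentumCorrectionSpec(**doc["momentum"])
    if "restraints" in doc:
        doc["restraints"] = [RestraintSpec(**r) for r in doc["restraints"]]
    return SimulationConfig(**doc), delta


def dump_config(config: SimulationConfig, delta: float, path) -> None:
    doc = asdict(config)
    doc["mismatch_delta"] = delta
    if doc.get("region_spec") is not None:
        doc["regions"] = doc.pop("region_spec")
    else:
        doc.pop("region_spec", None)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
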