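"""Loading of the shipped default circuit configuration.

The default parameter set (``data/default_circuit.yaml``) is a package
default tuned to produce the canonical four-domain trunk pattern; any
well-formed parameter set of the same schema runs the model.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .genecircuit import (
    BcdGradient,
    CircuitParams,
    ExternalInputs,
    Schedule,
    synthetic_external_inputs,
)


def _load_default_yaml() -> dict:
    with resources.files("gapscale.data").joinpath("default_circuit.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_circuit_config(
    cfg: dict,
) -> tuple[CircuitParams, BcdGradient, Schedule, ExternalInputs]:
    """Build (params, bcd, schedule, external inputs) from a config mapping."""
    params = CircuitParams.from_dict(cfg["circuit"])
    bcd_cfg = cfg.get("bcd", {})
    bcd = BcdGradient(A=bcd_cfg.get("A", 351.0), lam=bcd_cfg.get("lambda", 0.1651))
    s = cfg.get("schedule", {})
    schedule = Schedule(
        nc13_interphase=s.get("nc13_interphase", 16.0),
        mitosis=s.get("mitosis", 5.0),
        nc14_duration=s.get("nc14_duration", 50.0),
    )
    e = cfg.get("external_inputs", {})
    ext = synthetic_external_inputs(
        schedule,
        cad_amplitude=tuple(e.get("cad_amplitude", (75.0, 30.0))),
        cad_midpoint=e.get("cad_midpoint", 0.58),
        cad_width=e.get("cad_width", 0.05),
        tll_amplitude=e.get("tll_amplitude", 100.0),
        tll_midpoint=e.get("tll_midpoint", 0.82),
        tll_width=e.get("tll_width", 0.03),
        tll_ramp=tuple(e.get("tll_ramp", (5.0, 35.0))),
    )
    return params, bcd, schedule, ext


def default_circuit_params() -> tuple[CircuitParams, BcdGradient, Schedule, ExternalInputs]:
    """The shipped default circuit configuration."""
    return load_circuit_config(_load_default_yaml())
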