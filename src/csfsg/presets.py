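"""Canonical fixed parameter sets for single-run evaluation.

``FIXED_CASES`` holds three complete parameter sets, all with zero protected
length, that bracket the production-rate distribution: the ``central`` set
yields the mean of the Monte-Carlo production distribution, ``low``/``high``
yield mean ∓/± one standard deviation.  They are used for deterministic
verification runs and for comparing against the 3D benchmark values.

Note the ``high`` diffusion coefficient: internal consistency of the set
(its siblings are ~1.1e−5 cm²/s) and of the resulting production rate fixes
it at 1.08e−5 cm²/s.

``mean_parameter_values`` returns the means of the full marginal table
(protected length included) for nominal single runs.
"""

from __future__ import annotations

from .geometry import MicrovilliGeometry
from .sg1d import TransportParameters
from .uq import default_parameter_table

__all__ = ["FIXED_CASES", "mean_parameter_values", "case_to_model_inputs"]

FIXED_CASES: dict[str, dict[str, float]] = {
    # yields mean − SD of the production distribution (l_prot = 0)
    "low": {
        "l_mv": 2.329, "r_mv": 0.087, "sigma": 10.0, "A_app": 3.54,
        "l_prot": 0.0, "D": 1.12e-5, "C0": 0.2967, "Lp": 5.03e-6,
        "rho": 1.0002, "Q_meas": 7.071,
    },
    # yields the mean of the production distribution (l_prot = 0)
    "central": {
        "l_mv": 1.875, "r_mv": 0.104, "sigma": 15.3, "A_app": 3.85,
        "l_prot": 0.0, "D": 1.06e-5, "C0": 0.3129, "Lp": 9.82e-6,
        "rho": 1.0001, "Q_meas": 7.346,
    },
    # yields mean + SD of the production distribution (l_prot = 0)
    "high": {
        "l_mv": 1.959, "r_mv": 0.098, "sigma": 12.6, "A_app": 3.87,
        "l_prot": 0.0, "D": 1.08e-5, "C0": 0.3041, "Lp": 2.17e-5,
        "rho": 1.0002, "Q_meas": 7.072,
    },
}


def mean_parameter_values() -> dict[str, float]:
    """Means of the default marginal table, as a name → value mapping."""
    return {spec.name: spec.mean for spec in default_parameter_table()}


def case_to_model_inputs(
    values: dict[str, float],
) -> tuple[MicrovilliGeometry, TransportParameters]:
    """Split a flat ten-parameter mapping into geometry and transport inputs."""
    geom = MicrovilliGeometry(
        r_mv=values["r_mv"], l_mv=values["l_mv"],
        sigma=values["sigma"], A_app=values["A_app"],
    )
    params = TransportParameters(
        D=values["D"], C0=values["C0"], rho=values["rho"],
        Lp=values["Lp"], l_prot=values["l_prot"], Q_meas=values["Q_meas"],
    )
    return geom, params
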