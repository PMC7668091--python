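"""Versioned default-parameter registry for the bundled models.

Every constructor reads its defaults from here, and the registry hash is
stamped into run provenance so a result can be traced to the exact
parameter set that produced it.  The values are package defaults chosen to
place each model in its documented dynamical regime; they are not fitted to
any external dataset.
"""

from __future__ import annotations

import hashlib
import json

REGISTRY_VERSION = "1.0"

MODEL_DEFAULTS: dict[str, dict] = {
    "birth_death": {"r": 0.5, "d": 0.2},
    "cycle3": {"c": 1.0, "K": 500.0, "theta": 4.0, "d": 0.2},
    "bistable3": {
        "r": [0.5, 0.4, 0.3],
        "a": [[0.0, 1.5, 0.0], [1.5, 0.0, 0.0], [1.0, 1.0, 0.0]],
        "eps": 0.05,
        "sigma": 0.22,
    },
    "heteroclinic3": {
        "r": 1.0,
        "a_self": 1.0,
        "a_weak": 0.7,
        "a_strong": 1.4,
    },
    "single_repressilator": {
        "theta": 1.0,
        "K": 500.0,
        "c1": 1.0,
        "c": 2.0,
        "d": 0.1,
        "t_end": 2000.0,
    },
    "double_repressilator": {
        "alpha": 100.0,
        "theta": 3.0,
        "theta_x": None,
        "cross_shift": 0,
        "K": 2000.0,
        "Kx": 1.0,
        "c1": 1.0,
        "c": 2.0,
        "c_ratio": 1.618,
        "d": 0.1,
        "t_end": 4000.0,
    },
    "cross_feeding": {
        "Kc": 0.05,
        "d_m": 0.2,
        "uptake_scale": 3.0,
        "r_range": [0.5, 1.5],
        "a_range": [0.0, 1.0],
        "a_self_range": [0.2, 1.0],
        "s_range": [0.1, 0.5],
        "t_end": 400.0,
        "extinction_threshold": 1e-4,
    },
    "chemostat_cross_feeding": {
        "s_in": 5.0,
        "v_up": 1.0,
        "Ks": 0.5,
        "yield_x": 1.0,
        "Kc": 0.1,
        "t_end": 600.0,
    },
    "biosynthesis_toy": {
        "thetaR": 1.0,
        "nutrient_level": 1.0,
        "atp_yield": 20.0,
        "v_imp": 2.0,
        "v_enz": 5.0,
        "v_cat": 2.0,
        "v_pol": 8.0,
        "K": 0.1,
        "K_atp": 0.05,
    },
    "random_srn": {
        "n_nodes": 5,
        "n_fluxes": 8,
        "connectivity_exponent": 2.0,
    },
}


def registry_hash() -> str:
    """Stable content hash of the default registry (provenance stamp)."""
    blob = json.dumps(
        {"version": REGISTRY_VERSION, "defaults": MODEL_DEFAULTS},
        sort_keys=True,
        separators=(",", ":"),
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def defaults_for(model: str) -> dict:
    if model not in MODEL_DEFAULTS:
        raise KeyError(f"unknown model {model!r}; known: {sorted(MODEL_DEFAULTS)}")
    return json.loads(json.dumps(MODEL_DEFAULTS[model]))  # deep copy
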