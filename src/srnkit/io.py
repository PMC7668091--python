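"""Network schema serialization and the reproducible run pipeline.

Schema (YAML or JSON): top-level ``nodes`` (ordered list of strings) and
``reactions`` (list of mappings with keys ``id``, ``rate`` — an expression
string in node symbols and ``N`` — ``upstream``, ``downstream``,
``maintenance``, ``stoich``).  The writer emits a canonical form (sorted
keys, sorted set-lists); reading a canonical file and writing it back is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .autocatalysis import max_autocatalytic_circuit
from .dynamics import lambda_time_average, simulate_simplex
from .ergodic import classify_attractor, lambda_space_average, occupation_measure
from .network import FluxSpec, NetworkValidationError, ReactionNetwork, build_network
from .zoo import registry_hash
from . import zoo as _zoo

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "read_network",
    "write_network",
    "RunConfig",
    "run_pipeline",
]

SCHEMA_VERSION = 1


def network_to_dict(network: ReactionNetwork) -> dict:
    reactions = []
    for fx in network.fluxes:
        if not fx.symbolic:
            raise NetworkValidationError(
                f"flux {fx.id!r} has a callable rate; only expression rates serialize"
            )
        reactions.append(
            {
                "downstream": sorted(fx.downstream),
                "id": fx.id,
                "maintenance": sorted(fx.maintenance),
                "rate": fx.rate,
                "stoich": {k: float(v) for k, v in sorted(fx.stoich.items())},
                "upstream": sorted(fx.upstream),
            }
        )
    return {"nodes": list(network.nodes), "reactions": reactions, "schema_version": SCHEMA_VERSION}


def network_from_dict(data: dict) -> ReactionNetwork:
    try:
        nodes = list(data["nodes"])
        raw = data["reactions"]
    except KeyError as exc:
        raise NetworkValidationError(f"missing top-level key {exc.args[0]!r}") from exc
    fluxes = []
    for entry in raw:
        try:
            fx = FluxSpec(
                id=entry["id"],
                rate=entry["rate"],
                stoich={k: float(v) for k, v in entry["stoich"].items()},
                upstream=frozenset(entry.get("upstream", ())),
                downstream=frozenset(entry.get("downstream", ())),
                maintenance=frozenset(entry.get("maintenance", ())),
            )
        except KeyError as exc:
            raise NetworkValidationError(
                f"reaction entry {entry.get('id', '<no id>')!r} missing key {exc.args[0]!r}"
            ) from exc
        fluxes.append(fx)
    try:
        return build_network(nodes, fluxes)
    except NetworkValidationError:
        raise


def write_network(network: ReactionNetwork, path: str | Path) -> None:
    path = Path(path)
    data = network_to_dict(network)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True, default_flow_style=False))


def read_network(path: str | Path) -> ReactionNetwork:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return network_from_dict(data)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulate/classify/lambda run."""

    model: str | None = None  # zoo constructor name...
    model_params: dict = field(default_factory=dict)
    network_file: str | None = None  # ...or a schema file
    t_end: float = 400.0
    n_points: int = 2001
    burn_in: float | None = None
    seed: int = 0
    Y0: list | None = None
    rtol: float = 1e-9
    atol: float = 1e-12
    with_circuits: bool = True
    with_measure: bool = True
    out_dir: str | None = None

    def build(self) -> ReactionNetwork:
        if (self.model is None) == (self.network_file is None):
            raise ValueError("exactly one of model / network_file must be set")
        if self.network_file:
            return read_network(self.network_file)
        ctor = getattr(_zoo, self.model, None)
        if ctor is None:
            raise ValueError(f"unknown zoo model {self.model!r}")
        return ctor(**self.model_params)

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # output location does not affect results
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """build -> validate -> simulate -> classify -> growth rates -> circuits.

    Returns the JSON-ready summary; when ``config.out_dir`` is set, also
    writes ``summary.json`` (deterministic byte content for a given config
    and registry) and ``trajectory.csv``.
    """
    from .network import check_scalability

    net = config.build()
    report = check_scalability(net, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    Y0 = np.asarray(config.Y0, dtype=float) if config.Y0 is not None else rng.dirichlet(np.ones(net.n))
    traj = simulate_simplex(
        net, Y0, config.t_end, n_points=config.n_points,
        solver_opts={"rtol": config.rtol, "atol": config.atol},
    )
    est = lambda_time_average(traj, burn_in=config.burn_in)
    summary_cls = classify_attractor(traj, network=net)
    result = {
        "config_hash": config.hash(),
        "registry_hash": registry_hash(),
        "seed": config.seed,
        "is_srn": report.is_srn,
        "failing_fluxes": report.failing_fluxes(),
        "lambda_time_average": est.lam,
        "lambda_converged": est.converged,
        "label": summary_cls.label,
        "diameter": summary_cls.diameter,
        "period": summary_cls.period,
        "lle": summary_cls.lle,
    }
    if config.with_measure:
        burn = config.burn_in if config.burn_in is not None else 0.2 * config.t_end
        meas = occupation_measure(traj, burn_in=burn)
        result["lambda_space_average"] = lambda_space_average(meas)
    if config.with_circuits:
        circ = max_autocatalytic_circuit(net)
        result["max_circuit"] = sorted(circ.reactions) if circ else []
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
        traj.to_csv(out / "trajectory.csv")
    return result
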