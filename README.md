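# srnkit

Scalable reaction networks (SRNs): build nonlinear reaction networks whose
flux functions are positive, upstream-limited, and degree-one homogeneous;
integrate their biomass and simplex-projected dynamics; compute long-term
exponential growth rates as time averages or ergodic space averages;
classify growth modalities (balanced, periodic, quasiperiodic, chaotic,
heteroclinic); and detect autocatalytic circuits.

## Quick start

```python
import numpy as np
import srnkit as sk
from srnkit.zoo import single_repressilator

net = single_repressilator(theta=3.0, K=500.0)
report = sk.check_scalability(net)        # conditions 1-3 per flux
assert report.is_srn

traj = sk.simulate_simplex(net, [0.4, 0.25, 0.2, 0.15], t_end=1200.0)
est = sk.lambda_time_average(traj)        # long-term growth rate
summary = sk.classify_attractor(traj, network=net)
print(est.lam, summary.label, summary.diameter)

measure = sk.occupation_measure(traj, burn_in=600.0)
print(sk.lambda_space_average(measure))   # Birkhoff space average

from srnkit import max_autocatalytic_circuit
print(max_autocatalytic_circuit(net).reactions)
```

## Package layout

| module | contents |
| --- | --- |
| `srnkit.network` | `FluxSpec`, `ReactionNetwork`, `build_network`, the three scalability checks, `flux_from_unit_volume` |
| `srnkit.dynamics` | biomass/simplex RHS and integrators, `Trajectory`, `lambda_time_average` |
| `srnkit.ergodic` | attractor classification, diameter, largest Lyapunov exponent, occupation measures, `lambda_space_average`, parameter scans |
| `srnkit.stochastic` | Euler-Maruyama simplex SDE, regenerativity check, noise-unified growth rates |
| `srnkit.autocatalysis` | circuit predicate, maximal/minimal circuit search, random-network theorem screening |
| `srnkit.zoo` | model registry and constructors: birth-death, 3-node limit-cycle/bistable/heteroclinic systems, single/double repressilators, cross-feeding community (+ chemostat variant), 24-node biosynthesis toy, seeded random-SRN and parameter samplers |
| `srnkit.io` / `srnkit.cli` | YAML/JSON network schema, run pipeline, `srn` CLI |

Model defaults live in `srnkit/zoo/registry.py` and are hash-stamped into
run provenance.

## CLI

```bash
srn zoo list
srn zoo build single_repressilator -p theta=3.0 -p K=500.0 -o rep.yaml
srn simulate rep.yaml --t-end 500 --seed 1 --out run/
srn sde rep.yaml --sigma 0.02 --seed 1
srn circuits rep.yaml
srn screen --n 1000 --seed 0
srn scan --config scan.yaml --out scan.csv
```

Exit codes: 0 ok, 2 validation error, 3 non-convergence.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic ATP
balance fractions, competitive-exclusion statistics, balanced-growth
diameter, Birkhoff agreement, linear-network eigenvalue oracle,
circuit-enumeration equivalence, theorem screening, modality regimes).
The full suite takes ~8 minutes on one CPU.  One acceptance test
(`test_criterion4_double_repressilator_chaotic_at_alpha_500`) is expected
to fail: the chaotic regime of the double repressilator depends on
unpublished parameters and no chaotic default was found (see the test's
comment).

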