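"""Basal-ganglia firing-rate circuit whose STN activity is the mechanistic
parkinsonism-liability readout.

The network is a rectified-linear rate model of the cortico-striatal motor
loop: supplementary-motor-area cortex drives two striatal medium-spiny-neuron
populations — D₁⁺ MSNs projecting to the internal globus pallidus (direct
pathway) and D₂⁺ MSNs projecting to the external globus pallidus and, via
GPe disinhibition, the subthalamic nucleus (indirect pathway).  Each
population relaxes as

    τ · dr/dt = −r + ramp(baseline + Σ w·r_pre + drug modulation)

with ramp(x) = max(x, 0).  Two receptor-level modulations carry drug effects
into the circuit:

* D₂ blockade disinhibits D₂⁺ MSNs.  The net drive to MSN_D2 is scaled by
  ``1 + gain_d2 · (baseline_d2_activation − A)``, where ``A`` is the
  occupancy-weighted D₂ activation from the competition model (endogenous
  dopamine counts as a full agonist, bound antipsychotics contribute their
  intrinsic activity).
* 5-HT₂A antagonism damps the indirect pathway at its subthalamic limb: the
  net STN drive is scaled by ``1 − gain_5ht2a · occ_5HT2A``.

Elevated steady-state STN activity relative to the drug-free fixed point is
reported as the liability score; STN hyperactivity is the circuit correlate
of bradykinesia and rigidity.  The score is an ordinal risk index, not a
calibrated probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .pharmacology import Regimen, competitive_occupancy

__all__ = [
    "POPULATIONS",
    "EDGES",
    "CircuitParams",
    "PopulationRates",
    "EPSReadout",
    "CircuitConvergenceError",
    "default_circuit_params",
    "effective_d2_activation",
    "steady_state_rates",
    "stn_readout",
]

POPULATIONS = ("cortex_SMA", "MSN_D1", "MSN_D2", "GPe", "STN", "GPi")

#: (presynaptic, postsynaptic, sign): +1 excitatory, -1 inhibitory (GABAergic).
EDGES = (
    ("cortex_SMA", "MSN_D1", +1),
    ("cortex_SMA", "MSN_D2", +1),
    ("MSN_D1", "GPi", -1),
    ("MSN_D2", "GPe", -1),
    ("GPe", "STN", -1),
    ("STN", "GPi", +1),
)


class CircuitConvergenceError(RuntimeError):
    """Raised when the rate dynamics fail to settle; carries the last state."""

    def __init__(self, rates: "PopulationRates"):
        super().__init__(
            f"circuit did not converge (residual {rates.residual:.3e}); "
            "inspect .rates for the terminal state"
        )
        self.rates = rates


@dataclass(frozen=True)
class CircuitParams:
    """Connectivity, gains and time constants of the rate model.

    ``weights`` is keyed ``"pre->post"`` and must respect the sign of each
    anatomical edge (inhibitory ≤ 0, excitatory ≥ 0).  ``gain_d2`` sets how
    strongly loss of D₂ activation disinhibits D₂⁺ MSNs; ``gain_5ht2a`` (in
    [0, 1]) is the fractional STN-drive reduction per unit 5-HT₂A antagonist
    occupancy.  Rates and time constants are in arbitrary units; only the
    normalized STN readout is interpreted.
    """

    baseline_rates: dict[str, float]
    weights: dict[str, float]
    gain_d2: float = 2.0
    gain_5ht2a: float = 0.3
    baseline_d2_activation: float = 0.5
    tau: dict[str, float] | None = None
    tol: float = 1e-10
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        missing = [p for p in POPULATIONS if p not in self.baseline_rates]
        if missing:
            raise ValueError(f"baseline_rates missing populations {missing}")
        for p, r in self.baseline_rates.items():
            if r < 0:
                raise ValueError(f"baseline rate of {p} must be >= 0")
        for pre, post, sign in EDGES:
            key = f"{pre}->{post}"
            if key not in self.weights:
                raise ValueError(f"weights missing edge {key}")
            w = self.weights[key]
            if sign < 0 and w > 0:
                raise ValueError(f"{key} is inhibitory; weight must be <= 0")
            if sign > 0 and w < 0:
                raise ValueError(f"{key} is excitatory; weight must be >= 0")
        if not 0.0 <= self.gain_5ht2a <= 1.0:
            raise ValueError("gain_5ht2a must lie in [0, 1]")
        if not 0.0 < self.baseline_d2_activation <= 1.0:
            raise ValueError("baseline_d2_activation must lie in (0, 1]")
        if self.tau is not None and any(self.tau.get(p, 1.0) <= 0 for p in POPULATIONS):
            raise ValueError("time constants must be > 0")

    def tau_vector(self) -> np.ndarray:
        if self.tau is None:
            return np.ones(len(POPULATIONS))
        return np.array([self.tau.get(p, 1.0) for p in POPULATIONS])

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(
            baseline_rates=dict(d["baseline_rates"]),
            weights=dict(d["weights"]),
            gain_d2=float(d.get("gain_d2", 2.0)),
            gain_5ht2a=float(d.get("gain_5ht2a", 0.3)),
            baseline_d2_activation=float(d.get("baseline_d2_activation", 0.5)),
            tau=dict(d["tau"]) if d.get("tau") else None,
            tol=float(d.get("tol", 1e-10)),
            max_steps=int(d.get("max_steps", 100_000)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CircuitParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PopulationRates:
    """Converged (or terminal) firing rates, one entry per population."""

    rates: dict[str, float]
    converged: bool
    residual: float

    def __getitem__(self, pop: str) -> float:
        return self.rates[pop]


@dataclass(frozen=True)
class EPSReadout:
    """STN-based liability: relative STN-rate elevation over drug-free baseline."""

    stn_activity: float
    baseline_stn: float
    liability_score: float


def default_circuit_params() -> CircuitParams:
    """Bundled default parameters (drug-free fixed point interior)."""
    with resources.as_file(resources.files("apprisk.data") / "circuit_params.yaml") as p:
        return CircuitParams.from_yaml(p)


def effective_d2_activation(regimen: Regimen, dopamine_tone: float = 1.0) -> float:
    """Occupancy-weighted D₂ activation under drug competition.

    Endogenous dopamine acts as a full agonist (intrinsic activity 1), each
    antipsychotic contributes its own intrinsic activity, and free receptors
    contribute nothing:

        A = (r_DA + r_a·ε_a + r_b·ε_b) / (1 + r_DA + r_a + r_b)

    With no drug on board, A = tone / (1 + tone).
    """
    occ = competitive_occupancy(regimen, "D2R", dopamine_tone)
    return (
        occ.occ_endogenous
        + occ.occ_a * regimen.drug_a.intrinsic_activity_d2
        + occ.occ_b * regimen.drug_b.intrinsic_activity_d2
    )


_IDX = {p: i for i, p in enumerate(POPULATIONS)}


def _assemble(params: CircuitParams) -> tuple[np.ndarray, np.ndarray]:
    """Baseline vector and weight matrix W[post, pre] for vectorized drive."""
    baseline = np.array([params.baseline_rates[p] for p in POPULATIONS])
    w = np.zeros((len(POPULATIONS), len(POPULATIONS)))
    for pre, post, _ in EDGES:
        w[_IDX[post], _IDX[pre]] = params.weights[f"{pre}->{post}"]
    return baseline, w


def _net_drive(
    r: np.ndarray, params: CircuitParams, d2_activation: float, occ_5ht2a: float,
    assembled: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    baseline, w = assembled if assembled is not None else _assemble(params)
    drive = baseline + w @ r
    # D2 blockade disinhibits the indirect-pathway MSNs; rectify the scale
    # factor so a supra-baseline agonist cannot drive the population negative.
    scale_d2 = max(0.0, 1.0 + params.gain_d2 * (params.baseline_d2_activation - d2_activation))
    drive[_IDX["MSN_D2"]] *= scale_d2
    drive[_IDX["STN"]] *= 1.0 - params.gain_5ht2a * occ_5ht2a
    return np.maximum(drive, 0.0)


def steady_state_rates(
    params: CircuitParams, d2_activation: float, occ_5ht2a: float = 0.0
) -> PopulationRates:
    """Relax the rate equations to their fixed point by forward Euler.

    Step size is 0.1·min(τ).  Convergence is declared when the remaining
    rate change ``max_p |ramp(drive_p) − r_p|`` falls below ``params.tol``;
    otherwise the terminal state is returned flagged unconverged.
    """
    if not 0.0 <= d2_activation <= 1.0:
        raise ValueError("d2_activation must lie in [0, 1]")
    if not 0.0 <= occ_5ht2a <= 1.0:
        raise ValueError("occ_5ht2a must lie in [0, 1]")
    tau = params.tau_vector()
    dt = 0.1 * float(tau.min())
    r = np.array([params.baseline_rates[p] for p in POPULATIONS], dtype=float)
    residual = np.inf
    converged = False
    assembled = _assemble(params)
    for _ in range(params.max_steps):
        target = _net_drive(r, params, d2_activation, occ_5ht2a, assembled)
        delta = target - r
        residual = float(np.max(np.abs(delta)))
        if residual < params.tol:
            converged = True
            break
        r = np.maximum(r + (dt / tau) * delta, 0.0)
    rates = {p: float(r[i]) for i, p in enumerate(POPULATIONS)}
    return PopulationRates(rates=rates, converged=converged, residual=residual)


def stn_readout(
    regimen: Regimen,
    params: CircuitParams | None = None,
    dopamine_tone: float = 1.0,
) -> EPSReadout:
    """Mechanistic liability score for a two-drug regimen.

    Computes D₂ activation and total 5-HT₂A antagonist occupancy from the
    competition model, relaxes the circuit, and reports the STN rate
    normalized to the drug-free fixed point at the same dopamine tone:

        liability = (STN_drug − STN_baseline) / STN_baseline

    Deterministic; a zero-dose regimen scores exactly 0.
    """
    if params is None:
        params = default_circuit_params()
    a_drug = effective_d2_activation(regimen, dopamine_tone)
    occ5 = competitive_occupancy(regimen, "5HT2AR").total_drug_occupancy
    a_base = dopamine_tone / (1.0 + dopamine_tone)

    base = steady_state_rates(params, a_base, 0.0)
    if not base.converged:
        raise CircuitConvergenceError(base)
    drug = steady_state_rates(params, a_drug, occ5)
    if not drug.converged:
        raise CircuitConvergenceError(drug)

    stn0 = base["STN"]
    if stn0 <= 0:
        raise ValueError("drug-free STN rate is zero; baseline parameters degenerate")
    stn = drug["STN"]
    return EPSReadout(
        stn_activity=stn,
        baseline_stn=stn0,
        liability_score=(stn - stn0) / stn0,
    )
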