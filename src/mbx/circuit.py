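"""Rate-based simulator of the compartmentalized KC→MBON extinction circuit.

The model captures the causal skeleton of aversive-memory extinction in
the fly mushroom body:

* Sparse Kenyon-cell (KC) odor patterns drive four MBON compartments
  through non-negative weight vectors, all initialized to 1 (a balanced
  network: a naive fly shows no odor preference).
* Aversive training — CS+ coincident with punishment-coding PPL1 DANs —
  multiplicatively depresses the CS+-active KC synapses onto the
  approach-promoting compartments (γ1pedc / MVP2 and a lumped
  "approach-other" channel).
* MVP2 feeds forward inhibition whose form encodes its EM-measured synapse
  placement: divisive (shunting) onto M6, whose MVP2 inputs cluster at the
  dendritic root, and subtractive onto M4β′, whose MVP2 inputs sit on
  distal boutons.  Training therefore *disinhibits* the avoidance MBONs'
  axonal CS+ responses without touching their dendritic drive.
* M4β′/M6 output recurrently excites reward-coding γ5 PAM DANs.  During
  unreinforced CS+ re-exposure, the trained network preferentially drives
  these DANs above threshold, which depresses CS+-active KC→M6 (γ5)
  synapses — a parallel, opposing extinction memory.

All quantitative parameters are this package's own choices: the biology
constrains only the signs and the wiring.  Defaults live in one config
block (:meth:`CircuitState.default`) and are documented in the methods
note.  Dynamics are discrete-trial: one plasticity update per trial, no
spiking, no time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .behavior import ProtocolTimeline, TimelineEvent

__all__ = [
    "OdorPattern",
    "CircuitState",
    "NetworkResponse",
    "COMPARTMENTS",
    "make_odor_pair",
    "respond",
    "apply_plasticity",
    "run_protocol",
    "model_performance_index",
]

#: Model compartments: γ1pedc houses MVP2 (approach), γ5 houses M6
#: (avoidance), β′2 houses M4β′ (avoidance), plus a lumped approach channel.
COMPARTMENTS = ("gamma1pedc", "gamma5", "beta_p2", "approach_other")

#: Blockable elements (thermo/optogenetic silencing in the model's terms).
BLOCKABLE = ("PAM_gamma5_DAN", "PPL1_DAN", "M4M6_output")


@dataclass(frozen=True)
class OdorPattern:
    """A sparse binary KC activity vector."""

    label: str
    kc_activity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "kc_activity",
                           np.asarray(self.kc_activity, dtype=bool))
        if self.kc_activity.sum() < 1:
            raise ValueError("an odor must activate at least one KC")

    @property
    def n_active(self) -> int:
        return int(self.kc_activity.sum())


def make_odor_pair(n_kc: int = 200, active_fraction: float = 0.10,
                   rng: np.random.Generator | int | None = None,
                   labels: tuple[str, str] = ("CS+", "CS-"),
                   overlap_fraction: float = 0.0) -> tuple[OdorPattern, OdorPattern]:
    """Draw two equally sparse odor patterns.

    ``overlap_fraction`` is the fraction of active KCs shared; the default
    0 gives fully distinct odors (protocol odors must differ in at least
    half their active cells, so overlap is capped at 0.5).
    """
    if not 0.0 <= overlap_fraction <= 0.5:
        raise ValueError("overlap_fraction must lie in [0, 0.5]")
    rng = np.random.default_rng(rng)
    n_active = max(1, round(n_kc * active_fraction))
    n_shared = int(round(n_active * overlap_fraction))
    need = 2 * n_active - n_shared
    if need > n_kc:
        raise ValueError("not enough KCs for two odors at this sparseness")
    cells = rng.choice(n_kc, size=need, replace=False)
    shared = cells[:n_shared]
    own_a = cells[n_shared:n_shared + (n_active - n_shared)]
    own_b = cells[n_shared + (n_active - n_shared):]
    a = np.zeros(n_kc, dtype=bool)
    b = np.zeros(n_kc, dtype=bool)
    a[shared] = a[own_a] = True
    b[shared] = b[own_b] = True
    return OdorPattern(labels[0], a), OdorPattern(labels[1], b)


@dataclass
class CircuitState:
    """KC→MBON weights per compartment plus the fixed circuit parameters.

    ``g_shunt`` is the divisive MVP2→M6 gain, ``s_sub`` the subtractive
    MVP2→M4β′ gain.  ``eta_train`` / ``eta_extinction`` are per-trial
    multiplicative depression rates; ``dan_threshold`` gates the recurrent
    γ5 teaching signal; ``pi_softening`` is the ε in the model PI (of the
    order of the naive compartment drive, so PI spans a behaviour-like
    range instead of saturating at ±1).
    """

    weights: dict[str, np.ndarray]
    g_shunt: float = 0.05
    s_sub: float = 0.4
    eta_train: float = 0.5
    eta_extinction: float = 0.134
    dan_threshold: float = 25.0
    dan_gain: float = 1.0
    w_min: float = 0.05
    pi_softening: float = 40.0

    def __post_init__(self) -> None:
        if set(self.weights) != set(COMPARTMENTS):
            raise ValueError(f"weights must cover exactly {COMPARTMENTS}")
        n = {len(w) for w in self.weights.values()}
        if len(n) != 1:
            raise ValueError("all compartments must share one KC dimension")
        for c, w in self.weights.items():
            self.weights[c] = np.asarray(w, dtype=float)
            if np.any(self.weights[c] < self.w_min - 1e-12) or np.any(self.weights[c] > 1 + 1e-12):
                raise ValueError(f"compartment {c}: weights outside [w_min, 1]")
        if self.g_shunt < 0 or self.s_sub < 0:
            raise ValueError("inhibition gains must be non-negative")
        if not 0.0 <= self.eta_train <= 1.0 or not 0.0 <= self.eta_extinction <= 1.0:
            raise ValueError("plasticity rates must lie in [0, 1]")

    @property
    def n_kc(self) -> int:
        return len(self.weights[COMPARTMENTS[0]])

    @classmethod
    def default(cls, n_kc: int = 200, **overrides) -> "CircuitState":
        """Naive state: all weights 1 (the balanced network)."""
        weights = {c: np.ones(n_kc) for c in COMPARTMENTS}
        return cls(weights=weights, **overrides)

    def copy(self) -> "CircuitState":
        return replace(self, weights={c: w.copy() for c, w in self.weights.items()})


@dataclass(frozen=True)
class NetworkResponse:
    """Per-odor steady-state drives of the MBON network."""

    odor: str
    mvp2: float
    m6_dendrite: float
    m6_axon: float
    m4_dendrite: float
    m4_axon: float
    approach_other: float
    dan_gamma5: float
    valence: float


def respond(state: CircuitState, odor: OdorPattern) -> NetworkResponse:
    """One forward pass of the network for one odor.

    Dendritic drives are linear readouts ``w_c · kc``.  MVP2's output is
    its dendritic drive (no inhibition upstream of it).  M6's axonal
    output is shunted divisively, M4β′'s subtractively (floored at 0).
    The γ5 DAN drive is proportional to summed avoidance-MBON output, and
    valence is approach drive minus avoidance drive.
    """
    kc = odor.kc_activity.astype(float)
    if kc.size != state.n_kc:
        raise ValueError("odor and circuit disagree on KC count")
    mvp2 = float(state.weights["gamma1pedc"] @ kc)
    m6_dend = float(state.weights["gamma5"] @ kc)
    m4_dend = float(state.weights["beta_p2"] @ kc)
    approach_other = float(state.weights["approach_other"] @ kc)
    m6_axon = m6_dend / (1.0 + state.g_shunt * mvp2)
    m4_axon = max(0.0, m4_dend - state.s_sub * mvp2)
    dan = state.dan_gain * (m6_axon + m4_axon)
    valence = (mvp2 + approach_other) - (m6_axon + m4_axon)
    return NetworkResponse(odor.label, mvp2, m6_dend, m6_axon, m4_dend, m4_axon,
                           approach_other, dan, valence)


def apply_plasticity(state: CircuitState, odor: OdorPattern,
                     active_dan_compartments: Sequence[str],
                     rate: float | None = None) -> CircuitState:
    """Dopamine-gated depression, compartment-restricted and odor-specific.

    For each compartment whose DAN is active, the weights of exactly the
    odor-active KCs decay multiplicatively, ``w ← max(w_min, w·(1 − η))``;
    every other weight is untouched.  Returns a new state.
    """
    unknown = set(active_dan_compartments) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartments: {sorted(unknown)}")
    eta = state.eta_train if rate is None else rate
    new = state.copy()
    mask = odor.kc_activity
    for c in active_dan_compartments:
        w = new.weights[c]
        w[mask] = np.maximum(state.w_min, w[mask] * (1.0 - eta))
    return new


def model_performance_index(state: CircuitState, cs_plus: OdorPattern,
                            cs_minus: OdorPattern) -> float:
    """Model PI for an odor pair: softened, normalized valence contrast.

    ``PI = (V(CS+) − V(CS−)) / (|V(CS+)| + |V(CS−)| + ε)``; negative means
    the model avoids the CS+.
    """
    v_plus = respond(state, cs_plus).valence
    v_minus = respond(state, cs_minus).valence
    return (v_plus - v_minus) / (abs(v_plus) + abs(v_minus) + state.pi_softening)


# ---------------------------------------------------------------------------
# Protocol execution
# ---------------------------------------------------------------------------

#: Compartments depressed when CS+ coincides with PPL1 (punishment) DANs.
_TRAIN_TARGETS = ("gamma1pedc", "approach_other")


def _window_overlaps(event: TimelineEvent, window: tuple[float, float]) -> bool:
    t0, t1 = window
    if t1 < t0:
        raise ValueError(f"malformed block window {window}")
    return event.onset_s < t1 and t0 < event.onset_s + event.duration_s


def run_protocol(state: CircuitState, protocol: ProtocolTimeline,
                 cs_plus: OdorPattern | None = None,
                 cs_minus: OdorPattern | None = None,
                 blocks: Mapping[str, tuple[float, float]] | None = None,
                 seed: int | None = None) -> dict[str, object]:
    """Run a behavioural protocol timeline through the circuit.

    Odor trials are read off the timeline: a CS+ epoch containing shocks is
    a training (or retraining) trial and triggers PPL1-gated depression in
    the approach compartments; an unreinforced CS+ epoch is a re-exposure
    trial, during which the recurrent γ5 DAN drive is computed from the
    *current* M4β′/M6 axonal CS+ response and, if above threshold,
    depresses the CS+-active KC→M6 weights.  ``blocks`` maps a blockable
    element (``PAM_gamma5_DAN``, ``PPL1_DAN``, ``M4M6_output``) to its
    active time window in seconds.  The test event scores the model PI.

    Returns the trajectory: one record per trial/test with the phase,
    responses to both odors, the γ5 DAN drive, and the running PI.
    """
    if cs_plus is None or cs_minus is None:
        gen_plus, gen_minus = make_odor_pair(state.n_kc, rng=seed)
        cs_plus = cs_plus or gen_plus
        cs_minus = cs_minus or gen_minus
    blocks = dict(blocks or {})
    unknown = set(blocks) - set(BLOCKABLE)
    if unknown:
        raise ValueError(f"unknown block targets: {sorted(unknown)}")

    shocks = [e for e in protocol.events if e.label.startswith("shock")]

    def blocked(name: str, event: TimelineEvent) -> bool:
        return name in blocks and _window_overlaps(event, blocks[name])

    state = state.copy()
    trajectory: list[dict[str, object]] = []

    def record(phase: str, dan_drive: float | None = None) -> None:
        trajectory.append({
            "phase": phase,
            "response_cs_plus": respond(state, cs_plus),
            "response_cs_minus": respond(state, cs_minus),
            "dan_gamma5_drive": dan_drive,
            "pi_model": model_performance_index(state, cs_plus, cs_minus),
        })

    record("naive")
    for event in protocol.events:
        if event.label.startswith("odor_CS+"):
            has_shock = any(_window_overlaps(s, (event.onset_s,
                                                 event.onset_s + event.duration_s))
                            for s in shocks)
            if has_shock:
                if not blocked("PPL1_DAN", event):
                    state = apply_plasticity(state, cs_plus, _TRAIN_TARGETS,
                                             rate=state.eta_train)
                record(event.label.split(":", 1)[1])
            else:
                resp = respond(state, cs_plus)
                drive = 0.0 if blocked("M4M6_output", event) else resp.dan_gamma5
                if drive >= state.dan_threshold and not blocked("PAM_gamma5_DAN", event):
                    state = apply_plasticity(state, cs_plus, ["gamma5"],
                                             rate=state.eta_extinction)
                record(event.label.split(":", 1)[1], dan_drive=drive)
        elif event.label.startswith("odor_CS-") and "reexposure" in event.label:
            resp = respond(state, cs_minus)
            drive = 0.0 if blocked("M4M6_output", event) else resp.dan_gamma5
            if drive >= state.dan_threshold and not blocked("PAM_gamma5_DAN", event):
                state = apply_plasticity(state, cs_minus, ["gamma5"],
                                         rate=state.eta_extinction)
            record(event.label.split(":", 1)[1], dan_drive=drive)
        elif event.label == "test":
            record("test")

    return {
        "trajectory": trajectory,
        "final_state": state,
        "pi_model": trajectory[-1]["pi_model"],
        "cs_plus": cs_plus,
        "cs_minus": cs_minus,
    }
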