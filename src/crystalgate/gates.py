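"""Crystallization-as-logic readout.

pCa and pH traces are thresholded into Boolean traces (crystallization
active / inactive) and combined through standard two-input gates or
arbitrary gate circuits (DAGs), modeling chained crystallizer units.

Polarity convention: pCa falls as free Ca²⁺ (and acidity) rise, so the
crystallization-active encoding defaults to ``below`` for both pCa and
pH — the signal is 1 when the solution is more acidic than the
threshold.  Both polarities are exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .signals import TimeSeries

__all__ = [
    "BooleanTrace",
    "GateSpec",
    "CircuitNode",
    "CircuitSpec",
    "GATES",
    "threshold_encode",
    "eval_gate",
    "crystallization_logic",
    "eval_circuit",
    "align_traces",
    "cumulative_output",
]

Polarity = Literal["above", "below"]

#: Truth functions for the supported gates, on integer 0/1 arrays.
GATES = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "XOR": lambda a, b: a ^ b,
    "NAND": lambda a, b: 1 - (a & b),
    "NOR": lambda a, b: 1 - (a | b),
    "XNOR": lambda a, b: 1 - (a ^ b),
    "NOT": lambda a: 1 - a,
}
_UNARY = {"NOT"}


@dataclass(frozen=True)
class BooleanTrace:
    """A thresholded 0/1 signal on a strictly increasing time grid."""

    timestamps: np.ndarray
    bits: np.ndarray
    source: str = ""
    threshold: float = float("nan")
    polarity: str = "above"

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        b = np.asarray(self.bits, dtype=np.uint8)
        if t.size != b.size or t.size == 0:
            raise ValueError("timestamps and bits must be non-empty, same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all((b == 0) | (b == 1)):
            raise ValueError("bits must be 0 or 1")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "bits", b)

    def __len__(self) -> int:
        return int(self.bits.size)


@dataclass(frozen=True)
class GateSpec:
    gate: str
    arity: int = 2

    def __post_init__(self) -> None:
        g = self.gate.upper()
        if g not in GATES:
            raise ValueError(f"unknown gate {self.gate!r}")
        object.__setattr__(self, "gate", g)
        expected = 1 if g in _UNARY else 2
        if self.arity != expected:
            raise ValueError(f"{g} requires arity {expected}")


@dataclass(frozen=True)
class CircuitNode:
    id: str
    gate: str
    inputs: tuple[str, ...]


@dataclass(frozen=True)
class CircuitSpec:
    """A DAG of gate nodes with named external inputs and one output."""

    nodes: tuple[CircuitNode, ...]
    inputs: tuple[str, ...]
    output: str

    @classmethod
    def from_dict(cls, d: Mapping) -> "CircuitSpec":
        nodes = tuple(
            CircuitNode(n["id"], n["gate"].upper(), tuple(n["in"]))
            for n in d["nodes"]
        )
        inputs = tuple(d.get("inputs") or sorted(
            {i for n in nodes for i in n.inputs} - {n.id for n in nodes}))
        return cls(nodes=nodes, inputs=inputs, output=d["output"])

    @classmethod
    def from_json(cls, path_or_str) -> "CircuitSpec":
        try:
            text = path_or_str.read_text()          # pathlib.Path
        except AttributeError:
            text = path_or_str
        return cls.from_dict(json.loads(text))


def threshold_encode(
    series: TimeSeries,
    threshold: float,
    polarity: Polarity = "above",
) -> BooleanTrace:
    """Encode a signal as 1 where it is strictly beyond the threshold.

    ``polarity="above"``: bit = 1 iff value > θ; ``"below"``: bit = 1
    iff value < θ.  Equality maps to 0 in both polarities.
    """
    if polarity not in ("above", "below"):
        raise ValueError("polarity must be 'above' or 'below'")
    v = series.values
    bits = (v > threshold) if polarity == "above" else (v < threshold)
    return BooleanTrace(
        series.timestamps, bits.astype(np.uint8),
        source=series.channel_label, threshold=float(threshold),
        polarity=polarity,
    )


def schmitt_encode(
    series: TimeSeries,
    low: float,
    high: float,
    polarity: Polarity = "above",
    initial: int = 0,
) -> BooleanTrace:
    """Two-threshold (Schmitt trigger) encoding for noisy traces.

    For polarity ``above`` the output switches to 1 when the value
    exceeds ``high`` and back to 0 when it drops below ``low``; states
    persist inside the hysteresis band.  ``below`` mirrors the rule.
    """
    if not low < high:
        raise ValueError("require low < high")
    v = series.values if polarity == "above" else -series.values
    lo, hi = (low, high) if polarity == "above" else (-high, -low)
    bits = np.empty(v.size, dtype=np.uint8)
    state = 1 if initial else 0
    for k, x in enumerate(v):
        if x > hi:
            state = 1
        elif x < lo:
            state = 0
        bits[k] = state
    return BooleanTrace(series.timestamps, bits,
                        source=series.channel_label,
                        threshold=float(high), polarity=polarity)


def eval_gate(gate: GateSpec | str, a, b=None):
    """Apply a gate to scalar bits or aligned bit arrays."""
    name = gate.gate if isinstance(gate, GateSpec) else str(gate).upper()
    if name not in GATES:
        raise ValueError(f"unknown gate {name!r}")
    a_arr = np.asarray(a, dtype=np.int64)
    if name in _UNARY:
        if b is not None:
            raise ValueError(f"{name} takes a single operand")
        out = GATES[name](a_arr)
    else:
        if b is None:
            raise ValueError(f"{name} requires two operands")
        out = GATES[name](a_arr, np.asarray(b, dtype=np.int64))
    if np.isscalar(a) or a_arr.ndim == 0:
        return int(out)
    return out.astype(np.uint8)


def align_traces(*traces: BooleanTrace) -> list[BooleanTrace]:
    """Resample traces onto the coarsest grid by previous-value hold.

    The common grid is the grid of the trace with the largest mean time
    step, restricted to the overlap of all time ranges.  Each other
    trace is sampled at those times with zero-order hold.
    """
    if not traces:
        raise ValueError("no traces to align")
    t0 = max(tr.timestamps[0] for tr in traces)
    t1 = min(tr.timestamps[-1] for tr in traces)
    if t0 > t1:
        raise ValueError("trace time ranges do not overlap")
    coarsest = max(
        traces,
        key=lambda tr: (np.mean(np.diff(tr.timestamps))
                        if len(tr) > 1 else np.inf),
    )
    grid = coarsest.timestamps
    grid = grid[(grid >= t0) & (grid <= t1)]
    if grid.size == 0:
        raise ValueError("no common samples after alignment")
    out = []
    for tr in traces:
        idx = np.searchsorted(tr.timestamps, grid, side="right") - 1
        idx = np.clip(idx, 0, len(tr) - 1)
        out.append(BooleanTrace(grid, tr.bits[idx], source=tr.source,
                                threshold=tr.threshold, polarity=tr.polarity))
    return out


def crystallization_logic(
    pca: TimeSeries,
    ph: TimeSeries,
    theta_pca: float,
    theta_ph: float,
    gate: GateSpec | str = "AND",
    pca_polarity: Polarity = "below",
    ph_polarity: Polarity = "below",
) -> BooleanTrace:
    """Pointwise gate evaluation of thresholded pCa and pH channels.

    Defaults encode "more acidic / more Ca²⁺ than threshold" as 1 on
    both channels (polarity ``below``, since both p-scales fall as the
    activity rises).
    """
    a = threshold_encode(pca, theta_pca, polarity=pca_polarity)
    b = threshold_encode(ph, theta_ph, polarity=ph_polarity)
    a, b = align_traces(a, b)
    name = gate.gate if isinstance(gate, GateSpec) else str(gate).upper()
    bits = eval_gate(name, a.bits, b.bits)
    return BooleanTrace(a.timestamps, bits, source=f"{name}(pCa,pH)")


def eval_circuit(
    circuit: CircuitSpec,
    inputs: Mapping[str, BooleanTrace],
) -> BooleanTrace:
    """Evaluate a gate DAG pointwise over aligned input traces.

    Nodes are evaluated in topological order, so declaration order in
    the spec does not matter.  Raises on cycles and unresolved inputs.
    """
    import networkx as nx

    missing = set(circuit.inputs) - set(inputs)
    if missing:
        raise ValueError(f"missing circuit inputs: {sorted(missing)}")
    node_by_id = {n.id: n for n in circuit.nodes}
    if len(node_by_id) != len(circuit.nodes):
        raise ValueError("duplicate node ids")
    known = set(node_by_id) | set(circuit.inputs)
    for n in circuit.nodes:
        unresolved = set(n.inputs) - known
        if unresolved:
            raise ValueError(
                f"node {n.id!r} references unknown inputs {sorted(unresolved)}")
    if circuit.output not in known:
        raise ValueError(f"output {circuit.output!r} is not a node or input")

    g = nx.DiGraph()
    g.add_nodes_from(node_by_id)
    for n in circuit.nodes:
        for src in n.inputs:
            if src in node_by_id:
                g.add_edge(src, n.id)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        raise ValueError("circuit contains a cycle") from None

    aligned = align_traces(*(inputs[name] for name in circuit.inputs))
    values: dict[str, np.ndarray] = {
        name: tr.bits for name, tr in zip(circuit.inputs, aligned)
    }
    grid = aligned[0].timestamps
    for nid in order:
        node = node_by_id[nid]
        ops = [values[s] for s in node.inputs]
        spec = GateSpec(node.gate, arity=1 if node.gate in _UNARY else 2)
        values[nid] = eval_gate(spec, *ops)
    return BooleanTrace(grid, values[circuit.output],
                        source=f"circuit:{circuit.output}")


def cumulative_output(trace: BooleanTrace) -> TimeSeries:
    """Integrated gate output — a proxy for accumulated mineral mass.

    Returns the running time-integral of the 0/1 trace (bit value held
    over each sampling interval), in bit·seconds.
    """
    t = trace.timestamps
    if len(trace) == 1:
        return TimeSeries(t, np.zeros(1), channel_label="cumulative")
    hold = trace.bits[:-1].astype(float) * np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(hold)])
    return TimeSeries(t, cum, channel_label="cumulative", units="bit*s")
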