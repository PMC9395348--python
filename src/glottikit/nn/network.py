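"""A minimal DAG of named ops with reverse-mode differentiation.

Nodes are added in topological order (inputs must already exist).  A forward
pass produces a :class:`Tape` holding every activation and op cache, which
the backward pass consumes to return gradients *with respect to node
outputs* — this is what Seg-Grad-CAM needs, beyond plain parameter grads.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .ops import Op, Param

INPUT = "input"


@dataclass
class _Node:
    name: str
    op: Op
    inputs: tuple[str, ...]


@dataclass
class Tape:
    """Activations and caches from one forward pass."""

    acts: dict[str, np.ndarray]
    caches: dict[str, object] = field(default_factory=dict)
    train: bool = False

    def __getitem__(self, name: str) -> np.ndarray:
        return self.acts[name]


class Network:
    """Ordered collection of named ops forming a single-input DAG."""

    def __init__(self):
        self._nodes: list[_Node] = []
        self._by_name: dict[str, _Node] = {}

    # -- construction -----------------------------------------------------
    def add(self, name: str, op: Op, *inputs: str) -> str:
        if name == INPUT or name in self._by_name:
            raise ValueError(f"duplicate or reserved node name {name!r}")
        inputs = inputs or ((self._nodes[-1].name,) if self._nodes else (INPUT,))
        for src in inputs:
            if src != INPUT and src not in self._by_name:
                raise ValueError(f"unknown input node {src!r} for {name!r}")
        node = _Node(name, op, tuple(inputs))
        self._nodes.append(node)
        self._by_name[name] = node
        return name

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self._nodes]

    @property
    def output_name(self) -> str:
        return self._nodes[-1].name

    def params(self) -> list[Param]:
        out: list[Param] = []
        for node in self._nodes:
            out.extend(node.op.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- execution --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> Tape:
        tape = Tape(acts={INPUT: np.asarray(x, dtype=np.float32)}, train=train)
        for node in self._nodes:
            ins = [tape.acts[s] for s in node.inputs]
            y, cache = node.op.forward(*ins, train=train)
            tape.acts[node.name] = y
            tape.caches[node.name] = cache
        return tape

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train).acts[self.output_name]

    def descendants(self, name: str) -> set[str]:
        """Names of nodes that (transitively) consume ``name``."""
        out: set[str] = set()
        for node in self._nodes:
            if any(s == name or s in out for s in node.inputs):
                out.add(node.name)
        return out

    def forward_from(self, substitutions: dict[str, np.ndarray],
                     tape: Tape | None = None, train: bool = False) -> Tape:
        """Re-run the graph with some node outputs overridden.

        Nodes not downstream of any substituted node reuse activations from
        ``tape``; if ``tape`` is None, such nodes must not be required.
        """
        dirty: set[str] = set()
        for name in substitutions:
            dirty |= self.descendants(name)
        acts = dict(tape.acts) if tape is not None else {}
        acts.update({k: np.asarray(v, dtype=np.float32)
                     for k, v in substitutions.items()})
        new = Tape(acts=acts, train=train)
        for node in self._nodes:
            if node.name in substitutions or node.name not in dirty:
                continue
            missing = [s for s in node.inputs if s not in new.acts]
            if missing:
                raise ValueError(
                    f"node {node.name!r} needs activations {missing}; "
                    "provide a tape from a full forward pass")
            ins = [new.acts[s] for s in node.inputs]
            y, cache = node.op.forward(*ins, train=train)
            new.acts[node.name] = y
            new.caches[node.name] = cache
        return new

    def backward(self, tape: Tape, d_output: np.ndarray,
                 output: str | None = None) -> dict[str, np.ndarray]:
        """Accumulate parameter grads; return grads w.r.t. node outputs."""
        output = output or self.output_name
        start = next(i for i, n in enumerate(self._nodes) if n.name == output)
        pending: dict[str, np.ndarray] = {output: np.asarray(d_output,
                                                            dtype=np.float32)}
        out_grads: dict[str, np.ndarray] = {}
        for node in reversed(self._nodes[: start + 1]):
            dy = pending.pop(node.name, None)
            if dy is None:
                continue
            out_grads[node.name] = dy
            dxs = node.op.backward(dy, tape.caches[node.name])
            for src, dx in zip(node.inputs, dxs):
                if src in pending:
                    pending[src] = pending[src] + dx
                else:
                    pending[src] = dx
        if INPUT in pending:
            out_grads[INPUT] = pending[INPUT]
        return out_grads

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for node in self._nodes:
            op = node.op
            for i, p in enumerate(op.params()):
                state[f"{node.name}.p{i}"] = p.data.copy()
            for attr in ("running_mean", "running_var"):
                if hasattr(op, attr):
                    state[f"{node.name}.{attr}"] = getattr(op, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for node in self._nodes:
            op = node.op
            for i, p in enumerate(op.params()):
                p.data[...] = state[f"{node.name}.p{i}"]
            for attr in ("running_mean", "running_var"):
                if hasattr(op, attr):
                    getattr(op, attr)[...] = state[f"{node.name}.{attr}"]

    def save(self, path, meta: dict | None = None) -> None:
        """Write all weights (and optional JSON metadata) to one .npz file."""
        state = self.state_dict()
        if meta is not None:
            state["__meta__"] = np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **state)

    def load(self, path) -> dict | None:
        with np.load(path) as data:
            state = {k: data[k] for k in data.files if k != "__meta__"}
            meta = None
            if "__meta__" in data.files:
                meta = json.loads(bytes(data["__meta__"]).decode())
        self.load_state_dict(state)
        return meta

    def serialized_size(self) -> int:
        """Size in bytes of the single-file serialization."""
        buf = io.BytesIO()
        self.save(buf)
        return buf.getbuffer().nbytes
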