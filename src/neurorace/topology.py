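"""Directed "rich get richer" connectivity for a cell assembly.

The assembly is a directed weighted graph in which every neuron sends exactly
``k_out`` excitatory synapses to distinct other neurons.  Targets are drawn by
preferential attachment — the probability of receiving a new synapse grows
with the number already received — which produces a heavy-tailed, Zipf-like
in-degree distribution: a few hub neurons collect far more than ``k_out``
incoming synapses while most collect fewer.  Such assemblies ignite with less
external activation than uniformly wired ones, which is the property the
downstream simulator exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CATopology",
    "generate_topology",
    "in_degree_distribution",
    "zipf_rank_slope",
    "save_topology",
    "load_topology",
    "DEFAULT_WEIGHT",
]

# Uniform synaptic efficacy (nA per presynaptic spike) used when none is
# given: the package-wide calibrated value (see lif.calibrate_weight).
DEFAULT_WEIGHT = 0.30


@dataclass(frozen=True)
class CATopology:
    """Cell-assembly connectivity.

    Attributes
    ----------
    n_neurons
        Number of neurons in the assembly.
    k_out
        Outgoing synapses per neuron (identical for every neuron).
    pre, post
        Parallel integer arrays of length ``n_neurons * k_out``: the i-th
        synapse runs from neuron ``pre[i]`` to neuron ``post[i]``.
    weight
        Uniform synaptic efficacy: current increment in nA delivered to the
        postsynaptic neuron per presynaptic spike.
    seed
        RNG seed the generator used; identical seed reproduces the graph.
    """

    n_neurons: int
    k_out: int
    pre: np.ndarray = field(repr=False)
    post: np.ndarray = field(repr=False)
    weight: float = DEFAULT_WEIGHT
    seed: int = 0

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=np.int64)
        post = np.asarray(self.post, dtype=np.int64)
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if not (1 <= self.k_out <= self.n_neurons - 1):
            raise ValueError("k_out must be in [1, n_neurons - 1]")
        if self.weight <= 0:
            raise ValueError("weights must be strictly positive (excitatory assembly)")
        if pre.shape != post.shape or pre.ndim != 1:
            raise ValueError("pre/post must be parallel 1-d arrays")
        if len(pre) != self.n_neurons * self.k_out:
            raise ValueError(
                f"edge count {len(pre)} != n_neurons * k_out = {self.n_neurons * self.k_out}"
            )
        if np.any(pre == post):
            raise ValueError("self-edges are not allowed")
        if np.any((pre < 0) | (pre >= self.n_neurons) | (post < 0) | (post >= self.n_neurons)):
            raise ValueError("neuron ids out of range")
        pairs = pre * self.n_neurons + post
        if len(np.unique(pairs)) != len(pairs):
            raise ValueError("duplicate (pre, post) synapses are not allowed")
        out_deg = np.bincount(pre, minlength=self.n_neurons)
        if np.any(out_deg != self.k_out):
            raise ValueError("every neuron must have out-degree exactly k_out")

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def in_degrees(self) -> np.ndarray:
        """In-degree of every neuron (length ``n_neurons``)."""
        return np.bincount(self.post, minlength=self.n_neurons)

    def targets_matrix(self) -> np.ndarray:
        """Postsynaptic targets as an ``(n_neurons, k_out)`` int array.

        Row i lists the targets of neuron i; valid because out-degree is
        exactly ``k_out`` everywhere.  This is the layout the simulator uses.
        """
        order = np.argsort(self.pre, kind="stable")
        return self.post[order].reshape(self.n_neurons, self.k_out)


def generate_topology(
    n_neurons: int = 500,
    k_out: int = 30,
    weight: float = DEFAULT_WEIGHT,
    seed: int = 0,
) -> CATopology:
    """Grow a rich-get-richer directed graph with exact out-degree ``k_out``.

    Neurons emit their ``k_out`` synapses one neuron at a time, in a seeded
    random order.  Each target is drawn with probability proportional to its
    current in-degree plus one; self-edges and duplicate (pre, post) pairs
    are rejected and redrawn.  The +1 baseline keeps isolated neurons
    reachable while still letting early recipients snowball, which yields the
    heavy-tailed in-degree profile characteristic of preferential attachment.

    Parameters
    ----------
    n_neurons, k_out
        Assembly size and synapses leaving each neuron (assembly defaults:
        500 neurons, 30 outgoing synapses).
    weight
        Uniform synaptic efficacy in nA stored on every edge.
    seed
        Seed for the generator; the same seed reproduces the edge list
        byte-for-byte.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if not (1 <= k_out <= n_neurons - 1):
        raise ValueError(
            f"k_out={k_out} must be between 1 and n_neurons-1={n_neurons - 1}: "
            "cannot place that many distinct non-self targets"
        )
    rng = np.random.default_rng(seed)
    emit_order = rng.permutation(n_neurons)
    in_deg = np.zeros(n_neurons, dtype=np.int64)
    pre = np.empty(n_neurons * k_out, dtype=np.int64)
    post = np.empty(n_neurons * k_out, dtype=np.int64)
    e = 0
    for src in emit_order:
        chosen: set[int] = set()
        # attachment probability ∝ in-degree + 1, frozen at this neuron's turn
        prob = (in_deg + 1.0) / (in_deg.sum() + n_neurons)
        while len(chosen) < k_out:
            draws = rng.choice(n_neurons, size=k_out - len(chosen), p=prob)
            for tgt in draws:
                if tgt != src and tgt not in chosen:
                    chosen.add(int(tgt))
        for tgt in sorted(chosen):
            pre[e] = src
            post[e] = tgt
            e += 1
        in_deg[list(chosen)] += 1
    return CATopology(n_neurons=n_neurons, k_out=k_out, pre=pre, post=post, weight=weight, seed=seed)


def in_degree_distribution(topology: CATopology) -> dict[int, int]:
    """Histogram mapping in-degree -> number of neurons with that in-degree.

    Sums to ``n_neurons``; the degree-weighted sum equals the edge count
    (handshake lemma), so the mean in-degree is exactly ``k_out``.
    """
    deg = topology.in_degrees()
    values, counts = np.unique(deg, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}


def zipf_rank_slope(topology: CATopology | np.ndarray) -> tuple[float, bool]:
    """Least-squares slope of log(in-degree) vs log(rank), top half of ranks.

    Neurons are ranked by decreasing in-degree; a Zipf-like tail shows up as
    an approximately linear log-log relation with negative slope (slope -1
    for an exact Zipf law d_r = C/r).  Only the top half is fitted because
    the low-degree tail of a finite preferential-attachment graph bends away
    from the power law.  Accepts either a topology or a bare in-degree
    sequence.

    Returns
    -------
    (slope, degenerate)
        ``degenerate`` is True when all in-degrees are equal (regular graph),
        in which case the slope is reported as 0.0.
    """
    degrees = (
        topology.in_degrees() if isinstance(topology, CATopology) else np.asarray(topology)
    )
    if len(degrees) < 50:
        raise ValueError("rank-slope fit needs at least 50 neurons")
    deg = np.sort(degrees)[::-1].astype(float)
    if deg.min() == deg.max():
        return 0.0, True
    top = deg[: len(deg) // 2]
    top = top[top > 0]
    ranks = np.arange(1, len(top) + 1, dtype=float)
    slope = float(np.polyfit(np.log(ranks), np.log(top), 1)[0])
    return slope, False


def save_topology(topology: CATopology, csv_path: str | Path) -> None:
    """Write the edge list as ``pre,post,weight`` CSV with a JSON sidecar."""
    csv_path = Path(csv_path)
    with open(csv_path, "w") as fh:
        fh.write("pre,post,weight\n")
        for p, q in zip(topology.pre, topology.post):
            fh.write(f"{p},{q},{topology.weight}\n")
    meta = {"n_neurons": topology.n_neurons, "k_out": topology.k_out, "seed": topology.seed}
    csv_path.with_suffix(".json").write_text(json.dumps(meta))


def load_topology(csv_path: str | Path) -> CATopology:
    """Read an edge-list CSV + JSON sidecar; invariants are re-validated."""
    csv_path = Path(csv_path)
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return CATopology(
        n_neurons=int(meta["n_neurons"]),
        k_out=int(meta["k_out"]),
        pre=data[:, 0].astype(np.int64),
        post=data[:, 1].astype(np.int64),
        weight=float(data[0, 2]),
        seed=int(meta["seed"]),
    )
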