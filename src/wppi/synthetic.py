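"""Seeded synthetic PPI networks with planted complexes and matching expression.

The generator emulates the statistical structure the detection method
assumes: protein complexes are dense subgraphs whose members co-express.

* Topology: disjoint planted complexes with sizes uniform in ``size_range``;
  within-complex edges appear independently with probability ``p_in``, every
  other node pair with ``p_out``.  Each planted complex is redrawn (up to a
  rejection cap) until its induced subgraph is connected with hop diameter
  at most 2, so that perfect recovery under the default detection
  constraints is attainable.
* Expression: each complex carries a latent periodic profile — a sinusoid
  completing 3 cycles over the ``T`` time points with a random phase,
  standardized to unit variance, mimicking a metabolic-cycle time course.
  A member profile is ``sqrt(rho) * latent + sqrt(1 - rho) * noise`` plus
  additive observation noise of standard deviation ``noise_sd``; background
  nodes get independent profiles.  With unit-variance latent and
  idiosyncratic terms, the expected within-complex correlation is
  ``rho / (1 + noise_sd^2)``.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import ComplexSet

__all__ = ["SynthConfig", "generate", "perturb"]

_REJECTION_CAP = 1000


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic draw.

    ``T`` defaults to 36 points (three cycles of twelve), the shape of the
    classic yeast metabolic-cycle expression series.
    """

    n_complexes: int = 20
    size_range: tuple[int, int] = (4, 8)
    p_in: float = 0.95
    p_out: float = 0.005
    n_background_nodes: int = 40
    T: int = 36
    rho: float = 0.8
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ParameterError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if self.size_range[0] < 3 or self.size_range[1] < self.size_range[0]:
            raise ParameterError(f"invalid size_range {self.size_range} (min >= 3)")
        if not (0.0 <= self.rho <= 1.0):
            raise ParameterError(f"rho must be in [0, 1], got {self.rho}")
        if self.T < 2:
            raise ParameterError(f"need at least 2 time points, got T={self.T}")
        if self.n_complexes < 1:
            raise ParameterError("need at least one planted complex")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def _draw_complex_edges(
    rng: np.random.Generator, members: list[str], p_in: float
) -> list[tuple[str, str]]:
    """Within-complex Bernoulli(p_in) edges, redrawn until connected with diameter <= 2."""
    pairs = list(itertools.combinations(members, 2))
    for _ in range(_REJECTION_CAP):
        mask = rng.random(len(pairs)) < p_in
        edges = [e for e, keep in zip(pairs, mask) if keep]
        sub = nx.Graph()
        sub.add_nodes_from(members)
        sub.add_edges_from(edges)
        if nx.is_connected(sub) and nx.diameter(sub) <= 2:
            return edges
    raise ValidationError(
        f"could not draw a connected diameter<=2 complex of size {len(members)} "
        f"at p_in={p_in} within {_REJECTION_CAP} attempts"
    )


def generate(config: SynthConfig) -> tuple[nx.Graph, pd.DataFrame, ComplexSet]:
    """Draw (network, expression matrix, ground-truth complex set) from config."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    total_nodes = int(sizes.sum()) + config.n_background_nodes
    width = len(str(total_nodes - 1))
    names = [f"P{i:0{width}d}" for i in range(total_nodes)]

    complexes: list[frozenset[str]] = []
    cursor = 0
    g = nx.Graph()
    g.add_nodes_from(names)
    for size in sizes:
        members = names[cursor : cursor + int(size)]
        cursor += int(size)
        complexes.append(frozenset(members))
        g.add_edges_from(_draw_complex_edges(rng, members, config.p_in))

    member_of = {}
    for k, c in enumerate(complexes):
        for v in c:
            member_of[v] = k
    # background noise edges over every pair not inside a single complex
    if config.p_out > 0:
        for u, v in itertools.combinations(names, 2):
            if member_of.get(u, -1) == member_of.get(v, -2):
                continue
            if rng.random() < config.p_out:
                g.add_edge(u, v)

    # expression: shared latent sinusoid per complex + idiosyncratic noise
    tgrid = np.arange(config.T)
    profiles = np.empty((total_nodes, config.T))
    sqrt_rho = math.sqrt(config.rho)
    sqrt_com = math.sqrt(1.0 - config.rho)
    latents = []
    for _ in range(config.n_complexes):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        lat = np.sin(2.0 * math.pi * 3.0 * tgrid / config.T + phase)
        latents.append(lat * math.sqrt(2.0))  # unit variance
    for i, name in enumerate(names):
        k = member_of.get(name)
        if k is None:
            base = rng.standard_normal(config.T)
        else:
            base = sqrt_rho * latents[k] + sqrt_com * rng.standard_normal(config.T)
        profiles[i] = base + config.noise_sd * rng.standard_normal(config.T)

    expr = pd.DataFrame(profiles, index=names, columns=[f"t{i}" for i in range(config.T)])
    truth = ComplexSet(complexes=complexes, label="truth")
    return g, expr, truth


def perturb(g: nx.Graph, add_frac: float, remove_frac: float, seed: int) -> nx.Graph:
    """Random edge noise: remove then add fractions of the original edge count.

    Removes ``round(remove_frac * |E|)`` edges uniformly at random and adds
    ``round(add_frac * |E|)`` uniformly chosen non-edges of the input graph,
    so the result has exactly ``|E| - round(remove_frac |E|) + round(add_frac |E|)``
    edges.  The node set is unchanged.
    """
    if not (0.0 <= add_frac < 1.0) or not (0.0 <= remove_frac < 1.0):
        raise ParameterError("add_frac and remove_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    n_edges = len(edges)
    n_remove = round(remove_frac * n_edges)
    n_add = round(add_frac * n_edges)

    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    keep_idx = set(rng.choice(n_edges, size=n_edges - n_remove, replace=False)) if n_edges else set()
    out.add_edges_from(edges[i] for i in keep_idx)

    if n_add:
        nodes = sorted(g.nodes())
        present = set(edges)
        non_edges = [
            (u, v) for u, v in itertools.combinations(nodes, 2) if (u, v) not in present
        ]
        if n_add > len(non_edges):
            raise ValidationError("not enough non-edges to add the requested fraction")
        pick = rng.choice(len(non_edges), size=n_add, replace=False)
        out.add_edges_from(non_edges[i] for i in pick)
    return out
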