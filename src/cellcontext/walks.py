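"""Random walks on the context graph and cumulative path weights.

Walks start at a molecule node and take up to ``L - 1`` steps (a path visits
at most ``L`` nodes, the seed included).  The transition distribution over
the current node's neighbors is degree-based by default — p(next = u) is
proportional to degree(u) — with edge-weight-proportional and uniform modes
available.  The cumulative weight alpha of a visited node is the product of
edge weights along the path from the seed, so alpha is non-increasing and
quantifies how related the node is to the seed molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .context_graph import ContextGraph, NodeKind

__all__ = ["WalkConfig", "WalkPath", "transition_distribution", "sample_walk",
           "cumulative_weights", "walk_rng", "export_walks"]

TRANSITION_MODES = ("degree", "edge_weight", "uniform")


@dataclass
class WalkConfig:
    L: int = 4
    seed: int = 0
    transition_mode: str = "degree"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("walk length L must be >= 1")
        if self.transition_mode not in TRANSITION_MODES:
            raise ValueError(f"unknown transition mode {self.transition_mode!r}")


@dataclass
class WalkPath:
    """Ordered walk: the seed molecule followed by (node, incoming weight) steps."""

    start: str
    steps: list[tuple[str, float]] = field(default_factory=list)  # excludes start
    alphas: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def nodes(self) -> list[str]:
        return [self.start] + [nid for nid, _ in self.steps]

    def __len__(self) -> int:
        return 1 + len(self.steps)

    def targets(self) -> list[tuple[str, float]]:
        """(node_id, alpha) pairs, the seed itself included with alpha = 1."""
        return [(self.start, 1.0)] + [
            (nid, float(a)) for (nid, _), a in zip(self.steps, self.alphas)
        ]


def transition_distribution(
    graph: ContextGraph, current: str, mode: str = "degree"
) -> tuple[list[str], np.ndarray]:
    """Neighbor ids (sorted for determinism) and their transition probabilities.

    An isolated node yields an empty distribution; the walk terminates there.
    """
    if current not in graph:
        raise KeyError(f"node {current!r} not in graph")
    if mode not in TRANSITION_MODES:
        raise ValueError(f"unknown transition mode {mode!r}")
    neighbors = graph.neighbors(current)
    if not neighbors:
        return [], np.array([])
    if mode == "degree":
        raw = np.array([graph.degree(u) for u in neighbors], dtype=float)
    elif mode == "edge_weight":
        raw = np.array([graph.edge_weight(current, u) for u in neighbors], dtype=float)
    else:
        raw = np.ones(len(neighbors))
    return neighbors, raw / raw.sum()


def sample_walk(
    graph: ContextGraph,
    start: str,
    config: WalkConfig,
    rng: np.random.Generator | None = None,
) -> WalkPath:
    """Sample one random walk of at most ``config.L`` nodes from a molecule.

    Revisits are allowed (no self-avoidance or backtrack ban); a revisited
    node simply contributes another (target, alpha) pair.
    """
    if graph.kind(start) != NodeKind.MOLECULE:
        raise ValueError(f"walk must start at a molecule node, got {start!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    steps: list[tuple[str, float]] = []
    current = start
    for _ in range(config.L - 1):
        neighbors, probs = transition_distribution(graph, current, config.transition_mode)
        if not neighbors:
            break
        nxt = neighbors[rng.choice(len(neighbors), p=probs)]
        steps.append((nxt, graph.edge_weight(current, nxt)))
        current = nxt
    weights = [w for _, w in steps]
    return WalkPath(start=start, steps=steps, alphas=cumulative_weights(weights))


def cumulative_weights(weights: Iterable[float]) -> np.ndarray:
    """alpha_i = prod_{j <= i} w_j (exact left-fold product, no clamping)."""
    w = np.asarray(list(weights), dtype=float)
    if w.size and (np.any(w <= 0) or np.any(w > 1)):
        bad = w[(w <= 0) | (w > 1)]
        raise ValueError(f"edge weights outside (0, 1]: {bad[:5]}")
    return np.cumprod(w) if w.size else np.array([])


def walk_rng(run_seed: int, molecule_index: int, epoch: int) -> np.random.Generator:
    """Per-walk generator derived from (run seed, molecule index, epoch).

    Keeps walks reproducible under data shuffling: the same triple always
    yields the same walk regardless of batch composition.
    """
    return np.random.default_rng(np.random.SeedSequence([run_seed, molecule_index, epoch]))


def export_walks(paths: Iterable[WalkPath], out_path: str | Path) -> pd.DataFrame:
    """TSV export (start, step_index, node_id, w, alpha) for inspection."""
    rows = []
    for path in paths:
        rows.append({"start": path.start, "step_index": 0, "node_id": path.start,
                     "w": "", "alpha": 1.0})
        for i, ((nid, w), a) in enumerate(zip(path.steps, path.alphas), start=1):
            rows.append({"start": path.start, "step_index": i, "node_id": nid,
                         "w": w, "alpha": float(a)})
    frame = pd.DataFrame(rows, columns=["start", "step_index", "node_id", "w", "alpha"])
    frame.to_csv(out_path, sep="\t", index=False)
    return frame
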