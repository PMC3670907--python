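"""Two-choice lattice walk: a tiny discrete analogue of Monte Carlo
connection-probability estimation whose exact answer is computable by
exhaustive path enumeration.

A walker starts at ``(x, y) = (0, 0)``. At each of ``n_steps`` steps it
moves up one row and one column left or right: right with probability
``p_right``, left otherwise. The "connection probability" to a target set
of cells is the probability that the walk visits at least one target cell
(the start cell counts as visited). This mirrors the any-visit hit rule of
the streamline engine while keeping the exact probability enumerable.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

import numpy as np


def _normalise_targets(targets: Iterable[tuple[int, int]]) -> set[tuple[int, int]]:
    tset = {(int(x), int(y)) for x, y in targets}
    if not tset:
        raise ValueError("empty target set")
    return tset


def lattice_connection_probability_exact(
    p_right: float, n_steps: int, targets: Iterable[tuple[int, int]]
) -> float:
    """Exact visit probability by brute-force enumeration of all 2^n paths."""
    if not 0.0 <= p_right <= 1.0:
        raise ValueError("p_right must be in [0, 1]")
    if n_steps < 1 or n_steps > 22:
        raise ValueError("n_steps must be in [1, 22] for exhaustive enumeration")
    tset = _normalise_targets(targets)
    total = 0.0
    for choices in product((0, 1), repeat=n_steps):
        x, y = 0, 0
        visited = (x, y) in tset
        for c in choices:
            x += 1 if c else -1
            y += 1
            if (x, y) in tset:
                visited = True
        if visited:
            n_right = sum(choices)
            total += p_right**n_right * (1.0 - p_right) ** (n_steps - n_right)
    return total


def lattice_connection_probability_mc(
    p_right: float,
    n_steps: int,
    targets: Iterable[tuple[int, int]],
    n_samples: int,
    rng: np.random.Generator | int = 0,
) -> float:
    """Monte Carlo estimate of the same visit probability from
    ``n_samples`` simulated walks."""
    if not 0.0 <= p_right <= 1.0:
        raise ValueError("p_right must be in [0, 1]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    tset = _normalise_targets(targets)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    steps = np.where(rng.random((n_samples, n_steps)) < p_right, 1, -1)
    xs = np.concatenate([np.zeros((n_samples, 1), dtype=int), np.cumsum(steps, axis=1)], axis=1)
    ys = np.arange(n_steps + 1)
    hit = np.zeros(n_samples, dtype=bool)
    for tx, ty in tset:
        if 0 <= ty <= n_steps:
            hit |= xs[:, ty] == tx
    return float(hit.mean())
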