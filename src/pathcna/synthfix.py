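"""Synthetic multi-season metabolite panels with planted pathway modules.

The generator emulates the statistical structure the method exploits:
members of an active pathway co-vary across genotype lines, while
unrelated metabolites do not.  Each planted block has a latent factor per
line; a member's value is ``sqrt(rho) * factor + sqrt(1 - rho) * noise``,
so the expected within-block correlation equals ``rho``
(``within_block_correlation``).  Distractor metabolites are independent
noise.  Seasons share block membership but redraw factors and noise, which
mimics independent harvests of the same biology.

The ``TruthSet`` provides positives and negatives with no metabolite
shared between any two instances.  Positive pathways are disjoint parts
(size >= 2) of randomly partitioned blocks, consuming about half of the
panel; proper subsets of blocks emulate partial pathway coverage, and
unmeasured phantom compounds appended to each compound list push mapped
coverage below 1 and right-skew it.  Negative pathways are random chunks
of the remaining metabolites (block leftovers mixed with distractors),
with sizes drawn from the positive part sizes and each spanning more than
one block.  Zero metabolite reuse matters: when instances share nodes,
node-identity feature values recur between cross-validation folds and the
forest can score above (or below) chance even with no planted signal;
with disjoint instances the no-signal configuration stays at chance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import CorrelationNetwork, ProfileMatrix
from .pathmap import Pathway

__all__ = ["SimulationConfig", "TruthSet", "simulate_panel", "toy5"]


@dataclass
class SimulationConfig:
    n_lines: int = 70
    n_seasons: int = 3
    n_blocks: int = 12
    block_size_min: int = 3
    block_size_max: int = 8
    within_block_correlation: float = 0.8
    n_distractors: int = 30
    season_noise_sd: float = 0.0
    #: parts of a block partition are capped at this size (>= 2)
    max_part_size: int = 4
    #: mean number of phantom (unmeasured) compounds appended per pathway
    phantom_rate: float = 3.0
    #: truth-set instances per class (kept equal so CV folds balance exactly)
    n_instances_per_class: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size_min < 2:
            raise ValueError("block sizes must be >= 2")
        if self.block_size_min > self.block_size_max:
            raise ValueError("invalid block size range")
        if not (0 <= self.within_block_correlation < 1):
            raise ValueError("within_block_correlation must lie in [0, 1)")
        if self.n_lines < 4 or self.n_blocks < 1:
            raise ValueError("need at least 4 lines and 1 block")
        if self.season_noise_sd < 0:
            raise ValueError("season_noise_sd must be >= 0")


@dataclass
class TruthSet:
    positive_pathways: list[Pathway]
    negative_pathways: list[Pathway]
    blocks: list[tuple[str, ...]]

    @property
    def labels(self) -> dict[str, int]:
        out = {p.pathway_id: 1 for p in self.positive_pathways}
        out.update({p.pathway_id: 0 for p in self.negative_pathways})
        return out


def _block_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    return [int(rng.integers(config.block_size_min, config.block_size_max + 1))
            for _ in range(config.n_blocks)]


def simulate_panel(config: SimulationConfig | None = None) -> tuple[list[ProfileMatrix], TruthSet]:
    """Generate per-season profile tables plus ground-truth pathway labels."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    sizes = _block_sizes(config, rng)
    blocks: list[tuple[str, ...]] = []
    met_ids: list[str] = []
    for b, size in enumerate(sizes):
        members = tuple(f"B{b:02d}_M{i}" for i in range(size))
        blocks.append(members)
        met_ids.extend(members)
    distractors = [f"D{i:02d}" for i in range(config.n_distractors)]
    met_ids.extend(distractors)
    lines = [f"IL{i:03d}" for i in range(config.n_lines)]

    rho = config.within_block_correlation
    loading, noise_sd = np.sqrt(rho), np.sqrt(1.0 - rho)
    profiles = []
    for s in range(config.n_seasons):
        data = np.empty((config.n_lines, len(met_ids)))
        col = 0
        for members in blocks:
            factor = rng.standard_normal(config.n_lines)
            for _ in members:
                data[:, col] = loading * factor + noise_sd * rng.standard_normal(config.n_lines)
                col += 1
        for _ in distractors:
            data[:, col] = rng.standard_normal(config.n_lines)
            col += 1
        if config.season_noise_sd > 0:
            data += config.season_noise_sd * rng.standard_normal(data.shape)
        df = pd.DataFrame(data, index=lines, columns=met_ids)
        df.index.name = "line"
        profiles.append(ProfileMatrix(df, season_label=f"season{s + 1}"))

    truth = _truth_set(blocks, met_ids, config, rng)
    return profiles, truth


def _with_phantoms(members: tuple[str, ...], config: SimulationConfig,
                   rng: np.random.Generator, counter: list[int]) -> tuple[str, ...]:
    """Append unmeasured phantom compounds so mapped coverage is < 1."""
    n_phantom = int(rng.poisson(config.phantom_rate))
    phantoms = []
    for _ in range(n_phantom):
        phantoms.append(f"U{counter[0]:04d}")
        counter[0] += 1
    return members + tuple(phantoms)


def _truth_set(blocks: list[tuple[str, ...]], met_ids: list[str],
               config: SimulationConfig, rng: np.random.Generator) -> TruthSet:
    phantom_counter = [0]
    block_of = {m: b for b, block in enumerate(blocks) for m in block}
    n_per_class = config.n_instances_per_class

    # metabolite budget per class: half the panel, so the negative pool
    # (block leftovers + distractors) can mirror the positive sizes
    budget = len(met_ids) // 2

    # positives: disjoint within-block parts; sizes 2..max_part_size drawn
    # under the running budget so exactly n_per_class parts fit
    positives: list[Pathway] = []
    part_sizes: list[int] = []
    used: set[str] = set()
    block_order = iter(rng.permutation(len(blocks)))
    order: list[str] = []
    current_block = -1
    while len(positives) < n_per_class:
        if len(order) < 2:
            try:
                current_block = int(next(block_order))
            except StopIteration:
                raise ValueError(
                    "panel too small for n_instances_per_class; "
                    "increase n_blocks or block sizes") from None
            order = list(rng.permutation(blocks[current_block]))
        parts_left = n_per_class - len(positives)
        slack = (budget - len(used)) - 2 * (parts_left - 1)
        cap = min(config.max_part_size, slack, len(order))
        size = int(rng.integers(2, cap + 1)) if cap > 2 else 2
        part, order = tuple(sorted(order[:size])), order[size:]
        pid = f"BLOCK{current_block:02d}_P{len(positives)}"
        compounds = _with_phantoms(part, config, rng, phantom_counter)
        positives.append(Pathway(pid, pid, "positive_collection", compounds))
        part_sizes.append(len(part))
        used |= set(part)

    # negatives: same number and sizes, chunks of the remaining
    # metabolites (block leftovers and distractors), each spanning >1 block
    remaining = [m for m in met_ids if m not in used]
    negatives: list[Pathway] = []
    for _ in range(1000):
        order = list(rng.permutation(remaining))
        sizes = [int(s) for s in rng.permutation(part_sizes)]
        chunks: list[tuple[str, ...]] = []
        ok = True
        for size in sizes:
            chunk, order = order[:size], order[size:]
            if len(chunk) < size:
                ok = False
                break
            spanned = {block_of.get(m, -1 - i) for i, m in enumerate(chunk)}
            if len(spanned) < 2:
                ok = False
                break
            chunks.append(tuple(sorted(chunk)))
        if ok and len(chunks) == n_per_class:
            for members_t in chunks:
                nid = f"NEG{len(negatives):03d}"
                compounds = _with_phantoms(members_t, config, rng, phantom_counter)
                negatives.append(Pathway(nid, nid, "negative_collection", compounds))
            break
    if not negatives:
        raise RuntimeError("could not draw cross-block negative sets")
    return TruthSet(positives, negatives, blocks)


def toy5() -> CorrelationNetwork:
    """The fixed 5-node micro-fixture used throughout the feature tests.

    Nodes A..E; edges A-B 0.8, A-C 0.6, B-C 0.9, C-D -0.5; E isolated.
    """
    g = nx.Graph()
    g.add_nodes_from("ABCDE")
    for a, b, w in (("A", "B", 0.8), ("A", "C", 0.6), ("B", "C", 0.9), ("C", "D", -0.5)):
        g.add_edge(a, b, weight=w, pvalue=1e-6, absweight=abs(w), cost=1.0 - abs(w))
    return CorrelationNetwork("toy5", g, 0.3, 0.01)
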