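"""Overlapping 1-D block extraction and non-local similar-block grouping.

A signal is cut into overlapping blocks of ``block_len`` samples on a
``step`` grid (the last block is clamped to end exactly at the signal end,
so every sample is covered).  For each reference block, candidates whose
start lies within ``window`` start-positions are ranked by squared Euclidean
distance; the closest ``group_size`` (reference included, ties broken by
smaller start) form a group — the low-rank unit the denoiser operates on.

Index conventions are 0-based and half-open throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError

__all__ = [
    "PatchConfig",
    "Block",
    "PatchGroup",
    "block_starts",
    "extract_blocks",
    "block_distance",
    "find_similar",
    "build_groups",
    "group_member_indices",
]


@dataclass(frozen=True)
class PatchConfig:
    """Block matching parameters.

    block_len : samples per block (d); >= 2.
    step : stride between reference block starts; applied to candidate
        blocks as well.
    window : half-width of the candidate search range, in start positions
        (|candidate_start - reference_start| <= window).
    group_size : number of blocks per group, the reference included.
    threshold : optional squared-distance cutoff; candidates farther than
        this from the reference are dropped (the reference itself never is).
    """

    block_len: int = 32
    step: int = 1
    window: int = 256
    group_size: int = 16
    threshold: float | None = None

    def __post_init__(self):
        if self.block_len < 2:
            raise ValueError("block_len must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be nonnegative")


@dataclass(frozen=True)
class Block:
    """A contiguous excerpt of the signal and its 0-based start index."""

    values: np.ndarray
    start: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("block values must be 1-D")
        if self.start < 0:
            raise ValueError("start must be nonnegative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PatchGroup:
    """A d x g matrix whose columns are similar blocks.

    Column 0 is the reference block; ``member_starts`` gives each column's
    start index in the source signal.
    """

    matrix: np.ndarray
    member_starts: np.ndarray
    reference_start: int

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        starts = np.asarray(self.member_starts, dtype=int)
        if mat.ndim != 2:
            raise ValueError("group matrix must be 2-D")
        if starts.ndim != 1 or starts.size != mat.shape[1]:
            raise DimensionError("member_starts length must equal group size")
        if starts.size < 1:
            raise ValueError("a group needs at least one member")
        if len(np.unique(starts)) != starts.size:
            raise ValueError("member_starts must be unique")
        if starts[0] != self.reference_start:
            raise ValueError("column 0 must be the reference block")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "member_starts", starts)

    @property
    def block_len(self) -> int:
        return self.matrix.shape[0]

    @property
    def size(self) -> int:
        return self.matrix.shape[1]


def block_starts(n: int, block_len: int, step: int) -> np.ndarray:
    """Start indices 0, step, 2*step, ... with the last clamped to n - block_len."""
    if n < block_len:
        raise ValueError(f"signal length {n} shorter than block_len {block_len}")
    starts = list(range(0, n - block_len + 1, step))
    if starts[-1] != n - block_len:
        starts.append(n - block_len)
    return np.asarray(starts, dtype=int)


def extract_blocks(q: np.ndarray, cfg: PatchConfig) -> list[Block]:
    """Cut the signal into overlapping blocks on the configured grid."""
    q = np.asarray(q, dtype=float)
    starts = block_starts(q.size, cfg.block_len, cfg.step)
    return [Block(values=q[s : s + cfg.block_len], start=int(s)) for s in starts]


def block_distance(a: Block, b: Block) -> float:
    """Squared Euclidean distance ||a - b||_2^2 between two blocks."""
    if len(a) != len(b):
        raise DimensionError(f"block lengths differ: {len(a)} vs {len(b)}")
    diff = a.values - b.values
    return float(diff @ diff)


def find_similar(ref: Block, candidates: list[Block], cfg: PatchConfig) -> PatchGroup:
    """Group the reference with its nearest candidates inside the window.

    Candidates are filtered to |start - ref.start| <= window, ranked by
    ascending squared distance with ties broken by smaller start, and the
    best ``group_size`` members are kept (the reference always first).  With
    a threshold set, members beyond it are dropped; the group never shrinks
    below the reference alone.
    """
    pool = [
        c
        for c in candidates
        if abs(c.start - ref.start) <= cfg.window and c.start != ref.start
    ]
    ranked = sorted(pool, key=lambda c: (block_distance(ref, c), c.start))
    members = [ref]
    for c in ranked[: cfg.group_size - 1]:
        if cfg.threshold is not None and block_distance(ref, c) > cfg.threshold:
            break
        members.append(c)
    mat = np.column_stack([m.values for m in members])
    starts = np.asarray([m.start for m in members], dtype=int)
    return PatchGroup(matrix=mat, member_starts=starts, reference_start=ref.start)


def build_groups(q: np.ndarray, cfg: PatchConfig) -> list[PatchGroup]:
    """One group per reference block; every sample is covered by >= 1 group."""
    blocks = extract_blocks(q, cfg)
    return [find_similar(ref, blocks, cfg) for ref in blocks]


def group_member_indices(
    q: np.ndarray, cfg: PatchConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized block matching on the uniform start grid.

    Returns ``(starts, members)`` where ``starts`` are the block start
    positions and ``members[i]`` holds, for reference block i, the indices
    into ``starts`` of its group members (reference first, then ascending
    (distance, start)).  Equivalent to :func:`build_groups` without a
    threshold; used by the denoiser's fast path.

    Raises ValueError when a rectangular grouping is not possible (clamped
    non-uniform grid, or a window too narrow to fill every group); callers
    fall back to :func:`build_groups` then.
    """
    q = np.asarray(q, dtype=float)
    starts = block_starts(q.size, cfg.block_len, cfg.step)
    r = starts.size
    d = cfg.block_len
    g = min(cfg.group_size, r)
    k = cfg.window // cfg.step  # window radius in grid units
    if r >= 2 and not np.all(np.diff(starts) == cfg.step):
        raise ValueError("non-uniform start grid; use build_groups")
    if k + 1 < g:
        raise ValueError("window too narrow for a full group; use build_groups")

    blocks = q[starts[:, None] + np.arange(d)[None, :]]  # r x d
    sq = np.einsum("ij,ij->i", blocks, blocks)
    gram = blocks @ blocks.T
    dist = sq[:, None] + sq[None, :] - 2.0 * gram  # r x r squared distances
    np.maximum(dist, 0.0, out=dist)

    offs = np.arange(-k, k + 1)
    cols = np.arange(r)[:, None] + offs[None, :]
    valid = (cols >= 0) & (cols < r)
    cols_c = np.clip(cols, 0, r - 1)
    wdist = np.where(valid, dist[np.arange(r)[:, None], cols_c], np.inf)
    wdist[:, k] = -np.inf  # the reference sorts first
    order = np.argsort(wdist, axis=1, kind="stable")[:, :g]
    members = cols_c[np.arange(r)[:, None], order]
    return starts, members
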