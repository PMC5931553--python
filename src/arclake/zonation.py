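"""Stratigraphic zonation by optimal splitting of information content.

A stratigraphic sequence of compositional samples (rows of proportions,
ordered shallow to deep) is partitioned by recursive binary splitting.  The
information content of a contiguous block is the within-block
Kullback-Leibler deviance from the block-mean composition,

    I(block) = sum_i sum_j p_ij * ln(p_ij / q_j),   q_j = mean_i p_ij,

in nats; a split's worth is the reduction I(block) - I(left) - I(right),
always >= 0.  Splits are deemed significant while the proportion of the
total information they remove exceeds the broken-stick expectation for the
corresponding rank — the classical null in which a unit stick broken at
random into n pieces yields an expected k-th largest piece of
(1/n) * sum_{j=k..n} 1/j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssemblageMatrix",
    "Split",
    "ZonationResult",
    "zone_information",
    "optimal_split",
    "broken_stick_expectation",
    "recursive_zonation",
]


@dataclass
class AssemblageMatrix:
    """Row-stochastic proportion matrix of samples (shallow→deep) × taxa."""

    proportions: np.ndarray
    depths: np.ndarray
    taxa: list[str]
    ages: np.ndarray | None = None
    low_count: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be a 2-D samples × taxa array")
        n, j = self.proportions.shape
        if self.depths.size != n or len(self.taxa) != j:
            raise ValueError("depth/taxa dimensions do not match proportions")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("samples must be strictly ordered by depth")
        rows = self.proportions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("rows must sum to 1")
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)
            if self.ages.size != n:
                raise ValueError("ages length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=self.taxa)
        df.insert(0, "depth_cm", self.depths)
        if self.ages is not None:
            df.insert(1, "age_ad", self.ages)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssemblageMatrix":
        taxa = [c for c in df.columns if c not in ("depth_cm", "age_ad")]
        return cls(
            proportions=df[taxa].to_numpy(dtype=float),
            depths=df["depth_cm"].to_numpy(dtype=float),
            taxa=taxa,
            ages=df["age_ad"].to_numpy(dtype=float) if "age_ad" in df.columns else None,
        )


def zone_information(block: np.ndarray) -> float:
    """Information content (nats) of a contiguous block of proportion rows.

    Zero iff all rows are identical; terms with p_ij = 0 contribute nothing,
    and a taxon with zero block mean has p_ij = 0 throughout, so it drops out.
    """
    p = np.asarray(block, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.size == 0:
        raise ValueError("empty block")
    q = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(np.where(p > 0, p, 1.0) / np.where(q > 0, q, 1.0))
    return float(np.where(p > 0, terms, 0.0).sum())


def optimal_split(block: np.ndarray) -> tuple[int, float]:
    """Best between-sample cut of a block by information reduction.

    Returns ``(position, reduction)`` where ``position`` is the number of
    rows in the left (shallower) part, in ``1..n-1``.  Every cut is
    evaluated exhaustively; ties break toward the shallower cut.
    """
    p = np.asarray(block, dtype=float)
    n = p.shape[0]
    if n < 2:
        raise ValueError("block must contain at least 2 samples")
    total = zone_information(p)
    best_pos, best_red = 1, -np.inf
    for cut in range(1, n):
        red = total - zone_information(p[:cut]) - zone_information(p[cut:])
        if red > best_red + 1e-15:
            best_pos, best_red = cut, red
    return best_pos, max(best_red, 0.0)


def broken_stick_expectation(n_pieces: int, k: int) -> float:
    """Expected proportion of the k-th largest of n random stick pieces."""
    if not 1 <= k <= n_pieces:
        raise ValueError("k must satisfy 1 <= k <= n_pieces")
    return float(np.sum(1.0 / np.arange(k, n_pieces + 1)) / n_pieces)


@dataclass(frozen=True)
class Split:
    """One boundary: cut before sample ``position`` (global row index)."""

    position: int
    reduction: float
    broken_stick: float
    significant: bool
    order: int  # 1-based greedy selection order
    boundary_depth: float = float("nan")
    boundary_age: float = float("nan")


@dataclass
class ZonationResult:
    """Ordered splits with information reductions and broken-stick null."""

    splits: list[Split] = field(default_factory=list)
    n_significant: int = 0
    total_information: float = 0.0
    n_samples: int = 0

    @property
    def significant_boundaries(self) -> list[int]:
        return sorted(s.position for s in self.splits[: self.n_significant])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.splits) + 1),
                "position": [s.position for s in self.splits],
                "boundary_depth_cm": [s.boundary_depth for s in self.splits],
                "boundary_age_ad": [s.boundary_age for s in self.splits],
                "reduction": [s.reduction for s in self.splits],
                "broken_stick": [s.broken_stick for s in self.splits],
                "significant": [s.significant for s in self.splits],
            }
        )


def recursive_zonation(
    matrix: AssemblageMatrix | np.ndarray | Sequence[Sequence[float]],
    max_splits: int | None = None,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ZonationResult:
    """Greedy recursive binary zonation with broken-stick significance.

    At each step the block whose optimal cut yields the largest information
    reduction is split; the process stops after ``max_splits`` splits
    (default: n_samples - 1) or when no cut reduces information.  Splits are
    then ranked by decreasing reduction, and split rank k is significant
    while reduction_k / I(whole) exceeds the broken-stick expectation for
    the k-th largest of n_samples pieces; ``n_significant`` is the longest
    all-significant prefix.

    ``transform`` (e.g. ``numpy.sqrt``) is applied to the proportion matrix
    before any information is computed; proportions are used untransformed
    by default.
    """
    if isinstance(matrix, AssemblageMatrix):
        p = matrix.proportions
        depths: np.ndarray | None = matrix.depths
        ages = matrix.ages
    else:
        p = np.asarray(matrix, dtype=float)
        depths = None
        ages = None
    n = p.shape[0]
    if n < 3:
        raise ValueError("zonation needs at least 3 samples")
    if transform is not None:
        p = np.asarray(transform(p), dtype=float)
    if max_splits is None:
        max_splits = n - 1

    total_info = zone_information(p)
    blocks: list[tuple[int, int]] = [(0, n)]
    chosen: list[tuple[int, float]] = []  # (global cut position, reduction)
    while len(chosen) < max_splits:
        best = None
        for lo, hi in blocks:
            if hi - lo < 2:
                continue
            pos, red = optimal_split(p[lo:hi])
            if best is None or red > best[2] + 1e-15:
                best = (lo, hi, red, lo + pos)
        if best is None or best[2] <= 1e-12:
            break
        lo, hi, red, cut = best
        chosen.append((cut, red))
        blocks.remove((lo, hi))
        blocks.extend([(lo, cut), (cut, hi)])

    order = {cut: i + 1 for i, (cut, _) in enumerate(chosen)}
    ranked = sorted(chosen, key=lambda t: -t[1])
    splits: list[Split] = []
    n_sig = 0
    prefix_ok = True
    for k, (cut, red) in enumerate(ranked, start=1):
        b_k = broken_stick_expectation(n, k)
        sig = total_info > 0 and (red / total_info) > b_k
        if prefix_ok and sig:
            n_sig = k
        else:
            prefix_ok = False
        bd = float("nan")
        ba = float("nan")
        if depths is not None:
            bd = 0.5 * (depths[cut - 1] + depths[cut])
        if ages is not None:
            ba = 0.5 * (ages[cut - 1] + ages[cut])
        splits.append(
            Split(
                position=cut,
                reduction=red,
                broken_stick=b_k,
                significant=bool(sig),
                order=order[cut],
                boundary_depth=bd,
                boundary_age=ba,
            )
        )
    return ZonationResult(
        splits=splits,
        n_significant=n_sig,
        total_information=total_info,
        n_samples=n,
    )
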