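"""Delay embedding of a scalar series into a one-step-ahead training set.

A series of length N with window m and delay tau yields
``n = N - 1 - (m - 1) * tau`` input/target pairs: pair j has inputs
``series[j], series[j + tau], ..., series[j + (m-1) tau]`` and target
``series[j + (m-1) tau + 1]``. The classic 5000-sample / m=99 / tau=1 case
therefore gives 4901 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["EmbeddingConfig", "EmbeddedDataset", "embed", "split_train_eval"]


@dataclass(frozen=True)
class EmbeddingConfig:
    m: int = 99
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("window m must be >= 1")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")

    @property
    def span(self) -> int:
        """Series samples covered by one input window."""
        return (self.m - 1) * self.tau + 1

    def min_series_length(self) -> int:
        return (self.m - 1) * self.tau + 2

    def pair_count(self, series_length: int) -> int:
        return series_length - 1 - (self.m - 1) * self.tau


@dataclass
class EmbeddedDataset:
    """Supervised one-step-ahead pairs in time order.

    ``inputs`` is (n, m); ``targets`` is (n,); ``source_indices[j]`` is the
    0-based index of pair j's target sample in the original series.
    """

    inputs: np.ndarray
    targets: np.ndarray
    source_indices: np.ndarray
    config: EmbeddingConfig

    @property
    def n(self) -> int:
        return int(self.targets.size)

    def subset(self, idx: np.ndarray | slice) -> "EmbeddedDataset":
        return EmbeddedDataset(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            source_indices=self.source_indices[idx],
            config=self.config,
        )

    def save_csv(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        inputs_path = prefix.parent / (prefix.name + "inputs.csv")
        targets_path = prefix.parent / (prefix.name + "targets.csv")
        np.savetxt(inputs_path, self.inputs, delimiter=",")
        np.savetxt(targets_path, self.targets, delimiter=",")
        return inputs_path, targets_path


def embed(series: np.ndarray, config: EmbeddingConfig) -> EmbeddedDataset:
    """Build the delay-embedded dataset; see the module docstring for the
    index arithmetic."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    N = x.size
    n = config.pair_count(N)
    if n < 1:
        raise ValueError(
            f"series of length {N} is too short for m={config.m}, "
            f"tau={config.tau}; need at least {config.min_series_length()} samples"
        )
    span = (config.m - 1) * config.tau
    # inputs[j, k] = x[j + k*tau]
    windows = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:n]
    inputs = windows[:, :: config.tau].copy()
    targets = x[span + 1 : span + 1 + n].copy()
    source_indices = np.arange(span + 1, span + 1 + n)
    return EmbeddedDataset(
        inputs=inputs,
        targets=targets,
        source_indices=source_indices,
        config=config,
    )


def split_train_eval(
    dataset: EmbeddedDataset,
    boundary: Optional[int] = None,
    train_fraction: Optional[float] = None,
    strict: bool = False,
) -> tuple[EmbeddedDataset, EmbeddedDataset]:
    """Chronological split into (train, eval); never shuffles.

    ``boundary`` is the number of leading pairs kept for training; give
    either it or ``train_fraction``. In strict mode, evaluation pairs whose
    input window still contains a training-side target sample are dropped
    (assigned to neither side), preventing one-step leakage.
    """
    n = dataset.n
    if (boundary is None) == (train_fraction is None):
        raise ValueError("give exactly one of boundary or train_fraction")
    if boundary is None:
        boundary = int(np.floor(n * train_fraction))
    if not 0 < boundary < n:
        raise ValueError(f"boundary must lie strictly inside (0, {n})")
    train = dataset.subset(slice(0, boundary))
    eval_start = boundary
    if strict:
        eval_start = boundary + (dataset.config.m - 1) * dataset.config.tau + 1
        if eval_start >= n:
            raise ValueError("strict split leaves no evaluation pairs")
    return train, dataset.subset(slice(eval_start, n))
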