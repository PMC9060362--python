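"""Knot selection: the r individuals whose GRM block anchors the low-rank term.

Two designs are supported: uniform random sub-sampling (robust in simulated
tree-structured populations) and row-sum ordering — individuals with the
largest GRM row sums share the most genetic relationship with the rest of
the cohort and are the most informative anchors for predicting the
relatedness of the individuals left out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class KnotSet:
    """An ordered, distinct set of knot indices plus its provenance."""

    indices: np.ndarray
    method: str  # "random" | "rowsum"
    seed: int | None = None

    @property
    def r(self) -> int:
        return len(self.indices)

    def write(self, path: str | Path) -> None:
        """One index per line, with a comment header recording provenance."""
        with open(path, "w") as fh:
            fh.write(f"# method={self.method} seed={self.seed} r={self.r}\n")
            for i in self.indices:
                fh.write(f"{int(i)}\n")

    @classmethod
    def read(cls, path: str | Path) -> "KnotSet":
        method, seed = "unknown", None
        indices = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k == "method":
                            method = v
                        elif k == "seed" and v not in ("None", ""):
                            seed = int(v)
                elif line:
                    indices.append(int(line))
        return cls(indices=np.asarray(indices, dtype=np.int64), method=method, seed=seed)


def select_knots_random(n: int, r: int, seed: int) -> KnotSet:
    """Uniform without-replacement sample of r of the n individuals.

    Reproducible: the same seed always yields the same set (numpy PCG64
    generator, platform-stable).
    """
    if not 1 <= r <= n:
        raise ValueError(f"need 1 <= r <= n, got r={r}, n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=r, replace=False)
    return KnotSet(indices=idx.astype(np.int64), method="random", seed=seed)


def select_knots_rowsum(row_sums: np.ndarray, r: int) -> KnotSet:
    """Indices of the r largest GRM row sums, in descending row-sum order.

    Ties are broken by ascending original index (stable sort), making the
    selection deterministic.
    """
    rs = np.asarray(row_sums, dtype=np.float64)
    if rs.ndim != 1:
        raise ValueError("row_sums must be a vector")
    if not np.isfinite(rs).all():
        raise ValueError("row_sums must be finite")
    if not 1 <= r <= rs.size:
        raise ValueError(f"need 1 <= r <= N, got r={r}, N={rs.size}")
    order = np.argsort(-rs, kind="stable")
    return KnotSet(indices=order[:r].astype(np.int64), method="rowsum", seed=None)
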