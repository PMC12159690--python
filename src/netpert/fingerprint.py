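"""Connectome fingerprinting and reference-network stability.

Fingerprinting asks whether a subject's deviation matrix at baseline is
more similar to their own follow-up matrix than to anyone else's: the
Pearson correlation between strict-lower-triangle vectors is computed
for every baseline/follow-up pair and each baseline subject is matched
to the follow-up argmax.  Stability resampling rebuilds the reference
network from random control subsets of increasing size and correlates
each subsampled network with the full-cohort network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CovariateTable, RegionalUptakeTable
from .network import DeviationMatrix, build_reference_network

__all__ = [
    "FingerprintResult",
    "StabilityCurve",
    "fingerprint_identify",
    "reference_stability",
    "DEFAULT_STABILITY_SIZES",
]

#: default subsample sizes: 8 to 64 in steps of 4
DEFAULT_STABILITY_SIZES = tuple(range(8, 65, 4))


@dataclass
class FingerprintResult:
    """Baseline-to-follow-up identification outcome."""

    subject_ids: list[str]
    similarity: np.ndarray  # n_base x n_follow Pearson correlations
    matches: list[str]      # per-baseline best-matching follow-up id
    accuracy: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "matched_id": self.matches,
                "correct": [s == m for s, m in zip(self.subject_ids, self.matches)],
            }
        )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return np.clip(a @ b.T, -1.0, 1.0)


def fingerprint_identify(
    base: Sequence[DeviationMatrix], follow: Sequence[DeviationMatrix]
) -> FingerprintResult:
    """Match each baseline deviation matrix to its most correlated
    follow-up matrix; accuracy is the fraction matched to themselves.

    Argmax ties break toward the lower follow-up index (a measure-zero
    event with continuous data, but deterministic).
    """
    base = list(base)
    follow = list(follow)
    if len(base) < 2:
        raise ValueError("fingerprinting needs at least 2 subjects")
    base_ids = [d.subject_id for d in base]
    follow_ids = [d.subject_id for d in follow]
    if set(base_ids) != set(follow_ids):
        raise ValueError(
            "baseline and follow-up subject id sets differ: "
            f"{sorted(set(base_ids) ^ set(follow_ids))}"
        )
    order = [follow_ids.index(s) for s in base_ids]
    follow = [follow[i] for i in order]
    tri_base = np.vstack([d.lower_triangle() for d in base])
    tri_follow = np.vstack([d.lower_triangle() for d in follow])
    sim = _pearson_rows(tri_base, tri_follow)
    match_idx = sim.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    matches = [base_ids[i] for i in match_idx]
    accuracy = float(np.mean([m == s for m, s in zip(matches, base_ids)]))
    return FingerprintResult(
        subject_ids=base_ids, similarity=sim, matches=matches, accuracy=accuracy
    )


@dataclass
class StabilityCurve:
    """Subsample-vs-full network correlations across reference sizes."""

    sizes: list[int]
    correlations: np.ndarray  # len(sizes) x reps
    seed: int

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be strictly increasing")
        if self.correlations.shape[0] != len(self.sizes):
            raise ValueError("one correlation row per size is required")

    @property
    def reps(self) -> int:
        return self.correlations.shape[1]

    def mean_by_size(self) -> pd.Series:
        return pd.Series(
            self.correlations.mean(axis=1), index=self.sizes, name="mean_correlation"
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"size": s, "rep": r, "correlation": self.correlations[i, r]}
            for i, s in enumerate(self.sizes)
            for r in range(self.reps)
        ]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Mean +/- sd stability curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mean = self.correlations.mean(axis=1)
        sd = self.correlations.std(axis=1)
        ax.errorbar(self.sizes, mean, yerr=sd, marker="o", capsize=3)
        ax.set_xlabel("reference subset size")
        ax.set_ylabel("correlation with full-cohort network")
        ax.set_ylim(None, 1.02)
        return ax


def reference_stability(
    table: RegionalUptakeTable,
    cov: CovariateTable | None = None,
    sizes: Sequence[int] = DEFAULT_STABILITY_SIZES,
    reps: int = 20,
    seed: int = 0,
) -> StabilityCurve:
    """Stability of the reference network under control subsampling.

    For every subset size, ``reps`` subsets are drawn without
    replacement, the network (same covariate model) is rebuilt on each
    subset, and its strict lower triangle is Pearson-correlated with the
    full-cohort network's.  Each (size, rep) cell uses an independent
    substream spawned from the master seed.
    """
    sizes = sorted(int(s) for s in set(sizes))
    n = table.n_subjects
    k = 0 if cov is None else cov.design().shape[1]
    if sizes[-1] > n:
        raise ValueError(f"largest subsample size {sizes[-1]} exceeds cohort size {n}")
    if sizes[0] <= k + 2:
        raise ValueError(
            f"smallest size {sizes[0]} too small for the covariate model (need > {k + 2})"
        )
    full = build_reference_network(table, cov)
    full_tri = full.lower_triangle()
    streams = np.random.SeedSequence(seed).spawn(len(sizes) * reps)
    corr = np.empty((len(sizes), reps))
    for i, size in enumerate(sizes):
        for r in range(reps):
            rng = np.random.default_rng(streams[i * reps + r])
            # a small subset can make a covariate constant (e.g. single-sex
            # draw); such degenerate designs are redrawn
            for _ in range(100):
                idx = rng.choice(n, size=size, replace=False)
                try:
                    sub_net = build_reference_network(
                        table.subset(idx), None if cov is None else cov.subset(idx)
                    )
                    break
                except ValueError:
                    continue
            else:
                raise ValueError(
                    f"could not draw a non-degenerate subset of size {size}"
                )
            corr[i, r] = np.corrcoef(sub_net.lower_triangle(), full_tri)[0, 1]
    return StabilityCurve(sizes=list(sizes), correlations=corr, seed=seed)
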