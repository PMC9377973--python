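"""Per-class balance weights from training-set class counts.

Two weight vectors drive the double-balanced loss:

* the **size-balance factor** ``alpha``, the normalized inverse of the
  *effective sample size* ``E_n = (1 - beta^n) / (1 - beta)`` — a saturating
  count that models the diminishing return of additional samples whose
  features overlap those already seen; and
* the **prior probability** ``pp``, the normalized inverse class frequency
  raised to ``rho``, which sets how strongly the class prior enters the
  difficulty weight.

Both are computed once from the global training counts and frozen for a run;
they are not re-estimated per batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassCounts",
    "BalanceParams",
    "WeightTable",
    "effective_sample_sizes",
    "balance_factors",
    "prior_probabilities",
    "build_weight_table",
]


@dataclass(frozen=True)
class ClassCounts:
    """Ordered class labels and their training-sample counts ``n_i``."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "counts", counts)
        if len(labels) < 1:
            raise ValueError("at least one class is required")
        if len(labels) != len(counts):
            raise ValueError("labels and counts must have equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be unique")
        if any(c < 1 for c in counts):
            raise ValueError("every class count must be a positive integer")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @classmethod
    def from_mapping(cls, mapping: dict[str, int]) -> "ClassCounts":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    @classmethod
    def from_csv(cls, path) -> "ClassCounts":
        """Read a two-column CSV ``label,count`` (header optional)."""
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["label", "count"]:
            df = pd.read_csv(path, header=None, names=["label", "count"])
        return cls(tuple(df["label"].astype(str)), tuple(df["count"].astype(int)))

    def to_csv(self, path) -> None:
        pd.DataFrame({"label": self.labels, "count": self.counts}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class BalanceParams:
    """Hyperparameters of the two weighting schemes.

    ``beta`` in [0, 1) controls how fast the effective sample size saturates
    (beta -> 1 recovers the raw counts, beta -> 0 makes every class count as
    one sample); ``rho`` >= 0 controls the flexibility of the prior
    (rho = 0 gives a uniform prior, rho = 1 the inverse class frequency).
    Defaults are the values found near-optimal in the hyperparameter study.
    """

    beta: float = 0.99
    rho: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must lie in [0, 1); got {self.beta}")
        if self.rho < 0.0:
            raise ValueError(f"rho must be non-negative; got {self.rho}")


def _validate_beta(beta: float) -> float:
    beta = float(beta)
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must lie in [0, 1); got {beta}")
    return beta


def effective_sample_sizes(counts: ClassCounts, beta: float) -> np.ndarray:
    """Effective sample size ``E_i = (1 - beta^{n_i}) / (1 - beta)`` per class.

    Equals the partial geometric sum ``sum_{m=0}^{n_i - 1} beta^m``, so it is
    1 for a single sample, approaches ``n_i`` as beta -> 1, and saturates at
    ``1 / (1 - beta)`` for large ``n_i``.  ``beta = 0`` is the analytic limit
    ``E_i = 1`` for every class.
    """
    beta = _validate_beta(beta)
    n = counts.as_array()
    if beta == 0.0:
        return np.ones_like(n)
    # beta^n via exp(n log beta): no silent under/overflow for n up to 1e6+
    beta_pow_n = np.exp(n * np.log(beta))
    return (1.0 - beta_pow_n) / (1.0 - beta)


def balance_factors(counts: ClassCounts, beta: float) -> np.ndarray:
    """Size-balance factor ``alpha_i``: normalized inverse effective size.

    ``alpha_i = e_i / sum_j e_j`` with ``e_i = 1 / E_i``.  Sums to one;
    classes with fewer (effective) samples get larger factors.
    """
    e = 1.0 / effective_sample_sizes(counts, beta)
    return e / e.sum()


def prior_probabilities(counts: ClassCounts, rho: float) -> np.ndarray:
    """Prior probability ``pp_i = n_i^{-rho} / sum_j n_j^{-rho}``.

    rho = 0 yields the uniform prior 1/k; rho = 1 the normalized inverse
    class frequency; intermediate rho interpolates the sharpness.
    """
    rho = float(rho)
    if rho < 0.0:
        raise ValueError(f"rho must be non-negative; got {rho}")
    inv = counts.as_array() ** (-rho)
    return inv / inv.sum()


@dataclass(frozen=True)
class WeightTable:
    """Precomputed per-class weights for fixed ``(beta, rho)``."""

    counts: ClassCounts
    params: BalanceParams
    effective_sizes: np.ndarray = field(repr=False)
    inverse_effective: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    prior: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return self.counts.k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.counts.labels,
                "n": self.counts.counts,
                "E": self.effective_sizes,
                "alpha": self.alpha,
                "prior": self.prior,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_weight_table(
    counts: ClassCounts, params: BalanceParams | None = None
) -> WeightTable:
    """Bundle effective sizes, alpha and prior into one frozen record."""
    if params is None:
        params = BalanceParams()
    E = effective_sample_sizes(counts, params.beta)
    return WeightTable(
        counts=counts,
        params=params,
        effective_sizes=E,
        inverse_effective=1.0 / E,
        alpha=balance_factors(counts, params.beta),
        prior=prior_probabilities(counts, params.rho),
    )
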