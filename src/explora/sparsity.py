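"""Sparsity scaling C = c1/S: fitting, synthetic record tables, and the
random-matrix instability demonstration.

The fit regresses connectivity on 1/S through the origin (ordinary
least squares); a log-log variant with the slope pinned at -1 is
available for comparison.  The Monte-Carlo demo shows that random
community matrices with diagonal -d destabilize once sigma*sqrt(C*S)
exceeds d, and that C ~ 1/S makes the criterion size-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InvalidParameterError

__all__ = [
    "ScalingRecordSet",
    "ScalingFit",
    "fit_inverse_scaling",
    "generate_scaling_table",
    "may_instability_probability",
]


@dataclass
class ScalingRecordSet:
    """(label, size S, connectivity C) records for the scaling fit."""

    labels: list[str]
    S: np.ndarray
    C: np.ndarray
    n_clipped: int = 0

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=int)
        self.C = np.asarray(self.C, dtype=float)
        if not (len(self.labels) == self.S.size == self.C.size):
            raise InvalidParameterError("label/S/C length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidParameterError("labels must be unique")
        if np.any(self.S < 2):
            raise InvalidParameterError("sizes must be >= 2")
        if np.any(self.C <= 0) or np.any(self.C > 1):
            raise InvalidParameterError("connectivities must lie in (0, 1]")

    def __len__(self) -> int:
        return self.S.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "S": self.S, "C": self.C})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScalingRecordSet":
        df = pd.read_csv(path)
        missing = {"label", "S", "C"} - set(df.columns)
        if missing:
            raise InvalidParameterError(f"CSV missing columns: {sorted(missing)}")
        return cls(
            labels=df["label"].astype(str).tolist(),
            S=df["S"].to_numpy(),
            C=df["C"].to_numpy(),
        )


@dataclass(frozen=True)
class ScalingFit:
    c1: float
    c1_stderr: float
    n_records: int
    method: str = "origin-ols"


def fit_inverse_scaling(
    data: ScalingRecordSet, method: str = "origin-ols"
) -> ScalingFit:
    """Fit C = c1/S.

    ``origin-ols`` regresses C on x = 1/S through the origin:
    c1_hat = sum(C x) / sum(x^2).  Because realistic tables have
    multiplicative noise (residual spread shrinks with S), the reported
    standard error is the heteroscedasticity-robust (HC1 sandwich)
    estimate rather than the homoscedastic one, which badly undercovers
    here.  ``loglog`` averages log(C S) (slope fixed at -1 in log-log
    space) and maps the standard error back through the exponential.
    """
    if len(data) < 2:
        raise InvalidParameterError("need at least 2 records to fit")
    x = 1.0 / data.S
    if method == "origin-ols":
        n = len(data)
        sxx = float(np.sum(x * x))
        c1 = float(np.sum(data.C * x)) / sxx
        resid = data.C - c1 * x
        stderr = float(np.sqrt(n / (n - 1) * np.sum(x * x * resid * resid)) / sxx)
    elif method == "loglog":
        logs = np.log(data.C * data.S)
        mu = float(np.mean(logs))
        se_mu = float(np.std(logs, ddof=1) / np.sqrt(len(data)))
        c1 = float(np.exp(mu))
        stderr = c1 * se_mu
    else:
        raise InvalidParameterError(f"unknown fit method {method!r}")
    return ScalingFit(c1=c1, c1_stderr=stderr, n_records=len(data), method=method)


def generate_scaling_table(
    c1_true: float,
    n_networks: int,
    S_range: tuple[int, int] = (10, 1000),
    noise_cv: float = 0.3,
    seed=None,
) -> ScalingRecordSet:
    """Synthesize a record table obeying C = c1/S with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``.

    Sizes are drawn log-uniformly over ``S_range``; connectivities are
    clipped into [2/S, 1] (the connectedness floor and the dense
    ceiling), and the number of clipped records is reported.
    """
    if c1_true < 2:
        raise InvalidParameterError("c1_true must be >= 2 (connectedness floor)")
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    if n_networks < 1:
        raise InvalidParameterError("n_networks must be >= 1")
    lo, hi = S_range
    if lo < 2 or hi < lo:
        raise InvalidParameterError("invalid S_range")
    rng = np.random.default_rng(seed)
    S = np.exp(rng.uniform(np.log(lo), np.log(hi), n_networks)).round().astype(int)
    S = np.clip(S, lo, hi)
    raw = (c1_true / S) * (1.0 + rng.normal(0.0, noise_cv, n_networks))
    C = np.clip(raw, 2.0 / S, 1.0)
    return ScalingRecordSet(
        labels=[f"net{i:03d}" for i in range(n_networks)],
        S=S,
        C=C,
        n_clipped=int(np.sum(raw != C)),
    )


def may_instability_probability(
    S: int,
    C: float,
    sigma: float,
    d: float,
    n_matrices: int = 100,
    seed=None,
) -> float:
    """Monte-Carlo estimate of the probability that a random community
    matrix is unstable.

    Each matrix has diagonal -d; each off-diagonal entry is active with
    probability C and then drawn from N(0, sigma^2).  Returns the
    fraction of matrices whose spectral abscissa is positive; in the
    large-S limit this jumps from 0 to 1 as sigma*sqrt(C*S) crosses d.
    """
    if d <= 0:
        raise InvalidParameterError("d must be > 0")
    if n_matrices < 1:
        raise InvalidParameterError("n_matrices must be >= 1")
    if not (0 < C <= 1):
        raise InvalidParameterError("C must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    unstable = 0
    for _ in range(n_matrices):
        M = rng.normal(0.0, sigma, (S, S)) * (rng.random((S, S)) < C)
        np.fill_diagonal(M, -d)
        if np.max(np.linalg.eigvals(M).real) > 0:
            unstable += 1
    return unstable / n_matrices
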