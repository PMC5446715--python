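"""Methylation matrix container and the beta-value / M-value transforms.

Array methylation data come in two interchangeable scales: beta-values,
the methylated fraction in (0, 1), and M-values, their log2-odds.  All
statistics in this package are computed on M-values (which are roughly
homoscedastic); beta-values are the natural scale for mixing cell types.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["MethylationMatrix", "beta_to_m", "m_to_beta"]


def beta_to_m(beta):
    """Convert beta-values in (0, 1) to M-values, m = log2(beta / (1 - beta))."""
    beta = np.asarray(beta, dtype=float)
    if beta.size and (np.min(beta) <= 0.0 or np.max(beta) >= 1.0):
        raise ValueError("beta-values must lie strictly in (0, 1)")
    return np.log2(beta) - np.log2(1.0 - beta)


def m_to_beta(m):
    """Convert M-values to beta-values, beta = 2^m / (2^m + 1).

    Evaluated as 1 / (1 + 2^-m), which is stable for large |m|.
    """
    m = np.asarray(m, dtype=float)
    if m.size and not np.all(np.isfinite(m)):
        raise ValueError("M-values must be finite")
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass
class MethylationMatrix:
    """A probes x samples methylation matrix with an explicit scale tag.

    Parameters
    ----------
    values
        Real matrix of shape (p, n), probes as rows.
    probe_ids, sample_ids
        Unique identifiers for the p rows and n columns.
    scale
        ``"M"`` (any finite real) or ``"beta"`` (strictly inside (0, 1)).
    """

    values: np.ndarray
    probe_ids: Sequence[str]
    sample_ids: Sequence[str]
    scale: str = "M"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = list(map(str, self.probe_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples matrix")
        p, n = self.values.shape
        if p < 2 or n < 3:
            raise ValueError(f"need at least 2 probes and 3 samples, got {p} x {n}")
        if len(self.probe_ids) != p:
            raise ValueError("probe_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.probe_ids)) != p:
            raise ValueError("probe_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if self.scale not in ("M", "beta"):
            raise ValueError(f"scale must be 'M' or 'beta', got {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at probe {self.probe_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.scale == "beta":
            bad_rows = np.where(
                (self.values.min(axis=1) <= 0.0) | (self.values.max(axis=1) >= 1.0)
            )[0]
            if bad_rows.size:
                raise ValueError(
                    "beta-values must lie strictly in (0, 1); offending probes: "
                    + ", ".join(self.probe_ids[i] for i in bad_rows[:5])
                )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_m(self) -> "MethylationMatrix":
        """Return an M-value view (identity if already on the M scale)."""
        if self.scale == "M":
            return self
        return replace(self, values=beta_to_m(self.values), scale="M")

    def to_beta(self) -> "MethylationMatrix":
        """Return a beta-value view (identity if already on the beta scale)."""
        if self.scale == "beta":
            return self
        return replace(self, values=m_to_beta(self.values), scale="beta")
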