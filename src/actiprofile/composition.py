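"""Compositional operations for 24-hour activity-cycle behaviors.

A day's time budget (Sleep, SB, LPA, MVPA) carries only relative
information: the four parts are positive and constrained to a constant
total (1440 min, or 100 %). This module provides the closure (rescaling)
operation, the isometric log-ratio (ILR) transform built from a sequential
binary partition, its inverse, the compositional (geometric) mean, and
IQR-fence winsorization.

The default partition pivots out MVPA first, then SB, then LPA:

    ilr1 = sqrt(3/4) * ln( MVPA / (SB * LPA * Sleep)^(1/3) )
    ilr2 = sqrt(2/3) * ln( SB   / (LPA * Sleep)^(1/2) )
    ilr3 = sqrt(1/2) * ln( LPA  / Sleep )

so each coordinate is a balance of one behavior against the geometric mean
of the behaviors not yet partitioned out. A 4-part composition always maps
to exactly 3 unconstrained real coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical part order used throughout the package
PARTS = ("sleep", "sb", "lpa", "mvpa")

#: minutes in a nominal day — the default closure constant
MINUTES_PER_DAY = 1440.0


class CompositionError(ValueError):
    """Raised for invalid compositional input (nonpositive parts, etc.)."""


def _as_parts(parts) -> np.ndarray:
    x = np.asarray(parts, dtype=float)
    if x.shape[-1] != len(PARTS):
        raise CompositionError(
            f"expected {len(PARTS)} parts in order {PARTS}, got shape {x.shape}"
        )
    return x


def closure(parts, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Rescale positive parts to sum to the closure constant ``kappa``.

    Operates on the last axis; accepts a single 4-vector or an (n, 4)
    array. Idempotent, and the only place the constant-sum constraint is
    imposed.
    """
    x = _as_parts(parts)
    if not np.all(x > 0):
        raise CompositionError("closure requires strictly positive parts")
    total = x.sum(axis=-1, keepdims=True)
    return x * (kappa / total)


@dataclass(frozen=True)
class BehaviorComposition:
    """One participant's closed 4-part day composition."""

    sleep: float
    sb: float
    lpa: float
    mvpa: float
    kappa: float = MINUTES_PER_DAY

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(arr > 0):
            raise CompositionError("composition parts must be strictly positive")
        if abs(arr.sum() - self.kappa) > 1e-9 * max(1.0, self.kappa):
            raise CompositionError(
                f"parts sum to {arr.sum()!r}, expected kappa={self.kappa!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.sleep, self.sb, self.lpa, self.mvpa])

    @classmethod
    def from_parts(cls, parts, kappa: float = MINUTES_PER_DAY) -> "BehaviorComposition":
        closed = closure(parts, kappa)
        return cls(*closed, kappa=kappa)


def _default_codes() -> np.ndarray:
    # rows: balances (MVPA | SB,LPA,Sleep), (SB | LPA,Sleep), (LPA | Sleep)
    # columns follow PARTS order (sleep, sb, lpa, mvpa)
    return np.array(
        [
            [-1, -1, -1, +1],
            [-1, +1, -1, 0],
            [-1, 0, +1, 0],
        ],
        dtype=float,
    )


@dataclass(frozen=True)
class SequentialBinaryPartition:
    """Sign-code matrix defining the ILR balances.

    Each row splits the not-yet-partitioned parts into a numerator (+1)
    and denominator (−1) group; 0 marks parts already pivoted out. For a
    row with r numerator parts and s denominator parts the normalizing
    constant is sqrt(r*s / (r + s)).
    """

    codes: np.ndarray = field(default_factory=_default_codes)

    def __post_init__(self):
        c = np.asarray(self.codes, dtype=float)
        if c.shape != (len(PARTS) - 1, len(PARTS)):
            raise CompositionError(f"SBP codes must be {len(PARTS)-1}x{len(PARTS)}")
        if not np.all(np.isin(c, (-1.0, 0.0, 1.0))):
            raise CompositionError("SBP codes must be in {-1, 0, +1}")
        for row in c:
            if not ((row == 1).any() and (row == -1).any()):
                raise CompositionError("each SBP row needs both +1 and -1 codes")
        object.__setattr__(self, "codes", c)

    @property
    def contrast_matrix(self) -> np.ndarray:
        """Orthonormal 4×3 basis V with ilr(x) = V.T @ clr(x)."""
        rows = []
        for row in self.codes:
            r = float((row == 1).sum())
            s = float((row == -1).sum())
            v = np.zeros_like(row)
            v[row == 1] = np.sqrt(s / (r * (r + s)))
            v[row == -1] = -np.sqrt(r / (s * (r + s)))
            rows.append(v)
        return np.stack(rows, axis=1)  # shape (4, 3)


DEFAULT_SBP = SequentialBinaryPartition()


def ilr_transform(parts, sbp: SequentialBinaryPartition = DEFAULT_SBP) -> np.ndarray:
    """Map compositions (last axis = 4 parts) to 3 ILR balance coordinates.

    Scale-invariant: closing the input first does not change the result.
    """
    x = np.asarray(parts, dtype=float)
    if isinstance(parts, BehaviorComposition):
        x = parts.as_array()
    x = _as_parts(x)
    if not np.all(x > 0):
        raise CompositionError("ilr_transform requires strictly positive parts")
    return np.log(x) @ sbp.contrast_matrix


def ilr_inverse(
    coords,
    sbp: SequentialBinaryPartition = DEFAULT_SBP,
    kappa: float = MINUTES_PER_DAY,
) -> np.ndarray:
    """Map ILR coordinates back to the unique composition summing to kappa."""
    y = np.asarray(coords, dtype=float)
    if y.shape[-1] != len(PARTS) - 1:
        raise CompositionError(f"expected {len(PARTS)-1} ILR coordinates")
    if not np.all(np.isfinite(y)):
        raise CompositionError("ILR coordinates must be finite")
    logx = y @ sbp.contrast_matrix.T
    # subtract the rowwise max before exponentiating for numerical safety
    logx = logx - logx.max(axis=-1, keepdims=True)
    return closure(np.exp(logx), kappa)


def compositional_mean(comps, kappa: float | None = None) -> np.ndarray:
    """Geometric center of a compositional sample.

    Part-wise geometric mean, re-closed. Equals the inverse ILR of the
    arithmetic mean of the ILR coordinates (the Aitchison mean).
    """
    x = _as_parts(np.asarray(comps, dtype=float))
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        raise CompositionError("compositional_mean of an empty sample")
    if not np.all(x > 0):
        raise CompositionError("compositional_mean requires strictly positive parts")
    if kappa is None:
        kappa = float(x[0].sum())
    gm = np.exp(np.log(x).mean(axis=0))
    return closure(gm, kappa)


@dataclass(frozen=True)
class WinsorizeRule:
    """Tukey-fence screening with percentile replacement.

    Values below Q1 − k·IQR are replaced by the lower percentile of the
    *original* vector, values above Q3 + k·IQR by the upper percentile.
    Percentiles and quartiles use linear interpolation between order
    statistics (numpy's default, the "type 7" convention).
    """

    k: float = 1.5
    lower_pct: float = 5.0
    upper_pct: float = 95.0


def winsorize(values, rule: WinsorizeRule = WinsorizeRule()) -> np.ndarray:
    """Single-pass winsorization; fences and replacements from the input."""
    x = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    lo_fence = q1 - rule.k * iqr
    hi_fence = q3 + rule.k * iqr
    lo_rep, hi_rep = np.percentile(x, [rule.lower_pct, rule.upper_pct])
    out = x.copy()
    out[x < lo_fence] = lo_rep
    out[x > hi_fence] = hi_rep
    return out
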