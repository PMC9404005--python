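"""Retention factors, two-point retention-time correction, and LSS extrapolation.

Isocratic reversed-phase retention follows the linear solvent strength (LSS)
relation over the usual methanol range:

    log10 k = log k_w - S * phi

where phi is the methanol volume fraction, S the solvent-strength slope and
log k_w the extrapolated retention factor in 100% aqueous mobile phase —
the chromatographic lipophilicity index consumed by the QSRR models.
Retention factors come from k = (t_R - t_0) / t_0 with t_0 the dead time
(uracil marker). Observed retention times may first be recalibrated with the
double-point retention-time correction (DP-RTC): the affine map fixed by two
reference compounds' observed vs nominal times.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    FitQualityWarning,
    LowPointCountWarning,
    RetentionDomainError,
    SingularDesignError,
)

__all__ = [
    "Mode",
    "RetentionMeasurement",
    "LSSFit",
    "retention_factor",
    "dp_rtc_correct",
    "average_replicates",
    "fit_lss",
    "read_retention_table",
]

#: Residual sum of squares below which a fit is treated as exact (r2 := 1).
_EXACT_RSS = 1e-20


class Mode(str, Enum):
    """Chromatographic mode: ion suppression or ion pair."""

    IS = "IS"
    IP = "IP"


@dataclass(frozen=True)
class RetentionMeasurement:
    """One (compound, mode, phi) retention observation, times in minutes."""

    compound_id: str
    mode: Mode
    phi: float
    t_r: float
    t_0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(
                f"{self.compound_id}: phi must be a volume fraction in [0, 1], "
                f"got {self.phi}"
            )
        if self.t_0 <= 0.0:
            raise RetentionDomainError(
                f"{self.compound_id}: dead time t_0 must be positive, got {self.t_0}"
            )
        if self.t_r < self.t_0:
            raise RetentionDomainError(
                f"{self.compound_id}: t_r ({self.t_r}) < t_0 ({self.t_0}); "
                "solute elutes before the dead-time marker"
            )


@dataclass(frozen=True)
class LSSFit:
    """Per-solute LSS line: log10 k = log_kw - s * phi."""

    compound_id: str
    mode: Mode
    log_kw: float
    s: float
    r2: float
    n_points: int

    def to_json(self) -> str:
        d = asdict(self)
        d["mode"] = self.mode.value
        return json.dumps(d)


def retention_factor(t_r: float, t_0: float, denominator: str = "t0") -> float:
    """Retention factor k = (t_R - t_0) / t_0.

    ``denominator="tr"`` switches to (t_R - t_0) / t_R for replication of
    sources that print that variant; the standard definition is the default
    and is what extrapolated log k_w values assume.
    """
    if denominator not in ("t0", "tr"):
        raise ValueError(f"denominator must be 't0' or 'tr', got {denominator!r}")
    if t_0 <= 0.0:
        raise RetentionDomainError(f"t_0 must be positive, got {t_0}")
    if t_r < t_0:
        raise RetentionDomainError(
            f"t_r ({t_r}) < t_0 ({t_0}): unretained relative to dead time"
        )
    return (t_r - t_0) / (t_0 if denominator == "t0" else t_r)


def dp_rtc_correct(
    t_obs: float,
    ref_obs: tuple[float, float],
    ref_nominal: tuple[float, float],
) -> float:
    """Double-point retention-time correction.

    Solves the affine map t -> a*t + b that sends each reference compound's
    observed time to its nominal time, and applies it to ``t_obs``. Both
    anchors are reproduced exactly by construction.
    """
    (o1, o2), (n1, n2) = ref_obs, ref_nominal
    if math.isclose(o1, o2, rel_tol=0.0, abs_tol=1e-12):
        raise SingularDesignError(
            f"reference observed times coincide ({o1} min); the two-anchor "
            "affine correction is undefined"
        )
    a = (n2 - n1) / (o2 - o1)
    b = n1 - a * o1
    return a * t_obs + b


def average_replicates(
    measurements: Iterable[RetentionMeasurement],
) -> list[RetentionMeasurement]:
    """Average replicate injections at the (compound, mode, phi) level.

    Retention protocols replicate each injection (typically >= 3); the LSS
    fit consumes the per-condition mean of t_r (and of t_0, which should be
    constant within a condition).
    """
    groups: dict[tuple[str, Mode, float], list[RetentionMeasurement]] = defaultdict(list)
    order: list[tuple[str, Mode, float]] = []
    for m in measurements:
        key = (m.compound_id, m.mode, m.phi)
        if key not in groups:
            order.append(key)
        groups[key].append(m)
    out = []
    for key in order:
        grp = groups[key]
        out.append(
            RetentionMeasurement(
                compound_id=key[0],
                mode=key[1],
                phi=key[2],
                t_r=float(np.mean([m.t_r for m in grp])),
                t_0=float(np.mean([m.t_0 for m in grp])),
            )
        )
    return out


def fit_lss(
    measurements: Sequence[RetentionMeasurement],
    r2_gate: float = 0.99,
    denominator: str = "t0",
) -> LSSFit:
    """Ordinary least squares of log10 k on phi for one compound and mode.

    Returns the extrapolated ``log_kw`` (intercept at phi = 0) and the
    positive-convention slope ``s``. Quality handling follows measurement
    practice: r2 below ``r2_gate`` warns rather than rejects, so borderline
    solutes stay inspectable; fewer than 4 points warns (two distinct points
    still define a line, with r2 = 1 by the saturated-fit convention).
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements supplied")
    ids = {m.compound_id for m in ms}
    modes = {m.mode for m in ms}
    if len(ids) != 1 or len(modes) != 1:
        raise ValueError(
            f"measurements must share one compound and mode, got ids={sorted(ids)}, "
            f"modes={sorted(m.value for m in modes)}"
        )
    phis = np.array([m.phi for m in ms])
    if len(np.unique(phis)) < 2:
        raise SingularDesignError(
            f"{ms[0].compound_id}: need >= 2 distinct phi levels, got "
            f"{np.unique(phis).tolist()}"
        )
    ks = []
    for m in ms:
        k = retention_factor(m.t_r, m.t_0, denominator=denominator)
        if k <= 0.0:
            raise RetentionDomainError(
                f"{m.compound_id} at phi={m.phi}: k={k} is not positive; "
                "log k undefined (unretained solute)"
            )
        ks.append(k)
    logk = np.log10(ks)

    if len(ms) < 4:
        warnings.warn(
            f"{ms[0].compound_id} ({ms[0].mode.value}): only {len(ms)} retention "
            "points; >= 4 methanol fractions are recommended for LSS extrapolation",
            LowPointCountWarning,
            stacklevel=2,
        )

    res = stats.linregress(phis, logk)
    fitted = res.intercept + res.slope * phis
    rss = float(np.sum((logk - fitted) ** 2))
    tss = float(np.sum((logk - logk.mean()) ** 2))
    if rss < _EXACT_RSS:
        r2 = 1.0  # exact (incl. saturated two-point) fits
    elif tss == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - rss / tss
    if r2 < r2_gate:
        warnings.warn(
            f"{ms[0].compound_id} ({ms[0].mode.value}): LSS fit r2={r2:.4f} below "
            f"the {r2_gate} gate; inspect the log k-phi points",
            FitQualityWarning,
            stacklevel=2,
        )
    return LSSFit(
        compound_id=ms[0].compound_id,
        mode=ms[0].mode,
        log_kw=float(res.intercept),
        s=float(-res.slope),
        r2=float(r2),
        n_points=len(ms),
    )


def read_retention_table(path: str | Path) -> list[RetentionMeasurement]:
    """Read raw retention observations from CSV.

    Columns: ``compound_id,mode,phi,t_r,t_0`` with optional
    ``ref1_obs,ref1_nom,ref2_obs,ref2_nom``; when the reference columns are
    present the DP-RTC affine correction is applied to t_r before anything
    else. phi is a fraction (0.30), not a percentage.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = ["compound_id", "mode", "phi", "t_r", "t_0"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    ref_cols = ["ref1_obs", "ref1_nom", "ref2_obs", "ref2_nom"]
    has_refs = all(c in df.columns for c in ref_cols)
    out = []
    for _, row in df.iterrows():
        t_r = float(row["t_r"])
        if has_refs and not any(pd.isna(row[c]) for c in ref_cols):
            t_r = dp_rtc_correct(
                t_r,
                (float(row["ref1_obs"]), float(row["ref2_obs"])),
                (float(row["ref1_nom"]), float(row["ref2_nom"])),
            )
        out.append(
            RetentionMeasurement(
                compound_id=str(row["compound_id"]),
                mode=Mode(str(row["mode"])),
                phi=float(row["phi"]),
                t_r=t_r,
                t_0=float(row["t_0"]),
            )
        )
    return out
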