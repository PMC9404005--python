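"""Synthetic compound sets and retention data with known ground truth.

The generator emulates the statistical structure the pipeline assumes, so
every stage — LSS extrapolation, OLS fitting, the cascade — can be exercised
and its parameter recovery quantified without any measured data:

* descriptors drawn over the spans of the reference table (log k_w in
  [0.2, 5.7], n_e in [-2, 0], A in [0, 1.6], B in [0, 1.9]),
* a known linear log D structure over (log k_w, n_e, A, B) with Gaussian
  residual noise,
* per-solute linear log k-phi retention with Gaussian retention-time noise
  on a phi grid of at least four methanol fractions.

It does *not* emulate ion-pair equilibria, silanol secondary interactions or
pH-dependent retention — only the linear model the analysis fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import CompoundClass, CompoundRecord, CompoundSet
from .retention import Mode, RetentionMeasurement

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_compounds",
    "generate_retention",
]

#: Default true coefficients for the simulated log D structure; magnitudes
#: mirror the fitted mixed-model-group relation on this column system.
DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "intercept": 0.1,
    "log_kw": 1.1,
    "n_e": 2.4,
    "a": 0.1,
    "b": -1.6,
}

#: Descriptor spans mirroring the reference table.
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = {
    "log_kw": (0.2, 5.7),
    "n_e": (-2.0, 0.0),
    "a": (0.0, 1.6),
    "b": (0.0, 1.9),
}

#: Typical methanol solvent-strength slopes for small aromatics.
DEFAULT_S_RANGE = (2.0, 5.0)


@dataclass(frozen=True)
class SyntheticConfig:
    n_compounds: int = 50
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    descriptor_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    s_range: tuple[float, float] = DEFAULT_S_RANGE
    noise_sd_logd: float = 0.1
    phi_grid: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80)
    n_replicates: int = 1
    noise_sd_tr: float = 0.01  # minutes
    t_0: float = 1.0  # minutes
    min_k: float = 1e-3  # below this a phi level counts as unretained
    sampling: str = "uniform"  # or "bootstrap" from a template set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_logd < 0 or self.noise_sd_tr < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if len(set(self.phi_grid)) < 4:
            raise ValueError(
                "phi_grid needs >= 4 distinct methanol fractions (measurement "
                "protocols require at least four)"
            )
        if self.sampling not in ("uniform", "bootstrap"):
            raise ValueError(f"sampling must be 'uniform' or 'bootstrap'")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a generated set, for recovery tests."""

    coefficients: Mapping[str, float]
    log_kw: Mapping[str, float]
    s: Mapping[str, float]
    log_d_noiseless: Mapping[str, float]
    unretained: tuple[str, ...] = ()


def _rng(config: SyntheticConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def generate_compounds(
    config: SyntheticConfig,
    template: CompoundSet | None = None,
) -> tuple[CompoundSet, SyntheticTruth]:
    """Draw a compound set with a known linear log D structure.

    Descriptors are sampled uniformly over ``descriptor_ranges`` (or
    bootstrap-resampled from ``template`` rows when ``sampling="bootstrap"``),
    the observed ``log_d_ref`` is the true linear combination plus Gaussian
    noise, and per-compound LSS slopes are drawn for downstream retention
    simulation. Deterministic under a fixed seed.
    """
    rng = _rng(config)
    n = config.n_compounds
    if config.sampling == "bootstrap":
        if template is None:
            raise ValueError("bootstrap sampling requires a template CompoundSet")
        pool = [
            r
            for r in template.records
            if None not in (r.log_kw_ip, r.n_e, r.a, r.b)
        ]
        picks = rng.integers(0, len(pool), size=n)
        log_kw = np.array([pool[i].log_kw_ip for i in picks])
        n_e = np.array([pool[i].n_e for i in picks])
        a = np.array([pool[i].a for i in picks])
        b = np.array([pool[i].b for i in picks])
    else:
        spans = config.descriptor_ranges
        if all(lo == hi for lo, hi in spans.values()):
            warnings.warn(
                "all descriptor ranges are degenerate (min == max); the "
                "regression design will be singular",
                UserWarning,
                stacklevel=2,
            )
        log_kw = rng.uniform(*spans["log_kw"], size=n)
        n_e = rng.uniform(*spans["n_e"], size=n)
        a = rng.uniform(*spans["a"], size=n)
        b = rng.uniform(*spans["b"], size=n)
    coef = config.true_coefficients
    noiseless = (
        coef["intercept"]
        + coef["log_kw"] * log_kw
        + coef["n_e"] * n_e
        + coef["a"] * a
        + coef["b"] * b
    )
    log_d = noiseless + rng.normal(0.0, config.noise_sd_logd, size=n)
    s = rng.uniform(*config.s_range, size=n)

    records = []
    for i in range(n):
        cid = f"SYN{i + 1}"
        records.append(
            CompoundRecord(
                id=cid,
                name=f"synthetic solute {i + 1}",
                compound_class=(
                    CompoundClass.NEUTRAL if n_e[i] == 0.0 else CompoundClass.WEAK_ACID
                ),
                log_d_ref=float(log_d[i]),
                log_kw_is=float(log_kw[i]),
                log_kw_ip=float(log_kw[i]),
                n_e=float(n_e[i]),
                a=float(a[i]),
                b=float(b[i]),
            )
        )
    truth = SyntheticTruth(
        coefficients=dict(coef),
        log_kw={f"SYN{i + 1}": float(log_kw[i]) for i in range(n)},
        s={f"SYN{i + 1}": float(s[i]) for i in range(n)},
        log_d_noiseless={f"SYN{i + 1}": float(noiseless[i]) for i in range(n)},
    )
    return CompoundSet(tuple(records), ph=7.0), truth


def generate_retention(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    mode: Mode = Mode.IP,
) -> tuple[list[RetentionMeasurement], tuple[str, ...]]:
    """Simulate isocratic retention times from each solute's LSS line.

    For every phi on the grid, t_R = t_0 * (1 + 10**(log_kw - s*phi)) plus
    Gaussian instrument noise, floored just above the dead time. Grid points
    where the noiseless k falls below ``min_k`` are dropped (emulating
    effectively unretained conditions); solutes with no surviving phi are
    returned in the second element and excluded from the measurement list.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of compound draw
    measurements: list[RetentionMeasurement] = []
    unretained: list[str] = []
    floor = config.t_0 * (1.0 + 1e-6)
    for cid in truth.log_kw:
        kw, slope = truth.log_kw[cid], truth.s[cid]
        kept = [phi for phi in config.phi_grid if 10.0 ** (kw - slope * phi) >= config.min_k]
        if not kept:
            unretained.append(cid)
            continue
        for phi in kept:
            t_ideal = config.t_0 * (1.0 + 10.0 ** (kw - slope * phi))
            for _ in range(config.n_replicates):
                t_r = t_ideal + rng.normal(0.0, config.noise_sd_tr)
                measurements.append(
                    RetentionMeasurement(
                        compound_id=cid,
                        mode=mode,
                        phi=phi,
                        t_r=max(t_r, floor),
                        t_0=config.t_0,
                    )
                )
    return measurements, tuple(unretained)
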