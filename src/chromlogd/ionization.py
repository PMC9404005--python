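"""pH correction of lipophilicity: log P -> apparent log D for monoprotic acids.

For a monoprotic acid HA with dissociation constant Ka, only the neutral
fraction partitions appreciably into n-octanol, so the apparent distribution
coefficient at a given pH is

    log D(pH) = log P - log10(1 + 10**(pH - pKa))

For pH << pKa the correction vanishes (log D -> log P); around pH = pKa the
solute is half ionized and log D = log P - log10(2); for pH >> pKa log D
falls one unit per pH unit. Neutral solutes (no pKa in the working range)
have log D = log P identically.

Only the acid branch is implemented: in this workflow bases and polyprotic
species never need a computed log D (their values come from the retention
models), so those branches raise rather than silently returning the wrong
species correction.
"""

from __future__ import annotations

import math

__all__ = ["logd_at_ph"]


def logd_at_ph(
    log_p: float,
    pka: float | None = None,
    ph: float = 7.0,
    species: str = "acid",
) -> float:
    """Apparent distribution coefficient log D at ``ph``.

    Parameters
    ----------
    log_p : intrinsic (neutral-form) octanol/water partition coefficient, log10.
    pka : acid dissociation constant, log10 scale; ``None`` means the solute
        is neutral at any relevant pH and ``log_p`` is returned unchanged.
    ph : aqueous-phase pH of the mobile phase (the wwpH convention: measured
        on the aqueous buffer before mixing with organic modifier).
    species : only ``"acid"`` (monoprotic) is supported.
    """
    if not math.isfinite(log_p):
        raise ValueError(f"log_p must be finite, got {log_p!r}")
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"ph must be within [0, 14], got {ph!r}")
    if pka is None:
        return log_p
    if species != "acid":
        raise NotImplementedError(
            f"species {species!r}: only the monoprotic acid correction is "
            "implemented; bases and polyprotic species take their log D from "
            "the retention models instead"
        )
    if not math.isfinite(pka):
        raise ValueError(f"pka must be finite or None, got {pka!r}")
    delta = ph - pka
    if delta > 300.0:  # 10**delta would overflow; correction is exactly delta there
        return log_p - delta
    # log1p keeps full precision when the ionized fraction is tiny (ph << pka)
    return log_p - math.log1p(10.0**delta) / math.log(10.0)
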