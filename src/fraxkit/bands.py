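"""Five-year age bands used throughout the pipeline.

Bands are half-open [40,45) ... [75,80) plus the open band [80, inf),
written "40-44" ... "75-79", "80+". Age is completed years at the
admission date. The open band's nominal midpoint is 85 (the value used
when a single representative age is needed for an "80+" stratum).
"""

from __future__ import annotations

AGE_FLOOR = 40
OPEN_BAND = "80+"
OPEN_BAND_MIDPOINT = 85.0

AGE_BANDS: tuple[str, ...] = (
    "40-44", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", OPEN_BAND,
)


def band_bounds(band: str) -> tuple[int, int | None]:
    """Return (lower, upper_exclusive) for a band; upper is None for '80+'."""
    if band == OPEN_BAND:
        return 80, None
    lo_s, hi_s = band.split("-")
    return int(lo_s), int(hi_s) + 1


def band_of(age: float) -> str:
    """Band containing a completed age; raises for ages below the floor."""
    if age < AGE_FLOOR:
        raise ValueError(f"age {age} is below the {AGE_FLOOR}-year floor")
    if age >= 80:
        return OPEN_BAND
    lo = int(age) - (int(age) - AGE_FLOOR) % 5
    return f"{lo}-{lo + 4}"


def band_midpoint(band: str) -> float:
    lo, hi = band_bounds(band)
    if hi is None:
        return OPEN_BAND_MIDPOINT
    return (lo + hi) / 2.0
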