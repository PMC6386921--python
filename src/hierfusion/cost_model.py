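"""Per-frame online computation cost of the two fusion architectures.

The direct-fusion baseline pipeline processes every frame with two optical
flow extractions, three convolutional-network passes and up to four
recurrent passes, giving the per-frame time bound

    2*t_OF + 3*t_C1  <=  t1  <=  4*t_L1 + 2*t_OF + 3*t_C1.

The hierarchical pipeline runs one recurrent pass for the motion-state
routing and one image-network pass in the routed group, giving

    t_C2  <=  t2  <=  t_L2 + t_CL.

All constants are milliseconds per invocation, measured externally and
treated as inputs here (this module never times anything). With the
published constants (t_OF = 12.2, t_C1 = 9.709, t_L1 = 0.659, t_C2 = 2.395,
t_L2 = 0.659, t_CL = 4.103) the bounds are 53.527 <= t1 <= 56.163 and
2.395 <= t2 <= 4.762.

Sustainable frame rates follow as 1000 / t. Raw float rates are returned;
any rounding to integer fps is left to the caller because no single
rounding convention reproduces all published integer figures.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostParams", "t1_bounds", "t2_bounds", "fps_range", "PUBLISHED_PARAMS"]


@dataclass(frozen=True)
class CostParams:
    """Per-component timing constants in milliseconds.

    t_OF: optical-flow extraction per frame (baseline only).
    t_C1 / t_L1: baseline conv-net / recurrent passes.
    t_C2: image network pass of the hierarchical pipeline.
    t_L2: motion-routing recurrent pass.
    t_CL: combined conv+recurrent image-sequence pass.
    """

    t_OF: float = 0.0
    t_C1: float = 0.0
    t_L1: float = 0.0
    t_C2: float = 0.0
    t_L2: float = 0.0
    t_CL: float = 0.0

    def __post_init__(self) -> None:
        for name in ("t_OF", "t_C1", "t_L1", "t_C2", "t_L2", "t_CL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: The published measured constants (ms).
PUBLISHED_PARAMS = CostParams(
    t_OF=12.2, t_C1=9.709, t_L1=0.659, t_C2=2.395, t_L2=0.659, t_CL=4.103
)


def t1_bounds(p: CostParams) -> tuple[float, float]:
    """Per-frame cost bounds (ms) of the direct-fusion baseline pipeline."""
    lower = 2.0 * p.t_OF + 3.0 * p.t_C1
    upper = lower + 4.0 * p.t_L1
    return lower, upper


def t2_bounds(p: CostParams) -> tuple[float, float]:
    """Per-frame cost bounds (ms) of the hierarchical pipeline.

    Raises if the parameters would invert the bounds (upper < lower), which
    signals inconsistent measurements rather than a valid regime.
    """
    lower = p.t_C2
    upper = p.t_L2 + p.t_CL
    if upper < lower:
        raise ValueError(
            f"inconsistent cost params: upper bound {upper} ms < lower bound {lower} ms"
        )
    return lower, upper


def fps_range(t_lower: float, t_upper: float) -> tuple[float, float]:
    """Sustainable frame-rate interval (fps) from a per-frame cost interval (ms).

    The slowest per-frame time bounds the minimum rate and vice versa:
    fps_min = 1000 / t_upper, fps_max = 1000 / t_lower. Raw floats.
    """
    if t_lower <= 0 or t_upper <= 0:
        raise ValueError("per-frame times must be positive")
    if t_upper < t_lower:
        raise ValueError("t_upper must be >= t_lower")
    return 1000.0 / t_upper, 1000.0 / t_lower
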