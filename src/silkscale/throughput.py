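"""Production-rate arithmetic for semi-batch and microfluidic manufacture.

Steady-state, feed-limited basis: the headline rate counts only the time
the precursor is actually flowing.  Purification (centrifugation/wash)
downtime, which in practice reduces both formats' rates substantially,
can be modelled with ``cycle_overhead``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProcessSpec", "production_rate", "daily_output"]


@dataclass(frozen=True)
class ProcessSpec:
    """Nanoprecipitation process description.

    silk_concentration
        Precursor concentration in % w/v (g per 100 mL of precursor).
    antisolvent_ratio
        Antisolvent:precursor volume ratio (e.g. 5.0 for 5:1); must
        exceed 2 (at least 200% v/v antisolvent excess).
    mode
        ``"semibatch"`` — ``precursor_feed_rate`` (mL min⁻¹) feeds a batch
        of ``total_volume`` (mL, precursor + antisolvent);
        ``"microfluidic"`` — ``total_flow_rate`` (mL min⁻¹) through each
        of ``n_chips`` parallel chips.
    yield_fraction
        Recovered mass over fed silk mass, in [0, 1].
    """

    silk_concentration: float
    antisolvent_ratio: float
    yield_fraction: float
    mode: str = "semibatch"
    precursor_feed_rate: float | None = None
    total_flow_rate: float | None = None
    n_chips: int = 1
    total_volume: float | None = None

    def __post_init__(self) -> None:
        if self.silk_concentration <= 0:
            raise ValueError("silk_concentration must be > 0")
        if not self.antisolvent_ratio > 2:
            raise ValueError(
                "antisolvent_ratio must exceed 2 (>= 200% v/v antisolvent excess)"
            )
        if not 0 <= self.yield_fraction <= 1:
            raise ValueError("yield_fraction must lie in [0, 1]")
        if self.mode not in ("semibatch", "microfluidic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "semibatch" and not self.precursor_feed_rate:
            raise ValueError("semibatch mode needs precursor_feed_rate > 0")
        if self.mode == "microfluidic" and not self.total_flow_rate:
            raise ValueError("microfluidic mode needs total_flow_rate > 0")
        if self.n_chips < 1:
            raise ValueError("n_chips must be >= 1")


def production_rate(spec: ProcessSpec, cycle_overhead: float = 0.0) -> float:
    """Nanoparticle production rate in g h⁻¹.

    Semi-batch: the precursor fraction of the batch, total/(1+ratio), is
    fed at ``precursor_feed_rate``; rate = feed rate × concentration ×
    yield.  (Feed-limited, so the batch volume cancels.)  Microfluidic:
    precursor flow = total flow/(1+ratio) per chip, times ``n_chips``.

    ``cycle_overhead`` is extra non-productive time per unit feed time
    (e.g. 1.5 = purification takes 1.5× the feed time), scaling the rate
    by 1/(1+overhead).
    """
    if cycle_overhead < 0:
        raise ValueError("cycle_overhead must be >= 0")
    conc_g_per_ml = spec.silk_concentration / 100.0
    if spec.mode == "semibatch":
        precursor_per_min = spec.precursor_feed_rate
        chips = 1
    else:
        precursor_per_min = spec.total_flow_rate / (1.0 + spec.antisolvent_ratio)
        chips = spec.n_chips
    rate = precursor_per_min * 60.0 * conc_g_per_ml * spec.yield_fraction * chips
    return rate / (1.0 + cycle_overhead)


def daily_output(rate_g_per_h: float) -> float:
    """Continuous 24-h output in g day⁻¹."""
    if rate_g_per_h < 0:
        raise ValueError("rate must be >= 0")
    return 24.0 * rate_g_per_h
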