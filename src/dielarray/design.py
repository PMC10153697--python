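"""Sample designs for diel (light-dark cycle) time-series experiments.

Time points are labelled by hours into the light (``L``) or dark (``D``)
period, with a leading day index for the second and later light-dark
cycles (``2L3`` = 3 h into the light period of day 2).  The sunrise
instant carries the label ``D12`` for a 12 h night: it is the end of the
dark period, not the start of the light one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "SampleDesign",
    "make_design",
    "phase_label",
    "label_cycle_hour",
    "strip_day_prefix",
    "subset_timepoints",
]


@dataclass(frozen=True)
class SampleDesign:
    """One collected sample: a time point plus a replicate index."""

    sample_id: str
    clock_hour: float          # local clock time in [0, 24)
    phase_label: str           # e.g. "L3", "D12", "2L6"
    day_index: int             # light-dark cycle number, 1-based
    replicate: int             # 1-based
    hours_since_start: float


def _fmt_hours(h: float) -> str:
    return str(int(h)) if float(h).is_integer() else f"{h:g}"


def phase_label(clock_hour: float, sunrise_hour: float, daylight: float,
                day_index: int = 1) -> str:
    """Label a clock hour by hours into the light or dark period.

    ``s = (clock - sunrise) mod 24``: labels are ``L{s}`` for
    ``0 < s <= daylight`` and ``D{s - daylight mod 24}`` otherwise, so the
    sunrise instant itself (s = 0) maps to ``D{night length}``.
    """
    s = (clock_hour - sunrise_hour) % 24.0
    if 0.0 < s <= daylight:
        core = f"L{_fmt_hours(s)}"
    else:
        core = f"D{_fmt_hours((s - daylight) % 24.0)}"
    prefix = "" if day_index <= 1 else str(day_index)
    return prefix + core


def strip_day_prefix(label: str) -> str:
    """Drop a leading day index: ``2L6`` -> ``L6``, ``L6`` -> ``L6``."""
    return label.lstrip("0123456789")


def label_cycle_hour(label: str, daylight: float = 12.0) -> float:
    """Position of a phase label on the 24 h light-dark clock.

    Hours since sunrise: ``L{x}`` -> x, ``D{x}`` -> daylight + x.  The day
    prefix is ignored (the clock is circular).
    """
    core = strip_day_prefix(label)
    kind, hours = core[0], float(core[1:])
    if kind == "L":
        return hours % 24.0
    if kind == "D":
        return (daylight + hours) % 24.0
    raise ValueError(f"malformed phase label: {label!r}")


def make_design(n_timepoints: int, interval: float, n_replicates: int,
                sunrise_hour: float, daylight: float) -> list[SampleDesign]:
    """Build a diel sampling design starting one interval after sunrise.

    The first time point falls ``interval`` hours into the light period
    (label ``L{interval}``), matching field campaigns that begin shortly
    after dawn; subsequent points step by ``interval``.  A new day index
    starts every 24 h after the first sunrise, so a 10-point, 3 h design
    with a 12 h day reads L3 ... D9, 2D12, 2L3, 2L6.

    Returns one :class:`SampleDesign` per (time point, replicate),
    ordered by time then replicate.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if n_timepoints < 1:
        raise ValueError("need at least one time point")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    design: list[SampleDesign] = []
    for i in range(n_timepoints):
        since_sunrise = interval + i * interval   # first point is L{interval}
        clock = (sunrise_hour + since_sunrise) % 24.0
        # sunrise instants (since_sunrise = 24, 48, ...) open the new day
        day = int(since_sunrise // 24.0) + 1
        label = phase_label(clock, sunrise_hour, daylight, day_index=day)
        for rep in range(1, n_replicates + 1):
            design.append(SampleDesign(
                sample_id=f"{label}.{rep}",
                clock_hour=clock,
                phase_label=label,
                day_index=day,
                replicate=rep,
                hours_since_start=i * interval,
            ))
    return design


def subset_timepoints(design: list[SampleDesign],
                      labels: list[str]) -> list[SampleDesign]:
    """Order-preserving restriction of a design to the given phase labels."""
    known = {d.phase_label for d in design}
    unknown = [lb for lb in labels if lb not in known]
    if unknown:
        raise ValueError(f"labels not in design: {unknown}")
    keep = set(labels)
    return [d for d in design if d.phase_label in keep]
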