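"""The direct, timing-based over-ranging estimator.

The stationary bore dosimeter times the beam-on interval T (10%-level
crossing pair); the two table dosimeters time their own transit delay,
which over the known separation gives the table speed v.  The total
length irradiated is then

* ``v T + W`` under the *exposure* convention (film-verified: the beam
  exposes one half collimation width W/2 beyond each end of the table
  translation), or
* ``v T`` under the *translation* convention (what a scanner console
  reports as displacement).

Subtracting the operator-selected VOI length yields the over-ranging
length.  The two conventions differ by exactly one collimation width;
conflating them is what makes raw console readings overestimate the
over-range by half a collimation at each comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .edge_analysis import beam_on_duration, detect_edges, table_speed_from_traces
from .errors import InconsistentGeometryError
from .scan_model import DosimeterLayout
from .simulator import DosimeterTrace
from .uncertainty import UncertaintyBudget, budget_total

__all__ = ["OverrangeResult", "direct_overrange", "one_dosimeter_overrange"]

_CONVENTIONS = ("exposure", "translation")


@dataclass
class OverrangeResult:
    """An over-ranging length estimate with its provenance.

    ``includes_penumbra`` records whether the total length follows the
    exposure convention (True) or the translation convention (False).
    ``degenerate`` flags zero/negative lengths instead of raising, so
    parameter sweeps do not abort.  ``pitch`` is optional metadata used
    when grouping results for method comparisons.
    """

    length: float  # mm
    total_exposed_length: float  # mm
    voi_length: float  # mm
    table_speed: float  # mm/s
    beam_on_duration: float  # s
    uncertainty: float  # mm
    method: str  # direct | direct_one_dosimeter | dose_slope | console | console_adjusted
    includes_penumbra: bool = True
    degenerate: bool = False
    pitch: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "length_mm": self.length,
            "total_exposed_length_mm": self.total_exposed_length,
            "voi_length_mm": self.voi_length,
            "table_speed_mm_s": self.table_speed,
            "beam_on_duration_s": self.beam_on_duration,
            "uncertainty_mm": self.uncertainty,
            "method": self.method,
            "includes_penumbra": self.includes_penumbra,
            "degenerate": self.degenerate,
            "pitch": self.pitch,
            "diagnostics": self.diagnostics,
        }


def _assemble(
    speed: float,
    duration: float,
    voi_length: float,
    collimation: float,
    convention: str,
    method: str,
    uncertainty: float,
    sample_period: float,
) -> OverrangeResult:
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if voi_length <= 0:
        raise ValueError("voi_length must be positive")
    # The exposure (translation + one collimation width) must at least
    # cover the VOI; a bore plateau too short for the VOI transit means
    # the traces and the declared geometry do not describe the same scan.
    exposure = speed * duration + collimation
    if exposure < voi_length - 2.0 * speed * sample_period:
        raise InconsistentGeometryError(
            f"bore beam-on time ({duration:.3f} s) is too short to cover the "
            f"declared {voi_length:.0f} mm VOI at {speed:.1f} mm/s"
        )
    total = speed * duration + (collimation if convention == "exposure" else 0.0)
    length = total - voi_length
    return OverrangeResult(
        length=length,
        total_exposed_length=total,
        voi_length=voi_length,
        table_speed=speed,
        beam_on_duration=duration,
        uncertainty=uncertainty,
        method=method,
        includes_penumbra=(convention == "exposure"),
        degenerate=length <= 0,
    )


def direct_overrange(
    bore: DosimeterTrace,
    table_1: DosimeterTrace,
    table_2: DosimeterTrace,
    layout: DosimeterLayout,
    voi_length: float,
    collimation: float,
    convention: str = "exposure",
    *,
    threshold_fraction: float = 0.10,
    edge_mode: str = "lead",
    interpolate: bool = True,
    budget: UncertaintyBudget | None = None,
) -> OverrangeResult:
    """Estimate the over-ranging length from the three dosimeter traces.

    ``table_1`` must be the dosimeter the beam reaches first.  The VOI
    length comes from the scout/layout metadata, not from the traces: the
    table dosimeters only measure the speed and the bore trace the
    beam-on time.
    """
    e1 = detect_edges(table_1, threshold_fraction, interpolate=interpolate)
    e2 = detect_edges(table_2, threshold_fraction, interpolate=interpolate)
    speed = table_speed_from_traces(e1, e2, layout.separation, edge_mode)
    bore_edges = detect_edges(bore, threshold_fraction, interpolate=interpolate)
    duration = beam_on_duration(bore_edges)
    budget = budget if budget is not None else UncertaintyBudget()
    budget = replace(budget, table_speed=speed)
    unc = budget_total(budget, "three_dosimeter").total_mm
    result = _assemble(
        speed,
        duration,
        voi_length,
        collimation,
        convention,
        "direct",
        unc,
        bore.sample_period,
    )
    result.diagnostics = {
        "threshold_fraction": threshold_fraction,
        "edge_mode": edge_mode,
        "interpolate": interpolate,
        "bore_edges": (bore_edges.t_lead, bore_edges.t_trail),
        "table_lead_delay_s": e2.t_lead - e1.t_lead,
    }
    return result


def one_dosimeter_overrange(
    bore: DosimeterTrace,
    console_speed: float,
    voi_length: float,
    collimation: float,
    convention: str = "exposure",
    *,
    threshold_fraction: float = 0.10,
    interpolate: bool = True,
    budget: UncertaintyBudget | None = None,
) -> OverrangeResult:
    """Over-ranging from the bore trace alone, with a console-supplied speed.

    Identical arithmetic to :func:`direct_overrange`, but the table speed
    is taken from the console, which introduces a co-dependence on the
    console's distance calibration; the uncertainty budget therefore uses
    the 1-2 mm QC allowance rather than the measured-speed terms.
    """
    if console_speed <= 0:
        raise ValueError("console_speed must be positive")
    bore_edges = detect_edges(bore, threshold_fraction, interpolate=interpolate)
    duration = beam_on_duration(bore_edges)
    budget = budget if budget is not None else UncertaintyBudget()
    budget = replace(budget, table_speed=console_speed)
    scan_length = console_speed * duration + collimation
    unc = budget_total(budget, "one_dosimeter", scan_length=scan_length).total_mm
    result = _assemble(
        console_speed,
        duration,
        voi_length,
        collimation,
        convention,
        "direct_one_dosimeter",
        unc,
        bore.sample_period,
    )
    result.diagnostics = {
        "threshold_fraction": threshold_fraction,
        "interpolate": interpolate,
        "bore_edges": (bore_edges.t_lead, bore_edges.t_trail),
        "console_speed_mm_s": console_speed,
    }
    return result
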