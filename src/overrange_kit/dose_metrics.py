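"""Clinical dose metrics: DLP and the extra-dose fraction of over-ranging.

DLP (dose-length product, mGy.cm) is CTDIvol times irradiated length; it
is proportional to scan length, so over-ranging increases DLP without
changing CTDIvol.  CTDIvol is an input constant from the console or
published protocol tables, never derived from traces; the known
inaccuracy of CTDI at scan edges is accepted as a first approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DoseReport", "dlp", "dose_report"]


@dataclass(frozen=True)
class DoseReport:
    """DLP split into its VOI and over-ranging parts."""

    voi_dlp: float  # mGy.cm
    overrange_dlp: float  # mGy.cm
    total_dlp: float  # mGy.cm
    extra_fraction: float  # overrange_dlp / voi_dlp

    def to_dict(self) -> dict:
        return {
            "voi_dlp_mgycm": self.voi_dlp,
            "overrange_dlp_mgycm": self.overrange_dlp,
            "total_dlp_mgycm": self.total_dlp,
            "extra_fraction": self.extra_fraction,
        }


def dlp(ctdi_vol: float, length: float) -> float:
    """Dose-length product, mGy.cm, for a length given in mm."""
    if ctdi_vol < 0 or length < 0:
        raise ValueError("ctdi_vol and length must be non-negative")
    return ctdi_vol * length / 10.0


def dose_report(ctdi_vol: float, voi_length: float, overrange_length: float) -> DoseReport:
    """Split the scan's DLP into VOI and over-ranging contributions.

    ``voi_length`` must be positive for the extra-dose fraction to be
    defined.
    """
    if voi_length <= 0:
        raise ValueError("voi_length must be positive (extra_fraction undefined)")
    if overrange_length < 0:
        raise ValueError("overrange_length must be non-negative")
    voi = dlp(ctdi_vol, voi_length)
    over = dlp(ctdi_vol, overrange_length)
    return DoseReport(
        voi_dlp=voi,
        overrange_dlp=over,
        total_dlp=voi + over,
        extra_fraction=overrange_length / voi_length,
    )
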