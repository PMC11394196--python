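"""Printed-sheet layout description.

A paper ECG has a fixed print format: each horizontal strip (row band)
carries a calibration pulse followed by one or more leads recorded back to
back, and the sheet as a whole is printed at a paper speed (mm/s) and
sensitivity (mm/mV). The digitizer cannot discover this format from the
pixels alone, so it is supplied as a :class:`LeadLayout`.

Band and span positions are stored as fractions of the rectified page
(0..1, origin top-left, y downward) so one layout file serves any image
resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "LeadSpan",
    "RowBand",
    "SquareWaveSpec",
    "LeadLayout",
    "single_strip_layout",
    "standard_12_lead_layout",
]


@dataclass
class LeadSpan:
    """One lead's time window within its row's continuous recording."""

    name: str
    t0: float  # seconds from the row's signal start
    t1: float


@dataclass
class RowBand:
    """One printed strip: a vertical pixel band holding a continuous trace."""

    band: tuple[float, float]  # (top, bottom) as fractions of page height
    span: tuple[float, float]  # (left, right) as fractions of page width
    seconds: float             # signal duration excluding the pulse
    leads: list[LeadSpan]
    has_pulse: bool = True

    def band_px(self, height: int) -> tuple[int, int]:
        lo = int(round(self.band[0] * height))
        hi = int(round(self.band[1] * height))
        return lo, max(hi, lo + 1)

    def span_px(self, width: int) -> tuple[int, int]:
        lo = int(round(self.span[0] * width))
        hi = int(round(self.span[1] * width))
        return lo, max(hi, lo + 1)


@dataclass
class SquareWaveSpec:
    high_mV: float = 1.0
    width_s: float = 0.2  # high-level width; leading/trailing lows are equal


@dataclass
class LeadLayout:
    rows: list[RowBand]
    paper_speed: float = 25.0   # mm/s
    sensitivity: float = 10.0   # mm/mV
    boundary_discard_s: float = 0.1
    square_wave: SquareWaveSpec = field(default_factory=SquareWaveSpec)
    grid_color: str = "red"
    page_aspect: float | None = None  # width/height; optional rectify fallback

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "LeadLayout":
        """Load from a JSON string or file path."""
        if source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        rows = [
            RowBand(
                band=tuple(r["band"]),
                span=tuple(r["span"]),
                seconds=float(r["seconds"]),
                leads=[LeadSpan(**ls) for ls in r["leads"]],
                has_pulse=bool(r.get("has_pulse", True)),
            )
            for r in obj["rows"]
        ]
        sq = SquareWaveSpec(**obj.get("square_wave", {}))
        return cls(
            rows=rows,
            paper_speed=float(obj.get("paper_speed", 25.0)),
            sensitivity=float(obj.get("sensitivity", 10.0)),
            boundary_discard_s=float(obj.get("boundary_discard_s", 0.1)),
            square_wave=sq,
            grid_color=obj.get("grid_color", "red"),
            page_aspect=obj.get("page_aspect"),
        )

    # -- helpers ----------------------------------------------------------
    def row_total_seconds(self, row: RowBand) -> float:
        """Span duration including the calibration pulse, if printed."""
        extra = 3.0 * self.square_wave.width_s if row.has_pulse else 0.0
        return row.seconds + extra

    def lead_names(self) -> list[str]:
        return [ls.name for row in self.rows for ls in row.leads]


def single_strip_layout(
    seconds: float = 10.0,
    lead: str = "II",
    *,
    margin_frac: tuple[float, float] = (0.06, 0.18),
) -> LeadLayout:
    """One rhythm strip centred on the page: pulse then ``seconds`` of signal.

    ``margin_frac`` = (horizontal, vertical) page margins as fractions.
    """
    mx, my = margin_frac
    row = RowBand(
        band=(my, 1.0 - my),
        span=(mx, 1.0 - mx),
        seconds=seconds,
        leads=[LeadSpan(lead, 0.0, seconds)],
    )
    return LeadLayout(rows=[row])


_STANDARD_PAIRS = [
    ("I", "V1"), ("II", "V2"), ("III", "V3"),
    ("aVR", "V4"), ("aVL", "V5"), ("aVF", "V6"),
]


def standard_12_lead_layout(seconds_per_lead: float = 5.0) -> LeadLayout:
    """Standard 6x2 sheet: six strips, each printing a limb lead for the
    first half and a chest lead for the second, plus a lead II rhythm strip
    at the bottom. Each strip is one continuous recording.
    """
    rows: list[RowBand] = []
    n_rows = len(_STANDARD_PAIRS) + 1
    top, bottom = 0.06, 0.94
    h = (bottom - top) / n_rows
    for i, (left, right) in enumerate(_STANDARD_PAIRS):
        rows.append(
            RowBand(
                band=(top + i * h, top + (i + 1) * h),
                span=(0.04, 0.96),
                seconds=2 * seconds_per_lead,
                leads=[
                    LeadSpan(left, 0.0, seconds_per_lead),
                    LeadSpan(right, seconds_per_lead, 2 * seconds_per_lead),
                ],
            )
        )
    rows.append(
        RowBand(
            band=(top + len(_STANDARD_PAIRS) * h, bottom),
            span=(0.04, 0.96),
            seconds=2 * seconds_per_lead,
            leads=[LeadSpan("II-rhythm", 0.0, 2 * seconds_per_lead)],
        )
    )
    return LeadLayout(rows=rows)
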