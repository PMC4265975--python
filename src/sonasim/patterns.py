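"""The 'HIFU' heating pattern: ten 18-mm straight segments forming the
letters H, I, F and U, each produced by electronically steering the focal
point in 2-mm steps along the line.

Letter coordinates are a package convention (the hardware experiment's
exact layout is not published): each letter occupies an 18x18-mm box, the
letters sit left to right along +LR at a configurable pitch, and all
strokes are full 18-mm segments so every segment is steered identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import FocusTrajectory

SEGMENT_LENGTH_MM = 18.0
STEP_MM = 2.0
SEGMENTS_PER_LETTER = {"H": 3, "I": 1, "F": 3, "U": 3}


@dataclass(frozen=True)
class PatternSegment:
    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    letter: str
    order: int  # execution order, 1-based

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end_mm, self.start_mm)))

    def sample_points(self, step_mm: float = STEP_MM) -> np.ndarray:
        """Steering points along the segment, endpoints inclusive
        (an 18-mm line at 2-mm steps gives 10 points)."""
        n = int(round(self.length_mm / step_mm)) + 1
        frac = np.linspace(0.0, 1.0, n)[:, None]
        return np.asarray(self.start_mm) + frac * (
            np.asarray(self.end_mm) - np.asarray(self.start_mm)
        )


@dataclass(frozen=True)
class HifuPattern:
    segments: tuple[PatternSegment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != 10:
            raise ValueError("the pattern must have exactly 10 segments")
        if sorted(s.order for s in self.segments) != list(range(1, 11)):
            raise ValueError("segment orders must be a permutation of 1..10")
        for s in self.segments:
            if abs(s.length_mm - SEGMENT_LENGTH_MM) > 1e-6:
                raise ValueError(
                    f"segment {s.order} has length {s.length_mm} mm, "
                    f"expected {SEGMENT_LENGTH_MM} mm"
                )

    @property
    def letters(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in sorted(self.segments, key=lambda s: s.order):
            if s.letter not in seen:
                seen.append(s.letter)
        return tuple(seen)

    def letter_center_mm(self, letter: str) -> tuple[float, float, float]:
        segs = [s for s in self.segments if s.letter == letter]
        pts = np.array([s.start_mm for s in segs] + [s.end_mm for s in segs])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return tuple(float(v) for v in (lo + hi) / 2.0)

    def in_order(self) -> tuple[PatternSegment, ...]:
        return tuple(sorted(self.segments, key=lambda s: s.order))

    def trajectory_for(self, segment: PatternSegment,
                       interval_ms: float = 25.0,
                       step_mm: float = STEP_MM) -> FocusTrajectory:
        """Steering trajectory for one segment, as offsets from the natural
        focus when the transducer is positioned at the letter centre."""
        center = np.asarray(self.letter_center_mm(segment.letter))
        offsets = segment.sample_points(step_mm) - center
        return FocusTrajectory(points=tuple(tuple(p) for p in offsets),
                               interval_ms=interval_ms)


def generate_hifu_pattern(center_mm=(0.0, 0.0, 0.0),
                          letter_pitch_mm: float = 25.0) -> HifuPattern:
    """Deterministic 'HIFU' pattern: letters H, I, F, U left to right along
    +LR at ``letter_pitch_mm``, centred on ``center_mm``, in the z=const
    focal plane."""
    cx0, cy, cz = (float(v) for v in center_mm)
    h = SEGMENT_LENGTH_MM / 2.0
    letters = ("H", "I", "F", "U")
    centers = {
        letter: cx0 + (i - (len(letters) - 1) / 2.0) * letter_pitch_mm
        for i, letter in enumerate(letters)
    }

    def seg(letter, order, x0, y0, x1, y1):
        return PatternSegment(start_mm=(x0, y0 + cy, cz),
                              end_mm=(x1, y1 + cy, cz),
                              letter=letter, order=order)

    cH, cI, cF, cU = (centers[letter] for letter in letters)
    segments = (
        # H: two verticals and the crossbar
        seg("H", 1, cH - h, -h, cH - h, h),
        seg("H", 2, cH + h, -h, cH + h, h),
        seg("H", 3, cH - h, 0.0, cH + h, 0.0),
        # I: one vertical
        seg("I", 4, cI, -h, cI, h),
        # F: vertical, top bar, middle bar
        seg("F", 5, cF - h, -h, cF - h, h),
        seg("F", 6, cF - h, h, cF + h, h),
        seg("F", 7, cF - h, 0.0, cF + h, 0.0),
        # U: two verticals and the bottom bar
        seg("U", 8, cU - h, -h, cU - h, h),
        seg("U", 9, cU + h, -h, cU + h, h),
        seg("U", 10, cU - h, -h, cU + h, -h),
    )
    return HifuPattern(segments=segments)
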