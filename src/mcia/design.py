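"""Stimulus design: morphs, strength levels, test faces, and block structure.

The experiment categorizes morphed faces into one of two families (here the
abstract labels ``A`` and ``B``; the display aliases "Jones"/"Smith" are kept
only for pretty-printing). Each test face is built from a top and/or a bottom
half, each half carrying weak, medium, or strong evidence for one family.
Whole faces are shown ``together`` (normal configuration, promoting automatic
holistic processing) or ``split`` (halves offset horizontally, promoting
controlled processing); half faces have format ``half``.

Morph levels are expressed throughout as percent of the own-family target in
the pixelwise linear combination, in [50, 100]. Levels are kept as floats —
the 5.6% staircase step makes fractional levels inevitable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

STRENGTHS = ("weak", "medium", "strong")
STRENGTH_CODE = {"weak": "w", "medium": "m", "strong": "s"}
FAMILIES = ("A", "B")
FAMILY_ALIASES = {"A": "Jones", "B": "Smith"}
LOCATIONS = ("top", "bottom")
FORMATS = ("together", "split", "half")
WHOLE_FORMATS = ("together", "split")

#: 3x3 grid of screen offsets used to randomize initial fixation (pixels).
SCREEN_OFFSETS = (-100, 0, 100)


def morph_arrays(image_a: np.ndarray, image_b: np.ndarray, w: float) -> np.ndarray:
    """Pixelwise linear morph ``w*A + (1-w)*B`` of two same-shape gray images."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"morph requires same-shape images, got {a.shape} vs {b.shape}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"morph weight must lie in [0, 1], got {w}")
    return w * a + (1.0 - w) * b


def derive_levels(medium: float) -> tuple[float, float]:
    """Interpolate weak and strong morph levels (percent) from the medium level.

    The weak level sits midway between the medium level and the fully ambiguous
    50% morph; the strong level sits two-thirds of the way from the medium
    level to the 100% (pure-target) morph.
    """
    if not 50.0 <= medium <= 100.0:
        raise ValueError(f"medium level must lie in [50, 100] percent, got {medium}")
    weak = (medium + 50.0) / 2.0
    strong = medium + (2.0 / 3.0) * (100.0 - medium)
    return weak, strong


@dataclass(frozen=True)
class HalfSpec:
    """One half face: location on the test face, family it favors, strength."""

    location: str
    family: str
    strength: str

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.strength not in STRENGTHS:
            raise ValueError(f"strength must be one of {STRENGTHS}, got {self.strength!r}")

    @property
    def code(self) -> str:
        c = STRENGTH_CODE[self.strength]
        return f"{c}/" if self.location == "top" else f"/{c}"


@dataclass(frozen=True)
class TestFaceSpec:
    """A test face: optional top/bottom halves plus a presentation format.

    ``format == "half"`` iff exactly one half is present. Opposite faces (the
    two halves favoring different families) combine only medium with weak
    evidence; they serve as a manipulation check that weak evidence for one
    family is not read as evidence for the other.
    """

    __test__ = False  # keep pytest from collecting this domain class

    top: Optional[HalfSpec] = None
    bottom: Optional[HalfSpec] = None
    format: str = "together"

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")
        if self.top is not None and self.top.location != "top":
            raise ValueError("top slot holds a half with location 'top'")
        if self.bottom is not None and self.bottom.location != "bottom":
            raise ValueError("bottom slot holds a half with location 'bottom'")
        n_halves = (self.top is not None) + (self.bottom is not None)
        if n_halves == 0:
            raise ValueError("a test face needs at least one half")
        if (self.format == "half") != (n_halves == 1):
            raise ValueError("format 'half' iff exactly one half is present")
        if n_halves == 2 and self.top.family != self.bottom.family:
            strengths = {self.top.strength, self.bottom.strength}
            if strengths != {"medium", "weak"}:
                raise ValueError(
                    "opposite faces combine only medium with weak evidence"
                )

    @property
    def is_half(self) -> bool:
        return self.format == "half"

    @property
    def is_opposite(self) -> bool:
        return (
            self.top is not None
            and self.bottom is not None
            and self.top.family != self.bottom.family
        )

    @property
    def sole_half(self) -> HalfSpec:
        if not self.is_half:
            raise ValueError("sole_half is defined only for half faces")
        return self.top if self.top is not None else self.bottom

    def halves(self) -> tuple[HalfSpec, ...]:
        return tuple(h for h in (self.top, self.bottom) if h is not None)

    @property
    def condition(self) -> str:
        """Collapsed condition label: w/m/s, ww..ss, or wom.

        Family and top/bottom location are dropped; the pair of strength codes
        is sorted in w < m < s order so e.g. w/s and s/w both map to ``ws``.
        """
        if self.is_half:
            return STRENGTH_CODE[self.sole_half.strength]
        if self.is_opposite:
            return "wom"
        order = {"w": 0, "m": 1, "s": 2}
        codes = sorted(
            (STRENGTH_CODE[self.top.strength], STRENGTH_CODE[self.bottom.strength]),
            key=order.__getitem__,
        )
        return "".join(codes)

    def __str__(self) -> str:
        if self.is_half:
            h = self.sole_half
            return f"{h.code}{h.family} ({self.format})"
        t, b = self.top, self.bottom
        return (
            f"{STRENGTH_CODE[t.strength]}{t.family}/"
            f"{STRENGTH_CODE[b.strength]}{b.family} ({self.format})"
        )


def correct_family(face: TestFaceSpec) -> str:
    """Family label of the correct response for a test face.

    Same-family and half faces: that family. Opposite faces: the family of the
    stronger (medium) half — the response supported by the stronger evidence.
    """
    if face.is_half:
        return face.sole_half.family
    if not face.is_opposite:
        return face.top.family
    return face.top.family if face.top.strength == "medium" else face.bottom.family


@dataclass(frozen=True)
class CalibrationLevels:
    """Per (location x family) medium morph levels, percent of own family.

    Weak and strong levels are derived by :func:`derive_levels`; the invariant
    50 <= weak <= medium <= strong <= 100 then holds by construction.
    """

    medium: dict = field(default_factory=dict)  # (location, family) -> percent

    def __post_init__(self) -> None:
        for loc in LOCATIONS:
            for fam in FAMILIES:
                if (loc, fam) not in self.medium:
                    raise ValueError(f"missing medium level for ({loc}, {fam})")
        for key, val in self.medium.items():
            if not 50.0 <= val <= 100.0:
                raise ValueError(f"medium level for {key} outside [50, 100]: {val}")

    def level(self, half: HalfSpec) -> float:
        """Morph level (percent own family) for one calibrated half face."""
        med = self.medium[(half.location, half.family)]
        if half.strength == "medium":
            return med
        weak, strong = derive_levels(med)
        return weak if half.strength == "weak" else strong

    def to_json(self) -> str:
        payload = {
            loc: {fam: self.medium[(loc, fam)] for fam in FAMILIES}
            for loc in LOCATIONS
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationLevels":
        payload = json.loads(text)
        medium = {
            (loc, fam): float(payload[loc][fam])
            for loc in LOCATIONS
            for fam in FAMILIES
        }
        return cls(medium=medium)

    @classmethod
    def uniform(cls, medium: float = 82.0) -> "CalibrationLevels":
        """Same medium level for every half; convenient in tests and examples."""
        return cls(medium={(l, f): medium for l in LOCATIONS for f in FAMILIES})


def enumerate_test_faces(levels: Optional[CalibrationLevels] = None) -> list[TestFaceSpec]:
    """Enumerate the 56 test faces of one integration block's stimulus set.

    12 half faces (3 strengths x 2 locations x 2 families), 36 whole faces
    (3 top x 3 bottom strengths x 2 families, in both together and split
    formats) and 8 opposite faces (medium paired with weak across families,
    2 top strengths x 2 top families, both formats). ``levels`` is accepted for
    validation symmetry with block construction; the enumeration itself is
    purely structural.
    """
    if levels is not None and not isinstance(levels, CalibrationLevels):
        raise TypeError("levels must be a CalibrationLevels instance")
    faces: list[TestFaceSpec] = []
    for strength in STRENGTHS:
        for loc in LOCATIONS:
            for fam in FAMILIES:
                half = HalfSpec(loc, fam, strength)
                faces.append(
                    TestFaceSpec(
                        top=half if loc == "top" else None,
                        bottom=half if loc == "bottom" else None,
                        format="half",
                    )
                )
    for fmt in WHOLE_FORMATS:
        for fam in FAMILIES:
            for ts in STRENGTHS:
                for bs in STRENGTHS:
                    faces.append(
                        TestFaceSpec(
                            top=HalfSpec("top", fam, ts),
                            bottom=HalfSpec("bottom", fam, bs),
                            format=fmt,
                        )
                    )
    for fmt in WHOLE_FORMATS:
        for top_fam in FAMILIES:
            bottom_fam = "B" if top_fam == "A" else "A"
            for top_strength in ("medium", "weak"):
                bottom_strength = "weak" if top_strength == "medium" else "medium"
                faces.append(
                    TestFaceSpec(
                        top=HalfSpec("top", top_fam, top_strength),
                        bottom=HalfSpec("bottom", bottom_fam, bottom_strength),
                        format=fmt,
                    )
                )
    assert len(faces) == 56
    return faces


def _is_equal_strength_whole(face: TestFaceSpec) -> bool:
    return (
        not face.is_half
        and not face.is_opposite
        and face.top.strength == face.bottom.strength
    )


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: a test face plus the randomized screen position."""

    face: TestFaceSpec
    screen_x: int
    screen_y: int


def build_block(faces: Iterable[TestFaceSpec], rng_seed: int) -> list[TrialSpec]:
    """Build one 68-trial integration block from the full 56-face enumeration.

    Every face appears once; the equal-strength same-family whole faces
    (w/w, m/m, s/s in both formats and families) appear twice, adding 12
    trials. Order is shuffled and each trial gets one of 9 screen positions
    (offsets of -100/0/+100 pixels on each axis), all driven by ``rng_seed``.
    """
    faces = list(faces)
    if {str(f) for f in faces} != {str(f) for f in enumerate_test_faces()} or len(faces) != 56:
        raise ValueError("build_block requires the full 56-face enumeration")
    schedule = faces + [f for f in faces if _is_equal_strength_whole(f)]
    assert len(schedule) == 68
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(schedule))
    xs = rng.choice(SCREEN_OFFSETS, size=len(schedule))
    ys = rng.choice(SCREEN_OFFSETS, size=len(schedule))
    return [
        TrialSpec(face=schedule[i], screen_x=int(x), screen_y=int(y))
        for i, x, y in zip(order, xs, ys)
    ]


def block_seed(experiment_seed: int, participant: int, block: int) -> int:
    """Stable per-block shuffle seed derived from the experiment-level seed."""
    ss = np.random.SeedSequence([int(experiment_seed), int(participant), int(block)])
    return int(ss.generate_state(1)[0] % (2**31))
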