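"""Benchmark scales mapping agreement-coefficient magnitudes to labels.

Three published interpretation scales are provided: Landis & Koch (1977),
Altman (1991) and Fleiss (1981).  Each is an ordered list of contiguous
half-open bands over (-1, 1], closed on the upper end, so every value in
[-1, 1] receives exactly one label (printed gaps in the original tables,
e.g. ".20" followed by ".21 to .40", are treated as rounded band edges,
not real gaps).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BenchmarkScale:
    """An ordered set of (lower, upper, label) bands covering [-1, 1].

    Bands are half-open ``(lower, upper]`` except the first, which also
    includes its lower endpoint -1.
    """

    name: str
    bands: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        lo = -1.0
        for low, high, _ in self.bands:
            if low != lo:
                raise ValueError(f"{self.name}: bands not contiguous at {low}")
            if high <= low:
                raise ValueError(f"{self.name}: empty band ({low}, {high}]")
            lo = high
        if lo != 1.0:
            raise ValueError(f"{self.name}: bands do not reach 1.0")

    def classify(self, estimate: float) -> str:
        """Return the label of the band containing ``estimate``."""
        if not (-1.0 <= estimate <= 1.0):
            raise ValueError(f"estimate {estimate} outside [-1, 1]")
        for low, high, label in self.bands:
            if estimate <= high:
                return label
        raise AssertionError("unreachable: bands cover [-1, 1]")


# A coefficient of exactly 0 falls in the "Slight" band (not "Poor"):
# the study treats its printed 0 values as interpretable agreement.
LANDIS_KOCH = BenchmarkScale(
    "landis_koch",
    (
        (-1.0, -1e-12, "Poor"),
        (-1e-12, 0.20, "Slight"),
        (0.20, 0.40, "Fair"),
        (0.40, 0.60, "Moderate"),
        (0.60, 0.80, "Substantial"),
        (0.80, 1.00, "Almost Perfect"),
    ),
)

ALTMAN = BenchmarkScale(
    "altman",
    (
        (-1.0, 0.20, "Poor"),
        (0.20, 0.40, "Fair"),
        (0.40, 0.60, "Moderate"),
        (0.60, 0.80, "Good"),
        (0.80, 1.00, "Very Good"),
    ),
)

# Fleiss: "Intermediate to Good" covers [0.40, 0.75); values from 0.75 up
# are "Excellent".  Bands closed on the upper end elsewhere, so 0.40
# itself classifies as "Intermediate to Good" via a lower edge just below.
FLEISS = BenchmarkScale(
    "fleiss",
    (
        (-1.0, 0.40 - 1e-12, "Poor"),
        (0.40 - 1e-12, 0.75 - 1e-12, "Intermediate to Good"),
        (0.75 - 1e-12, 1.00, "Excellent"),
    ),
)

SCALES: dict[str, BenchmarkScale] = {
    s.name: s for s in (LANDIS_KOCH, ALTMAN, FLEISS)
}


def get_scale(name: str) -> BenchmarkScale:
    try:
        return SCALES[name]
    except KeyError:
        raise ValueError(
            f"unknown benchmark scale {name!r}; choose from {sorted(SCALES)}"
        ) from None


def classify(estimate: float, scale: BenchmarkScale | str) -> str:
    """Label an agreement coefficient under the given benchmark scale."""
    if isinstance(scale, str):
        scale = get_scale(scale)
    return scale.classify(estimate)


def classify_disagreement(
    estimate_a: float, estimate_b: float, scale: BenchmarkScale | str
) -> dict:
    """Report whether two coefficients for the same data land in different bands.

    Returns ``{"same_band": bool, "labels": (label_a, label_b)}``.
    """
    if isinstance(scale, str):
        scale = get_scale(scale)
    la, lb = scale.classify(estimate_a), scale.classify(estimate_b)
    return {"same_band": la == lb, "labels": (la, lb)}


def export_scales() -> dict[str, list[dict]]:
    """Structured (JSON-serializable) dump of all scales."""
    return {
        name: [
            {"lower": low, "upper": high, "label": label}
            for low, high, label in scale.bands
        ]
        for name, scale in SCALES.items()
    }
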