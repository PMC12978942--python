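"""Ommatidial class proportions.

Nymphalid retinas tile three ommatidial classes defined by the opsins of the
two distal photoreceptors R1 and R2: UV-UV, B-B, and UV-B.  Counts of the
three classes in one eye region are the common currency between the
immunostain pipeline, the co-expression model, and the cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ClassProportions:
    """Counts and proportions of UV-UV, B-B, and UV-B ommatidia for one region."""

    n_uvuv: int
    n_bb: int
    n_uvb: int

    def __post_init__(self) -> None:
        for name in ("n_uvuv", "n_bb", "n_uvb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_uvuv + self.n_bb + self.n_uvb

    @property
    def p_uvuv(self) -> float:
        return self.n_uvuv / self.n_total if self.n_total else 0.0

    @property
    def p_bb(self) -> float:
        return self.n_bb / self.n_total if self.n_total else 0.0

    @property
    def p_uvb(self) -> float:
        return self.n_uvb / self.n_total if self.n_total else 0.0

    def as_triple(self) -> tuple[float, float, float]:
        return (self.p_uvuv, self.p_bb, self.p_uvb)


def blue_photoreceptor_fraction(props) -> float:
    """Fraction of R1/R2 *cells* (not ommatidia) expressing the blue opsin.

    Each ommatidium contributes two cells: B-B contributes two blue cells,
    UV-B one, UV-UV none, so the fraction is (2*BB + UVB) / (2*total).
    Accepts a :class:`ClassProportions` or a (UVUV, BB, UVB) triple of
    fractions.
    """
    if isinstance(props, ClassProportions):
        if props.n_total == 0:
            raise ValueError("no ommatidia counted")
        return (2 * props.n_bb + props.n_uvb) / (2 * props.n_total)
    uvuv, bb, uvb = props
    total = uvuv + bb + uvb
    if total <= 0:
        raise ValueError("proportions sum to zero")
    return (2 * bb + uvb) / (2 * total)


def proportions_triple(props) -> tuple[float, float, float]:
    """Normalize a ClassProportions or 3-sequence to a (UVUV, BB, UVB) triple."""
    if isinstance(props, ClassProportions):
        return props.as_triple()
    triple = tuple(float(v) for v in props)
    if len(triple) != 3:
        raise ValueError("expected a (UVUV, BB, UVB) triple")
    return triple
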