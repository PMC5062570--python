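"""Censored potency values and their arithmetic.

Biochemical assays routinely top out at the highest concentration tested and
report potencies such as ">100 uM".  Treating such a value as a point estimate
silently overstates what was measured, so censored values are carried through
all ratio arithmetic as first-class :class:`Bound` objects.  A ratio involving
a bound yields another bound (or, when both operands are censored in
incompatible directions, an indeterminate result), never a point value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = ["Bound", "PotencyValue", "divide", "as_potency"]


@dataclass(frozen=True)
class Bound:
    """A one-sided censored value: ``Bound(100e-6, '>')`` means ">100 uM".

    Parameters
    ----------
    value : float
        The censoring limit, in whatever unit the caller uses consistently.
    relation : str
        Either ``'>'`` (true value exceeds the limit) or ``'<'``.
    """

    value: float
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in (">", "<"):
            raise ValueError(f"relation must be '>' or '<', got {self.relation!r}")
        if not self.value > 0:
            raise ValueError("bound limit must be positive")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.relation}{self.value:g}"


PotencyValue = Union[float, Bound]


def as_potency(text_or_number: Union[str, float, Bound]) -> PotencyValue:
    """Parse ``'>100e-6'`` / ``'<1e-9'`` / plain numbers into potency values."""
    if isinstance(text_or_number, Bound):
        return text_or_number
    if isinstance(text_or_number, str):
        s = text_or_number.strip()
        if s and s[0] in "><":
            return Bound(float(s[1:]), s[0])
        return float(s)
    return float(text_or_number)


def divide(numerator: PotencyValue, denominator: PotencyValue) -> PotencyValue:
    """Ratio of two potency values with censoring propagation.

    A lower-bound numerator over a point denominator stays a lower bound;
    a point numerator over a lower-bound denominator becomes an upper bound,
    and symmetrically for '<'.  Combinations whose direction is indeterminate
    (e.g. '>' over '>') raise ``ValueError`` rather than guess.
    """
    num_is_b = isinstance(numerator, Bound)
    den_is_b = isinstance(denominator, Bound)
    if not num_is_b and not den_is_b:
        if denominator <= 0:
            raise ValueError("denominator must be positive")
        return numerator / denominator
    if num_is_b and not den_is_b:
        return Bound(numerator.value / denominator, numerator.relation)
    if den_is_b and not num_is_b:
        flipped = ">" if denominator.relation == "<" else "<"
        return Bound(numerator / denominator.value, flipped)
    # both censored: only opposite relations give a definite direction
    assert isinstance(numerator, Bound) and isinstance(denominator, Bound)
    if numerator.relation == ">" and denominator.relation == "<":
        return Bound(numerator.value / denominator.value, ">")
    if numerator.relation == "<" and denominator.relation == ">":
        return Bound(numerator.value / denominator.value, "<")
    raise ValueError(
        f"ratio of {numerator} to {denominator} has indeterminate direction"
    )
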