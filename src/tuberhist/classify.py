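"""Histological tuber typing (A/B/C) and the perituberal definition.

The three patterns are defined on the giant-cell density (vimentin-positive
cells/mm^2), the dysmorphic-neuron density (SMI32-positive cells/mm^2) and
the presence of calcifications scored on H&E:

* type C — calcifications present (alongside giant cells and dysmorphic
  neurons); calcification takes precedence over the density rules;
* type B — high density: giant cells > 10/mm^2 OR dysmorphic neurons
  > 3/mm^2;
* type A — low density: both giant cells <= 10/mm^2 AND dysmorphic
  neurons <= 3/mm^2.

Perituberal cortex is defined by the complete absence of giant cells and
dysmorphic neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError

#: Giant-cell density cutoff separating type A from type B (cells/mm^2).
GIANT_CELL_CUTOFF = 10.0

#: Dysmorphic-neuron density cutoff separating type A from type B (cells/mm^2).
DYSMORPHIC_CUTOFF = 3.0


@dataclass(frozen=True)
class TuberFeatures:
    """Classifier inputs for one sample."""

    giant_cell_density: float
    dysmorphic_density: float
    calcification_present: bool = False

    def __post_init__(self):
        if self.giant_cell_density < 0 or self.dysmorphic_density < 0:
            raise InvalidInputError("densities must be non-negative")


@dataclass(frozen=True)
class TuberType:
    label: str

    def __post_init__(self):
        if self.label not in ("A", "B", "C"):
            raise InvalidInputError(f"unknown tuber type {self.label!r}")


def classify_tuber(
    f: TuberFeatures,
    gc_cutoff: float = GIANT_CELL_CUTOFF,
    dn_cutoff: float = DYSMORPHIC_CUTOFF,
) -> TuberType:
    """Assign exactly one type (A, B or C) to any valid feature triple.

    Total and exclusive: calcification forces C; otherwise exceeding either
    density cutoff gives B, and A requires both densities at or below their
    cutoffs (the boundary itself is type A).
    """
    if gc_cutoff <= 0 or dn_cutoff <= 0:
        raise InvalidInputError("cutoffs must be positive")
    if f.calcification_present:
        return TuberType("C")
    if f.giant_cell_density > gc_cutoff or f.dysmorphic_density > dn_cutoff:
        return TuberType("B")
    return TuberType("A")


def is_perituberal(f: TuberFeatures) -> bool:
    """True iff the sample shows no giant cells, no dysmorphic neurons and
    no calcifications."""
    return (
        f.giant_cell_density == 0.0
        and f.dysmorphic_density == 0.0
        and not f.calcification_present
    )


def locate_boundary(
    axis: str = "giant_cell",
    lo: float = 0.0,
    hi: float = 100.0,
    tol: float = 1e-6,
    gc_cutoff: float = GIANT_CELL_CUTOFF,
    dn_cutoff: float = DYSMORPHIC_CUTOFF,
) -> tuple[float, int]:
    """Locate the A->B decision boundary on one density axis by bisection.

    The other density is held at 0 and calcification at false. Returns the
    supremum of densities still classified A (to within ``tol``) and the
    number of classifier evaluations spent.
    """
    if axis not in ("giant_cell", "dysmorphic"):
        raise InvalidInputError(f"unknown axis {axis!r}")

    def label(x: float) -> str:
        feats = (
            TuberFeatures(x, 0.0, False)
            if axis == "giant_cell"
            else TuberFeatures(0.0, x, False)
        )
        return classify_tuber(feats, gc_cutoff, dn_cutoff).label

    n_eval = 2
    if label(lo) != "A" or label(hi) != "B":
        raise InvalidInputError("bracket does not straddle the A/B boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        n_eval += 1
        if label(mid) == "A":
            lo = mid
        else:
            hi = mid
    return lo, n_eval
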