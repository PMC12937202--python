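"""Virtual agarose gel: log-linear migration, band resolvability, lane tables.

Migration follows the standard log-linear mobility model
``distance = a - b * log10(size)``, floored at zero.  The default constants
approximate a 2.75% gel on which a 600 bp ladder spans the lane; no
quantitative claim depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10
from typing import Callable, Sequence

__all__ = [
    "GelModel",
    "GelLane",
    "migration_distance",
    "resolvable",
    "render_gel",
    "DEFAULT_LADDER",
]

#: 600 bp ladder marks (bp).
DEFAULT_LADDER: tuple[int, ...] = (100, 200, 300, 400, 500, 600)


def _default_delta(size: float) -> float:
    return max(10.0, 0.06 * size)


@dataclass(frozen=True)
class GelModel:
    """Log-linear gel mobility model for one agarose percentage."""

    gel_pct: float = 2.75
    a: float = 140.0  # intercept, mm
    b: float = 55.0   # slope, mm per log10(bp)
    min_resolvable_delta: Callable[[float], float] = field(default=_default_delta)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("slope b must be > 0 (migration must decrease with size)")


@dataclass(frozen=True)
class GelLane:
    """One lane: a label and (size bp, migration mm) bands sorted by size."""

    label: str
    bands: tuple[tuple[int, float], ...]


def migration_distance(size: int, model: GelModel | None = None) -> float:
    """Migration distance in mm for a band of ``size`` bp, floored at 0."""
    model = model or GelModel()
    if size < 1:
        raise ValueError(f"band size must be >= 1 bp, got {size}")
    return max(0.0, model.a - model.b * log10(size))


def resolvable(
    sizes: Sequence[int], model: GelModel | None = None
) -> tuple[bool, tuple[int, int] | None]:
    """Whether every adjacent (sorted) size pair separates on the gel.

    Returns ``(True, None)`` or ``(False, (smaller, larger))`` for the first
    offending pair.  Permutation-invariant in ``sizes``.
    """
    model = model or GelModel()
    if not sizes:
        raise ValueError("need at least one size")
    ordered = sorted(sizes)
    for a, b in zip(ordered, ordered[1:]):
        if b - a < model.min_resolvable_delta(a):
            return False, (a, b)
    return True, None


def make_lane(label: str, sizes: Sequence[int], model: GelModel | None = None) -> GelLane:
    model = model or GelModel()
    bands = tuple((s, round(migration_distance(s, model), 2)) for s in sorted(sizes))
    return GelLane(label=label, bands=bands)


def render_gel(
    lanes: Sequence[GelLane],
    ladder: Sequence[int] = DEFAULT_LADDER,
    model: GelModel | None = None,
    image_path: str | None = None,
) -> str:
    """Deterministic text rendering of a gel; optional PNG via matplotlib.

    The ladder is rendered as the first lane ``M``.  Returns the text table.
    """
    model = model or GelModel()
    all_lanes = [make_lane("M", ladder, model), *lanes]
    lines = ["lane\tband\tsize_bp\tdistance_mm"]
    for lane in all_lanes:
        if not lane.bands:
            lines.append(f"{lane.label}\t-\t-\t-")
            continue
        for i, (size, dist) in enumerate(lane.bands, start=1):
            lines.append(f"{lane.label}\t{i}\t{size}\t{dist:.2f}")
    text = "\n".join(lines) + "\n"

    if image_path is not None:
        _render_image(all_lanes, model, image_path)
    return text


def _render_image(lanes: Sequence[GelLane], model: GelModel, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(lanes)), 5))
    for x, lane in enumerate(lanes):
        for size, dist in lane.bands:
            ax.plot([x - 0.3, x + 0.3], [dist, dist], lw=4, color="black")
    ax.set_xticks(range(len(lanes)))
    ax.set_xticklabels([lane.label for lane in lanes], rotation=45, ha="right")
    ax.set_ylabel("migration (mm)")
    ax.invert_yaxis()
    ax.set_title(f"virtual gel ({model.gel_pct}% agarose)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
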