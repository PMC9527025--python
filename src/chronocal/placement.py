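"""End-to-end placement of a newly discovered taxon on a published timescale.

The pipeline reproduces the distance-calibration workflow: compute
uncorrected p-distances from the alignment, summarise them as species-pair
percent ranges, find the focal taxon's nearest relative, regress published
divergence times on percent distance over the *non-focal* species pairs
(the focal taxon must be absent from the chronogram — its true age would
otherwise leak into its own calibration), and insert the focal taxon's
distance into the fitted line to estimate its minimum divergence time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

from .calibration import (
    CalibrationError,
    CalibrationFit,
    CalibrationTable,
    Prediction,
    build_calibration_table,
    distance_range_summary,
    fit_calibration,
    predict_time,
)
from .chronogram import Chronogram, pair_time_table
from .msa import (
    Alignment,
    PairRangeTable,
    SpeciesMap,
    distance_matrix,
    species_pair_ranges,
    within_species_divergence,
)

__all__ = [
    "PlacementError",
    "PlacementReport",
    "nearest_relative",
    "place_taxon",
    "quaternary_flag",
]

#: base of the Quaternary period, My (ICS 2009 revision)
QUATERNARY_BOUNDARY_MY = 2.58


class PlacementError(ValueError):
    """Raised when the placement pipeline cannot proceed."""


def nearest_relative(
    ranges: PairRangeTable, focal: str
) -> tuple[str, tuple[float, float]]:
    """The non-focal species with the smallest minimum percent distance.

    Ties on the minimum are broken by smaller range midpoint, then
    lexicographically by species name, with a warning.
    """
    candidates = ranges.pairs_with(focal)
    if focal not in ranges.species:
        raise PlacementError(f"focal species {focal!r} not in the range table")
    if not candidates:
        raise PlacementError(f"no non-focal species to compare with {focal!r}")

    def sort_key(item: tuple[str, tuple[float, float]]):
        name, (lo, hi) = item
        return (lo, (lo + hi) / 2.0, name)

    ordered = sorted(candidates.items(), key=sort_key)
    best = ordered[0]
    if len(ordered) > 1 and ordered[1][1][0] == best[1][0]:
        warnings.warn(
            f"tie on minimum distance to {focal!r} "
            f"({best[0]!r} vs {ordered[1][0]!r}); broke by midpoint/name",
            stacklevel=2,
        )
    return best


def quaternary_flag(
    prediction: Prediction,
    boundary: float = QUATERNARY_BOUNDARY_MY,
    *,
    use_point: bool = False,
) -> bool:
    """True when the divergence pre-dates ``boundary`` (My).

    By default the *lower* bound of the uncertainty interval must exceed the
    boundary; ``use_point`` compares the point estimate instead.
    """
    value = prediction.point if use_point else prediction.lower
    return bool(value > boundary)


@dataclass(frozen=True)
class PlacementReport:
    """Machine-readable result of placing one focal taxon."""

    focal: str
    nearest: str
    nearest_range_percent: tuple[float, float]
    distance_summary_percent: float
    summary_kind: str
    fits: dict[str, dict[str, Any]]
    headline_mode: str
    prediction: Prediction
    prediction_through_origin: Prediction
    predates_quaternary: bool
    quaternary_boundary_my: float
    n_calibration_pairs: int
    within_focal_percent: tuple[float, float] | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict[str, Any]:
        return {
            "focal_species": self.focal,
            "nearest_relative": self.nearest,
            "nearest_range_percent": list(self.nearest_range_percent),
            "distance_summary_percent": self.distance_summary_percent,
            "summary_kind": self.summary_kind,
            "calibration_fits": self.fits,
            "headline_mode": self.headline_mode,
            "prediction": self.prediction.to_dict(),
            "prediction_through_origin":
                self.prediction_through_origin.to_dict(),
            "predates_quaternary": self.predates_quaternary,
            "quaternary_boundary_my": self.quaternary_boundary_my,
            "n_calibration_pairs": self.n_calibration_pairs,
            "within_focal_percent": (
                list(self.within_focal_percent)
                if self.within_focal_percent is not None
                else None
            ),
            "warnings": list(self.warnings),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True) + "\n"


def place_taxon(
    aln: Alignment,
    sm: SpeciesMap,
    tree_or_table: Chronogram | CalibrationTable,
    focal: str,
    *,
    use_min: bool = False,
    summary: str = "mean",
    decimals: int = 1,
    interval: str = "prediction",
    level: float = 0.95,
    fixed_halfwidth: float | None = None,
    cherries_only: bool = False,
    boundary: float = QUATERNARY_BOUNDARY_MY,
    deletion: str = "pairwise",
) -> PlacementReport:
    """Run the full placement pipeline for ``focal``.

    ``tree_or_table`` is either a :class:`Chronogram` whose tip labels are
    species names (the focal species must *not* appear on it), or a
    pre-built :class:`CalibrationTable`.  The calibration never includes
    pairs involving the focal species.  The distance inserted into the line
    is the midpoint of the focal-to-nearest percent range (the ``summary``
    convention), or its minimum with ``use_min`` ("smallest estimated
    genetic distance" taken literally).
    """
    if focal not in set(sm.entries.values()):
        raise PlacementError(f"focal species {focal!r} absent from species map")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        dm = distance_matrix(aln, deletion=deletion)
        ranges = species_pair_ranges(dm, sm, decimals=decimals)
        nearest, nrange = nearest_relative(ranges, focal)

        if isinstance(tree_or_table, Chronogram):
            if focal in tree_or_table:
                raise PlacementError(
                    f"focal species {focal!r} is a chronogram tip; its true "
                    "divergence time would leak into its own calibration — "
                    "prune it first"
                )
            times = pair_time_table(tree_or_table, cherries_only=cherries_only)
            table = build_calibration_table(
                ranges, times, summary=summary, exclude=(focal,)
            )
        elif isinstance(tree_or_table, CalibrationTable):
            table = tree_or_table
            involved = set(table.df["species_a"]) | set(table.df["species_b"])
            if focal in involved:
                raise PlacementError(
                    f"focal species {focal!r} appears in the calibration table"
                )
        else:
            raise PlacementError(
                "expected a Chronogram or CalibrationTable, got "
                f"{type(tree_or_table).__name__}"
            )

        fits = {mode: fit_calibration(table, mode) for mode in
                ("unconstrained", "through_origin")}
        headline = fits["unconstrained"]

        x_pred = (
            float(nrange[0]) if use_min
            else distance_range_summary(*nrange)
        )
        prediction = predict_time(
            headline,
            x_pred,
            interval=interval,
            level=level,
            fixed_halfwidth=fixed_halfwidth,
        )
        prediction_origin = predict_time(
            fits["through_origin"],
            x_pred,
            interval=interval,
            level=level,
            fixed_halfwidth=fixed_halfwidth,
        )

        within = None
        focal_tips = sm.tips_of(focal)
        if len(focal_tips) >= 2:
            w = within_species_divergence(dm, sm, focal, decimals=decimals)
            within = (w.min_percent, w.max_percent)

    return PlacementReport(
        focal=focal,
        nearest=nearest,
        nearest_range_percent=(float(nrange[0]), float(nrange[1])),
        distance_summary_percent=float(x_pred),
        summary_kind="min" if use_min else summary,
        fits={mode: fit.to_dict() for mode, fit in fits.items()},
        headline_mode="unconstrained",
        prediction=prediction,
        prediction_through_origin=prediction_origin,
        predates_quaternary=quaternary_flag(prediction, boundary),
        quaternary_boundary_my=boundary,
        n_calibration_pairs=len(table),
        within_focal_percent=within,
        warnings=tuple(str(w.message) for w in caught),
    )
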