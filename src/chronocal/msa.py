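"""Uncorrected p-distances from a multiple sequence alignment.

The uncorrected p-distance between two aligned sequences is the fraction of
differing sites among the pairwise-comparable positions, with no multiple-hit
correction.  A position is comparable only when both sequences carry an
unambiguous A, C, G or T there; gaps (``-``, ``.``), ``?``, ``N`` and every
other IUPAC ambiguity code are treated as missing and removed pair by pair
(pairwise deletion).  This mirrors the "missing" treatment applied by the
standard phylogenetics packages when computing uncorrected distances.

Distances are held internally as fractions in [0, 1]; species-level summaries
are reported as percent ranges (min–max over all cross-individual
comparisons), the conventional display for barcoding-style distance tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "SpeciesMap",
    "DistanceMatrix",
    "PairRangeTable",
    "WithinSpeciesDivergence",
    "AlignmentError",
    "read_alignment",
    "read_species_map",
    "p_distance",
    "distance_matrix",
    "species_pair_ranges",
    "within_species_divergence",
    "round_half_away",
]

# Unambiguous bases code to 0..3; everything else (gaps, ?, N, ambiguity
# codes) codes to MISSING and is excluded pairwise.
MISSING = np.uint8(255)
_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("U")] = _ENCODE[ord("T")]  # RNA-style input

#: symbols accepted in an alignment row (after upper-casing)
ALLOWED_SYMBOLS = frozenset("ACGTURYSWKMBDHVN-?.")

#: pairs with fewer comparable sites than this trigger a warning by default
DEFAULT_MIN_COMPARABLE_SITES = 50


class AlignmentError(ValueError):
    """Raised for malformed alignments or species maps."""


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (display convention for percent
    distances), unlike numpy's banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Alignment:
    """An aligned set of nucleotide sequences.

    Rows are upper-cased on construction and must be of equal length; tip
    identifiers must be unique.
    """

    tip_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tip_ids) != len(self.rows):
            raise AlignmentError("tip_ids and rows differ in length")
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        seen: set[str] = set()
        for tid in self.tip_ids:
            if tid in seen:
                raise AlignmentError(f"duplicate tip id {tid!r}")
            seen.add(tid)
        n = len(self.rows[0])
        if n < 1:
            raise AlignmentError("alignment has zero columns")
        for tid, row in zip(self.tip_ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"ragged alignment: record {tid!r} has length {len(row)}, "
                    f"expected {n}"
                )
            bad = set(row) - ALLOWED_SYMBOLS
            if bad:
                raise AlignmentError(
                    f"record {tid!r} contains invalid symbols {sorted(bad)!r}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def encoded(self) -> np.ndarray:
        """(n_rows, n_sites) uint8 matrix; non-ACGT symbols become MISSING."""
        buf = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.rows), self.n_sites)
        return _ENCODE[buf]

    def row(self, tip_id: str) -> str:
        try:
            return self.rows[self.tip_ids.index(tip_id)]
        except ValueError:
            raise KeyError(tip_id) from None

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid, row in zip(self.tip_ids, self.rows):
                fh.write(f">{tid}\n{row}\n")


@dataclass(frozen=True)
class SpeciesMap:
    """Assignment of alignment tips to species names."""

    entries: Mapping[str, str]

    def species_of(self, tip_id: str) -> str:
        try:
            return self.entries[tip_id]
        except KeyError:
            raise AlignmentError(f"tip id {tip_id!r} has no species assignment")

    def tips_of(self, species: str) -> list[str]:
        return [t for t, s in self.entries.items() if s == species]

    @property
    def species(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.entries.values():
            out[s] = out.get(s, 0) + 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tip_id\tspecies\n")
            for tid, sp in self.entries.items():
                fh.write(f"{tid}\t{sp}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Raises :class:`AlignmentError` (naming the offending record) on ragged
    rows, duplicate identifiers, invalid symbols, or a file with no FASTA
    records; ``FileNotFoundError`` when the path does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise AlignmentError(f"{path}: no FASTA records found ({exc})") from exc
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    return Alignment(
        tip_ids=tuple(r.id for r in records),
        rows=tuple(str(r.seq) for r in records),
    )


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a two-column TSV with header ``tip_id<TAB>species``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tip_id", "species"):
        if col not in df.columns:
            raise AlignmentError(f"{path}: species map missing column {col!r}")
    if df["tip_id"].duplicated().any():
        dup = df.loc[df["tip_id"].duplicated(), "tip_id"].iloc[0]
        raise AlignmentError(f"{path}: duplicate tip id {dup!r} in species map")
    return SpeciesMap(dict(zip(df["tip_id"], df["species"])))


def p_distance(
    row_a: str, row_b: str, *, complete_deletion_mask: np.ndarray | None = None
) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned rows.

    Returns ``(fraction, comparable_sites)``.  Sites where either symbol is
    not an unambiguous A/C/G/T are excluded pairwise; when no comparable
    sites remain the distance is ``nan`` (missing) with count 0.

    ``complete_deletion_mask`` optionally restricts the comparison to a
    pre-computed set of columns (used for the complete-deletion variant).
    """
    if len(row_a) != len(row_b):
        raise AlignmentError(
            f"length mismatch: {len(row_a)} vs {len(row_b)} sites"
        )
    ea = _ENCODE[np.frombuffer(row_a.upper().encode("ascii"), dtype=np.uint8)]
    eb = _ENCODE[np.frombuffer(row_b.upper().encode("ascii"), dtype=np.uint8)]
    ok = (ea != MISSING) & (eb != MISSING)
    if complete_deletion_mask is not None:
        ok &= complete_deletion_mask
    m = int(ok.sum())
    if m == 0:
        return float("nan"), 0
    return float((ea[ok] != eb[ok]).sum()) / m, m


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of uncorrected p-distances (fraction scale).

    ``p[i, j]`` is ``nan`` (never 0) when the pair shares no comparable
    sites; ``comparable_sites[i, j]`` counts the positions actually used.
    """

    tip_ids: tuple[str, ...]
    p: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.tip_ids)
        if self.p.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise AlignmentError("distance matrix shape mismatch")

    def index(self, tip_id: str) -> int:
        try:
            return self.tip_ids.index(tip_id)
        except ValueError:
            raise KeyError(tip_id) from None

    def get(self, a: str, b: str) -> float:
        return float(self.p[self.index(a), self.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.tip_ids, columns=self.tip_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="tip_id")


def distance_matrix(
    aln: Alignment,
    *,
    deletion: str = "pairwise",
    min_comparable_sites: int = DEFAULT_MIN_COMPARABLE_SITES,
) -> DistanceMatrix:
    """All-pairs uncorrected p-distances for an alignment.

    ``deletion`` is ``"pairwise"`` (default: each pair keeps the columns
    comparable for that pair) or ``"complete"`` (only columns that are
    unambiguous A/C/G/T in *every* row are used, for all pairs alike).
    Pairs with fewer than ``min_comparable_sites`` comparable positions
    trigger a warning because their percent distances are unstable.
    """
    if len(aln) < 2:
        raise AlignmentError("need at least 2 rows to compute distances")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    enc = aln.encoded()
    present = enc != MISSING
    n = len(aln)
    p = np.zeros((n, n), dtype=float)
    m = np.zeros((n, n), dtype=np.int64)
    global_mask = present.all(axis=0) if deletion == "complete" else None
    for i in range(n):
        m[i, i] = int(present[i].sum() if global_mask is None else global_mask.sum())
        for j in range(i + 1, n):
            ok = present[i] & present[j] if global_mask is None else global_mask
            mij = int(ok.sum())
            m[i, j] = m[j, i] = mij
            if mij == 0:
                warnings.warn(
                    f"pair {aln.tip_ids[i]!r}/{aln.tip_ids[j]!r} has no "
                    "comparable sites; distance is missing",
                    stacklevel=2,
                )
                p[i, j] = p[j, i] = np.nan
                continue
            if mij < min_comparable_sites:
                warnings.warn(
                    f"pair {aln.tip_ids[i]!r}/{aln.tip_ids[j]!r} has only "
                    f"{mij} comparable sites (< {min_comparable_sites}); "
                    "its percent distance is unstable",
                    stacklevel=2,
                )
            d = float((enc[i, ok] != enc[j, ok]).sum()) / mij
            p[i, j] = p[j, i] = d
    return DistanceMatrix(tip_ids=aln.tip_ids, p=p, comparable_sites=m)


@dataclass(frozen=True)
class PairRangeTable:
    """Percent-distance ranges between (and within) species.

    ``between`` maps each unordered species pair to ``(min_percent,
    max_percent)`` over all cross-individual comparisons; ``within`` maps a
    species with at least two individuals to its within-species range.
    Values are rounded half-away-from-zero to ``decimals`` places.
    """

    between: Mapping[tuple[str, str], tuple[float, float]]
    within: Mapping[str, tuple[float, float]]
    decimals: int = 1
    n_missing_dropped: int = 0

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> tuple[float, float]:
        if a == b:
            return self.within[a]
        return self.between[self._key(a, b)]

    @property
    def species(self) -> list[str]:
        names = {s for pair in self.between for s in pair} | set(self.within)
        return sorted(names)

    def pairs_with(self, species: str) -> dict[str, tuple[float, float]]:
        out = {}
        for (a, b), rng in self.between.items():
            if a == species:
                out[b] = rng
            elif b == species:
                out[a] = rng
        return out

    @staticmethod
    def format_range(rng: tuple[float, float]) -> str:
        lo, hi = rng
        if lo == hi:
            return f"{lo:g}"
        return f"{lo:g}–{hi:g}"

    def to_matrix_frame(self) -> pd.DataFrame:
        """Square lower-triangle table of "min–max" cells (diagonal holds the
        within-species range when available)."""
        sp = self.species
        data = [["" for _ in sp] for _ in sp]
        for i, a in enumerate(sp):
            if a in self.within:
                data[i][i] = self.format_range(self.within[a])
            for j in range(i):
                key = self._key(a, sp[j])
                if key in self.between:
                    data[i][j] = self.format_range(self.between[key])
        return pd.DataFrame(data, index=sp, columns=sp)

    def to_csv(self, path: str | Path) -> None:
        self.to_matrix_frame().to_csv(path, index_label="species")


def _rounded_range(values: Iterable[float], decimals: int) -> tuple[float, float]:
    vals = list(values)
    return (
        round_half_away(min(vals), decimals),
        round_half_away(max(vals), decimals),
    )


def species_pair_ranges(
    dm: DistanceMatrix, sm: SpeciesMap, decimals: int = 1
) -> PairRangeTable:
    """Min–max percent distance for every species pair (and within species).

    Every tip in ``dm`` must be mapped by ``sm``.  Missing distances (no
    comparable sites) are dropped from the ranges with a logged count.
    """
    groups: dict[str, list[int]] = {}
    for idx, tid in enumerate(dm.tip_ids):
        groups.setdefault(sm.species_of(tid), []).append(idx)
    species = sorted(groups)
    between: dict[tuple[str, str], tuple[float, float]] = {}
    within: dict[str, tuple[float, float]] = {}
    dropped = 0
    for si, a in enumerate(species):
        ia = groups[a]
        vals_w = [
            100.0 * dm.p[i, j]
            for k, i in enumerate(ia)
            for j in ia[k + 1 :]
            if not np.isnan(dm.p[i, j])
        ]
        n_within = len(ia) * (len(ia) - 1) // 2
        dropped += n_within - len(vals_w)
        if vals_w:
            within[a] = _rounded_range(vals_w, decimals)
        for b in species[si + 1 :]:
            vals = [
                100.0 * dm.p[i, j]
                for i in ia
                for j in groups[b]
                if not np.isnan(dm.p[i, j])
            ]
            dropped += len(ia) * len(groups[b]) - len(vals)
            if vals:
                between[(a, b)] = _rounded_range(vals, decimals)
    if dropped:
        logger.info("species_pair_ranges: dropped %d missing distances", dropped)
    return PairRangeTable(
        between=between, within=within, decimals=decimals,
        n_missing_dropped=dropped,
    )


@dataclass(frozen=True)
class WithinSpeciesDivergence:
    """Within-species percent-distance range compared to a reference band."""

    species: str
    min_percent: float
    max_percent: float
    reference: tuple[float, float]
    #: "inside", "below", "above" or "straddles" the reference interval
    relation: str = field(init=False)

    def __post_init__(self) -> None:
        lo, hi = self.reference
        if self.max_percent < lo:
            rel = "below"
        elif self.min_percent > hi:
            rel = "above"
        elif lo <= self.min_percent and self.max_percent <= hi:
            rel = "inside"
        else:
            rel = "straddles"
        object.__setattr__(self, "relation", rel)

    @property
    def inside_reference(self) -> bool:
        return self.relation == "inside"


def within_species_divergence(
    dm: DistanceMatrix,
    sm: SpeciesMap,
    species: str,
    *,
    reference: tuple[float, float] = (0.2, 0.9),
    decimals: int = 1,
) -> WithinSpeciesDivergence:
    """Percent-distance range among conspecific individuals.

    The default reference band 0.2–0.9% is the published range of
    conspecific 16S divergence in the study group; the result records
    whether the observed range falls inside it.
    """
    idx = [i for i, t in enumerate(dm.tip_ids) if sm.species_of(t) == species]
    if not idx:
        raise AlignmentError(f"species {species!r} has no tips in the matrix")
    if len(idx) < 2:
        raise AlignmentError(
            f"species {species!r} has a single individual; "
            "within-species divergence is undefined"
        )
    vals = [
        100.0 * dm.p[i, j]
        for k, i in enumerate(idx)
        for j in idx[k + 1 :]
        if not np.isnan(dm.p[i, j])
    ]
    if not vals:
        raise AlignmentError(
            f"species {species!r}: all within-species distances are missing"
        )
    lo, hi = _rounded_range(vals, decimals)
    return WithinSpeciesDivergence(
        species=species, min_percent=lo, max_percent=hi, reference=reference
    )
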