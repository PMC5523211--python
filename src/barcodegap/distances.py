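"""Pairwise p-distances under pairwise deletion and per-species summaries.

The p-distance between two aligned sequences is the proportion of differing
sites among the sites where *both* sequences have a determined nucleotide
(pairwise deletion).  When a pair shares no determined site its distance is
undefined, marked NaN, with overlap 0.

``species_summaries`` produces the per-species intra-/interspecific summary
table used for barcode-gap assessment: for each species the minimum, maximum,
mean and sample standard deviation of (a) all pairwise distances within the
species and (b) all distances from its members to members of every other
in-scope species.  Intraspecific fields are NA for singleton species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import LabeledAlignment, SpecimenRecord, MISSING_CODE, _CODE_LUT
from .errors import AlignmentShapeError, SummaryError, ValidationError

logger = logging.getLogger("barcodegap")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric specimen-by-specimen p-distance matrix with overlap counts.

    ``d[i, j]`` is NaN iff ``overlap[i, j] == 0``; the diagonal is 0 with
    overlap equal to the row's number of determined sites.
    """

    ids: tuple[str, ...]
    d: np.ndarray        # (n, n) float, proportions in [0, 1], NaN = undefined
    overlap: np.ndarray  # (n, n) int, sites determined in both sequences

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def is_complete(self) -> bool:
        return not np.isnan(self.d).any()

    def to_long_frame(self, species: dict[str, str] | None = None) -> pd.DataFrame:
        """Long-format table of all unordered pairs (id_a, id_b, distance, overlap)."""
        rows = []
        for i, j in itertools.combinations(range(self.n), 2):
            row = {
                "id_a": self.ids[i],
                "id_b": self.ids[j],
            }
            if species is not None:
                row["species_a"] = species[self.ids[i]]
                row["species_b"] = species[self.ids[j]]
            row["p_distance"] = self.d[i, j]
            row["overlap"] = int(self.overlap[i, j])
            rows.append(row)
        return pd.DataFrame(rows)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[arr]


def p_distance(row_a: str | np.ndarray, row_b: str | np.ndarray) -> tuple[float, int]:
    """p-distance and overlap for one pair of aligned rows.

    Accepts character strings or uint8 code arrays (A,C,G,T -> 0..3,
    missing -> 255).  Returns ``(nan, 0)`` when no site is determined in both.
    """
    a = _encode(row_a) if isinstance(row_a, str) else np.asarray(row_a, dtype=np.uint8)
    b = _encode(row_b) if isinstance(row_b, str) else np.asarray(row_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise AlignmentShapeError(
            f"length mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    both = (a != MISSING_CODE) & (b != MISSING_CODE)
    overlap = int(both.sum())
    if overlap == 0:
        return (float("nan"), 0)
    diff = int((a[both] != b[both]).sum())
    return (diff / overlap, overlap)


def pdist_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs p-distance and overlap matrices from a uint8 code matrix.

    Vectorized: overlap via the Gram matrix of the determined-site indicator,
    matches via per-base indicator Gram matrices.
    """
    valid = (codes != MISSING_CODE)
    v = valid.astype(np.float64)
    overlap = v @ v.T
    matches = np.zeros_like(overlap)
    for b in range(4):
        x = (codes == b).astype(np.float64)
        matches += x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (overlap - matches) / overlap
    d[overlap == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    # diagonal overlap = the row's own determined-site count (already is).
    return d, overlap.astype(np.int64)


def distance_matrix(aln: LabeledAlignment) -> DistanceMatrix:
    """Full pairwise p-distance matrix of a labeled alignment."""
    d, overlap = pdist_from_codes(aln.codes)
    return DistanceMatrix(ids=aln.ids, d=d, overlap=overlap)


SUMMARY_COLUMNS = [
    "species", "n",
    "intra_min", "intra_max", "intra_mean", "intra_sd", "intra_n_pairs",
    "inter_min", "inter_max", "inter_mean", "inter_sd", "inter_n_pairs",
]


def _set_stats(values: np.ndarray) -> tuple[float, float, float, float, int]:
    """min/max/mean/sample-sd/count of a distance set, NaN entries excluded.

    With exactly one value the sd is reported as 0.0 (degeneracy visible via
    the pair count).
    """
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        return (np.nan, np.nan, np.nan, np.nan, 0)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return (float(values.min()), float(values.max()), float(values.mean()), sd, n)


def species_summaries(
    dm: DistanceMatrix,
    records: tuple[SpecimenRecord, ...] | list[SpecimenRecord],
    scope: str = "ingroup_only",
) -> tuple[pd.DataFrame, dict]:
    """Per-species intra/inter p-distance summary plus group-level aggregates.

    ``scope`` is ``"ingroup_only"`` (outgroup specimens contribute to no row
    and no interspecific set) or ``"all"``.  Mean is the arithmetic mean of
    the pair-distance set; SD is the sample standard deviation (n-1
    denominator).  Undefined pairs are excluded with a logged count.

    Returns ``(table, aggregates)`` where ``aggregates`` holds the overall
    intraspecific maximum, overall interspecific min/max, and the species
    pair attaining the interspecific minimum.
    """
    if scope not in ("ingroup_only", "all"):
        raise ValidationError(f"unknown scope {scope!r}")
    by_id = {r.seq_id: r for r in records}
    missing = [sid for sid in dm.ids if sid not in by_id]
    if missing:
        raise ValidationError(f"ids without metadata record: {', '.join(missing)}")

    in_scope = [
        sid for sid in dm.ids
        if scope == "all" or by_id[sid].role == "ingroup"
    ]
    species_order: dict[str, list[int]] = {}
    idx_of = {sid: i for i, sid in enumerate(dm.ids)}
    for sid in in_scope:
        species_order.setdefault(by_id[sid].species, []).append(idx_of[sid])
    if len(species_order) < 2:
        raise ValidationError("need at least two species in scope")

    n_undefined = int(np.isnan(dm.d[np.triu_indices(dm.n, k=1)]).sum())
    if n_undefined:
        logger.warning("%d undefined pair distance(s) excluded from summaries",
                       n_undefined)

    rows = []
    inter_min = (np.inf, None)  # (value, (species_a, species_b))
    inter_max = -np.inf
    intra_max = -np.inf
    for sp, idx in species_order.items():
        idx = np.array(idx)
        others = np.array(
            [i for osp, oidx in species_order.items() if osp != sp for i in oidx]
        )
        if idx.size >= 2:
            ii, jj = np.triu_indices(idx.size, k=1)
            intra = dm.d[idx[ii], idx[jj]]
        else:
            intra = np.array([])
        inter = dm.d[np.ix_(idx, others)].ravel()
        i_min, i_max, i_mean, i_sd, i_n = _set_stats(intra)
        e_min, e_max, e_mean, e_sd, e_n = _set_stats(inter)
        if e_n == 0 and i_n == 0 and idx.size >= 2:
            raise SummaryError(f"species {sp!r}: all pair distances undefined")
        if idx.size < 2:
            i_min = i_max = i_mean = i_sd = np.nan
            i_n = 0
        rows.append({
            "species": sp, "n": idx.size,
            "intra_min": i_min, "intra_max": i_max,
            "intra_mean": i_mean, "intra_sd": i_sd, "intra_n_pairs": i_n,
            "inter_min": e_min, "inter_max": e_max,
            "inter_mean": e_mean, "inter_sd": e_sd, "inter_n_pairs": e_n,
        })
        if i_n > 0:
            intra_max = max(intra_max, i_max)
        # track group inter extremes with the attaining pair
        for osp, oidx in species_order.items():
            if osp == sp:
                continue
            block = dm.d[np.ix_(idx, np.array(oidx))]
            block = block[~np.isnan(block)]
            if block.size == 0:
                continue
            bmin, bmax = float(block.min()), float(block.max())
            if bmin < inter_min[0]:
                inter_min = (bmin, tuple(sorted((sp, osp))))
            inter_max = max(inter_max, bmax)

    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    aggregates = {
        "overall_intra_max": None if intra_max == -np.inf else intra_max,
        "overall_inter_min": None if inter_min[1] is None else inter_min[0],
        "overall_inter_max": None if inter_max == -np.inf else inter_max,
        "inter_min_species_pair": inter_min[1],
        "n_undefined_pairs_excluded": n_undefined,
    }
    return table, aggregates


def format_summary(table: pd.DataFrame, percent: bool = False) -> pd.DataFrame:
    """Render a summary table for reporting, optionally scaling to percent."""
    out = table.copy()
    if percent:
        for col in out.columns:
            if col.startswith(("intra_", "inter_")) and not col.endswith("n_pairs"):
                out[col] = out[col] * 100.0
    return out
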