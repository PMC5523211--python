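"""Site statistics and character-based "pure" diagnostic-site detection.

A site is *pure diagnostic* for a focal species when every determined
character of the focal species at that site is one single state, and no
determined character of any other species in the comparison universe equals
that state.  Species wholly missing at the site impose no constraint: they
can neither gain nor block a diagnosis there.  Ambiguity codes count as
missing, never as partial matches, so a diagnosis is always supported by
unambiguous calls only.

Site statistics follow the usual alignment conventions: a *variable* site
carries at least two distinct determined states; a *parsimony-informative*
site carries at least two states that are each present in at least two
sequences (missing characters excluded throughout).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .alignment_io import BASES, LabeledAlignment, MISSING_CODE
from .errors import ValidationError


@dataclass(frozen=True)
class SiteStats:
    """Alignment-level site counts (variable / parsimony-informative)."""

    L: int
    variable: int
    parsimony_informative: int

    def __post_init__(self):
        assert 0 <= self.parsimony_informative <= self.variable <= self.L


@dataclass(frozen=True)
class DiagnosticEntry:
    """One pure diagnostic: species fixed for ``state`` at 1-based ``site``."""

    species: str
    site: int
    state: str
    n_observed_focal: int
    n_missing_focal: int


@dataclass(frozen=True)
class DiagnosticTable:
    """All pure diagnostics plus the species-by-site state matrix view.

    ``matrix`` rows are species, columns are the union of diagnostic sites
    (ascending, 1-based labels); a cell holds the species' observed state,
    states joined with ``/`` if polymorphic, or ``-`` when every member is
    missing there.  ``counts`` includes species with zero diagnostics.
    """

    entries: tuple[DiagnosticEntry, ...]
    matrix: pd.DataFrame
    counts: dict[str, int]

    def sites_for(self, species: str) -> list[int]:
        return [e.site for e in self.entries if e.species == species]


def _base_counts(codes: np.ndarray) -> np.ndarray:
    """(4, L) per-site counts of each determined base."""
    return np.stack([(codes == b).sum(axis=0) for b in range(4)])


def site_statistics(aln: LabeledAlignment) -> SiteStats:
    """Count variable and parsimony-informative sites (missing excluded)."""
    counts = _base_counts(aln.codes)
    n_states = (counts > 0).sum(axis=0)
    variable = int((n_states >= 2).sum())
    informative = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return SiteStats(L=aln.L, variable=variable, parsimony_informative=informative)


def pure_diagnostic_sites(
    aln: LabeledAlignment,
    scope: set[str] | frozenset[str] | None = None,
    min_observed: int = 1,
) -> DiagnosticTable:
    """Detect pure diagnostic sites for every species in the comparison universe.

    ``scope`` is the set of species forming the comparison universe; by
    default the ingroup species.  ``min_observed`` is the minimum number of
    determined focal characters required to call fixation (default 1, which
    lets single-specimen species own diagnostics).
    """
    if min_observed < 1:
        raise ValidationError("min_observed must be >= 1")
    present = set(aln.species_labels())
    if scope is None:
        scope_list = list(aln.species_labels(role="ingroup"))
    else:
        absent = set(scope) - present
        if absent:
            raise ValidationError(
                f"species not in alignment: {', '.join(sorted(absent))}"
            )
        scope_list = [sp for sp in aln.species_labels() if sp in set(scope)]
    if len(scope_list) < 2:
        raise ValidationError("need at least two species in the comparison universe")

    codes = aln.codes
    rows_of = {sp: [] for sp in scope_list}
    for i, r in enumerate(aln.records):
        if r.species in rows_of:
            rows_of[r.species].append(i)

    # per-species, per-site base counts: (n_species, 4, L)
    sp_counts = np.stack([_base_counts(codes[rows_of[sp]]) for sp in scope_list])
    n_obs = sp_counts.sum(axis=1)               # (n_species, L) determined counts
    total_counts = sp_counts.sum(axis=0)        # (4, L) over the whole universe

    entries: list[DiagnosticEntry] = []
    for s, sp in enumerate(scope_list):
        focal = sp_counts[s]                    # (4, L)
        others = total_counts - focal
        n_focal = n_obs[s]
        fixed_state = np.argmax(focal > 0, axis=0)          # candidate state
        is_fixed = ((focal > 0).sum(axis=0) == 1) & (n_focal >= min_observed)
        absent_elsewhere = others[fixed_state, np.arange(aln.L)] == 0
        hits = np.flatnonzero(is_fixed & absent_elsewhere)
        n_members = len(rows_of[sp])
        for j in hits:
            entries.append(DiagnosticEntry(
                species=sp,
                site=int(j) + 1,
                state=BASES[int(fixed_state[j])],
                n_observed_focal=int(n_focal[j]),
                n_missing_focal=n_members - int(n_focal[j]),
            ))

    entries.sort(key=lambda e: (scope_list.index(e.species), e.site))
    sites = sorted({e.site for e in entries})
    matrix = _state_matrix(aln, scope_list, sites)
    counts = {sp: sum(1 for e in entries if e.species == sp) for sp in scope_list}
    return DiagnosticTable(entries=tuple(entries), matrix=matrix, counts=counts)


def _state_matrix(
    aln: LabeledAlignment, species: list[str], sites: list[int]
) -> pd.DataFrame:
    codes = aln.codes
    rows_of = {sp: [] for sp in species}
    for i, r in enumerate(aln.records):
        if r.species in rows_of:
            rows_of[r.species].append(i)
    data = {}
    for site in sites:
        col = []
        for sp in species:
            vals = codes[rows_of[sp], site - 1]
            determined = sorted(set(int(v) for v in vals if v != MISSING_CODE))
            col.append("/".join(BASES[v] for v in determined) if determined else "-")
        data[str(site)] = col
    return pd.DataFrame(data, index=pd.Index(species, name="species"))


def diagnostic_report(table: DiagnosticTable) -> str:
    """Render the diagnostics as a plain-text species-by-site matrix.

    Columns are the diagnostic sites in ascending order; each cell shows the
    species' observed state(s), with diagnostic cells flagged by a trailing
    ``*`` and wholly-missing cells shown as ``-``.  The output is
    tab-separated and parseable back into the entries list.
    """
    diag = {(e.species, e.site): e.state for e in table.entries}
    out = StringIO()
    sites = list(table.matrix.columns)
    out.write("\t".join(["species"] + sites) + "\n")
    for sp in table.matrix.index:
        cells = []
        for site in sites:
            cell = table.matrix.at[sp, site]
            if (sp, int(site)) in diag:
                cell = cell + "*"
            cells.append(cell)
        out.write("\t".join([sp] + cells) + "\n")
    return out.getvalue()


def parse_diagnostic_report(text: str) -> list[tuple[str, int, str]]:
    """Recover (species, site, state) diagnostic triples from the text matrix."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    triples = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        sp = parts[0]
        for site, cell in zip(header, parts[1:]):
            if cell.endswith("*"):
                triples.append((sp, int(site), cell[:-1]))
    return triples
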