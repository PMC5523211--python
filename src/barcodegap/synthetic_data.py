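"""Seeded generator of COI-like barcode datasets with known ground truth.

The generator emulates the statistical regime of a typical drosophilid
barcoding study: ~10 species with 1–9 specimens each, a ~660-site alignment,
intraspecific p-distances mostly below 1%, interspecific distances of
roughly 3–13%, a handful of species-fixed diagnostic sites, and missing
data appearing as unsequenced leading/trailing runs.

Model
-----
Substitutions are per-site Bernoulli events: a site mutates with the given
probability and moves to one of the three alternative bases uniformly.  A
root sequence is drawn uniformly; each species haplotype mutates away from
the root at rate ``inter_sub``; each specimen mutates away from its species
haplotype at rate ``intra_sub``.  ``planted_diagnostics`` sites per species
(disjoint across species) are overwritten so the focal species carries a
state distinct from the root while every other species carries the root
state.  Planted sites are exempt from specimen-level mutation for every
specimen and are drawn outside the maximal terminal-truncation window, so
every planted diagnostic is observable and pure by construction — recovery
tests then isolate detector correctness from simulation noise.  Outgroup
sequences are single haplotypes drawn at rate ``outgroup_sub``.

Everything is driven by one ``numpy`` Generator, so identical config + seed
reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import (
    BASES,
    LabeledAlignment,
    SpecimenRecord,
    write_fasta_alignment,
    write_metadata,
)
from .errors import ConfigError

#: Specimen counts mirroring a 44-sequence, 10-species study design.
DEFAULT_SPECIMENS = (1, 2, 9, 6, 6, 4, 3, 6, 4, 3)


@dataclass(frozen=True)
class SyntheticConfig:
    n_species: int = 10
    specimens_per_species: tuple[int, ...] = DEFAULT_SPECIMENS
    L: int = 664
    inter_sub: float = 0.05
    intra_sub: float = 0.005
    planted_diagnostics: int = 3
    missing_end_prob: float = 0.2
    missing_end_max: int = 60
    n_outgroups: int = 4
    outgroup_sub: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if len(self.specimens_per_species) != self.n_species:
            raise ConfigError(
                f"specimens_per_species has {len(self.specimens_per_species)} "
                f"entries for {self.n_species} species"
            )
        if any(m < 1 for m in self.specimens_per_species):
            raise ConfigError("every species needs >= 1 specimen")
        for name in ("inter_sub", "intra_sub", "missing_end_prob", "outgroup_sub"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.planted_diagnostics < 0 or self.n_outgroups < 0:
            raise ConfigError("counts must be non-negative")
        plantable = self.L - (2 * self.missing_end_max
                              if self.missing_end_prob > 0 else 0)
        if plantable < self.n_species * self.planted_diagnostics:
            raise ConfigError(
                f"L={self.L} leaves only {plantable} always-observed sites, "
                f"too few for {self.n_species} x {self.planted_diagnostics} "
                "disjoint planted sites"
            )
        if self.L < 1:
            raise ConfigError("L must be >= 1")

    def species_names(self) -> tuple[str, ...]:
        return tuple(f"species{i + 1:02d}" for i in range(self.n_species))

    def outgroup_names(self) -> tuple[str, ...]:
        return tuple(f"outgroup{i + 1}" for i in range(self.n_outgroups))


@dataclass(frozen=True)
class Truth:
    """Ground truth of a simulated dataset, for recovery tests."""

    haplotypes: dict[str, str]                       # species -> haplotype string
    planted: dict[str, tuple[tuple[int, str], ...]]  # species -> ((site1based, state),)
    mutations: dict[str, tuple[int, ...]]            # seq_id -> 1-based mutated sites
    missing_runs: dict[str, tuple[int, int]]         # seq_id -> (n_leading, n_trailing)
    expected: dict[str, float]                       # closed-form distance expectations


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            protect: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Bernoulli substitution to a uniform alternative base."""
    mask = rng.random(seq.size) < rate
    if protect is not None:
        mask[protect] = False
    hit = np.flatnonzero(mask)
    out = seq.copy()
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, hit


def _to_chars(codes: np.ndarray) -> np.ndarray:
    lut = np.array(list(BASES), dtype="<U1")
    return lut[codes]


def simulate_barcode_dataset(cfg: SyntheticConfig) -> tuple[LabeledAlignment, Truth]:
    """Generate a labeled alignment and its ground truth (fully seeded)."""
    rng = np.random.default_rng(cfg.seed)
    L, k = cfg.L, cfg.planted_diagnostics
    species = cfg.species_names()

    root = rng.integers(0, 4, size=L)

    haps = np.empty((cfg.n_species, L), dtype=np.int64)
    for s in range(cfg.n_species):
        haps[s], _ = _mutate(rng, root, cfg.inter_sub)

    # disjoint planted layout: focal gets a non-root state, others the root
    # state; sites drawn outside the truncation window so they are always
    # observed, and protected from specimen mutation so purity is exact
    lo = cfg.missing_end_max if cfg.missing_end_prob > 0 else 0
    hi = L - lo
    perm = lo + rng.permutation(hi - lo)
    planted: dict[str, list[tuple[int, str]]] = {sp: [] for sp in species}
    all_planted: list[int] = []
    for s, sp in enumerate(species):
        sites = np.sort(perm[s * k:(s + 1) * k])
        all_planted.extend(int(j) for j in sites)
        for j in sites:
            haps[:, j] = root[j]
            alt = (root[j] + rng.integers(1, 4)) % 4
            haps[s, j] = alt
            planted[sp].append((int(j) + 1, BASES[int(alt)]))

    protect_sites = np.array(sorted(all_planted), dtype=np.int64)
    records: list[SpecimenRecord] = []
    rows: list[np.ndarray] = []
    mutations: dict[str, tuple[int, ...]] = {}
    missing_runs: dict[str, tuple[int, int]] = {}
    for s, sp in enumerate(species):
        for m in range(cfg.specimens_per_species[s]):
            sid = f"{sp}_{m + 1}"
            seq, hit = _mutate(rng, haps[s], cfg.intra_sub,
                               protect=protect_sites)
            chars = _to_chars(seq)
            lead = trail = 0
            if cfg.missing_end_prob > 0 and rng.random() < cfg.missing_end_prob:
                run = int(rng.integers(1, cfg.missing_end_max + 1))
                if rng.random() < 0.5:
                    chars[:run] = "-"
                    lead = run
                else:
                    chars[L - run:] = "-"
                    trail = run
            records.append(SpecimenRecord(seq_id=sid, species=sp, role="ingroup"))
            rows.append(chars)
            mutations[sid] = tuple(int(h) + 1 for h in hit)
            missing_runs[sid] = (lead, trail)

    for o, name in enumerate(cfg.outgroup_names()):
        seq, hit = _mutate(rng, root, cfg.outgroup_sub)
        sid = f"{name}_1"
        records.append(SpecimenRecord(seq_id=sid, species=name, role="outgroup"))
        rows.append(_to_chars(seq))
        mutations[sid] = tuple(int(h) + 1 for h in hit)
        missing_runs[sid] = (0, 0)

    aln = LabeledAlignment(records=tuple(records), matrix=np.stack(rows))
    truth = Truth(
        haplotypes={sp: "".join(_to_chars(haps[s])) for s, sp in enumerate(species)},
        planted={sp: tuple(v) for sp, v in planted.items()},
        mutations=mutations,
        missing_runs=missing_runs,
        expected=expected_distance(cfg),
    )
    return aln, truth


def _p_differ(rates: list[float]) -> float:
    """Probability two sequence ends of a substitution path differ at a site.

    Each event on the path substitutes with probability ``a`` to a uniform
    alternative; composing events multiplies the (1 - 4a/3) eigenvalues of
    the one-event transition matrix, so P(differ) = 3/4 (1 - prod(1 - 4a/3)).
    For a two-branch path this reduces to 2a(1-a) + (2/3)a^2.
    """
    prod = 1.0
    for a in rates:
        prod *= 1.0 - 4.0 * a / 3.0
    return 0.75 * (1.0 - prod)


def expected_distance(cfg: SyntheticConfig) -> dict[str, float]:
    """Closed-form expected p-distances under the generator's scheme.

    Planted sites (n_species * k of them) are mutation-exempt for all
    specimens, so they are identical within a species and contribute nothing
    to the intraspecific expectation; for a pair of different species,
    exactly the pair's own 2k planted sites differ with certainty while
    sites planted for third species are identical (both reset to root).
    Elsewhere the per-site difference probability follows the path formula
    of :func:`_p_differ`: ``[p, p]`` for an intraspecific pair, ``[p, q, q,
    p]`` for an interspecific one.
    """
    p, q, L, k, n = (cfg.intra_sub, cfg.inter_sub, cfg.L,
                     cfg.planted_diagnostics, cfg.n_species)
    free = L - n * k
    intra = free * _p_differ([p, p]) / L
    inter = (free * _p_differ([p, q, q, p]) + 2 * k) / L
    return {"intra": intra, "inter": inter}


def write_dataset(
    aln: LabeledAlignment, truth: Truth, out_dir: str | Path,
    prefix: str = "synthetic",
) -> dict[str, Path]:
    """Write FASTA + metadata TSV + truth.json for a simulated dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{prefix}.fasta"
    meta = out_dir / f"{prefix}.tsv"
    truth_path = out_dir / f"{prefix}.truth.json"
    write_fasta_alignment(aln, fasta)
    write_metadata(aln.records, meta)
    payload = {
        "haplotypes": truth.haplotypes,
        "planted": {sp: list(map(list, v)) for sp, v in truth.planted.items()},
        "mutations": {k: list(v) for k, v in truth.mutations.items()},
        "missing_runs": {k: list(v) for k, v in truth.missing_runs.items()},
        "expected": truth.expected,
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return {"fasta": fasta, "metadata": meta, "truth": truth_path}
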