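"""End-to-end barcode species-delimitation analysis.

``run_analysis`` executes the whole workflow on one dataset: load and bind
the alignment, compute the p-distance matrix and per-species summaries,
build the NJ tree with bootstrap supports, test per-species monophyly,
count site statistics, detect pure diagnostic sites, and write a report
bundle of plain TSV/JSON/Newick files.  Re-running with identical inputs,
config and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment_io import LabeledAlignment, load_labeled_alignment
from .diagnostics import diagnostic_report, pure_diagnostic_sites, site_statistics
from .distances import distance_matrix, format_summary, species_summaries
from .errors import StageError, ValidationError
from .tree import bootstrap_supports, monophyly_report, write_newick

logger = logging.getLogger("barcodegap")

BUNDLE_FILES = (
    "distances.tsv", "summary.tsv", "tree.nwk", "monophyly.tsv",
    "diagnostics.tsv", "matrix.tsv", "sitestats.json", "run_log.json",
)


@dataclass(frozen=True)
class RunConfig:
    alignment: Path
    metadata: Path
    out_dir: Path
    scope: str = "ingroup_only"
    replicates: int = 1000
    seed: int = 0
    min_observed: int = 1
    percent: bool = False
    strict_binding: bool = True
    clamp_negative: bool = False

    def __post_init__(self):
        object.__setattr__(self, "alignment", Path(self.alignment))
        object.__setattr__(self, "metadata", Path(self.metadata))
        object.__setattr__(self, "out_dir", Path(self.out_dir))


@dataclass(frozen=True)
class ReportBundle:
    """Paths of the files written by one analysis run."""

    out_dir: Path
    files: dict[str, Path]
    summary: pd.DataFrame
    aggregates: dict
    monophyly: pd.DataFrame
    newick: str
    n_diagnostics: int


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format, na_rep="NA")


def run_analysis(cfg: RunConfig, aln: LabeledAlignment | None = None) -> ReportBundle:
    """Run the full analysis and write the report bundle.

    A failure in any stage raises :class:`StageError` naming the stage, and
    partial outputs are removed.  ``aln`` may be passed directly to skip the
    load stage (the config paths are then only recorded for provenance).
    """
    stage = "load"
    try:
        if aln is None:
            aln = load_labeled_alignment(
                cfg.alignment, cfg.metadata, strict=cfg.strict_binding
            )
        if not any(r.role == "ingroup" for r in aln.records):
            raise ValidationError("dataset has no ingroup specimens")

        stage = "distances"
        dm = distance_matrix(aln)
        long_df = dm.to_long_frame(species=aln.species_of())

        stage = "summaries"
        summary, aggregates = species_summaries(dm, aln.records, scope=cfg.scope)

        stage = "tree"
        tree = bootstrap_supports(
            aln, replicates=cfg.replicates, seed=cfg.seed,
            clamp_negative=cfg.clamp_negative,
        )
        newick = write_newick(tree)

        stage = "monophyly"
        mono = monophyly_report(tree, aln.records)

        stage = "site_statistics"
        stats = site_statistics(aln)

        stage = "diagnostics"
        scope_set = None if cfg.scope == "ingroup_only" else set(aln.species_labels())
        diag = pure_diagnostic_sites(aln, scope=scope_set,
                                     min_observed=cfg.min_observed)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise StageError(stage, exc) from exc

    stage = "write"
    out = cfg.out_dir
    tmp = out.parent / (out.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        files = {name: tmp / name for name in BUNDLE_FILES}
        _write_tsv(long_df, files["distances.tsv"])
        _write_tsv(format_summary(summary, percent=cfg.percent), files["summary.tsv"])
        files["tree.nwk"].write_text(newick)
        _write_tsv(mono, files["monophyly.tsv"])
        diag_df = pd.DataFrame(
            [{
                "species": e.species, "site": e.site, "state": e.state,
                "n_observed_focal": e.n_observed_focal,
                "n_missing_focal": e.n_missing_focal,
            } for e in diag.entries],
            columns=["species", "site", "state",
                     "n_observed_focal", "n_missing_focal"],
        )
        _write_tsv(diag_df, files["diagnostics.tsv"])
        files["matrix.tsv"].write_text(diagnostic_report(diag))
        files["sitestats.json"].write_text(json.dumps({
            "L": stats.L,
            "variable": stats.variable,
            "parsimony_informative": stats.parsimony_informative,
        }, indent=1) + "\n")
        run_log = {
            "package": "barcodegap",
            "version": __version__,
            "config": {k: str(v) if isinstance(v, Path) else v
                       for k, v in asdict(cfg).items()},
            "inputs": {
                "alignment_sha256": _sha256(cfg.alignment)
                if cfg.alignment.exists() else None,
                "metadata_sha256": _sha256(cfg.metadata)
                if cfg.metadata.exists() else None,
            },
            "n_sequences": aln.n,
            "n_sites": aln.L,
            "aggregates": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in aggregates.items()
            },
        }
        files["run_log.json"].write_text(
            json.dumps(run_log, indent=1, sort_keys=True) + "\n"
        )
        if out.exists():
            shutil.rmtree(out)
        tmp.rename(out)
    except Exception as exc:  # noqa: BLE001
        shutil.rmtree(tmp, ignore_errors=True)
        raise StageError(stage, exc) from exc

    files = {name: out / name for name in BUNDLE_FILES}
    return ReportBundle(
        out_dir=out, files=files, summary=summary, aggregates=aggregates,
        monophyly=mono, newick=newick, n_diagnostics=len(diag.entries),
    )
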