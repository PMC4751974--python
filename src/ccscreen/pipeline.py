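"""End-to-end pipeline and fixture generation.

The pipeline mirrors the four-stage funnel of the design protocol:
generate library -> interactome screen -> find pairs -> find quadruples,
logging the count at every stage so a run can be audited against expected
milestones (library size, evaluated pairs, stored interactions, accepted
sets).  Identical configuration gives byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import fixtures
from .config import RunConfig, default_config_dict, save_config
from .io import read_fasta_with_register, write_fasta_with_register
from .libgen import expand_template
from .screen import import_filter, screen_interactome, write_store
from .search import find_pairs, find_quadruples, write_sets

__all__ = ["PipelineReport", "PipelineError", "make_fixtures", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass(frozen=True)
class PipelineReport:
    """Stage-by-stage counts of one pipeline run."""

    library_size: int
    rejected_homodimer: int
    rejected_antiparallel: int
    retained: int
    evaluated_pairs: int
    stored_interactions: int
    pair_sets: int
    quadruple_sets: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the built-in reference inputs as files.

    Produces the eight-peptide FASTA (registers in headers), the degenerate
    template + symbol table, and the default configuration.  Regeneration is
    byte-identical: nothing timestamped goes into the files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "octet.fasta",
        "template": outdir / "template.txt",
        "symbols": outdir / "symbols.yaml",
        "config": outdir / "config.yaml",
    }
    write_fasta_with_register(fixtures.reference_octet(), paths["peptides"])
    paths["template"].write_text(fixtures.TEMPLATE_TEXT + "\n")
    save_config(
        {s: list(opts) for s, opts in fixtures.TEMPLATE_SYMBOLS.items()},
        paths["symbols"],
    )
    cfg = default_config_dict()
    cfg["template"] = {
        "text": fixtures.TEMPLATE_TEXT,
        "symbols": {s: list(o) for s, o in fixtures.TEMPLATE_SYMBOLS.items()},
        "start_letter": "g",
        "cap_prefix": fixtures.CAP_PREFIX,
        "cap_suffix": fixtures.CAP_SUFFIX,
        "constraint": "a:N=2,I=2",
    }
    save_config(cfg, paths["config"])
    return paths


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # re-tag with the failing stage
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineReport:
    """Execute generate -> screen -> find pairs -> find quadruples.

    The peptide input is the configured library FASTA if given, otherwise
    the expansion of the configured template (with its composition
    constraint).  Artifacts written to ``outdir``: library.fasta, store.tsv,
    heatmap.tsv, interactions.tsv, pairs.jsonl, quadruples.jsonl,
    report.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.library_path:
        peptides = _stage("generate-library")(
            read_fasta_with_register, config.library_path
        )
    elif config.template is not None:
        peptides = _stage("generate-library")(
            lambda: list(expand_template(config.template, config.constraint))
        )
    else:
        raise PipelineError("stage 'generate-library' failed: no library or template configured")
    library_size = len(peptides)
    logger.info("stage generate-library: %d peptides", library_size)
    write_fasta_with_register(peptides, outdir / "library.fasta")

    retained, rejections = _stage("import-filter")(
        import_filter, peptides, config.model, config.criteria
    )
    n_homo = sum(r.reason == "homodimer_tm" for r in rejections)
    n_anti = sum(r.reason == "antiparallel_complementary" for r in rejections)
    logger.info(
        "stage import-filter: %d retained (%d homodimer, %d antiparallel rejections)",
        len(retained), n_homo, n_anti,
    )

    interactome = _stage("screen")(
        screen_interactome, retained, config.model, config.criteria
    )
    stored = interactome.stored_interactions()
    logger.info(
        "stage screen: %d evaluated pairs, %d stored", interactome.n_pairs, len(stored)
    )
    write_store(stored, outdir / "store.tsv")
    interactome.export_heatmap(outdir / "heatmap.tsv", outdir / "interactions.tsv")

    pair_sets = _stage("find-pairs")(find_pairs, stored, interactome, config.criteria)
    logger.info("stage find-pairs: %d sets", len(pair_sets))
    write_sets(pair_sets, outdir / "pairs.jsonl")

    quad_sets = _stage("find-quadruples")(
        find_quadruples, pair_sets, interactome, config.criteria
    )
    logger.info("stage find-quadruples: %d sets", len(quad_sets))
    write_sets(quad_sets, outdir / "quadruples.jsonl")

    report = PipelineReport(
        library_size=library_size,
        rejected_homodimer=n_homo,
        rejected_antiparallel=n_anti,
        retained=len(retained),
        evaluated_pairs=interactome.n_pairs,
        stored_interactions=len(stored),
        pair_sets=len(pair_sets),
        quadruple_sets=len(quad_sets),
    )
    report.to_json(outdir / "report.json")
    return report
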