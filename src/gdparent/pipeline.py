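"""End-to-end analysis pipeline: parse -> triads -> (optional) dyads -> outputs.

This is the library-level entry point the command line wraps: it reads the
class-annotated genotype table, runs the triad analysis, optionally runs the
dyad fallback for offspring left without a declared triad, and writes the
tab-delimited result tables plus a run log.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .dyad import reported_pairs, run_dyad
from .errors import ConfigurationError
from .genotype import encode
from .triad import MOTHER_KEYS, FATHER_KEYS, OFFSPRING_KEYS, run_triad_analysis

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    max_ident: float = 0.1
    alpha: float = 0.01
    dyad_confidence: float = 0.99
    comparison_sample: int = 30
    seed: int = 0
    run_dyad: str = "auto"  # auto | always | never
    emit_plots: bool = False
    drop_monomorphic: bool = False
    prefix: str = ""

    def validate(self) -> None:
        if not 0 < self.max_ident <= 1:
            raise ConfigurationError(f"max_ident must be in (0,1], got {self.max_ident}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.dyad_confidence < 1:
            raise ConfigurationError(
                f"dyad_confidence must be in (0,1), got {self.dyad_confidence}"
            )
        if self.comparison_sample < 2:
            raise ConfigurationError("comparison_sample must be >= 2")
        if self.run_dyad not in ("auto", "always", "never"):
            raise ConfigurationError(
                f"run_dyad must be auto/always/never, got {self.run_dyad!r}"
            )


@dataclass
class RunResult:
    declared_triads: list
    dyad_records: list
    gap: object
    output_files: list[Path] = field(default_factory=list)


def _qc_warnings(scores) -> None:
    """Flag offspring with unusually low mean GD or usable-locus counts.

    Individuals more than 3 standard deviations below the population mean
    on either statistic are likely duplicated samples or badly genotyped
    and are worth inspecting before trusting the declarations.
    """
    with np.errstate(invalid="ignore"):
        mean_gd = np.nanmean(scores.gd, axis=0)
        mean_loci = scores.usable.mean(axis=0)
    for name, vals in (("mean GD", mean_gd), ("mean usable loci", mean_loci)):
        finite = np.isfinite(vals)
        if finite.sum() < 3:
            continue
        mu, sd = vals[finite].mean(), vals[finite].std()
        if sd == 0:
            continue
        for k in np.nonzero(finite & (vals < mu - 3 * sd))[0]:
            log.warning(
                "QC: individual %s has unusually low %s (%.4g vs population "
                "mean %.4g)", scores.offspring_ids[k], name, vals[k], mu,
            )


def run(cfg: RunConfig) -> RunResult:
    """Execute a full analysis; on any fatal error partial outputs are removed."""
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = out_dir / f"{cfg.prefix}run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gdparent")
    root.addHandler(handler)
    t0 = time.perf_counter()
    try:
        table = gio.read_genotype_table(cfg.input_path)
        log.info("read %d individuals x %d loci from %s",
                 table.n_individuals, table.n_loci, cfg.input_path)
        gm = encode(table, drop_monomorphic=cfg.drop_monomorphic)
        log.info("encoded %d loci (%d dropped)", gm.n_loci, table.n_loci - gm.n_loci)

        result = run_triad_analysis(
            gm,
            max_ident=cfg.max_ident,
            alpha=cfg.alpha,
            comparison_sample_size=cfg.comparison_sample,
            seed=cfg.seed,
        )
        scores, gap = result.scores, result.gap
        log.info(
            "usable loci per triad: mean %.1f, min %d",
            float(scores.usable.mean()), int(scores.usable.min()),
        )
        if gap.determinable:
            log.info(
                "gap: threshold=%.6g size=%.6g p=%.4g (%d GDs below threshold, "
                "%d in region)", gap.threshold, gap.gap_size, gap.gap_p,
                gap.n_below, gap.n_in_region,
            )
        _qc_warnings(scores)

        records = scores.records()
        all_path = out_dir / f"{cfg.prefix}Triad-All.tsv"
        sig_path = out_dir / f"{cfg.prefix}Triad-Sig.tsv"
        gio.write_triad_table(records, "all", all_path)
        written.append(all_path)
        gio.write_triad_table(records, "significant", sig_path)
        written.append(sig_path)
        log.info("declared %d triads", len(result.declared))

        dyad_records: list = []
        if cfg.run_dyad != "never":
            resolved = {r.offspring_id for r in result.declared}
            if cfg.run_dyad == "always":
                targets = list(scores.offspring_ids)
            else:
                targets = [k for k in scores.offspring_ids if k not in resolved]
            if targets:
                parents = sorted(
                    {i for i, key in zip(gm.ids, gm.class_keys)
                     if key in MOTHER_KEYS or key in FATHER_KEYS},
                    key=gm.index_of,
                )
                dyad_records = run_dyad(gm, targets, parents, cfg.dyad_confidence)
                dyad_path = out_dir / f"{cfg.prefix}Dyad-Sig.tsv"
                gio.write_dyad_table(dyad_records, dyad_path)
                written.append(dyad_path)
                log.info("dyad pairs reported: %d", len(reported_pairs(dyad_records)))
            else:
                log.info("all offspring resolved by triad analysis; dyad skipped")

        if cfg.emit_plots:
            from . import plots

            scatter = out_dir / f"{cfg.prefix}gd-scatter.png"
            plots.plot_gd_scatter(scores.flat_gd, gap, scatter)
            written.append(scatter)
            for k in sorted({r.offspring_id for r in reported_pairs(dyad_records)}):
                p = out_dir / f"{cfg.prefix}dyad-{k}.png"
                plots.plot_dyad_scores(dyad_records, k, p)
                written.append(p)

        log.info("run completed in %.1f s", time.perf_counter() - t0)
        return RunResult(
            declared_triads=result.declared,
            dyad_records=dyad_records,
            gap=gap,
            output_files=written,
        )
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
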