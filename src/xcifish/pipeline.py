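"""End-to-end orchestration of the RNA FISH co-transcription analysis.

A run takes per-cell scoring records (read from a TSV or simulated from
a preset), and for every cell type, scoring stratum and requested
statistic produces per-donor estimates with 95% CIs, a random-effects
group summary, CD-based null-divergence and between-group p-values, the
per-donor Xa-vs-Xi Monte Carlo tests, forest tables as TSV, and a JSON
report carrying all p-values and full seed provenance.

Strata are analyzed independently: a donor contributes to the whole-
cell ("any X") and Xa-restricted analyses with different denominators.
Combinations that cannot be computed (undefined statistic, too-sparse
bootstrap, no Xi in XY donors) appear in the report as explicit
not-testable entries rather than being dropped.  p-values are
unadjusted throughout.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .association import assoc_result
from .cd import (
    BootstrapConfig,
    DegenerateResampleError,
    binomial_cd,
    bootstrap_cd,
)
from .meta import MetaSummary, between_group_p, combine_cds, null_divergence_p
from .mctest import xa_vs_xi_test
from .scoring import (
    CellScore,
    CellType,
    Karyotype,
    Stratum,
    cross_classify,
    escape_counts,
    read_cell_table,
    write_cell_table,
    write_contingency_tables,
)
from .simulate import paper_like_preset, simulate_cohort

logger = logging.getLogger(__name__)

#: statistic -> (needs bootstrap, log-scale combination, null value)
STATISTICS = {
    "q": (True, False, 0.0),
    "obs_exp": (True, True, 1.0),
    "p_double": (False, False, None),
}

PRESETS = {"paper_like": paper_like_preset}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; every stochastic stage's seed derives from
    ``seed`` and is recorded in the report."""

    input_path: str | None = None
    preset: str | None = "paper_like"
    strata: tuple[str, ...] = ("any_x", "xa_only", "xi_only")
    statistics: tuple[str, ...] = ("q", "obs_exp", "p_double")
    bootstrap_replications: int = 10_000
    mc_replications: int = 1_000_000
    meta_model: str = "random_effects"
    seed: int = 0
    out_dir: str = "xcifish_out"
    preset_n_cells: int = 300

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path / preset is required")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for s in self.strata:
            Stratum(s)
        for s in self.statistics:
            if s not in STATISTICS:
                raise ValueError(f"unknown statistic {s!r}")


def _donor_seed(config: RunConfig, *key: str) -> np.random.SeedSequence:
    """Deterministic substream for one (stage, ..., donor) combination."""
    digest = [zlib.crc32(k.encode("utf-8")) for k in key]
    return np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(digest))


def _group_cells(
    cells: list[CellScore],
) -> dict[tuple[CellType, Karyotype], dict[str, list[CellScore]]]:
    out: dict[tuple[CellType, Karyotype], dict[str, list[CellScore]]] = {}
    for c in cells:
        out.setdefault((c.cell_type, c.group), {}).setdefault(
            c.donor_id, []
        ).append(c)
    return out


def _summary_record(summary: MetaSummary, p_null: float | None) -> dict:
    rec = {
        "mean": summary.mean,
        "ci_lower": summary.ci_lower,
        "ci_upper": summary.ci_upper,
        "tau2": summary.tau2,
        "model": summary.model,
        "log_scale": summary.log_scale,
        "n_donors": len(summary.donor_estimates),
        "donors": [
            {
                "donor_id": d.donor_id,
                "estimate": d.estimate,
                "ci_lower": d.ci_lower,
                "ci_upper": d.ci_upper,
            }
            for d in summary.donor_estimates
        ],
    }
    if p_null is not None:
        rec["p_null"] = p_null
    return rec


def _forest_tsv(path: Path, summary: MetaSummary) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("donor_id\testimate\tci_lower\tci_upper\n")
        for d in summary.donor_estimates:
            fh.write(
                f"{d.donor_id}\t{d.estimate:.6g}\t{d.ci_lower:.6g}\t"
                f"{d.ci_upper:.6g}\n"
            )
        fh.write(
            f"SUMMARY\t{summary.mean:.6g}\t{summary.ci_lower:.6g}\t"
            f"{summary.ci_upper:.6g}\n"
        )


def _analyze_stat(
    config: RunConfig,
    donors: dict[str, list[CellScore]],
    stratum: Stratum,
    statistic: str,
    group_label: str,
    cell_type: CellType,
) -> MetaSummary | str:
    """Group summary for one statistic, or a not-testable reason string."""
    needs_boot, log_scale, _ = STATISTICS[statistic]
    cds, labels, skipped = [], [], []
    for donor_id in sorted(donors):
        table = cross_classify(donors[donor_id], stratum)
        if table.n_total == 0:
            skipped.append((donor_id, "empty_stratum"))
            continue
        if needs_boot:
            seed = _donor_seed(
                config, "bootstrap", cell_type.value, stratum.value,
                statistic, donor_id,
            )
            try:
                cd = bootstrap_cd(
                    table,
                    statistic,
                    BootstrapConfig(
                        replications=config.bootstrap_replications, seed=seed
                    ),
                )
            except (ValueError, DegenerateResampleError) as exc:
                skipped.append((donor_id, str(exc)))
                continue
        else:
            cd = binomial_cd(table.a, table.n_total)
        cds.append(cd)
        labels.append(donor_id)
    for donor_id, reason in skipped:
        logger.info(
            "%s/%s/%s: donor %s not testable: %s",
            cell_type.value, stratum.value, statistic, donor_id, reason,
        )
    if not cds:
        return "no_testable_donors"
    try:
        return combine_cds(
            cds,
            model=config.meta_model,
            labels=labels,
            group=group_label,
            statistic=statistic,
            log_scale=log_scale,
        )
    except ValueError as exc:
        return str(exc)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``; returns the report dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.input_path is not None:
        cells = read_cell_table(config.input_path)
        source = {"input_path": str(config.input_path)}
    else:
        specs = PRESETS[config.preset](n_cells=config.preset_n_cells)
        cells, truth = simulate_cohort(
            specs, seed=np.random.SeedSequence(config.seed, spawn_key=(0,))
        )
        source = {"preset": config.preset,
                  "preset_n_cells": config.preset_n_cells}
        write_cell_table(cells, out_dir / "cells.tsv")
        with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1)
    logger.info("analyzing %d cells", len(cells))

    grouped = _group_cells(cells)
    report: dict = {
        "xcifish_version": __version__,
        "config": {
            **source,
            "strata": list(config.strata),
            "statistics": list(config.statistics),
            "bootstrap_replications": config.bootstrap_replications,
            "mc_replications": config.mc_replications,
            "meta_model": config.meta_model,
            "seed": config.seed,
            "seed_derivation": (
                "SeedSequence(seed, spawn_key=crc32(stage, cell_type, "
                "stratum, statistic, donor))"
            ),
            "p_value_adjustment": "none",
        },
        "groups": {},
        "between_group": [],
        "escape": {},
        "xa_vs_xi": {},
    }

    contingency_entries = []
    summaries: dict[tuple, MetaSummary] = {}
    cell_types = sorted({ct for ct, _ in grouped}, key=lambda x: x.value)
    for ct in cell_types:
        ct_rec = report["groups"].setdefault(ct.value, {})
        for stratum_name in config.strata:
            stratum = Stratum(stratum_name)
            st_rec = ct_rec.setdefault(stratum.value, {})
            for statistic in config.statistics:
                _, _, null_value = STATISTICS[statistic]
                stat_rec = st_rec.setdefault(statistic, {})
                for (ct2, grp), donors in sorted(
                    grouped.items(), key=lambda kv: kv[0][1].value
                ):
                    if ct2 is not ct:
                        continue
                    if stratum is Stratum.ANY_X and statistic == "q":
                        for donor_id in sorted(donors):
                            contingency_entries.append((
                                donor_id, stratum,
                                cross_classify(donors[donor_id], stratum),
                            ))
                    result = _analyze_stat(
                        config, donors, stratum, statistic, grp.value, ct
                    )
                    if isinstance(result, str):
                        stat_rec[grp.value] = {"not_testable": result}
                        continue
                    p_null = (
                        null_divergence_p(result, null_value)
                        if null_value is not None
                        else None
                    )
                    stat_rec[grp.value] = _summary_record(result, p_null)
                    summaries[(ct, stratum, statistic, grp)] = result
                    _forest_tsv(
                        out_dir
                        / f"forest_{ct.value}_{stratum.value}_{statistic}.{grp.value}.tsv",
                        result,
                    )
                # between-group comparisons for this statistic/stratum
                groups_here = [
                    g for (c, s, st, g) in summaries
                    if c is ct and s is stratum and st == statistic
                ]
                for i, ga in enumerate(groups_here):
                    for gb in groups_here[i + 1:]:
                        p = between_group_p(
                            summaries[(ct, stratum, statistic, ga)],
                            summaries[(ct, stratum, statistic, gb)],
                        )
                        report["between_group"].append({
                            "cell_type": ct.value,
                            "stratum": stratum.value,
                            "statistic": statistic,
                            "group_a": ga.value,
                            "group_b": gb.value,
                            "p": p,
                        })

    # XCI escape per gene, XX/XXY groups only
    for (ct, grp), donors in sorted(
        grouped.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        if grp is Karyotype.XY:
            continue
        esc_rec = report["escape"].setdefault(ct.value, {}).setdefault(
            grp.value, {}
        )
        for gene in ("TLR7", "TLR8"):
            cds, labels = [], []
            for donor_id in sorted(donors):
                ec = escape_counts(donors[donor_id], gene)
                if ec.n_positive_total == 0:
                    continue
                cds.append(binomial_cd(ec.n_escape, ec.n_positive_total))
                labels.append(donor_id)
            if not cds:
                esc_rec[gene] = {"not_testable": "no_positive_cells"}
                continue
            summary = combine_cds(
                cds, model=config.meta_model, labels=labels,
                group=grp.value, statistic=f"escape_{gene}",
            )
            esc_rec[gene] = _summary_record(summary, None)
            _forest_tsv(
                out_dir / f"forest_{ct.value}_escape_{gene}.{grp.value}.tsv",
                summary,
            )

    # Xa-vs-Xi Monte Carlo tests, XX/XXY donors
    for ct in cell_types:
        xi_cells = [
            c for c in cells
            if c.cell_type is ct and c.group is not Karyotype.XY
        ]
        if not xi_cells:
            report["xa_vs_xi"][ct.value] = {}
            continue
        seed = _donor_seed(config, "xa_vs_xi", ct.value)
        results = xa_vs_xi_test(
            xi_cells,
            replications=config.mc_replications,
            seed=int(seed.generate_state(1)[0] % (2**31)),
        )
        report["xa_vs_xi"][ct.value] = {
            donor: (
                None
                if res is None
                else {
                    "chi2": res.chi2,
                    "p": res.p,
                    "replications": res.replications,
                }
            )
            for donor, res in results.items()
        }

    if contingency_entries:
        write_contingency_tables(
            contingency_entries, out_dir / "contingency_any_x.tsv"
        )
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    logger.info("report written to %s", out_dir / "report.json")
    return report
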