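"""End-to-end orchestration: simulate -> quantify -> detest -> callback ->
enrich -> qpcr, from a single config, with a JSON run manifest.

Every stage reads only prior-stage files from the output directory and
writes deterministic TSVs, so a fixed config and seed reproduce the output
tree byte-for-byte (the manifest's wall-clock fields aside) and any
downstream stage can be re-run from upstream files alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import callback as cb
from . import detest, enrich, qpcr, quantify, simdata
from .io import (
    CountMatrix,
    arms_from_sheet,
    load_count_matrix,
    read_counts_tsv,
    read_ct_table,
    read_gene_lengths,
    read_gmt,
    read_sample_sheet,
    write_counts_tsv,
    write_ct_table,
    write_gene_lengths,
    write_gmt,
    write_sample_sheet,
    write_table,
)

PAPER_CONTRAST_SCHEME = "model_vs_normal, treatment_vs_model, treatment_vs_normal"


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: Path
    seed: int = 0
    simulate: simdata.SimConfig | None = None
    counts_path: Path | None = None
    samples_path: Path | None = None
    lengths_path: Path | None = None
    gmt_path: Path | None = None
    ct_path: Path | None = None
    normal_arm: str = "NC"
    model_arm: str = "ADM"
    treatments: tuple[str, ...] = ("W1CC", "W5CC")
    deg_lfc: float = 0.5
    deg_fdr: float = 0.05
    callback_thresholds: cb.CallbackThresholds = field(default_factory=cb.CallbackThresholds)
    enrich_method: str = "bonferroni"
    enrich_threshold: float = 0.05
    qpcr_reference_gene: str | None = None
    qpcr_calibrator_arm: str = "NC"

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError("exactly one of input paths or a simulation block must supply counts")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], **overrides: Any) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        kwargs["outdir"] = raw.get("outdir", "rescueseq_out")
        kwargs["seed"] = int(raw.get("seed", 0))
        if "simulate" in raw:
            sim_kwargs = dict(raw["simulate"] or {})
            for key in ("treatments",):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            for key in ("baseline_log_mean_range", "dispersion_model"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_kwargs.setdefault("seed", kwargs["seed"])
            kwargs["simulate"] = simdata.SimConfig(**sim_kwargs)
            kwargs["treatments"] = kwargs["simulate"].treatments
            kwargs["normal_arm"] = kwargs["simulate"].normal_arm
            kwargs["model_arm"] = kwargs["simulate"].model_arm
        if "inputs" in raw:
            inputs = raw["inputs"]
            kwargs["counts_path"] = Path(inputs["counts"])
            kwargs["samples_path"] = Path(inputs["samples"])
            for opt in ("lengths", "gmt", "ct"):
                if opt in inputs:
                    kwargs[f"{opt}_path"] = Path(inputs[opt])
        for key in ("normal_arm", "model_arm"):
            if key in raw:
                kwargs[key] = raw[key]
        if "treatments" in raw:
            kwargs["treatments"] = tuple(raw["treatments"])
        thr = raw.get("thresholds", {})
        kwargs["deg_lfc"] = float(thr.get("deg_lfc", 0.5))
        kwargs["deg_fdr"] = float(thr.get("deg_fdr", 0.05))
        kwargs["callback_thresholds"] = cb.CallbackThresholds(
            level1_lfc=float(thr.get("level1_lfc", 0.5)),
            level2_lfc=float(thr.get("level2_lfc", 0.1)),
            level3_treat_lfc=float(thr.get("level3_treat_lfc", 0.1)),
            fdr=float(thr.get("fdr", 0.05)),
        )
        kwargs["enrich_method"] = thr.get("enrich_method", "bonferroni")
        kwargs["enrich_threshold"] = float(thr.get("enrich_threshold", 0.05))
        qp = raw.get("qpcr", {})
        kwargs["qpcr_reference_gene"] = qp.get("reference_gene")
        kwargs["qpcr_calibrator_arm"] = qp.get("calibrator_arm", "NC")
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def contrasts(self) -> list[detest.Contrast]:
        """Injury contrast, each treatment vs model, each treatment vs normal."""
        out = [detest.Contrast(self.model_arm, self.normal_arm)]
        out += [detest.Contrast(t, self.model_arm) for t in self.treatments]
        out += [detest.Contrast(t, self.normal_arm) for t in self.treatments]
        return out


def validate_inputs(
    counts_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
    ct_path: str | Path | None = None,
) -> list[str]:
    """Schema and cross-file consistency checks; returns every violation found."""
    violations: list[str] = []
    counts = sheet = None
    try:
        counts = read_counts_tsv(counts_path)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        violations.append(f"{counts_path}: {exc}")
    if counts is not None:
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            violations.append(f"{counts_path}: non-numeric count values")
        else:
            bad = np.argwhere(~(np.mod(values, 1) == 0) | (values < 0))
            for g, s in bad[:10]:
                violations.append(
                    f"{counts_path}: non-negative integers required at "
                    f"gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
                )
        if counts.index.has_duplicates:
            violations.append(f"{counts_path}: duplicate gene ids")
    try:
        sheet = read_sample_sheet(samples_path)
    except Exception as exc:  # noqa: BLE001
        violations.append(f"{samples_path}: {exc}")
    if counts is not None and sheet is not None:
        sheet_samples = set(sheet["sample_id"])
        for sample in counts.columns:
            if sample not in sheet_samples:
                violations.append(f"sample {sample!r} in counts absent from sample sheet")
        arm_sizes = sheet.groupby("arm")["sample_id"].count()
        for arm, size in arm_sizes.items():
            if size < 2:
                violations.append(f"arm {arm!r} has {size} sample(s); contrasts need >= 2")
    if lengths_path is not None:
        try:
            lengths = read_gene_lengths(lengths_path)
            if counts is not None:
                missing = [g for g in counts.index if g not in lengths.index]
                if missing:
                    violations.append(
                        f"{lengths_path}: {len(missing)} genes lack lengths "
                        f"(first: {missing[:5]})"
                    )
            if (lengths <= 0).any():
                violations.append(f"{lengths_path}: non-positive lengths present")
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{lengths_path}: {exc}")
    if gmt_path is not None:
        try:
            read_gmt(gmt_path)
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{gmt_path}: {exc}")
    if ct_path is not None:
        try:
            ct = read_ct_table(ct_path)
            if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
                violations.append(f"{ct_path}: Ct values must be finite and positive")
        except Exception as exc:  # noqa: BLE001
            violations.append(f"{ct_path}: {exc}")
    return violations


def _config_echo(config: RunConfig) -> dict[str, Any]:
    """JSON-serializable echo of the run configuration for the manifest."""
    echo: dict[str, Any] = {
        "outdir": str(config.outdir),
        "seed": config.seed,
        "normal_arm": config.normal_arm,
        "model_arm": config.model_arm,
        "treatments": list(config.treatments),
        "deg_lfc": config.deg_lfc,
        "deg_fdr": config.deg_fdr,
        "callback_thresholds": {
            "level1_lfc": config.callback_thresholds.level1_lfc,
            "level2_lfc": config.callback_thresholds.level2_lfc,
            "level3_treat_lfc": config.callback_thresholds.level3_treat_lfc,
            "fdr": config.callback_thresholds.fdr,
        },
        "enrich_method": config.enrich_method,
        "enrich_threshold": config.enrich_threshold,
    }
    if config.simulate is not None:
        sim = config.simulate
        echo["simulate"] = {
            "n_genes": sim.n_genes,
            "n_replicates_per_arm": sim.n_replicates_per_arm,
            "treatments": list(sim.treatments),
            "baseline_log_mean_range": list(sim.baseline_log_mean_range),
            "dispersion_model": list(sim.dispersion_model),
            "archetype_fractions": sim.archetype_fractions,
            "injury_effect_log2fc": sim.injury_effect_log2fc,
            "rescue_fraction": sim.rescue_fraction,
            "partial_rescue_fraction": sim.partial_rescue_fraction,
            "library_size_log_sd": sim.library_size_log_sd,
            "seed": sim.seed,
        }
    else:
        echo["inputs"] = {
            "counts": str(config.counts_path),
            "samples": str(config.samples_path),
            "lengths": str(config.lengths_path) if config.lengths_path else None,
            "gmt": str(config.gmt_path) if config.gmt_path else None,
            "ct": str(config.ct_path) if config.ct_path else None,
        }
    return echo


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the run manifest.

    Partial failure leaves completed outputs on disk plus an ``error`` record
    in the manifest naming the failed stage.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "software": f"rescueseq {__version__}",
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
    }

    def _stage(name: str):
        def wrapper(fn):
            start = time.perf_counter()
            try:
                rows = fn()
            except Exception as exc:  # noqa: BLE001
                manifest["error"] = {"stage": name, "message": str(exc)}
                raise
            finally:
                manifest["stages"].setdefault(name, {})["wall_clock_s"] = round(
                    time.perf_counter() - start, 4
                )
            manifest["stages"][name]["rows"] = rows
            return rows

        return wrapper

    truth = None
    gene_sets = None
    ct_table = None
    reference_gene = config.qpcr_reference_gene

    try:
        if config.simulate is not None:
            @_stage("simulate")
            def _simulate() -> int:
                nonlocal truth, gene_sets, ct_table, reference_gene
                cm, truth = simdata.simulate_counts(config.simulate)
                write_counts_tsv(cm.counts, outdir / "counts.tsv")
                sheet = pd.DataFrame(
                    {
                        "sample_id": cm.sample_ids,
                        "arm": cm.arms.values,
                        "replicate": [s.rsplit("_", 1)[1] for s in cm.sample_ids],
                    }
                )
                write_sample_sheet(sheet, outdir / "samples.tsv")
                write_gene_lengths(cm.gene_lengths, outdir / "gene_lengths.tsv")
                write_table(truth, outdir / "truth.tsv", index_label="gene_id")
                gene_sets = simdata.simulate_gene_sets(
                    truth, n_sets=50, seed=config.seed + 1
                )
                write_gmt(gene_sets, outdir / "gene_sets.gmt")
                if reference_gene is None:
                    null_genes = truth.index[truth["archetype"] == "null"]
                    reference_gene = str(null_genes[0])
                # qPCR panel: strongly expressed restored genes (robust DEGs)
                restored = truth[
                    truth["archetype"].isin(("restored_up", "restored_down"))
                ]
                strong = restored.sort_values(
                    "baseline_mean", ascending=False
                ).index[:13]
                ct_table = simdata.simulate_ct_table(
                    truth,
                    genes=list(strong),
                    reference_gene=reference_gene,
                    config=config.simulate,
                    seed=config.seed + 2,
                )
                write_ct_table(ct_table, outdir / "ct.tsv")
                return len(cm.gene_ids)

            counts_path = outdir / "counts.tsv"
            samples_path = outdir / "samples.tsv"
            lengths_path = outdir / "gene_lengths.tsv"
            gmt_path = outdir / "gene_sets.gmt"
            ct_path = outdir / "ct.tsv"
        else:
            counts_path = config.counts_path
            samples_path = config.samples_path
            lengths_path = config.lengths_path
            gmt_path = config.gmt_path
            ct_path = config.ct_path

        @_stage("validate")
        def _validate() -> int:
            violations = validate_inputs(
                counts_path, samples_path, lengths_path, gmt_path, ct_path
            )
            if violations:
                raise ValueError("; ".join(violations))
            return 0

        cm = load_count_matrix(counts_path, samples_path, lengths_path)

        @_stage("quantify")
        def _quantify() -> int:
            factors = quantify.size_factors(cm, total_count_fallback=True)
            write_table(factors.to_frame(), outdir / "size_factors.tsv",
                        index_label="sample_id")
            if cm.gene_lengths is not None:
                expr = quantify.fpkm(cm)
                write_table(expr, outdir / "fpkm.tsv", index_label="gene_id")
                corr = quantify.replicate_correlation(expr)
                write_table(corr, outdir / "replicate_correlation.tsv",
                            index_label="sample_id")
            return len(cm.sample_ids)

        de_tables: dict[str, pd.DataFrame] = {}
        deg_lists: dict[str, list[str]] = {}

        @_stage("detest")
        def _detest() -> int:
            factors = quantify.size_factors(cm, total_count_fallback=True)
            for contrast in config.contrasts:
                de = detest.nb_test(cm, contrast, factors=factors)
                de_tables[str(contrast)] = de
                write_table(de, outdir / f"de_{contrast}.tsv", index_label="gene_id")
                degs = detest.call_degs(de, config.deg_lfc, config.deg_fdr)
                deg_lists[str(contrast)] = list(degs.index)
                write_table(degs, outdir / f"degs_{contrast}.tsv", index_label="gene_id")
            return sum(len(v) for v in deg_lists.values())

        @_stage("pca")
        def _pca() -> int:
            if cm.gene_lengths is None:
                return 0
            deg_union = sorted(set().union(*deg_lists.values())) if deg_lists else []
            if len(deg_union) < 2:
                return 0
            expr = quantify.fpkm(cm)
            result = quantify.pca_coordinates(expr, deg_union)
            write_table(result.scores, outdir / "pca_scores.tsv", index_label="sample_id")
            return len(result.scores)

        assignments: dict[str, pd.DataFrame] = {}

        @_stage("callback")
        def _callback() -> int:
            if not config.treatments:
                return 0
            model_key = str(detest.Contrast(config.model_arm, config.normal_arm))
            for treatment in config.treatments:
                treat_key = str(detest.Contrast(treatment, config.model_arm))
                assign = cb.classify_callback(
                    de_tables[model_key], de_tables[treat_key], config.callback_thresholds
                )
                assignments[treatment] = assign
                write_table(assign, outdir / f"callback_{treatment}.tsv",
                            index_label="gene_id")
            if len(assignments) >= 2:
                shared_rows = []
                for dir_class in cb.CALLED_BACK_CLASSES:
                    shared = cb.shared_callback(assignments, dir_class)
                    for level, entry in shared.items():
                        for name, genes in entry.items():
                            shared_rows.append(
                                {
                                    "direction_class": dir_class,
                                    "level": level,
                                    "set": name,
                                    "size": len(genes),
                                    "genes": ",".join(sorted(genes)),
                                }
                            )
                write_table(pd.DataFrame(shared_rows), outdir / "shared_callback.tsv")
            if len(deg_lists) >= 2:
                write_table(cb.upset_counts(deg_lists), outdir / "upset_counts.tsv")
            return int(sum((a["level"] > 0).sum() for a in assignments.values()))

        @_stage("enrich")
        def _enrich() -> int:
            if gmt_path is None or not assignments:
                return 0
            sets = read_gmt(gmt_path)
            annotated = set().union(*(set(gs.genes) for gs in sets)) if len(sets) else set()
            model_key = str(detest.Contrast(config.model_arm, config.normal_arm))
            tested = de_tables[model_key].index[
                de_tables[model_key]["p_value"].notna()
            ]
            universe = [g for g in tested if g in annotated]
            total = 0
            import warnings as _warnings

            for treatment, assign in assignments.items():
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    tables = enrich.enrich_by_level(
                        assign, sets, universe,
                        method=config.enrich_method, threshold=config.enrich_threshold,
                    )
                long = enrich.enrichment_long_format(tables)
                write_table(long, outdir / f"enrichment_{treatment}.tsv")
                total += len(long)
            return total

        @_stage("qpcr")
        def _qpcr() -> int:
            if ct_path is None or reference_gene is None:
                return 0
            ct = read_ct_table(ct_path)
            rel = qpcr.ddct(ct, reference_gene, config.qpcr_calibrator_arm)
            write_table(rel, outdir / "qpcr_relative_expression.tsv")
            # concordance over every contrast with both a qPCR recalibration
            # and a DE table: arms vs calibrator, plus treatments vs model
            q_parts, r_parts = [], []
            de_by_arm = {}
            for arm in (config.model_arm, *config.treatments):
                key = str(detest.Contrast(arm, config.qpcr_calibrator_arm))
                if key in de_tables:
                    de_by_arm[arm] = de_tables[key]
            if de_by_arm:
                q_vec, r_vec = qpcr.qpcr_vs_de_pairs(rel, de_by_arm,
                                                     config.qpcr_calibrator_arm)
                q_parts.append(q_vec)
                r_parts.append(r_vec)
            if config.model_arm != config.qpcr_calibrator_arm:
                de_vs_model = {}
                for arm in config.treatments:
                    key = str(detest.Contrast(arm, config.model_arm))
                    if key in de_tables:
                        de_vs_model[arm] = de_tables[key]
                if de_vs_model:
                    rel_model = qpcr.ddct(ct, reference_gene, config.model_arm)
                    q_vec, r_vec = qpcr.qpcr_vs_de_pairs(
                        rel_model, de_vs_model, config.model_arm
                    )
                    q_parts.append(q_vec)
                    r_parts.append(r_vec)
            if q_parts:
                q_all = pd.concat(q_parts)
                r_all = pd.concat(r_parts)
                if len(q_all) >= 3:
                    result = qpcr.concordance(q_all, r_all)
                    report = pd.DataFrame(
                        [
                            {
                                "pearson_r": result.pearson_r,
                                "pearson_p": result.pearson_p,
                                "sign_agreement": result.sign_agreement,
                                "n_pairs": result.n_pairs,
                            }
                        ]
                    )
                    write_table(report, outdir / "qpcr_concordance.tsv")
            return len(rel)

    finally:
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest
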