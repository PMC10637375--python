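"""End-to-end pipeline orchestration with a reproducible run manifest.

Stage order mirrors the analysis: generate or ingest datasets, gate the
marker-positive population, compute fractional contributions, correlate
and cluster subunits, screen the transcriptome against the panel sum,
and compare age groups.  Every stage reads and writes files, so any
stage can be rerun in isolation; the manifest records resolved
parameters, outputs and a config hash, and is written even when a stage
fails (partial, with the failing stage named).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, GabafcError, ValidationError
from .fc import aggregate_fc, fc1_profiles, summarize_dataset, FC_STATISTICS
from .gating import select_marker_positive
from .io import load_dataset_entry, load_registry, write_mtx_triplet
from .matrix import ExpressionMatrix
from .panel import default_panel
from .preprocess import QCParams, harmonize_symbols, log_normalize, qc_filter
from .screen import DEFAULT_P_MAX, export_gene_list, response_screen, select_top
from .groups import compare_fc_groups, fc_by_group_table
from .simulate import SyntheticTruth, simulate_multi
from .stoichiometry import cluster_correlation, subunit_correlation

logger = logging.getLogger("gabafc.pipeline")

STAGES = ("data", "gate", "fc", "correlate", "screen", "compare")


@dataclass
class RunManifest:
    """What a pipeline run did: config hash, parameters, outputs."""

    config_hash: str
    seed: int | None
    version: str = __version__
    started: str = ""
    finished: str = ""
    status: str = "running"
    failed_stage: str | None = None
    error: str | None = None
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, params: dict, outputs: list[str]) -> None:
        self.stages[stage] = {"params": params, "outputs": outputs}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _require(condition: bool, fieldpath: str, message: str) -> None:
    if not condition:
        raise ConfigError(fieldpath, message)


def validate_config(config: dict) -> dict:
    """Validate the pipeline config; raise ConfigError with a field path."""
    _require(isinstance(config, dict), "<root>", "config must be a mapping")
    _require(
        ("simulate" in config) != ("ingest" in config),
        "<root>",
        "exactly one of 'simulate' or 'ingest' must be given",
    )
    qc = config.get("qc", {})
    if qc.get("enabled", False):
        try:
            QCParams(
                min_cells_per_gene=int(qc.get("min_cells_per_gene", 3)),
                min_features=int(qc.get("min_features", 200)),
                max_features=int(qc.get("max_features", 3000)),
                max_mito_pct=float(qc.get("max_mito_pct", 5.0)),
                scale_factor=float(qc.get("scale_factor", 10_000.0)),
            )
        except ValidationError as exc:
            raise ConfigError("qc", str(exc)) from exc
    stat = config.get("fc", {}).get("statistic", "fc1_mean")
    _require(stat in FC_STATISTICS, "fc.statistic", f"must be one of {FC_STATISTICS}")
    mode = config.get("correlate", {}).get("mode", "dataset_means")
    _require(
        mode in ("dataset_means", "per_cell"), "correlate.mode",
        "must be dataset_means or per_cell",
    )
    top = config.get("screen", {}).get("top", 1000)
    _require(int(top) > 0, "screen.top", "must be positive")
    alpha = config.get("compare", {}).get("alpha", 0.05)
    _require(0 < float(alpha) < 1, "compare.alpha", "must be in (0, 1)")
    return config


def _concat_cells(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Pool cells across datasets on the shared gene set (first order)."""
    shared = [g for g in matrices[0].gene_symbols
              if all(g in set(m.gene_symbols) for m in matrices)]
    parts = [m.subset_genes(shared) for m in matrices]
    return ExpressionMatrix(
        dataset_id="pooled",
        cell_ids=[c for m in parts for c in m.cell_ids],
        gene_symbols=shared,
        values=np.vstack([m.values for m in parts]),
        unit=parts[0].unit,
        cell_meta=pd.concat([m.cell_meta for m in parts]),
    )


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute all stages; return (and write) the run manifest.

    ``seed`` overrides the config's seed for the synthetic generator.
    On stage failure the partial manifest is still written and the error
    re-raised with the failing stage named.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed if seed is not None else config.get("seed"),
        started=datetime.now(timezone.utc).isoformat(),
    )
    manifest_path = out / "manifest.json"
    stage = "setup"
    panel = default_panel()
    try:
        # ---- stage: data (simulate or ingest) ----------------------------
        stage = "data"
        if "simulate" in config:
            truth_cfg = dict(config["simulate"])
            if manifest.seed is not None:
                truth_cfg["seed"] = int(manifest.seed)
            try:
                truth = SyntheticTruth(**truth_cfg)
            except (ValidationError, TypeError) as exc:
                raise ConfigError("simulate", str(exc)) from exc
            matrices = [m for m, _ in simulate_multi(truth)]
        else:
            entries = load_registry(config["ingest"]["registry"])
            matrices = []
            for entry in entries:
                m = load_dataset_entry(entry)
                m = harmonize_symbols(
                    m, aliases=config["ingest"].get("aliases"), panel=panel
                )
                if entry.apply_qc or config.get("qc", {}).get("enabled", False):
                    m = qc_filter(m, _qc_params(config))
                if config.get("qc", {}).get("log_normalize", False):
                    m = log_normalize(m, _qc_params(config).scale_factor)
                matrices.append(m)
        data_outputs = []
        for m in matrices:
            write_mtx_triplet(m, out / "data" / m.dataset_id)
            data_outputs.append(str(out / "data" / m.dataset_id))
        manifest.record(
            "data",
            {"source": "simulate" if "simulate" in config else "ingest",
             "n_datasets": len(matrices)},
            data_outputs,
        )

        # ---- stage: gate -------------------------------------------------
        stage = "gate"
        marker = config.get("gate", {}).get("marker", "PDGFRA")
        min_value = config.get("gate", {}).get("min_value")
        gated, gate_records = [], {}
        for m in matrices:
            result, subset = select_marker_positive(m, marker, min_value)
            gated.append(subset)
            gate_records[m.dataset_id] = {
                "n_total": result.n_total,
                "n_selected": result.n_selected,
            }
        gate_path = out / "gate.json"
        gate_path.write_text(json.dumps(gate_records, indent=2))
        manifest.record("gate", {"marker": marker, "min_value": min_value},
                        [str(gate_path)])

        # ---- stage: fc ---------------------------------------------------
        stage = "fc"
        statistic = config.get("fc", {}).get("statistic", "fc1_mean")
        summaries = [summarize_dataset(g, panel) for g in gated]
        long_rows = []
        for s in summaries:
            t = s.table.reset_index()
            t.insert(0, "dataset", s.dataset_id)
            t["n_cells_total"] = s.n_cells_total
            t["n_cells_defined"] = s.n_cells_defined
            long_rows.append(t)
        fc_long = pd.concat(long_rows, ignore_index=True)
        fc_path = out / "fc_per_dataset.tsv"
        fc_long.to_csv(fc_path, sep="\t", index=False)
        cross = aggregate_fc(summaries, statistic=statistic)
        cross_path = out / "fc_cross_dataset.tsv"
        cross.table.to_csv(cross_path, sep="\t")
        grand = pd.DataFrame({"mean": cross.grand_mean, "se": cross.grand_se})
        grand_path = out / "fc_grand_mean.tsv"
        grand.to_csv(grand_path, sep="\t")
        manifest.record("fc", {"statistic": statistic},
                        [str(fc_path), str(cross_path), str(grand_path)])

        # ---- stage: correlate -------------------------------------------
        stage = "correlate"
        mode = config.get("correlate", {}).get("mode", "dataset_means")
        if mode == "per_cell":
            pooled = _concat_cells(gated)
            corr_input = fc1_profiles(pooled, panel)
        else:
            corr_input = cross.table
        corr = subunit_correlation(corr_input, mode=mode)
        clust = cluster_correlation(corr)
        r_path, p_path = out / "correlation_r.tsv", out / "correlation_p.tsv"
        corr.r.to_csv(r_path, sep="\t")
        corr.p.to_csv(p_path, sep="\t")
        link = pd.DataFrame(
            clust.linkage, columns=["index_a", "index_b", "height", "size"]
        )
        link_path = out / "correlation_linkage.tsv"
        link.to_csv(link_path, sep="\t", index=False)
        manifest.record("correlate", {"mode": mode, "n_obs": corr.n_obs},
                        [str(r_path), str(p_path), str(link_path)])

        # ---- stage: screen ----------------------------------------------
        stage = "screen"
        pooled = _concat_cells(gated)
        scr_cfg = config.get("screen", {})
        table = response_screen(
            pooled, panel=panel,
            exclude_panel=not scr_cfg.get("keep_panel", False),
        )
        screen_path = out / "screen.tsv"
        table.table.to_csv(screen_path, sep="\t", index=False)
        top = select_top(
            table,
            k=int(scr_cfg.get("top", 1000)),
            p_max=float(scr_cfg.get("p_max", DEFAULT_P_MAX)),
        )
        list_path = out / "top_genes.txt"
        if top:
            export_gene_list(
                top, list_path,
                k=int(scr_cfg.get("top", 1000)),
                p_max=float(scr_cfg.get("p_max", DEFAULT_P_MAX)),
                n_cells=table.n_cells, n_tests=len(table.table),
            )
        manifest.record(
            "screen",
            {"top": int(scr_cfg.get("top", 1000)),
             "p_max": float(scr_cfg.get("p_max", DEFAULT_P_MAX)),
             "n_selected": len(top)},
            [str(screen_path)] + ([str(list_path)] if top else []),
        )

        # ---- stage: compare ---------------------------------------------
        stage = "compare"
        group_key = config.get("compare", {}).get("group_key", "age_group")
        alpha = float(config.get("compare", {}).get("alpha", 0.05))
        by_group: dict[str, list[pd.DataFrame]] = {}
        for g in gated:
            if group_key not in g.cell_meta.columns:
                continue
            for group, sub in g.cell_meta.groupby(group_key, observed=True):
                subm = g.subset_cells(np.asarray(g.cell_meta[group_key] == group))
                by_group.setdefault(str(group), []).append(fc1_profiles(subm, panel))
        compare_outputs = []
        if len(by_group) >= 2:
            frames = {k: pd.concat(v) for k, v in by_group.items()}
            result = compare_fc_groups(frames, alpha=alpha)
            cmp_path = out / "group_comparison.tsv"
            result.pairwise_p.to_csv(cmp_path, sep="\t", index=False)
            kw_path = out / "group_kruskal.tsv"
            result.kruskal_p.to_frame().to_csv(kw_path, sep="\t")
            compare_outputs = [str(cmp_path), str(kw_path)]
        else:
            logger.warning("compare: fewer than 2 groups present; skipped")
        grp_summaries: dict[str, list] = {}
        for g, s in zip(gated, summaries):
            ag = g.cell_meta[group_key].iloc[0] if group_key in g.cell_meta.columns \
                and len(g.cell_meta) else None
            if ag is not None:
                grp_summaries.setdefault(str(ag), []).append(s)
        if grp_summaries:
            table_path = out / "fc_by_group.tsv"
            fc_by_group_table(grp_summaries, statistic=statistic).to_csv(
                table_path, sep="\t"
            )
            compare_outputs.append(str(table_path))
        manifest.record("compare", {"group_key": group_key, "alpha": alpha},
                        compare_outputs)

        manifest.status = "ok"
        return manifest
    except Exception as exc:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.error = str(exc)
        if isinstance(exc, GabafcError):
            raise GabafcError(f"stage {stage!r} failed: {exc}") from exc
        raise
    finally:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.write(manifest_path)


def _qc_params(config: dict) -> QCParams:
    qc = config.get("qc", {})
    return QCParams(
        min_cells_per_gene=int(qc.get("min_cells_per_gene", 3)),
        min_features=int(qc.get("min_features", 200)),
        max_features=int(qc.get("max_features", 3000)),
        max_mito_pct=float(qc.get("max_mito_pct", 5.0)),
        scale_factor=float(qc.get("scale_factor", 10_000.0)),
    )
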