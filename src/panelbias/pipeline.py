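"""End-to-end panel-comparison pipeline driven by one YAML configuration.

Stages: obtain genotypes (simulate or load a VCF), build each configured
panel (site subset), apply per-site QC, LD-prune, compute the selected
statistics, compare every panel against the reference, and write a report
directory.  A single root seed makes the whole run reproducible; every
stage is a pure function of (inputs, parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from . import diagnostics as diag
from . import fstats, panels, pca, prune, simulate
from .io import GenotypeMatrix, read_bed, read_pop_labels, read_site_list, read_vcf

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

CONFIG_VERSION = 1

_TOP_KEYS = {"version", "seed", "out_dir", "input", "panels", "reference",
             "qc", "prune", "statistics", "admixture", "plots"}
_INPUT_KEYS = {"kind", "vcf", "labels", "n_super", "pops_per_super",
               "n_per_pop", "m_snps", "drift_super", "drift_pop",
               "coordinate_layout"}
_PANEL_KEYS = {"name", "scheme", "n_sites", "fraction_aims", "bed",
               "site_list", "telomere_excl", "stretch", "take"}
_QC_KEYS = {"min_carriers", "min_inbreeding"}
_PRUNE_KEYS = {"window_kb", "step_snps", "r2"}
_ADMIX_KEYS = {"k_range", "folds", "restarts"}
_STATS = {"fst", "f3", "f4", "pca", "maf_variance", "admixture_cv"}
_SCHEMES = {"all", "random", "aims", "regions", "sites", "genome_scheme"}


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before any compute)."""


@dataclass
class PipelineConfig:
    raw: dict[str, Any]
    seed: int
    out_dir: Path
    input: dict[str, Any]
    panels: list[dict[str, Any]]
    reference: str
    qc: dict[str, Any]
    prune_params: dict[str, Any]
    statistics: list[str]
    admixture_params: dict[str, Any] = field(default_factory=dict)
    plots: bool = True


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Parse and validate a pipeline configuration (path, YAML text or dict)."""
    if isinstance(source, dict):
        raw = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    if raw.get("version", CONFIG_VERSION) != CONFIG_VERSION:
        raise ConfigError(f"unsupported config version {raw.get('version')}")

    inp = dict(raw.get("input", {"kind": "simulate"}))
    _check_keys(inp, _INPUT_KEYS, "input")
    if inp.get("kind", "simulate") not in {"simulate", "vcf"}:
        raise ConfigError(f"unknown input kind {inp.get('kind')!r}")

    panel_list = raw.get("panels", [{"name": "all", "scheme": "all"}])
    names = []
    for pd_ in panel_list:
        _check_keys(pd_, _PANEL_KEYS, f"panel {pd_.get('name')}")
        if "name" not in pd_:
            raise ConfigError("every panel needs a name")
        scheme = pd_.get("scheme", "all")
        if scheme not in _SCHEMES:
            raise ConfigError(f"unknown panel scheme {scheme!r}")
        names.append(pd_["name"])
    if len(set(names)) != len(names):
        raise ConfigError("panel names must be unique")
    reference = raw.get("reference", names[0])
    if reference not in names:
        raise ConfigError(f"reference panel {reference!r} not defined")

    qc = dict(raw.get("qc", {}))
    _check_keys(qc, _QC_KEYS, "qc")
    pr = dict(raw.get("prune", {}))
    _check_keys(pr, _PRUNE_KEYS, "prune")
    stats = list(raw.get("statistics", ["fst", "f3", "pca", "maf_variance"]))
    bad = set(stats) - _STATS
    if bad:
        raise ConfigError(f"unknown statistics: {sorted(bad)}")
    admix = dict(raw.get("admixture", {}))
    _check_keys(admix, _ADMIX_KEYS, "admixture")

    return PipelineConfig(
        raw=raw,
        seed=int(raw.get("seed", 0)),
        out_dir=Path(raw.get("out_dir", "panelbias_out")),
        input=inp,
        panels=panel_list,
        reference=reference,
        qc=qc,
        prune_params=pr,
        statistics=stats,
        admixture_params=admix,
        plots=bool(raw.get("plots", True)),
    )


def _param_hash(obj: Any) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def _obtain_genotypes(cfg: PipelineConfig
                      ) -> tuple[GenotypeMatrix, simulate.FrequencyPanel | None]:
    inp = cfg.input
    if inp.get("kind", "simulate") == "vcf":
        labels = read_pop_labels(inp["labels"]) if "labels" in inp else None
        g = read_vcf(inp["vcf"], labels=labels)
        return g, None
    sim_cfg = simulate.studylike_config(
        seed=cfg.seed,
        n_super=int(inp.get("n_super", 5)),
        pops_per_super=int(inp.get("pops_per_super", 3)),
        n_per_pop=int(inp.get("n_per_pop", 30)),
        m_snps=int(inp.get("m_snps", 20_000)),
        drift_super=float(inp.get("drift_super", 0.08)),
        drift_pop=float(inp.get("drift_pop", 0.01)),
    )
    layout = inp.get("coordinate_layout", "uniform")
    sim_cfg.coordinate_layout = layout
    panel, g = simulate.simulate_dataset(sim_cfg)
    return g, panel


def _build_panel(g: GenotypeMatrix, freq_panel, spec: dict, seed: int
                 ) -> GenotypeMatrix:
    scheme = spec.get("scheme", "all")
    if scheme == "all":
        return g
    if scheme == "random":
        n_sites = int(spec["n_sites"])
        name_tag = int.from_bytes(hashlib.sha256(spec["name"].encode())
                                  .digest()[:4], "big")
        rng = np.random.default_rng([seed, name_tag])
        idx = np.sort(rng.choice(g.n_sites, size=n_sites, replace=False))
        return g.take_sites(idx)
    if scheme == "aims":
        if freq_panel is None:
            pf = simulate.empirical_pop_freq(g)
            freq_panel = simulate.FrequencyPanel(
                ancestral_freq=pf.to_numpy().mean(axis=0), pop_freq=pf)
        idx = simulate.ascertain_aims(
            freq_panel, "maf_variance_top",
            fraction_aims=float(spec.get("fraction_aims", 0.8)),
            n_sites=int(spec["n_sites"]), seed=seed)
        return g.take_sites(idx)
    if scheme == "regions":
        return panels.intersect_variants(g, read_bed(spec["bed"]))
    if scheme == "sites":
        return panels.select_sites(g, read_site_list(spec["site_list"]))
    if scheme == "genome_scheme":
        chrom_lengths = {
            str(c): int(g.sites.loc[g.sites["chrom"] == c, "pos"].max()) + 1
            for c in pd.unique(g.sites["chrom"])
        }
        rs = panels.genome_scheme_regions(
            chrom_lengths,
            telomere_excl=int(spec.get("telomere_excl", 0)),
            stretch=int(spec.get("stretch", 10_000)),
            take=int(spec.get("take", 258)),
        )
        return panels.intersect_variants(g, rs)
    raise ConfigError(f"unknown panel scheme {scheme!r}")


def run_pipeline(config: PipelineConfig | str | Path | dict) -> Path:
    """Execute the full comparison; returns the populated report directory.

    On stage failure the partial outputs are retained alongside a ``FAILED``
    marker file and the exception is re-raised.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(cfg, out)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run(cfg: PipelineConfig, out: Path) -> Path:
    logger.info("stage=input params=%s", _param_hash(cfg.input))
    g, freq_panel = _obtain_genotypes(cfg)

    results: dict[str, diag.PanelResult] = {}
    for spec in cfg.panels:
        name = spec["name"]
        logger.info("stage=panel name=%s params=%s", name, _param_hash(spec))
        gp = _build_panel(g, freq_panel, spec, cfg.seed)

        min_carriers = int(cfg.qc.get("min_carriers", 0))
        if min_carriers:
            gp = panels.filter_carriers(gp, min_individuals=min_carriers)
        if "min_inbreeding" in cfg.qc:
            gp = panels.filter_inbreeding(gp, min_f=float(cfg.qc["min_inbreeding"]))

        if cfg.prune_params:
            pr = prune.indep_pairwise(
                gp,
                window_kb=float(cfg.prune_params.get("window_kb", 10_000)),
                step_snps=int(cfg.prune_params.get("step_snps", 10)),
                r2_thresh=float(cfg.prune_params.get("r2", 0.1)),
            )
            logger.info("stage=prune name=%s fraction_pruned=%.3f", name,
                        pr.fraction_pruned)
            gp = gp.take_sites(pr.kept)

        freqs = fstats.allele_frequencies(gp)
        blocks = fstats.coordinate_blocks(freqs.sites)
        panel_res = diag.PanelResult(
            name=name,
            fst=fstats.fst_matrix(freqs, blocks=blocks),
        )
        if "f3" in cfg.statistics:
            panel_res.f3_table = fstats.f3_scan(freqs, blocks=blocks)
        if "pca" in cfg.statistics:
            panel_res.eigenvalues = pca.run_pca(gp, n_components=10).eigenvalues
        if "maf_variance" in cfg.statistics:
            panel_res.maf_var = diag.maf_variance(freqs).variance
        if "admixture_cv" in cfg.statistics:
            ap = cfg.admixture_params
            curve = adm.cross_validation(
                gp,
                k_range=list(ap.get("k_range", [2, 3, 4])),
                folds=int(ap.get("folds", 3)),
                restarts=int(ap.get("restarts", 3)),
                seed=cfg.seed,
            )
            panel_res.cv_curve = pd.DataFrame(
                {"K": curve.k_values, "mean_error": curve.mean_errors})
        results[name] = panel_res

    comp = diag.compare_panels(results, cfg.reference)
    meta = {
        "seed": cfg.seed,
        "config_hash": _param_hash(cfg.raw),
        "statistics": cfg.statistics,
        "n_samples": g.n_samples,
        "n_sites_input": g.n_sites,
    }
    diag.report(comp, out, metadata=meta, plots=cfg.plots)
    return out
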