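"""Ascertainment diagnostics and cross-panel comparison summaries.

The key diagnostic for array-style ascertainment is the per-SNP
across-population variance of minor-allele frequency: a panel enriched for
ancestry-informative markers shows a right-shifted density of this variance
relative to a randomly drawn panel of the same size.  The cross-panel
summaries mirror the comparisons a panel-bias study reports: an F_ST
difference matrix against a reference panel, the Pearson correlation of
triad-wise f3 vectors, leading-eigenvalue ratios, and relative CV curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fstats import AlleleFrequencyTable

__all__ = ["SiteDiagnostics", "PanelResult", "PanelComparison",
           "maf_variance", "compare_panels", "report"]


@dataclass
class SiteDiagnostics:
    """Per-site minor-allele frequencies and their across-population variance."""

    maf: pd.DataFrame            # populations x sites, folded frequencies
    variance: np.ndarray         # per-site sample variance across populations
    n_skipped: int               # sites with <2 populations of data


def maf_variance(freqs: AlleleFrequencyTable, pooled_minor: bool = True
                 ) -> SiteDiagnostics:
    """Across-population variance of per-site minor-allele frequency.

    The minor allele is defined on the pooled sample (allele with pooled
    frequency <= 0.5; tie keeps the alternate allele) so the per-site number
    is the variance of the SAME allele's frequency across populations.  With
    ``pooled_minor=False`` each population's frequency is folded
    independently instead.  Variance uses the n-1 (sample) denominator.
    Sites where fewer than two populations have data are skipped.
    """
    f = freqs.freq.to_numpy()
    n = freqs.count.to_numpy()
    valid = n >= 2
    n_pops_ok = valid.sum(axis=0)
    usable = n_pops_ok >= 2
    n_skipped = int((~usable).sum())

    fv = np.where(valid, f, np.nan)
    if pooled_minor:
        totals = np.where(valid, n, 0.0)
        pooled = np.nansum(fv * totals, axis=0) / np.maximum(totals.sum(axis=0), 1)
        flip = pooled > 0.5
        folded = np.where(flip[None, :], 1.0 - fv, fv)
    else:
        folded = np.minimum(fv, 1.0 - fv)

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(folded, axis=0)
        var = np.nansum((folded - mean[None, :]) ** 2, axis=0) / np.maximum(
            n_pops_ok - 1, 1)
    var = np.where(usable, var, np.nan)
    return SiteDiagnostics(
        maf=pd.DataFrame(folded, index=freqs.populations),
        variance=var,
        n_skipped=n_skipped,
    )


@dataclass
class PanelResult:
    """Summary statistics computed on one panel (inputs to the comparison)."""

    name: str
    fst: pd.DataFrame                      # population x population matrix
    f3_table: pd.DataFrame | None = None   # triad scan (target, source_a, source_b, f3)
    eigenvalues: np.ndarray | None = None
    maf_var: np.ndarray | None = None      # per-site MAF variance
    cv_curve: pd.DataFrame | None = None   # columns: K, mean_error


@dataclass
class PanelComparison:
    reference: str
    fst_diff: dict[str, pd.DataFrame] = field(default_factory=dict)
    f3_correlation: dict[str, float] = field(default_factory=dict)
    leading_eigenvalue_ratio: dict[str, float] = field(default_factory=dict)
    maf_var_mean: dict[str, float] = field(default_factory=dict)
    relative_cv: dict[str, pd.DataFrame] = field(default_factory=dict)
    panels: dict[str, PanelResult] = field(default_factory=dict)


def _triad_key(row) -> tuple:
    a, b = sorted([row["source_a"], row["source_b"]])
    return (row["target"], a, b)


def compare_panels(results: dict[str, PanelResult], reference: str
                   ) -> PanelComparison:
    """Compare each panel's statistics against the named reference panel.

    Computes the elementwise F_ST difference matrix (panel minus reference),
    the Pearson correlation between matched triad f3 vectors, the
    leading-eigenvalue ratio, mean per-site MAF variance, and relative CV
    curves aligned on the shared K range.
    """
    if reference not in results:
        raise ValueError(f"reference panel {reference!r} not among results")
    ref = results[reference]
    ref_pops = list(ref.fst.index)
    comp = PanelComparison(reference=reference, panels=dict(results))
    for name, panel in results.items():
        pops = list(panel.fst.index)
        if set(pops) != set(ref_pops):
            raise ValueError(
                f"population sets differ between {name!r} and reference: "
                f"{sorted(set(pops) ^ set(ref_pops))}")
        fst = panel.fst.loc[ref_pops, ref_pops]
        comp.fst_diff[name] = fst - ref.fst
        if panel.f3_table is not None and ref.f3_table is not None:
            a = panel.f3_table.copy()
            b = ref.f3_table.copy()
            a["key"] = a.apply(_triad_key, axis=1)
            b["key"] = b.apply(_triad_key, axis=1)
            merged = a.merge(b, on="key", suffixes=("_p", "_r"))
            if len(merged) < 2:
                raise ValueError("fewer than 2 shared triads between panels")
            r = float(np.corrcoef(merged["f3_p"], merged["f3_r"])[0, 1])
            comp.f3_correlation[name] = r
        if panel.eigenvalues is not None and ref.eigenvalues is not None:
            comp.leading_eigenvalue_ratio[name] = float(
                panel.eigenvalues[0] / ref.eigenvalues[0])
        if panel.maf_var is not None:
            comp.maf_var_mean[name] = float(np.nanmean(panel.maf_var))
        if panel.cv_curve is not None:
            cv = panel.cv_curve.copy()
            shared_k = cv["K"]
            if ref.cv_curve is not None:
                shared = set(cv["K"]) & set(ref.cv_curve["K"])
                cv = cv[cv["K"].isin(shared)]
            ref_err = cv["mean_error"].max()
            cv["relative_error"] = cv["mean_error"] / ref_err
            comp.relative_cv[name] = cv.reset_index(drop=True)
    return comp


def report(comp: PanelComparison, out_dir: str | Path, metadata: dict | None = None,
           plots: bool = True) -> list[Path]:
    """Write the comparison as deterministic TSV tables, plots and metadata.

    Files written (per panel P): ``fst_P.tsv``, ``fst_diff_P.tsv``,
    ``f3_P.tsv`` (when available), ``cv_P.tsv`` (when available);
    plus ``summary.tsv`` and ``run_metadata.json``, and PNG plots when
    ``plots`` is on.  Rerunning with the same inputs produces byte-identical
    TSVs.
    """
    if not comp.panels:
        raise ValueError("empty comparison: nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, index: bool) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index, float_format="%.10g")
        written.append(p)

    summary_rows = []
    for name, panel in comp.panels.items():
        _write(panel.fst, f"fst_{name}.tsv", index=True)
        _write(comp.fst_diff[name], f"fst_diff_{name}.tsv", index=True)
        if panel.f3_table is not None:
            _write(panel.f3_table.drop(columns=["key"], errors="ignore"),
                   f"f3_{name}.tsv", index=False)
        if name in comp.relative_cv:
            _write(comp.relative_cv[name], f"cv_{name}.tsv", index=False)
        summary_rows.append({
            "panel": name,
            "f3_correlation_vs_ref": comp.f3_correlation.get(name, np.nan),
            "leading_eigenvalue_ratio": comp.leading_eigenvalue_ratio.get(name, np.nan),
            "mean_maf_variance": comp.maf_var_mean.get(name, np.nan),
        })
    _write(pd.DataFrame(summary_rows), "summary.tsv", index=False)

    meta = {"reference": comp.reference}
    if metadata:
        meta.update(metadata)
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(meta_path)

    if plots:
        written.extend(_plots(comp, out))
    return written


def _plots(comp: PanelComparison, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    # MAF-variance density
    panels_with_var = {n: p for n, p in comp.panels.items() if p.maf_var is not None}
    if panels_with_var:
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, panel in panels_with_var.items():
            v = panel.maf_var[np.isfinite(panel.maf_var)]
            if len(v) > 1:
                from scipy.stats import gaussian_kde
                xs = np.linspace(0, max(v.max(), 1e-6), 200)
                ax.plot(xs, gaussian_kde(v)(xs), label=name)
        ax.set_xlabel("across-population MAF variance")
        ax.set_ylabel("density")
        ax.legend()
        p = out / "maf_variance_density.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    # f3 vs f3 scatter
    ref = comp.panels[comp.reference]
    if ref.f3_table is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        for name, panel in comp.panels.items():
            if name == comp.reference or panel.f3_table is None:
                continue
            a = panel.f3_table.copy()
            b = ref.f3_table.copy()
            a["key"] = a.apply(_triad_key, axis=1)
            b["key"] = b.apply(_triad_key, axis=1)
            merged = a.merge(b, on="key", suffixes=("_p", "_r"))
            ax.scatter(merged["f3_r"], merged["f3_p"], s=8, label=name)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.5)
        ax.set_xlabel(f"f3 ({comp.reference})")
        ax.set_ylabel("f3 (panel)")
        ax.legend()
        p = out / "f3_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
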