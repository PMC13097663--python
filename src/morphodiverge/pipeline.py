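"""End-to-end 3D and 2D analysis pipelines.

``run_3d_analysis`` chains missing-landmark estimation (within species),
generalized Procrustes superimposition, bilateral-symmetry extraction,
permutational MANOVA on the symmetric shape components with log centroid
size and sex as covariates, post-hoc pairwise group-mean shape distances
against a null model without the grouping factor, and shape PCA.

``run_2d_analysis`` chains completeness filtering, allometric size
correction of the linear traits against snout-vent length, column
standardization, permutational MANOVA, pairwise LS-mean distances, and
trait PCA.

Model term order is configurable; the presets put covariates first
(logCS/sex), grouping factors next, interactions last, with island-within-
region nesting encoded as a region:island term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import TraitTable, fit_allometric_model, size_correct, standardize_matrix
from .errors import ValidationError
from .landmark_io import LandmarkDataset
from .missing_landmarks import estimate_missing
from .ordination import PCAResult, pca, pc_extreme_shape
from .rrpp_stats import (
    ModelSpec,
    PairwiseResult,
    RRPPModelFit,
    anova_table,
    fit_rrpp,
    format_p,
    pairwise_groups,
)
from .superimposition import gpa
from .symmetry import symmetry_decomposition

__all__ = ["RunConfig", "ReportBundle", "run_3d_analysis", "run_2d_analysis"]

logger = logging.getLogger("morphodiverge")

_3D_PRESETS = {
    "3d_species": (["logCS", "sex", "species", "sex:species"], ["logCS", "sex"], "species"),
    "3d_region": (["logCS", "sex", "region"], ["logCS", "sex"], "region"),
}
_2D_PRESETS = {
    "2d_species": (["sex", "species", "sex:species", "island"], ["sex", "island"], "species"),
    "2d_region": (["sex", "region", "region:island"], ["sex"], "region"),
    "2d_mahe": (["sex", "locality"], ["sex"], "locality"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    analysis: str  # 3d_species | 3d_region | 2d_species | 2d_region | 2d_mahe
    iter: int = 9999
    seed: int = 42
    terms: list[str] | None = None
    null_terms: list[str] | None = None
    group: str | None = None
    scope: str = "global"  # allometric slope scope for 2D analyses
    landmarks: str | None = None  # TPS file path
    metadata: str | None = None  # CSV path
    pairing: str | None = None  # YAML path with pairs/midline
    labels: str | None = None  # text file: one landmark label per line
    traits: str | None = None  # trait CSV path
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.analysis not in {**_3D_PRESETS, **_2D_PRESETS}:
            raise ValidationError(f"unknown analysis tag {self.analysis!r}")
        if self.iter < 99:
            raise ValidationError("iter must be >= 99")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def resolve_terms(self) -> tuple[list[str], list[str], str]:
        presets = {**_3D_PRESETS, **_2D_PRESETS}[self.analysis]
        terms = self.terms if self.terms is not None else presets[0]
        null_terms = self.null_terms if self.null_terms is not None else presets[1]
        group = self.group if self.group is not None else presets[2]
        return list(terms), list(null_terms), group


@dataclass
class ReportBundle:
    """All artifacts of one analysis run."""

    anova: pd.DataFrame
    pairwise: pd.DataFrame | None
    pca_scores: pd.DataFrame
    pca_variance: pd.DataFrame
    fit: RRPPModelFit
    pairwise_result: PairwiseResult | None
    pca_result: PCAResult
    log_lines: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.anova.to_csv(outdir / "anova.csv")
        if self.pairwise is not None:
            self.pairwise.to_csv(outdir / "pairwise.csv")
        self.pca_scores.to_csv(outdir / "pca_scores.csv")
        self.pca_variance.to_csv(outdir / "pca_variance.csv")
        with open(outdir / "run.log", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        self._write_figure(outdir / "pca_pc1_pc2.svg")

    def _write_figure(self, path: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        sc = self.pca_scores
        groups = sc["group"] if "group" in sc.columns else pd.Series(["all"] * len(sc))
        for level in sorted(groups.unique()):
            sub = sc[groups == level]
            ax.scatter(sub["PC1"], sub["PC2"], label=str(level), s=18)
        vf = self.pca_variance["variance_fraction"]
        ax.set_xlabel(f"PC1 ({vf.iloc[0] * 100:.1f}%)")
        ax.set_ylabel(f"PC2 ({vf.iloc[1] * 100:.1f}%)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def _formatted_pairwise(pw: PairwiseResult) -> pd.DataFrame:
    t = pw.table.copy()
    t["p_formatted"] = [format_p(p, pw.n_permutations) for p in t["p"]]
    return t


def run_3d_analysis(
    dataset: LandmarkDataset,
    analysis: str = "3d_species",
    iter: int = 9999,
    seed: int = 42,
    terms: list[str] | None = None,
    null_terms: list[str] | None = None,
    group: str | None = None,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Run the full 3D shape pipeline on a landmark dataset."""
    cfg = RunConfig(analysis=analysis, iter=iter, seed=seed, terms=terms,
                    null_terms=null_terms, group=group)
    terms, null_terms, group = cfg.resolve_terms()
    log: list[str] = [f"analysis={analysis} n={dataset.n} k={len(dataset.labels)}"]

    stage = "estimate_missing"
    try:
        completed, est_log = estimate_missing(dataset, group_by="species")
        log.append(f"{stage}: estimated {sum(est_log.values())} landmarks "
                   f"in {len(est_log)} specimens")
        stage = "gpa"
        proc = gpa(completed)
        log.append(f"{stage}: converged={proc.converged} iterations={proc.n_iterations}")
        stage = "symmetry_decomposition"
        sym = symmetry_decomposition(completed)
        log.append(f"{stage}: mean |asymmetry| = "
                   f"{float(np.linalg.norm(sym.asymmetric, axis=(1, 2)).mean()):.3e}")
        stage = "fit_rrpp"
        factors = completed.factor_frame()
        data = factors.copy()
        data["logCS"] = sym.log_cs
        Y = sym.flat_symmetric()
        fit = fit_rrpp(Y, ModelSpec(terms, data), iter=iter, seed=seed)
        log.append(f"{stage}: terms={terms}")
        stage = "pairwise_groups"
        fit_null = fit_rrpp(Y, ModelSpec(null_terms, data), iter=iter, seed=seed)
        pw = pairwise_groups(fit, fit_null, group=group, iter=iter, seed=seed)
        log.append(f"{stage}: group={group} pairs={len(pw.table)}")
        stage = "pca"
        pca_res = pca(Y)
        mean_shape = sym.symmetric.mean(axis=0)
        extremes = {
            f"PC{ax + 1}_{side}": pc_extreme_shape(
                pca_res, mean_shape, ax, float(score)
            )
            for ax in (0, 1)
            for side, score in (
                ("min", pca_res.scores[:, ax].min()),
                ("max", pca_res.scores[:, ax].max()),
            )
        }
        log.append(f"pca: PC1+PC2 variance = "
                   f"{pca_res.variance_fraction[:2].sum() * 100:.1f}%")
    except Exception as exc:
        raise ValidationError(f"3D pipeline failed at stage {stage!r}: {exc}") from exc

    scores = pd.DataFrame(
        pca_res.scores[:, : min(10, pca_res.rank)],
        columns=[f"PC{i + 1}" for i in range(min(10, pca_res.rank))],
    )
    scores.insert(0, "specimen_id", completed.specimen_ids)
    scores.insert(1, "group", factors[group].to_numpy())
    variance = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(pca_res.rank)],
            "eigenvalue": pca_res.eigenvalues,
            "variance_fraction": pca_res.variance_fraction,
        }
    )
    bundle = ReportBundle(
        anova=anova_table(fit),
        pairwise=_formatted_pairwise(pw),
        pca_scores=scores,
        pca_variance=variance,
        fit=fit,
        pairwise_result=pw,
        pca_result=pca_res,
        log_lines=log,
        extras={"symmetry": sym, "procrustes": proc, "pc_extremes": extremes,
                "estimated_landmarks": est_log},
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def run_2d_analysis(
    table: TraitTable,
    analysis: str = "2d_species",
    iter: int = 9999,
    seed: int = 42,
    terms: list[str] | None = None,
    null_terms: list[str] | None = None,
    group: str | None = None,
    scope: str | None = None,
    species: str | None = None,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Run the full 2D trait pipeline.

    For intraspecific analyses pass ``species`` to subset the table; the
    allometric slope scope defaults to global for the interspecific preset
    and per-species (i.e. within the subset) otherwise.
    """
    cfg = RunConfig(analysis=analysis, iter=iter, seed=seed, terms=terms,
                    null_terms=null_terms, group=group)
    terms, null_terms, group = cfg.resolve_terms()
    log: list[str] = [f"analysis={analysis} n_input={table.n}"]

    stage = "filter"
    try:
        n_in = table.n
        data_all = table.data
        if species is not None:
            data_all = data_all[data_all["species"] == species]
            log.append(f"subset species={species}: n={len(data_all)}")
        tab = TraitTable(data_all.reset_index(drop=True), table.traits)
        dropped = tab.data.loc[tab.incomplete, "specimen_id"].tolist()
        tab = tab.complete_rows()
        log.append(f"{stage}: kept {tab.n} of {n_in}; dropped incomplete {dropped}")
        stage = "allometry"
        model = fit_allometric_model(tab, scope="global")
        log.append(f"{stage}: mean SVL = {model.mean_svl:.2f} mm "
                   f"(slope scope: subset-global)")
        corrected = size_correct(tab, model)
        stage = "standardize"
        Y = standardize_matrix(corrected)
        stage = "fit_rrpp"
        data = corrected.data.copy()
        if analysis == "2d_mahe" and "locality" not in data.columns:
            raise ValidationError("2d_mahe analysis requires a locality column")
        fit = fit_rrpp(Y, ModelSpec(terms, data), iter=iter, seed=seed)
        log.append(f"{stage}: terms={terms}")
        stage = "pairwise_groups"
        pw = None
        if group in data.columns and data[group].nunique() > 1:
            fit_null = fit_rrpp(Y, ModelSpec(null_terms, data), iter=iter, seed=seed)
            pw = pairwise_groups(fit, fit_null, group=group, iter=iter, seed=seed)
            log.append(f"{stage}: group={group} pairs={len(pw.table)}")
        stage = "pca"
        pca_res = pca(Y)
        log.append(f"pca: PC1+PC2 variance = "
                   f"{pca_res.variance_fraction[:2].sum() * 100:.1f}%")
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(f"2D pipeline failed at stage {stage!r}: {exc}") from exc

    scores = pd.DataFrame(
        pca_res.scores[:, : min(10, pca_res.rank)],
        columns=[f"PC{i + 1}" for i in range(min(10, pca_res.rank))],
    )
    scores.insert(0, "specimen_id", corrected.data["specimen_id"].to_numpy())
    if group in corrected.data.columns:
        scores.insert(1, "group", corrected.data[group].to_numpy())
    variance = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(pca_res.rank)],
            "eigenvalue": pca_res.eigenvalues,
            "variance_fraction": pca_res.variance_fraction,
        }
    )
    loadings_unit = pd.DataFrame(
        pca_res.eigenvectors, index=corrected.traits,
        columns=[f"PC{i + 1}" for i in range(pca_res.rank)],
    )
    loadings_scaled = pd.DataFrame(
        pca_res.loadings, index=corrected.traits,
        columns=[f"PC{i + 1}" for i in range(pca_res.rank)],
    )
    bundle = ReportBundle(
        anova=anova_table(fit),
        pairwise=_formatted_pairwise(pw) if pw is not None else None,
        pca_scores=scores,
        pca_variance=variance,
        fit=fit,
        pairwise_result=pw,
        pca_result=pca_res,
        log_lines=log,
        extras={"allometric_model": model, "corrected": corrected,
                "loadings_unit": loadings_unit, "loadings_scaled": loadings_scaled},
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
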