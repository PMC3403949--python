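"""End-to-end scaling reports and batch mass estimation.

`run_scaling_report` reproduces the standard analysis products on any
measurement table: per-sample SMA fits with similarity codes for the
eight variable-pair analyses, the pairwise comparison families
(likelihood-ratio slope tests plus elevation t-tests at x = 0 and at the
pooled minimum x, FDR-corrected within each analysis), optional
independent-contrast and PGLS blocks when a tree is supplied, and a
model-score table for the body-mass predictors.  `run_mass_estimation`
turns a CSV of extinct-taxon stylopodial circumferences into mass
estimates with PPE ranges.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mass_estimation as me
from . import phylo, sma
from .core_data import (
    BivariateLogSample,
    MeasurementTable,
    SubsetCriteria,
    bivariate_sample,
    derive_variables,
    subset_table,
)

__all__ = ["ANALYSES", "default_config", "ScalingReport", "run_scaling_report", "run_mass_estimation"]

#: (x variable, y variable, similarity relation kind) of the 8 analyses
ANALYSES: list[tuple[str, str, str | None]] = [
    ("L_F", "C_F", "circumference~length"),
    ("L_H", "C_H", "circumference~length"),
    ("L_F", "BM", "mass~length"),
    ("C_F", "BM", "mass~circumference"),
    ("L_H", "BM", "mass~length"),
    ("C_H", "BM", "mass~circumference"),
    ("L_H", "L_F", None),
    ("C_H+F", "BM", "mass~circumference"),
]

_CLADES = ["Ungulata", "Carnivora", "Marsupialia", "Euarchonta", "Glires"]


def default_config() -> dict:
    """Analysis configuration with the standard choices made explicit."""
    return {
        "alpha": 0.05,
        "min_group_n": 10,
        "clades": list(_CLADES),
        "size_thresholds_kg": [20, 50, 100],
        "mass_cap_kg": 168,  # mammal subset matched to the largest reptile
        "exclude_species": [],  # e.g. the talpids for the predictive fit
        "branch_length_transform": "natural_log",
        "tip_name_normalization": True,
    }


@dataclass
class ScalingReport:
    fits: pd.DataFrame
    comparisons: pd.DataFrame
    model_scores: pd.DataFrame
    pic_fits: pd.DataFrame | None = None
    pgls_fits: pd.DataFrame | None = None
    notices: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Write TSV tables plus a full-precision JSON bundle."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle = {}
        for name in ("fits", "comparisons", "model_scores", "pic_fits", "pgls_fits"):
            df = getattr(self, name)
            if df is None:
                continue
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            bundle[name] = df.to_dict(orient="records")
        bundle["notices"] = self.notices
        bundle["config"] = self.config
        (outdir / "report.json").write_text(json.dumps(bundle, indent=1, default=str))


def _samples_for(
    table: MeasurementTable, config: dict
) -> dict[str, MeasurementTable]:
    """The named data subsets analysed side by side."""
    cap = config["mass_cap_kg"] * 1000.0
    out: dict[str, MeasurementTable] = {"All": subset_table(table, SubsetCriteria())}
    out["Mammalia"] = subset_table(table, SubsetCriteria(classes={"Mammalia"}))
    out["Reptilia"] = subset_table(table, SubsetCriteria(classes={"Reptilia"}))
    for clade in config["clades"]:
        out[clade] = subset_table(table, SubsetCriteria(clades={clade}))
    for thr in config["size_thresholds_kg"]:
        g = thr * 1000.0
        out[f"<= {thr} kg"] = subset_table(
            table, SubsetCriteria(classes={"Mammalia"}, mass_at_most_g=g)
        )
        out[f"> {thr} kg"] = subset_table(
            table, SubsetCriteria(classes={"Mammalia"}, mass_above_g=g)
        )
    out[f"Mammalia <= {config['mass_cap_kg']} kg"] = subset_table(
        table, SubsetCriteria(classes={"Mammalia"}, mass_at_most_g=cap)
    )
    return out


def _cell_row(cell: sma.ComparisonCell) -> dict:
    return {
        "analysis": cell.analysis,
        "group_a": cell.group_a,
        "group_b": cell.group_b,
        "ci_overlap": cell.ci_overlap,
        "common_slope": cell.common_slope,
        "lrt_stat": cell.lrt_stat,
        "lrt_p": cell.lrt_p,
        "lrt_p_fdr": cell.lrt_p_fdr,
        "t_intercept": cell.t_intercept,
        "p_intercept": cell.p_intercept,
        "p_intercept_fdr": cell.p_intercept_fdr,
        "t_shifted": cell.t_shifted,
        "p_shifted": cell.p_shifted,
        "p_shifted_fdr": cell.p_shifted_fdr,
        "x_star": cell.x_star,
    }


def _comparison_family(
    samples: dict[str, BivariateLogSample],
    analysis: str,
    config: dict,
    notices: list[str],
) -> list[sma.ComparisonCell]:
    """The 14-comparison family of one analysis.

    Ten clade pairs, Mammalia vs Reptilia, and the three size-class
    splits; FDR is applied across the family, separately for each of the
    three p-value columns.
    """
    alpha, min_n = config["alpha"], config["min_group_n"]
    pairs: list[tuple[str, str]] = list(itertools.combinations(config["clades"], 2))
    pairs.append(("Mammalia", "Reptilia"))
    for thr in config["size_thresholds_kg"]:
        pairs.append((f"<= {thr} kg", f"> {thr} kg"))
    x_star = min(
        (s.x.min() for s in samples.values() if s is not None), default=0.0
    )
    cells: list[sma.ComparisonCell] = []
    for a, b in pairs:
        sa, sb = samples.get(a), samples.get(b)
        if sa is None or sb is None or sa.n < min_n or sb.n < min_n:
            notices.append(
                f"{analysis}: comparison {a} vs {b} skipped (group too small)"
            )
            continue
        fa, fb = sma.fit_sma(sa, alpha), sma.fit_sma(sb, alpha)
        overlap = fa.ci_lower <= fb.ci_upper and fb.ci_lower <= fa.ci_upper
        common, stat, _, lrt_p = sma.compare_slopes_lrt([sa, sb])
        t0, _, p0 = sma.compare_intercepts(fa, fb, 0.0)
        ts, _, ps = sma.compare_intercepts(fa, fb, x_star)
        cells.append(sma.ComparisonCell(
            group_a=a, group_b=b, analysis=analysis, ci_overlap=overlap,
            common_slope=common, lrt_stat=stat, lrt_p=lrt_p,
            t_intercept=t0, p_intercept=p0, t_shifted=ts, p_shifted=ps,
            x_star=float(x_star),
        ))
    for raw, adj in [
        ("lrt_p", "lrt_p_fdr"),
        ("p_intercept", "p_intercept_fdr"),
        ("p_shifted", "p_shifted_fdr"),
    ]:
        for c, v in zip(cells, sma.adjust_fdr([getattr(c, raw) for c in cells])):
            setattr(c, adj, float(v))
    return cells


def _normalize(name: str) -> str:
    return name.replace(" ", "_")


def _tip_map(table_species: list[str], tree, normalize: bool) -> dict[str, str]:
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = {}
    for sp in table_species:
        if sp in tips:
            out[sp] = sp
        elif normalize and _normalize(sp) in tips:
            out[sp] = _normalize(sp)
    return out


def _model_score_rows(table: MeasurementTable, config: dict) -> list[dict]:
    df = derive_variables(table).df
    specs = [(("C_H+F",), "OLS"), (("C_H",), "OLS"), (("C_F",), "OLS"),
             (("L_H",), "OLS"), (("L_F",), "OLS"),
             (("C_H", "C_F"), "OLS"), (("L_H", "C_H", "L_F", "C_F"), "OLS")]
    from .core_data import VARIABLES

    rows = []
    for predictors, method in specs:
        cols = [f"log_{VARIABLES[p]}" for p in predictors]
        sub = df.dropna(subset=cols + ["log_body_mass_g"])
        if len(sub) < len(predictors) + 3:
            continue
        model = me.fit_ols(
            {p: sub[c].to_numpy() for p, c in zip(predictors, cols)},
            sub["log_body_mass_g"].to_numpy(),
            model_id="+".join(predictors),
        )
        rows.append({
            "model": model.model_id, "method": method, "n": model.n,
            "R2": model.R2, "SEE": model.SEE, "AIC": model.AIC,
            "mean_ppe": model.mean_ppe,
            "ppe_ci_lower": model.ppe_ci[0], "ppe_ci_upper": model.ppe_ci[1],
        })
    return rows


def run_scaling_report(
    table: MeasurementTable, tree=None, config: dict | None = None
) -> ScalingReport:
    """Full scaling analysis of a measurement table.

    Raises on an empty table.  Samples below the minimum group size are
    skipped with a notice; phylogenetic blocks are omitted with a notice
    when no tree is supplied.
    """
    if len(table) == 0:
        raise ValueError("empty measurement table")
    cfg = default_config()
    if config:
        cfg.update(config)
    if cfg["exclude_species"]:
        table = subset_table(
            table, SubsetCriteria(exclude_species=set(cfg["exclude_species"]))
        )
    table = derive_variables(table)
    notices: list[str] = []
    subsets = _samples_for(table, cfg)

    fit_rows: list[dict] = []
    comp_rows: list[dict] = []
    for x_var, y_var, relation in ANALYSES:
        analysis = f"{x_var} vs {y_var}"
        samples: dict[str, BivariateLogSample] = {}
        for label, sub in subsets.items():
            if len(sub) < 3:
                notices.append(f"{analysis}: sample {label!r} too small, skipped")
                continue
            try:
                samples[label] = bivariate_sample(sub, x_var, y_var)
            except ValueError:
                notices.append(f"{analysis}: sample {label!r} has <3 complete pairs")
        for label, s in samples.items():
            if s.n < cfg["min_group_n"] and label not in ("All",):
                notices.append(f"{analysis}: sample {label!r} n={s.n} below minimum")
                continue
            fit = sma.fit_sma(s, cfg["alpha"])
            verdict = sma.classify_similarity(fit, s, relation, cfg["alpha"])
            fit_rows.append({
                "analysis": analysis, "sample": label, "n": fit.n,
                "m": fit.m, "m_ci_lower": fit.ci_lower, "m_ci_upper": fit.ci_upper,
                "b": fit.b, "R2": fit.R2, "similarity": verdict.code,
            })
        comp_rows.extend(
            _cell_row(c) for c in _comparison_family(samples, analysis, cfg, notices)
        )

    pic_df = pgls_df = None
    if tree is not None:
        pic_rows, pgls_rows = [], []
        work = phylo.transform_branch_lengths(tree, cfg["branch_length_transform"])
        name_map = _tip_map(table.species, work, cfg["tip_name_normalization"])
        if len(name_map) < 3:
            notices.append("phylogenetic block omitted: <3 species match tree tips")
        else:
            df = table.df.set_index("species")
            from .core_data import VARIABLES

            for x_var, y_var, _ in ANALYSES:
                cx, cy = (f"log_{VARIABLES[v]}" for v in (x_var, y_var))
                sub = df.loc[list(name_map), [cx, cy]].dropna()
                if len(sub) < 3:
                    continue
                pruned = work.clone(depth=1)
                keep = {name_map[sp] for sp in sub.index}
                pruned.retain_taxa_with_labels(keep)
                xmap = {name_map[sp]: v for sp, v in sub[cx].items()}
                ymap = {name_map[sp]: v for sp, v in sub[cy].items()}
                xc = phylo.compute_contrasts(pruned, xmap, cfg["branch_length_transform"])
                yc = phylo.compute_contrasts(pruned, ymap, cfg["branch_length_transform"])
                fit = phylo.fit_sma_origin(xc.contrasts, yc.contrasts, cfg["alpha"])
                diag = phylo.check_standardization(xc)
                pic_rows.append({
                    "analysis": f"{x_var} vs {y_var}", "n_contrasts": len(xc),
                    "m": fit.m, "m_ci_lower": fit.ci_lower,
                    "m_ci_upper": fit.ci_upper, "R2": fit.R2,
                    "standardization_ok": diag.passed,
                })
                gls = phylo.fit_pgls(pruned, {x_var: xmap}, ymap)
                pgls_rows.append({
                    "analysis": f"{x_var} vs {y_var}", "n": gls.n,
                    "slope": float(gls.coefficients[0]),
                    "intercept": gls.intercept,
                    "slope_se": float(gls.se[1]), "loglik": gls.loglik,
                })
            pic_df = pd.DataFrame(pic_rows)
            pgls_df = pd.DataFrame(pgls_rows)
    else:
        notices.append("no tree supplied: PIC and PGLS blocks omitted")

    report = ScalingReport(
        fits=pd.DataFrame(fit_rows),
        comparisons=pd.DataFrame(comp_rows),
        model_scores=pd.DataFrame(_model_score_rows(table, cfg)),
        pic_fits=pic_df,
        pgls_fits=pgls_df,
        notices=notices,
        config=cfg,
    )
    for msg in notices:
        warnings.warn(msg, stacklevel=2)
    return report


def run_mass_estimation(
    input_csv,
    model: str | me.RegressionModel = "eq2",
    output_path=None,
) -> pd.DataFrame:
    """Estimate body mass for each row of an extinct-taxon CSV.

    The CSV needs columns taxon, specimen, humerus_circ_mm,
    femur_circ_mm.  Returns (and optionally writes as TSV) one estimate
    per input row: combined circumference, point estimate and PPE range
    in kg (full precision in the file; round for display).
    """
    if isinstance(model, str):
        registry = me.published_equations()
        if model not in registry:
            raise KeyError(f"unknown equation {model!r}; have {sorted(registry)}")
        model = registry[model]
    taxa = pd.read_csv(input_csv)
    required = {"taxon", "specimen", "humerus_circ_mm", "femur_circ_mm"}
    missing = required - set(taxa.columns)
    if missing:
        raise ValueError(f"input CSV missing columns: {sorted(missing)}")
    rows = []
    for i, rec in taxa.iterrows():
        ch, cf = rec["humerus_circ_mm"], rec["femur_circ_mm"]
        if not (np.isfinite(ch) and np.isfinite(cf)):
            raise ValueError(f"row {i} ({rec['taxon']}): missing circumference")
        est = me.estimate_mass(float(ch), float(cf), model)
        rows.append({
            "taxon": rec["taxon"], "specimen": rec["specimen"],
            "chf_mm": float(ch) + float(cf), "mass_kg": est.point_kg,
            "lower_kg": est.lower_kg, "upper_kg": est.upper_kg,
            "model": model.model_id,
        })
    out = pd.DataFrame(rows)
    if output_path is not None:
        out.to_csv(output_path, sep="\t", index=False)
    return out
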