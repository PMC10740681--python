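"""Association statistics and the report bundle.

Pearson correlation, simple linear regression with a 95% mean-response
band, one-way ANOVA with Tukey HSD, and a renderer that turns the stage
outputs into the standard figure/table bundle with a manifest.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

#: p-value thresholds for one and two stars.
STAR_THRESHOLDS = (0.05, 0.01)

SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def significance_stars(p: float, thresholds: tuple[float, float] = STAR_THRESHOLDS) -> str:
    """Pure mapping p -> '', '*' or '**'."""
    one, two = thresholds
    if p < two:
        return "**"
    if p < one:
        return "*"
    return ""


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    stars: str
    n: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    fitted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson_association(
    x, y, x_name: str = "x", y_name: str = "y"
) -> AssociationResult:
    """Product-moment correlation with a t-based two-sided p-value."""
    x, y = _clean_pair(x, y)
    if len(x) < 3:
        raise DomainError("need at least three paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return AssociationResult(
        x_name=x_name, y_name=y_name, r=float(r), p=float(p),
        stars=significance_stars(float(p)), n=len(x),
    )


def simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with a pointwise 95% mean-response band."""
    x, y = _clean_pair(x, y)
    if len(x) < 3:
        raise DomainError("need at least three observations (df for the slope)")
    if np.ptp(x) == 0:
        raise DomainError("constant x: design matrix is singular")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    band = model.get_prediction(sm.add_constant(x)).conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_slope=float(model.pvalues[1]),
        n=len(x),
        fitted=model.fittedvalues,
        ci_lower=band[:, 0],
        ci_upper=band[:, 1],
    )


@dataclass
class AnovaResult:
    f: float
    p: float
    tukey: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject
    letters: dict[str, str]


def _grouping_letters(groups: list[str], means: dict[str, float],
                      distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups not significantly different share a letter."""
    ordered = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all((min(g, h), max(g, h)) not in distinct for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least two groups")
    blocks = [values[labels == g] for g in uniq]
    small = [str(g) for g, b in zip(uniq, blocks) if len(b) < 2]
    if small:
        raise ValidationError(f"groups with fewer than two observations: {small}")

    if all(np.ptp(b) == 0 for b in blocks) and np.ptp(values) == 0:
        f_stat, p = 0.0, 1.0
        pairs = [
            {"group_a": str(a), "group_b": str(b), "mean_diff": 0.0,
             "p_adj": 1.0, "reject": False}
            for i, a in enumerate(uniq) for b in uniq[i + 1:]
        ]
        tukey = pd.DataFrame(pairs)
    else:
        f_stat, p = sps.f_oneway(*blocks)
        res = pairwise_tukeyhsd(values, labels)
        tukey = pd.DataFrame(
            {
                "group_a": [str(a) for a in res.groupsunique[res._multicomp.pairindices[0]]],
                "group_b": [str(b) for b in res.groupsunique[res._multicomp.pairindices[1]]],
                "mean_diff": res.meandiffs,
                "p_adj": res.pvalues,
                "reject": res.reject,
            }
        )
    means = {str(g): float(np.mean(b)) for g, b in zip(uniq, blocks)}
    distinct = {
        (min(r.group_a, r.group_b), max(r.group_a, r.group_b))
        for r in tukey.itertuples()
        if r.reject
    }
    letters = _grouping_letters([str(g) for g in uniq], means, distinct)
    return AnovaResult(f=float(f_stat), p=float(p), tukey=tukey, letters=letters)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _config_hash(config) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def _triangle_xy(sim, repl, rich):
    """Barycentric (Sim, Repl, RichDiff) -> 2D triangle coordinates."""
    corners = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    bary = np.column_stack([sim, repl, rich])
    return bary @ corners


def render_report(dataset, tli, fd, beta, outdir) -> dict:
    """Write the figure/table bundle for one analysis run.

    Parameters are the stage outputs: the synthetic (or loaded) dataset,
    a TLIResult, the per-sample functional diversity table and a
    BetaDecomposition.  Returns the manifest (also written as JSON).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .beta_partition import braycurtis_matrix, cluster_samples, site_profiles, triad_table
    from .functional_traits import TRAIT_CATEGORIES, composition_by_modality, dominance_screen
    from .io import write_json

    for name, stage in (("dataset", dataset), ("tli", tli), ("fd", fd), ("beta", beta)):
        if stage is None:
            raise ValidationError(f"missing stage output: {name}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figures: list[str] = []
    tables: list[str] = []
    other: list[str] = []

    community = dataset.community
    months = community.meta["month"]
    merged = tli.table.join(fd, how="inner")

    # --- tables ---------------------------------------------------------
    def save_table(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        frame.to_csv(outdir / name, index=index)
        tables.append(name)

    save_table(tli.table.reset_index().rename(columns={"index": "sample_id"}), "tli.csv")
    save_table(fd.reset_index(), "fd.csv")

    comp_long = pd.concat(
        [
            composition_by_modality(community, dataset.traits, cat).to_long()
            for cat in TRAIT_CATEGORIES
        ],
        ignore_index=True,
    )
    save_table(comp_long, "composition.csv")
    save_table(dominance_screen(community), "dominance.csv")

    triads = triad_table(beta)
    save_table(triads.table, "beta_triads.csv")

    fd_vars = ["fric", "feve", "fdiv"]
    assoc_rows = []
    for var in fd_vars:
        sub = merged[["tlic", var]].dropna()
        try:
            a = pearson_association(sub["tlic"], sub[var], "tlic", var)
            assoc_rows.append(
                {"x": "tlic", "y": var, "r": a.r, "p": a.p, "stars": a.stars, "n": a.n}
            )
        except DomainError as exc:  # degenerate synthetic corner cases
            logger.warning("association tlic~%s skipped: %s", var, exc)
    associations = pd.DataFrame(assoc_rows)
    save_table(associations, "associations.csv")

    season = months.map(SEASON_OF_MONTH)
    tli_season = tli.table.join(season.rename("season"), how="inner")
    anova = anova_tukey(tli_season["tlic"], tli_season["season"])
    anova_frame = anova.tukey.copy()
    anova_frame.insert(0, "F", anova.f)
    anova_frame.insert(1, "p_overall", anova.p)
    save_table(anova_frame, "anova_seasonal.csv")

    # --- non-tabular artifacts -----------------------------------------
    bc_sites = braycurtis_matrix(site_profiles(community))
    dendro = cluster_samples(bc_sites)
    (outdir / "dendrogram.nwk").write_text(dendro.newick + "\n", encoding="utf-8")
    other.append("dendrogram.nwk")
    write_json(
        {p: float(w) for p, w in tli.weights.items()}, outdir / "weights.json"
    )
    other.append("weights.json")

    # --- figures --------------------------------------------------------
    def save_fig(fig, name: str) -> None:
        fig.savefig(outdir / name, dpi=120)
        plt.close(fig)
        figures.append(name)

    fig, ax = plt.subplots(figsize=(7, 4))
    tli.table.join(months)[["month", "tlic"]].boxplot(by="month", column="tlic", ax=ax)
    ax.set_xlabel("month"); ax.set_ylabel("TLIc"); ax.set_title("Composite trophic index by month")
    fig.suptitle("")
    save_fig(fig, "fig_tli_monthly.png")

    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram
    fig, ax = plt.subplots(figsize=(7, 4))
    scipy_dendrogram(dendro.linkage_matrix, labels=dendro.labels, ax=ax)
    ax.set_ylabel("Bray-Curtis distance")
    save_fig(fig, "fig_dendrogram.png")

    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    for ax, cat in zip(axes.ravel(), TRAIT_CATEGORIES):
        comp = composition_by_modality(community, dataset.traits, cat)
        monthly = comp.absolute.groupby(months).sum()
        frac = monthly.div(monthly.sum(axis=1), axis=0)
        frac.plot.bar(stacked=True, ax=ax, legend=False, width=0.9)
        ax2 = ax.twinx()
        comp.totals.groupby(months).mean().plot(ax=ax2, color="black", marker="o", lw=1)
        ax.set_title(cat); ax.set_xlabel("month")
    save_fig(fig, "fig_composition.png")

    fig, ax = plt.subplots(figsize=(4.5, 4))
    names = ["tlic"] + fd_vars
    corr = merged[names].corr()
    im = ax.imshow(corr, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(names)), names, rotation=45)
    ax.set_yticks(range(len(names)), names)
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, f"{corr.iloc[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax)
    save_fig(fig, "fig_associations.png")

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, var in zip(axes, ("feve", "fdiv")):
        sub = merged[["tlic", var]].dropna().sort_values("tlic")
        ax.scatter(sub["tlic"], sub[var], s=12, alpha=0.6)
        if len(sub) >= 3 and np.ptp(sub["tlic"].to_numpy()) > 0:
            reg = simple_regression(sub["tlic"], sub[var])
            ax.plot(sub["tlic"], reg.fitted, color="C1")
            ax.fill_between(sub["tlic"], reg.ci_lower, reg.ci_upper, alpha=0.25, color="C1")
            ax.set_title(f"{var}: slope={reg.slope:.3g}, R2={reg.r_squared:.3f}, p={reg.p_slope:.3g}")
        ax.set_xlabel("TLIc"); ax.set_ylabel(var)
    save_fig(fig, "fig_regressions.png")

    fig, ax = plt.subplots(figsize=(5, 4.6))
    xy = _triangle_xy(triads.table["sim"], triads.table["repl"], triads.table["richdiff"])
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="grey")
    ax.scatter(xy[:, 0], xy[:, 1], s=10, alpha=0.6)
    mean_xy = _triangle_xy(*[[v] for v in triads.mean_triple])
    ax.scatter(mean_xy[:, 0], mean_xy[:, 1], s=90, color="red", zorder=3)
    for label, (x0, y0) in zip(("Sim", "Repl", "RichDiff"), tri[:3]):
        ax.annotate(label, (x0, y0), textcoords="offset points", xytext=(0, 6), ha="center")
    ax.set_aspect("equal"); ax.axis("off")
    save_fig(fig, "fig_triads.png")

    manifest = {
        "config_hash": _config_hash(dataset.config),
        "coefficient_set": tli.coefficient_set,
        "beta_family": beta.family,
        "figures": figures,
        "tables": tables,
        "other": other,
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
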