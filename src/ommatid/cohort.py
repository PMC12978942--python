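"""Cohort-level statistics for eye-organization surveys.

Covers the four procedures applied across individuals: hierarchical
clustering of ventral ommatidial-class distributions (Euclidean distance,
average/UPGMA linkage), all-pairs t-tests with Holm–Bonferroni correction
summarized as a compact letter display, two-way species x sex ANOVA with
interaction (Type-II sums of squares for unbalanced designs), and qPCR
triplicate QC with the UV2:UV1 relative-expression ratio.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, fcluster, leaves_list, linkage

from .reflectance import holm_decisions

# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    """UPGMA tree over per-individual class-proportion triples.

    ``linkage_matrix`` is in scipy format (merge heights are mean pairwise
    Euclidean distances and are non-decreasing for average linkage).
    """

    linkage_matrix: np.ndarray
    points: np.ndarray

    def cut(self, k: int | None = None, height: float | None = None) -> np.ndarray:
        """Flat labels by cutting to k clusters or at merge height."""
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            return fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return fcluster(self.linkage_matrix, t=height, criterion="distance")

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.linkage_matrix)

    def plot_dendrogram(self, ax=None, labels=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dendrogram(self.linkage_matrix, ax=ax, labels=labels)
        ax.set_ylabel("mean pairwise Euclidean distance")
        return ax


def hclust_average(points) -> ClusterResult:
    """Agglomerative clustering: Euclidean metric, average (UPGMA) linkage.

    ``points`` is a sequence of (UVUV, BB, UVB) triples (or any fixed-width
    numeric vectors); one row per individual.
    """
    pts = [p.as_triple() if hasattr(p, "as_triple") else tuple(float(v) for v in p)
           for p in points]
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 points to cluster")
    z = linkage(arr, method="average", metric="euclidean")
    return ClusterResult(linkage_matrix=z, points=arr)


# ---------------------------------------------------------------------------
# pairwise tests with compact letter display


@dataclass
class PairwiseResult:
    """All-pairs tests, Holm-corrected, with a compact letter display.

    Groups sharing no letter differ significantly; two groups share a
    letter iff their Holm-adjusted test is non-significant.
    """

    table: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def pairwise_tests_holm(groups: dict, alpha: float = 0.05,
                        equal_var: bool = False) -> PairwiseResult:
    """Two-sample t-tests (Welch by default) for every pair of named groups.

    Holm–Bonferroni is applied over the family of pairs.  The letter
    display assigns one letter per maximal clique of the graph whose edges
    connect non-significantly-different groups, with deterministic
    ordering by group name.
    """
    names = sorted(groups)
    arrays = {}
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r}: need n >= 2")
        arrays[name] = arr
    pairs = list(itertools.combinations(names, 2))
    pvals = []
    tstats = []
    for a, b in pairs:
        t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=equal_var)
        tstats.append(float(t))
        pvals.append(float(p))
    reject, p_adj = holm_decisions(pvals, alpha=alpha)
    table = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "t": tstats,
        "p_raw": pvals,
        "p_holm": p_adj,
        "significant": reject,
    })
    letters = _compact_letter_display(names, pairs, reject)
    return PairwiseResult(table=table, letters=letters, alpha=alpha)


def _compact_letter_display(names, pairs, reject) -> dict[str, str]:
    g = nx.Graph()
    g.add_nodes_from(names)
    for (a, b), rej in zip(pairs, reject):
        if not rej:
            g.add_edge(a, b)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort()  # deterministic letter assignment
    letters = {name: "" for name in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for member in clique:
            letters[member] += letter
    return letters


# ---------------------------------------------------------------------------
# two-way ANOVA


def anova_species_sex(table: pd.DataFrame, response: str = "response",
                      species: str = "species", sex: str = "sex") -> pd.DataFrame:
    """Two-way factorial ANOVA (species, sex, interaction).

    Type-II sums of squares via model comparison, the standard choice for
    unbalanced observational designs (identical to the textbook
    decomposition when the design is balanced).  Returns a frame indexed
    species/sex/interaction/residual with sum_sq, df, df_resid, F, p.
    Infinite F (zero residual variance with a real effect) is reported as
    inf and flagged in a ``note`` column.  Empty design cells raise.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[species, sex, response]].dropna().copy()
    df.columns = ["species", "sex", "y"]
    for col in ("species", "sex"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    cells = df.groupby(["species", "sex"], observed=True).size()
    full = itertools.product(df["species"].unique(), df["sex"].unique())
    for cell in full:
        if cell not in cells.index:
            raise ValueError(f"empty design cell {cell!r}")

    if np.ptp(df["y"].to_numpy()) == 0:
        # constant response: no variance to partition
        idx = ["species", "sex", "interaction", "residual"]
        dfs = [df["species"].nunique() - 1, df["sex"].nunique() - 1,
               (df["species"].nunique() - 1) * (df["sex"].nunique() - 1), 0]
        dfs[3] = len(df) - 1 - sum(dfs[:3])
        out = pd.DataFrame({"sum_sq": 0.0, "df": dfs}, index=idx)
        out["df_resid"] = dfs[3]
        out["F"] = [0.0, 0.0, 0.0, np.nan]
        out["p"] = [1.0, 1.0, 1.0, np.nan]
        out["note"] = ""
        return out

    model = smf.ols("y ~ C(species) * C(sex)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={
        "C(species)": "species", "C(sex)": "sex",
        "C(species):C(sex)": "interaction", "Residual": "residual",
    })
    df_resid = float(aov.loc["residual", "df"])
    ms_resid = aov.loc["residual", "sum_sq"] / df_resid if df_resid > 0 else 0.0
    if ms_resid <= 1e-12 * max(float(aov["sum_sq"].sum()), 1e-300):
        ms_resid = 0.0  # residual variance is numerically zero
    out = aov.rename(columns={"PR(>F)": "p"})[["sum_sq", "df", "F", "p"]].copy()
    out["df_resid"] = df_resid
    out["note"] = ""
    for term in ("species", "sex", "interaction"):
        if ms_resid == 0 and out.loc[term, "sum_sq"] > 0:
            out.loc[term, ["F", "p"]] = [np.inf, 0.0]
            out.loc[term, "note"] = "zero residual variance; F unbounded"
        elif out.loc[term, "sum_sq"] == 0:
            out.loc[term, ["F", "p"]] = [0.0, 1.0]
    return out[["sum_sq", "df", "df_resid", "F", "p", "note"]]


# ---------------------------------------------------------------------------
# qPCR


QPCR_GENES = ("UV1", "UV2", "LW", "EF1a")


@dataclass
class QPCRRecord:
    """One triplicate qPCR measurement of one gene in one sample.

    A record is discarded (for re-testing) when the sample standard
    deviation of its triplicate Ct values exceeds 1 cycle (strictly).
    """

    sample: str
    gene: str
    cts: tuple[float, float, float]
    sd: float = field(init=False)
    status: str = field(init=False)

    def __post_init__(self) -> None:
        cts = tuple(float(c) for c in self.cts)
        if len(cts) != 3:
            raise ValueError("expected a Ct triplicate")
        object.__setattr__(self, "cts", cts)
        self.sd = float(np.std(cts, ddof=1)) if not any(math.isnan(c) for c in cts) else float("nan")
        self.status = "discarded" if self.sd > 1.0 else "kept"

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))

    @property
    def detected(self) -> bool:
        return not any(math.isnan(c) for c in self.cts)


@dataclass
class QPCRResult:
    """Relative UV1:UV2 expression for one sample.

    ``fold_uv2_vs_uv1`` = 2**(meanCt_UV1 - meanCt_UV2) under the equal-
    efficiency (delta-Ct) assumption: a fold of 16 means UV2 transcripts
    are 16x more abundant than UV1.  ``log2_ratio`` is its log2 (= delta
    Ct).  ``status``: 'ok', 'not_detected' (a UV gene absent), or 'retest'
    (a required record discarded by the SD rule).
    """

    sample: str
    status: str
    fold_uv2_vs_uv1: float = float("nan")
    log2_ratio: float = float("nan")


def qpcr_relative(records: list[QPCRRecord]) -> QPCRResult:
    """Relative UV2:UV1 expression for one sample's records.

    The SD > 1 discard rule is applied first; LW and EF1a records are
    quality controls only and do not enter the ratio.
    """
    if not records:
        raise ValueError("no qPCR records supplied")
    sample = records[0].sample
    if any(r.sample != sample for r in records):
        raise ValueError("records span multiple samples")
    by_gene = {g: [r for r in records if r.gene == g] for g in ("UV1", "UV2")}
    for gene, recs in by_gene.items():
        if not recs or not any(r.detected for r in recs):
            return QPCRResult(sample=sample, status="not_detected")
    kept = {}
    for gene, recs in by_gene.items():
        usable = [r for r in recs if r.detected and r.status == "kept"]
        if not usable:
            return QPCRResult(sample=sample, status="retest")
        kept[gene] = usable[0]
    delta_ct = kept["UV1"].mean_ct - kept["UV2"].mean_ct
    return QPCRResult(
        sample=sample, status="ok",
        fold_uv2_vs_uv1=float(2.0**delta_ct), log2_ratio=float(delta_ct),
    )


def qpcr_table(records: list[QPCRRecord]) -> pd.DataFrame:
    """Tidy per-record QC table (sample, gene, mean Ct, SD, status)."""
    return pd.DataFrame([
        {"sample": r.sample, "gene": r.gene, "ct1": r.cts[0], "ct2": r.cts[1],
         "ct3": r.cts[2], "mean_ct": r.mean_ct, "sd": r.sd, "status": r.status}
        for r in records
    ])


def qpcr_records_from_frame(df: pd.DataFrame) -> list[QPCRRecord]:
    """Build records from a tidy frame with columns sample, gene, ct1..ct3."""
    return [
        QPCRRecord(sample=str(r["sample"]), gene=str(r["gene"]),
                   cts=(r["ct1"], r["ct2"], r["ct3"]))
        for _, r in df.iterrows()
    ]
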