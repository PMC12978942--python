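"""The blue-cell LW co-expression probability model.

In the expanded Nymphalid mosaic, a blue-opsin R1/R2 cell may co-express
the long-wavelength (LW) opsin; any LW-positive cell recruits red screening
pigment, turning the ommatidium's eyeshine red.  Under the assumption that
every B cell co-expresses independently with the same probability ``p``,
the fraction of yellow eyeshine is

    Yellow = UVUV + (1 - p)^2 * BB + (1 - p) * UVB

since UV-UV ommatidia have no B cell (always yellow), B-B ommatidia stay
yellow only when neither B cell co-expresses, and UV-B only when the single
B cell does not.  Given an observed yellow fraction and the ommatidial
class proportions from antibody staining, ``p`` is recovered by least
squares: the closed form solves the quadratic in q = 1 - p and clamps to
the feasible interval; a grid-search minimizer serves as a cross-check.

:class:`CoexpressionModel` wraps the fit in a model/results pair: build it
from per-group (yellow fraction, class proportions) rows, call ``fit()``,
and read per-group estimates, residuals, and a summary table from the
returned :class:`CoexpressionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .proportions import ClassProportions, proportions_triple

RESIDUAL_TOL = 1e-6
_EPS = 1e-12


def predict_yellow(proportions, p) -> float:
    """Forward model: yellow-eyeshine fraction at co-expression probability p.

    ``proportions`` is a (UVUV, BB, UVB) triple or ClassProportions summing
    to 1.  Strictly decreasing in p whenever BB + UVB > 0; ranges from 1 at
    p = 0 down to UVUV at p = 1.
    """
    uvuv, bb, uvb = _checked_triple(proportions)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    out = uvuv + q**2 * bb + q * uvb
    return float(out) if out.ndim == 0 else out


def _checked_triple(proportions) -> tuple[float, float, float]:
    triple = proportions_triple(proportions)
    if abs(sum(triple) - 1.0) > 1e-6:
        raise ValueError(f"class proportions {triple!r} must sum to 1")
    return triple


@dataclass(frozen=True)
class CoexpressionFit:
    """Result of inverting the yellow-eyeshine equation for one group.

    ``feasible`` is True when the model can reproduce the observed yellow
    fraction (squared residual below tolerance).  ``identifiable`` is False
    when BB = UVB = 0, where no B cell exists and p drops out of the model;
    p_hat is then NaN.  ``ambiguous`` flags the degenerate case of two
    admissible roots.
    """

    p_hat: float
    residual: float
    feasible: bool
    method: str
    y_obs: float
    proportions: tuple[float, float, float]
    identifiable: bool = True
    ambiguous: bool = False


def fit_p(y_obs: float, proportions, method: str = "closed_form",
          residual_tol: float = RESIDUAL_TOL) -> CoexpressionFit:
    """Least-squares estimate of the co-expression probability p.

    Solves BB q^2 + UVB q + (UVUV - Y) = 0 for q = 1 - p, keeping the root
    in [0, 1].  When no root is admissible (Y outside [UVUV, 1]), p_hat is
    the boundary value minimizing the squared residual and ``feasible`` is
    False.  ``method='grid'`` uses the 1e-6-step grid-search minimizer
    instead of the closed form.
    """
    if not -1e-9 <= y_obs <= 1.0 + 1e-9:
        raise ValueError("observed yellow fraction must lie in [0, 1]")
    y_obs = float(np.clip(y_obs, 0.0, 1.0))
    uvuv, bb, uvb = _checked_triple(proportions)
    if method == "grid":
        return _fit_p_grid(y_obs, (uvuv, bb, uvb), residual_tol=residual_tol)
    if method != "closed_form":
        raise ValueError(f"unknown method {method!r}")

    c = uvuv - y_obs
    ambiguous = False
    if bb > _EPS:
        disc = uvb * uvb - 4.0 * bb * c
        roots = []
        if disc >= 0:
            # numerically stable quadratic roots (avoids cancellation when
            # the admissible root is near 0, i.e. p near 1)
            sq = np.sqrt(disc)
            denom = -(uvb + sq) / 2.0
            roots = [denom / bb, c / denom] if denom != 0 else [0.0]
        admissible = [q for q in roots if -1e-12 <= q <= 1 + 1e-12]
        if len(admissible) == 2 and not np.isclose(admissible[0], admissible[1]):
            # both roots in [0,1] happens only in degenerate configurations;
            # pick deterministically and flag
            admissible.sort(key=lambda q: abs(q - 0.5))
            ambiguous = True
        if admissible:
            q_hat = float(np.clip(admissible[0], 0.0, 1.0))
        else:
            q_hat = _best_boundary(y_obs, (uvuv, bb, uvb))
    elif uvb > _EPS:
        q_hat = float(np.clip((y_obs - uvuv) / uvb, 0.0, 1.0))
    else:
        # UVUV = 1: no blue cells, p is unidentifiable
        residual = c * c
        return CoexpressionFit(
            p_hat=float("nan"), residual=float(residual),
            feasible=bool(residual <= residual_tol), method="closed_form",
            y_obs=float(y_obs), proportions=(uvuv, bb, uvb), identifiable=False,
        )

    residual = (predict_yellow((uvuv, bb, uvb), 1.0 - q_hat) - y_obs) ** 2
    return CoexpressionFit(
        p_hat=float(1.0 - q_hat), residual=float(residual),
        feasible=bool(residual <= residual_tol), method="closed_form",
        y_obs=float(y_obs), proportions=(uvuv, bb, uvb), ambiguous=ambiguous,
    )


def _best_boundary(y_obs: float, triple) -> float:
    resid = [(predict_yellow(triple, 1.0 - q) - y_obs) ** 2 for q in (0.0, 1.0)]
    return 0.0 if resid[0] <= resid[1] else 1.0


def _fit_p_grid(y_obs: float, triple, step: float = 1e-6,
                residual_tol: float = RESIDUAL_TOL) -> CoexpressionFit:
    """Grid-search minimizer over p in [0, 1] at 1e-6 resolution.

    Two-stage (1e-3 coarse, then 1e-6 within the bracketing interval):
    the squared residual is unimodal in q on [0, 1] because the quadratic
    BB q^2 + UVB q + c is monotone there, so refinement around the coarse
    minimum is exact to the fine step.
    """
    uvuv, bb, uvb = triple

    def resid(q):
        return (uvuv + q * q * bb + q * uvb - y_obs) ** 2

    coarse = np.arange(0.0, 1.0 + 1e-9, 1e-3)
    i = int(np.argmin(resid(coarse)))
    lo = max(0.0, coarse[i] - 1e-3)
    hi = min(1.0, coarse[i] + 1e-3)
    fine = np.arange(lo, hi + step / 2, step)
    q_hat = float(fine[int(np.argmin(resid(fine)))])
    residual = float(resid(q_hat))
    identifiable = bb > _EPS or uvb > _EPS
    return CoexpressionFit(
        p_hat=float(1.0 - q_hat) if identifiable else float("nan"),
        residual=residual,
        feasible=bool(residual <= residual_tol),
        method="grid", y_obs=float(y_obs), proportions=triple,
        identifiable=identifiable,
    )


FIT_COLUMNS = ["group", "y_obs", "p_uvuv", "p_bb", "p_uvb",
               "p_hat", "residual", "feasible", "identifiable"]


def fit_group_p(group_table: pd.DataFrame, method: str = "closed_form") -> pd.DataFrame:
    """Apply :func:`fit_p` to each row of a tidy group-means table.

    Expected columns: group, yellow_fraction, p_uvuv, p_bb, p_uvb.  Rows
    with missing values are skipped with a warning.
    """
    rows = []
    for _, row in group_table.iterrows():
        vals = row[["yellow_fraction", "p_uvuv", "p_bb", "p_uvb"]]
        if vals.isna().any():
            warnings.warn(f"group {row.get('group', '?')!r}: missing values, row skipped")
            continue
        fit = fit_p(float(row["yellow_fraction"]),
                    (row["p_uvuv"], row["p_bb"], row["p_uvb"]), method=method)
        rows.append({
            "group": row.get("group", ""), "y_obs": fit.y_obs,
            "p_uvuv": fit.proportions[0], "p_bb": fit.proportions[1],
            "p_uvb": fit.proportions[2], "p_hat": fit.p_hat,
            "residual": fit.residual, "feasible": fit.feasible,
            "identifiable": fit.identifiable,
        })
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


class CoexpressionModel:
    """Model object relating yellow-eyeshine fractions to class proportions.

    Parameters
    ----------
    yellow_fraction : per-group observed ventral yellow-eyeshine fractions.
    proportions : per-group (UVUV, BB, UVB) triples (ClassProportions or
        fraction triples) from antibody staining.
    groups : group labels; defaults to 0..k-1.
    individuals : optional tidy per-individual frame (columns group,
        yellow_fraction, p_uvuv, p_bb, p_uvb) enabling bootstrap
        uncertainty; the fit itself always uses group means.
    """

    def __init__(self, yellow_fraction, proportions, groups=None,
                 individuals: pd.DataFrame | None = None):
        yellow = np.atleast_1d(np.asarray(yellow_fraction, dtype=float))
        triples = [proportions_triple(p) for p in proportions]
        if len(triples) != len(yellow):
            raise ValueError("yellow_fraction and proportions must align")
        self.groups = list(groups) if groups is not None else list(range(len(yellow)))
        self.table = pd.DataFrame({
            "group": self.groups,
            "yellow_fraction": yellow,
            "p_uvuv": [t[0] for t in triples],
            "p_bb": [t[1] for t in triples],
            "p_uvb": [t[2] for t in triples],
        })
        self.individuals = individuals

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group",
                       yellow_col: str = "yellow_fraction",
                       proportion_cols=("p_uvuv", "p_bb", "p_uvb")) -> "CoexpressionModel":
        return cls(
            yellow_fraction=df[yellow_col].to_numpy(),
            proportions=df[list(proportion_cols)].to_numpy(),
            groups=df[group_col].tolist(),
        )

    @classmethod
    def from_individuals(cls, df: pd.DataFrame, group_col: str = "group",
                         yellow_col: str = "yellow_fraction",
                         proportion_cols=("p_uvuv", "p_bb", "p_uvb")) -> "CoexpressionModel":
        """Aggregate per-individual rows to group means, keeping the rows for bootstrap."""
        means = df.groupby(group_col, sort=False)[[yellow_col, *proportion_cols]].mean()
        model = cls(
            yellow_fraction=means[yellow_col].to_numpy(),
            proportions=means[list(proportion_cols)].to_numpy(),
            groups=means.index.tolist(),
        )
        model.individuals = df.rename(columns={group_col: "group", yellow_col: "yellow_fraction"})
        return model

    def predict(self, p) -> np.ndarray:
        """Yellow fraction each group would show at co-expression probability p."""
        return np.array([
            predict_yellow((r.p_uvuv, r.p_bb, r.p_uvb), p)
            for r in self.table.itertuples()
        ])

    def fit(self, method: str = "closed_form") -> "CoexpressionResults":
        fits = fit_group_p(self.table, method=method)
        return CoexpressionResults(model=self, fits=fits, method=method)


class CoexpressionResults:
    """Per-group co-expression estimates with diagnostics.

    ``params`` is a Series of p_hat indexed by group; ``fits`` the full
    tidy table (residuals, feasibility, identifiability).
    """

    def __init__(self, model: CoexpressionModel, fits: pd.DataFrame, method: str):
        self.model = model
        self.fits = fits
        self.method = method

    @property
    def params(self) -> pd.Series:
        return self.fits.set_index("group")["p_hat"]

    @property
    def residuals(self) -> pd.Series:
        return self.fits.set_index("group")["residual"]

    def predict(self, p=None) -> np.ndarray:
        """Fitted (default) or counterfactual yellow fractions per group."""
        if p is not None:
            return self.model.predict(p)
        return np.array([
            predict_yellow((r.p_uvuv, r.p_bb, r.p_uvb), r.p_hat)
            if r.identifiable else np.nan
            for r in self.fits.itertuples()
        ])

    def bootstrap(self, n_boot: int = 1000, seed: int = 0,
                  ci: float = 0.95) -> pd.DataFrame:
        """Nonparametric bootstrap over individuals within each group.

        Requires the model to have been built from per-individual data.
        Returns per-group standard errors and percentile intervals for
        p_hat.
        """
        df = self.model.individuals
        if df is None:
            raise ValueError("bootstrap needs per-individual data "
                             "(build the model with from_individuals)")
        rng = np.random.default_rng(seed)
        lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
        rows = []
        for group, sub in df.groupby("group", sort=False):
            vals = sub[["yellow_fraction", "p_uvuv", "p_bb", "p_uvb"]].to_numpy()
            n = len(vals)
            estimates = np.empty(n_boot)
            for b in range(n_boot):
                pick = vals[rng.integers(0, n, n)].mean(axis=0)
                triple = pick[1:] / pick[1:].sum()
                estimates[b] = fit_p(min(max(pick[0], 0.0), 1.0), triple).p_hat
            rows.append({
                "group": group,
                "p_se": float(np.nanstd(estimates, ddof=1)),
                "p_lo": float(np.nanquantile(estimates, lo_q)),
                "p_hi": float(np.nanquantile(estimates, hi_q)),
                "n_individuals": n,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Blue-cell LW co-expression fit",
            f"method: {self.method}   groups: {len(self.fits)}",
            "",
        ]
        table = self.fits.copy()
        table["p_hat"] = table["p_hat"].map(lambda v: f"{v:.4f}")
        table["residual"] = table["residual"].map(lambda v: f"{v:.2e}")
        lines.append(
            table[["group", "y_obs", "p_uvuv", "p_bb", "p_uvb",
                   "p_hat", "residual", "feasible"]].to_string(index=False)
        )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CoexpressionResults: {len(self.fits)} groups, method={self.method}>"
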