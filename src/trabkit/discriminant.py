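"""Canonical discriminant analysis of trabecular trait suites.

statsmodels-style API: :class:`CanonicalDiscriminant` is built from a
feature table and group labels; ``fit`` (all variables entered together) or
``fit_stepwise`` (greedy Wilks-Λ minimization with F-to-enter/remove)
return a :class:`DiscriminantResults` carrying canonical coefficients,
eigenvalues and explained variance, Wilks' Λ with Bartlett χ² tests, the
pooled within-group structure matrix, group centroids, classification and
confusion tables, and pairwise Mahalanobis F-tests between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["CanonicalDiscriminant", "DiscriminantResults", "ConfusionMatrix",
           "PairwiseF", "stepwise_select"]


def _round1(x: float) -> float:
    """One-decimal half-up rounding (reporting convention for % correct)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Classification table: rows = true group, columns = predicted."""

    counts: pd.DataFrame
    group_order: list

    @classmethod
    def from_counts(cls, counts, group_order) -> "ConfusionMatrix":
        df = pd.DataFrame(np.asarray(counts, dtype=int),
                          index=group_order, columns=group_order)
        return cls(df, list(group_order))

    @classmethod
    def from_labels(cls, predictions, truth, group_order) -> "ConfusionMatrix":
        preds = pd.Series(predictions).reset_index(drop=True)
        true = pd.Series(truth).reset_index(drop=True)
        known = set(group_order)
        unknown = (set(preds) | set(true)) - known
        if not set(preds).issubset(known) or not set(true).issubset(known):
            raise ValueError(f"labels outside the group vocabulary: "
                             f"{sorted(unknown - known)}")
        counts = pd.crosstab(true, preds).reindex(index=group_order,
                                                  columns=group_order,
                                                  fill_value=0)
        return cls(counts, list(group_order))

    @property
    def group_n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def percent_correct(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts), index=self.group_order)
        return (100.0 * diag / self.group_n).map(_round1)

    @property
    def overall_percent(self) -> float:
        return _round1(100.0 * np.trace(self.counts) / self.counts.to_numpy().sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def summary(self) -> str:
        table = self.counts.copy()
        table.insert(0, "n", self.group_n)
        table["%correct"] = self.percent_correct
        return (table.to_string()
                + f"\n\nOverall correct: {self.n_correct} of "
                  f"{int(self.counts.to_numpy().sum())} "
                  f"({self.overall_percent}%)")


@dataclass
class PairwiseF:
    """Pairwise group separation tests on Mahalanobis distances.

    ``f`` and ``p`` are symmetric group × group DataFrames; ``df`` is the
    (numerator, denominator) pair shared by every comparison.
    """

    f: pd.DataFrame
    p: pd.DataFrame
    df: tuple[int, int]

    def table(self) -> pd.DataFrame:
        """Report layout: F below the diagonal, p above, 'X' on it."""
        groups = self.f.index
        out = pd.DataFrame("", index=groups, columns=groups, dtype=object)
        for i, gi in enumerate(groups):
            for j, gj in enumerate(groups):
                if i == j:
                    out.iloc[i, j] = "X"
                elif i > j:
                    out.iloc[i, j] = f"{self.f.iloc[i, j]:.2f}"
                else:
                    out.iloc[i, j] = f"{self.p.iloc[i, j]:.4g}"
        return out


class CanonicalDiscriminant:
    """Linear discriminant model for a labelled feature table.

    Parameters
    ----------
    features : DataFrame (n × p)
    groups : Series of group labels aligned with ``features``
    priors : 'equal' or 'proportional'
    """

    def __init__(self, features: pd.DataFrame, groups, priors: str = "equal"):
        self.features = pd.DataFrame(features).astype(float)
        self.groups = pd.Series(groups).reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)
        if priors not in ("equal", "proportional"):
            raise ValueError("priors must be 'equal' or 'proportional'")
        self.priors = priors
        counts = self.groups.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least two groups")
        if counts.min() < 2:
            raise ValueError("every group needs at least two specimens")
        self.group_order = list(pd.unique(self.groups))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str,
                       feature_cols: list[str] | None = None,
                       priors: str = "equal"):
        cols = feature_cols or [c for c in df.columns if c != group_col]
        return cls(df[cols], df[group_col], priors=priors)

    # ---- sums of squares -------------------------------------------------
    def _sscp(self, cols=None):
        X = self.features[cols].to_numpy() if cols is not None \
            else self.features.to_numpy()
        g = self.groups.to_numpy()
        grand = X.mean(axis=0)
        W = np.zeros((X.shape[1],) * 2)
        B = np.zeros_like(W)
        for lab in self.group_order:
            Xg = X[g == lab]
            d = Xg - Xg.mean(axis=0)
            W += d.T @ d
            dm = (Xg.mean(axis=0) - grand)[:, None]
            B += len(Xg) * (dm @ dm.T)
        return W, B

    def wilks_lambda(self, cols) -> float:
        """Wilks' Λ = det(W)/det(W+B) for a variable subset."""
        if not cols:
            return 1.0
        W, B = self._sscp(list(cols))
        sign_w, logdet_w = np.linalg.slogdet(W)
        sign_t, logdet_t = np.linalg.slogdet(W + B)
        if sign_w <= 0 or sign_t <= 0:
            raise ValueError("singular within-group SSCP for subset "
                             f"{list(cols)}")
        return float(np.exp(logdet_w - logdet_t))

    # ---- fitting ---------------------------------------------------------
    def fit(self, feature_subset: list[str] | None = None) -> "DiscriminantResults":
        cols = feature_subset or list(self.features.columns)
        X = self.features[cols].to_numpy()
        n, p = X.shape
        g = len(self.group_order)
        W, B = self._sscp(cols)
        try:
            evals, evecs = linalg.eigh(B, W)
        except linalg.LinAlgError as exc:
            diag = np.diag(W)
            worst = cols[int(np.argmin(diag))]
            raise ValueError("singular within-group covariance "
                             f"(check variable {worst!r})") from exc
        m = min(g - 1, p)
        order = np.argsort(evals)[::-1][:m]
        lam = np.clip(evals[order], 0, None)
        # eigh(B, W) yields aᵀWa = 1; rescale so pooled within-variance of
        # scores aᵀ(W/(n−g))a = 1
        A = evecs[:, order] * np.sqrt(n - g)

        Sw = W / (n - g)
        grand = X.mean(axis=0)
        means = pd.DataFrame({lab: X[self.groups == lab].mean(axis=0)
                              for lab in self.group_order}, index=cols).T
        centroids = (means.to_numpy() - grand) @ A

        # Wilks Λ for successive function sets + Bartlett's χ²
        wilks, chi2, chi2_p, dfs = [], [], [], []
        for k in range(m):
            lam_k = np.prod(1.0 / (1.0 + lam[k:]))
            c = n - 1 - (p + g) / 2.0
            x2 = -c * np.log(lam_k)
            df = (p - k) * (g - 1 - k)
            wilks.append(float(lam_k))
            chi2.append(float(x2))
            chi2_p.append(float(stats.chi2.sf(x2, df)))
            dfs.append(df)

        total = lam.sum()
        pct = 100.0 * lam / total if total > 0 else np.zeros(m)
        structure = (Sw @ A) / np.sqrt(np.diag(Sw))[:, None]

        counts = self.groups.value_counts()
        if self.priors == "equal":
            priors = pd.Series(1.0 / g, index=self.group_order)
        else:
            priors = (counts / n).reindex(self.group_order)

        return DiscriminantResults(
            model=self, variables=cols,
            coef=pd.DataFrame(A, index=cols,
                              columns=[f"F{i+1}" for i in range(m)]),
            eigenvalues=lam, pct_variance=pct,
            wilks=np.array(wilks), chi2=np.array(chi2),
            chi2_p=np.array(chi2_p), chi2_df=dfs,
            structure_matrix=pd.DataFrame(
                structure, index=cols,
                columns=[f"F{i+1}" for i in range(m)]),
            group_means=means,
            centroids=pd.DataFrame(
                centroids, index=self.group_order,
                columns=[f"F{i+1}" for i in range(m)]),
            pooled_within_cov=pd.DataFrame(Sw, index=cols, columns=cols),
            priors=priors)

    def fit_stepwise(self, f_enter: float = 3.84,
                     f_remove: float = 2.71) -> "DiscriminantResults":
        selected = stepwise_select(self.features, self.groups,
                                   f_enter=f_enter, f_remove=f_remove,
                                   model=self)
        if not selected:
            raise ValueError("stepwise selection retained no variables")
        res = self.fit(feature_subset=selected)
        res.selected = selected
        return res


def stepwise_select(features: pd.DataFrame, groups, f_enter: float = 3.84,
                    f_remove: float = 2.71, model=None) -> list[str]:
    """Greedy Wilks-Λ stepwise variable selection (SPSS-style F thresholds).

    At each step the variable with the largest partial F enters if it
    reaches ``f_enter``; any entered variable whose partial F falls below
    ``f_remove`` is removed.  Terminates at a fixed point; deterministic.
    """
    if f_enter < f_remove:
        raise ValueError("f_enter must be at least f_remove")
    m = model or CanonicalDiscriminant(features, groups)
    n = len(m.groups)
    g = len(m.group_order)
    selected: list[str] = []

    def partial_f(lam_old, lam_new, p0):
        # F-change for one variable added to p0 already-entered variables
        return ((n - g - p0) / (g - 1)) * (lam_old / lam_new - 1.0)

    while True:
        changed = False
        lam_cur = m.wilks_lambda(selected)
        candidates = [c for c in m.features.columns if c not in selected]
        best, best_f, best_lam = None, -np.inf, None
        for c in candidates:
            try:
                lam_new = m.wilks_lambda(selected + [c])
            except ValueError:
                continue
            f = partial_f(lam_cur, lam_new, len(selected))
            if f > best_f:
                best, best_f, best_lam = c, f, lam_new
        if best is not None and best_f >= f_enter:
            selected.append(best)
            changed = True
        # removal pass
        for c in list(selected):
            rest = [v for v in selected if v != c]
            lam_without = m.wilks_lambda(rest)
            lam_with = m.wilks_lambda(selected)
            f = partial_f(lam_without, lam_with, len(rest))
            if f < f_remove:
                selected.remove(c)
                changed = True
        if not changed:
            return selected


@dataclass
class DiscriminantResults:
    """Fitted canonical discriminant functions and everything derived from them."""

    model: CanonicalDiscriminant
    variables: list
    coef: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    wilks: np.ndarray
    chi2: np.ndarray
    chi2_p: np.ndarray
    chi2_df: list
    structure_matrix: pd.DataFrame
    group_means: pd.DataFrame
    centroids: pd.DataFrame
    pooled_within_cov: pd.DataFrame
    priors: pd.Series
    selected: list | None = None

    # ---- scores & classification ----------------------------------------
    def scores(self, features: pd.DataFrame | None = None) -> pd.DataFrame:
        X = (features if features is not None
             else self.model.features)[self.variables].to_numpy()
        grand = self.model.features[self.variables].to_numpy().mean(axis=0)
        return pd.DataFrame((X - grand) @ self.coef.to_numpy(),
                            columns=self.coef.columns)

    def predict(self, features: pd.DataFrame | None = None) -> pd.Series:
        """Assign each row to the group minimizing Mahalanobis distance
        (pooled within-group covariance) penalized by −2·ln(prior)."""
        X = (features if features is not None
             else self.model.features)
        if not set(self.variables).issubset(X.columns):
            raise ValueError("features lack the fitted variables")
        X = X[self.variables].to_numpy()
        Sw_inv = np.linalg.inv(self.pooled_within_cov.to_numpy())
        scores = np.empty((len(X), len(self.centroids.index)))
        for j, lab in enumerate(self.centroids.index):
            d = X - self.group_means.loc[lab].to_numpy()
            scores[:, j] = np.einsum("ij,jk,ik->i", d, Sw_inv, d) \
                - 2.0 * np.log(self.priors[lab])
        labels = np.asarray(self.centroids.index)[np.argmin(scores, axis=1)]
        return pd.Series(labels)

    def predict_loo(self) -> pd.Series:
        """Leave-one-out classification (refit without each specimen)."""
        feats, groups = self.model.features, self.model.groups
        out = []
        for i in range(len(feats)):
            keep = feats.index != feats.index[i]
            sub = CanonicalDiscriminant(feats[keep], groups[keep],
                                        priors=self.model.priors)
            res = sub.fit(feature_subset=self.variables)
            out.append(res.predict(feats.iloc[[i]]).iloc[0])
        return pd.Series(out)

    def confusion(self, predictions=None) -> ConfusionMatrix:
        preds = predictions if predictions is not None else self.predict()
        return ConfusionMatrix.from_labels(preds, self.model.groups,
                                           self.model.group_order)

    # ---- pairwise group separation ---------------------------------------
    def pairwise_f(self) -> PairwiseF:
        """F-tests on pairwise Mahalanobis distances between group centroids.

        F = [(n−g−p+1)/(p(n−g))]·[n_i·n_j/(n_i+n_j)]·D²_ij with
        DF = (p, n−g−p+1).
        """
        n = len(self.model.groups)
        g = len(self.model.group_order)
        p = len(self.variables)
        if p >= n - g:
            raise ValueError("too many variables for the pairwise F test")
        df1, df2 = p, n - g - p + 1
        Sw_inv = np.linalg.inv(self.pooled_within_cov.to_numpy())
        counts = self.model.groups.value_counts()
        order = self.model.group_order
        F = pd.DataFrame(0.0, index=order, columns=order)
        P = pd.DataFrame(1.0, index=order, columns=order)
        for i, gi in enumerate(order):
            for j, gj in enumerate(order):
                if j <= i:
                    continue
                d = (self.group_means.loc[gi] - self.group_means.loc[gj]).to_numpy()
                d2 = float(d @ Sw_inv @ d)
                ni, nj = counts[gi], counts[gj]
                f = (df2 / (p * (n - g))) * (ni * nj / (ni + nj)) * d2
                pv = float(stats.f.sf(f, df1, df2))
                F.loc[gi, gj] = F.loc[gj, gi] = f
                P.loc[gi, gj] = P.loc[gj, gi] = pv
        return PairwiseF(F, P, (df1, df2))

    # ---- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = ["Canonical discriminant function analysis",
                 "=" * 48,
                 f"n = {len(self.model.groups)}, groups = "
                 f"{len(self.model.group_order)}, variables = "
                 f"{', '.join(map(str, self.variables))}", ""]
        lines.append(f"{'function':<10}{'eigenvalue':>12}{'% variance':>12}"
                     f"{'Wilks L':>10}{'chi2':>10}{'df':>5}{'p':>10}")
        for i in range(len(self.eigenvalues)):
            lines.append(f"F{i+1:<9}{self.eigenvalues[i]:>12.4f}"
                         f"{self.pct_variance[i]:>12.1f}{self.wilks[i]:>10.4f}"
                         f"{self.chi2[i]:>10.2f}{self.chi2_df[i]:>5}"
                         f"{self.chi2_p[i]:>10.3g}")
        lines += ["", "Structure matrix (pooled within-group correlations):",
                  self.structure_matrix.round(3).to_string(), "",
                  "Group centroids (canonical space):",
                  self.centroids.round(3).to_string()]
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of the first two canonical functions, coloured by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        s = self.scores()
        if s.shape[1] < 2:
            raise ValueError("need at least two canonical functions to plot")
        for lab in self.model.group_order:
            sel = (self.model.groups == lab).to_numpy()
            ax.scatter(s.iloc[sel, 0], s.iloc[sel, 1], label=str(lab), s=18)
        ax.set_xlabel(f"Function 1 ({self.pct_variance[0]:.1f}%)")
        ax.set_ylabel(f"Function 2 ({self.pct_variance[1]:.1f}%)")
        ax.legend(fontsize=7)
        return ax
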