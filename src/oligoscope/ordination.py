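"""Redundancy analysis (RDA) of oligotype abundances on environmental data.

Response matrices (sites × oligotypes) are Hellinger transformed and
explanatory variables z-scored before fitting.  :class:`RDA` follows the
model/results idiom: ``RDA(Y, X).fit()`` returns an :class:`RDAResults`
holding eigenvalues, the constrained-variation fraction, adjusted R²,
scaling-2 triplot scores and (after :meth:`RDAResults.permutation_test`) a
permutation p-value of the pseudo-F statistic.  Forward selection uses the
double-stopping rule: candidates enter only while their marginal
permutation test is significant and the cumulative adjusted R² stays below
that of the global model, and nothing enters at all unless the global model
itself is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

#: Default explanatory candidates, in reporting order.
DEFAULT_CANDIDATES = ("protein", "cpe", "easting", "northing", "depth", "porosity")

_PRETTY = {
    "protein": "Protein",
    "cpe": "CPE",
    "easting": "Easting",
    "northing": "Northing",
    "depth": "Depth",
    "porosity": "Porosity",
}


class InvalidCountsError(ValueError):
    pass


class DegenerateVariableError(ValueError):
    pass


class CollinearityError(np.linalg.LinAlgError):
    pass


def hellinger(matrix, warn_zero_rows: bool = False) -> np.ndarray:
    """Hellinger transform: square root of row-relative abundances.

    y'_hj = sqrt(y_hj / y_h+).  Rows of zeros map to zero rows.  Rows of a
    transformed matrix with positive totals have unit Euclidean norm, which
    makes Euclidean-based ordination behave like a Hellinger-distance one.
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise InvalidCountsError("Hellinger transform needs non-negative entries")
    sums = x.sum(axis=-1, keepdims=True)
    if warn_zero_rows and (sums == 0).any():
        import warnings

        warnings.warn("all-zero rows map to all-zero Hellinger rows", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(np.where(sums > 0, x / np.where(sums == 0, 1.0, sums), 0.0))
    return out


def zscore(env: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scoring (zero mean, unit sample SD).

    Constant columns cannot be standardised; they are dropped with a
    :class:`DegenerateVariableError` logged as a warning.
    """
    env = env.astype(float)
    sd = env.std(ddof=ddof)
    constant = sd[sd == 0].index
    if len(constant):
        import warnings

        warnings.warn(
            f"dropping constant variables: {list(constant)}", stacklevel=2
        )
        env = env.drop(columns=constant)
        sd = sd.drop(constant)
    if env.shape[1] == 0:
        raise DegenerateVariableError("no variable with nonzero variance")
    return (env - env.mean()) / sd


# ---------------------------------------------------------------------------
# the model / results pair


@dataclass
class RDAResults:
    """Fitted redundancy analysis.

    ``constrained_fraction`` is SS(fitted)/SS(total) of the centred
    response; ``eigenvalues`` are the canonical eigenvalues followed by the
    residual (unconstrained) ones, which together sum to the total variance.
    Scores are type-2 scaling: oligotype (species) scores carry the
    eigenvalue magnitudes, site scores are standardised linear combinations.
    """

    model: "RDA"
    eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    constrained_fraction: float
    adjusted_r2: float
    site_scores: pd.DataFrame
    oligotype_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    pseudo_f: float
    p_value: float | None = None
    p_adjusted: float | None = None
    vif: pd.Series | None = None
    selected_variables: list[str] = field(default_factory=list)

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum() + self.residual_eigenvalues.sum())

    def permutation_test(self, n_perm: int = 999, seed: int = 0) -> float:
        """Permutation p-value for the global pseudo-F (add-one rule)."""
        self.p_value = self.model.permutation_pvalue(n_perm=n_perm, seed=seed)
        return self.p_value

    def formula(self) -> str:
        terms = self.selected_variables or list(self.model.var_names)
        rhs = " + ".join(_PRETTY.get(v, v) for v in terms) if terms else "1"
        return f"Y ~ {rhs}"

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  model:                 {self.formula()}",
            f"  sites, oligotypes:     {self.model.n} , {self.model.Y.shape[1]}",
            f"  constrained variation: {100 * self.constrained_fraction:.1f}%",
            f"  adjusted R2:           {self.adjusted_r2:.3f}",
            f"  pseudo-F:              {self.pseudo_f:.3f}",
        ]
        if self.p_value is not None:
            lines.append(f"  permutation P:         {self.p_value:.4g}")
        if self.p_adjusted is not None:
            lines.append(f"  adjusted P (BH):       {self.p_adjusted:.4g}")
        if self.vif is not None and len(self.vif):
            vifs = ", ".join(f"{k}={v:.2f}" for k, v in self.vif.items())
            lines.append(f"  VIF:                   {vifs}")
        return "\n".join(lines)


class RDA:
    """Redundancy analysis model of a site × oligotype response.

    Parameters
    ----------
    Y : DataFrame or ndarray, sites × oligotypes
        Response matrix; expected Hellinger-transformed (see
        :func:`hellinger`), centred internally.
    X : DataFrame or ndarray, sites × variables
        Explanatory matrix; expected z-scored (see :func:`zscore`),
        centred internally.
    """

    def __init__(self, Y, X):
        self.Y = np.asarray(Y, dtype=float)
        if isinstance(X, pd.DataFrame):
            self.var_names = list(X.columns)
            self.X = X.to_numpy(float)
        else:
            self.X = np.asarray(X, dtype=float)
            if self.X.ndim == 1:
                self.X = self.X[:, None]
            self.var_names = [f"x{i}" for i in range(self.X.shape[1])]
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X must have aligned site rows")
        self.n = self.Y.shape[0]
        q = self.X.shape[1]
        if self.n <= q + 1:
            raise ValueError("need n_sites > n_variables + 1")
        self.oligotype_names = (
            list(Y.columns) if isinstance(Y, pd.DataFrame) else
            [f"oligo{i}" for i in range(self.Y.shape[1])]
        )
        self.site_names = (
            list(Y.index) if isinstance(Y, pd.DataFrame) else
            [f"site{i}" for i in range(self.n)]
        )
        self.Yc = self.Y - self.Y.mean(axis=0)
        self.Xc = self.X - self.X.mean(axis=0)
        if np.linalg.matrix_rank(self.Xc) < q:
            raise CollinearityError(
                f"rank-deficient explanatory matrix over {self.var_names}"
            )
        # hat matrix of the centred constraints; reused by permutations
        self._hat = self.Xc @ np.linalg.pinv(self.Xc)
        self._ss_total = float((self.Yc**2).sum())

    # -- sums of squares ----------------------------------------------------
    def _ss_fit(self, Yc: np.ndarray) -> float:
        return float((Yc * (self._hat @ Yc)).sum())

    def pseudo_f(self, Yc: np.ndarray | None = None) -> float:
        """Pseudo-F = (SS_fit/q) / (SS_res/(n−1−q))."""
        Yc = self.Yc if Yc is None else Yc
        q = self.X.shape[1]
        ss_fit = self._ss_fit(Yc)
        ss_res = float((Yc**2).sum()) - ss_fit
        if ss_res <= 0:
            return np.inf
        return (ss_fit / q) / (ss_res / (self.n - 1 - q))

    def permutation_pvalue(self, n_perm: int = 999, seed: int = 0) -> float:
        """Permute response rows; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)."""
        rng = np.random.default_rng(seed)
        f_obs = self.pseudo_f()
        if not np.isfinite(f_obs):
            return 1.0 / (1.0 + n_perm)
        count = 0
        for _ in range(n_perm):
            Yp = self.Yc[rng.permutation(self.n)]
            Yp = Yp - Yp.mean(axis=0)
            if self.pseudo_f(Yp) >= f_obs:
                count += 1
        return (1.0 + count) / (1.0 + n_perm)

    def fit(self) -> RDAResults:
        """Least-squares projection and eigen-decomposition of fitted values."""
        q = self.X.shape[1]
        Yhat = self._hat @ self.Yc
        resid = self.Yc - Yhat
        ss_fit = float((Yhat**2).sum())
        frac = ss_fit / self._ss_total if self._ss_total > 0 else 0.0
        # canonical axes from the SVD of the fitted values
        u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
        lam = s**2 / (self.n - 1)
        keep = s > max(s[0], 1e-30) * 1e-9 if s.size else np.array([], bool)
        u, s, vt, lam = u[:, keep], s[keep], vt[keep], lam[keep]
        _, s_res, _ = np.linalg.svd(resid, full_matrices=False)
        lam_res = s_res**2 / (self.n - 1)
        lam_res = lam_res[lam_res > (lam_res[0] if lam_res.size else 0) * 1e-12]
        r2 = frac
        adj = 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - 1 - q)

        naxes = lam.size
        axes = [f"RDA{k + 1}" for k in range(naxes)]
        # scaling 2: species scores weighted by sqrt(lambda/total)
        tot = self._ss_total / (self.n - 1)
        species = vt.T * np.sqrt(lam / tot) if naxes else np.empty((len(vt.T), 0))
        sites_sc = u * np.sqrt(self.n - 1)  # standardised LC scores
        biplot = np.zeros((q, naxes))
        for k in range(naxes):
            for j in range(q):
                xj = self.Xc[:, j]
                denom = xj.std() * sites_sc[:, k].std()
                biplot[j, k] = (
                    np.corrcoef(xj, sites_sc[:, k])[0, 1] if denom > 0 else 0.0
                )
        res = RDAResults(
            model=self,
            eigenvalues=lam,
            residual_eigenvalues=lam_res,
            constrained_fraction=float(frac),
            adjusted_r2=float(adj),
            site_scores=pd.DataFrame(sites_sc, index=self.site_names, columns=axes),
            oligotype_scores=pd.DataFrame(
                species, index=self.oligotype_names, columns=axes
            ),
            biplot_scores=pd.DataFrame(biplot, index=self.var_names, columns=axes),
            pseudo_f=self.pseudo_f(),
            selected_variables=list(self.var_names),
        )
        if q >= 1:
            res.vif = vif(pd.DataFrame(self.X, columns=self.var_names))
        return res


def rda_fit(Y, X) -> RDAResults:
    """Convenience wrapper: ``RDA(Y, X).fit()``."""
    return RDA(Y, X).fit()


# ---------------------------------------------------------------------------
# inference helpers


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1/(1−R²_k) per variable.

    R²_k regresses variable k on the remaining variables (with intercept).
    A single variable has VIF 1; perfectly collinear variables report inf.
    """
    X = X.astype(float)
    cols = list(X.columns)
    out = {}
    for k in cols:
        others = [c for c in cols if c != k]
        y = X[k].to_numpy()
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if not others or ss_tot == 0:
            out[k] = 1.0
            continue
        Z = X[others].to_numpy()
        Zc = Z - Z.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Zc, yc, rcond=None)
        ss_res = float(((yc - Zc @ beta) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[k] = float(np.inf) if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return pd.Series(out)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def forward_select(
    Y,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> list[str]:
    """Forward selection of explanatory variables with double stopping.

    Gate 1: the global model (all candidates) must be significant at
    ``alpha`` under the permutation test, otherwise nothing is selected.
    Then candidates are added greedily by explained variance while the
    marginal permutation p-value of the addition is ≤ alpha; selection
    halts once the cumulative adjusted R² reaches the global model's
    adjusted R² (the variable that reaches the cap is retained, then no
    further one enters — with few sites the df-penalised global adjusted
    R² routinely sits below that of a single strong predictor, so
    rejecting the capping variable would discard genuine signal).
    Returns the (possibly empty) ordered list of selected variable names.
    """
    if X.shape[1] == 0:
        return []
    rng = np.random.default_rng(seed)
    global_model = RDA(Y, X)
    global_res = global_model.fit()
    p_global = global_model.permutation_pvalue(
        n_perm=n_perm, seed=int(rng.integers(2**31))
    )
    if p_global > alpha:
        return []
    adj_cap = global_res.adjusted_r2

    selected: list[str] = []
    remaining = list(X.columns)
    while remaining:
        best, best_r2 = None, -np.inf
        for cand in remaining:
            r = RDA(Y, X[selected + [cand]]).fit()
            if r.constrained_fraction > best_r2:
                best, best_r2 = cand, r.constrained_fraction
        trial = RDA(Y, X[selected + [best]])
        trial_res = trial.fit()
        # marginal test: does adding `best` beat permuted responses?
        p_marg = _marginal_pvalue(
            Y, X, selected, best, n_perm, int(rng.integers(2**31))
        )
        if p_marg > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        if trial_res.adjusted_r2 >= adj_cap:
            break
    return selected


def _marginal_pvalue(
    Y, X: pd.DataFrame, selected: list[str], cand: str, n_perm: int, seed: int
) -> float:
    """Permutation p-value for adding one candidate to the current model.

    Uses the partial pseudo-F of the candidate given the selected terms,
    permuting the residuals of the reduced model (permutation of residuals
    under the reduced model).
    """
    rng = np.random.default_rng(seed)
    Yc = np.asarray(Y, dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    n = Yc.shape[0]

    def hat(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.zeros((n, n))
        Z = X[cols].to_numpy(float)
        Zc = Z - Z.mean(axis=0)
        return Zc @ np.linalg.pinv(Zc)

    h_red = hat(selected)
    h_full = hat(selected + [cand])
    q_full = len(selected) + 1

    def partial_f(Ym: np.ndarray) -> float:
        ss_full = float((Ym * (h_full @ Ym)).sum())
        ss_red = float((Ym * (h_red @ Ym)).sum())
        ss_res = float((Ym**2).sum()) - ss_full
        if ss_res <= 0:
            return np.inf
        return (ss_full - ss_red) / (ss_res / (n - 1 - q_full))

    f_obs = partial_f(Yc)
    if not np.isfinite(f_obs):
        return 1.0 / (1.0 + n_perm)
    resid = Yc - h_red @ Yc
    fitted = h_red @ Yc
    count = 0
    for _ in range(n_perm):
        Ym = fitted + resid[rng.permutation(n)]
        Ym = Ym - Ym.mean(axis=0)
        if partial_f(Ym) >= f_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def select_models(
    results: dict[str, RDAResults],
    min_constrained: float = 0.50,
    alpha: float = 0.05,
    meta_by_otu: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Report OTUs whose model passes the reporting thresholds.

    BH-adjusts the models' global p-values as one family, then keeps models
    with constrained fraction strictly above ``min_constrained`` and
    adjusted p < ``alpha``.  Returns one row per kept OTU with taxonomy,
    number of oligotypes, the model formula and constrained variation (%).
    """
    otus = list(results)
    if not otus:
        return pd.DataFrame(
            columns=["class", "order", "n_oligotypes", "model",
                     "constrained_pct", "p_adjusted"]
        )
    pvals = np.array([
        results[o].p_value if results[o].p_value is not None else 1.0 for o in otus
    ])
    padj = fdr_bh(pvals)
    rows = []
    for o, pa in zip(otus, padj):
        res = results[o]
        res.p_adjusted = float(pa)
        if res.constrained_fraction > min_constrained and pa < alpha:
            m = (meta_by_otu or {}).get(o, {})
            rows.append(
                {
                    "otu_id": o,
                    "class": m.get("class", "-"),
                    "order": m.get("order", "-"),
                    "n_oligotypes": res.model.Y.shape[1],
                    "model": res.formula(),
                    "constrained_pct": round(100 * res.constrained_fraction),
                    "p_adjusted": float(pa),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["class", "order", "n_oligotypes", "model",
                     "constrained_pct", "p_adjusted"]
        )
    return pd.DataFrame(rows).set_index("otu_id")
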