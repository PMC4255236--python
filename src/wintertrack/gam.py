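"""Additive habitat-selection models with population interactions.

The model follows the statsmodels convention of a model object built from
data whose :meth:`~HabitatSelectionGAM.fit` returns a results object.

The response is ln(density + 1) per grid cell per population.  The global
model gives every population its own smooth of every covariate (habitat
variables, cross-sea distance from the colony, and competitor densities
whose self column is aliased to zero):

    y ~ population + sum_v  population x s(v)

Smooths are cubic P-splines with shrinkage penalties (so a term can be
penalized out of the model); smoothing parameters are selected by GCV via
coordinate descent on a log-lambda grid, which is deterministic for given
data.  AIC uses the Gaussian log-likelihood with the model's effective
degrees of freedom, so reported d.f. are fractional.  Model selection
removes population interactions one at a time (shared smooth replaces the
per-population smooths) and, where a removal is supported, drops the
variable entirely — ranked by AIC.  A latitude-longitude tensor smooth on
a 4 x 4 degree basis can be added to absorb residual spatial
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grids import haversine_km
from .splines import BSplineBasis1D, tensor_design, tensor_penalty


class GAMError(RuntimeError):
    pass


@dataclass(frozen=True)
class Smooth:
    """A smooth term: s(var), optionally interacted with the group factor."""

    var: str
    by_group: bool = True
    k: int = 10          # basis dimension


@dataclass(frozen=True)
class TensorSmooth:
    """2-D lon/lat smooth with knot spacing in degrees (default 4 x 4)."""

    lon_var: str = "lon"
    lat_var: str = "lat"
    spacing_deg: float = 4.0


LAMBDA_GRID = 10.0 ** np.arange(-3.0, 7.0)


class HabitatSelectionGAM:
    """Gaussian additive model of log bird density on habitat covariates.

    Parameters
    ----------
    table : DataFrame
        One row per (cell x population); see ``build_model_table``.
    response : str
        Response column (ln(density+1)).
    smooths : sequence of Smooth
        Covariate smooths; ``by_group=True`` fits one smooth per population.
    group_col : str
        Population factor column.
    tensor : TensorSmooth, optional
        Spatial tensor smooth absorbing residual autocorrelation.
    """

    def __init__(self, table: pd.DataFrame, response: str, smooths,
                 group_col: str = "population", tensor: TensorSmooth | None = None,
                 basis_cache: dict | None = None):
        self.table = table.reset_index(drop=True)
        self.response = response
        self.smooths = tuple(smooths)
        self.group_col = group_col
        self.tensor = tensor
        missing = [s.var for s in self.smooths if s.var not in table.columns]
        if missing:
            raise GAMError(f"covariates not in table: {missing}")
        if table[[s.var for s in self.smooths] + [response]].isna().any().any():
            raise GAMError("model table contains missing values")
        self.groups = sorted(table[group_col].unique())
        # bases shared across model variants so AICs are comparable
        self._bases = basis_cache if basis_cache is not None else {}
        self._build_design()

    @classmethod
    def from_dataframe(cls, table, response="log_density", smooths=None,
                       group_col="population", tensor=None):
        if smooths is None:
            skip = {response, group_col, "lon", "lat", "cell"}
            smooths = [Smooth(c) for c in table.columns
                       if c not in skip and np.issubdtype(table[c].dtype, np.number)]
        return cls(table, response, smooths, group_col, tensor)

    # -- design assembly --------------------------------------------------
    def _basis_for(self, var: str, k: int) -> BSplineBasis1D:
        key = (var, k)
        if key not in self._bases:
            self._bases[key] = BSplineBasis1D.for_data(self.table[var], n_basis=k)
        return self._bases[key]

    def _build_design(self):
        tbl = self.table
        n = len(tbl)
        cols = [np.ones((n, 1))]
        names = ["(intercept)"]
        # group intercepts (first level absorbed)
        gvals = tbl[self.group_col].to_numpy()
        for g in self.groups[1:]:
            cols.append((gvals == g).astype(float)[:, None])
            names.append(f"{self.group_col}[{g}]")
        blocks = []  # (term label, start, stop, penalty)
        start = sum(c.shape[1] for c in cols)
        for sm in self.smooths:
            basis = self._basis_for(sm.var, sm.k)
            B = basis.design(tbl[sm.var].to_numpy())
            S = basis.penalty()
            if sm.by_group:
                for g in self.groups:
                    ind = gvals == g
                    Bg = np.zeros_like(B)
                    Bg[ind] = B[ind] - B[ind].mean(axis=0)
                    if not np.any(np.abs(Bg).sum(axis=0) > 0):
                        raise GAMError(f"term s({sm.var}):{g} is empty "
                                       "(rank-deficient design)")
                    cols.append(Bg)
                    blocks.append((f"s({sm.var}):{g}", start, start + B.shape[1], S))
                    start += B.shape[1]
            else:
                Bc = B - B.mean(axis=0)
                cols.append(Bc)
                blocks.append((f"s({sm.var})", start, start + B.shape[1], S))
                start += B.shape[1]
        if self.tensor is not None:
            t = self.tensor
            lon = tbl[t.lon_var].to_numpy()
            lat = tbl[t.lat_var].to_numpy()
            def marg(v, vals):
                lo, hi = float(vals.min()), float(vals.max())
                nb = max(int(np.ceil((hi - lo) / t.spacing_deg)) + 3, 4)
                return BSplineBasis1D(lo, hi, n_basis=nb)
            bx, by = marg(t.lon_var, lon), marg(t.lat_var, lat)
            T = tensor_design(bx, by, lon, lat)
            T = T - T.mean(axis=0)
            cols.append(T)
            blocks.append((f"te({t.lon_var},{t.lat_var})", start,
                           start + T.shape[1], tensor_penalty(bx, by)))
            start += T.shape[1]
        self.X = np.hstack(cols)
        self.y = tbl[self.response].to_numpy(dtype=float)
        self.blocks = blocks
        self.param_names = names

    # -- fitting -----------------------------------------------------------
    def _penalty_matrix(self, lambdas) -> np.ndarray:
        p = self.X.shape[1]
        P = np.zeros((p, p))
        for lam, (_, a, b, S) in zip(lambdas, self.blocks):
            P[a:b, a:b] += lam * S
        return P

    def _solve(self, lambdas):
        XtX = self._XtX
        A = XtX + self._penalty_matrix(lambdas)
        try:
            f = cho_factor(A + 1e-10 * np.eye(len(A)))
        except np.linalg.LinAlgError as e:
            raise GAMError(f"rank-deficient design ({e})") from e
        beta = cho_solve(f, self._Xty)
        M = cho_solve(f, XtX)          # influence in coefficient space
        edf = float(np.trace(M))
        rss = float(self._yty - 2 * beta @ self._Xty + beta @ (XtX @ beta))
        rss = max(rss, 1e-12)
        return beta, edf, rss, M

    def fit(self, n_sweeps: int = 2, lambda_grid=LAMBDA_GRID,
            gcv_gamma: float = 1.4) -> "GAMResults":
        """Select smoothing parameters by GCV coordinate descent and fit.

        ``gcv_gamma`` inflates the effective-d.f. cost in the GCV score
        (the usual remedy for GCV's tendency to undersmooth).
        """
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)
        n = len(self.y)
        lambdas = np.ones(len(self.blocks))
        if len(self.blocks):
            for _ in range(n_sweeps):
                for j in range(len(self.blocks)):
                    best, best_gcv = lambdas[j], np.inf
                    for lam in lambda_grid:
                        trial = lambdas.copy()
                        trial[j] = lam
                        _, edf, rss, _ = self._solve(trial)
                        gcv = n * rss / max(n - gcv_gamma * edf, 1.0) ** 2
                        if gcv < best_gcv:
                            best, best_gcv = lam, gcv
                    lambdas[j] = best
        beta, edf, rss, M = self._solve(lambdas)
        edf_by_term = {"parametric": float(np.trace(M[:len(self.param_names),
                                                     :len(self.param_names)]))}
        for (label, a, b, _), lam in zip(self.blocks, lambdas):
            edf_by_term[label] = float(np.trace(M[a:b, a:b]))
        fitted = self.X @ beta
        return GAMResults(self, beta, lambdas, edf, edf_by_term, rss, fitted)


class GAMResults:
    """Fit results: coefficients, effective d.f., AIC, partial effects."""

    def __init__(self, model, params, lambdas, edf, edf_by_term, rss, fitted):
        self.model = model
        self.params = params
        self.lambdas = lambdas
        self.edf = edf
        self.edf_by_term = edf_by_term
        self.rss = rss
        self.fittedvalues = fitted
        self.resid = model.y - fitted
        self.nobs = len(model.y)

    @property
    def sigma2(self) -> float:
        return self.rss / self.nobs

    @property
    def llf(self) -> float:
        n = self.nobs
        return -0.5 * n * (np.log(2 * np.pi * self.sigma2) + 1.0)

    @property
    def aic(self) -> float:
        # effective d.f. + 1 for the residual variance
        return -2.0 * self.llf + 2.0 * (self.edf + 1.0)

    def partial_effect(self, var: str, group: str | None = None,
                       x: np.ndarray | None = None):
        """(x, f(x)) for a smooth term's centered partial effect curve."""
        label = f"s({var}):{group}" if group is not None else f"s({var})"
        for (lab, a, b, _) in self.model.blocks:
            if lab == label:
                sm = next(s for s in self.model.smooths if s.var == var)
                basis = self.model._basis_for(var, sm.k)
                if x is None:
                    x = np.linspace(basis.lo, basis.hi, 200)
                B = basis.design(x)
                B = B - B.mean(axis=0)
                return x, B @ self.params[a:b]
        raise GAMError(f"no term {label!r} in model")

    def summary(self) -> str:
        lines = [f"Habitat-selection GAM  (n={self.nobs})",
                 f"  RSS {self.rss:.4g}   sigma^2 {self.sigma2:.4g}",
                 f"  edf {self.edf:.2f}   AIC {self.aic:.2f}",
                 "  term                                edf      lambda"]
        lams = {lab: lam for (lab, *_), lam in zip(self.model.blocks, self.lambdas)}
        for lab, e in self.edf_by_term.items():
            lam = lams.get(lab)
            lines.append(f"  {lab:<34s} {e:7.2f}  "
                         + (f"{lam:9.3g}" if lam is not None else ""))
        return "\n".join(lines)

    def residual_variogram(self, max_lag_km: float = 2000.0, n_bins: int = 20,
                           max_pairs: int = 200_000, seed: int = 0,
                           min_pairs: int = 30) -> pd.DataFrame:
        """Empirical semivariance of residuals by great-circle lag bin.

        gamma(h) = 0.5 * mean[(r_a - r_b)^2] over point pairs in the bin.
        Pairs are subsampled for large tables.  Bins with fewer than
        ``min_pairs`` pairs are flagged.
        """
        lon = self.model.table["lon"].to_numpy()
        lat = self.model.table["lat"].to_numpy()
        r = self.resid
        n = len(r)
        rng = np.random.default_rng(seed)
        ia = rng.integers(0, n, max_pairs)
        ib = rng.integers(0, n, max_pairs)
        keep = ia != ib
        ia, ib = ia[keep], ib[keep]
        h = haversine_km(lon[ia], lat[ia], lon[ib], lat[ib])
        sel = h <= max_lag_km
        h, dv = h[sel], 0.5 * (r[ia[sel]] - r[ib[sel]]) ** 2
        edges = np.linspace(0, max_lag_km, n_bins + 1)
        which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
        gamma = np.full(n_bins, np.nan)
        counts = np.bincount(which, minlength=n_bins)
        sums = np.bincount(which, weights=dv, minlength=n_bins)
        ok = counts > 0
        gamma[ok] = sums[ok] / counts[ok]
        return pd.DataFrame({"lag_km": 0.5 * (edges[:-1] + edges[1:]),
                             "gamma": gamma, "n_pairs": counts,
                             "flagged": counts < min_pairs})

    def refit_with_tensor(self, spacing_deg: float = 4.0) -> "GAMResults":
        """Refit adding a lon/lat tensor smooth with the given basis spacing."""
        m = HabitatSelectionGAM(self.model.table, self.model.response,
                                self.model.smooths, self.model.group_col,
                                TensorSmooth(spacing_deg=spacing_deg),
                                basis_cache=self.model._bases)
        return m.fit()

    def plot_partial(self, var: str, ax=None):  # pragma: no cover - thin wrapper
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for g in self.model.groups:
            try:
                x, f = self.partial_effect(var, g)
                ax.plot(x, f, label=str(g))
            except GAMError:
                x, f = self.partial_effect(var)
                ax.plot(x, f, label="shared")
                break
        ax.set_xlabel(var)
        ax.set_ylabel(f"partial effect on {self.model.response}")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# model selection

def select_model(table: pd.DataFrame, smooths, response: str = "log_density",
                 group_col: str = "population", tensor: TensorSmooth | None = None,
                 second_stage: bool = True) -> pd.DataFrame:
    """Backward AIC selection from the global model.

    Stage 1 removes each population x s(term) interaction in turn
    (replacing it with one shared smooth); stage 2, for removals that beat
    the global model, drops the variable altogether.  Returns a table of
    (model, df, AIC, dAIC) sorted by AIC; the best model has dAIC = 0.
    Individual fit failures are recorded with NaN AIC, not fatal.
    """
    smooths = [replace(s, by_group=True) for s in smooths]
    cache: dict = {}

    def try_fit(name, terms, stage):
        try:
            res = HabitatSelectionGAM(table, response, terms, group_col,
                                      tensor, basis_cache=cache).fit()
            return {"model": name, "df": res.edf, "AIC": res.aic,
                    "stage": stage, "_res": res}
        except GAMError as e:
            return {"model": name, "df": np.nan, "AIC": np.nan,
                    "stage": stage, "error": str(e), "_res": None}

    rows = [try_fit("Global", smooths, 0)]
    global_aic = rows[0]["AIC"]
    for i, sm in enumerate(smooths):
        terms = smooths[:i] + [replace(sm, by_group=False)] + smooths[i + 1:]
        rows.append(try_fit(f"Population x s({sm.var})", terms, 1))
    if second_stage and np.isfinite(global_aic):
        for i, sm in enumerate(smooths):
            r1 = rows[1 + i]
            if np.isfinite(r1["AIC"]) and r1["AIC"] < global_aic:
                terms = smooths[:i] + smooths[i + 1:]
                rows.append(try_fit(f"drop s({sm.var})", terms, 2))
    out = pd.DataFrame([{k: v for k, v in r.items() if k != "_res"}
                        for r in rows])
    best = np.nanmin(out["AIC"].to_numpy())
    out["dAIC"] = out["AIC"] - best
    return out.sort_values("AIC", na_position="last").reset_index(drop=True)


def selection_tables(table, smooths, response="log_density",
                     group_col="population", tensor_spacing_deg: float = 4.0,
                     second_stage: bool = True):
    """The paired selection ladders, without and with the spatial tensor smooth."""
    without = select_model(table, smooths, response, group_col, None, second_stage)
    with_t = select_model(table, smooths, response, group_col,
                          TensorSmooth(spacing_deg=tensor_spacing_deg), second_stage)
    without.insert(0, "tensor", False)
    with_t.insert(0, "tensor", True)
    return pd.concat([with_t, without], ignore_index=True)
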