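"""Bivariate animal model: REML variance components, BLUP breeding values.

The model is ``y = X b + Z a + e`` with trait-by-site cell means as fixed
effects, one additive genetic effect per pedigree member with covariance
``G0 (x) A`` (Kronecker product, individuals within trait), and residuals
``R0 (x) I`` restricted to the observed trait rows of each individual.

Two restricted-likelihood evaluation paths share one criterion:

* a fast path for complete-case data (every phenotyped individual has all
  traits) that diagonalizes the observed block of A once, after which each
  likelihood evaluation costs O(n) — this is what makes replicate recovery
  studies cheap; and
* a general dense path that supports arbitrary per-trait missingness.

The REML criterion includes a ``-log|X'X|`` term so that its value is
invariant to the choice of fixed-effect basis.  G0 and R0 are optimized
under a log-Cholesky parameterization, which keeps every iterate positive
(semi-)definite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.sparse as sp
from scipy.stats import norm

from .pedigree import Pedigree, RelationshipMatrix

_LOG2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class ModelSpec:
    """Which phenotype columns are traits and which identify record structure."""

    traits: tuple
    id_col: str = "individual"
    site_col: str = "site"

    def __post_init__(self):
        if not 1 <= len(self.traits) <= 2:
            raise ModelError("ModelSpec supports 1 or 2 traits")


@dataclass
class Design:
    """Assembled observation structure for one model fit.

    Observation rows are ordered trait-major (all trait-1 rows, then trait-2),
    and within a trait by pedigree order of the observed individuals.
    """

    spec: ModelSpec
    sites: tuple
    obs_ids: tuple  # individuals with >= 1 record, pedigree-ordered
    site_of_ind: np.ndarray  # site index per obs individual
    trait_ind: list  # per trait: indices into obs_ids of rows present
    trait_y: list  # per trait: observed response vector
    complete: bool

    @property
    def n_obs_rows(self) -> int:
        return sum(len(y) for y in self.trait_y)

    @property
    def n_traits(self) -> int:
        return len(self.spec.traits)

    @property
    def n_fixed(self) -> int:
        return self.n_traits * len(self.sites)

    def fixed_labels(self) -> list:
        return [f"{t}:{s}" for t in self.spec.traits for s in self.sites]

    def x_rows(self) -> tuple:
        """Dense X and the (trait, individual) index of every observation row."""
        p = self.n_fixed
        S = len(self.sites)
        rows = []
        which = []
        for t, (ind, y) in enumerate(zip(self.trait_ind, self.trait_y)):
            for i in ind:
                r = np.zeros(p)
                r[t * S + self.site_of_ind[i]] = 1.0
                rows.append(r)
            which.extend((t, i) for i in ind)
        return np.array(rows), which

    def y_stacked(self) -> np.ndarray:
        return np.concatenate(self.trait_y)


def build_design(spec: ModelSpec, phenotypes: pd.DataFrame, pedigree_ids: Sequence) -> Design:
    """Validate phenotypes against the pedigree and assemble the design.

    Traits with no records at all are dropped (the bivariate code then reduces
    to a univariate fit); an empty trait-by-site cell for a retained trait is
    an error, as is a phenotyped individual missing from the pedigree.
    """
    for col in (spec.id_col, spec.site_col):
        if col not in phenotypes.columns:
            raise ModelError(f"phenotype table lacks column {col!r}")
    if phenotypes[spec.id_col].duplicated().any():
        raise ModelError("phenotype table must have one row per individual")

    ped_index = {v: i for i, v in enumerate(pedigree_ids)}
    missing = [i for i in phenotypes[spec.id_col] if i not in ped_index]
    if missing:
        raise ModelError(f"individuals absent from pedigree: {missing[:5]}")

    traits = [t for t in spec.traits if phenotypes[t].notna().any()]
    if not traits:
        raise ModelError("no trait has any records")
    spec = ModelSpec(tuple(traits), spec.id_col, spec.site_col)

    observed = phenotypes[phenotypes[list(traits)].notna().any(axis=1)].copy()
    observed = observed.sort_values(
        spec.id_col, key=lambda s: s.map(ped_index), kind="stable"
    ).reset_index(drop=True)
    obs_ids = tuple(observed[spec.id_col])
    sites = tuple(sorted(observed[spec.site_col].unique()))
    site_index = {s: i for i, s in enumerate(sites)}
    site_of_ind = observed[spec.site_col].map(site_index).to_numpy()

    trait_ind, trait_y = [], []
    for t in traits:
        mask = observed[t].notna().to_numpy()
        cells = set(zip(itertools.repeat(t), observed.loc[mask, spec.site_col]))
        empty = [s for s in sites if (t, s) not in cells]
        if empty:
            raise ModelError(f"no {t} records at site(s) {empty}")
        trait_ind.append(np.flatnonzero(mask))
        trait_y.append(observed.loc[mask, t].to_numpy(dtype=float))

    complete = all(len(ind) == len(obs_ids) for ind in trait_ind)
    return Design(spec, sites, obs_ids, site_of_ind, trait_ind, trait_y, complete)


# ---------------------------------------------------------------------------
# variance components


_COMPONENT_NAMES = {
    1: ("sigma2_a1", "sigma2_e1"),
    2: ("sigma2_a1", "sigma_a12", "sigma2_a2", "sigma2_e1", "sigma_e12", "sigma2_e2"),
}


def _tri_to_mat(v: np.ndarray, t: int) -> np.ndarray:
    if t == 1:
        return np.array([[v[0]]])
    return np.array([[v[0], v[1]], [v[1], v[2]]])


def _mat_to_tri(m: np.ndarray) -> np.ndarray:
    if m.shape == (1, 1):
        return np.array([m[0, 0]])
    return np.array([m[0, 0], m[0, 1], m[1, 1]])


@dataclass
class VarianceComponents:
    """REML estimates of the trait-level covariance matrices."""

    traits: tuple
    G0: np.ndarray
    R0: np.ndarray
    loglik: float
    converged: bool
    n_evals: int
    vcov: Optional[np.ndarray] = None  # asymptotic covariance of the components
    trace: list = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def component_names(self) -> tuple:
        return _COMPONENT_NAMES[self.n_traits]

    def components(self) -> np.ndarray:
        return np.concatenate([_mat_to_tri(self.G0), _mat_to_tri(self.R0)])


def _theta_to_cov(theta: np.ndarray, t: int) -> tuple:
    """Log-Cholesky: diag entries exponentiated, off-diagonal free."""
    k = 1 if t == 1 else 3
    def build(v):
        if t == 1:
            L = np.array([[np.exp(v[0])]])
        else:
            L = np.array([[np.exp(v[0]), 0.0], [v[1], np.exp(v[2])]])
        return L @ L.T
    return build(theta[:k]), build(theta[k:])


def _cov_to_theta(G0: np.ndarray, R0: np.ndarray) -> np.ndarray:
    def unbuild(m):
        L = np.linalg.cholesky(m + 1e-8 * np.eye(m.shape[0]))
        if m.shape[0] == 1:
            return np.array([np.log(L[0, 0])])
        return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
    return np.concatenate([unbuild(G0), unbuild(R0)])


class REMLProblem:
    """A reusable restricted-likelihood evaluator for one design + A matrix.

    The expensive pieces (the observed block of A and, on the complete-case
    path, its eigendecomposition and the rotated design) are computed once in
    the constructor; :meth:`with_response` swaps in a new response vector
    without redoing them, which makes parametric-bootstrap refits cheap.
    """

    def __init__(self, design: Design, A: RelationshipMatrix | np.ndarray):
        self.design = design
        if isinstance(A, RelationshipMatrix):
            A_oo = A.submatrix(design.obs_ids)
        else:
            A_oo = np.asarray(A, dtype=float)
            if A_oo.shape != (len(design.obs_ids),) * 2:
                raise ModelError("A block does not match observed individuals")
        self.A_oo = A_oo
        self.t = design.n_traits
        if np.allclose(A_oo, np.eye(len(design.obs_ids)), atol=1e-10):
            warnings.warn(
                "relationship matrix block is the identity: additive and "
                "residual variances are not separable without replication",
                UserWarning,
            )
        self._setup()

    # -- setup -------------------------------------------------------------
    def _setup(self) -> None:
        d = self.design
        n_o = len(d.obs_ids)
        S = len(d.sites)
        if d.complete:
            evals, U = np.linalg.eigh(self.A_oo)
            self._d = np.clip(evals, 0.0, None)
            self._U = U
            X_site = np.zeros((n_o, S))
            X_site[np.arange(n_o), d.site_of_ind] = 1.0
            self._Xt = U.T @ X_site
            self._yt = [U.T @ y for y in d.trait_y]
            # basis-invariance constant: log|X'X| for the block-diagonal X
            counts = X_site.sum(axis=0)
            self._logdet_xtx = self.t * float(np.sum(np.log(counts)))
        else:
            X, which = d.x_rows()
            self._X = X
            sel = [t * n_o + i for t, i in which]
            self._sel = np.asarray(sel)
            self._y = d.y_stacked()
            sign, logdet = np.linalg.slogdet(X.T @ X)
            if sign <= 0:
                raise ModelError("fixed-effect design is rank deficient")
            self._logdet_xtx = float(logdet)

    def with_response(self, trait_y: Sequence[np.ndarray]) -> "REMLProblem":
        new = object.__new__(REMLProblem)
        new.__dict__.update(self.__dict__)
        d = self.design
        new.design = Design(
            d.spec, d.sites, d.obs_ids, d.site_of_ind, d.trait_ind,
            [np.asarray(y, dtype=float) for y in trait_y], d.complete,
        )
        if d.complete:
            new._yt = [self._U.T @ np.asarray(y, float) for y in trait_y]
        else:
            new._y = new.design.y_stacked()
        return new

    # -- likelihood --------------------------------------------------------
    def loglik(self, G0: np.ndarray, R0: np.ndarray) -> float:
        if self.design.complete:
            return self._loglik_eigen(G0, R0)
        return self._loglik_dense(G0, R0)

    def _loglik_eigen(self, G0, R0) -> float:
        d_ = self._d
        Xt, yt = self._Xt, self._yt
        n_o, S = Xt.shape
        if self.t == 1:
            v = G0[0, 0] * d_ + R0[0, 0]
            if np.any(v <= 0):
                return -np.inf
            w = 1.0 / v
            logdetV = float(np.sum(np.log(v)))
            XtViX = Xt.T @ (w[:, None] * Xt)
            XtViy = Xt.T @ (w * yt[0])
            ytViy = float(w @ (yt[0] ** 2))
            m, p = n_o, S
        else:
            m11 = G0[0, 0] * d_ + R0[0, 0]
            m12 = G0[0, 1] * d_ + R0[0, 1]
            m22 = G0[1, 1] * d_ + R0[1, 1]
            det = m11 * m22 - m12 * m12
            if np.any(det <= 0) or np.any(m11 <= 0):
                return -np.inf
            logdetV = float(np.sum(np.log(det)))
            w11, w22, w12 = m22 / det, m11 / det, -m12 / det
            B11 = Xt.T @ (w11[:, None] * Xt)
            B22 = Xt.T @ (w22[:, None] * Xt)
            B12 = Xt.T @ (w12[:, None] * Xt)
            XtViX = np.block([[B11, B12], [B12.T, B22]])
            y1, y2 = yt
            XtViy = np.concatenate(
                [Xt.T @ (w11 * y1 + w12 * y2), Xt.T @ (w12 * y1 + w22 * y2)]
            )
            ytViy = float(w11 @ (y1**2) + 2.0 * (w12 @ (y1 * y2)) + w22 @ (y2**2))
            m, p = 2 * n_o, 2 * S
        return self._assemble(XtViX, XtViy, ytViy, logdetV, m, p)

    def _loglik_dense(self, G0, R0) -> float:
        n_o = len(self.design.obs_ids)
        big = np.kron(G0, self.A_oo) + np.kron(R0, np.eye(n_o))
        V = big[np.ix_(self._sel, self._sel)]
        try:
            cf = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ViX = sla.cho_solve(cf, self._X)
        Viy = sla.cho_solve(cf, self._y)
        XtViX = self._X.T @ ViX
        XtViy = self._X.T @ Viy
        ytViy = float(self._y @ Viy)
        m, p = len(self._y), self._X.shape[1]
        return self._assemble(XtViX, XtViy, ytViy, logdetV, m, p)

    def _assemble(self, XtViX, XtViy, ytViy, logdetV, m, p) -> float:
        try:
            cf = sla.cho_factor(XtViX, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        b = sla.cho_solve(cf, XtViy)
        quad = ytViy - float(b @ XtViy)
        return -0.5 * (
            logdetV + logdetC - self._logdet_xtx + quad + (m - p) * _LOG2PI
        )

    def loglik_components(self, phi: np.ndarray) -> float:
        k = 1 if self.t == 1 else 3
        return self.loglik(_tri_to_mat(phi[:k], self.t), _tri_to_mat(phi[k:], self.t))

    # -- optimization ------------------------------------------------------
    def _start(self) -> tuple:
        d = self.design
        t = self.t
        resid = []
        for ti in range(t):
            y = d.trait_y[ti]
            site = d.site_of_ind[d.trait_ind[ti]]
            means = np.array([y[site == s].mean() for s in range(len(d.sites))])
            resid.append(y - means[site])
        var = [max(float(np.var(r)), 1e-6) for r in resid]
        G0 = np.diag([0.4 * v for v in var])
        R0 = np.diag([0.6 * v for v in var])
        return G0, R0

    def fit(
        self,
        init: Optional[tuple] = None,
        max_iter: int = 500,
        ftol: float = 1e-10,
        gtol: float = 1e-5,
        compute_vcov: bool = True,
    ) -> VarianceComponents:
        if init is not None:
            starts = [init]
        else:
            G0_s, R0_s = self._start()
            # fallback start with a different additive/residual split
            starts = [(G0_s, R0_s), (0.25 * (G0_s + R0_s), 0.75 * (G0_s + R0_s))]
        trace: list = []

        def nll(theta):
            G0, R0 = _theta_to_cov(theta, self.t)
            ll = self.loglik(G0, R0)
            trace.append(float(ll))
            return 1e12 if not np.isfinite(ll) else -ll

        res = None
        for G0_init, R0_init in starts:
            theta0 = _cov_to_theta(np.asarray(G0_init, float), np.asarray(R0_init, float))
            res = opt.minimize(
                nll, theta0, method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol},
            )
            if bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4:
                break
        G0, R0 = _theta_to_cov(res.x, self.t)
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
        if not converged:
            raise ConvergenceError(
                f"REML did not converge after {res.nfev} evaluations: {res.message}",
                trace,
            )
        vcov = self._component_vcov(G0, R0) if compute_vcov else None
        return VarianceComponents(
            self.design.spec.traits, G0, R0, float(-res.fun),
            converged, int(res.nfev), vcov, trace,
        )

    def _component_vcov(self, G0, R0) -> np.ndarray:
        """Inverse observed information of the (co)variance components."""
        phi = np.concatenate([_mat_to_tri(G0), _mat_to_tri(R0)])
        k = len(phi)
        h = 1e-4 * (np.abs(phi) + 1e-3)
        H = np.zeros((k, k))
        f0 = self.loglik_components(phi)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = self.loglik_components(phi + ei + ej)
                fpm = self.loglik_components(phi + ei - ej)
                fmp = self.loglik_components(phi - ei + ej)
                fmm = self.loglik_components(phi - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        info = -H
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn("singular REML information matrix; using pseudo-inverse")
            return np.linalg.pinv(info)


def reml_fit(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    A: RelationshipMatrix,
    init: Optional[tuple] = None,
    compute_vcov: bool = True,
) -> VarianceComponents:
    """Fit variance components by REML (see :class:`REMLProblem`)."""
    design = build_design(spec, phenotypes, A.ids)
    return REMLProblem(design, A).fit(init=init, compute_vcov=compute_vcov)


# ---------------------------------------------------------------------------
# mixed-model equations


@dataclass
class MMEResult:
    """Solution of Henderson's mixed-model equations at fixed components."""

    design: Design
    fixed: pd.Series  # indexed by "trait:site"
    fixed_cov: pd.DataFrame
    breeding_values: pd.DataFrame  # individual + bv_<trait> (+ se_<trait>)
    G0: np.ndarray
    R0: np.ndarray

    def site_effects(self, trait) -> pd.Series:
        labels = [f"{trait}:{s}" for s in self.design.sites]
        eff = self.fixed[labels]
        eff.index = list(self.design.sites)
        return eff


def solve_mme(
    design: Design,
    pedigree: Pedigree,
    A: RelationshipMatrix,
    vc: VarianceComponents,
    compute_pev: bool = True,
) -> MMEResult:
    """Solve the MME for fixed effects and breeding values of all pedigree members.

    Uses a dense inverse of A (adequate at desk scale) and per-individual
    residual weights obtained by inverting the observed submatrix of R0.
    """
    t = design.n_traits
    S = len(design.sites)
    n_ped = len(pedigree)
    p = t * S
    ped_index = {v: i for i, v in enumerate(pedigree.ids)}
    obs_ped = np.array([ped_index[i] for i in design.obs_ids])
    n_o = len(design.obs_ids)

    # observation rows, trait-major; columns of Z are trait-major over pedigree
    rows_x, rows_z, ys = [], [], []
    row_of = {}  # (trait, obs individual index) -> row number
    for ti in range(t):
        for i, y in zip(design.trait_ind[ti], design.trait_y[ti]):
            row_of[(ti, i)] = len(ys)
            rows_x.append(ti * S + design.site_of_ind[i])
            rows_z.append(ti * n_ped + obs_ped[i])
            ys.append(y)
    m = len(ys)
    y = np.array(ys)
    X = sp.csr_matrix((np.ones(m), (np.arange(m), rows_x)), shape=(m, p))
    Z = sp.csr_matrix((np.ones(m), (np.arange(m), rows_z)), shape=(m, t * n_ped))

    # residual weight matrix W = R^{-1}, block per individual over observed traits
    wi, wj, wv = [], [], []
    for i in range(n_o):
        present = [ti for ti in range(t) if (ti, i) in row_of]
        Rsub = vc.R0[np.ix_(present, present)]
        Winv = np.linalg.inv(Rsub)
        for a_, ta in enumerate(present):
            for b_, tb in enumerate(present):
                wi.append(row_of[(ta, i)])
                wj.append(row_of[(tb, i)])
                wv.append(Winv[a_, b_])
    W = sp.csr_matrix((wv, (wi, wj)), shape=(m, m))

    Ainv = np.linalg.inv(A.values)
    G0inv = np.linalg.inv(vc.G0 + 1e-10 * np.eye(t))
    Ginv = np.kron(G0inv, Ainv)

    XtW = (X.T @ W).tocsr()
    ZtW = (Z.T @ W).tocsr()
    C = np.zeros((p + t * n_ped, p + t * n_ped))
    C[:p, :p] = (XtW @ X).toarray()
    C[:p, p:] = (XtW @ Z).toarray()
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = (ZtW @ Z).toarray() + Ginv
    rhs = np.concatenate([XtW @ y, ZtW @ y])

    try:
        cf = sla.cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ModelError(
            "singular mixed-model equations (confounded fixed effects?)"
        ) from exc
    sol = sla.cho_solve(cf, rhs)
    b, a = sol[:p], sol[p:]

    eye_p = np.zeros((p + t * n_ped, p))
    eye_p[:p, :p] = np.eye(p)
    Cinv_p = sla.cho_solve(cf, eye_p)
    b_cov = Cinv_p[:p, :p]

    labels = design.fixed_labels()
    bv = {"individual": list(pedigree.ids)}
    for ti, trait in enumerate(design.spec.traits):
        bv[f"bv_{trait}"] = a[ti * n_ped:(ti + 1) * n_ped]
    if compute_pev:
        Cinv = sla.cho_solve(cf, np.eye(p + t * n_ped))
        pev = np.diag(Cinv)[p:]
        for ti, trait in enumerate(design.spec.traits):
            bv[f"se_{trait}"] = np.sqrt(
                np.clip(pev[ti * n_ped:(ti + 1) * n_ped], 0.0, None)
            )
    return MMEResult(
        design,
        pd.Series(b, index=labels),
        pd.DataFrame(b_cov, index=labels, columns=labels),
        pd.DataFrame(bv),
        vc.G0,
        vc.R0,
    )


# ---------------------------------------------------------------------------
# summaries


def heritability(vc: VarianceComponents, trait) -> tuple:
    """Narrow-sense h2 = s2_a / (s2_a + s2_e) with a delta-method SE."""
    ti = vc.traits.index(trait)
    names = vc.component_names
    ia = names.index(f"sigma2_a{ti + 1}")
    ie = names.index(f"sigma2_e{ti + 1}")
    va, ve = vc.G0[ti, ti], vc.R0[ti, ti]
    tot = va + ve
    if tot <= 0:
        raise ModelError("zero phenotypic variance")
    h2 = va / tot
    se = float("nan")
    if vc.vcov is not None:
        g = np.zeros(len(names))
        g[ia] = ve / tot**2
        g[ie] = -va / tot**2
        se = float(np.sqrt(max(g @ vc.vcov @ g, 0.0)))
    return float(h2), se


def genetic_correlation(vc: VarianceComponents) -> tuple:
    """Additive correlation r_a = cov / sqrt(va1 * va2) with a delta-method SE."""
    if vc.n_traits != 2:
        raise ModelError("genetic correlation needs a bivariate fit")
    va1, va2, cov = vc.G0[0, 0], vc.G0[1, 1], vc.G0[0, 1]
    if va1 < 1e-10 or va2 < 1e-10:
        raise ModelError("additive variance at the zero boundary; r_a undefined")
    ra = cov / np.sqrt(va1 * va2)
    se = float("nan")
    if vc.vcov is not None:
        g = np.zeros(len(vc.component_names))
        g[0] = -0.5 * cov / (va1**1.5 * np.sqrt(va2))  # d/d va1
        g[1] = 1.0 / np.sqrt(va1 * va2)  # d/d cov
        g[2] = -0.5 * cov / (va2**1.5 * np.sqrt(va1))  # d/d va2
        se = float(np.sqrt(max(g @ vc.vcov @ g, 0.0)))
    return float(ra), se


def site_contrasts(mme: MMEResult, trait=None, alpha: float = 0.05) -> tuple:
    """All pairwise site-effect differences with Wald z p-values.

    Returns ``(table, fraction_significant)`` where the table has one row per
    unordered site pair.
    """
    trait = mme.design.spec.traits[0] if trait is None else trait
    sites = mme.design.sites
    labels = [f"{trait}:{s}" for s in sites]
    b = mme.fixed[labels].to_numpy()
    V = mme.fixed_cov.loc[labels, labels].to_numpy()
    rows = []
    for i, j in itertools.combinations(range(len(sites)), 2):
        diff = b[i] - b[j]
        var = V[i, i] + V[j, j] - 2 * V[i, j]
        se = np.sqrt(max(var, 0.0))
        z = diff / se if se > 0 else 0.0
        pval = 2 * norm.sf(abs(z)) if se > 0 else 1.0
        rows.append((sites[i], sites[j], diff, se, z, pval))
    table = pd.DataFrame(
        rows, columns=["site_i", "site_j", "difference", "se", "z", "p_value"]
    )
    frac = float((table["p_value"] < alpha).mean())
    return table, frac


def gxe_diagnostic(
    phenotypes: pd.DataFrame, pedigree: Pedigree, trait: str = "mai"
) -> dict:
    """Optional genotype-by-environment check (off by default in the pipeline).

    Univariate REML comparison of a maternal-family model with vs without a
    family-by-site interaction variance, on site cell means as fixed effects.
    Returns the likelihood-ratio statistic and a chi-square(1) p-value, which
    is conservative for a variance tested at its boundary.  This is a rough
    screen, not a substitute for the animal model.
    """
    dam_of = {ind: d for ind, _, d in pedigree.records}
    df = phenotypes.dropna(subset=[trait]).copy()
    df["family"] = df["individual"].map(dam_of)
    df = df.dropna(subset=["family"])
    y = df[trait].to_numpy(dtype=float)
    site_idx, _ = pd.factorize(df["site"])
    fam_idx, _ = pd.factorize(df["family"])
    _, cell_idx = np.unique(
        site_idx * (fam_idx.max() + 1) + fam_idx, return_inverse=True
    )
    m = len(y)
    X = np.zeros((m, site_idx.max() + 1))
    X[np.arange(m), site_idx] = 1.0
    Zf = np.zeros((m, fam_idx.max() + 1))
    Zf[np.arange(m), fam_idx] = 1.0
    Zc = np.zeros((m, cell_idx.max() + 1))
    Zc[np.arange(m), cell_idx] = 1.0
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    def remlik(V):
        cf = sla.cho_factor(V, lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ViX = sla.cho_solve(cf, X)
        Viy = sla.cho_solve(cf, y)
        XtViX = X.T @ ViX
        b = np.linalg.solve(XtViX, X.T @ Viy)
        quad = float(y @ Viy) - float(b @ (X.T @ Viy))
        _, logdetC = np.linalg.slogdet(XtViX)
        p = X.shape[1]
        return -0.5 * (logdetV + logdetC - logdet_xtx + quad + (m - p) * _LOG2PI)

    ZfZf = Zf @ Zf.T
    ZcZc = Zc @ Zc.T
    eye = np.eye(m)
    v0 = float(np.var(y))

    def fit(with_gxe: bool) -> float:
        def nll(logv):
            V = np.exp(logv[0]) * ZfZf + np.exp(logv[-1]) * eye
            if with_gxe:
                V = V + np.exp(logv[1]) * ZcZc
            return -remlik(V)

        x0 = np.log([0.2 * v0, 0.1 * v0, 0.7 * v0]) if with_gxe else np.log(
            [0.25 * v0, 0.75 * v0]
        )
        res = opt.minimize(nll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        return -float(res.fun)

    ll_red = fit(False)
    ll_full = fit(True)
    lrt = max(0.0, 2.0 * (ll_full - ll_red))
    from scipy.stats import chi2

    return {"lrt": lrt, "df": 1, "p_value": float(chi2.sf(lrt, 1)),
            "loglik_full": ll_full, "loglik_reduced": ll_red}


@dataclass
class ModelFit:
    """Bundle of everything downstream stages need from one model fit."""

    spec: ModelSpec
    vc: VarianceComponents
    mme: MMEResult
    h2: dict  # trait -> (estimate, se)
    r_a: Optional[tuple]


def fit_animal_model(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    A: RelationshipMatrix,
    traits: Sequence = ("mai", "density"),
    compute_pev: bool = True,
) -> ModelFit:
    """REML + MME + summary statistics in one call."""
    spec = ModelSpec(tuple(traits))
    design = build_design(spec, phenotypes, pedigree.ids)
    problem = REMLProblem(design, A)
    vc = problem.fit()
    mme = solve_mme(design, pedigree, A, vc, compute_pev=compute_pev)
    h2 = {t: heritability(vc, t) for t in vc.traits}
    ra = genetic_correlation(vc) if vc.n_traits == 2 else None
    return ModelFit(design.spec, vc, mme, h2, ra)
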