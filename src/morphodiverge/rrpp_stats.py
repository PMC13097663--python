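"""Permutational linear models via randomized residual permutation (RRPP).

Multivariate responses (shape coordinates, standardized trait matrices) are
modelled with ordinary least squares over an ordered sequence of terms.
Sums of squares are sequential (type I): each term is evaluated against the
null model of all preceding terms.  Significance comes from permutation:
residuals of the reduced (null) model are randomly permuted and added back
to its fitted values, and the term statistic is recomputed; the observed
arrangement counts as one permutation, so the smallest attainable p-value is
1/(iterations + 1).

Effect sizes Z are standard deviates of the observed statistic within its
permutation distribution, computed on log-transformed values for F-type
statistics and raw values for distances.

Factor terms are encoded as one-hot blocks with aliased columns dropped by
incremental rank checks, which handles interactions and nesting (e.g.
``region:island`` for islands nested in regions) uniformly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ModelSpec",
    "RRPPModelFit",
    "PairwiseResult",
    "fit_rrpp",
    "anova_table",
    "pairwise_groups",
    "effect_size",
    "format_p",
]

_RANK_TOL = 1e-8


@dataclass
class ModelSpec:
    """An ordered model formula: term names resolved against a predictor table.

    ``terms`` entries are column names ("logCS", "sex") or colon-joined
    interactions ("sex:species", "region:island").  Numeric columns are
    covariates; all other columns are treated as factors.  Term order is
    meaningful: sequential SS depend on it.
    """

    terms: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.terms = list(self.terms)
        for term in self.terms:
            for part in term.split(":"):
                if part not in self.data.columns:
                    raise ValidationError(f"term {term!r}: no column {part!r} in data")


class _Encoder:
    """Builds the sequential full-rank design and keeps enough structure to
    encode new (prediction) data identically."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        df = spec.data
        self.numeric = {
            c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
        }
        self.levels = {
            c: sorted(df[c].astype(str).unique())
            for c in df.columns
            if c not in self.numeric
        }
        n = len(df)
        # incremental QR: Q holds an orthonormal basis of the design so far
        self.Q = np.ones((n, 1)) / np.sqrt(n)  # intercept
        self.term_kept: dict[str, list[tuple[tuple[str, str | None], ...]]] = {}
        self.term_q: dict[str, np.ndarray] = {}  # per-term new orthonormal columns
        self.X_cols: list[np.ndarray] = [np.ones(n)]
        self.q_before: dict[str, int] = {}
        for term in spec.terms:
            self.q_before[term] = self.Q.shape[1]
            specs, cols = self._candidates(term, df)
            kept, qnew = [], []
            for colspec, col in zip(specs, cols):
                r = col - self.Q @ (self.Q.T @ col)
                if qnew:
                    B = np.column_stack(qnew)
                    r = r - B @ (B.T @ r)
                norm = np.linalg.norm(r)
                if norm > _RANK_TOL * max(np.linalg.norm(col), 1.0):
                    qnew.append(r / norm)
                    kept.append(colspec)
                    self.X_cols.append(col)
            if not kept:
                raise ValidationError(
                    f"term {term!r} is fully aliased with preceding terms "
                    "(rank-deficient design)"
                )
            self.term_kept[term] = kept
            self.term_q[term] = np.column_stack(qnew)
            self.Q = np.hstack([self.Q, self.term_q[term]])
        self.X = np.column_stack(self.X_cols)
        self.rank = self.Q.shape[1]

    def _part_columns(
        self, part: str, df: pd.DataFrame
    ) -> list[tuple[tuple[str, str | None], np.ndarray]]:
        if part in self.numeric:
            return [((part, None), df[part].to_numpy(dtype=float))]
        vals = df[part].astype(str).to_numpy()
        return [
            ((part, lev), (vals == lev).astype(float)) for lev in self.levels[part]
        ]

    def _candidates(self, term: str, df: pd.DataFrame):
        parts = term.split(":")
        pieces = [self._part_columns(p, df) for p in parts]
        specs, cols = [], []
        for combo in itertools.product(*pieces):
            spec = tuple(s for s, _ in combo)
            col = np.ones(len(df))
            for _, c in combo:
                col = col * c
            if np.any(col != 0):
                specs.append(spec)
                cols.append(col)
        return specs, cols

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        """Encode new data into the kept design columns (incl. intercept)."""
        cols = [np.ones(len(df))]
        for term in self.spec.terms:
            for colspec in self.term_kept[term]:
                col = np.ones(len(df))
                for var, level in colspec:
                    if level is None:
                        col = col * df[var].to_numpy(dtype=float)
                    else:
                        col = col * (df[var].astype(str).to_numpy() == level)
                cols.append(col)
        return np.column_stack(cols)


@dataclass
class RRPPModelFit:
    """Sequential permutation ANOVA fit for a (possibly multivariate) response."""

    table: pd.DataFrame  # per-term df, SS, MS, Rsq, F, Z, p
    ss_residual: float
    ss_total: float
    df_residual: int
    n_permutations: int
    seed: int
    permutation_distributions: dict[str, np.ndarray]  # per-term F over permutations
    spec: ModelSpec = field(repr=False)
    Y: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    encoder: _Encoder = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def terms(self) -> list[str]:
        return list(self.table.index)


def _permutation_matrix(rng: np.random.Generator, n: int, iter: int) -> np.ndarray:
    perms = np.empty((iter + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for i in range(1, iter + 1):
        perms[i] = rng.permutation(n)
    return perms


def fit_rrpp(
    Y: np.ndarray,
    spec: ModelSpec,
    iter: int = 999,
    seed: int = 1,
    permutations: np.ndarray | None = None,
) -> RRPPModelFit:
    """Fit an ordered linear model to Y with RRPP significance tests.

    ``Y`` is n x p (a 1-D vector is treated as n x 1).  For each term the
    reduced model holds all preceding terms; permutations shuffle
    reduced-model residual rows (one shared permutation schedule across
    terms) and the F statistic is recomputed on the permuted response.

    ``permutations`` overrides the random schedule with an explicit index
    matrix whose first row must be the identity (e.g. the full enumeration
    of row permutations on tiny samples); ``iter`` is then ignored.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if iter < 1:
        raise ValidationError("iter must be >= 1")
    n = Y.shape[0]
    if len(spec.data) != n:
        raise ValidationError(f"response has {n} rows but data has {len(spec.data)}")
    enc = _Encoder(spec)
    if n <= enc.rank:
        raise ValidationError(
            f"n={n} must exceed total model df={enc.rank} (incl. intercept)"
        )
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    Qfull = enc.Q
    resid_full = Y - Qfull @ (Qfull.T @ Y)
    ss_res = float((resid_full**2).sum())
    df_res = n - enc.rank

    if permutations is not None:
        perms = np.asarray(permutations, dtype=np.intp)
        if perms.ndim != 2 or perms.shape[1] != n:
            raise ValidationError(f"permutations must be m x {n}")
        if not np.array_equal(perms[0], np.arange(n)):
            raise ValidationError("first permutation row must be the identity")
        iter = perms.shape[0] - 1
    else:
        rng = np.random.default_rng(seed)
        perms = _permutation_matrix(rng, n, iter)

    rows = []
    dists: dict[str, np.ndarray] = {}
    for term in spec.terms:
        qb = enc.q_before[term]
        Qred = Qfull[:, :qb]
        Qnew = enc.term_q[term]
        df_t = Qnew.shape[1]
        fitted_red = Qred @ (Qred.T @ Y)
        E = Y - fitted_red  # reduced-model residuals
        f_perm = np.empty(iter + 1)
        chunk = max(1, int(2e7 / max(E.size, 1)))
        for start in range(0, iter + 1, chunk):
            pk = perms[start : start + chunk]
            Ep = E[pk]  # c x n x p
            Yp = fitted_red[None] + Ep
            ss_t = np.einsum("jn,cnp->cjp", Qnew.T, Yp)
            ss_t = (ss_t**2).sum(axis=(1, 2))
            # residual SS of the complete model on the permuted response
            proj = np.einsum("nj,cnp->cjp", Qfull, Yp)
            rss = (Yp**2).sum(axis=(1, 2)) - (proj**2).sum(axis=(1, 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                f_perm[start : start + chunk] = (ss_t / df_t) / (rss / df_res)
        f_perm = np.nan_to_num(f_perm, nan=0.0, posinf=np.inf)
        f_obs = f_perm[0]
        ss_obs = float((((Qnew.T @ Y)) ** 2).sum())
        p = float(np.mean(f_perm >= f_obs * (1 - 1e-12)))
        z = effect_size(f_obs, f_perm, transform="log")
        rows.append(
            {
                "term": term,
                "df": df_t,
                "SS": ss_obs,
                "MS": ss_obs / df_t,
                "Rsq": ss_obs / ss_total if ss_total > 0 else 0.0,
                "F": f_obs,
                "Z": z,
                "p": p,
            }
        )
        dists[term] = f_perm

    if rows:
        table = pd.DataFrame(rows).set_index("term")
    else:  # intercept-only null model
        table = pd.DataFrame(
            columns=["df", "SS", "MS", "Rsq", "F", "Z", "p"],
            index=pd.Index([], name="term"),
        )
    # partition check (relative 1e-8): sum of term SS + residual SS = total SS
    gap = abs(table["SS"].sum() + ss_res - ss_total)
    if ss_total > 0 and gap > 1e-6 * ss_total:
        warnings.warn(
            f"SS partition mismatch (relative {gap / ss_total:.2e})", RuntimeWarning
        )
    return RRPPModelFit(
        table=table,
        ss_residual=ss_res,
        ss_total=ss_total,
        df_residual=df_res,
        n_permutations=iter,
        seed=seed,
        permutation_distributions=dists,
        spec=spec,
        Y=Y,
        encoder=enc,
    )


def anova_table(fit: RRPPModelFit) -> pd.DataFrame:
    """ANOVA table with a residual and total row completing the partition."""
    t = fit.table.copy()
    resid = pd.DataFrame(
        {
            "df": [fit.df_residual],
            "SS": [fit.ss_residual],
            "MS": [fit.ss_residual / fit.df_residual if fit.df_residual else np.nan],
            "Rsq": [fit.ss_residual / fit.ss_total if fit.ss_total else np.nan],
            "F": [np.nan],
            "Z": [np.nan],
            "p": [np.nan],
        },
        index=["Residuals"],
    )
    total = pd.DataFrame(
        {
            "df": [int(t["df"].sum()) + fit.df_residual],
            "SS": [fit.ss_total],
            "MS": [np.nan],
            "Rsq": [1.0],
            "F": [np.nan],
            "Z": [np.nan],
            "p": [np.nan],
        },
        index=["Total"],
    )
    return pd.concat([t, resid, total])


def effect_size(observed: float, permuted: np.ndarray, transform: str = "identity") -> float:
    """Standard deviate of the observed statistic in its permutation distribution.

    ``transform="log"`` for F-type statistics (values floored at a small
    positive epsilon before the log), identity for distances.
    """
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValidationError("empty permutation distribution")
    if transform == "log":
        g = lambda v: np.log(np.maximum(v, 1e-12))
    elif transform == "identity":
        g = lambda v: v
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    gp = g(permuted)
    sd = float(np.std(gp, ddof=1)) if permuted.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("degenerate permutation distribution (sd=0); Z set to 0", RuntimeWarning)
        return 0.0
    return float((g(np.asarray(observed)) - gp.mean()) / sd)


@dataclass
class PairwiseResult:
    """Post-hoc pairwise LS-mean distances under permutation."""

    table: pd.DataFrame  # index "a:b"; columns d, UCL95, Z, p
    ls_means: pd.DataFrame  # group level x p matrix of LS means
    group: str
    n_permutations: int
    seed: int
    permuted_d: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _model_factors(enc: _Encoder) -> set[str]:
    used: set[str] = set()
    for term in enc.spec.terms:
        for part in term.split(":"):
            if part in enc.levels:
                used.add(part)
    return used


def _ls_mean_design(enc: _Encoder, group: str, data: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """One prediction row per group level.

    Covariates sit at their grand means.  Factors fully crossed with the
    group (every level co-occurs with more than one group level, e.g. sex)
    are balanced explicitly; factors nested in the group (e.g. islands
    within species) stay at the group's own observed rows, so LS means
    never extrapolate to factor combinations that cannot occur.
    """
    if group not in enc.levels:
        raise ValidationError(f"{group!r} is not a factor in the model data")
    g_levels = enc.levels[group]
    gvals = data[group].astype(str)
    counts = gvals.value_counts()
    for lev in g_levels:
        if counts.get(lev, 0) == 0:
            raise ValidationError(f"group level {lev!r} has no specimens")
    factors = [f for f in _model_factors(enc) if f != group and f in data.columns]
    crossed = [
        f
        for f in factors
        if all(
            data.loc[data[f].astype(str) == lev, group].astype(str).nunique() > 1
            for lev in data[f].astype(str).unique()
        )
    ]
    cov_means = {c: float(data[c].mean()) for c in enc.numeric if c in data.columns}
    rows = []
    for lev in g_levels:
        sub = data.loc[gvals == lev].copy()
        for c, m in cov_means.items():
            sub[c] = m
        blocks = []
        combos = list(itertools.product(*[enc.levels[f] for f in crossed])) or [()]
        for combo in combos:
            block = sub.copy()
            for f, flev in zip(crossed, combo):
                block[f] = flev
            blocks.append(enc.encode(block).mean(axis=0))
        rows.append(np.mean(blocks, axis=0))
    return g_levels, np.vstack(rows)


def pairwise_groups(
    fit_full: RRPPModelFit,
    fit_null: RRPPModelFit,
    group: str,
    iter: int | None = None,
    seed: int | None = None,
) -> PairwiseResult:
    """Pairwise distances between group LS means with RRPP significance.

    LS means come from the full-model fit at mean covariate values; the
    permutation scheme resamples *null-model* residuals (the null model
    excludes the group terms, so covariate effects are held out of the
    test).  For shape data the LS-mean distance is the Procrustes distance
    between covariate-adjusted group mean shapes.
    """
    if fit_full.Y.shape != fit_null.Y.shape or not np.allclose(fit_full.Y, fit_null.Y):
        raise ValidationError("full and null fits must share the same response")
    extra = set(fit_null.spec.terms) - set(fit_full.spec.terms)
    if extra:
        raise ValidationError(f"null model is not nested in the full model: extra {extra}")
    iter = fit_full.n_permutations if iter is None else iter
    seed = fit_full.seed if seed is None else seed
    Y = fit_full.Y
    n = Y.shape[0]
    enc_full = fit_full.encoder
    enc_null = fit_null.encoder
    data = fit_full.spec.data

    levels, Xpred = _ls_mean_design(enc_full, group, data)
    pinvX = np.linalg.pinv(enc_full.X)
    project = Xpred @ pinvX  # G x n: maps response rows to LS means

    Qnull = enc_null.Q
    fitted_null = Qnull @ (Qnull.T @ Y)
    E = Y - fitted_null

    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(rng, n, iter)

    G = len(levels)
    pairs = [(i, j) for i in range(G) for j in range(i + 1, G)]
    d_perm = np.empty((iter + 1, len(pairs)))
    chunk = max(1, int(2e7 / max(E.size, 1)))
    for start in range(0, iter + 1, chunk):
        pk = perms[start : start + chunk]
        Yp = fitted_null[None] + E[pk]  # c x n x p
        mu = np.einsum("gn,cnp->cgp", project, Yp)
        for col, (i, j) in enumerate(pairs):
            d_perm[start : start + chunk, col] = np.linalg.norm(
                mu[:, i] - mu[:, j], axis=1
            )
    mu_obs = project @ Y

    rows = []
    dists: dict[str, np.ndarray] = {}
    for col, (i, j) in enumerate(pairs):
        name = f"{levels[i]}:{levels[j]}"
        dvec = d_perm[:, col]
        d_obs = dvec[0]
        p = float(np.mean(dvec >= d_obs * (1 - 1e-12)))
        rows.append(
            {
                "pair": name,
                "d": float(d_obs),
                "UCL95": float(np.percentile(dvec, 95)),
                "Z": effect_size(d_obs, dvec, transform="identity"),
                "p": p,
            }
        )
        dists[name] = dvec
    table = pd.DataFrame(rows).set_index("pair")
    ls_means = pd.DataFrame(mu_obs, index=levels)
    return PairwiseResult(
        table=table,
        ls_means=ls_means,
        group=group,
        n_permutations=iter,
        seed=seed,
        permuted_d=dists,
    )


def format_p(p: float, iter: int) -> str:
    """Report-style p formatting: '< 0.001'-style below 10/(iter+1)."""
    floor = 10.0 / (iter + 1)
    return f"< {floor:g}" if p < floor else f"{p:.4g}"
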