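"""Phenotype summaries: REML variance components, BLUPs, LSmeans, correlations.

The mixed model is deliberately small — random accession, optional random
environment, optional random block (subpopulation) — fitted by direct
maximization of the profiled restricted likelihood.  Balanced one-way
designs take the exact ANOVA-REML closed form, which the numerical
optimum coincides with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "TraitMatrix",
    "fit_two_level_reml",
    "lsmeans",
    "log_transform",
    "pearson_with_t",
    "correlation_matrix",
    "blup_matrix",
]


@dataclass
class VarianceComponents:
    sigma2_accession: float
    sigma2_env: float
    sigma2_resid: float
    sigma2_block: float = 0.0
    method: str = "REML"

    def __post_init__(self) -> None:
        for name in ("sigma2_accession", "sigma2_env", "sigma2_resid", "sigma2_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TraitMatrix:
    """Accession-by-trait table of BLUPs or LSmeans with per-trait transform tags."""

    values: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)
    kind: str = "blup"  # blup | lsmean

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated trait names")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated accession rows")
        for t in self.values.columns:
            self.transforms.setdefault(t, "identity")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)


def _design(labels: Sequence) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(labels))
    lookup = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [lookup[v] for v in labels]] = 1.0
    return Z, levels


def _profiled_reml(y: np.ndarray, X: np.ndarray, ZZts: list[np.ndarray], log_gammas: np.ndarray):
    """Restricted log-likelihood with the residual variance profiled out.

    ``ZZts`` are precomputed Z Z' blocks; variance ratios are
    gamma_k = sigma2_k / sigma2_resid.
    """
    n, p = X.shape
    V0 = np.eye(n)
    for ZZt, lg in zip(ZZts, log_gammas):
        V0 += np.exp(lg) * ZZt
    L = np.linalg.cholesky(V0)
    logdet_V0 = 2.0 * np.log(np.diag(L)).sum()
    Vi_y = np.linalg.solve(V0, y)
    Vi_X = np.linalg.solve(V0, X)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid_quad = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    sigma2 = max(resid_quad / (n - p), 1e-300)
    ll = -0.5 * ((n - p) * np.log(sigma2) + logdet_V0 + logdet_XtViX + (n - p))
    return ll, sigma2, beta, V0


def fit_two_level_reml(
    records: pd.DataFrame,
    trait: str,
    include_env: bool = True,
    blocks: Mapping[str, str] | None = None,
) -> tuple[VarianceComponents, pd.Series]:
    """REML fit of ``y = mu + accession + [env] + [block] + resid`` (all random
    but the intercept), returning variance components and per-accession BLUPs.

    Balanced one-way data (single environment, no blocks, equal replicate
    counts) are solved in closed form: ``sigma2_e = MSW``,
    ``sigma2_a = max(0, (MSB - MSW)/r)`` and
    ``BLUP_i = sigma2_a/(sigma2_a + sigma2_e/r) * (ybar_i - ybar)``.
    """
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    y = sub["value"].to_numpy(dtype=float)
    acc = sub["accession"].tolist()
    env = sub["environment"].tolist()
    acc_levels = list(dict.fromkeys(acc))
    if len(acc_levels) < 2:
        raise ValueError("need at least 2 accessions")

    if float(np.var(y)) == 0.0:
        warnings.warn(f"trait {trait!r} has zero variance; BLUPs set to 0")
        vc = VarianceComponents(0.0, 0.0, 0.0)
        return vc, pd.Series(0.0, index=acc_levels, name=trait)

    env_levels = list(dict.fromkeys(env))
    use_env = include_env and len(env_levels) > 1
    use_block = blocks is not None

    counts = pd.Series(acc).value_counts()
    balanced_oneway = (
        not use_env and not use_block and counts.nunique() == 1 and counts.iloc[0] >= 1
    )
    if balanced_oneway:
        return _closed_form_oneway(y, acc, acc_levels, trait)

    Za, _ = _design(acc)
    Zs = [Za]
    names = ["accession"]
    if use_env:
        Ze, _ = _design(env)
        Zs.append(Ze)
        names.append("env")
    if use_block:
        blk = [blocks[a] for a in acc]
        Zb, _ = _design(blk)
        Zs.append(Zb)
        names.append("block")
    X = np.ones((len(y), 1))
    ZZts = [Z @ Z.T for Z in Zs]

    def negll(lg: np.ndarray) -> float:
        lg = np.clip(lg, -30.0, 30.0)
        try:
            ll, *_ = _profiled_reml(y, X, ZZts, lg)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    x0 = np.zeros(len(Zs))
    res = optimize.minimize(
        negll, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
    )
    lg = np.clip(res.x, -30.0, 30.0)
    ll, sigma2_e, beta, V0 = _profiled_reml(y, X, ZZts, lg)
    gammas = dict(zip(names, np.exp(lg)))
    sigma2_a = gammas["accession"] * sigma2_e
    sigma2_env = gammas.get("env", 0.0) * sigma2_e
    sigma2_blk = gammas.get("block", 0.0) * sigma2_e

    resid = y - X @ beta
    u = gammas["accession"] * (Za.T @ np.linalg.solve(V0, resid))
    blups = pd.Series(u, index=acc_levels, name=trait)
    vc = VarianceComponents(sigma2_a, sigma2_env, sigma2_e, sigma2_blk)
    return vc, blups


def _closed_form_oneway(y, acc, acc_levels, trait):
    frame = pd.DataFrame({"acc": acc, "y": y})
    grp = frame.groupby("acc", sort=False)["y"]
    means = grp.mean().reindex(acc_levels)
    r = int(grp.size().iloc[0])
    a = len(acc_levels)
    grand = float(np.mean(y))
    ssw = float(((frame["y"] - frame["acc"].map(means)) ** 2).sum())
    ssb = float(r * ((means - grand) ** 2).sum())
    msw = ssw / (a * (r - 1)) if r > 1 else 0.0
    msb = ssb / (a - 1)
    sigma2_e = msw
    sigma2_a = max(0.0, (msb - msw) / r)
    denom = sigma2_a + sigma2_e / r
    shrink = sigma2_a / denom if denom > 0 else 0.0
    blups = shrink * (means - grand)
    blups.name = trait
    return VarianceComponents(sigma2_a, 0.0, sigma2_e), blups


def lsmeans(records: pd.DataFrame, trait: str) -> pd.Series:
    """Least-squares (adjusted) means from a fixed accession + environment model.

    Balanced data reduce to plain accession means.  When an accession is
    missing from an environment a warning is issued and the LSmean averages
    the model prediction over all environment levels (minimum-norm solve).
    """
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    acc = sub["accession"].tolist()
    env = sub["environment"].tolist()
    y = sub["value"].to_numpy(dtype=float)
    acc_levels = list(dict.fromkeys(acc))
    env_levels = list(dict.fromkeys(env))

    cells = sub.groupby(["accession", "environment"]).size()
    if len(env_levels) > 1:
        missing = [
            (a, e)
            for a in acc_levels
            for e in env_levels
            if (a, e) not in cells.index
        ]
        if missing:
            warnings.warn(
                f"accession(s) absent from some environments: {missing[:5]}...; "
                "LSmeans use the least-squares solution over available cells"
            )

    Za, _ = _design(acc)
    if len(env_levels) > 1:
        Ze, _ = _design(env)
        X = np.hstack([Za, Ze[:, 1:]])  # env baseline = first level
    else:
        X = Za
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha = coef[: len(acc_levels)]
    env_eff = np.concatenate([[0.0], coef[len(acc_levels):]])
    ls = alpha + env_eff.mean()
    return pd.Series(ls, index=acc_levels, name=trait)


def log_transform(values, trait: str | None = None) -> np.ndarray:
    """Natural-log transform; raises naming the first offending record."""
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0))[0]
    if bad.size:
        label = f" for trait {trait!r}" if trait else ""
        raise ValueError(
            f"nonpositive value at record {int(bad[0])}{label}: {arr[bad[0]]!r}"
        )
    return np.log(arr)


def pearson_with_t(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p-value on n - 2 df.

    Zero-variance input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance input: correlation undefined")
        return float("nan"), float("nan")
    r = float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1.0, 1.0))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlation_matrix(tm: TraitMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and p matrices over complete rows per pair."""
    traits = tm.traits
    r_mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p_mat = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pair = tm.values[[a, b]].dropna()
            r, p = pearson_with_t(pair[a], pair[b])
            r_mat.loc[a, b] = r_mat.loc[b, a] = r
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return r_mat, p_mat


def blup_matrix(
    records: pd.DataFrame,
    traits: Sequence[str] | None = None,
    log_traits: Sequence[str] = (),
    include_env: bool = True,
    blocks: Mapping[str, str] | None = None,
) -> TraitMatrix:
    """Per-trait BLUPs assembled into a TraitMatrix.

    Traits in ``log_traits`` are log-transformed at the record level before
    fitting (and tagged ``log``).
    """
    if traits is None:
        traits = list(dict.fromkeys(records["trait"]))
    cols = {}
    transforms = {}
    for t in traits:
        sub = records[records["trait"] == t].copy()
        if t in log_traits:
            sub["value"] = log_transform(sub["value"].to_numpy(), t)
            transforms[t] = "log"
        else:
            transforms[t] = "identity"
        _, blups = fit_two_level_reml(sub, t, include_env=include_env, blocks=blocks)
        cols[t] = blups
    values = pd.DataFrame(cols)
    return TraitMatrix(values=values, transforms=transforms, kind="blup")
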